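"""Synthetic cellular-barcoding data.

Generates composite barcode libraries (left/right 18-mer modules joined by a
4 bp linker), clonal population trajectories through the stages of a
regression/recurrence experiment (in vitro expansion, primary tumor, early and
late residual disease, recurrence), and error-containing single-end 40 bp
FASTQ reads — so the whole downstream pipeline can be exercised without any
external sequencing data.

The population model is intentionally simple: a clone is a set of cells
carrying one barcode; stage transitions are (1) a cell-sampling bottleneck
(multinomial approximation to sampling without replacement) followed by
(2) stochastic exponential growth in which clone *i* multiplies by
``exp((ln 2 + s_i) * g)`` over ``g`` generations, with per-clone selection
coefficients ``s_i``. Supplying the same ``s_i`` vector to independently
evolved replicates reproduces the hallmark of heritable clone fitness:
the same clones dominate every replicate tumor.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BarcodeLibrary",
    "ClonePopulation",
    "StageSpec",
    "ReadSimConfig",
    "RouteParams",
    "Scenario",
    "make_library",
    "initialize_population",
    "evolve_stage",
    "apply_recurrence_route",
    "generate_reads",
    "measure_population",
    "simulate_cohort",
    "default_scenario",
    "scaled_scenario",
]

DEFAULT_LINKER = "ACGA"
MODULE_LENGTH = 18
LINKER_LENGTH = 4
READ_LENGTH = 2 * MODULE_LENGTH + LINKER_LENGTH

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Steepness of the clone-size skew: log-normal sigma = _SKEW_SCALE * (1 - evenness).
# At evenness 0.97 the most abundant of ~17,000 clones holds ~0.5-1% of cells,
# matching a barcoded pool expanded in vitro without strong selection.
_SKEW_SCALE = 40.0


def _validate_module(seq: str, what: str) -> None:
    if len(seq) != MODULE_LENGTH or set(seq) - set("ACGT"):
        raise ValueError(f"{what} must be {MODULE_LENGTH} bp over ACGT, got {seq!r}")


@dataclass(frozen=True)
class BarcodeLibrary:
    """Reference of valid clone tags.

    A barcode identity is the pair (left module, right module), written
    ``"<left index>:<right index>"`` with 1-based indices.
    """

    left_modules: tuple[str, ...]
    right_modules: tuple[str, ...]
    linker: str = DEFAULT_LINKER

    def __post_init__(self) -> None:
        for seq in self.left_modules:
            _validate_module(seq, "left module")
        for seq in self.right_modules:
            _validate_module(seq, "right module")
        if len(set(self.left_modules)) != len(self.left_modules):
            raise ValueError("left modules are not unique")
        if len(set(self.right_modules)) != len(self.right_modules):
            raise ValueError("right modules are not unique")
        if len(self.linker) != LINKER_LENGTH or set(self.linker) - set("ACGT"):
            raise ValueError(f"linker must be {LINKER_LENGTH} bp over ACGT")

    @property
    def n_left(self) -> int:
        return len(self.left_modules)

    @property
    def n_right(self) -> int:
        return len(self.right_modules)

    @property
    def n_barcodes(self) -> int:
        """Size of the composite barcode space."""
        return self.n_left * self.n_right

    def barcode_id(self, left_index: int, right_index: int) -> str:
        """1-based composite identifier, e.g. ``"5:9"``."""
        if not (1 <= left_index <= self.n_left and 1 <= right_index <= self.n_right):
            raise IndexError(f"barcode ({left_index}:{right_index}) outside library")
        return f"{left_index}:{right_index}"

    def barcode_sequence(self, barcode_id: str) -> str:
        """Full 40 bp sequence left + linker + right for a barcode id."""
        li, ri = parse_barcode_id(barcode_id)
        return self.left_modules[li - 1] + self.linker + self.right_modules[ri - 1]


def parse_barcode_id(barcode_id: str) -> tuple[int, int]:
    """Split ``"i:j"`` into 1-based integer module indices."""
    try:
        left, right = barcode_id.split(":")
        return int(left), int(right)
    except ValueError as exc:
        raise ValueError(f"malformed barcode id {barcode_id!r}") from exc


def _min_hamming_to_set(candidate: np.ndarray, accepted: np.ndarray) -> int:
    if accepted.shape[0] == 0:
        return MODULE_LENGTH + 1
    return int((accepted != candidate).sum(axis=1).min())


def _sample_modules(
    n: int, min_dist: int, rng: np.random.Generator, max_attempts: int
) -> list[str]:
    accepted = np.empty((n, MODULE_LENGTH), dtype=np.uint8)
    count = 0
    attempts = 0
    while count < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not sample {n} modules at pairwise Hamming distance "
                f">= {min_dist} within {max_attempts} attempts"
            )
        attempts += 1
        cand = _BASES[rng.integers(0, 4, size=MODULE_LENGTH)]
        if _min_hamming_to_set(cand, accepted[:count]) >= min_dist:
            accepted[count] = cand
            count += 1
    return [bytes(row).decode() for row in accepted]


def make_library(
    n_left: int,
    n_right: int,
    min_pairwise_distance: int = 5,
    seed: int = 0,
    linker: str = DEFAULT_LINKER,
) -> BarcodeLibrary:
    """Sample a composite barcode library by rejection.

    Within each side, modules are pairwise at Hamming distance >=
    ``min_pairwise_distance``; at distance >= 5 the standard two-mismatch
    mapping can never be ambiguous for reads with <= 2 errors per half.
    Deterministic given ``seed``.
    """
    if n_left < 1 or n_right < 1:
        raise ValueError("n_left and n_right must be >= 1")
    if min_pairwise_distance < 0 or min_pairwise_distance > MODULE_LENGTH:
        raise ValueError("min_pairwise_distance out of range for 18-mers")
    rng = np.random.default_rng(seed)
    max_attempts_l = 200 * n_left + 1000
    max_attempts_r = 200 * n_right + 1000
    left = _sample_modules(n_left, min_pairwise_distance, rng, max_attempts_l)
    right = _sample_modules(n_right, min_pairwise_distance, rng, max_attempts_r)
    return BarcodeLibrary(tuple(left), tuple(right), linker)


@dataclass
class ClonePopulation:
    """Simulator state: per-clone cell counts plus recorded stage fitness.

    ``fitness`` maps a stage name to the per-clone selection coefficients
    used when that stage was evolved. Clones at zero cells are extinct and
    never reappear.
    """

    clone_ids: np.ndarray  # array of "i:j" strings, unique
    cells: np.ndarray  # int64, >= 0, parallel to clone_ids
    fitness: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.clone_ids = np.asarray(self.clone_ids, dtype=object)
        self.cells = np.asarray(self.cells, dtype=np.int64)
        if self.clone_ids.shape != self.cells.shape:
            raise ValueError("clone_ids and cells must be parallel arrays")
        if (self.cells < 0).any():
            raise ValueError("cell counts must be non-negative")
        if len(set(self.clone_ids)) != len(self.clone_ids):
            raise ValueError("clone_ids must be unique")

    @property
    def n_clones(self) -> int:
        return len(self.clone_ids)

    @property
    def total_cells(self) -> int:
        return int(self.cells.sum())

    @property
    def n_surviving(self) -> int:
        return int((self.cells > 0).sum())

    def frequencies(self) -> np.ndarray:
        """Relative abundance of every clone (zeros included)."""
        total = self.total_cells
        if total == 0:
            raise ValueError("population is extinct")
        return self.cells / total

    def abundance(self) -> pd.Series:
        """Relative abundances of surviving clones, indexed by barcode id."""
        alive = self.cells > 0
        freqs = self.cells[alive] / self.total_cells
        return pd.Series(freqs, index=self.clone_ids[alive], name="frequency")


@dataclass(frozen=True)
class StageSpec:
    """One stage transition: a bottleneck then selective growth.

    ``fitness_correlation`` is the correlation of this stage's per-clone
    fitness ranking with the previous stage's (used by
    :func:`simulate_cohort`): 1 means the same clones stay fit (e.g. the
    persistence advantage carried through residual disease), 0 means a fresh,
    independent selective pressure.
    """

    name: str
    bottleneck_size: int
    growth_generations: int
    fitness_scale: float = 0.0
    fitness_correlation: float = 0.0
    recurrence_route: str = "none"

    _NAMES = ("in_vitro_expansion", "primary", "residual_early", "residual_late", "recurrent")

    def __post_init__(self) -> None:
        if self.name not in self._NAMES:
            raise ValueError(f"unknown stage name {self.name!r}; expected one of {self._NAMES}")
        if self.bottleneck_size < 1:
            raise ValueError("bottleneck_size must be >= 1")
        if self.growth_generations < 0:
            raise ValueError("growth_generations must be >= 0")
        if self.fitness_scale < 0:
            raise ValueError("fitness_scale must be >= 0")
        if not -1.0 <= self.fitness_correlation <= 1.0:
            raise ValueError("fitness_correlation must lie in [-1, 1]")
        if self.recurrence_route != "none" and self.name != "recurrent":
            raise ValueError("recurrence_route applies only to the recurrent stage")


@dataclass(frozen=True)
class ReadSimConfig:
    """Read-generation settings for 40 bp barcode amplicon reads."""

    n_reads: int
    substitution_rate: float = 0.005
    base_quality_mean: int = 37
    fraction_low_quality: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if not 0.0 <= self.substitution_rate <= 0.25:
            raise ValueError("substitution_rate must lie in [0, 0.25]")
        if not 0 <= self.base_quality_mean <= 41:
            raise ValueError("base_quality_mean must be representable in Phred+33")
        if not 0.0 <= self.fraction_low_quality <= 1.0:
            raise ValueError("fraction_low_quality must lie in [0, 1]")


def initialize_population(
    library: BarcodeLibrary,
    n_clones: int = 17_000,
    cells_per_clone: int = 5_000,
    evenness: float = 0.97,
    seed: int = 0,
) -> ClonePopulation:
    """Create the barcoded starting pool.

    ``n_clones`` distinct barcodes are drawn without replacement from the
    library's composite pair space. Clone sizes follow a log-normal skew
    controlled by ``evenness`` in (0, 1]: at 1 every clone has exactly
    ``cells_per_clone`` cells; just below 1 the pool is nearly even with the
    top clone under 1% of cells, as seen for barcoded pools expanded in
    culture. Total cells equal ``n_clones * cells_per_clone``.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if cells_per_clone < 1:
        raise ValueError("cells_per_clone must be >= 1")
    if not 0.0 < evenness <= 1.0:
        raise ValueError("evenness must lie in (0, 1]")
    if n_clones > library.n_barcodes:
        raise ValueError(
            f"n_clones={n_clones} exceeds the library's pair space of {library.n_barcodes}"
        )
    rng = np.random.default_rng(seed)
    flat = rng.choice(library.n_barcodes, size=n_clones, replace=False)
    left_idx = flat // library.n_right + 1
    right_idx = flat % library.n_right + 1
    ids = np.array([f"{li}:{ri}" for li, ri in zip(left_idx, right_idx)], dtype=object)
    total = n_clones * cells_per_clone
    if evenness == 1.0:
        cells = np.full(n_clones, cells_per_clone, dtype=np.int64)
    else:
        sigma = _SKEW_SCALE * (1.0 - evenness)
        # clone-size spread is bounded like the fitness spread: expansion in
        # culture cannot produce arbitrarily outsized clones
        z = np.clip(rng.normal(0.0, 1.0, size=n_clones), -_FITNESS_Z_CAP, _FITNESS_Z_CAP)
        weights = np.exp(sigma * z)
        cells = rng.multinomial(total, weights / weights.sum()).astype(np.int64)
    return ClonePopulation(ids, cells)


def evolve_stage(
    pop: ClonePopulation,
    stage: StageSpec,
    shared_fitness: np.ndarray | None = None,
    seed: int = 0,
) -> ClonePopulation:
    """Pass a population through one bottleneck + selective-growth stage.

    The bottleneck is a multinomial draw of ``stage.bottleneck_size`` cells
    from the current relative abundances (the cell-level sampling of a
    transplant or regression event); requesting the whole population is the
    identity. Growth then multiplies clone *i* by ``exp((ln2 + s_i) * g)`` in
    expectation, realized as a Poisson draw, with ``s_i`` taken from
    ``shared_fitness`` when given (so replicate tumors evolved from the same
    pool enrich the same clones) and otherwise drawn i.i.d.
    ``Normal(0, stage.fitness_scale)``.
    """
    if pop.n_clones == 0:
        raise ValueError("population is empty")
    total = pop.total_cells
    if stage.bottleneck_size > total:
        raise ValueError(
            f"bottleneck_size={stage.bottleneck_size} exceeds the {total} cells present; "
            "cells are sampled without replacement"
        )
    rng = np.random.default_rng(seed)
    if stage.bottleneck_size == total:
        sampled = pop.cells.copy()
    else:
        sampled = rng.multinomial(stage.bottleneck_size, pop.frequencies()).astype(np.int64)

    if shared_fitness is not None:
        s = np.asarray(shared_fitness, dtype=float)
        if s.shape != pop.cells.shape:
            raise ValueError("shared_fitness must cover every clone")
    else:
        s = rng.normal(0.0, stage.fitness_scale, size=pop.n_clones)

    g = stage.growth_generations
    if g == 0:
        grown = sampled
    else:
        mean = sampled * np.exp((np.log(2.0) + s) * g)
        grown = rng.poisson(mean).astype(np.int64)

    fitness = dict(pop.fitness)
    fitness[stage.name] = s
    return ClonePopulation(pop.clone_ids.copy(), grown, fitness)


@dataclass(frozen=True)
class RouteParams:
    """Parameters of the recurrence routes.

    ``dominant_fraction``: final share of cells held by the expanding clone in
    the clonal routes. ``fitness_noise``: s.d. of the i.i.d. log-growth noise
    of the polyclonal route (small values keep the recurrent profile close to
    the pre-regression one; the default keeps the Jensen-Shannon divergence
    well below ``similarity_threshold``). ``expansion_factor``: common
    regrowth multiplier of the polyclonal route.
    """

    dominant_fraction: float = 0.95
    similarity_threshold: float = 0.1
    fitness_noise: float = 0.05
    expansion_factor: float = 100.0


ROUTES = ("denovo_driver", "dominant_preexisting", "polyclonal")


def apply_recurrence_route(
    pop: ClonePopulation,
    route: str,
    params: RouteParams | None = None,
    seed: int = 0,
) -> ClonePopulation:
    """Regrow a residual population into a recurrent tumor by one of three routes.

    ``denovo_driver``: a uniformly chosen surviving clone acquires a driver
    (an abstract fitness jump) and expands to ``params.dominant_fraction`` of
    cells. ``dominant_preexisting``: the currently most abundant clone
    expands likewise. ``polyclonal``: every surviving clone regrows with small
    i.i.d. fitness noise, broadly preserving the residual/primary profile.
    """
    params = params or RouteParams()
    if route not in ROUTES:
        raise ValueError(f"unknown recurrence route {route!r}; expected one of {ROUTES}")
    alive = np.flatnonzero(pop.cells > 0)
    if alive.size == 0:
        raise ValueError("population is extinct; no clone can seed recurrence")
    rng = np.random.default_rng(seed)
    cells = pop.cells.copy()

    if route == "polyclonal":
        noise = rng.normal(0.0, params.fitness_noise, size=alive.size)
        grown = np.rint(cells[alive] * params.expansion_factor * np.exp(noise))
        cells[alive] = np.maximum(grown, 1).astype(np.int64)
        return ClonePopulation(pop.clone_ids.copy(), cells, dict(pop.fitness))

    if route == "denovo_driver":
        winner = int(rng.choice(alive))
    else:  # dominant_preexisting
        winner = int(alive[np.argmax(cells[alive])])

    f = params.dominant_fraction
    if not 0.0 < f <= 1.0:
        raise ValueError("dominant_fraction must lie in (0, 1]")
    if f == 1.0:
        total = cells.sum()
        cells[:] = 0
        cells[winner] = total
    else:
        others = cells.sum() - cells[winner]
        cells[winner] = int(np.ceil(f / (1.0 - f) * others)) if others else cells[winner]
    return ClonePopulation(pop.clone_ids.copy(), cells, dict(pop.fitness))


def _format_read_ids(n: int) -> np.ndarray:
    """Fixed-width read ids r00000000 ... as an (n, 9) uint8 matrix."""
    digits = np.arange(n, dtype=np.int64)
    out = np.empty((n, 9), dtype=np.uint8)
    out[:, 0] = ord("r")
    for col in range(8):
        power = 10 ** (7 - col)
        out[:, col + 1] = ord("0") + (digits // power) % 10
    return out


def generate_reads(
    pop: ClonePopulation,
    library: BarcodeLibrary,
    cfg: ReadSimConfig,
    fastq: str | _io.IOBase,
    truth: str | None = None,
) -> pd.DataFrame:
    """Write simulated 40 bp FASTQ reads and return the truth table.

    Each read's barcode is drawn multinomially from the clone relative
    abundances; its sequence is left module + linker + right module with
    i.i.d. substitution errors; per-base qualities scatter around
    ``base_quality_mean``, except for a ``fraction_low_quality`` subset of
    reads forced to mean Phred < 30 (these are meant to be removed by QC).
    Byte-identical output for identical seeds.

    Returns a DataFrame with columns ``read_id`` and ``barcode_id`` and, when
    ``truth`` is a path, writes it there as TSV.
    """
    n = cfg.n_reads
    if n > 0 and pop.total_cells == 0:
        raise ValueError("cannot generate reads from an extinct population")
    rng = np.random.default_rng(cfg.seed)

    if n == 0:
        counts = np.zeros(pop.n_clones, dtype=np.int64)
    else:
        counts = rng.multinomial(n, pop.frequencies())
    clone_of_read = np.repeat(np.arange(pop.n_clones), counts)

    left_idx = np.empty(pop.n_clones, dtype=np.int64)
    right_idx = np.empty(pop.n_clones, dtype=np.int64)
    for k, cid in enumerate(pop.clone_ids):
        li, ri = parse_barcode_id(cid)
        left_idx[k] = li - 1
        right_idx[k] = ri - 1

    left_mat = np.frombuffer("".join(library.left_modules).encode(), dtype=np.uint8).reshape(
        library.n_left, MODULE_LENGTH
    )
    right_mat = np.frombuffer("".join(library.right_modules).encode(), dtype=np.uint8).reshape(
        library.n_right, MODULE_LENGTH
    )
    linker = np.frombuffer(library.linker.encode(), dtype=np.uint8)

    seq = np.empty((n, READ_LENGTH), dtype=np.uint8)
    seq[:, :MODULE_LENGTH] = left_mat[left_idx[clone_of_read]]
    seq[:, MODULE_LENGTH : MODULE_LENGTH + LINKER_LENGTH] = linker
    seq[:, MODULE_LENGTH + LINKER_LENGTH :] = right_mat[right_idx[clone_of_read]]

    if cfg.substitution_rate > 0 and n > 0:
        err = rng.random((n, READ_LENGTH)) < cfg.substitution_rate
        k = int(err.sum())
        if k:
            base_to_idx = np.zeros(256, dtype=np.uint8)
            base_to_idx[_BASES] = np.arange(4)
            orig = base_to_idx[seq[err]]
            seq[err] = _BASES[(orig + rng.integers(1, 4, size=k)) % 4]

    # Per-read quality: a clipped-normal read mean plus +-1 per-base jitter.
    # Low-quality reads are centred at Phred 20 and capped at 28, so their
    # mean is always below the Q30 retention threshold.
    low = rng.random(n) < cfg.fraction_low_quality
    read_q = np.clip(np.rint(rng.normal(cfg.base_quality_mean, 2.0, size=n)), 2, 41)
    read_q[low] = np.clip(np.rint(rng.normal(20.0, 2.0, size=int(low.sum()))), 2, 28)
    qual = read_q[:, None] + rng.integers(-1, 2, size=(n, READ_LENGTH))
    qual = np.clip(qual, 2, 41).astype(np.uint8) + 33

    ids = _format_read_ids(n)
    # record layout: @<id>\n<seq>\n+\n<qual>\n  (fixed width -> one buffer)
    rec_len = 1 + 9 + 1 + READ_LENGTH + 1 + 2 + READ_LENGTH + 1
    rec = np.empty((n, rec_len), dtype=np.uint8)
    rec[:, 0] = ord("@")
    rec[:, 1:10] = ids
    rec[:, 10] = ord("\n")
    rec[:, 11:51] = seq
    rec[:, 51] = ord("\n")
    rec[:, 52] = ord("+")
    rec[:, 53] = ord("\n")
    rec[:, 54:94] = qual
    rec[:, 94] = ord("\n")

    payload = rec.tobytes()
    if isinstance(fastq, (str, bytes)):
        with open(fastq, "wb") as fh:
            fh.write(payload)
    else:
        buf = fastq
        if hasattr(buf, "buffer"):
            buf.buffer.write(payload)  # text handle wrapping a binary one
        else:
            try:
                buf.write(payload)
            except TypeError:
                buf.write(payload.decode())

    read_ids = ids.tobytes().decode()
    read_ids = [read_ids[i * 9 : (i + 1) * 9] for i in range(n)]
    truth_df = pd.DataFrame(
        {"read_id": read_ids, "barcode_id": pop.clone_ids[clone_of_read]}
    )
    if truth is not None:
        truth_df.to_csv(truth, sep="\t", index=False)
    return truth_df


def measure_population(
    pop: ClonePopulation, n_cells: int = 97_000, seed: int = 0
) -> pd.Series:
    """Sample ``n_cells`` cells from a population, as barcode sequencing does.

    Returns detected barcode counts (cells with each barcode among those
    sampled; zero-count clones dropped), the in-silico analogue of the
    count table a sequencing run yields for one sample.
    """
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_cells, pop.frequencies())
    detected = counts > 0
    return pd.Series(
        counts[detected].astype(np.int64), index=pop.clone_ids[detected], name="count"
    )


@dataclass(frozen=True)
class Scenario:
    """A full experiment: pool construction plus the ordered stage cascade.

    Defaults reproduce the study conditions the pipeline is designed around:
    a ~17,000-clone starting pool of 85 million cells with top clone < 1%,
    an injection/engraftment bottleneck with strong in vivo selection giving
    primary tumors with a few thousand detected clones and a top clone near
    8% of reads, then regression and residual-disease attrition driving the
    clones-at-50%-of-reads down to the tens and then single digits.
    """

    n_left: int = 150
    n_right: int = 150
    min_pairwise_distance: int = 5
    n_clones: int = 17_000
    cells_per_clone: int = 5_000
    evenness: float = 0.97
    stages: tuple[StageSpec, ...] = (
        StageSpec("primary", bottleneck_size=1_000_000, growth_generations=10,
                  fitness_scale=0.27),
        StageSpec("residual_early", bottleneck_size=20_000, growth_generations=5,
                  fitness_scale=0.22, fitness_correlation=0.5),
        StageSpec("residual_late", bottleneck_size=5_000, growth_generations=4,
                  fitness_scale=0.20, fitness_correlation=1.0),
    )
    recurrence_route: str = "polyclonal"


# Truncation of per-clone fitness scores (standard deviations): growth-rate
# advantages saturate rather than growing without bound.
_FITNESS_Z_CAP = 3.7


def default_scenario() -> Scenario:
    return Scenario()


def scaled_scenario(
    n_left: int = 150,
    n_right: int = 150,
    n_clones: int = 17_000,
    cells_per_clone: int = 5_000,
    evenness: float = 0.97,
    min_pairwise_distance: int = 5,
) -> Scenario:
    """A scenario with stage bottlenecks scaled to the pool size.

    Keeps the default scenario's bottleneck ratios (pool : primary engraftment
    : early residual : late residual = 85e6 : 1e6 : 2e4 : 5e3) so that small,
    fast test scenarios preserve the shape of the full-scale trajectory. With
    the default arguments this is exactly :func:`default_scenario`.
    """
    pool = n_clones * cells_per_clone
    primary_b = max(10, round(pool / 85))
    early_b = max(5, round(primary_b / 50))
    late_b = max(2, round(early_b / 4))
    return Scenario(
        n_left=n_left,
        n_right=n_right,
        min_pairwise_distance=min_pairwise_distance,
        n_clones=n_clones,
        cells_per_clone=cells_per_clone,
        evenness=evenness,
        stages=(
            StageSpec("primary", primary_b, 10, fitness_scale=0.27),
            StageSpec("residual_early", early_b, 5, fitness_scale=0.22,
                      fitness_correlation=0.5),
            StageSpec("residual_late", late_b, 4, fitness_scale=0.20,
                      fitness_correlation=1.0),
        ),
    )


def simulate_cohort(
    scenario: Scenario | None = None,
    n_replicates: int = 6,
    seed: int = 0,
    include_recurrent: bool = False,
) -> dict:
    """Run one scenario: shared per-stage fitness, replicate tumors per stage.

    Per-clone fitness for each stage is drawn once and shared by all
    replicates (clone fitness is heritable), while bottleneck and growth
    randomness is replicate-specific. Returns a dict with the library, the
    starting ``pool``, and per-stage lists of replicate ``ClonePopulation``s
    under ``stages[<name>]``.
    """
    scenario = scenario or default_scenario()
    root = np.random.default_rng(seed)

    def sub() -> int:
        return int(root.integers(0, 2**31 - 1))

    library = make_library(
        scenario.n_left, scenario.n_right, scenario.min_pairwise_distance, seed=sub()
    )
    pool = initialize_population(
        library, scenario.n_clones, scenario.cells_per_clone, scenario.evenness, seed=sub()
    )
    # Per-clone fitness is heritable: drawn once per stage and shared by all
    # replicates, with optional correlation to the previous stage's ranking.
    # Scores are standard-normal, truncated at +-4 sd: fitness advantages
    # saturate, so no pool carries a freak jackpot clone far beyond the
    # distribution's natural range — mirroring the graded, reproducible
    # spectrum of tumorigenic potential seen across real replicate tumors.
    shared: dict[str, np.ndarray] = {}
    prev_z: np.ndarray | None = None
    for st in scenario.stages:
        fresh = np.clip(
            np.random.default_rng(sub()).normal(0.0, 1.0, pool.n_clones),
            -_FITNESS_Z_CAP, _FITNESS_Z_CAP,
        )
        rho = st.fitness_correlation
        if prev_z is not None and rho != 0.0:
            z = rho * prev_z + np.sqrt(1.0 - rho * rho) * fresh
        else:
            z = fresh
        shared[st.name] = st.fitness_scale * z
        prev_z = z
    stages: dict[str, list[ClonePopulation]] = {}
    previous = [pool] * n_replicates
    for st in scenario.stages:
        current = [
            evolve_stage(prev, st, shared_fitness=shared[st.name], seed=sub())
            for prev in previous
        ]
        stages[st.name] = current
        previous = current
    if include_recurrent:
        stages["recurrent"] = [
            apply_recurrence_route(prev, scenario.recurrence_route, seed=sub())
            for prev in previous
        ]
    return {"library": library, "pool": pool, "stages": stages, "scenario": scenario}
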