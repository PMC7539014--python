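"""Barcode deconvolution: 40 bp reads -> per-sample clone count table.

A read is kept when its mean Phred quality is >= 30 and its length is exactly
40 bp; it is then split into an 18 bp left half, a 4 bp central linker
(removed), and an 18 bp right half. Each half is mapped to its side of the
barcode library allowing up to two mismatches; a read is assigned the
composite barcode ``"Li:Rj"`` only when both halves map uniquely. Ambiguous
or unmapped halves discard the read, with per-reason tallies kept so that
assigned + discarded always equals the input read count.

Mapping is exact, not heuristic: each 18-mer is partitioned into three 6-mer
seeds, and with at most two mismatches at least one seed matches exactly
(pigeonhole), so a seed-index lookup followed by full Hamming verification
finds every module within distance 2 — identical to an exhaustive scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simdata import BarcodeLibrary, LINKER_LENGTH, MODULE_LENGTH, READ_LENGTH

__all__ = [
    "ReadRecord",
    "HalfMatch",
    "CountTable",
    "mean_phred",
    "qc_filter",
    "split_read",
    "map_half",
    "assign_barcode",
    "assign_reads",
    "build_count_table",
    "HalfIndex",
]

PHRED_OFFSET = 33
SEED_LENGTH = 6
N_SEEDS = MODULE_LENGTH // SEED_LENGTH

DISCARD_REASONS = (
    "low_quality",
    "wrong_length",
    "left_unmapped",
    "right_unmapped",
    "both_unmapped",
    "ambiguous",
)

UNMAPPED = -1
AMBIGUOUS = -2


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sequence: str
    qualities: str  # Phred+33 encoded

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )


@dataclass(frozen=True)
class HalfMatch:
    """Mapping result for one read half."""

    side: str  # "L" or "R"
    module_index: int | None  # 1-based, set iff uniquely mapped
    mismatches: int | None
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.side not in ("L", "R"):
            raise ValueError("side must be 'L' or 'R'")
        if (self.module_index is None) != (self.mismatches is None):
            raise ValueError("module_index and mismatches must be set together")

    @property
    def mapped(self) -> bool:
        return self.module_index is not None


def mean_phred(qualities: str, offset: int = PHRED_OFFSET) -> float:
    """Arithmetic mean of the Phred scores encoded in a quality string."""
    if not qualities:
        raise ValueError("empty quality string")
    arr = np.frombuffer(qualities.encode("ascii"), dtype=np.uint8)
    below = np.flatnonzero(arr < offset)
    if below.size:
        pos = int(below[0])
        raise ValueError(
            f"quality character {qualities[pos]!r} at position {pos + 1} is below "
            f"the encoding offset {offset}"
        )
    return float(arr.mean()) - offset


def qc_filter(
    read: ReadRecord,
    min_mean_phred: float = 30.0,
    required_length: int = READ_LENGTH,
) -> tuple[bool, str | None]:
    """Quality gate: mean Phred >= threshold, then exact length.

    Returns ``(True, None)`` on pass, else ``(False, reason)`` with reason
    ``"low_quality"`` or ``"wrong_length"``.
    """
    if mean_phred(read.qualities) < min_mean_phred:
        return False, "low_quality"
    if len(read.sequence) != required_length:
        return False, "wrong_length"
    return True, None


def split_read(sequence: str) -> tuple[str, str, str]:
    """Split a 40-mer into (left 18-mer, right 18-mer, observed linker)."""
    if len(sequence) != READ_LENGTH:
        raise ValueError(f"expected a {READ_LENGTH} bp sequence, got {len(sequence)} bp")
    left = sequence[:MODULE_LENGTH]
    linker = sequence[MODULE_LENGTH : MODULE_LENGTH + LINKER_LENGTH]
    right = sequence[MODULE_LENGTH + LINKER_LENGTH :]
    return left, right, linker


class HalfIndex:
    """Seed index over one side's modules for exact <=2-mismatch lookup."""

    def __init__(self, modules: tuple[str, ...]):
        self.n = len(modules)
        self.matrix = np.frombuffer("".join(modules).encode(), dtype=np.uint8).reshape(
            self.n, MODULE_LENGTH
        )
        self.exact: dict[bytes, int] = {m.encode(): i for i, m in enumerate(modules)}
        self.seeds: list[dict[bytes, list[int]]] = []
        for k in range(N_SEEDS):
            d: dict[bytes, list[int]] = {}
            for i, m in enumerate(modules):
                key = m[k * SEED_LENGTH : (k + 1) * SEED_LENGTH].encode()
                d.setdefault(key, []).append(i)
            self.seeds.append(d)

    def lookup(self, half: bytes, max_mismatches: int = 2) -> tuple[int, int]:
        """Return (module index 0-based | UNMAPPED | AMBIGUOUS, mismatches).

        Exact for ``max_mismatches`` <= 2 by the pigeonhole guarantee; larger
        thresholds fall back to a full scan so results always equal the
        exhaustive Hamming search.
        """
        hit = self.exact.get(half)
        if hit is not None:
            return hit, 0
        if max_mismatches <= 0:
            return UNMAPPED, -1
        if max_mismatches > 2:
            return self._scan(half, max_mismatches)
        candidates: set[int] = set()
        for k in range(N_SEEDS):
            key = half[k * SEED_LENGTH : (k + 1) * SEED_LENGTH]
            candidates.update(self.seeds[k].get(key, ()))
        if not candidates:
            return UNMAPPED, -1
        arr = np.frombuffer(half, dtype=np.uint8)
        idx = np.fromiter(candidates, dtype=np.int64, count=len(candidates))
        dists = (self.matrix[idx] != arr).sum(axis=1)
        best = int(dists.min())
        if best > max_mismatches:
            return UNMAPPED, -1
        winners = idx[dists == best]
        if winners.size > 1:
            return AMBIGUOUS, best
        return int(winners[0]), best

    def _scan(self, half: bytes, max_mismatches: int) -> tuple[int, int]:
        arr = np.frombuffer(half, dtype=np.uint8)
        dists = (self.matrix != arr).sum(axis=1)
        best = int(dists.min())
        if best > max_mismatches:
            return UNMAPPED, -1
        winners = np.flatnonzero(dists == best)
        if winners.size > 1:
            return AMBIGUOUS, best
        return int(winners[0]), best


_INDEX_CACHE: dict[tuple[int, str], HalfIndex] = {}


def _index_for(library: BarcodeLibrary, side: str) -> HalfIndex:
    key = (id(library), side)
    idx = _INDEX_CACHE.get(key)
    if idx is None:
        modules = library.left_modules if side == "L" else library.right_modules
        idx = HalfIndex(modules)
        _INDEX_CACHE[key] = idx
    return idx


def map_half(
    half: str, side: str, library: BarcodeLibrary, max_mismatches: int = 2
) -> HalfMatch:
    """Map an 18-mer read half to its side of the library.

    The unique module at minimal Hamming distance <= ``max_mismatches`` wins;
    ties at the minimal distance are reported as ambiguous rather than broken
    arbitrarily. Any non-ACGT read character simply mismatches every module
    at that position.
    """
    if len(half) != MODULE_LENGTH:
        raise ValueError(f"half must be {MODULE_LENGTH} bp, got {len(half)}")
    if side not in ("L", "R"):
        raise ValueError("side must be 'L' or 'R'")
    code, mm = _index_for(library, side).lookup(half.encode(), max_mismatches)
    if code == UNMAPPED:
        return HalfMatch(side, None, None)
    if code == AMBIGUOUS:
        return HalfMatch(side, None, None, ambiguous=True)
    return HalfMatch(side, code + 1, mm)


def assign_barcode(left: HalfMatch, right: HalfMatch) -> tuple[str | None, str | None]:
    """Combine two half matches into a composite barcode id.

    Returns ``(barcode_id, None)`` when both halves mapped uniquely, else
    ``(None, reason)``. Both halves unmapped dominates; any ambiguity is
    reported next; then the single unmapped side.
    """
    if left.side != "L" or right.side != "R":
        raise ValueError("assign_barcode expects a left and a right HalfMatch")
    if left.mapped and right.mapped:
        return f"{left.module_index}:{right.module_index}", None
    if not left.mapped and not right.mapped and not (left.ambiguous or right.ambiguous):
        return None, "both_unmapped"
    if left.ambiguous or right.ambiguous:
        return None, "ambiguous"
    if not left.mapped:
        return None, "left_unmapped"
    return None, "right_unmapped"


@dataclass
class CountTable:
    """Sample x barcode read counts plus per-sample QC accounting.

    ``df`` is indexed by barcode id with one integer column per sample; every
    retained barcode has a positive count in at least one sample. ``qc`` maps
    each sample to ``{"total", "assigned", "discarded": {reason: n}}``.
    """

    df: pd.DataFrame
    qc: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.df.values < 0).any():
            raise ValueError("counts must be non-negative")
        for sample, rec in self.qc.items():
            discarded = sum(rec["discarded"].values())
            if rec["assigned"] + discarded != rec["total"]:
                raise ValueError(
                    f"sample {sample!r}: assigned + discarded != total input reads"
                )

    @property
    def samples(self) -> list[str]:
        return list(self.df.columns)

    @property
    def barcodes(self) -> list[str]:
        return list(self.df.index)

    def sample_counts(self, sample: str) -> pd.Series:
        """Detected (positive) barcode counts for one sample."""
        col = self.df[sample]
        return col[col > 0]


def _vector_mean_phred(quals: list[str]) -> np.ndarray:
    if not quals:
        return np.empty(0)
    joined = np.frombuffer("".join(quals).encode("ascii", "replace"), dtype=np.uint8)
    lens = np.fromiter((len(q) for q in quals), dtype=np.int64, count=len(quals))
    ends = np.cumsum(lens)
    starts = ends - lens
    sums = np.add.reduceat(joined.astype(np.int64), starts)
    # reduceat misbehaves on zero-length slices; empty quality strings are
    # rejected upstream by the FASTQ reader, so lens > 0 throughout.
    return sums / lens - PHRED_OFFSET


def _map_unique_halves(
    halves: np.ndarray, index: HalfIndex, max_mismatches: int
) -> np.ndarray:
    out = np.empty(halves.size, dtype=np.int64)
    lookup = index.lookup
    for i, h in enumerate(halves):
        out[i] = lookup(bytes(h), max_mismatches)[0]
    return out


# per-read outcome codes in the chunk assigner: >= 0 is the composite barcode
# code li * n_right + ri; negatives index DISCARD_REASONS.
_REASON_CODE = {reason: -(k + 1) for k, reason in enumerate(DISCARD_REASONS)}


def _assign_chunk(
    seqs: list[str],
    quals: list[str],
    lib: BarcodeLibrary,
    left_index: HalfIndex,
    right_index: HalfIndex,
    min_mean_phred: float,
    max_mismatches: int,
) -> np.ndarray:
    """Per-read outcome codes for one chunk of reads."""
    n = len(seqs)
    out = np.empty(n, dtype=np.int64)
    means = _vector_mean_phred(quals)
    ok_q = means >= min_mean_phred
    lens = np.fromiter((len(s) for s in seqs), dtype=np.int64, count=n)
    ok_len = lens == READ_LENGTH
    out[~ok_q] = _REASON_CODE["low_quality"]
    out[ok_q & ~ok_len] = _REASON_CODE["wrong_length"]
    keep = np.flatnonzero(ok_q & ok_len)
    if keep.size == 0:
        return out
    mat = np.frombuffer(
        "".join(seqs[i] for i in keep).encode("ascii", "replace"), dtype=np.uint8
    ).reshape(keep.size, READ_LENGTH)
    left = np.ascontiguousarray(mat[:, :MODULE_LENGTH]).view(f"S{MODULE_LENGTH}").ravel()
    right = np.ascontiguousarray(mat[:, MODULE_LENGTH + LINKER_LENGTH :]).view(
        f"S{MODULE_LENGTH}"
    ).ravel()

    uniq_l, inv_l = np.unique(left, return_inverse=True)
    uniq_r, inv_r = np.unique(right, return_inverse=True)
    li = _map_unique_halves(uniq_l, left_index, max_mismatches)[inv_l]
    ri = _map_unique_halves(uniq_r, right_index, max_mismatches)[inv_r]

    both_unmapped = (li == UNMAPPED) & (ri == UNMAPPED)
    any_ambiguous = ~both_unmapped & ((li == AMBIGUOUS) | (ri == AMBIGUOUS))
    left_only = (li < 0) & (ri >= 0) & ~any_ambiguous
    right_only = (ri < 0) & (li >= 0) & ~any_ambiguous
    assigned = (li >= 0) & (ri >= 0)

    codes = np.empty(keep.size, dtype=np.int64)
    codes[both_unmapped] = _REASON_CODE["both_unmapped"]
    codes[any_ambiguous] = _REASON_CODE["ambiguous"]
    codes[left_only] = _REASON_CODE["left_unmapped"]
    codes[right_only] = _REASON_CODE["right_unmapped"]
    codes[assigned] = li[assigned] * lib.n_right + ri[assigned]
    out[keep] = codes
    return out


def assign_reads(
    fastq_path,
    library: BarcodeLibrary,
    min_mean_phred: float = 30.0,
    max_mismatches: int = 2,
    chunk_size: int = 200_000,
) -> pd.DataFrame:
    """Per-read assignment for one FASTQ file.

    Returns a DataFrame with columns ``read_id``, ``barcode_id`` (NA for
    discarded reads) and ``reason`` (NA for assigned reads), in file order —
    the per-read view behind :func:`build_count_table`, useful for
    sensitivity analyses against a simulator truth table.
    """
    from .io import read_fastq

    left_index = _index_for(library, "L")
    right_index = _index_for(library, "R")
    ids: list[str] = []
    seqs: list[str] = []
    quals: list[str] = []
    codes: list[np.ndarray] = []
    for rec in read_fastq(fastq_path):
        ids.append(rec.read_id)
        seqs.append(rec.sequence)
        quals.append(rec.qualities)
        if len(seqs) >= chunk_size:
            codes.append(_assign_chunk(seqs, quals, library, left_index, right_index,
                                       min_mean_phred, max_mismatches))
            seqs, quals = [], []
    if seqs:
        codes.append(_assign_chunk(seqs, quals, library, left_index, right_index,
                                   min_mean_phred, max_mismatches))
    code = np.concatenate(codes) if codes else np.empty(0, dtype=np.int64)
    assigned = code >= 0
    barcode = np.where(
        assigned,
        [f"{c // library.n_right + 1}:{c % library.n_right + 1}" if c >= 0 else ""
         for c in code],
        None,
    )
    reason_names = np.array(DISCARD_REASONS, dtype=object)
    reason = np.where(assigned, None, reason_names[np.clip(-code - 1, 0, None)])
    return pd.DataFrame({"read_id": ids, "barcode_id": barcode, "reason": reason})


def build_count_table(
    fastq_inputs: dict[str, str] | list[tuple[str, str]],
    library: BarcodeLibrary,
    min_mean_phred: float = 30.0,
    max_mismatches: int = 2,
    min_count: int = 1,
    chunk_size: int = 200_000,
) -> CountTable:
    """Extract a sample x barcode count table from per-sample FASTQ files.

    ``fastq_inputs`` maps sample id -> FASTQ path (plain or gzip). Barcodes
    never observed (count below ``min_count`` in every sample) are dropped;
    QC and assignment discards are tallied per sample by reason. The whole
    procedure is deterministic.
    """
    from .io import read_fastq  # local import to avoid a cycle

    if isinstance(fastq_inputs, dict):
        items = list(fastq_inputs.items())
    else:
        items = list(fastq_inputs)
    sample_ids = [s for s, _ in items]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids in fastq_inputs")
    if min_count < 1:
        raise ValueError("min_count must be >= 1")

    left_index = _index_for(library, "L")
    right_index = _index_for(library, "R")

    per_sample: dict[str, dict[int, int]] = {}
    qc: dict[str, dict] = {}
    for sample, path in items:
        tally: dict[int, int] = {}
        reasons = {r: 0 for r in DISCARD_REASONS}
        total = 0
        assigned = 0

        def flush(seqs: list[str], quals: list[str]) -> None:
            nonlocal total, assigned
            codes = _assign_chunk(
                seqs, quals, library, left_index, right_index,
                min_mean_phred, max_mismatches,
            )
            total += codes.size
            kept = codes[codes >= 0]
            assigned += kept.size
            for k, reason in enumerate(DISCARD_REASONS):
                reasons[reason] += int((codes == -(k + 1)).sum())
            uniq, counts = np.unique(kept, return_counts=True)
            for code, c in zip(uniq.tolist(), counts.tolist()):
                tally[code] = tally.get(code, 0) + c

        seqs: list[str] = []
        quals: list[str] = []
        for rec in read_fastq(path):
            seqs.append(rec.sequence)
            quals.append(rec.qualities)
            if len(seqs) >= chunk_size:
                flush(seqs, quals)
                seqs, quals = [], []
        if seqs:
            flush(seqs, quals)
        per_sample[sample] = tally
        qc[sample] = {"total": total, "assigned": assigned, "discarded": reasons}

    all_codes = sorted(set().union(*(t.keys() for t in per_sample.values())) if per_sample else ())
    ids = [f"{code // library.n_right + 1}:{code % library.n_right + 1}" for code in all_codes]
    data = {
        sample: [per_sample[sample].get(code, 0) for code in all_codes]
        for sample in sample_ids
    }
    df = pd.DataFrame(data, index=pd.Index(ids, name="barcode"), dtype=np.int64)
    if len(df) and min_count > 1:
        df = df[(df >= min_count).any(axis=1)]
    elif len(df):
        df = df[(df > 0).any(axis=1)]
    return CountTable(df, qc)
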