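"""Clonal-composition metrics on barcode count tables.

Per-sample statistics: number of detected barcodes, Shannon diversity index
H = -sum p_i ln p_i (natural log), the minimal number of top clones reaching a
cumulative read fraction (the "barcodes composing 50% of reads"), the top
clone's share, and cumulative-abundance curves. Between samples: the
Jensen-Shannon divergence JSD(p, q) = 1/2 KL(p||m) + 1/2 KL(q||m) with
m = (p + q)/2, computed on the union of the two supports and bounded by ln 2.
A rarefaction routine re-estimates Shannon at fixed read depths to check
robustness to sequencing depth, resampling multinomially so depths above the
observed total are allowed.

Natural logarithms are used throughout, and the divergence itself (not its
square root) is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DiversitySummary",
    "ArchitectureThresholds",
    "relative_abundance",
    "shannon_index",
    "n_barcodes_for_fraction",
    "top_barcode_fraction",
    "cumulative_abundance_curve",
    "jensen_shannon_divergence",
    "divergence_matrix",
    "rarefy",
    "classify_architecture",
    "summarize",
    "summarize_table",
]

_TOL = 1e-9


def _as_profile(profile: pd.Series | np.ndarray | list) -> pd.Series:
    """Validate an abundance profile: positive frequencies summing to 1."""
    if not isinstance(profile, pd.Series):
        profile = pd.Series(np.asarray(profile, dtype=float))
        profile.index = [str(i) for i in range(len(profile))]
    p = profile.astype(float)
    if len(p) == 0:
        raise ValueError("empty abundance profile")
    if (p.values <= 0).any():
        raise ValueError("profile frequencies must be strictly positive")
    if abs(p.values.sum() - 1.0) > _TOL:
        raise ValueError(f"profile must sum to 1 (got {p.values.sum()!r})")
    return p


def relative_abundance(counts: pd.Series | np.ndarray | list) -> pd.Series:
    """Normalize read counts to clone frequencies, dropping zero counts."""
    if not isinstance(counts, pd.Series):
        counts = pd.Series(np.asarray(counts))
        counts.index = [str(i) for i in range(len(counts))]
    vals = counts.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("counts must be non-negative")
    total = vals.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero count vector")
    kept = counts[vals > 0]
    return (kept / total).rename("frequency")


def shannon_index(profile: pd.Series | np.ndarray | list) -> float:
    """Shannon diversity H = -sum p_i ln p_i; 0 for a single clone."""
    p = _as_profile(profile).to_numpy()
    return float(-(p * np.log(p)).sum())


def _sorted_desc(p: pd.Series) -> pd.Series:
    # ties in abundance broken by barcode id, lexicographically, for determinism
    ids = np.asarray(p.index.astype(str))
    order = np.lexsort((ids, -p.to_numpy()))
    return p.iloc[order]


def n_barcodes_for_fraction(profile: pd.Series | np.ndarray | list, fraction: float = 0.5) -> int:
    """Minimal number of most-abundant clones whose summed frequency >= fraction."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    p = _sorted_desc(_as_profile(profile)).to_numpy()
    cum = np.cumsum(p)
    return int(np.searchsorted(cum, fraction - _TOL) + 1)


def top_barcode_fraction(profile: pd.Series | np.ndarray | list) -> tuple[str, float, bool]:
    """Most abundant clone: (barcode id, frequency, tied?).

    Ties at the maximum are broken lexicographically and flagged.
    """
    p = _as_profile(profile)
    top = p.to_numpy().max()
    winners = sorted(str(i) for i in p.index[np.isclose(p.to_numpy(), top, rtol=0, atol=0)])
    return winners[0], float(top), len(winners) > 1


def cumulative_abundance_curve(profile: pd.Series | np.ndarray | list) -> pd.DataFrame:
    """Descending-abundance cumulative curve: columns rank, cumulative_fraction."""
    p = _sorted_desc(_as_profile(profile))
    cum = np.cumsum(p.to_numpy())
    return pd.DataFrame(
        {"rank": np.arange(1, len(p) + 1), "cumulative_fraction": cum},
        index=p.index,
    )


def _align_union(p: pd.Series, q: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    union = p.index.union(q.index)
    return (
        p.reindex(union, fill_value=0.0).to_numpy(),
        q.reindex(union, fill_value=0.0).to_numpy(),
    )


def jensen_shannon_divergence(
    p: pd.Series | np.ndarray | list, q: pd.Series | np.ndarray | list
) -> float:
    """JSD in nats on the union support, with 0 ln 0 = 0; in [0, ln 2]."""
    pv, qv = _align_union(_as_profile(p), _as_profile(q))
    m = 0.5 * (pv + qv)
    with np.errstate(divide="ignore", invalid="ignore"):
        term_p = np.where(pv > 0, pv * (np.log(pv) - np.log(m)), 0.0)
        term_q = np.where(qv > 0, qv * (np.log(qv) - np.log(m)), 0.0)
    return float(0.5 * term_p.sum() + 0.5 * term_q.sum())


def divergence_matrix(profiles: dict[str, pd.Series] | list[pd.Series]) -> pd.DataFrame:
    """All pairwise Jensen-Shannon divergences; symmetric, zero diagonal."""
    if isinstance(profiles, dict):
        names = list(profiles.keys())
        plist = [_as_profile(profiles[n]) for n in names]
    else:
        names = [str(i) for i in range(len(profiles))]
        plist = [_as_profile(p) for p in profiles]
    if len(plist) < 2:
        raise ValueError("need at least two profiles")
    n = len(plist)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = jensen_shannon_divergence(plist[i], plist[j])
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=names, columns=names)


def rarefy(
    counts: pd.Series | np.ndarray | list,
    depths: list[int],
    n_replicates: int = 10,
    seed: int = 0,
    with_replacement: bool = True,
) -> pd.DataFrame:
    """Shannon index re-estimated on reads subsampled to fixed depths.

    With replacement (default) reads are drawn multinomially from the
    empirical frequencies, which supports depths above the observed total;
    the without-replacement mode draws a multivariate hypergeometric sample
    and requires depth <= total reads. Returns a DataFrame with columns
    depth, shannon_mean, shannon_sd.
    """
    p = relative_abundance(counts)
    freqs = p.to_numpy()
    obs = None
    if not with_replacement:
        if not isinstance(counts, pd.Series):
            counts = pd.Series(np.asarray(counts))
        obs = counts[counts > 0].to_numpy(dtype=np.int64)
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for depth in depths:
        depth = int(depth)
        if depth < 1:
            raise ValueError("depths must be >= 1")
        vals = np.empty(n_replicates)
        for r in range(n_replicates):
            if with_replacement:
                sample = rng.multinomial(depth, freqs)
            else:
                if depth > obs.sum():
                    raise ValueError(
                        "without-replacement rarefaction needs depth <= total reads"
                    )
                sample = rng.multivariate_hypergeometric(obs, depth)
            kept = sample[sample > 0]
            q = kept / depth
            vals[r] = float(-(q * np.log(q)).sum())
        rows.append((depth, vals.mean(), vals.std(ddof=1) if n_replicates > 1 else 0.0))
    return pd.DataFrame(rows, columns=["depth", "shannon_mean", "shannon_sd"])


@dataclass(frozen=True)
class DiversitySummary:
    """Per-sample metrics bundle."""

    n_barcodes: int
    shannon: float
    n50_barcodes: int
    top_fraction: float

    def __post_init__(self) -> None:
        if self.n_barcodes < 1:
            raise ValueError("n_barcodes must be >= 1")
        if not -1e-12 <= self.shannon <= np.log(self.n_barcodes) + 1e-9:
            raise ValueError("Shannon index must lie in [0, ln n_barcodes]")
        if not 1 <= self.n50_barcodes <= self.n_barcodes:
            raise ValueError("n50_barcodes out of range")
        if self.top_fraction < 1.0 / self.n_barcodes - 1e-12 or self.top_fraction > 1.0:
            raise ValueError("top_fraction out of range")


@dataclass(frozen=True)
class ArchitectureThresholds:
    """Configurable cut-offs for the qualitative clonal-architecture label.

    Defaults formalize the qualitative tiers seen in recurrent tumors: a
    single clone with nearly all reads (clonal), a handful of dominant
    clones (oligoclonal), or thousands of evenly distributed clones
    (polyclonal).
    """

    clonal_top_fraction: float = 0.9
    oligoclonal_max_n50: int = 8
    polyclonal_min_barcodes: int = 1000
    polyclonal_max_top_fraction: float = 0.1


def classify_architecture(
    summary: DiversitySummary, thresholds: ArchitectureThresholds | None = None
) -> str:
    """Label a sample clonal / oligoclonal / polyclonal / intermediate."""
    t = thresholds or ArchitectureThresholds()
    if summary.top_fraction >= t.clonal_top_fraction:
        return "clonal"
    if summary.n50_barcodes <= t.oligoclonal_max_n50:
        return "oligoclonal"
    if (
        summary.n_barcodes >= t.polyclonal_min_barcodes
        and summary.top_fraction < t.polyclonal_max_top_fraction
    ):
        return "polyclonal"
    return "intermediate"


def summarize(counts: pd.Series | np.ndarray | list, fraction: float = 0.5) -> DiversitySummary:
    """All per-sample metrics from one count vector."""
    p = relative_abundance(counts)
    _, top, _ = top_barcode_fraction(p)
    return DiversitySummary(
        n_barcodes=len(p),
        shannon=shannon_index(p),
        n50_barcodes=n_barcodes_for_fraction(p, fraction),
        top_fraction=top,
    )


def summarize_table(df: pd.DataFrame, fraction: float = 0.5) -> pd.DataFrame:
    """Per-sample diversity summaries for a barcode x sample count table."""
    rows = {}
    for sample in df.columns:
        s = summarize(df[sample], fraction)
        rows[sample] = {
            "n_barcodes": s.n_barcodes,
            "shannon": s.shannon,
            "n50_barcodes": s.n50_barcodes,
            "top_fraction": s.top_fraction,
        }
    out = pd.DataFrame(rows).T
    out.index.name = "sample"
    out["n_barcodes"] = out["n_barcodes"].astype(int)
    out["n50_barcodes"] = out["n50_barcodes"].astype(int)
    return out
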