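"""Cross-sample, cross-stage analyses.

Clone trajectory tracking across samples and stages, fold-change reporting,
Welch's two-sample t-test for comparing diversity metrics between tumor
cohorts, the fixed-effects two-way ANOVA interaction test,
and within- vs between-group comparison of Jensen-Shannon divergences.
Raw, unadjusted p-values are reported throughout; no multiple-testing
correction is applied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "STAGES",
    "CloneTrajectory",
    "WelchResult",
    "AnovaResult",
    "GroupDivergence",
    "validate_metadata",
    "track_clone",
    "fold_change",
    "format_fold_change",
    "welch_t_test",
    "anova_interaction",
    "group_divergence_summary",
]

STAGES = ("injected", "primary", "late_primary", "residual_4wk", "residual_8wk", "recurrent")


def validate_metadata(metadata: pd.DataFrame, samples: list[str] | None = None) -> pd.DataFrame:
    """Check a sample metadata table (sample_id, stage, group, replicate)."""
    required = {"sample_id", "stage"}
    missing = required - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata is missing columns: {sorted(missing)}")
    if metadata["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    bad = set(metadata["stage"]) - set(STAGES)
    if bad:
        raise ValueError(f"unknown stages in metadata: {sorted(bad)}; expected {STAGES}")
    if samples is not None:
        unknown = set(samples) - set(metadata["sample_id"])
        if unknown:
            raise ValueError(f"samples missing from metadata: {sorted(unknown)}")
    return metadata


@dataclass(frozen=True)
class CloneTrajectory:
    """One clone's frequency across samples and mean per stage."""

    barcode_id: str
    per_sample: pd.Series  # frequency in every sample (0 where absent)
    per_stage_mean: pd.Series
    per_stage_max: pd.Series
    per_stage_min: pd.Series
    absent_everywhere: bool


def track_clone(
    barcode_id: str, table, metadata: pd.DataFrame
) -> CloneTrajectory:
    """Follow one barcode through every sample of a count table.

    ``table`` may be a CountTable or a barcode x sample DataFrame. A clone
    absent from the table's universe yields an all-zero trajectory with a
    warning rather than an error.
    """
    df = table.df if hasattr(table, "df") else table
    meta = validate_metadata(metadata)
    extra = set(meta["sample_id"]) - set(df.columns)
    if extra:
        raise ValueError(f"metadata names samples absent from the table: {sorted(extra)}")
    totals = df.sum(axis=0)
    if barcode_id in df.index:
        freqs = (df.loc[barcode_id] / totals.replace(0, np.nan)).fillna(0.0)
    else:
        warnings.warn(
            f"barcode {barcode_id!r} not detected in any sample; returning zero trajectory",
            stacklevel=2,
        )
        freqs = pd.Series(0.0, index=df.columns)
    freqs = freqs.rename(barcode_id)
    stage_of = meta.set_index("sample_id")["stage"]
    grouped = freqs.groupby(stage_of.reindex(freqs.index))
    observed_stages = [s for s in STAGES if s in set(stage_of.reindex(freqs.index))]
    mean = grouped.mean().reindex(observed_stages)
    return CloneTrajectory(
        barcode_id=barcode_id,
        per_sample=freqs,
        per_stage_mean=mean,
        per_stage_max=grouped.max().reindex(observed_stages),
        per_stage_min=grouped.min().reindex(observed_stages),
        absent_everywhere=bool((freqs == 0).all()),
    )


def fold_change(freq_after: float, freq_before: float) -> tuple[float, bool]:
    """Frequency ratio after/before; (value, is_infinite).

    A zero 'before' frequency reports an infinite fold change with a flag
    instead of raising, since a clone can be undetected before expansion.
    """
    if freq_after < 0 or freq_before < 0:
        raise ValueError("frequencies must be non-negative")
    if freq_before == 0:
        return math.inf, True
    return freq_after / freq_before, False


def format_fold_change(value: float) -> str:
    """Report text at one significant figure, e.g. 311.1 -> '300-fold'."""
    if math.isinf(value):
        return "infinite"
    if value <= 0:
        return "0-fold"
    exponent = math.floor(math.log10(value))
    rounded = round(value / 10**exponent) * 10**exponent
    if rounded >= 1:
        return f"{rounded:.0f}-fold"
    return f"{rounded:g}-fold"


class WelchResult(NamedTuple):
    statistic: float
    df: float
    pvalue: float


def welch_t_test(x, y) -> WelchResult:
    """Welch's unequal-variance two-sample t-test, two-sided.

    t = (mean x - mean y) / sqrt(sx^2/nx + sy^2/ny), with Welch-Satterthwaite
    degrees of freedom; the tail probability comes from the Student-t
    distribution via the regularized incomplete beta function. Two samples
    with zero variance and equal means return t = 0, p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample must contain at least two observations")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    nx, ny = x.size, y.size
    se2 = vx / nx + vy / ny
    if se2 == 0:
        if x.mean() == y.mean():
            return WelchResult(0.0, float(nx + ny - 2), 1.0)
        # two exactly constant samples at different levels: unbounded evidence
        sign = 1.0 if x.mean() > y.mean() else -1.0
        return WelchResult(sign * math.inf, float(nx + ny - 2), 0.0)
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    # two-sided tail of Student's t via I_x(df/2, 1/2)
    p = float(special.betainc(df / 2.0, 0.5, df / (df + t * t)))
    return WelchResult(float(t), float(df), p)


class AnovaResult(NamedTuple):
    F: float
    df: tuple[int, int]
    pvalue: float


def anova_interaction(values, factor_a, factor_b) -> AnovaResult:
    """Interaction term of a fixed-effects two-way ANOVA.

    Fits ``value ~ C(a) + C(b) + C(a):C(b)`` by ordinary least squares
    (type-II sums of squares, which coincide with the classical balanced
    decomposition) and returns the unadjusted interaction F and p. Requires
    every factor-level cell to be observed and at least one cell with
    replication, otherwise the interaction is not estimable.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "a": pd.Categorical([str(v) for v in factor_a]),
            "b": pd.Categorical([str(v) for v in factor_b]),
        }
    )
    cells = data.groupby(["a", "b"], observed=False).size()
    if (cells == 0).any():
        raise ValueError("every factor combination needs at least one observation")
    n_a = data["a"].nunique()
    n_b = data["b"].nunique()
    df_resid = len(data) - n_a * n_b
    if df_resid < 1:
        raise ValueError("interaction not estimable without within-cell replication")
    model = smf.ols("value ~ C(a) * C(b)", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    row = table.loc["C(a):C(b)"]
    f_val, p_val = float(row["F"]), float(row["PR(>F)"])
    # degenerate noise-free layouts: a numerically zero interaction sum of
    # squares is "no interaction" (F=0, p=1); a zero residual with a real
    # interaction is unbounded evidence for one
    scale = float(np.var(data["value"])) or 1.0
    if float(row["sum_sq"]) <= 1e-12 * scale * len(data):
        f_val, p_val = 0.0, 1.0
    elif float(table.loc["Residual", "sum_sq"]) <= 1e-12 * scale * len(data):
        f_val, p_val = float("inf"), 0.0
    return AnovaResult(f_val, (int(row["df"]), df_resid), p_val)


@dataclass(frozen=True)
class GroupDivergence:
    """Within-group vs between-group Jensen-Shannon divergence comparison."""

    within_a: np.ndarray
    between: np.ndarray
    within_a_mean: float
    between_mean: float
    test: WelchResult


def group_divergence_summary(
    matrix: pd.DataFrame, metadata: pd.DataFrame, group_a: str, group_b: str,
    group_column: str = "stage",
) -> GroupDivergence:
    """Compare clonal-composition similarity within group A to A-vs-B.

    Collects within-A entries of the divergence matrix (each unordered pair
    once, no diagonal) and all A x B entries, and compares them with Welch's
    t-test — the comparison behind statements like "primary tumors are
    similar to one another but dissimilar from the injected pool".
    """
    meta = metadata.set_index("sample_id")
    ids_a = [s for s in matrix.index if s in meta.index and meta.loc[s, group_column] == group_a]
    ids_b = [s for s in matrix.index if s in meta.index and meta.loc[s, group_column] == group_b]
    if len(ids_a) < 2:
        raise ValueError(f"group {group_a!r} needs at least two samples in the matrix")
    if len(ids_b) < 1:
        raise ValueError(f"group {group_b!r} has no samples in the matrix")
    within = np.array(
        [matrix.loc[a1, a2] for i, a1 in enumerate(ids_a) for a2 in ids_a[i + 1 :]]
    )
    between = np.array([matrix.loc[a, b] for a in ids_a for b in ids_b])
    if within.size >= 2 and between.size >= 2:
        test = welch_t_test(within, between)
    else:
        test = WelchResult(float("nan"), float("nan"), float("nan"))
    return GroupDivergence(
        within_a=within,
        between=between,
        within_a_mean=float(within.mean()),
        between_mean=float(between.mean()),
        test=test,
    )
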