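"""The distal ratio: length-normalized distal vs proximal 3'UTR coverage.

The statistic is ``(D/Ld) / (D/Ld + P/Lp)`` where D and P are summed read
depths over the distal and proximal regions and Ld, Lp their lengths.  It
estimates the fraction of transcripts using the distal polyadenylation site
under the two-isoform model in which the short isoform covers only the
proximal region and the long isoform covers both (estimand L/(S+2L) for
short/long abundances S and L, hence bounded above by 0.5).

Group comparisons use the two-sided Mann-Whitney U test with a
fold-change-of-medians effect size, ordinal trends use Spearman rank
correlation, and single-cell ratios use the same length-normalized formula
per cell with a minimum-reads filter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .regions import CoverageTrack, RegionSpec

__all__ = [
    "SampleRatio",
    "CohortComparison",
    "compute_distal_ratio",
    "compare_cohorts",
    "stratified_compare",
    "trend_test",
    "fraction_compare",
    "single_cell_ratios",
]


@dataclass(frozen=True)
class SampleRatio:
    sample_id: str
    ratio: float  # NaN when both regions have zero depth
    proximal_mean_depth: float
    distal_mean_depth: float

    @property
    def missing(self) -> bool:
        return math.isnan(self.ratio)


@dataclass(frozen=True)
class CohortComparison:
    fold_change: float  # median(case)/median(control); NaN if control median 0
    p_value: float
    n_case: int
    n_control: int
    median_case: float
    median_control: float
    median_diff: float
    low_power: bool = False


def compute_distal_ratio(cov: CoverageTrack, spec: RegionSpec,
                         sample_id: str = "") -> SampleRatio:
    """Length-normalized distal-site usage ratio for one coverage track.

    Returns a missing (NaN) ratio when both regions have zero total depth,
    mirroring the exclusion of runs without long-3'UTR coverage.
    """
    p = float(np.sum(cov.slice(spec.proximal)))
    d = float(np.sum(cov.slice(spec.distal)))
    lp, ld = len(spec.proximal), len(spec.distal)
    pm = p / lp
    dm = d / ld
    if pm + dm == 0:
        ratio = float("nan")
    elif p.is_integer() and d.is_integer():
        # reduced integer fraction D*Lp / (D*Lp + P*Ld): exactly invariant
        # under scaling every depth by a common integer factor
        num = int(d) * lp
        den = num + int(p) * ld
        g = math.gcd(num, den)
        ratio = (num // g) / (den // g)
    else:
        ratio = dm / (dm + pm)
    return SampleRatio(sample_id, ratio, pm, dm)


def _clean(values) -> np.ndarray:
    a = np.asarray(
        [v.ratio if isinstance(v, SampleRatio) else v for v in values],
        dtype=float,
    )
    return a[~np.isnan(a)]


def _mannwhitney(case: np.ndarray, control: np.ndarray) -> float:
    """Two-sided Mann-Whitney U: exact for small tie-free groups, else the
    normal approximation with tie correction."""
    has_ties = len(np.unique(np.concatenate([case, control]))) < len(case) + len(control)
    method = "exact" if (max(len(case), len(control)) <= 8 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(case, control, alternative="two-sided",
                                    method=method).pvalue)


def compare_cohorts(ratios_case, ratios_control) -> CohortComparison:
    """Compare two groups of distal ratios (missing values dropped)."""
    case = _clean(ratios_case)
    control = _clean(ratios_control)
    if len(case) == 0 or len(control) == 0:
        raise ValueError("a group is empty after dropping missing ratios")
    med_case = float(np.median(case))
    med_control = float(np.median(control))
    fold = med_case / med_control if med_control > 0 else float("nan")
    return CohortComparison(
        fold_change=fold,
        p_value=_mannwhitney(case, control),
        n_case=len(case),
        n_control=len(control),
        median_case=med_case,
        median_control=med_control,
        median_diff=med_case - med_control,
        low_power=min(len(case), len(control)) < 2,
    )


def stratified_compare(
    df: pd.DataFrame,
    stratum_key: str,
    known_levels=None,
    reference: str = "MM",
    case_label: str = "case",
    control_label: str = "control",
):
    """Per-stratum case/control comparisons plus within-case tests.

    ``df`` needs columns ``ratio``, ``group`` and ``stratum_key``.  Each
    stratum gets a case-vs-control :class:`CohortComparison`; additionally
    each non-reference stratum is rank-tested against the reference stratum
    *within cases*.  Strata with fewer than 2 samples in a group are flagged
    low-power but still reported.  Values outside ``known_levels`` (when
    given) are pooled under ``"other"`` with a warning.
    """
    df = df.dropna(subset=["ratio"]).copy()
    if stratum_key not in df.columns:
        raise KeyError(f"stratum key {stratum_key!r} not in table")
    strata = df[stratum_key].astype(str)
    if known_levels is not None:
        unknown = set(strata) - set(map(str, known_levels))
        if unknown:
            warnings.warn(
                f"unknown {stratum_key} values {sorted(unknown)} grouped under 'other'",
                stacklevel=2,
            )
            strata = strata.where(~strata.isin(unknown), "other")
    df["_stratum"] = strata

    per_stratum: dict[str, CohortComparison] = {}
    for level, sub in df.groupby("_stratum", sort=False):
        case = sub.loc[sub["group"] == case_label, "ratio"].to_numpy()
        control = sub.loc[sub["group"] == control_label, "ratio"].to_numpy()
        if len(case) == 0 or len(control) == 0:
            warnings.warn(f"stratum {level}: a group is empty, skipped", stacklevel=2)
            continue
        per_stratum[level] = compare_cohorts(case, control)

    cases = df[df["group"] == case_label]
    ref = cases.loc[cases["_stratum"] == str(reference), "ratio"].to_numpy()
    rows = []
    for level, sub in cases.groupby("_stratum", sort=False):
        if level == str(reference) or len(ref) == 0:
            continue
        vals = sub["ratio"].to_numpy()
        rows.append(
            {
                "stratum": level,
                "n": len(vals),
                "n_reference": len(ref),
                "median": float(np.median(vals)),
                "median_reference": float(np.median(ref)),
                "p_value": _mannwhitney(vals, ref),
                "low_power": min(len(vals), len(ref)) < 2,
            }
        )
    within_case = pd.DataFrame(
        rows,
        columns=["stratum", "n", "n_reference", "median", "median_reference",
                 "p_value", "low_power"],
    )
    return per_stratum, within_case


def trend_test(ratios, stages):
    """Spearman rank correlation of ratio against an ordinal stage.

    Returns ``(rho, p, degenerate)``; constant ratios give (0.0, 1.0, True).
    """
    r = np.asarray([v.ratio if isinstance(v, SampleRatio) else v for v in ratios],
                   dtype=float)
    s = np.asarray(stages, dtype=float)
    keep = ~(np.isnan(r) | np.isnan(s))
    r, s = r[keep], s[keep]
    if len(np.unique(s)) < 3:
        raise ValueError("need >= 3 distinct stages for a trend test")
    if len(np.unique(r)) < 2:
        return 0.0, 1.0, True
    res = stats.spearmanr(r, s)
    return float(res.statistic), float(res.pvalue), False


def fraction_compare(df: pd.DataFrame) -> pd.DataFrame:
    """Median distal ratio per cell fraction plus the nuclear/cytoplasmic fold.

    ``df`` needs columns ``ratio`` and ``fraction``; rows with a missing
    fraction label or ratio are excluded.  The returned frame has one row
    per fraction; the fold is attached as ``df.attrs['nuclear_cytoplasmic_fold']``
    (NaN when either fraction is absent).
    """
    sub = df.dropna(subset=["ratio", "fraction"])
    out = (
        sub.groupby("fraction")["ratio"]
        .agg(n="count", median_ratio="median")
        .reset_index()
    )
    med = dict(zip(out["fraction"], out["median_ratio"]))
    fold = float("nan")
    if "nuclear" in med and "cytoplasmic" in med and med["cytoplasmic"] > 0:
        fold = med["nuclear"] / med["cytoplasmic"]
    out.attrs["nuclear_cytoplasmic_fold"] = fold
    return out


def single_cell_ratios(
    counts: pd.DataFrame,
    clusters,
    spec: RegionSpec,
    min_total_reads: int = 3,
    pooled: bool = False,
):
    """Per-cell distal ratios and per-cluster distributions.

    ``counts`` needs columns ``cell``, ``proximal`` and ``distal`` (integer
    region read counts).  Cells with fewer than ``min_total_reads`` total
    region reads are excluded.  ``clusters`` maps cell -> cluster label.
    Returns ``(per_cell, per_cluster)`` where ``per_cluster`` maps cluster ->
    ``{"ratios": array, "median": float, "n": int}``.  In ``pooled`` mode the
    cluster ratio is computed from summed counts instead of per-cell ratios.
    """
    lp, ld = len(spec.proximal), len(spec.distal)
    df = counts.copy()
    if (df[["proximal", "distal"]] < 0).any().any():
        raise ValueError("negative region counts")
    df["cluster"] = df["cell"].map(dict(clusters) if not isinstance(clusters, pd.Series)
                                   else clusters)
    total = df["proximal"] + df["distal"]
    kept = df[total >= min_total_reads].copy()
    if kept.empty:
        warnings.warn("no cells pass the min_total_reads filter", stacklevel=2)
    pm = kept["proximal"] / lp
    dm = kept["distal"] / ld
    kept["ratio"] = dm / (dm + pm)
    per_cluster: dict = {}
    for label, sub in kept.groupby("cluster", sort=False):
        if pooled:
            ppm = sub["proximal"].sum() / lp
            pdm = sub["distal"].sum() / ld
            pooled_ratio = pdm / (pdm + ppm) if ppm + pdm > 0 else float("nan")
            per_cluster[label] = {
                "ratios": sub["ratio"].to_numpy(),
                "median": pooled_ratio,
                "n": len(sub),
            }
        else:
            per_cluster[label] = {
                "ratios": sub["ratio"].to_numpy(),
                "median": float(sub["ratio"].median()),
                "n": len(sub),
            }
    dropped = set(df["cluster"].dropna()) - set(per_cluster)
    for label in sorted(map(str, dropped)):
        warnings.warn(f"cluster {label}: no cells pass filtering, omitted",
                      stacklevel=2)
    return kept[["cell", "cluster", "proximal", "distal", "ratio"]], per_cluster
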