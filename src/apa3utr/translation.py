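"""Deletion-construct reporter model of 3'UTR translation repression.

Reporter constructs delete subsets of four distal 3'UTR regions; normalized
nanoluciferase/firefly expression is modelled with no intercept as

    y_c = t1*x_c1 + t2*x_c2 + t3*x_c3 + t4*x_c4

where x_ci = 1 when region i is *absent* (deleted) from construct c.  Under
this parameterization the full-length (Long) construct predicts 0 and the
Short construct (all four regions deleted) predicts sum(t): each coefficient
t_i is the share of translation repression attributable to region i.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "REGIONS",
    "ConstructDesign",
    "TranslationCoefficients",
    "default_deletion_design",
    "normalize_luminescence",
    "fit_region_coefficients",
    "predict_expression",
    "variance_attribution",
    "delta_ct",
    "stability_table",
    "compare_stability",
]

REGIONS = ["region1", "region2", "region3", "region4"]


@dataclass(frozen=True)
class ConstructDesign:
    """Region-absence membership matrix for a set of reporter constructs.

    ``membership`` is indexed by construct name with one 0/1 column per
    region; 1 means the region is deleted from that construct.
    """

    membership: pd.DataFrame
    short_name: str = "Short"
    long_name: str = "Long"

    def __post_init__(self) -> None:
        m = self.membership
        if list(m.columns) != REGIONS:
            raise ValueError(f"membership columns must be {REGIONS}")
        if not m.isin([0, 1]).all().all():
            raise ValueError("membership entries must be 0/1")
        if self.short_name in m.index and not (m.loc[self.short_name] == 1).all():
            raise ValueError("Short construct must have all regions absent")
        if self.long_name in m.index and not (m.loc[self.long_name] == 0).all():
            raise ValueError("Long construct must have all regions present")

    def row(self, construct: str) -> np.ndarray:
        return self.membership.loc[construct].to_numpy(dtype=float)


def default_deletion_design() -> ConstructDesign:
    """Eight-construct design: Short, Long and six deletions.

    Honors the constraints of the original deletion series (Deletion 1
    removes regions 2, 3 and 4; Deletions 5 and 6 both retain regions 3 and
    4) while keeping the membership matrix full rank so that all four
    coefficients are identifiable.
    """
    rows = {
        "Short": (1, 1, 1, 1),
        "Long": (0, 0, 0, 0),
        "Del1": (0, 1, 1, 1),
        "Del2": (1, 0, 0, 0),
        "Del3": (0, 0, 1, 0),
        "Del4": (0, 0, 0, 1),
        "Del5": (1, 1, 0, 0),
        "Del6": (0, 1, 0, 0),
    }
    m = pd.DataFrame.from_dict(rows, orient="index", columns=REGIONS)
    return ConstructDesign(m)


@dataclass(frozen=True)
class TranslationCoefficients:
    t: np.ndarray  # four region coefficients
    se: np.ndarray
    r_squared: float
    negative_flagged: bool

    def table(self) -> pd.DataFrame:
        """Region / coefficient +/- SE table in the published layout."""
        return pd.DataFrame(
            {
                "Region": [f"Region {i + 1}" for i in range(4)],
                "Translation Coefficient": [
                    f"{t:.2f}±{s:.2f}" for t, s in zip(self.t, self.se)
                ],
            }
        )


def normalize_luminescence(lum: pd.DataFrame, design: ConstructDesign | None = None,
                           short_name: str = "Short",
                           method: str = "short") -> pd.DataFrame:
    """Scale raw nano/firefly ratios to [0, 1] per batch.

    ``lum`` needs columns ``construct``, ``batch`` and ``value``.  The
    default method divides each batch by that batch's mean Short-construct
    value (Short maps to 1; a batch without Short is an error); values above
    1 are clipped with a ``clipped`` flag.  ``method="minmax"`` rescales each
    batch to its own [min, max] instead.
    """
    if short_name is None and design is not None:
        short_name = design.short_name
    out = lum.copy()
    out["normalized"] = np.nan
    out["clipped"] = False
    for batch, sub in lum.groupby("batch"):
        if method == "minmax":
            lo, hi = sub["value"].min(), sub["value"].max()
            if hi == lo:
                norm = pd.Series(1.0, index=sub.index)
            else:
                norm = (sub["value"] - lo) / (hi - lo)
        else:
            short_vals = sub.loc[sub["construct"] == short_name, "value"]
            if short_vals.empty:
                raise ValueError(f"batch {batch!r} has no {short_name} construct")
            norm = sub["value"] / short_vals.mean()
        out.loc[sub.index, "normalized"] = norm
    over = out["normalized"] > 1
    if over.any():
        out.loc[over, "clipped"] = True
        warnings.warn(
            f"{int(over.sum())} value(s) exceeded the normalization "
            "reference and were clipped to 1",
            stacklevel=2,
        )
    out["normalized"] = out["normalized"].clip(0.0, 1.0)
    return out


def _check_rank(X: np.ndarray, constructs) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the regions involved in the collinearity via the null space
        _, s, vt = np.linalg.svd(X)
        null = vt[rank:]
        bad = sorted(
            {REGIONS[j] for v in null for j in np.flatnonzero(np.abs(v) > 1e-8)}
        )
        raise ValueError(
            f"membership matrix is rank-deficient over constructs "
            f"{list(constructs)}; unidentifiable regions: {bad}"
        )


def fit_region_coefficients(design: ConstructDesign,
                            lum: pd.DataFrame) -> TranslationCoefficients:
    """No-intercept OLS of normalized expression on region-absence indicators.

    Each replicate is one observation.  R^2 is the squared Pearson
    correlation between predicted and observed per-construct mean
    expression (the predicted-vs-measured convention of reporter assays).
    Negative coefficients are reported but flagged.
    """
    ycol = "normalized" if "normalized" in lum.columns else "value"
    constructs = lum["construct"].to_numpy()
    unknown = set(constructs) - set(design.membership.index)
    if unknown:
        raise ValueError(f"constructs missing from design: {sorted(unknown)}")
    X = design.membership.loc[constructs].to_numpy(dtype=float)
    y = lum[ycol].to_numpy(dtype=float)
    _check_rank(X, pd.unique(constructs))
    fit = sm.OLS(y, X).fit()
    t = np.asarray(fit.params, dtype=float)
    se = np.asarray(fit.bse, dtype=float)
    if not np.all(np.isfinite(se)):
        warnings.warn("standard errors undefined (no residual degrees of "
                      "freedom); reported as NaN", stacklevel=2)
    means = lum.groupby("construct")[ycol].mean()
    pred = design.membership.loc[means.index].to_numpy(dtype=float) @ t
    obs = means.to_numpy(dtype=float)
    if np.allclose(pred, pred[0]) or np.allclose(obs, obs[0]):
        r2 = 1.0 if np.allclose(pred, obs) else float("nan")
    else:
        r2 = float(np.corrcoef(pred, obs)[0, 1] ** 2)
    neg = bool(np.any(t < 0))
    if neg:
        warnings.warn("negative translation coefficient(s); inspect the fit",
                      stacklevel=2)
    return TranslationCoefficients(t=t, se=se, r_squared=r2, negative_flagged=neg)


def predict_expression(coeffs: TranslationCoefficients | np.ndarray,
                       x, clip: bool = True) -> float:
    """Predicted normalized expression for one membership row."""
    t = coeffs.t if isinstance(coeffs, TranslationCoefficients) else np.asarray(coeffs)
    x = np.asarray(x, dtype=float)
    if x.shape != (4,) or not np.isin(x, (0.0, 1.0)).all():
        raise ValueError("x must be four 0/1 membership entries")
    val = float(t @ x)
    return float(np.clip(val, 0.0, 1.0)) if clip else val


def variance_attribution(coeffs: TranslationCoefficients | np.ndarray,
                         subset) -> float:
    """Fraction of total translation repression attributable to a region subset.

    ``subset`` holds 1-based region numbers, e.g. ``{1, 3, 4}``.
    """
    t = coeffs.t if isinstance(coeffs, TranslationCoefficients) else np.asarray(coeffs, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative coefficients; inspect the fit before "
                         "attributing variance")
    total = float(t.sum())
    if total == 0:
        raise ValueError("all coefficients are zero; attribution undefined")
    idx = sorted(set(int(i) for i in subset))
    if any(i < 1 or i > 4 for i in idx):
        raise ValueError("region numbers must be in 1..4")
    return float(sum(t[i - 1] for i in idx) / total)


def delta_ct(ct_target: float, ct_reference: float):
    """qPCR ΔCT = CT_target - CT_reference and relative level 2^(-ΔCT)."""
    if ct_target is None or ct_reference is None or \
            np.isnan(ct_target) or np.isnan(ct_reference):
        return float("nan"), float("nan")
    d = float(ct_target) - float(ct_reference)
    return d, 2.0 ** (-d)


def stability_table(qpcr: pd.DataFrame) -> pd.DataFrame:
    """Add ``delta_ct`` / ``relative_level`` columns to a qPCR table.

    Expects columns ``ct_target`` and ``ct_reference`` (plus whatever
    identifiers the caller uses, typically ``sample`` and ``timepoint``).
    """
    out = qpcr.copy()
    out["delta_ct"] = out["ct_target"].astype(float) - out["ct_reference"].astype(float)
    out["relative_level"] = 2.0 ** (-out["delta_ct"])
    return out


def compare_stability(qpcr: pd.DataFrame, group_key: str = "sample",
                      tol: float = 1.0) -> str:
    """Classify two decay trajectories as "similar" or "different".

    Mean ΔCT per timepoint is compared between the two groups; trajectories
    within ``tol`` cycles at every shared timepoint are "similar".
    """
    tab = stability_table(qpcr)
    groups = tab[group_key].unique()
    if len(groups) != 2:
        raise ValueError("compare_stability expects exactly two groups")
    prof = tab.pivot_table(index="timepoint", columns=group_key,
                           values="delta_ct", aggfunc="mean").dropna()
    if prof.empty:
        raise ValueError("no shared timepoints between groups")
    gap = float((prof[groups[0]] - prof[groups[1]]).abs().max())
    return "similar" if gap <= tol else "different"
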