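"""Two-dimensional volcano scoring of RNA-binding-protein effects.

Each RBP contributes one point: x = log2 differential-expression fold change
in disease (COPD vs control), y = the distal ratio measured after shRNA
knockdown of that RBP, centred on the empty-vector control ratio.  The
knockdown displacement dy shows what *less* of the protein does to distal
site usage; dx < 0 means there is less of it in disease.  Hence the
predicted disease effect on the distal ratio has the sign of dx*dy flipped:
dx*dy > 0 -> the RBP decreases the distal ratio in disease, dx*dy < 0 ->
increases it.  Effect size is the signed log2 Euclidean distance from the
plot centre.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RBPRecord",
    "RBPEffect",
    "classify_direction",
    "effect_distance",
    "bh_adjust",
    "select_candidates",
]


@dataclass(frozen=True)
class RBPRecord:
    name: str
    kd_ratio: float  # distal ratio under shRNA knockdown, in [0, 1]
    kd_p: float  # p-value of kd_ratio vs empty-vector control
    de_lfc: float  # log2 fold change COPD vs control
    de_padj: float  # BH-adjusted differential-expression p-value

    def __post_init__(self) -> None:
        if not 0 <= self.kd_ratio <= 1:
            raise ValueError(f"kd_ratio {self.kd_ratio} outside [0, 1]")
        for p in (self.kd_p, self.de_padj):
            if not 0 <= p <= 1:
                raise ValueError(f"p-value {p} outside [0, 1]")


@dataclass(frozen=True)
class RBPEffect:
    name: str
    direction: str  # "increase" | "decrease" | "null"
    signed_score: float
    significant: bool


def _deltas(rec: RBPRecord, control_ratio: float) -> tuple[float, float]:
    if not 0 < control_ratio < 1:
        raise ValueError("control_ratio must be in (0, 1)")
    return rec.de_lfc, rec.kd_ratio - control_ratio


def classify_direction(rec: RBPRecord, control_ratio: float) -> str:
    """Predicted direction of the RBP's effect on the distal ratio in disease."""
    dx, dy = _deltas(rec, control_ratio)
    prod = dx * dy
    if prod > 0:
        return "decrease"
    if prod < 0:
        return "increase"
    return "null"


def effect_distance(rec: RBPRecord, control_ratio: float) -> float:
    """Signed log2 Euclidean distance from the volcano-plot centre.

    Positive for predicted increase of the distal ratio, negative for
    decrease, 0 for records on an axis (null direction) or at the centre.
    """
    dx, dy = _deltas(rec, control_ratio)
    d = math.hypot(dx, dy)
    if d == 0:
        return 0.0
    direction = classify_direction(rec, control_ratio)
    sign = {"increase": 1.0, "decrease": -1.0, "null": 0.0}[direction]
    return sign * math.log2(d)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, order-preserving)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_candidates(records, control_ratio: float, dist_threshold: float = 1.0,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Rank RBPs by predicted effect and flag the significant large-effect set.

    A record is significant when its BH-adjusted knockdown p-value and its
    (already adjusted) differential-expression p-value are both below
    ``alpha`` and ``|log2(d)| > dist_threshold`` for its Euclidean distance
    d from the plot centre.  Output is sorted by |signed_score| descending;
    the increase/decrease counts among significant records are attached as
    ``df.attrs["n_increase"]`` / ``df.attrs["n_decrease"]``.
    """
    recs: list[RBPRecord] = []
    for r in records:
        if isinstance(r, RBPRecord):
            recs.append(r)
            continue
        try:
            recs.append(
                RBPRecord(
                    name=r["name"],
                    kd_ratio=float(r["kd_ratio"]),
                    kd_p=float(r["kd_p"]),
                    de_lfc=float(r["de_lfc"]),
                    de_padj=float(r["de_padj"]),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            warnings.warn(f"skipping record {r!r}: {exc}", stacklevel=2)
    if not recs:
        raise ValueError("no usable records")
    kd_padj = bh_adjust([r.kd_p for r in recs])
    rows = []
    for rec, kp in zip(recs, kd_padj):
        dx, dy = _deltas(rec, control_ratio)
        d = math.hypot(dx, dy)
        direction = classify_direction(rec, control_ratio)
        score = effect_distance(rec, control_ratio)
        log2d = math.log2(d) if d > 0 else float("-inf")
        significant = bool(
            d > 0
            and kp < alpha
            and rec.de_padj < alpha
            and abs(log2d) > dist_threshold
        )
        rows.append(
            {
                "name": rec.name,
                "direction": direction,
                "signed_score": score,
                "distance": d,
                "kd_padj": float(kp),
                "de_padj": rec.de_padj,
                "significant": significant,
            }
        )
    df = pd.DataFrame(rows)
    df = df.reindex(df["signed_score"].abs().sort_values(ascending=False).index)
    df = df.reset_index(drop=True)
    sig = df[df["significant"]]
    df.attrs["n_increase"] = int((sig["direction"] == "increase").sum())
    df.attrs["n_decrease"] = int((sig["direction"] == "decrease").sum())
    return df
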