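"""Structure-derived summaries: SHAPE reactivity classes, pairing entropy,
and motif-site accessibility.

SHAPE reactivity measures per-nucleotide backbone flexibility: high values
indicate unpaired, accessible nucleotides.  The standard colour convention
is used for classification (low < 0.4 <= intermediate < 0.85 <= high).
Shannon entropy of the base-pairing probability distribution,
H_i = -sum_j P_ij log10 P_ij over pairing partners, distinguishes
well-defined structures (low entropy) from disordered regions.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "REACTIVITY_INTERMEDIATE",
    "REACTIVITY_HIGH",
    "classify_reactivity",
    "shannon_entropy",
    "motif_accessibility",
]

REACTIVITY_INTERMEDIATE = 0.4
REACTIVITY_HIGH = 0.85


def classify_reactivity(r, low: float = REACTIVITY_INTERMEDIATE,
                        high: float = REACTIVITY_HIGH):
    """Classify SHAPE reactivity as low / intermediate / high / nodata.

    Boundary ownership: ``r == low`` is intermediate, ``r == high`` is high.
    Accepts a scalar or array; missing values (NaN) map to "nodata".
    """
    arr = np.asarray(r, dtype=float)
    out = np.where(
        np.isnan(arr),
        "nodata",
        np.where(arr >= high, "high", np.where(arr >= low, "intermediate", "low")),
    )
    return out.item() if np.isscalar(r) or arr.ndim == 0 else out


def shannon_entropy(P, include_unpaired: bool = False,
                    atol: float = 1e-8) -> np.ndarray:
    """Per-nucleotide Shannon entropy of base-pairing probabilities.

    H_i = -sum_j P[i, j] log10 P[i, j] over pairing partners (0*log 0 = 0).
    ``include_unpaired`` adds the unpaired-probability term
    -(1 - sum_j P[i, j]) log10(.) as well.  P must be symmetric with entries
    in [0, 1] and row sums <= 1.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("P must be a square matrix")
    if not np.allclose(P, P.T, atol=atol):
        raise ValueError("P must be symmetric")
    if np.any(P < -atol) or np.any(P > 1 + atol):
        raise ValueError("P entries must lie in [0, 1]")
    rowsum = P.sum(axis=1)
    if np.any(rowsum > 1 + 1e-6):
        raise ValueError("row sums exceed 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, P * np.log10(P), 0.0)
    H = -terms.sum(axis=1)
    if include_unpaired:
        q = np.clip(1.0 - rowsum, 0.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            H -= np.where(q > 0, q * np.log10(q), 0.0)
    return np.maximum(H, 0.0)


def motif_accessibility(reactivity, start: int, end: int,
                        threshold: float = REACTIVITY_INTERMEDIATE):
    """Median SHAPE reactivity over a motif site and an accessibility call.

    ``[start, end)`` indexes the per-nucleotide reactivity profile (NaN =
    no data).  Requires at least 50% of site nucleotides with data;
    otherwise returns ``(nan, False, "nodata")``.  Accessible when the
    median reactivity reaches the intermediate-reactivity boundary.
    """
    prof = np.asarray(reactivity, dtype=float)
    if not 0 <= start < end <= len(prof):
        raise ValueError("site outside the reactivity profile")
    site = prof[start:end]
    vals = site[~np.isnan(site)]
    if len(vals) < 0.5 * len(site) or len(vals) == 0:
        return float("nan"), False, "nodata"
    med = float(np.median(vals))
    return med, med >= threshold, ""
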