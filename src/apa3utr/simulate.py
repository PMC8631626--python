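"""Synthetic-data generators with planted truth for every pipeline stage.

These generators emulate the statistical structure of the pipeline's inputs —
two-isoform 3'UTR coverage, clustered 3'-end counts, replicate reporter
luminescence, and RBP knockdown/differential-expression tables — so every
estimator can be exercised against known truth.  All randomness flows
through explicit integer seeds (numpy Generator); there is no global state.

Coverage noise is per-base negative binomial in the standard mean-dispersion
parameterization, var = mu + dispersion * mu^2 (dispersion 0 degrades to
Poisson), sampled as a gamma-Poisson mixture.

The two-isoform model: a short isoform (abundance S) covers only the
proximal region, the long isoform (abundance L) covers both, so expected
per-base depth is mean_depth*(S+L) proximally and mean_depth*L distally and
the distal-ratio estimand is L/(S+2L) — bounded above by 0.5.  Target
cohort ratios are inverted through L = r, S = 1 - 2r (valid for r < 0.5;
draws are capped at 0.45 with a warning).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pas import EndCountTrack
from .regions import CoverageTrack, GenomicInterval, RegionSpec, serpina1_region_spec

__all__ = [
    "IsoformModel",
    "CohortModel",
    "simulate_coverage",
    "simulate_cohort",
    "simulate_end_seq",
    "simulate_luminescence",
    "simulate_rbp_table",
    "RATIO_CAP",
]

RATIO_CAP = 0.45


def _nb(rng: np.random.Generator, mean, dispersion: float) -> np.ndarray:
    """Negative binomial draws with var = mu + dispersion*mu^2 (gamma-Poisson)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if dispersion == 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


@dataclass(frozen=True)
class IsoformModel:
    """Two-isoform abundance model over a region specification."""

    S: float  # short-isoform abundance
    L: float  # long-isoform abundance
    spec: RegionSpec = field(default_factory=serpina1_region_spec)
    mean_depth: float = 100.0
    dispersion: float = 0.1

    def __post_init__(self) -> None:
        if self.S < 0 or self.L < 0 or self.S + self.L <= 0:
            raise ValueError("require S, L >= 0 and S + L > 0")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")

    @property
    def true_ratio(self) -> float:
        return self.L / (self.S + 2 * self.L)


def _mean_profile(model: IsoformModel) -> tuple[GenomicInterval, np.ndarray]:
    span = model.spec.span
    mu = np.zeros(len(span))
    for iv, m in (
        (model.spec.proximal, model.mean_depth * (model.S + model.L)),
        (model.spec.distal, model.mean_depth * model.L),
    ):
        mu[iv.start - span.start : iv.end - span.start] = m
    return span, mu


def simulate_coverage(model: IsoformModel, seed: int) -> CoverageTrack:
    """One coverage track over the hull of the proximal and distal regions."""
    rng = np.random.default_rng(seed)
    span, mu = _mean_profile(model)
    return CoverageTrack(span, _nb(rng, mu, model.dispersion))


@dataclass(frozen=True)
class CohortModel:
    """Case/control cohort of distal ratios with a planted median fold."""

    n_case: int
    n_control: int
    fold: float = 2.0
    beta_a: float = 4.0
    beta_b: float = 76.0
    mean_depth: float = 100.0
    dispersion: float = 0.1
    spec: RegionSpec = field(default_factory=serpina1_region_spec)

    def __post_init__(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("sample sizes must be >= 2")
        if self.fold <= 0:
            raise ValueError("fold must be positive")


def simulate_cohort(model: CohortModel, seed: int):
    """Per-sample coverage tracks plus a truth table of planted ratios.

    Control ratios are Beta(a, b) draws; case ratios are the same draws
    scaled by ``fold`` so the population median is fold x the control
    median.  Each ratio is inverted to (S, L) abundances and run through
    the coverage generator.  Returns ``(samples, truth)`` where ``samples``
    is a list of ``(sample_id, group, CoverageTrack)`` and ``truth`` a
    DataFrame with the planted per-sample ratios.
    """
    rng = np.random.default_rng(seed)
    from scipy.stats import beta as beta_dist

    pop_median = float(beta_dist.ppf(0.5, model.beta_a, model.beta_b))
    if model.fold * pop_median >= 1:
        raise ValueError("fold pushes the case median to >= 1")
    n = model.n_case + model.n_control
    draws = rng.beta(model.beta_a, model.beta_b, size=n)
    scale = np.concatenate(
        [np.full(model.n_case, model.fold), np.ones(model.n_control)]
    )
    ratios = draws * scale
    if np.any(ratios > RATIO_CAP):
        warnings.warn(
            f"{int((ratios > RATIO_CAP).sum())} planted ratio(s) capped at "
            f"{RATIO_CAP}: the two-isoform estimand cannot exceed 0.5",
            stacklevel=2,
        )
        ratios = np.minimum(ratios, RATIO_CAP)
    L = ratios
    S = 1.0 - 2.0 * ratios
    groups = ["case"] * model.n_case + ["control"] * model.n_control

    # vectorized coverage generation: one (n_samples, span) matrix
    span = model.spec.span
    mu = np.zeros((n, len(span)))
    p0, p1 = model.spec.proximal.start - span.start, model.spec.proximal.end - span.start
    d0, d1 = model.spec.distal.start - span.start, model.spec.distal.end - span.start
    mu[:, p0:p1] = (model.mean_depth * (S + L))[:, None]
    mu[:, d0:d1] = (model.mean_depth * L)[:, None]
    depth = _nb(rng, mu, model.dispersion)

    samples = [
        (f"{g}_{i:03d}", g, CoverageTrack(span, depth[i]))
        for i, g in enumerate(groups)
    ]
    truth = pd.DataFrame(
        {
            "sample_id": [s[0] for s in samples],
            "group": groups,
            "true_ratio": ratios,
            "S": S,
            "L": L,
        }
    )
    return samples, truth


def simulate_end_seq(sites, fractions, n_reads: int, jitter_sd: float,
                     seed: int, interval: GenomicInterval) -> EndCountTrack:
    """Clustered 3'-end counts around cleavage sites.

    Reads are assigned to sites multinomially by the usage ``fractions``
    (must sum to 1); each read's position is the site plus rounded Gaussian
    jitter, clipped to the interval.  Total counts equal ``n_reads``.
    """
    sites = np.asarray(sites, dtype=int)
    fractions = np.asarray(fractions, dtype=float)
    if len(sites) != len(fractions):
        raise ValueError("sites and fractions must align")
    if not np.isclose(fractions.sum(), 1.0):
        raise ValueError("usage fractions must sum to 1")
    rng = np.random.default_rng(seed)
    counts = np.zeros(len(interval), dtype=np.int64)
    if n_reads > 0:
        per_site = rng.multinomial(n_reads, fractions)
        for site, k in zip(sites, per_site):
            if k == 0:
                continue
            pos = site + np.round(rng.normal(0.0, jitter_sd, size=k)).astype(int)
            pos = np.clip(pos, interval.start, interval.end - 1)
            np.add.at(counts, pos - interval.start, 1)
    return EndCountTrack(interval, counts)


def simulate_luminescence(design, t_true, sigma: float, n_replicates: int,
                          seed: int, n_batches: int = 1) -> pd.DataFrame:
    """Replicate reporter values from the no-intercept region model.

    Each replicate is sum(t_i * x_i) + Gaussian(0, sigma), truncated at 0.
    Returns a long table (construct, batch, replicate, value) on the
    normalized scale.
    """
    t_true = np.asarray(t_true, dtype=float)
    if t_true.shape != (4,):
        raise ValueError("t_true must have length 4")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if n_replicates == 1:
        warnings.warn("single replicate: standard errors will be undefined",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    rows = []
    X = design.membership
    for batch in range(1, n_batches + 1):
        for construct in X.index:
            mean = float(X.loc[construct].to_numpy() @ t_true)
            vals = np.maximum(mean + rng.normal(0.0, sigma, size=n_replicates), 0.0)
            for rep, v in enumerate(vals, 1):
                rows.append(
                    {"construct": construct, "batch": batch,
                     "replicate": rep, "value": float(v)}
                )
    return pd.DataFrame(rows)


def simulate_rbp_table(n_null: int, planted, control_ratio: float, seed: int,
                       null_dx_sd: float = 0.02, null_dy_sd: float = 0.005):
    """An RBP table with planted knockdown/expression effects plus truth.

    ``planted`` is a list of ``(direction, dx, dy)`` with direction
    "increase" or "decrease" (consistency with the sign rule dx*dy is
    checked).  Planted records get vanishingly small p-values; null records
    sit near the origin with uniform raw p-values.  The differential-
    expression column is emitted the way a DE pipeline would emit it:
    raw ``de_p`` plus BH-adjusted ``de_padj`` computed across the table.
    Returns ``(table, truth)``.
    """
    rng = np.random.default_rng(seed)
    rows, truth_rows = [], []
    for i in range(n_null):
        dx = rng.normal(0.0, null_dx_sd)
        dy = rng.normal(0.0, null_dy_sd)
        rows.append(
            {
                "name": f"NULL{i:03d}",
                "kd_ratio": float(np.clip(control_ratio + dy, 0.0, 1.0)),
                "kd_p": rng.uniform(),
                "de_lfc": dx,
                "de_p": rng.uniform(),
            }
        )
        truth_rows.append({"name": rows[-1]["name"], "direction": "null"})
    for j, (direction, dx, dy) in enumerate(planted):
        prod = dx * dy
        want = "decrease" if prod > 0 else ("increase" if prod < 0 else "null")
        if want != direction:
            raise ValueError(
                f"planted effect ({dx}, {dy}) implies {want!r}, not {direction!r}"
            )
        kd_ratio = control_ratio + dy
        if not 0 <= kd_ratio <= 1:
            raise ValueError("planted dy pushes kd_ratio outside [0, 1]")
        rows.append(
            {
                "name": f"PLANT{j:02d}_{direction[:3].upper()}",
                "kd_ratio": float(kd_ratio),
                "kd_p": 1e-30,
                "de_lfc": float(dx),
                "de_p": 1e-20,
            }
        )
        truth_rows.append({"name": rows[-1]["name"], "direction": direction})
    table = pd.DataFrame(rows)
    from .rbp import bh_adjust

    table["de_padj"] = bh_adjust(table["de_p"].to_numpy())
    table = table.sample(frac=1.0, random_state=int(rng.integers(2**31)))
    table = table.reset_index(drop=True)
    return table, pd.DataFrame(truth_rows)
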