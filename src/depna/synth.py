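"""Synthetic multi-subject cohorts with a planted influence hub.

The generator emulates the statistical structure the analysis assumes,
at the reference study's scale (74 subjects, 14 ROIs in two sub-networks,
two ~44-volume conditions at TR = 3 s): one designated hub node acts as a
common cause of every other node, more strongly in the high-intensity
condition, so the hub's partial-correlation influence genuinely differs
between conditions.  Behavioral scores are coupled to each subject's
planted low-minus-high influence difference, and rating traces follow a
smoothed low-to-high step so the epoch search recovers the two
conditions.  No claim of hemodynamic realism is made — influence is
planted via common-cause coupling because the dependency measure is by
construction a common-cause/mediation detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .core import SubjectTimeSeries
from .epochs import RatingTrace, rating_auc
from .roi import RoiSet, default_roiset

__all__ = ["CohortSpec", "Cohort", "simulate_cohort", "simulate_null_pool"]


@dataclass
class CohortSpec:
    """Parameters of a simulated cohort.

    Defaults mirror the reference design: n = 74 subjects, the packaged
    14-node two-network roster, 44 volumes per condition at TR = 3 s
    (132-s epochs), and the vmPFC as the planted hub whose coupling rises
    from 0.15 (low condition) to 0.45 (high condition).  ``behavior_slope``
    couples behavior to the subject's low-minus-high coupling difference;
    a negative slope makes subjects whose hub gains more influence in the
    high condition report higher behavior scores.
    """

    n_subjects: int = 74
    roiset: RoiSet = field(default_factory=default_roiset)
    t_per_condition: int = 44
    tr_seconds: float = 3.0
    hub_label: str = "vmPFC"
    coupling_low: float = 0.15
    coupling_high: float = 0.45
    shared_factor_sd: float = 0.3
    noise_sd: float = 1.0
    behavior_slope: float = -1.0
    behavior_noise_sd: float = 0.3
    subject_coupling_sd: float = 0.10
    rating_rate_hz: float = 10.0
    rating_scale_levels: int = 21
    rating_low_level: float = 3.0
    rating_high_level: float = 15.0
    rating_noise_sd: float = 0.8
    ar1_rho: float = 0.0  # AR(1) stress-test option; white noise by default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.t_per_condition < 3:
            raise ValueError("t_per_condition must be >= 3")
        if self.hub_label not in self.roiset.labels:
            raise ValueError(f"hub {self.hub_label!r} not in the ROI roster")
        for name in ("coupling_low", "coupling_high"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        for name in ("shared_factor_sd", "noise_sd", "behavior_noise_sd",
                     "subject_coupling_sd", "rating_noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not -1 < self.ar1_rho < 1:
            raise ValueError("ar1_rho must lie in (-1, 1)")


@dataclass
class Cohort:
    """A simulated cohort: per-subject series for both conditions, plus
    behavior and rating tables."""

    spec: CohortSpec
    low: List[SubjectTimeSeries]
    high: List[SubjectTimeSeries]
    behavior: pd.DataFrame  # index subject_id; anger_auc, trait_anger, ...
    ratings: List[RatingTrace]
    coupling: pd.DataFrame  # planted per-subject beta_low / beta_high

    @property
    def subject_ids(self) -> List[str]:
        return [ts.subject_id for ts in self.low]


def _noise(rng: np.random.Generator, shape, sd: float, rho: float) -> np.ndarray:
    eps = rng.normal(0.0, sd, size=shape)
    if rho == 0.0:
        return eps
    out = np.empty_like(eps)
    out[0] = eps[0]
    scale = np.sqrt(1 - rho**2)
    for t in range(1, eps.shape[0]):
        out[t] = rho * out[t - 1] + scale * eps[t]
    return out


def _simulate_condition(
    rng: np.random.Generator, spec: CohortSpec, beta: float
) -> np.ndarray:
    """One subject/condition T x N matrix: hub h ~ N(0,1); every other node
    x_i = beta*h + g*f_net + eps_i with f_net shared within its sub-network."""
    t = spec.t_per_condition
    labels = spec.roiset.labels
    n = len(labels)
    hub_idx = spec.roiset.index(spec.hub_label)
    h = rng.standard_normal(t)
    factors = {
        net: rng.standard_normal(t) for net in ("reactivity", "regulation")
    }
    data = np.empty((t, n))
    for i, lbl in enumerate(labels):
        if i == hub_idx:
            data[:, i] = h
        else:
            eps = _noise(rng, t, spec.noise_sd, spec.ar1_rho)
            data[:, i] = (
                beta * h + spec.shared_factor_sd * factors[spec.roiset.network[lbl]] + eps
            )
    return data


def _rating_trace(
    rng: np.random.Generator, spec: CohortSpec, subject_id: str,
    plateau_shift: float = 0.0,
) -> RatingTrace:
    """Smoothed low-to-high step covering both conditions, with per-subject
    jitter in transition time and sample noise, clipped to the scale.
    ``plateau_shift`` raises/lowers the subject's high plateau, which is how
    the planted coupling difference reaches the rating-derived AUC."""
    total_s = 2 * spec.t_per_condition * spec.tr_seconds
    n = int(round(total_s * spec.rating_rate_hz))
    tt = np.arange(n) / spec.rating_rate_hz
    mid = total_s / 2 + rng.normal(0.0, 2.0)
    width = 8.0  # seconds for the sigmoid rise
    base = spec.rating_low_level + (
        spec.rating_high_level + plateau_shift - spec.rating_low_level
    ) / (1.0 + np.exp(-(tt - mid) / width))
    samples = base + rng.normal(0.0, spec.rating_noise_sd, size=n)
    samples = np.clip(samples, 0.0, spec.rating_scale_levels - 1)
    return RatingTrace(subject_id, samples, spec.rating_rate_hz,
                       spec.rating_scale_levels)


def simulate_cohort(spec: Optional[CohortSpec] = None, **overrides) -> Cohort:
    """Simulate a full cohort reproducibly from ``spec.seed``.

    Per subject s and condition c the hub drives every other node with
    coupling beta_{s,c} = coupling_c + jitter (jitter drawn independently
    per subject and condition), so the hub's influence difference between
    conditions varies across subjects.  Behavior is
    ``behavior_slope * (beta_low - beta_high) + noise`` — with the default
    negative slope, subjects with a larger high-condition influence gain
    score higher — plus the rating-derived AUC and two trait-regulation
    columns built the same way.
    """
    if spec is None:
        spec = CohortSpec(**overrides)
    elif overrides:
        spec = replace(spec, **overrides)
    rng = np.random.default_rng(spec.seed)
    low, high, ratings = [], [], []
    rows = []
    for s in range(spec.n_subjects):
        sid = f"sub-{s + 1:03d}"
        b_lo = spec.coupling_low + rng.normal(0.0, spec.subject_coupling_sd)
        b_hi = spec.coupling_high + rng.normal(0.0, spec.subject_coupling_sd)
        low.append(SubjectTimeSeries(
            sid, _simulate_condition(rng, spec, b_lo), spec.tr_seconds, spec.roiset))
        high.append(SubjectTimeSeries(
            sid, _simulate_condition(rng, spec, b_hi), spec.tr_seconds, spec.roiset))
        delta = b_lo - b_hi
        # subjects whose hub gains more influence in the high condition
        # (delta more negative) rate the high epoch more intensely when
        # behavior_slope < 0
        trace = _rating_trace(
            rng, spec, sid, plateau_shift=10.0 * spec.behavior_slope * delta
        )
        ratings.append(trace)
        rows.append(dict(
            subject_id=sid,
            beta_low=b_lo,
            beta_high=b_hi,
            anger_auc=rating_auc(trace),
            trait_anger=(
                25.0 + 8.0 * spec.behavior_slope * delta
                + rng.normal(0.0, 8.0 * spec.behavior_noise_sd)
            ),
            reappraisal=(
                4.0 + spec.behavior_slope * delta
                + rng.normal(0.0, spec.behavior_noise_sd)
            ),
            suppression=(
                3.5 + spec.behavior_slope * delta
                + rng.normal(0.0, spec.behavior_noise_sd)
            ),
        ))
    table = pd.DataFrame(rows).set_index("subject_id")
    behavior = table[["anger_auc", "trait_anger", "reappraisal", "suppression"]]
    coupling = table[["beta_low", "beta_high"]]
    return Cohort(spec, low, high, behavior, ratings, coupling)


def simulate_null_pool(
    n_nodes: int, t: int, n_pool: int, seed: int = 0
) -> np.ndarray:
    """Pool of i.i.d. Gaussian candidate node time series, shape (n_pool, t),
    for the specificity bootstrap (stands in for random gray-matter regions)."""
    if n_pool < n_nodes:
        raise ValueError(f"pool size {n_pool} smaller than network size {n_nodes}")
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n_pool, t))
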