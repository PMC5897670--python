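"""Dependency network analysis on a single subject/condition.

The method ranks network nodes by how much each one "carries" the pairwise
correlations between all other nodes.  For nodes *i*, *k* and a third node
*j*, the first-order partial correlation

    PC(i,k|j) = (C(i,k) - C(i,j) C(k,j)) / sqrt((1 - C(i,j)^2)(1 - C(k,j)^2))

is the i–k correlation with the linear contribution of *j* removed.  The
*influence* of *j* on the i–k link is the drop

    d(i,k|j) = C(i,k) - PC(i,k|j),  floored at zero,

which is large only when a substantial fraction of the i–k correlation is
explained by *j*.  Averaging over links gives the dependency matrix

    D(i,j) = 1/(N-1) * sum_{k != j} d(i,k|j)

(the average influence of node *j* on node *i*'s correlations; asymmetric),
and column sums of D give each node's *influencing degree*, its
system-level out-influence.  Restricting the node sets yields the
intra-network and the two inter-network influence variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Literal, Optional, Sequence, Tuple

import numpy as np

from .roi import RoiSet

__all__ = [
    "SubjectTimeSeries",
    "CorrelationMatrix",
    "DependencyMatrix",
    "InfluenceProfile",
    "pearson_correlations",
    "fisher_z",
    "partial_correlation",
    "influence_d",
    "dependency_matrix",
    "influencing_degree",
    "intra_network_influence",
    "inter_network_influence_within",
    "inter_network_influence_between",
    "total_inter_network_influence",
    "standardize_columns",
]

_CLIP = 1.0 - 1e-7
_Z_DENOM_FLOOR = 1e-12

Scheme = Literal["global_degree", "intra", "inter_within_other", "inter_between"]
INTER_SCHEMES = ("inter_within_other", "inter_between")


@dataclass
class SubjectTimeSeries:
    """One subject's T x N signal matrix (rows = time, columns = ROIs)."""

    subject_id: str
    data: np.ndarray
    tr_seconds: float
    roiset: Optional[RoiSet] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be a 2-D T x N array")
        if not np.isfinite(self.data).all():
            raise ValueError(f"non-finite values in time series of {self.subject_id!r}")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.roiset is not None and self.data.shape[1] != len(self.roiset):
            raise ValueError(
                f"{self.subject_id!r}: {self.data.shape[1]} columns but "
                f"{len(self.roiset)} ROIs in the roster"
            )
        t, n = self.data.shape
        if t < n + 2:
            warnings.warn(
                f"{self.subject_id!r}: only {t} time points for {n} ROIs; "
                "correlation estimates will be unstable",
                stacklevel=2,
            )

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    def window(self, start: int, stop: int, tag: str = "") -> "SubjectTimeSeries":
        """Half-open TR-index window [start, stop) as a new series."""
        sub = self.data[start:stop]
        sid = self.subject_id if not tag else f"{self.subject_id}:{tag}"
        return SubjectTimeSeries(sid, sub, self.tr_seconds, self.roiset)


@dataclass
class CorrelationMatrix:
    """Symmetric N x N ROI-ROI matrix, either raw Pearson r or Fisher z."""

    values: np.ndarray
    transform: Literal["raw_r", "fisher_z"] = "raw_r"
    labels: Optional[Tuple[str, ...]] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if self.transform == "raw_r":
            if np.any(np.abs(v) > 1 + 1e-12):
                raise ValueError("raw correlations must lie in [-1, 1]")
            if not np.allclose(np.diag(v), 1.0, atol=1e-12):
                raise ValueError("raw correlation matrix must have unit diagonal")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class DependencyMatrix:
    """N x N non-negative matrix; entry (i, j) = influence of node j on node i.

    Asymmetric in general; diagonal is identically zero.
    """

    values: np.ndarray
    condition_tag: str = ""
    labels: Optional[Tuple[str, ...]] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dependency matrix must be square")
        if np.any(v < -1e-12):
            raise ValueError("dependency entries must be non-negative")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValueError("dependency diagonal must be zero")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class InfluenceProfile:
    """Per-node influence scores under one aggregation scheme."""

    scheme: Scheme
    scores: Dict[str, float]
    source_network: Optional[str] = None
    target_network: Optional[str] = None
    agg: str = "mean"

    def __post_init__(self) -> None:
        if any(s < -1e-12 for s in self.scores.values()):
            raise ValueError("influence scores must be non-negative")

    def as_array(self, order: Sequence[str]) -> np.ndarray:
        return np.array([self.scores[lbl] for lbl in order], dtype=float)


# ---------------------------------------------------------------------------
# correlations


def standardize_columns(data: np.ndarray) -> np.ndarray:
    """Column z-scoring (ddof=1).  Pearson r is scale invariant, so this is
    cosmetic for the default path, but it stabilizes the fisher_z route."""
    data = np.asarray(data, dtype=float)
    mu = data.mean(axis=0, keepdims=True)
    sd = data.std(axis=0, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("cannot standardize a constant column")
    return (data - mu) / sd


def pearson_correlations(ts: SubjectTimeSeries) -> CorrelationMatrix:
    """ROI-ROI Pearson correlation matrix for one subject/condition.

    Raises
    ------
    ValueError
        If fewer than 3 time points, or if any ROI has zero variance
        (the offending ROI is named).
    """
    data = ts.data
    if data.shape[0] < 3:
        raise ValueError(
            f"{ts.subject_id!r}: need at least 3 time points, got {data.shape[0]}"
        )
    sd = data.std(axis=0)
    if np.any(sd == 0):
        idx = int(np.argmin(sd))
        name = ts.roiset.labels[idx] if ts.roiset is not None else f"column {idx}"
        raise ValueError(f"{ts.subject_id!r}: ROI {name!r} has zero variance")
    r = np.corrcoef(data, rowvar=False)
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    r = (r + r.T) / 2.0
    labels = ts.roiset.labels if ts.roiset is not None else None
    return CorrelationMatrix(r, "raw_r", labels)


def fisher_z(c: CorrelationMatrix) -> CorrelationMatrix:
    """Fisher z (atanh) applied off-diagonal; |r| clipped below 1 first."""
    if c.transform != "raw_r":
        raise ValueError("matrix is already Fisher-z transformed")
    r = c.values.copy()
    off = ~np.eye(c.n, dtype=bool)
    if np.any(np.abs(r[off]) >= 1.0):
        warnings.warn(
            "off-diagonal |r| = 1 clipped before Fisher z transform", stacklevel=2
        )
    r[off] = np.clip(r[off], -_CLIP, _CLIP)
    z = np.zeros_like(r)
    z[off] = np.arctanh(r[off])
    np.fill_diagonal(z, np.diag(c.values))
    return CorrelationMatrix(z, "fisher_z", c.labels)


# ---------------------------------------------------------------------------
# partial correlation and influence


def _check_triplet(n: int, i: int, k: int, j: int) -> None:
    if len({i, k, j}) != 3:
        raise ValueError(f"nodes must be distinct, got i={i}, k={k}, j={j}")
    for idx in (i, k, j):
        if not 0 <= idx < n:
            raise IndexError(f"node index {idx} out of range for N={n}")


def partial_correlation(c: CorrelationMatrix, i: int, k: int, j: int) -> float:
    """First-order partial correlation PC(i,k|j) from the correlation matrix.

    On raw r this equals the Pearson correlation of the residuals of columns
    i and k after regressing out column j.  On Fisher-z input the same
    algebra is applied literally (the historical convention); the
    denominator is floored to keep it defined for |z| >= 1.
    """
    v = c.values
    _check_triplet(c.n, i, k, j)
    cij, ckj = v[i, j], v[k, j]
    if c.transform == "raw_r":
        if abs(cij) >= 1.0 or abs(ckj) >= 1.0:
            pair = (i, j) if abs(cij) >= 1.0 else (k, j)
            raise ValueError(
                f"degenerate conditioning: |C{pair}| = 1, partial correlation undefined"
            )
        denom = np.sqrt((1.0 - cij**2) * (1.0 - ckj**2))
    else:
        raw = (1.0 - cij**2) * (1.0 - ckj**2)
        if raw < _Z_DENOM_FLOOR:
            warnings.warn(
                "Fisher-z partial-correlation denominator floored; "
                "result is not a correlation",
                stacklevel=2,
            )
        denom = np.sqrt(max(raw, _Z_DENOM_FLOOR))
    return float((v[i, k] - cij * ckj) / denom)


def influence_d(c: CorrelationMatrix, i: int, k: int, j: int) -> float:
    """Influence of node j on the i-k link: max(0, C(i,k) - PC(i,k|j)).

    Symmetric in (i, k); negatives are floored at zero so that sums never
    mix signed contributions.
    """
    return max(0.0, float(c.values[i, k]) - partial_correlation(c, i, k, j))


def _influence_cube(c: CorrelationMatrix) -> np.ndarray:
    """d[j, i, k] = max(0, C(i,k) - PC(i,k|j)) for all triplets, vectorized.

    Entries with j in {i, k} are set to 0 (they never contribute to any
    aggregate; the k = i slot is identically 0 by construction anyway).
    """
    v = c.values
    n = c.n
    cj = v.T  # cj[j, i] = C(i, j)
    if c.transform == "raw_r":
        one_minus = 1.0 - cj**2
    else:
        one_minus = np.maximum(1.0 - cj**2, _Z_DENOM_FLOOR)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(one_minus[:, :, None] * one_minus[:, None, :])
        pc = (v[None, :, :] - cj[:, :, None] * cj[:, None, :]) / denom
    d = v[None, :, :] - pc
    d = np.where(np.isfinite(d), d, 0.0)
    np.maximum(d, 0.0, out=d)
    idx = np.arange(n)
    d[idx, idx, :] = 0.0  # i == j
    d[idx, :, idx] = 0.0  # k == j
    d[:, idx, idx] = 0.0  # k == i (identically 0 in exact arithmetic)
    return d


def dependency_matrix(
    c: CorrelationMatrix, condition_tag: str = ""
) -> DependencyMatrix:
    """Dependency matrix D with D(i,j) = mean over k != j of d(i,k|j).

    The k = i term is included in the sum as written (it contributes
    exactly zero since C(i,i) = 1 implies PC(i,i|j) = 1); the normalizer
    is N - 1.  The diagonal is forced to zero.
    """
    n = c.n
    if n < 3:
        raise ValueError("dependency matrix needs N >= 3 nodes")
    if c.transform == "raw_r":
        off = np.abs(c.values - np.eye(n))
        if np.any(off >= 1.0):
            i, j = np.argwhere(off >= 1.0)[0]
            raise ValueError(
                f"degenerate conditioning: |C({i},{j})| = 1; "
                "use fisher_z transform with clipping or fix the input"
            )
    d = _influence_cube(c)
    # D(i, j) = (1/(N-1)) * sum_{k != j} d[j, i, k]; the cube already has
    # the k = j slot zeroed, so a plain sum over k is the Eq-3 sum.
    dep = d.sum(axis=2).T / (n - 1)
    np.fill_diagonal(dep, 0.0)
    return DependencyMatrix(dep, condition_tag, c.labels)


def influencing_degree(dm: DependencyMatrix) -> InfluenceProfile:
    """System-level out-influence of each node: score(j) = sum_{i != j} D(i,j)."""
    v = dm.values
    scores = v.sum(axis=0)  # diagonal is zero, so this is the i != j sum
    labels = dm.labels if dm.labels is not None else tuple(
        f"node{i}" for i in range(dm.n)
    )
    return InfluenceProfile(
        "global_degree", {lbl: float(s) for lbl, s in zip(labels, scores)}, agg="sum"
    )


# ---------------------------------------------------------------------------
# network-restricted variants


def _net_indices(c: CorrelationMatrix, roiset: RoiSet, net: str) -> Tuple[int, ...]:
    if c.labels is not None and tuple(c.labels) != tuple(roiset.labels):
        raise ValueError("correlation-matrix labels do not match the RoiSet order")
    if c.n != len(roiset):
        raise ValueError("correlation matrix size does not match the RoiSet")
    return roiset.member_indices(net)


def intra_network_influence(
    c: CorrelationMatrix,
    roiset: RoiSet,
    net: str,
    mode: Literal["subnetwork", "masked_full"] = "subnetwork",
) -> InfluenceProfile:
    """Each member's influence on links inside its own sub-network.

    ``subnetwork`` (default) recomputes the whole dependency pipeline on the
    sub-network's node set alone — conditioning triplets never leave the
    sub-network — and sums each node's dependency column, exactly the
    global pipeline applied to the sub-matrix.  ``masked_full`` instead
    masks the full-network dependency matrix to within-network entries.
    """
    idx = _net_indices(c, roiset, net)
    members = roiset.members(net)
    if len(idx) < 3:
        raise ValueError(f"network {net!r} has {len(idx)} members; need >= 3")
    if mode == "subnetwork":
        sub = CorrelationMatrix(
            c.values[np.ix_(idx, idx)], c.transform, tuple(members)
        )
        dep = dependency_matrix(sub)
        prof = influencing_degree(dep)
        scores = prof.scores
    elif mode == "masked_full":
        dep = dependency_matrix(c)
        block = dep.values[np.ix_(idx, idx)]
        scores = {lbl: float(s) for lbl, s in zip(members, block.sum(axis=0))}
    else:
        raise ValueError(f"unknown intra mode {mode!r}")
    return InfluenceProfile("intra", scores, source_network=net, target_network=net,
                            agg="sum")


def inter_network_influence_within(
    c: CorrelationMatrix,
    roiset: RoiSet,
    source_net: str,
    target_net: str,
    agg: Literal["mean", "sum"] = "mean",
) -> InfluenceProfile:
    """Influence of each source-network node on links *within* the target
    network: aggregate of d(i,k|j) over unordered pairs {i,k} in the target
    network, each pair counted once."""
    if source_net == target_net:
        raise ValueError("source and target networks must differ")
    src = _net_indices(c, roiset, source_net)
    tgt = _net_indices(c, roiset, target_net)
    if len(tgt) < 2:
        raise ValueError(f"target network {target_net!r} needs >= 2 members")
    d = _influence_cube(c)
    tgt_arr = np.array(tgt)
    iu, ku = np.triu_indices(len(tgt), k=1)
    pair_i, pair_k = tgt_arr[iu], tgt_arr[ku]
    scores = {}
    for j, lbl in zip(src, roiset.members(source_net)):
        vals = d[j, pair_i, pair_k]
        scores[lbl] = float(vals.mean() if agg == "mean" else vals.sum())
    return InfluenceProfile(
        "inter_within_other", scores, source_network=source_net,
        target_network=target_net, agg=agg,
    )


def inter_network_influence_between(
    c: CorrelationMatrix,
    roiset: RoiSet,
    source_net: str,
    target_net: str,
    agg: Literal["mean", "sum"] = "mean",
) -> InfluenceProfile:
    """Influence of each source-network node j on links *between* the two
    networks: aggregate of d(i,k|j) over i in the target network and k in
    the source network excluding j itself."""
    if source_net == target_net:
        raise ValueError("source and target networks must differ")
    src = _net_indices(c, roiset, source_net)
    tgt = _net_indices(c, roiset, target_net)
    if len(src) < 2:
        raise ValueError(
            f"source network {source_net!r} needs >= 2 members to form cross links"
        )
    d = _influence_cube(c)
    scores = {}
    for j, lbl in zip(src, roiset.members(source_net)):
        ks = [k for k in src if k != j]
        vals = d[j][np.ix_(tgt, ks)]
        scores[lbl] = float(vals.mean() if agg == "mean" else vals.sum())
    return InfluenceProfile(
        "inter_between", scores, source_network=source_net,
        target_network=target_net, agg=agg,
    )


def total_inter_network_influence(profile: InfluenceProfile) -> float:
    """Total influence of one network on the other: sum of the per-node
    inter-network scores."""
    if profile.scheme not in INTER_SCHEMES:
        raise ValueError(
            f"total inter-network influence requires an inter-network profile, "
            f"got scheme {profile.scheme!r}"
        )
    return float(sum(profile.scores.values()))
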