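"""Group-level inference on influence measures.

Condition contrasts (paired t per node with Benjamini–Hochberg FDR),
edgewise dependency-difference graphs, behavior correlations with an
outlier rule, and an empirical specificity test that compares an observed
statistic against the same statistic recomputed on random node sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Iterable, Literal, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupResult",
    "paired_condition_ttest",
    "bh_fdr",
    "edge_contrast_graph",
    "behavior_correlation",
    "specificity_bootstrap",
    "bootstrap_stats_from_pool",
]


@dataclass
class GroupResult:
    """Per-node paired-t contrast (high minus low) with BH-adjusted q."""

    label: str
    t: float
    p: float
    q: float
    df: int
    direction: int  # sign of mean(high - low)
    mean_low: float
    sd_low: float
    mean_high: float
    sd_high: float
    zero_variance: bool = False


def _paired_t(diff: np.ndarray) -> Tuple[float, float, bool]:
    """Two-tailed paired t on a difference vector; degenerate zero-variance
    differences yield signed infinity (p -> 0) with an explicit flag rather
    than NaN."""
    n = diff.size
    sd = diff.std(ddof=1)
    if sd == 0:
        m = diff.mean()
        if m == 0:
            return 0.0, 1.0, True
        return float(np.sign(m) * np.inf), 0.0, True
    t = diff.mean() / (sd / np.sqrt(n))
    p = 2 * sps.t.sf(abs(t), df=n - 1)
    return float(t), float(p), False


def paired_condition_ttest(
    scores_low: pd.DataFrame,
    scores_high: pd.DataFrame,
    fdr_m: Optional[int] = None,
) -> pd.DataFrame:
    """Per-node paired t-test of influence scores between two conditions.

    Parameters
    ----------
    scores_low, scores_high
        Subjects x nodes tables, identically indexed (same subjects) and
        identically labeled columns.
    fdr_m
        Number of tests for the BH correction; defaults to the number of
        nodes tested.

    Returns
    -------
    DataFrame indexed by node with columns
    ``mean_low, sd_low, mean_high, sd_high, t, df, p, q, direction,
    zero_variance``, with high minus low as the tested difference.
    """
    if list(scores_low.index) != list(scores_high.index):
        raise ValueError("conditions must contain the same subjects in the same order")
    if list(scores_low.columns) != list(scores_high.columns):
        raise ValueError("conditions must share node labels")
    n = len(scores_low)
    if n < 3:
        raise ValueError("paired t-test needs at least 3 subjects")
    rows = []
    for col in scores_low.columns:
        lo = scores_low[col].to_numpy(float)
        hi = scores_high[col].to_numpy(float)
        t, p, degenerate = _paired_t(hi - lo)
        rows.append(
            dict(
                label=col,
                mean_low=lo.mean(), sd_low=lo.std(ddof=1),
                mean_high=hi.mean(), sd_high=hi.std(ddof=1),
                t=t, df=n - 1, p=p,
                direction=int(np.sign(hi.mean() - lo.mean())),
                zero_variance=degenerate,
            )
        )
    out = pd.DataFrame(rows).set_index("label")
    # degenerate zero-variance rows carry p = 0; floor them for the BH step
    p_for_fdr = np.clip(out["p"].to_numpy(), np.finfo(float).tiny, 1.0)
    out["q"] = bh_fdr(p_for_fdr, m=fdr_m or len(out))
    return out[["mean_low", "sd_low", "mean_high", "sd_high",
                "t", "df", "p", "q", "direction", "zero_variance"]]


def bh_fdr(pvals: Sequence[float], m: Optional[int] = None) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    ``m`` is the family size; it may exceed ``len(pvals)`` when only a
    subset of a larger family is being adjusted (the extra tests are
    treated as p = 1, which leaves the step-up minimum of the observed
    entries intact).
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-D vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = int(m) if m is not None else p.size
    if m < p.size:
        raise ValueError("family size m cannot be smaller than len(pvals)")
    padded = np.concatenate([p, np.ones(m - p.size)])
    _, q, _, _ = multipletests(padded, method="fdr_bh")
    return q[: p.size]


def edge_contrast_graph(
    dep_low: np.ndarray,
    dep_high: np.ndarray,
    labels: Sequence[str],
    alpha: float = 0.05,
    node_scores: Optional[Dict[str, float]] = None,
) -> nx.DiGraph:
    """Directed graph of dependency entries that differ between conditions.

    Parameters
    ----------
    dep_low, dep_high
        Subject-aligned stacks of dependency matrices, shape (S, N, N);
        entry (i, j) is the influence of node j on node i.
    alpha
        Per-edge two-tailed threshold; entries with p < alpha become
        edges j -> i (the direction of influence).
    node_scores
        Optional per-node attribute (e.g., the condition-difference
        influencing degree) attached to the nodes.

    Each retained edge carries ``t``, ``p`` and ``direction`` (sign of the
    high-minus-low difference).
    """
    dep_low = np.asarray(dep_low, float)
    dep_high = np.asarray(dep_high, float)
    if dep_low.shape != dep_high.shape or dep_low.ndim != 3:
        raise ValueError("dependency stacks must be aligned (S, N, N) arrays")
    s, n, n2 = dep_low.shape
    if n != n2 or n != len(labels):
        raise ValueError("stack width must match the label list")
    g = nx.DiGraph()
    for idx, lbl in enumerate(labels):
        attrs = {"index": idx}
        if node_scores is not None:
            attrs["score"] = float(node_scores.get(lbl, 0.0))
        g.add_node(lbl, **attrs)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            t, p, _ = _paired_t(dep_high[:, i, j] - dep_low[:, i, j])
            if p < alpha:
                g.add_edge(
                    labels[j], labels[i], t=t, p=p,
                    direction=int(np.sign(t)) if np.isfinite(t) else int(np.sign(t)),
                )
    return g


def behavior_correlation(
    delta_scores: pd.Series,
    behavior: pd.Series,
    exclusion_sd: float = 3.0,
) -> Tuple[float, float, int]:
    """Pearson correlation between per-subject influence differences and a
    behavioral measure.

    Missing behavior entries are dropped listwise; subjects whose value on
    either variable deviates from that variable's mean by more than
    ``exclusion_sd`` standard deviations are excluded.  Returns
    ``(r, p, n_used)``.
    """
    df = pd.concat({"delta": delta_scores, "behavior": behavior}, axis=1).dropna()
    if len(df) < 4:
        raise ValueError(f"need >= 4 complete pairs, got {len(df)}")
    keep = np.ones(len(df), dtype=bool)
    for col in ("delta", "behavior"):
        x = df[col].to_numpy(float)
        sd = x.std(ddof=1)
        if sd > 0:
            keep &= np.abs(x - x.mean()) <= exclusion_sd * sd
    df = df[keep]
    if len(df) < 4:
        raise ValueError(f"fewer than 4 pairs remain after outlier exclusion")
    r, p = sps.pearsonr(df["delta"], df["behavior"])
    return float(r), float(p), int(len(df))


def specificity_bootstrap(
    observed_stat: float,
    random_stats: Iterable[float],
    mode: Literal["tstat", "correlation"] = "tstat",
    literal_count: bool = False,
) -> float:
    """Empirical p-value of an observed statistic against a random-network
    background distribution.

    By default the p-value counts random statistics *at least as extreme as
    the observed one in its direction* — for ``tstat`` that is
    ``random >= observed`` (the observed t is a planted increase); for
    ``correlation`` the tail follows the observed sign — with add-one
    smoothing: ``p = (count + 1) / (k + 1)``.  ``literal_count=True``
    instead counts random values *smaller or equal* to the observed one
    (the historical printed formula), which rewards unremarkable findings
    and is kept only for reproduction.
    """
    rand = np.asarray(list(random_stats), dtype=float)
    k = rand.size
    if k < 1:
        raise ValueError("need at least one random statistic")
    if literal_count:
        count = int(np.sum(rand <= observed_stat))
    elif mode == "tstat":
        count = int(np.sum(rand >= observed_stat))
    elif mode == "correlation":
        if observed_stat >= 0:
            count = int(np.sum(rand >= observed_stat))
        else:
            count = int(np.sum(rand <= observed_stat))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return (count + 1) / (k + 1)


def bootstrap_stats_from_pool(
    pool: np.ndarray,
    n_nodes: int,
    stat_fn: Callable[[np.ndarray], float],
    k: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Background distribution of ``stat_fn`` over random size-matched node
    sets drawn (without replacement, per draw) from a pool of candidate
    node time series.

    ``pool`` has shape (n_pool, T); each of the ``k`` draws selects
    ``n_nodes`` rows and hands the resulting (T, n_nodes) matrix to
    ``stat_fn``.
    """
    pool = np.asarray(pool, float)
    if pool.ndim != 2:
        raise ValueError("pool must be a (n_pool, T) array")
    if pool.shape[0] < n_nodes:
        raise ValueError(
            f"pool of {pool.shape[0]} candidate nodes is smaller than the "
            f"network size {n_nodes}"
        )
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = rng or np.random.default_rng()
    out = np.empty(k)
    for b in range(k):
        idx = rng.choice(pool.shape[0], size=n_nodes, replace=False)
        out[b] = stat_fn(pool[idx].T)
    return out
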