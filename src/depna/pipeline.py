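"""End-to-end analysis pipeline.

Epoch selection from ratings → per-subject, per-condition dependency
analysis (global, intra-network, both inter-network variants, totals) →
group condition contrasts with BH-FDR → edgewise contrast graph exports →
behavior correlations → optional random-network specificity bootstrap.
Everything is driven by a :class:`PipelineConfig` and is deterministic
given identical inputs and seed.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as dio
from .core import (
    CorrelationMatrix,
    SubjectTimeSeries,
    dependency_matrix,
    fisher_z,
    influencing_degree,
    inter_network_influence_between,
    inter_network_influence_within,
    intra_network_influence,
    pearson_correlations,
    standardize_columns,
    total_inter_network_influence,
)
from .epochs import epochs_to_tr, find_epoch_pair
from .roi import REACTIVITY, REGULATION, RoiSet
from .stats import (
    behavior_correlation,
    bootstrap_stats_from_pool,
    edge_contrast_graph,
    paired_condition_ttest,
    specificity_bootstrap,
)
from .synth import simulate_null_pool

log = logging.getLogger("depna")

SCHEMES = ("global_degree", "intra_regulation", "inter_within_reactivity",
           "inter_between")


@dataclass
class PipelineConfig:
    """Paths and options for one pipeline run."""

    manifest: str
    roiset: str
    ratings: Optional[str] = None
    behavior: Optional[str] = None
    out_dir: str = "depna_out"
    tr_seconds: float = 3.0
    # epoch search
    epoch_alpha: float = 0.01
    epoch_pairing: str = "subjects"
    lag_seconds: float = 0.0
    rating_rate_hz: float = 10.0
    # dependency options
    correlation_transform: str = "raw_r"  # or "fisher_z"
    intra_mode: str = "subnetwork"  # or "masked_full"
    inter_agg: str = "mean"  # or "sum"
    standardize_epochs: bool = True
    # group stats
    alpha_edges: float = 0.05
    fdr_q: float = 0.05
    exclusion_sd: float = 3.0
    bootstrap_k: int = 0  # 0 disables the specificity stage
    bootstrap_pool_size: int = 200
    literal_eq5: bool = False
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) \
            else json.loads(text)
        return cls(**data)

    def validate(self) -> None:
        for name in ("manifest", "roiset"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")
        if self.correlation_transform not in ("raw_r", "fisher_z"):
            raise ValueError("correlation_transform must be raw_r or fisher_z")
        if self.intra_mode not in ("subnetwork", "masked_full"):
            raise ValueError("intra_mode must be subnetwork or masked_full")
        if self.inter_agg not in ("mean", "sum"):
            raise ValueError("inter_agg must be mean or sum")


def _condition_correlation(
    ts: SubjectTimeSeries, start: int, stop: int, cfg: PipelineConfig, tag: str
) -> CorrelationMatrix:
    win = ts.window(start, stop, tag)
    if cfg.standardize_epochs:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            win = SubjectTimeSeries(
                win.subject_id, standardize_columns(win.data),
                win.tr_seconds, win.roiset,
            )
    c = pearson_correlations(win)
    if cfg.correlation_transform == "fisher_z":
        c = fisher_z(c)
    return c


def subject_condition_profiles(
    c: CorrelationMatrix, roiset: RoiSet, cfg: PipelineConfig
) -> Dict[str, Dict[str, float]]:
    """All four influence aggregates for one correlation matrix."""
    dep = dependency_matrix(c)
    out: Dict[str, Dict[str, float]] = {}
    out["global_degree"] = influencing_degree(dep).scores
    out["intra_regulation"] = intra_network_influence(
        c, roiset, REGULATION, mode=cfg.intra_mode
    ).scores
    out["inter_within_reactivity"] = inter_network_influence_within(
        c, roiset, REGULATION, REACTIVITY, agg=cfg.inter_agg
    ).scores
    out["inter_between"] = inter_network_influence_between(
        c, roiset, REGULATION, REACTIVITY, agg=cfg.inter_agg
    ).scores
    return out


def random_network_tstats(
    n_subjects: int,
    n_nodes: int,
    t_len: int,
    k: int,
    pool_size: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Background distribution of condition-contrast t-values on random
    node sets.

    For each of the ``k`` draws a size-matched random network is selected
    from a pool of null candidate node series (a synthetic stand-in for
    random gray-matter regions, one pool per subject and condition), the
    identical dependency analysis is run for every subject in both
    conditions, and the draw's statistic is the maximum per-node paired t.
    """
    rng = np.random.default_rng(seed)
    pools_lo = [simulate_null_pool(n_nodes, t_len, pool_size,
                                   int(rng.integers(2**31)))
                for _ in range(n_subjects)]
    pools_hi = [simulate_null_pool(n_nodes, t_len, pool_size,
                                   int(rng.integers(2**31)))
                for _ in range(n_subjects)]
    from .stats import _paired_t

    out = np.empty(k)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for b in range(k):
            idx = rng.choice(pool_size, size=n_nodes, replace=False)
            degrees = {"low": [], "high": []}
            for s in range(n_subjects):
                for tag, pool in (("low", pools_lo[s]), ("high", pools_hi[s])):
                    ts = SubjectTimeSeries(f"rand{s}", pool[idx].T, 1.0)
                    dep = dependency_matrix(pearson_correlations(ts))
                    degrees[tag].append(dep.values.sum(axis=0))
            lo = np.vstack(degrees["low"])
            hi = np.vstack(degrees["high"])
            tvals = [
                _paired_t(hi[:, j] - lo[:, j])[0] for j in range(n_nodes)
            ]
            out[b] = max(tvals)
    return out


def run_pipeline(cfg: PipelineConfig) -> Dict[str, object]:
    """Execute the full workflow and write the result bundle to
    ``cfg.out_dir``.  Returns the in-memory results keyed by stage."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    roiset = dio.read_roiset(cfg.roiset)
    series = dio.read_cohort_timeseries(cfg.manifest, cfg.tr_seconds, roiset)
    if not series:
        raise RuntimeError("epochs stage: manifest lists no subjects")
    results: Dict[str, object] = {}

    # ---- epochs -----------------------------------------------------------
    if cfg.ratings is not None and Path(cfg.ratings).exists():
        traces = dio.read_ratings(cfg.ratings, cfg.rating_rate_hz)
        pair = find_epoch_pair(traces, alpha=cfg.epoch_alpha,
                               pairing=cfg.epoch_pairing)  # type: ignore[arg-type]
        pair = epochs_to_tr(pair, cfg.tr_seconds, cfg.lag_seconds)
    else:
        # no ratings: split each run into equal halves (low first)
        t = series[0].n_timepoints
        half_s = (t // 2) * cfg.tr_seconds
        from .epochs import EpochPair

        pair = epochs_to_tr(
            EpochPair((0.0, half_s), (half_s, 2 * half_s), wilcoxon_p=float("nan")),
            cfg.tr_seconds,
        )
        log.warning("no ratings supplied; using first/second half as low/high")
    dio.write_epochs(pair, out / "epochs.json")
    results["epochs"] = pair
    lo_win = pair.tr_windows["low"]
    hi_win = pair.tr_windows["high"]

    # ---- per-subject dependency analysis ---------------------------------
    subject_ids = [ts.subject_id for ts in series]
    profiles = {s: {"low": None, "high": None} for s in subject_ids}
    dep_stacks = {"low": [], "high": []}
    for ts in series:
        for tag, (a, b) in (("low", lo_win), ("high", hi_win)):
            try:
                c = _condition_correlation(ts, a, b, cfg, tag)
            except ValueError as err:
                raise RuntimeError(f"depna stage: {err}") from err
            profiles[ts.subject_id][tag] = subject_condition_profiles(c, roiset, cfg)
            dep_stacks[tag].append(dependency_matrix(c, tag).values)

    scheme_tables: Dict[str, Dict[str, pd.DataFrame]] = {}
    for scheme in SCHEMES:
        tabs = {}
        for tag in ("low", "high"):
            tabs[tag] = pd.DataFrame(
                {s: profiles[s][tag][scheme] for s in subject_ids}
            ).T.loc[subject_ids]
            tabs[tag].index.name = "subject_id"
            tabs[tag].to_csv(out / f"influence_{scheme}_{tag}.csv")
        scheme_tables[scheme] = tabs
    results["influence"] = scheme_tables

    totals = {
        tag: scheme_tables["inter_within_reactivity"][tag].sum(axis=1)
        for tag in ("low", "high")
    }
    pd.DataFrame(totals).rename_axis("subject_id").to_csv(
        out / "total_inter_network_influence.csv"
    )
    results["total_inter"] = totals

    # ---- group contrasts --------------------------------------------------
    contrasts = {}
    for scheme, tabs in scheme_tables.items():
        res = paired_condition_ttest(tabs["low"], tabs["high"])
        res.to_csv(out / f"contrast_{scheme}.csv")
        contrasts[scheme] = res
    # total inter-network influence: a single paired test
    tot = paired_condition_ttest(
        pd.DataFrame({"total": totals["low"]}),
        pd.DataFrame({"total": totals["high"]}),
    )
    tot.to_csv(out / "contrast_total_inter.csv")
    contrasts["total_inter"] = tot
    results["contrasts"] = contrasts

    # ---- edge contrast graph ---------------------------------------------
    deg = contrasts["global_degree"]
    node_scores = (deg["mean_high"] - deg["mean_low"]).to_dict()
    g = edge_contrast_graph(
        np.stack(dep_stacks["low"]), np.stack(dep_stacks["high"]),
        list(roiset.labels), alpha=cfg.alpha_edges, node_scores=node_scores,
    )
    dio.write_graphml(g, out / "edge_contrast.graphml")
    dio.write_brainnet(g, roiset, out / "edge_contrast.node",
                       out / "edge_contrast.edge")
    results["graph"] = g

    # ---- behavior correlations -------------------------------------------
    behav_rows = []
    if cfg.behavior is not None and Path(cfg.behavior).exists():
        behavior = dio.read_behavior(cfg.behavior)
        sig = deg.index[deg["q"] < cfg.fdr_q].tolist()
        for node in sig:
            delta = (
                scheme_tables["global_degree"]["low"][node]
                - scheme_tables["global_degree"]["high"][node]
            )
            for col in behavior.columns:
                if col.startswith("beta_"):
                    continue
                try:
                    r, p, n_used = behavior_correlation(
                        delta, behavior[col], cfg.exclusion_sd
                    )
                except ValueError as err:
                    log.warning("behavior correlation %s/%s skipped: %s",
                                node, col, err)
                    continue
                behav_rows.append(dict(node=node, measure=col, r=r, p=p,
                                       n_used=n_used))
        pd.DataFrame(
            behav_rows, columns=["node", "measure", "r", "p", "n_used"]
        ).to_csv(out / "behavior_correlations.csv", index=False)
    else:
        log.warning("behavior stage skipped: no behavior table supplied")
    results["behavior"] = behav_rows

    # ---- specificity bootstrap -------------------------------------------
    if cfg.bootstrap_k > 0:
        hub = deg["t"].abs().idxmax()
        observed_t = float(deg.loc[hub, "t"])
        rand_stats = random_network_tstats(
            n_subjects=len(subject_ids),
            n_nodes=len(roiset),
            t_len=lo_win[1] - lo_win[0],
            k=cfg.bootstrap_k,
            pool_size=cfg.bootstrap_pool_size,
            seed=cfg.seed,
        )
        p_spec = specificity_bootstrap(observed_t, rand_stats, mode="tstat",
                                       literal_count=cfg.literal_eq5)
        spec_payload = {"node": hub, "observed_t": observed_t,
                        "k": cfg.bootstrap_k, "p": p_spec}
        (out / "specificity.json").write_text(
            json.dumps(spec_payload, indent=2, sort_keys=True) + "\n"
        )
        results["specificity"] = spec_payload

    # ---- provenance -------------------------------------------------------
    prov = {k: v for k, v in asdict(cfg).items() if k != "out_dir"}
    prov["software_version"] = __version__
    prov["n_subjects"] = len(subject_ids)
    prov["n_rois"] = len(roiset)
    dio.write_provenance(prov, out / "provenance.json")
    return results
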