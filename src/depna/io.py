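"""Readers and writers for the package's file layout.

All tabular data are plain delimited text: per-subject ROI time series
(header row of ROI labels) listed in a manifest, an ROI roster CSV,
rating traces in long or wide CSV, and a behavior table.  Graphs export
to BrainNet-Viewer ``.node``/``.edge`` text files and GraphML; matrices
to labeled CSV with a JSON sidecar recording config, seed and version.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd

from .core import SubjectTimeSeries
from .epochs import EpochPair, RatingTrace
from .roi import RoiSet
from .synth import Cohort

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# RoiSet

def read_roiset(path: PathLike) -> RoiSet:
    """Load an ROI roster CSV with columns label, network[, x, y, z]."""
    df = pd.read_csv(path)
    required = {"label", "network"}
    if not required.issubset(df.columns):
        raise ValueError(f"ROI roster must have columns {sorted(required)}")
    coords = None
    if {"x", "y", "z"}.issubset(df.columns) and df[["x", "y", "z"]].notna().all(axis=None):
        coords = {
            str(r.label): (float(r.x), float(r.y), float(r.z))
            for r in df.itertuples()
        }
    return RoiSet(
        tuple(str(l) for l in df["label"]),
        {str(r.label): str(r.network) for r in df.itertuples()},
        coords,
    )


def write_roiset(roiset: RoiSet, path: PathLike) -> None:
    roiset.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# time series + manifest

def write_timeseries(ts: SubjectTimeSeries, path: PathLike) -> None:
    labels = ts.roiset.labels if ts.roiset is not None else [
        f"node{i}" for i in range(ts.n_rois)
    ]
    pd.DataFrame(ts.data, columns=list(labels)).to_csv(path, index=False)


def read_timeseries(
    path: PathLike, subject_id: str, tr_seconds: float, roiset: Optional[RoiSet] = None
) -> SubjectTimeSeries:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if roiset is not None:
        missing = [l for l in roiset.labels if l not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing ROI columns {missing}")
        df = df[list(roiset.labels)]
    return SubjectTimeSeries(subject_id, df.to_numpy(float), tr_seconds, roiset)


def write_manifest(mapping: Dict[str, PathLike], path: PathLike) -> None:
    """Manifest CSV mapping subject_id -> time-series file path."""
    pd.DataFrame(
        {"subject_id": list(mapping), "path": [str(p) for p in mapping.values()]}
    ).to_csv(path, index=False)


def read_manifest(path: PathLike) -> Dict[str, Path]:
    df = pd.read_csv(path)
    base = Path(path).parent
    out = {}
    for r in df.itertuples():
        p = Path(str(r.path))
        out[str(r.subject_id)] = p if p.is_absolute() else base / p
    return out


def read_cohort_timeseries(
    manifest_path: PathLike, tr_seconds: float, roiset: Optional[RoiSet] = None
) -> List[SubjectTimeSeries]:
    return [
        read_timeseries(p, sid, tr_seconds, roiset)
        for sid, p in read_manifest(manifest_path).items()
    ]


# ---------------------------------------------------------------------------
# ratings

def write_ratings(traces: Sequence[RatingTrace], path: PathLike) -> None:
    """Long-format CSV: subject_id, t_seconds, value."""
    frames = []
    for tr in traces:
        frames.append(pd.DataFrame({
            "subject_id": tr.subject_id,
            "t_seconds": tr.times_s,
            "value": tr.samples,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_ratings(
    path: PathLike, rate_hz: float = 10.0, scale_levels: int = 21
) -> List[RatingTrace]:
    """Read rating traces from long CSV (subject_id, t_seconds, value) or
    wide CSV (t_seconds plus one column per subject)."""
    df = pd.read_csv(path)
    traces = []
    if {"subject_id", "value"}.issubset(df.columns):
        for sid, grp in df.groupby("subject_id", sort=False):
            grp = grp.sort_values("t_seconds") if "t_seconds" in grp else grp
            traces.append(RatingTrace(str(sid), grp["value"].to_numpy(float),
                                      rate_hz, scale_levels))
    else:
        cols = [c for c in df.columns if c != "t_seconds"]
        for c in cols:
            traces.append(RatingTrace(str(c), df[c].to_numpy(float),
                                      rate_hz, scale_levels))
    if not traces:
        raise ValueError(f"no rating traces found in {path}")
    return traces


# ---------------------------------------------------------------------------
# behavior

def read_behavior(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ValueError("behavior table must have a subject_id column")
    return df.set_index("subject_id")


def write_behavior(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, index=True)


# ---------------------------------------------------------------------------
# matrices, epochs, provenance

def write_matrix(
    values: np.ndarray, labels: Sequence[str], path: PathLike,
    sidecar: Optional[dict] = None,
) -> None:
    """Labeled CSV matrix; optional JSON sidecar (config/seed/version)."""
    pd.DataFrame(values, index=list(labels), columns=list(labels)).to_csv(path)
    if sidecar is not None:
        Path(str(path) + ".json").write_text(
            json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
        )


def read_matrix(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_epochs(pair: EpochPair, path: PathLike) -> None:
    payload = {
        "low_window_s": list(pair.low_window),
        "high_window_s": list(pair.high_window),
        "length_s": pair.length_s,
        "wilcoxon_p": pair.wilcoxon_p,
        "median_diff": pair.median_diff,
        "tr_windows": pair.tr_windows,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_epochs(path: PathLike) -> EpochPair:
    d = json.loads(Path(path).read_text())
    return EpochPair(
        low_window=tuple(d["low_window_s"]),
        high_window=tuple(d["high_window_s"]),
        wilcoxon_p=d["wilcoxon_p"],
        median_diff=d.get("median_diff", float("nan")),
        tr_windows=d.get("tr_windows"),
    )


def write_provenance(info: dict, path: PathLike) -> None:
    Path(path).write_text(json.dumps(info, indent=2, sort_keys=True, default=str) + "\n")


# ---------------------------------------------------------------------------
# graph exports

def write_brainnet(
    g: nx.DiGraph, roiset: RoiSet, node_path: PathLike, edge_path: PathLike,
) -> None:
    """BrainNet-Viewer text files: ``.node`` rows are ``x y z color size
    label``; ``.edge`` is the N x N signed t-value adjacency (row = source).

    Nodes are colored by network (1 = reactivity, 2 = regulation) and sized
    by their ``score`` attribute when present.  Missing coordinates export
    as zeros.
    """
    labels = list(roiset.labels)
    lines = []
    for lbl in labels:
        x = y = z = 0.0
        if roiset.coords_mm is not None and lbl in roiset.coords_mm:
            x, y, z = roiset.coords_mm[lbl]
        color = 1 if roiset.network[lbl] == "reactivity" else 2
        size = g.nodes[lbl].get("score", 1.0) if lbl in g else 1.0
        lines.append(
            f"{x:.3f}\t{y:.3f}\t{z:.3f}\t{color}\t{size:.6f}\t{lbl.replace(' ', '_')}"
        )
    Path(node_path).write_text("\n".join(lines) + "\n")
    n = len(labels)
    adj = np.zeros((n, n))
    idx = {lbl: i for i, lbl in enumerate(labels)}
    for u, v, attrs in g.edges(data=True):
        adj[idx[u], idx[v]] = attrs.get("t", 1.0)
    Path(edge_path).write_text(
        "\n".join("\t".join(f"{x:.6f}" for x in row) for row in adj) + "\n"
    )


def write_graphml(g: nx.DiGraph, path: PathLike) -> None:
    nx.write_graphml(g, str(path))


# ---------------------------------------------------------------------------
# simulated-cohort layout

def write_cohort(cohort: Cohort, out_dir: PathLike) -> Dict[str, Path]:
    """Write the full input layout (roster, manifests, per-subject CSVs,
    ratings, behavior, spec JSON) consumable by the pipeline."""
    out = Path(out_dir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    write_roiset(cohort.spec.roiset, out / "roiset.csv")
    paths["roiset"] = out / "roiset.csv"
    for tag, series in (("low", cohort.low), ("high", cohort.high)):
        mapping = {}
        for ts in series:
            p = out / "timeseries" / f"{ts.subject_id}_{tag}.csv"
            write_timeseries(ts, p)
            mapping[ts.subject_id] = p.relative_to(out)
        mpath = out / f"manifest_{tag}.csv"
        write_manifest(mapping, mpath)
        paths[f"manifest_{tag}"] = mpath
    # one continuous run per subject (low followed by high), for the
    # end-to-end pipeline that re-derives the epochs from the ratings
    mapping = {}
    for lo, hi in zip(cohort.low, cohort.high):
        ts = SubjectTimeSeries(
            lo.subject_id, np.vstack([lo.data, hi.data]), lo.tr_seconds, lo.roiset
        )
        p = out / "timeseries" / f"{ts.subject_id}_run.csv"
        write_timeseries(ts, p)
        mapping[ts.subject_id] = p.relative_to(out)
    write_manifest(mapping, out / "manifest.csv")
    paths["manifest"] = out / "manifest.csv"
    write_ratings(cohort.ratings, out / "ratings.csv")
    paths["ratings"] = out / "ratings.csv"
    write_behavior(cohort.behavior, out / "behavior.csv")
    paths["behavior"] = out / "behavior.csv"
    spec_dict = {
        k: v for k, v in vars(cohort.spec).items() if k != "roiset"
    }
    (out / "cohort_spec.json").write_text(
        json.dumps(spec_dict, indent=2, sort_keys=True) + "\n"
    )
    paths["spec"] = out / "cohort_spec.json"
    return paths
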