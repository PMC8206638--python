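"""Readers and writers for the pipeline's plain-text interchange formats.

Source series sets round-trip either as a directory containing a matrix TSV
(row = ROI, column = sample, full double precision) plus a YAML metadata
sidecar, or as a single HDF5 container; the two layouts parse to identical
objects.  Candidate/edge/null tables are TSV with documented headers, and
metric records are flat JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .connectivity import EdgeCandidate, SurrogateNull
from .core import SourceSeriesSet
from .metrics import MetricsRecord
from .network import Edge, FunctionalNetwork

__all__ = [
    "write_source_series",
    "read_source_series",
    "write_candidates",
    "read_candidates",
    "write_null",
    "write_network",
    "read_network",
    "write_adjacency",
    "write_metrics",
    "write_outcomes",
    "read_outcomes",
]

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


def write_source_series(sset: SourceSeriesSet, path: str | Path, fmt: str = "tsv") -> Path:
    """Write a series set as a TSV directory (default) or an HDF5 file."""
    path = Path(path)
    if fmt == "tsv":
        path.mkdir(parents=True, exist_ok=True)
        np.savetxt(path / "series.tsv", sset.data, fmt=_FLOAT_FMT, delimiter="\t")
        meta = {
            "subject_id": sset.subject_id,
            "timepoint": sset.timepoint,
            "fs": float(sset.fs),
            "roi_labels": list(sset.roi_labels),
        }
        (path / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
        return path
    if fmt == "h5":
        if path.suffix != ".h5":
            path = path.with_suffix(".h5")
        with h5py.File(path, "w") as f:
            d = f.create_dataset("data", data=sset.data)
            d.attrs["subject_id"] = sset.subject_id
            d.attrs["timepoint"] = sset.timepoint
            d.attrs["fs"] = float(sset.fs)
            f.create_dataset(
                "roi_labels", data=np.array(sset.roi_labels, dtype="S")
            )
        return path
    raise ValueError(f"unknown format {fmt!r}; use 'tsv' or 'h5'")


def read_source_series(path: str | Path) -> SourceSeriesSet:
    """Read either layout back; ``read(write(x)) == x`` bit-for-bit."""
    path = Path(path)
    if path.is_dir():
        meta_path = path / "meta.yaml"
        if not meta_path.exists():
            raise FileNotFoundError(f"missing metadata sidecar {meta_path}")
        meta = yaml.safe_load(meta_path.read_text())
        for key in ("subject_id", "timepoint", "fs", "roi_labels"):
            if key not in meta:
                raise KeyError(f"metadata sidecar is missing required field '{key}'")
        data = np.loadtxt(path / "series.tsv", delimiter="\t", ndmin=2)
        return SourceSeriesSet(
            subject_id=str(meta["subject_id"]),
            timepoint=str(meta["timepoint"]),
            fs=float(meta["fs"]),
            roi_labels=[str(x) for x in meta["roi_labels"]],
            data=data,
        )
    with h5py.File(path, "r") as f:
        d = f["data"]
        if "fs" not in d.attrs:
            raise KeyError("HDF5 container is missing required field 'fs'")
        return SourceSeriesSet(
            subject_id=str(d.attrs["subject_id"]),
            timepoint=str(d.attrs["timepoint"]),
            fs=float(d.attrs["fs"]),
            roi_labels=[s.decode() for s in f["roi_labels"][()]],
            data=d[()],
        )


def write_candidates(candidates: list[EdgeCandidate], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "roi_i": [c.pair[0] for c in candidates],
            "roi_j": [c.pair[1] for c in candidates],
            "f_star_Hz": [c.f_star for c in candidates],
            "z_max": [c.z_max for c in candidates],
            "connected": [int(c.connected) for c in candidates],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def read_candidates(path: str | Path) -> list[EdgeCandidate]:
    df = pd.read_csv(path, sep="\t")
    return [
        EdgeCandidate(
            pair=(r.roi_i, r.roi_j),
            f_star=float(r.f_star_Hz),
            z_max=float(r.z_max),
            connected=bool(r.connected),
        )
        for r in df.itertuples()
    ]


def write_null(null: SurrogateNull, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"freq_Hz": null.freqs, "mu": null.mu, "sigma": null.sigma}).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )
    return path


def write_network(net: FunctionalNetwork, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "roi_i": [e.i for e in net.edges],
            "roi_j": [e.j for e in net.edges],
            "f_star_Hz": [e.f_star for e in net.edges],
            "z_max": [e.z_max for e in net.edges],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    labels_path = path.with_suffix(".nodes.tsv")
    pd.DataFrame({"roi": net.node_labels}).to_csv(labels_path, sep="\t", index=False)
    return path


def read_network(path: str | Path) -> FunctionalNetwork:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    labels = pd.read_csv(path.with_suffix(".nodes.tsv"), sep="\t")["roi"].tolist()
    edges = [
        Edge(i=r.roi_i, j=r.roi_j, f_star=float(r.f_star_Hz), z_max=float(r.z_max))
        for r in df.itertuples()
    ]
    return FunctionalNetwork(node_labels=labels, edges=edges)


def write_adjacency(net: FunctionalNetwork, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        net.adjacency_matrix(), index=net.node_labels, columns=net.node_labels
    ).to_csv(path, sep="\t")
    return path


def write_metrics(record: MetricsRecord, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(record.to_dict(), indent=2) + "\n")
    return path


def write_outcomes(outcomes: dict[str, float], path: str | Path, timepoint: str = "free_access") -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "subject_id": list(outcomes),
            "timepoint": timepoint,
            "outcome_g_per_kg": list(outcomes.values()),
        }
    ).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def read_outcomes(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["subject_id"].astype(str), df["outcome_g_per_kg"].astype(float)))
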