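"""Delimited-text file formats and their validation.

Everything on disk is plain text: atlas TSV, connectome TSV with a JSON
sidecar, clinical CSV, and per-run time-series TSVs with companion
motion/task/nuisance TSVs.  Connectome matrices are written with 17
significant digits so a write-then-read round trip is bit-identical.

Edge indexing everywhere: upper triangle, row-major, with 1-based node
ids in files (0-based internally).
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import ParcelAtlas
from .connectivity import Connectome, SubjectRunTimeSeries
from .errors import FormatError

ATLAS_COLUMNS = ["node_id", "node_name", "network", "hemisphere"]
SYMMETRY_TOL = 1e-9


# --- atlas ---------------------------------------------------------------

def read_atlas(path) -> ParcelAtlas:
    """Read and validate an atlas TSV (node_id, node_name, network, ...)."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    missing = set(ATLAS_COLUMNS[:3]) - set(table.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    ids = table["node_id"].to_numpy()
    dup = pd.Series(ids).duplicated()
    if dup.any():
        raise FormatError(
            f"{path}: duplicate node_id {ids[dup.argmax()]} at line {int(dup.idxmax()) + 2}"
        )
    expected = np.arange(1, len(ids) + 1)
    if not np.array_equal(ids, expected):
        bad = int(np.flatnonzero(ids != expected)[0])
        raise FormatError(f"{path}: node_ids not consecutive at line {bad + 2}")
    if "hemisphere" not in table.columns:
        table["hemisphere"] = "subcortical-neutral"
    return ParcelAtlas(table=table, atlas_id=path.stem)


def write_atlas(atlas: ParcelAtlas, path) -> None:
    atlas.table.to_csv(path, sep="\t", index=False)


def packaged_atlas(name: str = "atlas_343_synthetic") -> ParcelAtlas:
    """Load one of the packaged atlas fixtures.

    ``atlas_343_synthetic``: 343 nodes (333 cortical over 12 intrinsic
    networks + 10 subcortical); a synthetic stand-in with the structure,
    not the parcel geometry, of the published template.
    ``atlas_40_test``: 40-node atlas for tests and examples.
    """
    ref = resources.files("ptsdconn") / "data" / f"{name}.tsv"
    with resources.as_file(ref) as p:
        atlas = read_atlas(p)
    return ParcelAtlas(table=atlas.table, atlas_id=name)


# --- connectome ----------------------------------------------------------

def write_connectome(conn: Connectome, path, extra_meta: dict | None = None) -> None:
    """Square TSV with 1-based node-id header/index + JSON sidecar."""
    path = Path(path)
    n = conn.z_matrix.shape[0]
    ids = [str(i) for i in range(1, n + 1)]
    df = pd.DataFrame(conn.z_matrix, index=ids, columns=ids)
    df.to_csv(path, sep="\t", float_format="%.17g", index_label="node_id")
    meta = {
        "subject_id": conn.subject_id,
        "session": conn.session,
        "atlas_id": conn.atlas_id,
        "n_retained_frames": conn.n_retained_frames,
    }
    if extra_meta:
        meta.update(extra_meta)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_connectome(path, atlas: ParcelAtlas | None = None) -> Connectome:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    z = df.to_numpy(dtype=float)
    if z.shape[0] != z.shape[1]:
        raise FormatError(f"{path}: matrix is {z.shape[0]}x{z.shape[1]}, not square")
    if np.isnan(z).any():
        i, j = np.argwhere(np.isnan(z))[0]
        raise FormatError(f"{path}: NaN cell at ({i + 1}, {j + 1})")
    if np.abs(z - z.T).max() > SYMMETRY_TOL:
        raise FormatError(f"{path}: matrix asymmetric beyond {SYMMETRY_TOL}")
    header = [str(c) for c in df.columns]
    expected = [str(i) for i in range(1, z.shape[0] + 1)]
    if header != expected:
        missing = sorted(set(expected) - set(header))
        raise FormatError(
            f"{path}: header does not match 1..{z.shape[0]}"
            + (f"; missing node {missing[0]}" if missing else "")
        )
    if atlas is not None and z.shape[0] != atlas.n_nodes:
        raise FormatError(
            f"{path}: {z.shape[0]} nodes but atlas {atlas.atlas_id} has {atlas.n_nodes}"
        )
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return Connectome(
        subject_id=meta.get("subject_id", path.stem),
        session=meta.get("session", "baseline"),
        z_matrix=z,
        atlas_id=meta.get("atlas_id", atlas.atlas_id if atlas else "unknown"),
        n_retained_frames=int(meta.get("n_retained_frames", 0)),
    )


# --- clinical ------------------------------------------------------------

def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "group"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    bad = ~df["group"].isin(["patient", "control"])
    if bad.any():
        raise FormatError(
            f"{path}: unknown group {df.loc[bad, 'group'].iloc[0]!r}"
        )
    return df


def write_clinical(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


# --- run time series -----------------------------------------------------

def write_run(run: SubjectRunTimeSeries, directory) -> None:
    """Write one run as data/motion/task/nuisance TSVs plus a sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"{run.subject_id}_{run.session}_{run.run_id}"
    n = run.data.shape[0]
    pd.DataFrame(
        run.data, index=[str(i) for i in range(1, n + 1)]
    ).to_csv(directory / f"{stem}_timeseries.tsv", sep="\t",
             float_format="%.17g", index_label="node_id", header=False)
    motion = pd.DataFrame(run.motion_params.T,
                          columns=["tx", "ty", "tz", "rx", "ry", "rz"])
    motion["fd"] = run.fd_trace
    motion.to_csv(directory / f"{stem}_motion.tsv", sep="\t", index=False,
                  float_format="%.17g")
    pd.DataFrame(run.task_covariates.T).to_csv(
        directory / f"{stem}_task.tsv", sep="\t", index=False,
        float_format="%.17g")
    pd.DataFrame(run.nuisance_signals.T).to_csv(
        directory / f"{stem}_nuisance.tsv", sep="\t", index=False,
        float_format="%.17g")
    meta = {
        "subject_id": run.subject_id,
        "session": run.session,
        "run_id": run.run_id,
        "tr_seconds": run.tr_seconds,
    }
    (directory / f"{stem}_meta.json").write_text(json.dumps(meta, indent=2))


def read_run(directory, stem: str) -> SubjectRunTimeSeries:
    directory = Path(directory)
    meta = json.loads((directory / f"{stem}_meta.json").read_text())
    data = pd.read_csv(
        directory / f"{stem}_timeseries.tsv", sep="\t", index_col=0, header=None,
        float_precision="round_trip",
    ).to_numpy(dtype=float)
    motion = pd.read_csv(directory / f"{stem}_motion.tsv", sep="\t")
    fd = motion.pop("fd").to_numpy(dtype=float)
    task_path = directory / f"{stem}_task.tsv"
    task = (pd.read_csv(task_path, sep="\t").to_numpy(dtype=float).T
            if task_path.exists() else np.empty((0, data.shape[1])))
    nuis_path = directory / f"{stem}_nuisance.tsv"
    nuis = (pd.read_csv(nuis_path, sep="\t").to_numpy(dtype=float).T
            if nuis_path.exists() else np.empty((0, data.shape[1])))
    return SubjectRunTimeSeries(
        subject_id=meta["subject_id"],
        session=meta["session"],
        run_id=meta["run_id"],
        data=data,
        tr_seconds=float(meta["tr_seconds"]),
        motion_params=motion.to_numpy(dtype=float).T,
        task_covariates=task,
        nuisance_signals=nuis,
        fd_trace=fd,
    )


# --- NBS / results -------------------------------------------------------

def write_nbs_result(result, atlas: ParcelAtlas, directory, prefix="nbs") -> None:
    """Edge-list TSV (for components) + JSON summary."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nets = atlas.networks
    rows = []
    for cid, comp in enumerate(result.components, start=1):
        for i, j in comp.edges:
            rows.append(
                dict(node_i=i + 1, node_j=j + 1,
                     network_i=nets[i], network_j=nets[j],
                     component_id=cid,
                     corrected_p=float(result.corrected_p[cid - 1]))
            )
    pd.DataFrame(
        rows, columns=["node_i", "node_j", "network_i", "network_j",
                       "component_id", "corrected_p"]
    ).to_csv(directory / f"{prefix}_edges.tsv", sep="\t", index=False)
    summary = {
        "component_sizes": list(map(int, result.component_sizes)),
        "corrected_p": [float(p) for p in result.corrected_p],
        "n_significant_edges": len(result.significant_edges),
        "threshold_p": result.threshold_p,
        "alpha": result.alpha,
        "tail": result.tail,
        "n_perm": result.n_perm,
        "seed": result.seed,
    }
    (directory / f"{prefix}_summary.json").write_text(json.dumps(summary, indent=2))
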