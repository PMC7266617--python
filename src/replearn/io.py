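"""File formats: TSV + JSON-sidecar pattern datasets, RDMs, NIfTI ingestion.

The canonical interchange format is plain text for desk-scale
reproducibility: a ``patterns_<session>.tsv`` matrix (rows = condition x
run, columns = voxels), an optional ``residuals_<session>.tsv``, and a
``sidecar_<session>.json`` holding the row labels and metadata. NIfTI
volumes plus a binary region mask are supported read-only for real data;
masked voxels are flattened in row-major (C) order over the mask with
0-based indices, and that convention is recorded in the sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import GroupMap, Neighborhood, PatternDataset, RDM


def write_pattern_dataset(ds: PatternDataset, directory, session=None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tag = ds.session if session is None else session
    tag = 0 if tag is None else tag
    np.savetxt(directory / f"patterns_{tag}.tsv", ds.data, delimiter="\t")
    sidecar = {
        "condition_id": [int(c) if isinstance(c, (int, np.integer)) else str(c)
                         for c in ds.condition_ids],
        "partition": [int(p) if isinstance(p, (int, np.integer)) else str(p)
                      for p in ds.partition_ids],
        "session": tag if not isinstance(tag, np.integer) else int(tag),
        "n_voxels": int(ds.n_voxels),
        "voxel_order": "row-major over mask, 0-based",
        "dof": None if ds.dof is None else int(ds.dof),
    }
    if ds.sequence_type is not None:
        sidecar["sequence_type"] = {str(k): v for k, v in ds.sequence_type.items()}
    with open(directory / f"sidecar_{tag}.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
    if ds.residuals is not None:
        np.savetxt(directory / f"residuals_{tag}.tsv", ds.residuals,
                   delimiter="\t")


def read_pattern_dataset(directory, session) -> PatternDataset:
    """Read a TSV + JSON-sidecar pattern dataset; validates consistency."""
    directory = Path(directory)
    data = np.loadtxt(directory / f"patterns_{session}.tsv", delimiter="\t",
                      ndmin=2)
    with open(directory / f"sidecar_{session}.json") as fh:
        sidecar = json.load(fh)
    cond = np.asarray(sidecar["condition_id"])
    part = np.asarray(sidecar["partition"])
    if len(cond) != data.shape[0] or len(part) != data.shape[0]:
        raise ValueError(
            f"sidecar rows ({len(cond)}) do not match the pattern matrix "
            f"({data.shape[0]} rows)")
    if data.shape[1] != sidecar.get("n_voxels", data.shape[1]):
        raise ValueError("sidecar n_voxels does not match the matrix")
    if not np.all(np.isfinite(data)):
        raise ValueError("pattern matrix contains non-finite values")
    residuals, dof = None, sidecar.get("dof")
    res_path = directory / f"residuals_{session}.tsv"
    if res_path.exists():
        residuals = np.loadtxt(res_path, delimiter="\t", ndmin=2)
    seq_type = sidecar.get("sequence_type")
    if seq_type is not None:
        seq_type = {type(cond[0].item())(k) if cond.dtype.kind in "iu" else k: v
                    for k, v in seq_type.items()}
    return PatternDataset(
        data=data, condition_ids=cond, partition_ids=part,
        sequence_type=seq_type, session=sidecar.get("session", session),
        residuals=residuals, dof=dof,
    )


def read_nifti_patterns(volumes, mask_path, condition_ids, partition_ids,
                        **kwargs) -> PatternDataset:
    """Build a PatternDataset from NIfTI beta volumes and a region mask.

    ``volumes`` is a list of NIfTI paths (one condition-by-run beta image
    each); voxels where ``mask > 0`` are flattened in row-major order
    (0-based), matching the sidecar convention of the TSV format.
    """
    import nibabel as nib

    mask = np.asanyarray(nib.load(str(mask_path)).dataobj) > 0
    rows = []
    for path in volumes:
        vol = np.asanyarray(nib.load(str(path)).dataobj, dtype=float)
        if vol.shape != mask.shape:
            raise ValueError(f"{path}: volume shape {vol.shape} does not "
                             f"match mask {mask.shape}")
        rows.append(vol[mask])  # row-major (C-order) flattening over mask
    return PatternDataset(data=np.vstack(rows), condition_ids=condition_ids,
                          partition_ids=partition_ids, **kwargs)


def write_rdm(rdm: RDM, path) -> None:
    """RDM as TSV (pair_i, pair_j, value) with a JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        [(a, b, v) for (a, b), v in zip(rdm.pairs, rdm.values)],
        columns=["pair_i", "pair_j", "value"],
    )
    df.to_csv(path, sep="\t", index=False)
    sidecar = {"metric": rdm.metric, "n_conditions": len(rdm.conditions),
               "conditions": [int(c) if isinstance(c, (int, np.integer))
                              else str(c) for c in rdm.conditions],
               "pair_order": "lexicographic in condition_id"}
    if rdm.sequence_type is not None:
        sidecar["sequence_type"] = {str(k): v
                                    for k, v in rdm.sequence_type.items()}
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_rdm(path) -> RDM:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    with open(path.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    seq_type = sidecar.get("sequence_type")
    conds = sidecar["conditions"]
    if seq_type is not None and conds and isinstance(conds[0], int):
        seq_type = {int(k): v for k, v in seq_type.items()}
    return RDM(values=df["value"].to_numpy(), conditions=conds,
               metric=sidecar["metric"], sequence_type=seq_type)


def read_neighborhoods(path) -> list[Neighborhood]:
    """Neighborhood TSV: columns ``center_id`` then member voxel indices
    (whitespace-separated in a ``members`` column)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        members = np.array([int(v) for v in str(row["members"]).split(",")])
        out.append(Neighborhood(center_id=row["center_id"], members=members))
    return out


def write_group_map(gmap: GroupMap, path) -> None:
    """GroupMap as long-format TSV (subject, location, value)."""
    rows = []
    for s in range(gmap.n_subjects):
        for j, loc in enumerate(gmap.location_ids):
            rows.append((s, loc, gmap.data[s, j]))
    pd.DataFrame(rows, columns=["subject", "location", "value"]).to_csv(
        path, sep="\t", index=False)


def read_group_map(path, adjacency_path=None) -> GroupMap:
    df = pd.read_csv(path, sep="\t")
    piv = df.pivot_table(index="subject", columns="location", values="value")
    if piv.isna().any().any():
        raise ValueError("missing subject x location cells")
    adjacency = None
    if adjacency_path is not None:
        adf = pd.read_csv(adjacency_path, sep="\t")
        loc_index = {loc: i for i, loc in enumerate(piv.columns.tolist())}
        adjacency = {}
        for _, row in adf.iterrows():
            adjacency.setdefault(loc_index[row["location"]], []).append(
                loc_index[row["neighbor"]])
    return GroupMap(data=piv.to_numpy(), location_ids=piv.columns.tolist(),
                    adjacency=adjacency)
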