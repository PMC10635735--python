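"""Readers and writers for the on-disk formats the pipeline touches:
4-D NIfTI datasets, TSV onset tables, TSV matrices, YAML/JSON run
configuration and JSON provenance sidecars.

Conventions: onset TSVs use 0-based sample indices and always carry a
``time_s`` column (seconds = index * TR).  The TR is taken from the NIfTI
header (pixdim[4]) unless a config/CLI override is given; a header TR of 0
is treated as missing.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import OnsetTrain

__all__ = [
    "read_nifti_4d",
    "write_nifti",
    "read_onsets_tsv",
    "write_onsets_tsv",
    "read_config",
    "write_sidecar",
    "write_matrix_tsv",
    "read_matrix_tsv",
]

ONSET_COLUMNS = ["voxel_id", "sample_index", "time_s", "detector", "boundary_flag"]


def read_nifti_4d(path, tr: float | None = None):
    """Load a 4-D NIfTI time-series dataset.

    Returns ``(data, affine, tr)``.  The TR comes from the header's
    pixdim[4] unless ``tr`` overrides it; a header TR of 0 counts as
    missing and, without an override, raises.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D time-series NIfTI, got {data.ndim}-D")
    if tr is None:
        header_tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
        if header_tr <= 0:
            raise ValueError("TR missing from header; pass an explicit tr override")
        tr = header_tr
    return data, img.affine, float(tr)


def write_nifti(data: np.ndarray, path, affine=None, tr: float | None = None) -> None:
    """Write an array as NIfTI-1; for 4-D data, records TR in pixdim[4]."""
    data = np.asarray(data)
    affine = np.eye(4) if affine is None else np.asarray(affine)
    img = nib.Nifti1Image(data.astype(np.float64), affine)
    if data.ndim == 4:
        if tr is not None:
            zooms = list(img.header.get_zooms())
            zooms[3] = tr
            img.header.set_zooms(zooms)
        else:
            img.header["pixdim"][4] = 0.0  # mark the TR as unknown
    nib.save(img, str(path))


def write_onsets_tsv(trains: dict[str, OnsetTrain] | OnsetTrain, path) -> None:
    """Write one or several onset trains as a TSV.

    Columns: voxel_id, sample_index, time_s, detector, boundary_flag.
    A bare train is written under the id ``timecourse``.
    """
    if isinstance(trains, OnsetTrain):
        trains = {"timecourse": trains}
    rows = []
    for vid, train in trains.items():
        for idx, flag in zip(train.indices, train.boundary):
            rows.append(
                {
                    "voxel_id": vid,
                    "sample_index": int(idx),
                    "time_s": float(idx * train.tr),
                    "detector": train.detector,
                    "boundary_flag": int(flag),
                }
            )
    df = pd.DataFrame(rows, columns=ONSET_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_onsets_tsv(path, tr: float | None = None) -> dict[str, OnsetTrain]:
    """Read onset trains from TSV.

    Requires an id column (``voxel_id`` or ``component``) and either
    ``sample_index`` or ``time_s`` (converted via ``tr``).  Unsorted rows
    are sorted with a warning; duplicate indices per id are an error.
    """
    df = pd.read_csv(path, sep="\t")
    id_col = next((c for c in ("voxel_id", "component", "id") if c in df.columns), None)
    if id_col is None:
        raise ValueError("onset TSV needs a voxel_id/component column")
    if "sample_index" not in df.columns:
        if "time_s" not in df.columns:
            raise ValueError("onset TSV needs sample_index or time_s")
        if tr is None:
            raise ValueError("time_s-only onset TSV requires tr")
        df["sample_index"] = np.rint(df["time_s"] / tr).astype(int)
    if (df["sample_index"] < 0).any():
        raise ValueError("negative sample indices")
    trains: dict[str, OnsetTrain] = {}
    for vid, grp in df.groupby(id_col, sort=False):
        idx = grp["sample_index"].to_numpy()
        if np.unique(idx).size != idx.size:
            raise ValueError(f"duplicate onset indices for id {vid!r}")
        order = np.argsort(idx)
        if not np.array_equal(order, np.arange(idx.size)):
            import warnings

            warnings.warn(f"onsets for id {vid!r} were unsorted; sorting")
        idx = idx[order]
        detector = str(grp["detector"].iloc[0]) if "detector" in grp else "ground_truth"
        flags = (
            grp["boundary_flag"].to_numpy()[order].astype(bool)
            if "boundary_flag" in grp
            else None
        )
        row_tr = tr
        if row_tr is None:
            if "time_s" in grp and idx.size and idx[np.flatnonzero(idx)].size:
                nz = np.flatnonzero(idx)
                row_tr = float(grp["time_s"].to_numpy()[order][nz[0]] / idx[nz[0]])
            else:
                row_tr = 1.0
        trains[str(vid)] = OnsetTrain(idx, tr=row_tr, detector=detector, boundary=flags)
    return trains


def read_config(path) -> dict:
    """Read a YAML or JSON run configuration."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def write_sidecar(path, config: dict, seed=None) -> None:
    """Write a JSON provenance sidecar (config, seed, package version).

    Content is deterministic for a fixed config/seed, so artifacts can be
    compared byte-for-byte across reruns.
    """
    from . import __version__

    payload = {"config": config, "seed": seed, "package_version": __version__}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    """Write an ROI matrix as TSV with labels; missing cells as NA."""
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g", index_label="roi")


def read_matrix_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return df
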