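"""Readers and writers for the standard formats the pipeline touches.

Volumes are NIfTI-1, tractograms are TRK or TCK (via nibabel.streamlines,
always converted to world mm on read), tables are comma-separated UTF-8 CSV
with a header row. All geometry is world-mm internally.
"""
from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import (
    Parcellation,
    StimulationSite,
    Tractogram,
    VolumeGrid,
    normalize_label,
)

REQUIRED_SITE_COLUMNS = ("site_id", "patient_id", "x_mm", "y_mm", "z_mm", "label")


# ---------------------------------------------------------------------------
# volumes


def read_volume(path, allow_4d: bool = False) -> VolumeGrid:
    """Load a NIfTI volume into a :class:`VolumeGrid`.

    4-D images are rejected unless ``allow_4d`` is set (vector fields such as
    fiber-peak directions are stored as X x Y x Z x 3).
    """
    img = nib.load(os.fspath(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and not allow_4d:
        raise ValueError(
            f"{path}: got a 4-D image where a 3-D volume was expected "
            "(pass allow_4d=True for vector fields)"
        )
    if data.ndim not in (3, 4):
        raise ValueError(f"{path}: unsupported dimensionality {data.ndim}")
    affine = np.asarray(img.affine, dtype=float)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError(f"{path}: affine is not invertible")
    return VolumeGrid(data.shape[:3], affine, data)


def write_volume(grid: VolumeGrid, path, dtype=None) -> None:
    data = grid.data
    if dtype is not None:
        data = np.asarray(data).astype(dtype)
    nib.save(nib.Nifti1Image(data, grid.affine), os.fspath(path))


def write_parcellation(parc: Parcellation, nii_path, labels_csv_path) -> None:
    """Parcellation volume as int16 NIfTI plus the label table as CSV."""
    write_volume(parc.grid, nii_path, dtype=np.int16)
    parc.table.to_csv(labels_csv_path, index=False)


def read_parcellation(nii_path, labels_csv_path) -> Parcellation:
    grid = read_volume(nii_path)
    grid.data = np.asarray(grid.data).astype(np.int64)
    table = pd.read_csv(labels_csv_path)
    return Parcellation(grid, table)


# ---------------------------------------------------------------------------
# tractograms


def _trk_header(grid: VolumeGrid | None) -> dict:
    if grid is None:
        # Minimal self-consistent header for world-mm data with no reference
        # volume: identity voxel grid large enough to be irrelevant.
        return {
            "voxel_sizes": np.ones(3, dtype=np.float32),
            "dimensions": np.array([1, 1, 1], dtype=np.int16),
            "voxel_to_rasmm": np.eye(4, dtype=np.float32),
        }
    return {
        "voxel_sizes": grid.voxel_sizes.astype(np.float32),
        "dimensions": np.asarray(grid.shape, dtype=np.int16),
        "voxel_to_rasmm": grid.affine.astype(np.float32),
    }


def write_tractogram(t: Tractogram, path, grid: VolumeGrid | None = None,
                     tags_path=None) -> None:
    """Write streamlines to TRK or TCK (chosen by the file extension).

    TRK's voxel-space convention is handled by nibabel: points are handed
    over in world mm with an identity ``affine_to_rasmm``. A per-streamline
    tag sidecar CSV is written when ``tags_path`` is given.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix not in (".trk", ".tck"):
        raise ValueError(f"unsupported tractogram dialect {suffix!r}; use .trk or .tck")
    nt = nib.streamlines.Tractogram(t.streamlines, affine_to_rasmm=np.eye(4))
    if suffix == ".trk":
        f = nib.streamlines.TrkFile(nt, header=_trk_header(grid))
    else:
        f = nib.streamlines.TckFile(nt)
    f.save(os.fspath(path))
    if tags_path is not None:
        tags = t.tags if t.tags is not None else [""] * len(t)
        pd.DataFrame({"streamline_index": range(len(t)), "bundle": tags}).to_csv(
            tags_path, index=False
        )


def read_tractogram(path, tags_path=None) -> Tractogram:
    """Read a TRK/TCK file; streamlines are returned in world mm."""
    fmt = nib.streamlines.detect_format(os.fspath(path))
    if fmt is None:
        raise ValueError(f"{path}: unrecognized tractogram format; expected TRK or TCK")
    try:
        tf = nib.streamlines.load(os.fspath(path))
    except Exception as exc:
        raise ValueError(f"{path}: not a readable tractogram; expected TRK or TCK ({exc})")
    streamlines = [np.asarray(s, dtype=float) for s in tf.streamlines]
    tags = None
    if tags_path is not None:
        df = pd.read_csv(tags_path)
        tags = [str(b) for b in df.sort_values("streamline_index")["bundle"]]
    return Tractogram(streamlines, tags)


# ---------------------------------------------------------------------------
# site tables


def read_sites(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read and validate a stimulation-site table.

    Required columns: site_id, patient_id, x_mm, y_mm, z_mm, label (optional
    intensity_mA, true_bundle). ``column_map`` renames caller columns to the
    canonical ones, accommodating supplementary-table layouts. Labels are
    normalized case-insensitively against the closed response vocabulary.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"site table is missing required columns {missing}")
    if df["site_id"].duplicated().any():
        dupes = df.loc[df["site_id"].duplicated(), "site_id"].tolist()
        raise ValueError(f"duplicate site_ids: {dupes}")
    for c in ("x_mm", "y_mm", "z_mm"):
        coerced = pd.to_numeric(df[c], errors="coerce")
        if coerced.isna().any():
            bad = df.loc[coerced.isna(), "site_id"].tolist()
            raise ValueError(f"non-numeric {c} for sites {bad}")
        df[c] = coerced.astype(float)
    if not np.isfinite(df[["x_mm", "y_mm", "z_mm"]].to_numpy()).all():
        raise ValueError("site coordinates must be finite")
    df["label"] = [normalize_label(lab) for lab in df["label"]]
    if "intensity_mA" in df.columns:
        df["intensity_mA"] = pd.to_numeric(df["intensity_mA"], errors="coerce")
    return df.reset_index(drop=True)


def sites_from_table(df: pd.DataFrame) -> list[StimulationSite]:
    sites = []
    for _, row in df.iterrows():
        sites.append(
            StimulationSite(
                site_id=str(row["site_id"]),
                patient_id=str(row["patient_id"]),
                center=np.array([row["x_mm"], row["y_mm"], row["z_mm"]], dtype=float),
                label=row["label"],
                intensity_mA=(
                    float(row["intensity_mA"])
                    if "intensity_mA" in row and pd.notna(row.get("intensity_mA"))
                    else None
                ),
                true_bundle=(
                    str(row["true_bundle"])
                    if "true_bundle" in row and pd.notna(row.get("true_bundle"))
                    else None
                ),
            )
        )
    return sites


def write_sites(sites: list[StimulationSite], path) -> None:
    rows = []
    for s in sites:
        rows.append(
            {
                "site_id": s.site_id,
                "patient_id": s.patient_id,
                "x_mm": s.center[0],
                "y_mm": s.center[1],
                "z_mm": s.center[2],
                "label": s.label,
                "intensity_mA": s.intensity_mA,
                "true_bundle": s.true_bundle,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# matrices


def write_matrix_long(counts: np.ndarray, parcel_ids, path) -> None:
    """Long-format CSV (parcel_a, parcel_b, count) of the upper triangle."""
    ids = list(parcel_ids)
    rows = []
    p = len(ids)
    for i in range(p):
        for j in range(i + 1, p):
            c = int(counts[i, j])
            if c:
                rows.append({"parcel_a": ids[i], "parcel_b": ids[j], "count": c})
    pd.DataFrame(rows, columns=["parcel_a", "parcel_b", "count"]).to_csv(path, index=False)


def write_matrix_dense(counts: np.ndarray, parcel_ids, path) -> None:
    ids = [str(i) for i in parcel_ids]
    pd.DataFrame(np.asarray(counts), index=ids, columns=ids).to_csv(path, index_label="parcel_id")
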