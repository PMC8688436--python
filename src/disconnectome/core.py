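"""Core containers shared across the pipeline.

All geometry is carried in world millimetres. Voxel indices appear only at
I/O and sampling boundaries: a world point maps to the voxel whose index is
the rounded inverse-affine image (nearest-voxel convention, 0-based).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

#: Closed vocabulary of behavioural response labels. The first three are
#: alexia subtypes (phonological, lexical-semantic, pure); the rest are
#: language disturbances used as control stimulations.
RESPONSE_LABELS = (
    "Ph-A",
    "Ls-A",
    "Pu-A",
    "phonological paraphasia",
    "semantic paraphasia",
    "anomia",
)
ALEXIA_LABELS = RESPONSE_LABELS[:3]

_CANONICAL = {lab.lower(): lab for lab in RESPONSE_LABELS}

# Stimulus metadata carried as documentation constants only (never used in
# any computation): biphasic stimulation at 60 Hz, 1 ms pulse width, trains
# of at most 4 s, intensities between 1.75 and 3.50 mA.
STIMULUS_FREQUENCY_HZ = 60.0
STIMULUS_PULSE_WIDTH_MS = 1.0
STIMULUS_MAX_TRAIN_S = 4.0
STIMULUS_INTENSITY_RANGE_MA = (1.75, 3.50)


def normalize_label(raw: str) -> str:
    """Map a response label to its canonical spelling (case-insensitive)."""
    key = str(raw).strip().lower()
    if key not in _CANONICAL:
        raise ValueError(
            f"unknown response label {raw!r}; allowed labels are {list(RESPONSE_LABELS)}"
        )
    return _CANONICAL[key]


class VolumeGrid:
    """A voxel grid with an invertible voxel->world (mm) affine.

    Parameters
    ----------
    shape : tuple of int
        Grid dimensions (3 axes).
    affine : (4, 4) array
        Voxel->world map in millimetres.
    data : ndarray, optional
        Scalar (``shape``) or vector (``shape + (k,)``) field over voxels.
    """

    def __init__(self, shape, affine, data=None):
        self.shape = tuple(int(s) for s in shape)
        if len(self.shape) != 3:
            raise ValueError(f"expected a 3-D grid shape, got {self.shape}")
        affine = np.asarray(affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        self.affine = affine
        self._inv = np.linalg.inv(affine)
        self.data = data

    def voxel_to_world(self, idx) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        single = idx.ndim == 1
        idx = np.atleast_2d(idx)
        out = idx @ self.affine[:3, :3].T + self.affine[:3, 3]
        return out[0] if single else out

    def world_to_voxel(self, pts) -> np.ndarray:
        """Nearest-voxel indices of world points (may fall outside the grid)."""
        pts = np.asarray(pts, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        vox = np.rint(pts @ self._inv[:3, :3].T + self._inv[:3, 3]).astype(np.int64)
        return vox[0] if single else vox

    def in_bounds(self, idx) -> np.ndarray:
        idx = np.asarray(idx)
        single = idx.ndim == 1
        idx = np.atleast_2d(idx)
        ok = np.all((idx >= 0) & (idx < np.asarray(self.shape)), axis=1)
        return bool(ok[0]) if single else ok

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)


@dataclass
class Parcellation:
    """Integer label volume plus a label table (parcel_id, name, lobe)."""

    grid: VolumeGrid
    table: pd.DataFrame

    def __post_init__(self):
        required = {"parcel_id", "name", "lobe"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"label table is missing columns {sorted(missing)}")
        ids = self.table["parcel_id"].to_numpy()
        if len(ids) != len(set(ids)):
            raise ValueError("parcel_ids must be unique")
        if len(ids) and (ids <= 0).any():
            raise ValueError("parcel_ids must be positive")

    @property
    def labels(self) -> np.ndarray:
        return self.grid.data

    @property
    def parcel_ids(self) -> tuple[int, ...]:
        return tuple(int(i) for i in self.table["parcel_id"])

    def name_of(self, parcel_id: int) -> str:
        row = self.table.loc[self.table["parcel_id"] == parcel_id]
        if row.empty:
            raise KeyError(f"no parcel with id {parcel_id}")
        return str(row["name"].iloc[0])


class Tractogram:
    """An ordered collection of streamlines (world-mm polylines).

    Optional per-streamline ``tags`` carry ground-truth bundle names in
    synthetic mode; analysis operations never read them — only tests and QC.
    """

    def __init__(self, streamlines: Sequence[np.ndarray], tags: Sequence[str] | None = None):
        self.streamlines = [np.asarray(s, dtype=float) for s in streamlines]
        for s in self.streamlines:
            if s.ndim != 2 or s.shape[1] != 3:
                raise ValueError("each streamline must be an (n, 3) array of world-mm points")
        if tags is not None and len(tags) != len(self.streamlines):
            raise ValueError("tags must align with streamlines")
        self.tags = list(tags) if tags is not None else None

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.streamlines)

    def __getitem__(self, i) -> np.ndarray:
        return self.streamlines[i]

    def subset(self, mask) -> "Tractogram":
        mask = np.asarray(mask, dtype=bool)
        kept = [s for s, m in zip(self.streamlines, mask) if m]
        tags = None
        if self.tags is not None:
            tags = [t for t, m in zip(self.tags, mask) if m]
        return Tractogram(kept, tags)


@dataclass
class StimulationSite:
    """A positive stimulation site: an MNI-mm point with a response label."""

    site_id: str
    patient_id: str
    center: np.ndarray
    label: str
    intensity_mA: float | None = None
    true_bundle: str | None = None

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        if self.center.shape != (3,) or not np.all(np.isfinite(self.center)):
            raise ValueError("site center must be a finite 3-vector (mm)")
        self.label = normalize_label(self.label)


@dataclass
class SphericalVOI:
    """Spherical volume of interest around a stimulation site."""

    center: np.ndarray
    radius_mm: float = 2.5

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        if self.radius_mm <= 0:
            raise ValueError("VOI radius must be positive")

    @property
    def volume_mm3(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius_mm**3


@dataclass
class DisconnectivityMatrix:
    """Symmetric P x P streamline counts over an ordered parcel list.

    The diagonal is zero: streamlines with both endpoints in the same parcel
    are excluded from the matrix and tallied in ``qc_excluded`` together with
    streamlines that have an unlabeled endpoint.
    """

    counts: np.ndarray
    parcel_ids: tuple[int, ...]
    site_id: str | None = None
    params: dict = field(default_factory=dict)
    qc_excluded: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        p = len(self.parcel_ids)
        if self.counts.shape != (p, p):
            raise ValueError("counts shape must match the parcel list")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if not np.array_equal(self.counts, self.counts.T):
            raise ValueError("counts must be symmetric")
        if np.any(np.diag(self.counts) != 0):
            raise ValueError("diagonal must be zero")

    def upper_triangle_total(self) -> int:
        return int(np.triu(self.counts, k=1).sum())
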