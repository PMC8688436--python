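"""Per-site "disconnected" streamline sets and parcel disconnectivity matrices.

A stimulation site is represented by a spherical VOI (default radius 2.5 mm,
the spatial resolution of the bipolar stimulation probe; 3.0 and 3.5 mm for
the radius sensitivity analysis). The site's disconnected set is every
template streamline with at least one segment entering the sphere —
membership is segment-based, not vertex-based, so a thin sphere cannot be
jumped over by a 1 mm step. Streamline endpoints are embedded in the
parcellation to build a symmetric P x P inter-parcel count matrix per site.
"""
from __future__ import annotations

import warnings
from collections import Counter

import numpy as np
import pandas as pd

from .core import (
    DisconnectivityMatrix,
    Parcellation,
    SphericalVOI,
    StimulationSite,
    Tractogram,
)

DEFAULT_RADII_MM = (2.5, 3.0, 3.5)


def make_voi(site: StimulationSite, radius_mm: float = 2.5) -> SphericalVOI:
    return SphericalVOI(center=site.center, radius_mm=radius_mm)


def _point_segment_dist2(center: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    """Squared distance from ``center`` to each closed segment [p0_i, p1_i]."""
    d = p1 - p0
    dd = (d * d).sum(axis=1)
    t = np.zeros(len(p0))
    nz = dd > 1e-24
    t[nz] = ((center - p0[nz]) * d[nz]).sum(axis=1) / dd[nz]
    t = np.clip(t, 0.0, 1.0)
    closest = p0 + t[:, None] * d
    diff = closest - center
    return (diff * diff).sum(axis=1)


def segment_sphere_intersects(p0, p1, voi: SphericalVOI) -> bool:
    """True iff the closed segment [p0, p1] comes within the sphere radius."""
    d2 = _point_segment_dist2(
        np.asarray(voi.center, float),
        np.atleast_2d(np.asarray(p0, float)),
        np.atleast_2d(np.asarray(p1, float)),
    )
    return bool(d2[0] <= voi.radius_mm**2)


class StreamlineGeometryIndex:
    """Pre-concatenated segment arrays for fast repeated VOI queries."""

    def __init__(self, t: Tractogram):
        self.tractogram = t
        p0, p1, offsets = [], [], [0]
        for s in t:
            p0.append(s[:-1])
            p1.append(s[1:])
            offsets.append(offsets[-1] + len(s) - 1)
        self._p0 = np.vstack(p0) if p0 else np.empty((0, 3))
        self._p1 = np.vstack(p1) if p1 else np.empty((0, 3))
        self._offsets = np.asarray(offsets[:-1], dtype=np.intp)
        self._n = len(t)

    def min_dist2(self, center) -> np.ndarray:
        """Per-streamline squared distance from ``center`` to the polyline."""
        if self._n == 0:
            return np.empty(0)
        d2 = _point_segment_dist2(np.asarray(center, float), self._p0, self._p1)
        return np.minimum.reduceat(d2, self._offsets)

    def intersect_mask(self, voi: SphericalVOI) -> np.ndarray:
        if self._n == 0:
            return np.zeros(0, dtype=bool)
        return self.min_dist2(voi.center) <= voi.radius_mm**2


def filter_by_voi(t: Tractogram, voi: SphericalVOI) -> Tractogram:
    """Exactly the streamlines with >= 1 segment intersecting the sphere,
    order preserved."""
    return t.subset(StreamlineGeometryIndex(t).intersect_mask(voi))


# ---------------------------------------------------------------------------
# endpoint embedding


def endpoint_label(point, parcellation: Parcellation, search_radius_vox: int = 1) -> int:
    """Parcel label at a streamline terminus.

    Nearest-voxel label; when that voxel is background and
    ``search_radius_vox`` > 0, the most frequent nonzero label within the
    cubic neighborhood (ties broken by smallest parcel_id); 0 when nothing is
    found or the point falls outside the grid.
    """
    grid = parcellation.grid
    vox = grid.world_to_voxel(np.asarray(point, float))
    if not grid.in_bounds(vox):
        return 0
    lab = int(parcellation.labels[tuple(vox)])
    if lab != 0 or search_radius_vox <= 0:
        return lab
    r = int(search_radius_vox)
    lo = np.maximum(vox - r, 0)
    hi = np.minimum(vox + r + 1, grid.shape)
    block = parcellation.labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    nonzero = block[block != 0]
    if nonzero.size == 0:
        return 0
    counts = Counter(int(v) for v in nonzero)
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
    return best[0]


def endpoint_pairs(t: Tractogram, parcellation: Parcellation,
                   search_radius_vox: int = 1) -> np.ndarray:
    """(n, 2) array of endpoint parcel labels (0 = unlabeled) per streamline."""
    out = np.zeros((len(t), 2), dtype=np.int64)
    for i, s in enumerate(t):
        out[i, 0] = endpoint_label(s[0], parcellation, search_radius_vox)
        out[i, 1] = endpoint_label(s[-1], parcellation, search_radius_vox)
    return out


def matrix_from_pairs(pairs: np.ndarray, parcel_ids, site_id=None,
                      params=None) -> DisconnectivityMatrix:
    """Symmetric count matrix from endpoint-label pairs.

    Streamlines with an unlabeled endpoint or both endpoints in the same
    parcel are excluded and tallied in the QC count.
    """
    ids = list(parcel_ids)
    index = {pid: k for k, pid in enumerate(ids)}
    p = len(ids)
    counts = np.zeros((p, p), dtype=np.int64)
    excluded = 0
    for a, b in np.asarray(pairs, dtype=np.int64):
        if a <= 0 or b <= 0 or a == b or a not in index or b not in index:
            excluded += 1
            continue
        i, j = index[int(a)], index[int(b)]
        counts[i, j] += 1
        counts[j, i] += 1
    return DisconnectivityMatrix(
        counts=counts,
        parcel_ids=tuple(ids),
        site_id=site_id,
        params=dict(params or {}),
        qc_excluded=excluded,
    )


def build_matrix(disconnected: Tractogram, parcellation: Parcellation,
                 search_radius_vox: int = 1, site_id=None,
                 params=None) -> DisconnectivityMatrix:
    """Disconnectivity matrix of a site's VOI-filtered streamline set."""
    pairs = endpoint_pairs(disconnected, parcellation, search_radius_vox)
    return matrix_from_pairs(pairs, parcellation.parcel_ids, site_id, params)


# ---------------------------------------------------------------------------
# group summaries


def sum_by_group(matrices, site_labels: dict) -> dict:
    """Elementwise sums of per-site matrices by group label.

    ``site_labels`` maps site_id -> label. Labels without any matrix yield a
    zero matrix with a warning. Mixed parcel orderings are rejected.
    """
    if not matrices:
        raise ValueError("no matrices to sum")
    ref = matrices[0].parcel_ids
    for m in matrices:
        if m.parcel_ids != ref:
            raise ValueError("matrices have mixed parcel orderings")
    by_label: dict[str, list[DisconnectivityMatrix]] = {}
    for m in matrices:
        lab = site_labels[m.site_id]
        by_label.setdefault(lab, []).append(m)
    out = {}
    for lab in dict.fromkeys(site_labels.values()):
        members = by_label.get(lab, [])
        if not members:
            warnings.warn(f"group {lab!r} has no sites; emitting a zero matrix")
            total = np.zeros((len(ref), len(ref)), dtype=np.int64)
        else:
            total = np.sum([m.counts for m in members], axis=0)
        out[lab] = DisconnectivityMatrix(
            counts=total,
            parcel_ids=ref,
            site_id=None,
            params={"group": lab, "n_sites": len(members)},
            qc_excluded=sum(m.qc_excluded for m in members),
        )
    return out


def export_chord_table(summed: DisconnectivityMatrix, label_table: pd.DataFrame,
                       n_sites: int | None = None) -> pd.DataFrame:
    """Long-format chord-diagram table of the nonzero upper-triangle cells.

    Rows carry both raw summed counts and the per-site average (the two
    readings of chord thickness), plus per-lobe marginal shares: a lobe's
    marginal is the summed count of every cell touching that lobe (a cell is
    counted once even when both endpoints share the lobe), so "X% of the
    disconnections within <lobe>" is cell count / lobe marginal.
    """
    if n_sites is None:
        n_sites = int(summed.params.get("n_sites", 0)) or None
    ids = list(summed.parcel_ids)
    meta = label_table.set_index("parcel_id")
    lobe_marginal: dict[str, float] = {}
    cells = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            c = int(summed.counts[i, j])
            if not c:
                continue
            la = str(meta.loc[ids[i], "lobe"])
            lb = str(meta.loc[ids[j], "lobe"])
            cells.append((ids[i], ids[j], la, lb, c))
            for lobe in {la, lb}:
                lobe_marginal[lobe] = lobe_marginal.get(lobe, 0) + c
    rows = []
    for pa, pb, la, lb, c in cells:
        rows.append(
            {
                "parcel_a": pa,
                "parcel_b": pb,
                "name_a": str(meta.loc[pa, "name"]),
                "name_b": str(meta.loc[pb, "name"]),
                "lobe_a": la,
                "lobe_b": lb,
                "count": c,
                "mean_count_per_site": (c / n_sites) if n_sites else np.nan,
                "share_of_lobe_a_pct": 100.0 * c / lobe_marginal[la],
                "share_of_lobe_b_pct": 100.0 * c / lobe_marginal[lb],
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "parcel_a", "parcel_b", "name_a", "name_b", "lobe_a", "lobe_b",
            "count", "mean_count_per_site", "share_of_lobe_a_pct", "share_of_lobe_b_pct",
        ],
    )
    if len(df):
        df = df.sort_values(["lobe_a", "lobe_b", "parcel_a", "parcel_b"]).reset_index(drop=True)
    return df
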