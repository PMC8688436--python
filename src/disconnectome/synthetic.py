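"""Synthetic toy world: parcellations, ground-truth bundles, peak fields and
stimulation-site cohorts.

The generator stands in for the population-averaged fiber template, the
left-hemisphere parcellation and the surgical site coordinates, so that every
downstream stage is testable without any download. The default toy world is a
40 x 40 x 40 grid at 1 mm isotropic with eight box parcels and five bundles
named after the association tracts implicated in reading (lsAF, pAF, ILF,
IFOF, VOF analogues). Ground-truth bundle tags ride along in tractogram
metadata and are never consumed by analysis operations — only by tests.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Parcellation, StimulationSite, Tractogram, VolumeGrid

#: interior fraction of a polyline eligible for site placement; termini are
#: cortical, stimulation happens in white matter
_INTERIOR_MARGIN = 0.15


@dataclass
class ParcelSpec:
    """Axis-aligned box parcel. ``box`` is ((x0,x1),(y0,y1),(z0,z1)) in voxel
    indices, half-open on the right."""

    parcel_id: int
    name: str
    lobe: str
    box: tuple

    def __post_init__(self):
        if self.parcel_id <= 0:
            raise ValueError("parcel_id must be positive")
        box = tuple((int(a), int(b)) for a, b in self.box)
        for a, b in box:
            if b <= a:
                raise ValueError(f"degenerate box for parcel {self.name!r}")
        self.box = box

    def center_voxel(self) -> np.ndarray:
        return np.array([(a + b - 1) / 2.0 for a, b in self.box])


@dataclass
class BundleSpec:
    name: str
    start_parcel: int
    end_parcel: int
    waypoints: list
    n_streamlines: int
    jitter_mm: float = 0.0

    def __post_init__(self):
        if self.start_parcel == self.end_parcel:
            raise ValueError(f"bundle {self.name!r}: start and end parcel must differ")
        if self.n_streamlines < 1:
            raise ValueError(f"bundle {self.name!r}: n_streamlines must be >= 1")
        if self.jitter_mm < 0:
            raise ValueError(f"bundle {self.name!r}: jitter must be nonnegative")
        self.waypoints = [np.asarray(w, dtype=float) for w in self.waypoints]


@dataclass
class GroupSpec:
    n_sites: int
    target_bundles: list
    placement_noise_mm: float = 0.8

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("each group needs at least one site")
        if not self.target_bundles:
            raise ValueError("each group needs at least one target bundle")
        if self.placement_noise_mm < 0:
            raise ValueError("placement noise must be nonnegative")


@dataclass
class CohortSpec:
    groups: dict  # label -> GroupSpec
    seed: int = 0


@dataclass
class BundleSet:
    """Generated bundles: a tagged tractogram plus the noiseless centerlines."""

    tractogram: Tractogram
    centerlines: dict  # name -> (n, 3) polyline at 1 mm spacing
    specs: list

    @property
    def names(self) -> list:
        return [s.name for s in self.specs]

    def streamlines_of(self, name: str) -> list:
        return [s for s, t in zip(self.tractogram.streamlines, self.tractogram.tags) if t == name]


# ---------------------------------------------------------------------------
# parcellation


def make_toy_parcellation(grid_shape, parcel_specs, affine=None) -> Parcellation:
    """Paint each box parcel into an integer label volume (0 = background)."""
    if affine is None:
        affine = np.eye(4)
    grid_shape = tuple(int(s) for s in grid_shape)
    ids = [s.parcel_id for s in parcel_specs]
    if len(ids) != len(set(ids)):
        raise ValueError("parcel_ids must be unique")
    for spec in parcel_specs:
        for (a, b), n in zip(spec.box, grid_shape):
            if a < 0 or b > n:
                raise ValueError(f"parcel {spec.name!r} box exceeds the grid")
    for i, si in enumerate(parcel_specs):
        for sj in parcel_specs[i + 1 :]:
            if all(ai < bj and aj < bi for (ai, bi), (aj, bj) in zip(si.box, sj.box)):
                raise ValueError(
                    f"overlapping parcels: {si.name!r} (id {si.parcel_id}) and "
                    f"{sj.name!r} (id {sj.parcel_id})"
                )
    labels = np.zeros(grid_shape, dtype=np.int64)
    for spec in parcel_specs:
        (x0, x1), (y0, y1), (z0, z1) = spec.box
        labels[x0:x1, y0:y1, z0:z1] = spec.parcel_id
    table = pd.DataFrame(
        [(s.parcel_id, s.name, s.lobe) for s in parcel_specs],
        columns=["parcel_id", "name", "lobe"],
    )
    return Parcellation(VolumeGrid(grid_shape, affine, labels), table)


# ---------------------------------------------------------------------------
# bundles


def resample_polyline(points: np.ndarray, spacing_mm: float = 1.0) -> np.ndarray:
    """Piecewise-linear resampling at (approximately) fixed arc-length spacing,
    endpoints preserved."""
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        raise ValueError("degenerate polyline of zero length")
    n = max(int(round(total / spacing_mm)) + 1, 2)
    targets = np.linspace(0.0, total, n)
    out = np.empty((n, 3))
    for k in range(3):
        out[:, k] = np.interp(targets, cum, points[:, k])
    return out


def _perpendicular_offset(rng: np.random.Generator, axis: np.ndarray, max_norm: float) -> np.ndarray:
    if max_norm == 0:
        return np.zeros(3)
    axis = axis / np.linalg.norm(axis)
    while True:
        v = rng.normal(size=3)
        v = v - axis * (v @ axis)
        n = np.linalg.norm(v)
        if n > 1e-9:
            break
    r = max_norm * np.sqrt(rng.uniform())  # uniform over the disk
    return v / n * r


def make_bundles(parcellation: Parcellation, bundle_specs, rng_seed: int = 0) -> BundleSet:
    """Sample ``n_streamlines`` polylines per bundle along the waypoint curve.

    Each streamline is the centerline (resampled at 1 mm, matching the
    tracker step size) plus a constant lateral offset of norm <= jitter_mm,
    so first and last points stay inside the start/end parcel boxes for
    jitter small relative to the box size.
    """
    rng = np.random.default_rng(rng_seed)
    grid = parcellation.grid
    specs_by_id = {int(i): None for i in parcellation.table["parcel_id"]}
    streamlines, tags, centerlines = [], [], {}
    for spec in bundle_specs:
        for pid in (spec.start_parcel, spec.end_parcel):
            if pid not in specs_by_id:
                raise ValueError(f"bundle {spec.name!r}: parcel {pid} not in parcellation")
        for w in spec.waypoints:
            if not grid.in_bounds(grid.world_to_voxel(w)):
                raise ValueError(f"bundle {spec.name!r}: waypoint {w} outside the grid")
        start = _parcel_center_world(parcellation, spec.start_parcel)
        end = _parcel_center_world(parcellation, spec.end_parcel)
        nodes = np.vstack([start] + [np.asarray(w) for w in spec.waypoints] + [end])
        center = resample_polyline(nodes, 1.0)
        centerlines[spec.name] = center
        axis = end - start
        for _ in range(spec.n_streamlines):
            off = _perpendicular_offset(rng, axis, spec.jitter_mm)
            streamlines.append(center + off)
            tags.append(spec.name)
    return BundleSet(Tractogram(streamlines, tags), centerlines, list(bundle_specs))


def _parcel_center_world(parcellation: Parcellation, parcel_id: int) -> np.ndarray:
    vox = np.argwhere(parcellation.labels == parcel_id)
    if len(vox) == 0:
        raise ValueError(f"parcel {parcel_id} has no voxels")
    return parcellation.grid.voxel_to_world(vox.mean(axis=0))


# ---------------------------------------------------------------------------
# peak field


def make_peak_field(bundle_set: BundleSet, grid: VolumeGrid, qa_on: float = 0.30,
                    qa_off: float = 0.05, rng_seed: int = 0):
    """Rasterize bundle tangents into a one-peak-per-voxel direction field.

    Voxels traversed by at least one bundle streamline receive anisotropy
    ``qa_on`` and the principal direction of the local segment tangents
    (sign-symmetric: accumulated as outer products, so d and -d are
    equivalent); all other voxels receive ``qa_off`` and an arbitrary unit
    direction. Returns ``(field, qc_report)`` where the QC report flags
    voxels whose tangent distribution has no dominant direction (crossing
    bundles), without treating them as errors.

    Import is deferred to avoid a circular dependency with the tracking
    module, which defines :class:`PeakField`.
    """
    from .tracking import PeakField

    if not (qa_on > qa_off >= 0):
        raise ValueError("need qa_on > qa_off >= 0")
    shape = grid.shape
    rng = np.random.default_rng(rng_seed)
    outer = np.zeros(shape + (3, 3))
    hit = np.zeros(shape, dtype=bool)
    step = 0.25 * float(np.min(grid.voxel_sizes))
    for sl in bundle_set.tractogram:
        dense, tangents = _densify_with_tangents(sl, step)
        vox = grid.world_to_voxel(dense)
        ok = grid.in_bounds(vox)
        vox, tangents = vox[ok], tangents[ok]
        hit[vox[:, 0], vox[:, 1], vox[:, 2]] = True
        tt = tangents[:, :, None] * tangents[:, None, :]
        np.add.at(outer, (vox[:, 0], vox[:, 1], vox[:, 2]), tt)

    direction = _random_unit_directions(rng, shape)
    qa = np.full(shape, float(qa_off))
    unreliable = []
    idx = np.argwhere(hit)
    if len(idx):
        mats = outer[idx[:, 0], idx[:, 1], idx[:, 2]]
        vals, vecs = np.linalg.eigh(mats)
        principal = vecs[:, :, -1]
        principal = _canonical_sign(principal)
        direction[idx[:, 0], idx[:, 1], idx[:, 2]] = principal
        qa[idx[:, 0], idx[:, 1], idx[:, 2]] = float(qa_on)
        # no dominant direction: largest eigenvalue below 2/3 of the trace
        trace = vals.sum(axis=1)
        weak = vals[:, -1] < (2.0 / 3.0) * trace
        unreliable = [tuple(int(v) for v in idx[k]) for k in np.flatnonzero(weak)]
    field = PeakField(grid=VolumeGrid(shape, grid.affine), direction=direction, qa=qa)
    qc = {"n_corridor_voxels": int(hit.sum()), "unreliable_voxels": unreliable}
    return field, qc


def _densify_with_tangents(points: np.ndarray, step: float):
    p0, p1 = points[:-1], points[1:]
    seg = p1 - p0
    lengths = np.linalg.norm(seg, axis=1)
    keep = lengths > 1e-12
    p0, seg, lengths = p0[keep], seg[keep], lengths[keep]
    tangents = seg / lengths[:, None]
    dense, dense_t = [], []
    n_samples = np.maximum((lengths / step).astype(int) + 1, 2)
    for a, d, t, n in zip(p0, seg, tangents, n_samples):
        ts = np.linspace(0.0, 1.0, n)
        dense.append(a + ts[:, None] * d)
        dense_t.append(np.repeat(t[None, :], n, axis=0))
    return np.vstack(dense), np.vstack(dense_t)


def _canonical_sign(vectors: np.ndarray) -> np.ndarray:
    """Representative of {d, -d} whose first nonzero component is >= 0."""
    v = np.array(vectors, dtype=float)
    flat = v.reshape(-1, 3)
    for k in range(flat.shape[0]):
        for c in flat[k]:
            if abs(c) > 1e-12:
                if c < 0:
                    flat[k] = -flat[k]
                break
    return flat.reshape(v.shape)


def _random_unit_directions(rng: np.random.Generator, shape) -> np.ndarray:
    v = rng.normal(size=shape + (3,))
    v /= np.linalg.norm(v, axis=-1, keepdims=True)
    return _canonical_sign(v)


# ---------------------------------------------------------------------------
# cohorts


def _interior_vertex_range(n: int) -> tuple[int, int]:
    lo = int(np.floor(n * _INTERIOR_MARGIN))
    hi = int(np.ceil(n * (1.0 - _INTERIOR_MARGIN)))
    return lo, max(hi, lo + 1)


def make_cohort(cohort_spec: CohortSpec, bundle_set: BundleSet) -> list[StimulationSite]:
    """Place each group's sites on its target bundles.

    Within a group, targets are assigned by cycling through the (possibly
    repeated) target list in site order, so programmed effects have
    deterministic coverage; the point along the chosen bundle is random.
    Centers are a random interior polyline vertex of a random streamline of
    the target bundle plus isotropic Gaussian noise of sd
    ``placement_noise_mm``. Reproducible from ``cohort_spec.seed``.
    """
    rng = np.random.default_rng(cohort_spec.seed)
    names = set(bundle_set.names)
    sites: list[StimulationSite] = []
    for label, group in cohort_spec.groups.items():
        for target in group.target_bundles:
            if target not in names:
                raise ValueError(f"group {label!r}: unknown target bundle {target!r}")
        for i in range(group.n_sites):
            target = group.target_bundles[i % len(group.target_bundles)]
            members = bundle_set.streamlines_of(target)
            sl = members[rng.integers(len(members))]
            lo, hi = _interior_vertex_range(len(sl))
            point = sl[rng.integers(lo, hi)]
            center = point + rng.normal(0.0, group.placement_noise_mm, size=3)
            sites.append(
                StimulationSite(
                    site_id=f"{label}-{i:02d}",
                    patient_id=f"pt-{label}-{i:02d}",
                    center=center,
                    label=label,
                    true_bundle=target,
                )
            )
    return sites


def make_null_cohort(n_per_group: dict, bundle_set: BundleSet, rng_seed: int = 0,
                     placement_noise_mm: float = 0.8) -> list[StimulationSite]:
    """Cohort in which every group draws from the same placement distribution
    (uniform over all bundles' interior polyline vertices): labels carry no
    information, giving a type-I-error surface for the group contrasts."""
    for label, n in n_per_group.items():
        if n < 1:
            raise ValueError(f"group {label!r} must have at least one site")
    rng = np.random.default_rng(rng_seed)
    pool = bundle_set.tractogram.streamlines
    tags = bundle_set.tractogram.tags
    sites: list[StimulationSite] = []
    for label, n in n_per_group.items():
        for i in range(n):
            k = rng.integers(len(pool))
            sl = pool[k]
            lo, hi = _interior_vertex_range(len(sl))
            point = sl[rng.integers(lo, hi)]
            center = point + rng.normal(0.0, placement_noise_mm, size=3)
            sites.append(
                StimulationSite(
                    site_id=f"{label}-{i:02d}",
                    patient_id=f"pt-{label}-{i:02d}",
                    center=center,
                    label=label,
                    true_bundle=tags[k] if tags else None,
                )
            )
    return sites


# ---------------------------------------------------------------------------
# default toy world

TOY_GRID_SHAPE = (40, 40, 40)


def toy_parcel_specs() -> list[ParcelSpec]:
    """Eight left-hemisphere-like box parcels grouped into four lobes."""
    return [
        ParcelSpec(1, "MFG-toy", "Frontal", ((2, 9), (26, 35), (16, 25))),
        ParcelSpec(2, "SPL-toy", "Parietal", ((16, 25), (30, 38), (28, 36))),
        ParcelSpec(3, "ITG-ant-toy", "Temporal", ((4, 11), (2, 9), (4, 11))),
        ParcelSpec(4, "ITG-mid-toy", "Temporal", ((12, 19), (2, 9), (10, 17))),
        ParcelSpec(5, "ITG-post-toy", "Temporal", ((20, 27), (2, 9), (4, 11))),
        ParcelSpec(6, "LOcC-toy", "Occipital", ((30, 38), (6, 15), (18, 27))),
        ParcelSpec(7, "MVOcC-toy", "Occipital", ((30, 38), (20, 29), (4, 13))),
        ParcelSpec(8, "IFG-toy", "Frontal", ((2, 9), (16, 25), (26, 34))),
    ]


def toy_bundle_specs(n_streamlines: int = 40, jitter_mm: float = 0.6) -> list[BundleSpec]:
    """Toy analogues of the reading-related association tracts.

    Waypoints are gentle (corner angles well below the 40 degree angular
    threshold after 1 mm resampling) and mid-spans of distinct bundles stay
    more than 5 mm apart so a 2.5 mm VOI cannot capture a neighbour.
    """
    return [
        BundleSpec("lsAF-toy", 1, 3, [(6, 22, 17), (6, 14, 12)], n_streamlines, jitter_mm),
        BundleSpec("pAF-toy", 2, 4, [(18, 24, 26), (16, 14, 19)], n_streamlines, jitter_mm),
        BundleSpec("ILF-toy", 6, 5, [(29, 8, 17), (26, 6, 12)], n_streamlines, jitter_mm),
        BundleSpec("IFOF-toy", 8, 6, [(13, 18, 27), (23, 14, 24)], n_streamlines, jitter_mm),
        BundleSpec("VOF-toy", 6, 7, [(33, 17, 15)], n_streamlines, jitter_mm),
    ]


def toy_world(rng_seed: int = 0, n_streamlines: int = 40, jitter_mm: float = 0.6):
    """Convenience constructor: (parcellation, bundle_set, peak_field, qc)."""
    parc = make_toy_parcellation(TOY_GRID_SHAPE, toy_parcel_specs())
    bundles = make_bundles(parc, toy_bundle_specs(n_streamlines, jitter_mm), rng_seed)
    field, qc = make_peak_field(bundles, parc.grid, rng_seed=rng_seed)
    return parc, bundles, field, qc


def specs_from_config(doc: dict):
    """Parse one YAML/JSON document into (grid_shape, parcel specs, bundle
    specs, cohort spec). Expected keys: ``grid_shape``, ``parcels`` (each
    with parcel_id/name/lobe/box), ``bundles`` (name/start_parcel/end_parcel/
    waypoints/n_streamlines/jitter_mm), ``cohort`` (groups + seed), ``seed``.
    """
    grid_shape = tuple(doc.get("grid_shape", TOY_GRID_SHAPE))
    parcels = [ParcelSpec(**p) for p in doc.get("parcels", [])]
    bundles = [BundleSpec(**b) for b in doc.get("bundles", [])]
    cohort = None
    if "cohort" in doc:
        groups = {lab: GroupSpec(**g) for lab, g in doc["cohort"]["groups"].items()}
        cohort = CohortSpec(groups=groups, seed=int(doc["cohort"].get("seed", doc.get("seed", 0))))
    return grid_shape, parcels, bundles, cohort


def world_from_config(doc: dict, rng_seed: int | None = None):
    """Build (parcellation, bundles, field, cohort sites) from one document."""
    grid_shape, parcel_specs, bundle_specs, cohort = specs_from_config(doc)
    seed = int(doc.get("seed", 0)) if rng_seed is None else int(rng_seed)
    parc = make_toy_parcellation(grid_shape, parcel_specs)
    bundles = make_bundles(parc, bundle_specs, seed)
    field, qc = make_peak_field(bundles, parc.grid, rng_seed=seed)
    sites = make_cohort(cohort, bundles) if cohort is not None else []
    return parc, bundles, field, sites


def alexia_cohort_spec(seed: int = 0, placement_noise_mm: float = 0.8,
                       strong_effect: bool = False, include_language: bool = False) -> CohortSpec:
    """Cohort at the study's group sizes: 4 Ph-A, 16 Ls-A, 7 Pu-A sites (plus
    45 language-control sites when ``include_language`` is set, split 15/15/15
    across the three control labels — the study reports only their total).

    The default ("demo") programming mirrors the reported fingerprint: Ph-A
    predominantly hits the lsAF analogue, Pu-A the VOF analogue, and the ILF
    and pAF analogues are hit across groups. ``strong_effect`` instead gives
    Ph-A sites exclusively on the lsAF analogue, the recovery benchmark's
    programmed effect.
    """
    if strong_effect:
        groups = {
            "Ph-A": GroupSpec(4, ["lsAF-toy"], placement_noise_mm),
            "Ls-A": GroupSpec(16, ["ILF-toy", "pAF-toy"], placement_noise_mm),
            "Pu-A": GroupSpec(7, ["ILF-toy", "pAF-toy"], placement_noise_mm),
        }
    else:
        groups = {
            "Ph-A": GroupSpec(4, ["lsAF-toy", "lsAF-toy", "lsAF-toy", "pAF-toy"], placement_noise_mm),
            "Ls-A": GroupSpec(16, ["ILF-toy", "pAF-toy"], placement_noise_mm),
            "Pu-A": GroupSpec(
                7, ["VOF-toy", "VOF-toy", "VOF-toy", "ILF-toy", "pAF-toy"], placement_noise_mm
            ),
        }
    if include_language:
        groups["phonological paraphasia"] = GroupSpec(
            15, ["lsAF-toy", "pAF-toy"], placement_noise_mm
        )
        groups["semantic paraphasia"] = GroupSpec(15, ["IFOF-toy", "ILF-toy"], placement_noise_mm)
        groups["anomia"] = GroupSpec(15, ["ILF-toy", "IFOF-toy", "pAF-toy"], placement_noise_mm)
    return CohortSpec(groups=groups, seed=seed)
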