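"""End-to-end orchestration: world -> tracking -> VOI filtering -> matrices
-> group fingerprints -> statistics, with seeding, logging and a manifest.

A single master seed fans out to per-stage seeds through a documented
derivation (``derive_seed``), so each stage is independently reproducible
and no two stages share a stream. Identical config + seed reproduces every
output byte-for-byte.
"""
from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from . import matrices as dmat
from . import recognition as drec
from . import stats as dstats
from . import synthetic as dsyn
from .core import Tractogram
from .tracking import TrackingParams, generate_tractogram

log = logging.getLogger("disconnectome")

ALPHA = 0.05


def derive_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed: mix the master seed with a CRC of the stage name."""
    return (int(master_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """One document driving the whole analysis.

    Synthetic mode (default) generates the toy world; real mode consumes an
    atlas + label table, a site CSV, and either a precomputed tractogram or a
    peak field to track over.
    """

    master_seed: int = 0
    mode: str = "synthetic"  # or "real"
    out_dir: str | None = None
    # synthetic world
    n_streamlines: int = 40
    jitter_mm: float = 0.6
    cohort: str = "demo"  # "demo" | "strong" | "null"
    include_language: bool = False
    placement_noise_mm: float = 0.8
    # template tractogram
    tractogram_source: str = "bundles"  # "bundles" | "track"
    tracking: TrackingParams = field(default_factory=lambda: TrackingParams(n_seeds=1500))
    # analysis
    radii: tuple = dmat.DEFAULT_RADII_MM
    angle_sweep: tuple = (40.0, 50.0, 60.0)
    contrasts: list | None = None  # None: all label pairs with >= 2 sites
    q: float = 0.05
    z_crit: float = dstats.Z_CRIT_DEFAULT
    tau_mm: float = 4.0
    n_points: int = 20
    endpoint_search_radius_vox: int = 1
    # real-mode inputs
    atlas_path: str | None = None
    labels_path: str | None = None
    sites_path: str | None = None
    fibers_path: str | None = None
    direction_path: str | None = None
    qa_path: str | None = None

    def __post_init__(self):
        radii = tuple(float(r) for r in self.radii)
        if any(r <= 0 for r in radii) or list(radii) != sorted(radii):
            raise ValueError("radii must be positive and ascending")
        self.radii = radii
        self.angle_sweep = tuple(float(a) for a in self.angle_sweep)
        if isinstance(self.tracking, dict):
            self.tracking = TrackingParams(**self.tracking)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            doc = yaml.safe_load(f) or {}
        return cls(**doc)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["radii"] = list(self.radii)
        d["angle_sweep"] = list(self.angle_sweep)
        return d


def demo_config(out_dir=None, master_seed: int = 0) -> PipelineConfig:
    """Bundled demo: the synthetic mirror of the reported fingerprint
    (Ph-A predominantly lsAF-toy, Pu-A predominantly VOF-toy, ILF/pAF
    analogues shared across groups)."""
    return PipelineConfig(master_seed=master_seed, out_dir=out_dir, cohort="demo")


@dataclass
class PipelineReport:
    config: PipelineConfig
    parcellation: object
    sites: list
    template: Tractogram
    matrices_by_radius: dict  # radius -> list[DisconnectivityMatrix]
    group_sums: dict  # label -> DisconnectivityMatrix (main radius)
    chord_tables: dict  # label -> DataFrame
    comparisons: dict  # (a, b) -> ComparisonResult
    thresholded: dict  # (a, b) -> DataFrame
    tract_counts: pd.DataFrame
    unassigned: dict
    kruskal: dict  # tract -> {"H", "p", "dunn": DataFrame}
    voxel_stats: dict  # (a, b) -> VoxelStatMap
    monotonicity: pd.DataFrame
    manifest: dict
    bundle_set: object = None

    def significant_tracts(self, contrast) -> tuple:
        """Tracts whose omnibus test rejects and whose Dunn pair for this
        contrast is significant (adjusted p < 0.05)."""
        a, b = contrast
        out = []
        for tract, res in self.kruskal.items():
            if res["p"] >= ALPHA:
                continue
            dunn = res["dunn"]
            row = dunn[
                ((dunn.group_a == a) & (dunn.group_b == b))
                | ((dunn.group_a == b) & (dunn.group_b == a))
            ]
            if len(row) and float(row["p_adjusted"].iloc[0]) < ALPHA:
                out.append(tract)
        return tuple(sorted(out))


def _build_world(config: PipelineConfig):
    """Returns (parcellation, bundle_set, field, sites, models)."""
    if config.mode == "synthetic":
        world_seed = derive_seed(config.master_seed, "world")
        parc, bundles, fieldv, _qc = dsyn.toy_world(
            rng_seed=world_seed,
            n_streamlines=config.n_streamlines,
            jitter_mm=config.jitter_mm,
        )
        cohort_seed = derive_seed(config.master_seed, "cohort")
        if config.cohort == "null":
            sites = dsyn.make_null_cohort(
                {"Ph-A": 4, "Ls-A": 16, "Pu-A": 7}, bundles, cohort_seed,
                config.placement_noise_mm,
            )
        else:
            spec = dsyn.alexia_cohort_spec(
                seed=cohort_seed,
                placement_noise_mm=config.placement_noise_mm,
                strong_effect=(config.cohort == "strong"),
                include_language=config.include_language,
            )
            sites = dsyn.make_cohort(spec, bundles)
        models = drec.models_from_bundle_set(bundles, config.tau_mm, config.n_points)
        return parc, bundles, fieldv, sites, models
    # real mode
    from .tracking import PeakField

    parc = dio.read_parcellation(config.atlas_path, config.labels_path)
    sites = dio.sites_from_table(dio.read_sites(config.sites_path))
    fieldv = None
    if config.direction_path and config.qa_path:
        dgrid = dio.read_volume(config.direction_path, allow_4d=True)
        qgrid = dio.read_volume(config.qa_path)
        fieldv = PeakField(grid=qgrid, direction=dgrid.data, qa=qgrid.data)
    return parc, None, fieldv, sites, []


def _template_tractogram(config: PipelineConfig, bundles, fieldv,
                         max_angle_deg: float | None = None) -> Tractogram:
    if config.tractogram_source == "bundles":
        if bundles is None:
            return dio.read_tractogram(config.fibers_path)
        return bundles.tractogram
    params = TrackingParams(**{**asdict(config.tracking),
                               "rng_seed": derive_seed(config.master_seed, "tracking"),
                               **({"max_angle_deg": max_angle_deg} if max_angle_deg else {})})
    log.info("tracking: %d seeds, angle %.0f deg", params.n_seeds, params.max_angle_deg)
    return generate_tractogram(fieldv, params)


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the full analysis and (optionally) write every artifact."""
    parc, bundles, fieldv, sites, models = _build_world(config)
    template = _template_tractogram(config, bundles, fieldv)
    log.info("template tractogram: %d streamlines; %d sites", len(template), len(sites))

    index = dmat.StreamlineGeometryIndex(template)
    pairs = dmat.endpoint_pairs(template, parc, config.endpoint_search_radius_vox)
    site_labels = {s.site_id: s.label for s in sites}

    matrices_by_radius: dict = {}
    filtered_main: dict = {}
    mono_rows = []
    for radius in config.radii:
        mats = []
        for s in sites:
            voi = dmat.make_voi(s, radius)
            mask = index.intersect_mask(voi)
            m = dmat.matrix_from_pairs(
                pairs[mask], parc.parcel_ids, site_id=s.site_id,
                params={"radius_mm": radius},
            )
            mats.append(m)
            mono_rows.append(
                {"site_id": s.site_id, "radius_mm": radius,
                 "n_disconnected": int(mask.sum())}
            )
            if radius == config.radii[0]:
                filtered_main[s.site_id] = template.subset(mask)
        matrices_by_radius[radius] = mats
    monotonicity = pd.DataFrame(mono_rows)

    main_radius = config.radii[0]
    main_matrices = matrices_by_radius[main_radius]
    group_sums = dmat.sum_by_group(main_matrices, site_labels)
    chord_tables = {lab: dmat.export_chord_table(gm, parc.table)
                    for lab, gm in group_sums.items()}

    # group contrasts at the matrix level
    label_counts = pd.Series([s.label for s in sites]).value_counts()
    eligible = [lab for lab in dict.fromkeys(site_labels.values()) if label_counts[lab] >= 2]
    contrasts = config.contrasts or list(combinations(eligible, 2))
    by_label: dict[str, list] = {}
    for m in main_matrices:
        by_label.setdefault(site_labels[m.site_id], []).append(m)
    comparisons, thresholded = {}, {}
    for a, b in contrasts:
        res = dstats.matrixwise_compare(by_label[a], by_label[b], (a, b))
        comparisons[(a, b)] = res
        thresholded[(a, b)] = dstats.threshold_pairs(res, config.z_crit)

    # tract-level counts and tests
    if models:
        tract_counts, unassigned = drec.count_disconnected_by_tract(
            filtered_main, models, site_labels
        )
    else:
        tract_counts, unassigned = pd.DataFrame(
            columns=["site_id", "label", "tract_name", "n_streamlines"]
        ), {}
    kruskal = {}
    group_order = list(dict.fromkeys(site_labels.values()))
    for tract in sorted(tract_counts["tract_name"].unique()):
        sub = tract_counts[tract_counts.tract_name == tract]
        labels = [lab for lab in group_order if (sub.label == lab).any()]
        groups = [sub[sub.label == lab]["n_streamlines"].to_numpy() for lab in labels]
        h, p = dstats.kruskal_wallis(groups)
        dunn = dstats.dunn_posthoc(groups, labels=labels)
        kruskal[tract] = {"H": h, "p": p, "dunn": dunn}

    # voxel-level chi-square with BH-FDR
    site_maps = {sid: dstats.binarize_tractogram(t, parc.grid)
                 for sid, t in filtered_main.items()}
    voxel_stats = {}
    for a, b in contrasts:
        maps_a = [site_maps[s.site_id] for s in sites if s.label == a]
        maps_b = [site_maps[s.site_id] for s in sites if s.label == b]
        voxel_stats[(a, b)] = dstats.voxelwise_chisq(maps_a, maps_b, q=config.q)

    manifest = {
        "config": config.to_dict(),
        "derived_seeds": {stage: derive_seed(config.master_seed, stage)
                          for stage in ("world", "cohort", "tracking")},
        "n_sites": len(sites),
        "n_template_streamlines": len(template),
        "contrasts": [list(c) for c in contrasts],
        "outputs": {},
    }
    report = PipelineReport(
        config=config, parcellation=parc, sites=sites, template=template,
        matrices_by_radius=matrices_by_radius, group_sums=group_sums,
        chord_tables=chord_tables, comparisons=comparisons, thresholded=thresholded,
        tract_counts=tract_counts, unassigned=unassigned, kruskal=kruskal,
        voxel_stats=voxel_stats, monotonicity=monotonicity, manifest=manifest,
        bundle_set=bundles,
    )
    if config.out_dir:
        _write_outputs(report, Path(config.out_dir))
    return report


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_outputs(report: PipelineReport, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cfg = report.config
    parc = report.parcellation
    written: dict[str, str] = {}

    def emit_csv(df: pd.DataFrame, name: str):
        path = out / name
        df.to_csv(path, index=False)
        written[name] = _sha256(path)

    dio.write_sites(report.sites, out / "sites.csv")
    written["sites.csv"] = _sha256(out / "sites.csv")
    dio.write_parcellation(parc, out / "parcellation.nii.gz", out / "parcel_labels.csv")
    written["parcel_labels.csv"] = _sha256(out / "parcel_labels.csv")

    main_radius = cfg.radii[0]
    per_site = []
    for m in report.matrices_by_radius[main_radius]:
        ids = list(m.parcel_ids)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if m.counts[i, j]:
                    per_site.append({"site_id": m.site_id, "parcel_a": ids[i],
                                     "parcel_b": ids[j], "count": int(m.counts[i, j])})
    emit_csv(pd.DataFrame(per_site, columns=["site_id", "parcel_a", "parcel_b", "count"]),
             "site_matrices_long.csv")

    for lab, gm in report.group_sums.items():
        safe = lab.replace(" ", "_")
        dio.write_matrix_dense(gm.counts, gm.parcel_ids, out / f"group_{safe}_dense.csv")
        written[f"group_{safe}_dense.csv"] = _sha256(out / f"group_{safe}_dense.csv")
        emit_csv(report.chord_tables[lab], f"chord_{safe}.csv")

    for (a, b), res in report.comparisons.items():
        safe = f"{a}_vs_{b}".replace(" ", "_")
        dio.write_matrix_dense(res.Z, res.parcel_ids, out / f"Z_{safe}.csv")
        written[f"Z_{safe}.csv"] = _sha256(out / f"Z_{safe}.csv")
        dio.write_matrix_dense(res.p, res.parcel_ids, out / f"p_{safe}.csv")
        written[f"p_{safe}.csv"] = _sha256(out / f"p_{safe}.csv")
        emit_csv(report.thresholded[(a, b)], f"pairs_{safe}.csv")

    emit_csv(report.tract_counts, "tract_counts.csv")
    emit_csv(report.monotonicity, "radius_monotonicity.csv")

    stats_report = {
        "alpha": ALPHA,
        "q": cfg.q,
        "z_crit": cfg.z_crit,
        "kruskal_wallis": {
            tract: {"H": res["H"], "p": res["p"],
                    "dunn": res["dunn"].to_dict(orient="records")}
            for tract, res in report.kruskal.items()
        },
        "voxel_rejections": {
            f"{a} vs {b}": int(vm.fdr_mask.sum())
            for (a, b), vm in report.voxel_stats.items()
        },
        "unassigned_streamlines": report.unassigned,
    }
    (out / "stats_report.json").write_text(json.dumps(stats_report, indent=2, sort_keys=True))
    written["stats_report.json"] = _sha256(out / "stats_report.json")

    from .core import VolumeGrid

    for (a, b), vm in report.voxel_stats.items():
        safe = f"{a}_vs_{b}".replace(" ", "_")
        for name, data, dtype in (("chi2", vm.chi2, np.float32),
                                  ("p", vm.p, np.float32),
                                  ("fdr_mask", vm.fdr_mask.astype(np.uint8), np.uint8)):
            path = out / f"voxel_{name}_{safe}.nii.gz"
            dio.write_volume(VolumeGrid(parc.grid.shape, parc.grid.affine, data), path, dtype)

    report.manifest["outputs"] = written
    try:
        import importlib.metadata as md
        versions = {"disconnectome": md.version("disconnectome"), "numpy": np.__version__}
    except Exception:  # pragma: no cover
        versions = {"numpy": np.__version__}
    report.manifest["versions"] = versions
    (out / "manifest.json").write_text(json.dumps(report.manifest, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# sensitivity sweep


@dataclass
class SweepReport:
    concordance: pd.DataFrame  # contrast, angle, radius, significant_tracts
    concordant: dict  # contrast -> bool (identical sets across the sweep)
    monotonic_ok: bool
    monotonicity: pd.DataFrame


def run_sensitivity(config: PipelineConfig) -> SweepReport:
    """Rerun the tract-level contrasts over radii x angular thresholds.

    Emits a concordance table (per contrast: the set of significant tracts in
    each sweep cell) and the per-site disconnected-count monotonicity audit
    over radii. When the template comes from precomputed bundles the angular
    threshold has no effect by construction; the sweep is primarily meaningful
    with ``tractogram_source='track'``.
    """
    parc, bundles, fieldv, sites, models = _build_world(config)
    site_labels = {s.site_id: s.label for s in sites}
    label_counts = pd.Series([s.label for s in sites]).value_counts()
    eligible = [lab for lab in dict.fromkeys(site_labels.values()) if label_counts[lab] >= 2]
    contrasts = config.contrasts or list(combinations(eligible, 2))
    group_order = list(dict.fromkeys(site_labels.values()))

    rows, mono_rows = [], []
    for angle in config.angle_sweep:
        template = _template_tractogram(config, bundles, fieldv, max_angle_deg=angle)
        index = dmat.StreamlineGeometryIndex(template)
        for radius in config.radii:
            filtered = {}
            for s in sites:
                mask = index.intersect_mask(dmat.make_voi(s, radius))
                filtered[s.site_id] = template.subset(mask)
                mono_rows.append({"site_id": s.site_id, "angle_deg": angle,
                                  "radius_mm": radius, "n_disconnected": int(mask.sum())})
            counts, _ = drec.count_disconnected_by_tract(filtered, models, site_labels)
            sig_by_contrast = _significant_tracts(counts, group_order, contrasts)
            for contrast, tracts in sig_by_contrast.items():
                rows.append({"contrast": " vs ".join(contrast), "angle_deg": angle,
                             "radius_mm": radius,
                             "significant_tracts": ";".join(tracts)})
    concordance = pd.DataFrame(rows)
    concordant = {}
    for contrast in concordance["contrast"].unique():
        sets = concordance.loc[concordance.contrast == contrast, "significant_tracts"]
        concordant[contrast] = bool(sets.nunique() == 1)

    mono = pd.DataFrame(mono_rows)
    monotonic_ok = True
    for (sid, angle), sub in mono.groupby(["site_id", "angle_deg"]):
        counts = sub.sort_values("radius_mm")["n_disconnected"].to_numpy()
        if np.any(np.diff(counts) < 0):
            monotonic_ok = False
    return SweepReport(concordance=concordance, concordant=concordant,
                       monotonic_ok=monotonic_ok, monotonicity=mono)


def _significant_tracts(tract_counts: pd.DataFrame, group_order, contrasts) -> dict:
    out = {tuple(c): () for c in contrasts}
    kw = {}
    for tract in sorted(tract_counts["tract_name"].unique()):
        sub = tract_counts[tract_counts.tract_name == tract]
        labels = [lab for lab in group_order if (sub.label == lab).any()]
        groups = [sub[sub.label == lab]["n_streamlines"].to_numpy() for lab in labels]
        h, p = dstats.kruskal_wallis(groups)
        dunn = dstats.dunn_posthoc(groups, labels=labels)
        kw[tract] = (p, dunn)
    for a, b in contrasts:
        sig = []
        for tract, (p, dunn) in kw.items():
            if p >= ALPHA:
                continue
            row = dunn[((dunn.group_a == a) & (dunn.group_b == b))
                       | ((dunn.group_a == b) & (dunn.group_b == a))]
            if len(row) and float(row["p_adjusted"].iloc[0]) < ALPHA:
                sig.append(tract)
        out[(a, b)] = tuple(sorted(sig))
    return out
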