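"""Monte-Carlo benchmarks of the pipeline on the synthetic toy world.

Three studies, all at the study's group sizes (4 Ph-A, 16 Ls-A, 7 Pu-A):

- ``null_calibration``: type-I-error surface of the matrix-cell
  Mann-Whitney maps on cohorts whose labels carry no information.
- ``fingerprint_recovery``: recovery of a programmed strong subtype->bundle
  effect (Ph-A exclusively on the lsAF analogue) at the matrix, tract and
  voxel levels.
- ``angle_sweep_concordance``: invariance of the significant-tract sets
  under angular thresholds of 40/50/60 degrees, with actual tracking.

The world (parcellation, bundles, peak field) is built once per study; only
the cohorts are redrawn across replicates, which is the stochastic element
the studies probe.
"""
from __future__ import annotations

import numpy as np

from . import matrices as dmat
from . import recognition as drec
from . import stats as dstats
from . import synthetic as dsyn
from .pipeline import ALPHA, PipelineConfig, derive_seed, run_sensitivity

STUDY_GROUP_SIZES = {"Ph-A": 4, "Ls-A": 16, "Pu-A": 7}


def _prepared_world(seed: int):
    parc, bundles, fieldv, _ = dsyn.toy_world(rng_seed=derive_seed(seed, "world"))
    index = dmat.StreamlineGeometryIndex(bundles.tractogram)
    pairs = dmat.endpoint_pairs(bundles.tractogram, parc)
    return parc, bundles, fieldv, index, pairs


def _per_site_matrices(sites, index, pairs, parcel_ids, radius=2.5):
    mats, masks = [], {}
    for s in sites:
        mask = index.intersect_mask(dmat.make_voi(s, radius))
        masks[s.site_id] = mask
        mats.append(dmat.matrix_from_pairs(pairs[mask], parcel_ids, site_id=s.site_id))
    return mats, masks


def null_calibration(seed: int = 0, n_replicates: int = 200,
                     group_sizes: dict | None = None) -> dict:
    """Mean fraction of |Z| > 1.96 cells across null-cohort replicates.

    Cells entering the fraction are those with any nonzero per-site count in
    either group of the contrast (all-zero cells are untestable and carry
    Z = 0 by convention). All three pairwise contrasts contribute.
    """
    group_sizes = dict(group_sizes or STUDY_GROUP_SIZES)
    parc, bundles, _, index, pairs = _prepared_world(seed)
    labels = list(group_sizes)
    fractions = []
    for rep in range(n_replicates):
        sites = dsyn.make_null_cohort(
            group_sizes, bundles, rng_seed=derive_seed(seed, f"null-{rep}")
        )
        mats, _ = _per_site_matrices(sites, index, pairs, parc.parcel_ids)
        by_label: dict[str, list] = {}
        for s, m in zip(sites, mats):
            by_label.setdefault(s.label, []).append(m)
        n_flagged = n_tested = 0
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                res = dstats.matrixwise_compare(
                    by_label[labels[i]], by_label[labels[j]], (labels[i], labels[j])
                )
                upper = np.triu(np.ones_like(res.tested, dtype=bool), k=1)
                tested = res.tested & upper
                n_tested += int(tested.sum())
                n_flagged += int((np.abs(res.Z[tested]) > dstats.Z_CRIT_DEFAULT).sum())
        fractions.append(n_flagged / n_tested if n_tested else 0.0)
    fractions = np.asarray(fractions)
    return {
        "mean_fraction": float(fractions.mean()),
        "n_replicates": int(n_replicates),
        "fractions": fractions,
    }


TRUE_PAIR = (1, 3)  # MFG-toy <-> ITG-ant-toy, the lsAF analogue's endpoints
TRUE_TRACT = "lsAF-toy"
EFFECT_GROUP = "Ph-A"
REFERENCE_GROUP = "Ls-A"


def fingerprint_recovery(seed: int = 0, n_replicates: int = 50) -> dict:
    """Strong-effect recovery rates at the matrix, tract and voxel levels.

    Per replicate the programmed cohort places every Ph-A site on the lsAF
    analogue and every Ls-A/Pu-A site on the shared ILF/pAF analogues, and
    the replicate succeeds at:

    - matrix level when the lsAF endpoints' parcel pair is among the
      |Z| > 1.96 cells of the Ph-A vs Ls-A contrast;
    - tract level when Kruskal-Wallis rejects on the lsAF-analogue counts and
      Dunn's Ph-A vs Ls-A comparison is significant after adjustment;
    - voxel level when the BH-FDR mask of the Ph-A vs Ls-A voxelwise
      chi-square is nonempty and lies entirely within the lsAF analogue's
      ground-truth corridor.
    """
    parc, bundles, _, index, pairs = _prepared_world(seed)
    models = drec.models_from_bundle_set(bundles)
    from .core import Tractogram

    corridor = dstats.binarize_tractogram(
        Tractogram(bundles.streamlines_of(TRUE_TRACT)), parc.grid
    ).astype(bool)
    i_true = parc.parcel_ids.index(TRUE_PAIR[0])
    j_true = parc.parcel_ids.index(TRUE_PAIR[1])

    hits_matrix = hits_tract = hits_voxel = 0
    for rep in range(n_replicates):
        spec = dsyn.alexia_cohort_spec(
            seed=derive_seed(seed, f"strong-{rep}"), strong_effect=True
        )
        sites = dsyn.make_cohort(spec, bundles)
        mats, masks = _per_site_matrices(sites, index, pairs, parc.parcel_ids)
        by_label: dict[str, list] = {}
        for s, m in zip(sites, mats):
            by_label.setdefault(s.label, []).append(m)

        res = dstats.matrixwise_compare(
            by_label[EFFECT_GROUP], by_label[REFERENCE_GROUP],
            (EFFECT_GROUP, REFERENCE_GROUP),
        )
        if abs(res.Z[i_true, j_true]) > dstats.Z_CRIT_DEFAULT:
            hits_matrix += 1

        site_labels = {s.site_id: s.label for s in sites}
        filtered = {s.site_id: bundles.tractogram.subset(masks[s.site_id]) for s in sites}
        counts, _ = drec.count_disconnected_by_tract(filtered, models, site_labels)
        sub = counts[counts.tract_name == TRUE_TRACT]
        labels = list(STUDY_GROUP_SIZES)
        groups = [sub[sub.label == lab]["n_streamlines"].to_numpy() for lab in labels]
        h, p = dstats.kruskal_wallis(groups)
        if p < ALPHA:
            dunn = dstats.dunn_posthoc(groups, labels=labels)
            row = dunn[((dunn.group_a == EFFECT_GROUP) & (dunn.group_b == REFERENCE_GROUP))
                       | ((dunn.group_a == REFERENCE_GROUP) & (dunn.group_b == EFFECT_GROUP))]
            if len(row) and float(row["p_adjusted"].iloc[0]) < ALPHA:
                hits_tract += 1

        maps_a = [dstats.binarize_tractogram(filtered[s.site_id], parc.grid)
                  for s in sites if s.label == EFFECT_GROUP]
        maps_b = [dstats.binarize_tractogram(filtered[s.site_id], parc.grid)
                  for s in sites if s.label == REFERENCE_GROUP]
        vm = dstats.voxelwise_chisq(maps_a, maps_b)
        if vm.fdr_mask.any() and not (vm.fdr_mask & ~corridor).any():
            hits_voxel += 1

    n = float(n_replicates)
    return {
        "n_replicates": n_replicates,
        "matrix_rate": hits_matrix / n,
        "tract_rate": hits_tract / n,
        "voxel_rate": hits_voxel / n,
    }


def angle_sweep_concordance(seed: int = 0, n_seeds: int = 1200) -> dict:
    """Track the strong-effect cohort at 40/50/60 degrees and check that the
    per-contrast significant-tract sets are identical across thresholds."""
    from .tracking import TrackingParams

    config = PipelineConfig(
        master_seed=seed, cohort="strong", tractogram_source="track",
        tracking=TrackingParams(n_seeds=n_seeds), radii=(2.5,),
        angle_sweep=(40.0, 50.0, 60.0),
    )
    sweep = run_sensitivity(config)
    return {
        "all_concordant": bool(all(sweep.concordant.values())),
        "concordant": sweep.concordant,
        "monotonic_ok": sweep.monotonic_ok,
        "concordance": sweep.concordance,
    }
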