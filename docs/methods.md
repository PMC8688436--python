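# Methods

## The analysis model

A stimulation site is modelled as a point perturbation of the white matter:
a sphere of radius 2.5 mm (the spatial resolution of the bipolar probe)
centred on the site's MNI coordinate. Its *disconnectome* is the set of
template streamlines passing through that sphere, and its *disconnectivity
fingerprint* is the symmetric P × P matrix counting, for every pair of
parcels, the disconnected streamlines whose two endpoints fall in those
parcels. Groups of sites (one group per behavioural response) are contrasted
at three granularities: matrix cells (Mann–Whitney Z), named tracts
(Kruskal–Wallis + Dunn on recognized-streamline counts) and voxels
(chi-square on binarized traversal maps, BH-FDR).

The package consumes a fiber-peak + anisotropy template (or a precomputed
tractogram); it does not reconstruct orientations from diffusion data.

## Deterministic tracking

One peak per voxel. From a seed, propagation runs in both ±peak directions;
at each 1.0 mm step the new direction is

    normalize((1 − s) · peak_signed + s · prev),   s = 0.20 by default,

where `peak_signed` is the voxel peak flipped, if necessary, to agree with
the previous direction (peaks are sign-symmetric). The scalar smoothing
formula is the common deterministic-tracker convention; the analysis this
package reproduces names a smoothing value without printing a formula, so
the convention is stated here explicitly. A half terminates when the next
point leaves the grid (the out-of-grid point is dropped), the voxel
anisotropy falls below the threshold (0.12, chosen to exclude background),
the angle between consecutive propagation directions exceeds the angular
threshold (50°; 40° and 60° in sensitivity sweeps), or the length budget is
exhausted. The budget is split half per direction so the concatenated
streamline never exceeds `max_length_mm` (300 mm default — never binding in
the 40 mm toy world). With smoothing 0 the tracker reduces exactly to pure
peak-following (verified against an independent reference implementation).

Direction and label lookup are nearest-voxel: labels are categorical and the
template grid is 1 mm isotropic, so nearest sampling is adequate and keeps
every step reproducible and auditable. Two post-hoc audits (max turning
angle, min visited anisotropy) are exported for QC and enforced in tests.

Seeding: the default strategy seeds uniformly inside the supra-threshold
mask and applies the VOI as an intersection filter ("fibers intersecting the
VOI"); VOI-restricted seeding is available for efficiency. Whether the
original analysis seeded whole-brain or per-VOI is not stated; both are
supported, neither asserted.

## VOI filtering and matrices

Sphere membership is segment-based (closest approach of each streamline
segment to the centre), so a 2.5 mm sphere cannot be jumped over by a 1 mm
step. Per-site counts are therefore non-decreasing in the radius
(2.5 → 3.0 → 3.5 mm), which the sensitivity audit checks exhaustively.

Endpoints are embedded with a 1-voxel fallback search (most frequent
nonzero label in the cubic neighbourhood, ties to the smallest parcel id):
streamline termini often sit at label borders. Strict lookup
(`search_radius_vox=0`) is available. Streamlines with an unlabeled endpoint
or with both endpoints in the same parcel are excluded from the matrix and
tallied in a QC count, preserving the conservation law

    upper-triangle total + QC-excluded = filtered streamline count.

Same-parcel exclusion follows from reading the fingerprint as *pairwise*
disconnection between distinct areas; the original work does not state its
choice, and the tally keeps the excluded mass visible. Only left-hemisphere
parcels populate the label table, so interhemispheric streamlines drop out
through the unlabeled-endpoint rule.

Chord tables report both the raw summed count and the per-site mean (the
two possible readings of chord thickness), plus per-lobe marginal shares
(cell count ÷ summed count of all cells touching that lobe).

## Statistics

*Mann–Whitney.* Tie-corrected normal approximation without continuity
correction; Z is positive when the first group's counts rank higher;
all-tied cells carry Z = 0, p = 1. Cells that are zero in every site of both
groups are not testable and are excluded from the tested family. No
multiplicity correction at this level, matching the exploratory use of the
serial tests; the reporting cutoff |Z| > 1.96 is the two-sided 5% normal
critical value. The exhaustive permutation oracle in the test suite shows
the approximation agrees with the exact test in the rejection region but can
differ substantially (up to ~0.5 in p) near the centre of the discrete,
heavily tied null distribution at these sample sizes — the reported Z values
are a ranking device, not calibrated central p-values.

*Kruskal–Wallis / Dunn.* Tie-corrected H with chi-square reference (k−1 df);
Dunn z from pooled tie-corrected ranks, Bonferroni-adjusted over the
k(k−1)/2 pairs by default (Šidák available). The original analysis names
"Dunn's test" without the adjustment; Bonferroni is the conservative common
default.

*Voxelwise chi-square.* Per voxel, the 2 × 2 table group × traversed/not,
Pearson chi-square with 1 df and no continuity correction (none is
mentioned in the source analysis; a switch exists in the 2 × 2 formula if
needed). The FDR family is the set of voxels traversed in at least one map —
untested voxels have undefined tables. BH step-up at q = 0.05.

## The synthetic world

The toy world is a 40 × 40 × 40 voxel grid at 1 mm isotropic (the template
resolution, desk scale): eight box parcels in four lobes and five bundles
named after the reading-related association tracts (lsAF, pAF, ILF, IFOF,
VOF analogues). Bundle centerlines are piecewise-linear waypoint curves
resampled at 1 mm — matching the tracker step so synthetic tangents are well
defined — with corner angles kept well below 40° so all sweep thresholds
track them. Members get a constant lateral offset of norm ≤ jitter (0.6 mm
default), keeping endpoint parcels exact. The peak field accumulates segment
tangents per voxel as outer products and takes the principal eigenvector
(sign-symmetric by construction; serialized with the first nonzero component
nonnegative); corridor voxels get anisotropy 0.30, background 0.05 —
straddling the 0.12 threshold by construction. Voxels whose largest tangent
eigenvalue is below 2/3 of the trace (no dominant direction, i.e. bundle
crossings) are flagged "unreliable" in the QC report, not errored.

Cohorts: surgery provides no generative model for site placement, so the
generator's Gaussian-on-bundle placement is this package's own assumption.
A site is a random interior polyline vertex of its target bundle plus
isotropic Gaussian noise (sd 0.8 mm default, comfortably inside the 2.5 mm
VOI). Placement uses the interior 70% of each polyline: termini are
cortical, stimulation is in white matter, and interior placement prevents
spurious cross-capture where several bundles share a terminus region.
Within a group the target bundle cycles deterministically through the
(possibly repeated) target list in site order while the position along the
bundle stays random: programmed effects then have deterministic coverage
even at n = 4, where uniform random choice would leave the effect bundle
unhit in a non-negligible fraction of draws. Null cohorts draw every group
from the pooled distribution over all bundles, so labels carry no
information.

Group sizes follow the study: 4 Ph-A, 16 Ls-A, 7 Pu-A (27 alexia sites),
plus 45 language-control sites when enabled. The study reports only the
total of 45; the generator splits them 15/15/15 across phonological
paraphasia, semantic paraphasia and anomia.

What the toy world does *not* emulate: realistic brain geometry, multi-fiber
voxels, partial-volume and registration error, lesion-induced template
mismatch, and the spatial sampling bias of surgical access. Passing tests
therefore demonstrate the correctness and calibration of the *pipeline*, not
the reproducibility of any particular empirical coordinate-level result.

## Recognition

Bundle assignment is nearest-exemplar classification under the minimum
average direct-flip (MDF) distance on 20-point resampled streamlines, with a
per-bundle threshold τ = 4 mm in the toy geometry (bundle separations are
≫ τ and member jitter ≪ τ). Original toolbox "recognize" algorithms are
proprietary; this surrogate is standard, reproducible and oracle-testable,
and no numerical tract count from the reference analysis is treated as an
implementation-reproducible target.

## Problem sizes and numerical choices

Toy analyses use 40 streamlines per bundle, 800–1500 tracker seeds, 200
null-calibration replicates and 50 recovery replicates — sizes chosen so the
whole study re-runs in minutes on one CPU while keeping Monte-Carlo rates
stable to well under the 90%/7% decision margins. The tracker's parameter
defaults remain the full-scale ones (50 000 seeds); toy configs override
them explicitly. Master seeds fan out to per-stage seeds via
`seed * 1000003 + crc32(stage) mod 2^31`, recorded in the manifest.
Degenerate inputs are handled explicitly: zero-length streamlines are
rejected at resampling, a zero peak vector terminates propagation, all-tied
samples return (Z = 0, p = 1), identical pooled data returns (H = 0, p = 1),
and empty groups in summation yield a zero matrix with a warning.

## Known limitations

- One peak per voxel: crossing, kissing and fanning configurations collapse
  to the principal direction (flagged in QC, not resolved).
- Recognition quality depends on exemplar coverage and a single global τ per
  bundle; atlas-scale automatic segmentation is out of scope.
- Matrix-level p-values are uncorrected and, with n = 4 per group, the
  normal approximation is a ranking device (see above); tract- and
  voxel-level results carry the corrected inference.
- Counts are raw streamline counts; no normalization by template streamline
  totals or probabilistic disconnection weighting.
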