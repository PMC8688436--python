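"""Group contrasts: matrix-cell Mann-Whitney Z maps, tract-count
Kruskal-Wallis with Dunn post hoc, and voxelwise chi-square with BH-FDR.

Conventions (the source analyses report the statistics without spelling
these out, so they are fixed here):

- Mann-Whitney uses the normal approximation with tie-corrected variance and
  no continuity correction; Z is positive when the FIRST group's per-site
  counts rank higher; all-tied data yields Z = 0, p = 1.
- Matrix-cell comparisons are deliberately left uncorrected for multiple
  comparisons (exploratory serial tests); the reporting cutoff |Z| > 1.96 is
  the two-sided standard-normal critical value at alpha = 0.05.
- Dunn's post hoc z uses pooled tie-corrected ranks; the default adjustment
  is Bonferroni over the k(k-1)/2 pairs (Sidak available).
- The voxelwise test is Pearson chi-square on the 2x2 traversal table with
  1 df and no continuity correction; the FDR family is the voxels traversed
  in at least one map (untested voxels have undefined tables).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import DisconnectivityMatrix, Tractogram, VolumeGrid

Z_CRIT_DEFAULT = 1.96  # two-sided alpha = 0.05 under the standard normal


# ---------------------------------------------------------------------------
# Mann-Whitney


def mannwhitney_z(x, y):
    """Rank-sum U, tie-corrected normal Z and two-sided p for two samples.

    Returns ``(U, Z, p)`` where U is the first sample's U statistic. All-tied
    data (zero variance) yields ``(n1*n2/2, 0.0, 1.0)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    n = n1 + n2
    ranks = sps.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return (n1 * n2 / 2.0, 0.0, 1.0)
    z = (u1 - n1 * n2 / 2.0) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return (float(u1), float(z), float(min(p, 1.0)))


@dataclass
class ComparisonResult:
    """Per-cell Z and uncorrected p matrices for a two-group contrast."""

    Z: np.ndarray
    p: np.ndarray
    group_names: tuple
    n: tuple  # (n_first, n_second) sites per group
    parcel_ids: tuple
    tested: np.ndarray = None  # cells with any nonzero data in either group

    def summary(self, z_crit: float = Z_CRIT_DEFAULT, max_rows: int = 10) -> str:
        pairs = threshold_pairs(self, z_crit)
        lines = [
            f"Matrix-cell Mann-Whitney contrast: {self.group_names[0]} "
            f"(n={self.n[0]}) vs {self.group_names[1]} (n={self.n[1]})",
            f"cells tested: {int(self.tested.sum()) if self.tested is not None else 'n/a'}; "
            f"|Z| > {z_crit:g}: {len(pairs)}",
        ]
        for _, row in pairs.head(max_rows).iterrows():
            lines.append(
                f"  parcels ({row['parcel_a']}, {row['parcel_b']}): "
                f"Z = {row['Z']:+.2f}, p = {row['p']:.4f}"
            )
        return "\n".join(lines)


def matrixwise_compare(group_a, group_b, group_names=("A", "B")) -> ComparisonResult:
    """Cellwise Mann-Whitney over per-site disconnectivity counts.

    Each upper-triangle cell is tested on the per-site counts of the two
    groups (>= 2 sites each); Z and p are mirrored to full symmetric
    matrices. No multiple-comparison adjustment is applied.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 sites")
    ref = group_a[0].parcel_ids
    for m in list(group_a) + list(group_b):
        if m.parcel_ids != ref:
            raise ValueError("matrices have mixed parcel orderings")
    p_count = len(ref)
    a = np.stack([m.counts for m in group_a])
    b = np.stack([m.counts for m in group_b])
    Z = np.zeros((p_count, p_count))
    P = np.ones((p_count, p_count))
    tested = np.zeros((p_count, p_count), dtype=bool)
    for i in range(p_count):
        for j in range(i + 1, p_count):
            xa, xb = a[:, i, j], b[:, i, j]
            if not (xa.any() or xb.any()):
                continue  # all-zero in both groups: Z = 0, p = 1
            _, z, p = mannwhitney_z(xa, xb)
            Z[i, j] = Z[j, i] = z
            P[i, j] = P[j, i] = p
            tested[i, j] = tested[j, i] = True
    return ComparisonResult(
        Z=Z, p=P, group_names=tuple(group_names), n=(len(group_a), len(group_b)),
        parcel_ids=ref, tested=tested,
    )


def threshold_pairs(result: ComparisonResult, z_crit: float = Z_CRIT_DEFAULT) -> pd.DataFrame:
    """Upper-triangle cells with |Z| > z_crit, sorted by |Z| descending."""
    ids = list(result.parcel_ids)
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            z = result.Z[i, j]
            if abs(z) > z_crit:
                rows.append(
                    {"parcel_a": ids[i], "parcel_b": ids[j],
                     "Z": float(z), "p": float(result.p[i, j])}
                )
    df = pd.DataFrame(rows, columns=["parcel_a", "parcel_b", "Z", "p"])
    if len(df):
        df = df.astype({"parcel_a": int, "parcel_b": int})
        df = df.reindex(df["Z"].abs().sort_values(ascending=False).index).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# tract-level tests


def kruskal_wallis(groups):
    """Tie-corrected Kruskal-Wallis H and chi-square p (k-1 df)."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(pooled == pooled[0]):
        return (0.0, 1.0)
    h, p = sps.kruskal(*groups)
    return (float(h), float(p))


def dunn_posthoc(groups, labels=None, adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's pairwise post hoc from pooled tie-corrected ranks.

    Returns one row per group pair with z, unadjusted p and adjusted p
    (Bonferroni: ``min(1, p * k(k-1)/2)``; Sidak: ``1 - (1-p)^m``).
    """
    if adjust not in ("bonferroni", "sidak"):
        raise ValueError("adjust must be 'bonferroni' or 'sidak'")
    k = len(groups)
    if k < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes, pos = [], [], 0
    for g in arrays:
        mean_ranks.append(float(ranks[pos : pos + len(g)].mean()))
        sizes.append(len(g))
        pos += len(g)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum())
    base_var = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))
    m = k * (k - 1) // 2
    rows = []
    for i, j in combinations(range(k), 2):
        se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se <= 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
        if adjust == "bonferroni":
            p_adj = min(1.0, p * m)
        else:
            p_adj = 1.0 - (1.0 - p) ** m
        rows.append(
            {"group_a": labels[i], "group_b": labels[j],
             "z": float(z), "p_unadjusted": p, "p_adjusted": float(p_adj)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# voxel-level tests


def binarize_tractogram(t: Tractogram, grid: VolumeGrid) -> np.ndarray:
    """Binary traversal map: voxel = 1 iff >= 1 streamline segment passes
    through it (segments sampled at <= half the smallest voxel size)."""
    vol = np.zeros(grid.shape, dtype=np.uint8)
    step = 0.5 * float(np.min(grid.voxel_sizes))
    for s in t:
        p0, p1 = s[:-1], s[1:]
        lengths = np.linalg.norm(p1 - p0, axis=1)
        pieces = [s[:1]]
        for a, b, L in zip(p0, p1, lengths):
            n = max(int(np.ceil(L / step)), 1)
            ts = np.linspace(0.0, 1.0, n + 1)[1:]
            pieces.append(a + ts[:, None] * (b - a))
        dense = np.vstack(pieces)
        vox = grid.world_to_voxel(dense)
        ok = grid.in_bounds(vox)
        vox = vox[ok]
        vol[vox[:, 0], vox[:, 1], vox[:, 2]] = 1
    return vol


@dataclass
class VoxelStatMap:
    chi2: np.ndarray
    p: np.ndarray
    fdr_mask: np.ndarray
    tested: np.ndarray
    q: float = 0.05


def voxelwise_chisq(maps_a, maps_b, q: float = 0.05) -> VoxelStatMap:
    """Voxelwise two-sided Pearson chi-square between two groups of binary
    traversal maps, BH-FDR corrected at level ``q`` over the tested voxels."""
    maps_a = np.stack([np.asarray(m) for m in maps_a])
    maps_b = np.stack([np.asarray(m) for m in maps_b])
    if maps_a.shape[1:] != maps_b.shape[1:]:
        raise ValueError("groups must share the voxel grid")
    if maps_a.shape[0] < 2 or maps_b.shape[0] < 2:
        raise ValueError("each group needs at least 2 maps")
    na, nb = maps_a.shape[0], maps_b.shape[0]
    a = maps_a.sum(axis=0).astype(float)  # traversed in group A
    c = maps_b.sum(axis=0).astype(float)
    b = na - a
    d = nb - c
    n = float(na + nb)
    tested = (a + c) > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = (a + b) * (c + d) * (a + c) * (b + d)
        chi2 = np.where(denom > 0, n * (a * d - b * c) ** 2 / np.where(denom > 0, denom, 1.0), 0.0)
    chi2 = np.where(tested, chi2, 0.0)
    p = np.where(tested, sps.chi2.sf(chi2, df=1), 1.0)
    fdr_mask = np.zeros(tested.shape, dtype=bool)
    if tested.any():
        fdr_mask[tested] = bh_fdr(p[tested], q=q)
    return VoxelStatMap(chi2=chi2, p=p, fdr_mask=fdr_mask, tested=tested, q=q)


def bh_fdr(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject
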