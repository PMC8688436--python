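"""Assignment of streamlines to named reference bundles.

Recognition is nearest-exemplar classification under the minimum average
direct-flip (MDF) metric: a streamline is resampled to the model's point
count, its MDF distance to every exemplar of every bundle model is taken,
and it is assigned to the closest model if that distance is within the
model's threshold tau (default 4 mm in the toy geometry), else left
unassigned. This is a standard, reproducible surrogate for toolbox-specific
bundle "recognize" functions, whose algorithms are not public.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Tractogram


def resample_streamline(points: np.ndarray, n_points: int) -> np.ndarray:
    """``n_points`` equidistant points along arc length, endpoints preserved."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        raise ValueError("cannot resample a streamline with fewer than 2 points")
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] <= 0:
        raise ValueError("cannot resample a zero-length streamline")
    targets = np.linspace(0.0, cum[-1], n_points)
    out = np.empty((n_points, 3))
    for k in range(3):
        out[:, k] = np.interp(targets, cum, points[:, k])
    return out


def mdf_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum average direct-flip distance between equal-length streamlines.

    The minimum over the direct and the flipped point ordering of the mean
    point-to-point Euclidean distance; symmetric, zero iff the streamlines
    are identical up to orientation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"streamlines must share n_points; got {a.shape} vs {b.shape}")
    direct = float(np.linalg.norm(a - b, axis=1).mean())
    flipped = float(np.linalg.norm(a - b[::-1], axis=1).mean())
    return min(direct, flipped)


@dataclass
class BundleModel:
    """A named bundle: resampled exemplar streamlines plus a threshold tau."""

    name: str
    exemplars: list
    tau_mm: float = 4.0
    n_points: int = 20

    def __post_init__(self):
        if not self.exemplars:
            raise ValueError(f"bundle model {self.name!r} needs at least one exemplar")
        self.exemplars = [resample_streamline(e, self.n_points) for e in self.exemplars]

    @classmethod
    def from_streamlines(cls, name, streamlines, tau_mm=4.0, n_points=20):
        return cls(name=name, exemplars=list(streamlines), tau_mm=tau_mm, n_points=n_points)

    def distance(self, resampled: np.ndarray) -> float:
        return min(mdf_distance(resampled, e) for e in self.exemplars)


def recognize(streamline: np.ndarray, models: list) -> str | None:
    """Closest model under MDF if within its tau, else None; ties broken by
    lexicographic model name."""
    if not models:
        raise ValueError("no bundle models given")
    n_points = models[0].n_points
    if any(m.n_points != n_points for m in models):
        raise ValueError("all bundle models must share n_points")
    s = resample_streamline(streamline, n_points)
    scored = [(m.distance(s), m.name, m) for m in models]
    dist, name, best = min(scored, key=lambda x: (x[0], x[1]))
    return name if dist <= best.tau_mm else None


def count_disconnected_by_tract(per_site_filtered: dict, models: list,
                                site_labels: dict):
    """Per-site, per-tract counts of recognized VOI-filtered streamlines.

    Returns ``(table, unassigned)`` where ``table`` has one row per
    site x tract (site_id, label, tract_name, n_streamlines) and
    ``unassigned`` maps site_id -> number of filtered streamlines matching no
    model, so per site: sum over tracts + unassigned = filtered count.
    """
    rows = []
    unassigned: dict[str, int] = {}
    tract_names = [m.name for m in models]
    for site_id, t in per_site_filtered.items():
        tally = {name: 0 for name in tract_names}
        miss = 0
        for s in t:
            name = recognize(s, models)
            if name is None:
                miss += 1
            else:
                tally[name] += 1
        unassigned[site_id] = miss
        for name in tract_names:
            rows.append(
                {
                    "site_id": site_id,
                    "label": site_labels[site_id],
                    "tract_name": name,
                    "n_streamlines": tally[name],
                }
            )
    table = pd.DataFrame(rows, columns=["site_id", "label", "tract_name", "n_streamlines"])
    return table, unassigned


def models_from_bundle_set(bundle_set, tau_mm: float = 4.0, n_points: int = 20,
                           max_exemplars: int = 5) -> list:
    """Bundle models from a synthetic bundle set: the noiseless centerline
    plus a few member streamlines as exemplars."""
    models = []
    for spec in bundle_set.specs:
        exemplars = [bundle_set.centerlines[spec.name]]
        exemplars += bundle_set.streamlines_of(spec.name)[: max_exemplars - 1]
        models.append(BundleModel.from_streamlines(spec.name, exemplars, tau_mm, n_points))
    return models
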