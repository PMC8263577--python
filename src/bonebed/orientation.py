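"""Circular statistics for bone long-axis fabric.

Bone long axes are *axial* (undirected) data: a trend of 30 deg is the
same reading as 210 deg.  Axial statistics follow the standard doubling
construction — angles are doubled modulo 360, directional statistics are
computed, and the mean is halved back into [0, 180).  The mean resultant
length R-bar measures concentration (1 = all parallel, 0 = no preferred
axis) and the Rayleigh statistic z = n R-bar^2 tests uniformity.

Plunge (inclination from horizontal, [0, 90]) is profiled against flat /
intermediate / steep thresholds, and per-cluster summaries feed stereonet
and rose-diagram exports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .specimens import SpecimenTable

__all__ = [
    "CircularSummary",
    "circular_mean",
    "rayleigh_test",
    "rayleigh_p",
    "plunge_profile",
    "fabric_by_cluster",
]


@dataclass
class CircularSummary:
    """Mean direction/axis, resultant length and uniformity test for a set
    of angles (degrees)."""

    n: int
    mean_deg: float | None  # [0,360) directional, [0,180) axial; None if R=0
    resultant_length: float
    rayleigh_z: float
    p_value: float | None
    axial: bool


def _resultant(angles_rad: np.ndarray) -> tuple[float, float]:
    c, s = np.cos(angles_rad).sum(), np.sin(angles_rad).sum()
    n = len(angles_rad)
    return math.hypot(c, s) / n, math.atan2(s, c)


def circular_mean(angles_deg, axial: bool = False) -> CircularSummary:
    """Mean direction (or mean axis, via angle doubling) and mean resultant
    length of a sample of angles in degrees.  With R-bar = 0 the mean is
    undefined and reported as missing."""
    a = np.asarray(angles_deg, dtype=float)
    a = a[np.isfinite(a)]
    n = len(a)
    if n < 1:
        raise ValueError("need at least one angle")
    work = np.radians(2 * a if axial else a)
    rbar, theta = _resultant(work)
    if rbar < 1e-12:
        mean = None
        rbar = 0.0
    else:
        mean = math.degrees(theta) % 360.0
        if axial:
            mean = (mean / 2.0) % 180.0
    z = n * rbar**2
    p = rayleigh_p(z, n) if n >= 4 else None
    return CircularSummary(n=n, mean_deg=mean, resultant_length=rbar, rayleigh_z=z, p_value=p, axial=axial)


def rayleigh_p(z: float, n: int) -> float:
    """Series approximation to the Rayleigh uniformity p-value,
    p ~ e^-z [1 + (2z - z^2)/(4n) - (24z - 132z^2 + 76z^3 - 9z^4)/(288n^2)],
    clipped to [0, 1]."""
    with np.errstate(over="ignore"):
        p = math.exp(-z) * (
            1
            + (2 * z - z**2) / (4 * n)
            - (24 * z - 132 * z**2 + 76 * z**3 - 9 * z**4) / (288 * n**2)
        )
    return float(min(max(p, 0.0), 1.0))


def rayleigh_test(angles_deg, axial: bool = False) -> tuple[float, float]:
    """Rayleigh test of circular uniformity: returns (z, p) with
    z = n R-bar^2 (computed on doubled angles for axial data).  Requires
    n >= 4 for the series approximation."""
    a = np.asarray(angles_deg, dtype=float)
    a = a[np.isfinite(a)]
    n = len(a)
    if n < 4:
        raise ValueError("Rayleigh p approximation requires n >= 4")
    work = np.radians(2 * a if axial else a)
    rbar, _ = _resultant(work)
    z = n * rbar**2
    return z, rayleigh_p(z, n)


def plunge_profile(
    table: SpecimenTable | np.ndarray,
    flat_threshold: float = 10.0,
    steep_threshold: float = 45.0,
) -> dict[str, float]:
    """Fractions of flat (< flat threshold), intermediate and steep
    (> steep threshold) plunges among records with a plunge value."""
    p = (
        table.df["plunge_deg"].dropna().to_numpy()
        if isinstance(table, SpecimenTable)
        else np.asarray(table, dtype=float)
    )
    p = p[np.isfinite(p)]
    if len(p) == 0:
        raise ValueError("no plunge values")
    n = len(p)
    flat = float((p < flat_threshold).sum()) / n
    steep = float((p > steep_threshold).sum()) / n
    return {
        "n": n,
        "flat": flat,
        "intermediate": 1.0 - flat - steep,
        "steep": steep,
        "flat_threshold": flat_threshold,
        "steep_threshold": steep_threshold,
    }


def fabric_by_cluster(
    trend_deg: np.ndarray,
    plunge_deg: np.ndarray,
    cluster_labels: np.ndarray,
    level_id: str = "",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Axial fabric summary per cluster.

    One row per cluster (noise points, label 0, summarised under
    "noise"): mean axis, resultant length, Rayleigh z/p, and a
    ``preferential`` flag — False where uniformity cannot be rejected at
    ``alpha`` (no preferred orientation).  Clusters with n < 4 get no
    p-value.  Also carries mean plunge for stereogram export.
    """
    trend = np.asarray(trend_deg, dtype=float)
    plunge = np.asarray(plunge_deg, dtype=float)
    labels = np.asarray(cluster_labels)
    rows = []
    for lab in sorted(set(labels.tolist())):
        mask = labels == lab
        t = trend[mask]
        t = t[np.isfinite(t)]
        if len(t) == 0:
            continue
        s = circular_mean(t, axial=True)
        rows.append(
            {
                "level": level_id,
                "cluster": "noise" if lab == 0 else int(lab),
                "n": s.n,
                "mean_axis_deg": s.mean_deg,
                "resultant_length": s.resultant_length,
                "rayleigh_z": s.rayleigh_z,
                "p_value": s.p_value,
                "preferential": (s.p_value is not None and s.p_value < alpha),
                "mean_plunge_deg": float(np.nanmean(plunge[mask])) if mask.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)
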