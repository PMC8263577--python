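"""Figure helpers: density/residual maps, K and L curves, cluster scatters,
axial rose diagrams and polar trend/plunge stereograms.

All functions draw onto a provided or fresh matplotlib Axes and return it;
callers handle saving.  Stereograms use an equal-angle polar projection
(azimuth clockwise from north, plunge increasing inward).
"""

from __future__ import annotations

import math

import matplotlib

matplotlib.use("Agg")  # headless by default; callers may switch backends first

import matplotlib.pyplot as plt
import numpy as np

from .pointpattern import KFunctionResult, QuadratTestResult, centered_l

__all__ = ["plot_density", "plot_pearson_residuals", "plot_k_l", "plot_clusters",
           "plot_rose", "plot_stereogram"]


def _ax(ax, **kw):
    if ax is None:
        _, ax = plt.subplots(**kw)
    return ax


def plot_density(dens: dict, ax=None):
    """Heat map of a kernel intensity surface from :func:`density_map`."""
    ax = _ax(ax)
    m = ax.pcolormesh(dens["x"], dens["y"], dens["intensity"], shading="nearest")
    ax.set_aspect("equal")
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    plt.colorbar(m, ax=ax, label="intensity (points / m$^2$)")
    return ax


def plot_pearson_residuals(result: QuadratTestResult, ax=None):
    """Quadrat Pearson residual heat map (departures from CSR)."""
    ax = _ax(ax)
    lim = max(1.0, np.abs(result.pearson_residuals).max())
    m = ax.imshow(
        result.pearson_residuals, origin="lower", cmap="RdBu_r", vmin=-lim, vmax=lim
    )
    ax.set_title(f"chi2 = {result.chi2:.0f}, p = {result.p_value:.2g}")
    plt.colorbar(m, ax=ax, label="Pearson residual")
    return ax


def plot_k_l(result: KFunctionResult, ax=None):
    """Empirical vs CSR-theoretical K, with the centred L inset."""
    ax = _ax(ax)
    ax.plot(result.r, result.k_hat, "k-", label=r"$\hat K(r)$")
    ax.plot(result.r, result.k_theo, "r--", label=r"$\pi r^2$ (CSR)")
    ax.set_xlabel("r (m)")
    ax.set_ylabel("K(r)")
    ax.legend()
    inset = ax.inset_axes([0.58, 0.12, 0.38, 0.32])
    inset.plot(result.r, centered_l(result), "k-")
    inset.axhline(0.0, color="r", ls="--", lw=0.8)
    inset.set_title(r"$\hat L(r) - r$", fontsize=8)
    return ax


def plot_clusters(points: np.ndarray, labels: np.ndarray, ax=None):
    """Scatter of a point pattern coloured by cluster id (noise in grey)."""
    ax = _ax(ax)
    points = np.asarray(points)
    noise = labels == 0
    ax.scatter(points[noise, 0], points[noise, 1], s=6, c="lightgrey", label="noise")
    for lab in sorted(set(labels[~noise].tolist())):
        m = labels == lab
        ax.scatter(points[m, 0], points[m, 1], s=8, label=f"cluster {lab}")
    ax.set_aspect("equal")
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    return ax


def plot_rose(trend_deg: np.ndarray, bin_width: float = 10.0, axial: bool = True, ax=None):
    """Rose diagram of long-axis trends; axial roses are mirrored so each
    reading appears at theta and theta + 180."""
    ax = _ax(ax, subplot_kw={"projection": "polar"})
    t = np.asarray(trend_deg, dtype=float)
    t = t[np.isfinite(t)]
    if axial:
        t = np.concatenate([t % 180.0, t % 180.0 + 180.0])
    edges = np.arange(0, 360 + bin_width, bin_width)
    counts, _ = np.histogram(t % 360.0, bins=edges)
    theta = np.radians(edges[:-1] + bin_width / 2)
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    ax.bar(theta, counts, width=math.radians(bin_width), bottom=0.0, edgecolor="k", alpha=0.7)
    return ax


def plot_stereogram(trend_deg: np.ndarray, plunge_deg: np.ndarray, ax=None, **scatter_kw):
    """Polar trend/plunge scatter: azimuth clockwise from north, plunge 0
    (horizontal) on the rim and 90 (vertical) at the centre."""
    ax = _ax(ax, subplot_kw={"projection": "polar"})
    t = np.radians(np.asarray(trend_deg, dtype=float))
    p = np.asarray(plunge_deg, dtype=float)
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    ax.scatter(t, 90.0 - p, s=scatter_kw.pop("s", 8), **scatter_kw)
    ax.set_rlim(0, 90)
    ax.set_yticks([0, 30, 60, 90])
    ax.set_yticklabels(["90", "60", "30", "0"])
    return ax
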