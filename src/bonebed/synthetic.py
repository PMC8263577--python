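"""Synthetic excavation-table generator.

Emulates the structure the analysis pipeline assumes in a real bonebed:

* two (configurable) vertically separated fossil bands — by default 0-50 cm
  and 60-90 cm above the site datum, separated by a sterile 10 cm gap, with
  a slight NE-SW dip (1 cm/m along azimuth 45 deg by default);
* horizontally clustered, inhomogeneous planar patterns from a Thomas
  cluster process (Poisson parents, Poisson offspring counts, isotropic
  Gaussian offspring displacement);
* an axial long-axis fabric concentrated around a NE mean axis (von Mises
  on doubled angles with a uniform contamination fraction) and mostly flat
  plunges (79% < 10 deg, 4% > 45 deg by default);
* per-specimen taphonomic attributes drawn from multinomial frequencies
  matching the published assemblage-level proportions.

Every draw comes from one seeded generator, so the same seed yields a
byte-identical table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fixture import _TAXON_ROWS
from .pointpattern import Window
from .specimens import LENGTH_CLASSES, SpecimenTable, derive_length_class, taxon_vocabulary

__all__ = ["LevelSpec", "SyntheticSiteConfig", "simulate_site", "simulate_thomas"]


@dataclass(frozen=True)
class LevelSpec:
    """One fossil band: base height and thickness (cm), specimen count."""

    base_cm: float
    thickness_cm: float
    n: int
    level_id: str = ""


@dataclass
class SyntheticSiteConfig:
    """Generator configuration; defaults describe the reference two-band,
    39 m^2 site geometry."""

    window: Window = field(default_factory=lambda: Window(0.0, 6.5, 0.0, 6.0))
    levels: tuple[LevelSpec, ...] = (
        LevelSpec(0.0, 50.0, 1000, "L1"),
        LevelSpec(60.0, 30.0, 1000, "L2"),
    )
    gap_cm: float = 10.0
    dip_azimuth_deg: float = 45.0
    dip_gradient_cm_per_m: float = 1.0
    thomas_parent_intensity: float = 0.45  # parents per m^2
    thomas_mean_offspring: float = 40.0
    thomas_sigma_m: float = 0.35
    trend_mean_axis_deg: float = 35.0
    trend_kappa: float = 4.0
    trend_uniform_fraction: float = 0.10
    plunge_flat_fraction: float = 0.79
    plunge_steep_fraction: float = 0.04
    max_band_thickness_cm: float = 30.0
    seed: int = 0

    def validate(self) -> None:
        if self.window.area <= 0:
            raise ValueError("window must have positive area")
        if not (0 <= self.trend_uniform_fraction <= 1):
            raise ValueError("uniform fraction must be in [0, 1]")
        if self.plunge_flat_fraction + self.plunge_steep_fraction > 1:
            raise ValueError("plunge mixture fractions exceed 1")
        bands = sorted(self.levels, key=lambda b: b.base_cm)
        for b in bands:
            if b.thickness_cm <= 0 or b.n < 0:
                raise ValueError(f"infeasible band {b}")
        for a, b in zip(bands, bands[1:]):
            if b.base_cm - (a.base_cm + a.thickness_cm) < self.gap_cm:
                raise ValueError(
                    f"bands at {a.base_cm} and {b.base_cm} cm violate the "
                    f"{self.gap_cm} cm inter-level gap"
                )


# ---------------------------------------------------------------------------
# Point processes
# ---------------------------------------------------------------------------


def simulate_thomas(
    window: Window,
    parent_intensity: float,
    mean_offspring: float,
    sigma: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Simulate a Thomas cluster process clipped to ``window``.

    Parents are Poisson with the given intensity, uniform in the window
    buffered by 4 sigma (so clusters seeded just outside still contribute);
    each parent gets a Poisson(mean_offspring) brood displaced by an
    isotropic Gaussian(sigma).  The stationary intensity is
    ``parent_intensity * mean_offspring`` points per unit area.
    """
    if parent_intensity <= 0 or mean_offspring <= 0 or sigma <= 0:
        raise ValueError("Thomas parameters must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    buf = 4 * sigma
    bw = Window(window.x0 - buf, window.x1 + buf, window.y0 - buf, window.y1 + buf)
    n_parents = rng.poisson(parent_intensity * bw.area)
    parents = np.column_stack(
        [rng.uniform(bw.x0, bw.x1, n_parents), rng.uniform(bw.y0, bw.y1, n_parents)]
    )
    counts = rng.poisson(mean_offspring, n_parents)
    pts = np.repeat(parents, counts, axis=0) + rng.normal(0, sigma, (int(counts.sum()), 2))
    return pts[Window.contains(window, pts)] if len(pts) else pts.reshape(0, 2)


def _thomas_conditional(
    window: Window, n: int, parent_intensity: float, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Exactly ``n`` Thomas-style offspring in the window: parents as in
    :func:`simulate_thomas`, each of the n points attached to a uniformly
    chosen parent, displacements redrawn until inside the window."""
    buf = 4 * sigma
    bw = Window(window.x0 - buf, window.x1 + buf, window.y0 - buf, window.y1 + buf)
    n_parents = max(1, rng.poisson(parent_intensity * bw.area))
    parents = np.column_stack(
        [rng.uniform(bw.x0, bw.x1, n_parents), rng.uniform(bw.y0, bw.y1, n_parents)]
    )
    out = np.empty((n, 0 + 2))
    assign = rng.integers(0, n_parents, n)
    pts = parents[assign] + rng.normal(0, sigma, (n, 2))
    bad = ~window.contains(pts)
    while bad.any():
        k = int(bad.sum())
        assign2 = rng.integers(0, n_parents, k)
        pts[bad] = parents[assign2] + rng.normal(0, sigma, (k, 2))
        bad = ~window.contains(pts)
    out[:] = pts
    return out


# ---------------------------------------------------------------------------
# Fabric sampling
# ---------------------------------------------------------------------------


def _sample_axial_trend(
    n: int, mean_axis_deg: float, kappa: float, uniform_fraction: float, rng
) -> np.ndarray:
    """Axial von Mises sample: draw on doubled angles, halve into [0, 180),
    with a uniform contamination fraction."""
    doubled = rng.vonmises(math.radians(2 * mean_axis_deg), kappa, n)
    trend = (np.degrees(doubled) / 2.0) % 180.0
    contam = rng.random(n) < uniform_fraction
    trend[contam] = rng.uniform(0, 180, int(contam.sum()))
    return np.round(trend, 1)


def _sample_plunge(n: int, flat: float, steep: float, rng) -> np.ndarray:
    u = rng.random(n)
    p = np.empty(n)
    lo = u < flat
    hi = u >= 1 - steep
    mid = ~lo & ~hi
    p[lo] = rng.uniform(0.0, 9.9, int(lo.sum()))
    p[mid] = rng.uniform(10.0, 45.0, int(mid.sum()))
    p[hi] = rng.uniform(45.1, 90.0, int(hi.sum()))
    return np.round(p, 1)


# ---------------------------------------------------------------------------
# Attribute frequencies (assemblage-level proportions of the reference site)
# ---------------------------------------------------------------------------

_N_REF = 1609
_TAXON_PROBS = [(t, n / _N_REF) for t, n, _, _ in _TAXON_ROWS]
_LONG_ELEMENTS = ("tibia", "humerus", "radius", "femur", "metacarpal", "metatarsal", "ulna", "long_bone")
_OTHER_ELEMENTS = ("vertebra", "rib", "cranium", "mandible", "scapula", "pelvis", "phalanx", "indeterminate")
_LENGTH_RANGES = ((0.6, 2.9), (3.1, 5.0), (5.1, 10.0), (10.1, 25.0))
_LENGTH_PROBS = (585 / _N_REF, 382 / _N_REF, 382 / _N_REF, 260 / _N_REF)


def _sample_attributes(df: pd.DataFrame, rng: np.random.Generator) -> None:
    """Fill taphonomic attribute columns in place with draws from the
    reference multinomial frequencies."""
    n = len(df)
    vocab = taxon_vocabulary()
    taxa = [t for t, _ in _TAXON_PROBS]
    probs = np.array([p for _, p in _TAXON_PROBS])
    probs /= probs.sum()
    choice = rng.choice(len(taxa), n, p=probs)
    df["taxon"] = [taxa[i] for i in choice]
    df["trophic_group"] = [vocab.loc[t, "trophic_group"] for t in df["taxon"]]
    df["size_class"] = [vocab.loc[t, "size_class"] for t in df["taxon"]]

    is_tooth = rng.random(n) < 235 / _N_REF
    u = rng.random(n)
    elements = np.where(
        is_tooth,
        "tooth",
        np.where(
            u < 0.35,
            rng.choice(_LONG_ELEMENTS, n),
            rng.choice(_OTHER_ELEMENTS, n),
        ),
    )
    df["element"] = elements
    df["is_tooth"] = is_tooth
    df["side"] = rng.choice(["left", "right", "unknown"], n, p=[0.35, 0.35, 0.3])
    df["age_class"] = rng.choice(
        ["adult", "juvenile", "infantile", "senile", "unknown"], n,
        p=[0.45, 0.2, 0.1, 0.05, 0.2],
    )

    cls = rng.choice(4, n, p=np.array(_LENGTH_PROBS) / sum(_LENGTH_PROBS))
    lengths = np.empty(n)
    for k, (lo, hi) in enumerate(_LENGTH_RANGES):
        m = cls == k
        lengths[m] = np.round(rng.uniform(lo, hi, int(m.sum())), 1)
    df["length_cm"] = lengths
    df["length_class"] = [derive_length_class(v) for v in lengths]

    long_mask = pd.Series(elements).isin(_LONG_ELEMENTS).to_numpy()
    frac = np.full(n, "none", dtype=object)
    fr = long_mask & (rng.random(n) < 0.5)
    green = fr & (rng.random(n) < 186 / 338)
    frac[fr] = "dry"
    frac[green] = "green"
    df["fracture_type"] = frac
    circ = np.full(n, "n/a", dtype=object)
    cc = rng.choice(["1", "2", "3"], n, p=[126 / 186, 33 / 186, 27 / 186])
    circ[green] = cc[green]
    df["circumference_type"] = circ

    df["weathering_stage"] = np.where(rng.random(n) < 148 / _N_REF, 1, 0)
    df["surface_preservation"] = np.where(
        ~is_tooth & (rng.random(n) < 427 / 1374), "poor", "good"
    )
    df["abrasion_stage"] = rng.choice(
        ["none", "light", "intermediate", "intense"], n,
        p=[(1609 - 642) / _N_REF, 189 / _N_REF, 242 / _N_REF, 211 / _N_REF],
    )
    df["oxide_staining"] = rng.random(n) < 307 / _N_REF
    df["calcitic_concretion"] = rng.random(n) < 155 / _N_REF
    df["biochemical_alteration"] = rng.random(n) < 402 / _N_REF
    markable = ~is_tooth & (df["surface_preservation"] == "good").to_numpy()
    marked = markable & (rng.random(n) < 43 / 947)
    df["tm_pits"] = np.where(marked, 1, 0)
    df["tm_scores"] = np.where(marked & (rng.random(n) < 4 / 43), 1, 0)
    df["tm_punctures"] = 0
    df["furrowing"] = rng.random(n) < 17 / _N_REF
    df["taphotype"] = np.nan
    df["notch_type"] = "none"


# ---------------------------------------------------------------------------
# Site simulation
# ---------------------------------------------------------------------------


def simulate_site(
    config: SyntheticSiteConfig | None = None, seed: int | None = None
) -> SpecimenTable:
    """Generate a full synthetic specimen table.

    Per level: planar points from a Thomas cluster process conditioned to
    the configured count; z = band base + dip trend (linear in the position
    projected on the dip azimuth, centred on the window) + uniform within
    the band thickness; axial trends, plunges and taphonomic attributes
    from the configured distributions.  ``seed`` overrides ``config.seed``.
    """
    cfg = config or SyntheticSiteConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    w = cfg.window
    az = math.radians(cfg.dip_azimuth_deg)
    ux, uy = math.sin(az), math.cos(az)  # compass azimuth: 0 = +y (north)
    cx, cy = (w.x0 + w.x1) / 2, (w.y0 + w.y1) / 2

    frames = []
    for k, band in enumerate(sorted(cfg.levels, key=lambda b: b.base_cm)):
        if band.n == 0:
            continue
        pts = _thomas_conditional(w, band.n, cfg.thomas_parent_intensity, cfg.thomas_sigma_m, rng)
        proj = (pts[:, 0] - cx) * ux + (pts[:, 1] - cy) * uy
        z = band.base_cm + cfg.dip_gradient_cm_per_m * proj + rng.uniform(
            0, band.thickness_cm, band.n
        )
        df = pd.DataFrame(
            {
                "x": np.round(pts[:, 0], 3),
                "y": np.round(pts[:, 1], 3),
                "z": np.round(z, 1),
                "level": band.level_id or f"L{k + 1}",
                "trend_deg": _sample_axial_trend(
                    band.n, cfg.trend_mean_axis_deg, cfg.trend_kappa,
                    cfg.trend_uniform_fraction, rng,
                ),
                "plunge_deg": _sample_plunge(
                    band.n, cfg.plunge_flat_fraction, cfg.plunge_steep_fraction, rng
                ),
            }
        )
        _sample_attributes(df, rng)
        frames.append(df)
    if not frames:
        df = pd.DataFrame(columns=["x", "y", "z"])
        return SpecimenTable(pd.DataFrame({"specimen_id": []}), provenance={"seed": cfg.seed})
    out = pd.concat(frames, ignore_index=True)
    out["specimen_id"] = [f"SYN-{i + 1:05d}" for i in range(len(out))]
    return SpecimenTable(out, provenance={"generator": "simulate_site", "seed": cfg.seed})
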