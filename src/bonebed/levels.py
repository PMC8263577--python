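"""Palaeostratigraphic level detection and consensus classification.

The deposit is a palimpsest: discrete fossiliferous levels are vertically
separated bands of bone concentration.  The workflow has three stages:

1. **Unsupervised proposal** — a 1-D Gaussian kernel density estimate of
   stratigraphic height (Scott bandwidth) is split at interior density
   minima that fall below a fraction *f* of the smaller adjacent mode,
   yielding candidate level bands sorted bottom-up.
2. **Human-in-the-loop curation** — file-driven overrides (merge, split at
   a height, boundary adjustment, discard) applied to the candidates, with
   every action logged and disjointness re-validated.
3. **Supervised consensus** — two probabilistic classifiers on the raw
   coordinates (x, y, z): an ensemble of decision trees (random forest)
   and an RBF-kernel max-margin classifier with calibrated posteriors
   (SVM).  A specimen is assigned the agreed label; on disagreement the
   more confident classifier decides (and is recorded as decisive); if
   neither posterior reaches the confidence threshold (default 80%) the
   specimen is left indeterminate.

Inter-classifier reliability is summarised by raw agreement, Cohen's
kappa, and the share of disagreements each classifier resolved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.calibration import CalibratedClassifierCV
from sklearn.svm import SVC

from .specimens import SpecimenTable

__all__ = [
    "LevelBand",
    "LevelAssignment",
    "ConsensusReport",
    "ConsensusModel",
    "propose_levels",
    "apply_hitl",
    "train_consensus",
    "classify_specimens",
    "cohens_kappa",
    "consensus_report",
]


@dataclass
class LevelBand:
    """A fossiliferous level: contiguous z-range (cm above site datum)."""

    level_id: str
    z_min: float
    z_max: float
    dip_azimuth_deg: float | None = None
    dip_gradient_cm_per_m: float | None = None
    provenance: str = "unsupervised"

    def contains(self, z: np.ndarray) -> np.ndarray:
        return (np.asarray(z) >= self.z_min) & (np.asarray(z) <= self.z_max)


@dataclass
class LevelAssignment:
    specimen_id: str
    rf_label: str
    rf_prob: float
    svm_label: str
    svm_prob: float
    final_label: str | None
    decisive_classifier: str | None = None

    @property
    def indeterminate(self) -> bool:
        return self.final_label is None


@dataclass
class ConsensusReport:
    n_assigned: dict[str, int]
    n_indeterminate: int
    n_skipped: int
    agreement_rate: float
    kappa: float
    rf_decisiveness: float | None
    rf_mean_confidence: float
    rf_confidence_bounds: tuple[float, float]
    svm_mean_confidence: float
    svm_confidence_bounds: tuple[float, float]


# ---------------------------------------------------------------------------
# Stage 1: unsupervised proposal
# ---------------------------------------------------------------------------


def propose_levels(
    table: SpecimenTable | np.ndarray,
    valley_fraction: float = 0.5,
    grid_size: int = 512,
    bw_scale: float = 0.4,
    min_fraction: float = 0.05,
) -> list[LevelBand]:
    """Propose level bands from the kernel density of stratigraphic height.

    The density is evaluated on a regular grid; candidate boundaries are
    interior local minima whose density is below ``valley_fraction`` times
    the smaller of the two adjacent modes.  Each retained segment becomes a
    band spanning the z-extent of its specimens, sorted bottom-up.

    The kernel uses Scott's factor scaled by ``bw_scale`` (< 1): Scott's
    rule targets mean integrated squared error for a roughly unimodal
    density and over-smooths the narrow sterile gaps that separate fossil
    bands, so mode *detection* needs a finer kernel.  The relative
    ``valley_fraction`` criterion guards against the extra variance
    introducing spurious splits.
    """
    z = (
        table.df["z"].dropna().to_numpy()
        if isinstance(table, SpecimenTable)
        else np.asarray(table, dtype=float)
    )
    z = z[np.isfinite(z)]
    if z.size < 2:
        raise ValueError("need at least 2 specimens with stratigraphic height")
    if np.ptp(z) == 0:
        import warnings

        warnings.warn("all heights identical; returning one degenerate band")
        return [LevelBand("L1", float(z[0]), float(z[0]))]

    kde = gaussian_kde(z, bw_method="scott")
    kde.set_bandwidth(kde.factor * bw_scale)
    pad = 2 * z.std() * kde.factor
    grid = np.linspace(z.min() - pad, z.max() + pad, grid_size)
    dens = kde(grid)

    d = np.diff(dens)
    maxima = [i for i in range(1, grid_size - 1) if d[i - 1] > 0 >= d[i]]
    minima = [i for i in range(1, grid_size - 1) if d[i - 1] < 0 <= d[i]]

    cuts = []
    for m in minima:
        left = [i for i in maxima if i < m]
        right = [i for i in maxima if i > m]
        if not left or not right:
            continue
        smaller_mode = min(dens[max(left, key=lambda i: dens[i])],
                           dens[max(right, key=lambda i: dens[i])])
        if dens[m] < valley_fraction * smaller_mode:
            cuts.append(grid[m])

    edges = [-np.inf, *sorted(cuts), np.inf]
    segments = []
    for k in range(len(edges) - 1):
        members = z[(z > edges[k]) & (z <= edges[k + 1])]
        if members.size:
            segments.append(members)
    # a level must hold a non-negligible share of the finds: merge stray
    # outlier bumps into their larger neighbour
    min_members = max(2, int(math.ceil(min_fraction * z.size)))
    while len(segments) > 1:
        sizes = [s.size for s in segments]
        k = int(np.argmin(sizes))
        if sizes[k] >= min_members:
            break
        if k == 0:
            j = 1
        elif k == len(segments) - 1:
            j = k - 1
        else:
            j = k - 1 if sizes[k - 1] >= sizes[k + 1] else k + 1
        lo, hi = min(j, k), max(j, k)
        segments[lo : hi + 1] = [np.concatenate([segments[lo], segments[hi]])]
    return [
        LevelBand(f"L{k + 1}", float(s.min()), float(s.max()))
        for k, s in enumerate(segments)
    ]


# ---------------------------------------------------------------------------
# Stage 2: human-in-the-loop curation
# ---------------------------------------------------------------------------


def apply_hitl(candidates: list[LevelBand], overrides: list[dict] | None) -> list[LevelBand]:
    """Apply curation overrides to candidate bands.

    Each override is a mapping with an ``action`` key:

    - ``{"action": "merge", "levels": [id1, id2]}``
    - ``{"action": "split", "level": id, "at": z}``
    - ``{"action": "adjust", "level": id, "z_min": ..., "z_max": ...}``
    - ``{"action": "discard", "level": id}``

    Band ids are reassigned bottom-up afterwards and disjointness is
    re-validated; every action is recorded on the returned bands'
    ``provenance``.
    """
    bands = {b.level_id: LevelBand(**vars(b)) for b in candidates}

    def get(level_id):
        if level_id not in bands:
            raise KeyError(f"override references unknown level {level_id!r}")
        return bands[level_id]

    for ov in overrides or []:
        action = ov["action"]
        if action == "merge":
            parts = [get(l) for l in ov["levels"]]
            merged = LevelBand(
                parts[0].level_id,
                min(p.z_min for p in parts),
                max(p.z_max for p in parts),
                provenance="curated:merge",
            )
            for p in parts:
                del bands[p.level_id]
            bands[merged.level_id] = merged
        elif action == "split":
            b = get(ov["level"])
            at = float(ov["at"])
            if not (b.z_min < at < b.z_max):
                raise ValueError(f"split height {at} outside band {b.level_id}")
            del bands[b.level_id]
            bands[b.level_id + "a"] = LevelBand(b.level_id + "a", b.z_min, at, provenance="curated:split")
            bands[b.level_id + "b"] = LevelBand(b.level_id + "b", at, b.z_max, provenance="curated:split")
        elif action == "adjust":
            b = get(ov["level"])
            b.z_min = float(ov.get("z_min", b.z_min))
            b.z_max = float(ov.get("z_max", b.z_max))
            b.provenance = "curated:adjust"
        elif action == "discard":
            del bands[get(ov["level"]).level_id]
        else:
            raise ValueError(f"unknown curation action {action!r}")

    out = sorted(bands.values(), key=lambda b: b.z_min)
    for a, b in zip(out, out[1:]):
        if b.z_min < a.z_max:
            raise ValueError(f"curated bands {a.level_id} and {b.level_id} overlap")
    for k, b in enumerate(out):
        b.level_id = f"L{k + 1}"
    return out


# ---------------------------------------------------------------------------
# Stage 3: supervised consensus
# ---------------------------------------------------------------------------


@dataclass
class ConsensusModel:
    rf: RandomForestClassifier
    svm: CalibratedClassifierCV
    bands: list[LevelBand]
    cv_accuracy: dict[str, float] = field(default_factory=dict)


def _features_labels(table: SpecimenTable, bands: list[LevelBand]):
    df = table.df
    has_xyz = df[["x", "y", "z"]].notna().all(axis=1)
    X = df.loc[has_xyz, ["x", "y", "z"]].to_numpy(float)
    ids = df.loc[has_xyz, "specimen_id"].to_numpy()
    labels = np.full(len(X), "", dtype=object)
    for b in bands:
        labels[b.contains(X[:, 2])] = b.level_id
    return X, labels, ids, df.loc[~has_xyz, "specimen_id"].tolist()


def train_consensus(
    table: SpecimenTable,
    bands: list[LevelBand],
    cv_folds: int = 3,
    seed: int = 0,
    n_estimators: int = 500,
    evaluate: bool = True,
    labels: np.ndarray | None = None,
) -> ConsensusModel:
    """Train the random-forest / calibrated-SVM pair on (x, y, z).

    Specimens falling in inter-band gaps are held out of training (they
    are prediction-only).  With ``evaluate=True`` a stratified
    cross-validated accuracy is recorded for each classifier.  ``labels``
    overrides the band-derived training labels (one per located specimen;
    empty string = hold out) — used for permutation diagnostics.
    """
    X, labels_auto, _, _ = _features_labels(table, bands)
    if labels is None:
        labels = labels_auto
    labels = np.asarray(labels, dtype=object)
    mask = labels != ""
    Xt, yt = X[mask], labels[mask].astype(str)
    counts = pd.Series(yt).value_counts()
    if (counts < cv_folds).any():
        small = counts[counts < cv_folds].index.tolist()
        raise ValueError(
            f"bands {small} have fewer members than cv_folds={cv_folds}; reduce folds"
        )
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    svm = CalibratedClassifierCV(SVC(kernel="rbf", random_state=seed), ensemble=False)
    model = ConsensusModel(rf=rf, svm=svm, bands=list(bands))
    if evaluate:
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        model.cv_accuracy = {
            "rf": float(cross_val_score(rf, Xt, yt, cv=skf).mean()),
            "svm": float(cross_val_score(svm, Xt, yt, cv=skf).mean()),
        }
    rf.fit(Xt, yt)
    svm.fit(Xt, yt)
    return model


def classify_specimens(
    model: ConsensusModel, table: SpecimenTable, threshold: float = 0.80
) -> tuple[list[LevelAssignment], list[str]]:
    """Assign every specimen with coordinates to a level.

    Agreement takes the shared label; disagreement is arbitrated by the
    higher posterior (recorded as the decisive classifier); when both
    posteriors fall below ``threshold`` the specimen is indeterminate.
    Returns ``(assignments, skipped_ids)`` where skipped specimens lack
    coordinates.
    """
    X, _, ids, skipped = _features_labels(table, model.bands)
    if len(X) == 0:
        return [], skipped
    rf_proba = model.rf.predict_proba(X)
    svm_proba = model.svm.predict_proba(X)
    rf_classes, svm_classes = model.rf.classes_, model.svm.classes_
    out = []
    for k in range(len(X)):
        ri = int(np.argmax(rf_proba[k]))
        si = int(np.argmax(svm_proba[k]))
        rl, rp = str(rf_classes[ri]), float(rf_proba[k, ri])
        sl, sp = str(svm_classes[si]), float(svm_proba[k, si])
        decisive = None
        if rp < threshold and sp < threshold:
            final = None
        elif rl == sl:
            final = rl
        else:
            final, decisive = (rl, "rf") if rp >= sp else (sl, "svm")
        out.append(LevelAssignment(str(ids[k]), rl, rp, sl, sp, final, decisive))
    return out, skipped


def cohens_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement from a square cross-tabulation of two
    raters' labels: kappa = (p_o - p_e) / (1 - p_e)."""
    m = np.asarray(confusion, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (m < 0).any():
        raise ValueError("counts must be non-negative")
    total = m.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(m) / total
    p_e = float((m.sum(axis=1) * m.sum(axis=0)).sum()) / total**2
    if p_e >= 1.0 - 1e-12:
        if p_o >= 1.0 - 1e-12:
            return 1.0  # perfect degenerate agreement
        raise ValueError("kappa undefined: chance agreement is 1 with observed < 1")
    return float((p_o - p_e) / (1 - p_e))


def consensus_report(assignments: list[LevelAssignment]) -> ConsensusReport:
    """Summarise a batch of dual-classifier assignments (agreement rate,
    Cohen's kappa, decisiveness, per-classifier confidence)."""
    if not assignments:
        raise ValueError("no assignments to report on")
    assigned = [a for a in assignments if not a.indeterminate]
    n_level: dict[str, int] = {}
    for a in assigned:
        n_level[a.final_label] = n_level.get(a.final_label, 0) + 1
    agree = [a for a in assigned if a.rf_label == a.svm_label]
    disagree = [a for a in assigned if a.rf_label != a.svm_label]
    labels = sorted({a.rf_label for a in assigned} | {a.svm_label for a in assigned})
    idx = {l: i for i, l in enumerate(labels)}
    conf = np.zeros((len(labels), len(labels)))
    for a in assigned:
        conf[idx[a.rf_label], idx[a.svm_label]] += 1
    kappa = cohens_kappa(conf) if len(assigned) else math.nan
    decis = (
        sum(1 for a in disagree if a.decisive_classifier == "rf") / len(disagree)
        if disagree
        else None
    )
    rf_p = np.array([a.rf_prob for a in assignments])
    svm_p = np.array([a.svm_prob for a in assignments])
    return ConsensusReport(
        n_assigned=n_level,
        n_indeterminate=sum(a.indeterminate for a in assignments),
        n_skipped=0,
        agreement_rate=len(agree) / len(assigned) if assigned else math.nan,
        kappa=kappa,
        rf_decisiveness=decis,
        rf_mean_confidence=float(rf_p.mean()),
        rf_confidence_bounds=(float(rf_p.max() - rf_p.mean()), float(rf_p.mean() - rf_p.min())),
        svm_mean_confidence=float(svm_p.mean()),
        svm_confidence_bounds=(float(svm_p.max() - svm_p.mean()), float(svm_p.mean() - svm_p.min())),
    )
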