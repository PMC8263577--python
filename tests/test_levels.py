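"""Level detection: band proposal, curation, consensus classification."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

from bonebed.levels import (
    ConsensusModel,
    LevelAssignment,
    LevelBand,
    apply_hitl,
    classify_specimens,
    cohens_kappa,
    consensus_report,
    propose_levels,
    train_consensus,
)
from bonebed.specimens import SpecimenTable
from bonebed.synthetic import LevelSpec, SyntheticSiteConfig, simulate_site


class TestProposeLevels:
    def test_bimodal_geometry_gives_two_bands(self, rng):
        z = np.concatenate([rng.uniform(0, 50, 500), rng.uniform(60, 90, 500)])
        bands = propose_levels(z)
        assert len(bands) == 2
        assert 50 < (bands[0].z_max + bands[1].z_min) / 2 < 60

    def test_unimodal_gives_one_band(self, rng):
        assert len(propose_levels(rng.normal(40, 5, 400))) == 1

    def test_three_bands_recovered_in_order(self, rng):
        z = np.concatenate(
            [rng.uniform(0, 20, 300), rng.uniform(40, 60, 300), rng.uniform(80, 100, 300)]
        )
        bands = propose_levels(z)
        assert len(bands) == 3
        assert bands[0].z_max < bands[1].z_min < bands[1].z_max < bands[2].z_min

    def test_identical_heights_degenerate_band(self):
        with pytest.warns(UserWarning):
            bands = propose_levels(np.full(10, 5.0))
        assert len(bands) == 1 and bands[0].z_min == bands[0].z_max == 5.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            propose_levels(np.array([1.0]))


class TestHitl:
    def _bands(self):
        return [LevelBand("L1", 0, 20), LevelBand("L2", 30, 50), LevelBand("L3", 60, 80)]

    def test_empty_overrides_identity(self):
        out = apply_hitl(self._bands(), [])
        assert [(b.z_min, b.z_max) for b in out] == [(0, 20), (30, 50), (60, 80)]

    def test_merge_reduces_count(self):
        out = apply_hitl(self._bands(), [{"action": "merge", "levels": ["L1", "L2"]}])
        assert len(out) == 2 and out[0].z_max == 50

    def test_split_shares_cut(self):
        out = apply_hitl(self._bands(), [{"action": "split", "level": "L2", "at": 40}])
        assert len(out) == 4
        assert out[1].z_max == 40 and out[2].z_min == 40

    def test_discard(self):
        out = apply_hitl(self._bands(), [{"action": "discard", "level": "L3"}])
        assert len(out) == 2

    def test_overlapping_adjustment_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            apply_hitl(self._bands(), [{"action": "adjust", "level": "L1", "z_max": 35}])

    def test_unknown_level_rejected(self):
        with pytest.raises(KeyError):
            apply_hitl(self._bands(), [{"action": "discard", "level": "L9"}])


class _Stub:
    """Fixed-posterior classifier used to exercise the arbitration rule."""

    def __init__(self, classes, proba):
        self.classes_ = np.array(classes)
        self._proba = np.atleast_2d(proba)

    def predict_proba(self, X):
        return np.repeat(self._proba, len(X), axis=0)


def _one_specimen_table():
    import pandas as pd

    return SpecimenTable(
        pd.DataFrame({"specimen_id": ["A"], "x": [1.0], "y": [1.0], "z": [10.0]})
    )


class TestArbitration:
    def _classify(self, rf_proba, svm_proba, threshold=0.80):
        model = ConsensusModel(
            rf=_Stub(["L1", "L2"], rf_proba),
            svm=_Stub(["L1", "L2"], svm_proba),
            bands=[LevelBand("L1", 0, 20), LevelBand("L2", 30, 50)],
        )
        out, _ = classify_specimens(model, _one_specimen_table(), threshold=threshold)
        return out[0]

    def test_agreement_needs_no_arbitration(self):
        a = self._classify([0.99, 0.01], [0.99, 0.01])
        assert a.final_label == "L1" and a.decisive_classifier is None

    def test_disagreement_resolved_by_higher_posterior(self):
        a = self._classify([0.95, 0.05], [0.15, 0.85])
        assert a.final_label == "L1" and a.decisive_classifier == "rf"
        b = self._classify([0.85, 0.15], [0.05, 0.95])
        assert b.final_label == "L2" and b.decisive_classifier == "svm"

    def test_both_below_threshold_is_indeterminate(self):
        a = self._classify([0.6, 0.4], [0.3, 0.7])
        assert a.indeterminate

    def test_specimen_without_coordinates_skipped(self):
        import pandas as pd

        table = SpecimenTable(
            pd.DataFrame({"specimen_id": ["A", "B"], "x": [1.0, None], "y": [1.0, 2.0], "z": [10.0, 5.0]})
        )
        model = ConsensusModel(
            rf=_Stub(["L1", "L2"], [0.9, 0.1]),
            svm=_Stub(["L1", "L2"], [0.9, 0.1]),
            bands=[LevelBand("L1", 0, 20)],
        )
        out, skipped = classify_specimens(model, table)
        assert len(out) == 1 and skipped == ["B"]


class TestKappa:
    @pytest.mark.parametrize(
        "matrix, expected",
        [([[45, 5], [5, 45]], 0.8), ([[30, 0], [0, 70]], 1.0), ([[25, 25], [25, 25]], 0.0)],
    )
    def test_hand_cases(self, matrix, expected):
        assert cohens_kappa(np.array(matrix)) == pytest.approx(expected)

    def test_against_sklearn_on_random_matrices(self, rng):
        for _ in range(200):
            k = rng.integers(2, 4)
            m = rng.integers(0, 20, size=(k, k))
            if m.sum() == 0:
                continue
            # expand the cross-tabulation into paired label vectors
            a, b = [], []
            for i in range(k):
                for j in range(k):
                    a += [i] * m[i, j]
                    b += [j] * m[i, j]
            if len(set(a)) < 2 and len(set(b)) < 2 and a == b:
                continue  # degenerate chance agreement
            expected = cohen_kappa_score(a, b)
            if np.isnan(expected):
                continue
            assert cohens_kappa(m) == pytest.approx(expected, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            cohens_kappa(np.array([[1, -1], [0, 2]]))


class TestConsensusReport:
    def _assignment(self, i, rf, svm, rfp=0.99, svmp=0.9):
        final = rf if rf == svm else (rf if rfp >= svmp else svm)
        decisive = None if rf == svm else ("rf" if rfp >= svmp else "svm")
        return LevelAssignment(f"S{i}", rf, rfp, svm, svmp, final, decisive)

    def test_headline_agreement_rate(self):
        asg = [self._assignment(i, "L1", "L1") for i in range(195)] + [
            self._assignment(200 + i, "L1", "L2") for i in range(5)
        ]
        rep = consensus_report(asg)
        assert rep.agreement_rate == pytest.approx(0.975)

    def test_decisiveness_share(self):
        asg = [self._assignment(i, "L1", "L1") for i in range(90)]
        asg += [self._assignment(100 + i, "L1", "L2", rfp=0.99, svmp=0.9) for i in range(7)]
        asg += [self._assignment(200, "L1", "L2", rfp=0.85, svmp=0.95)]
        rep = consensus_report(asg)
        assert rep.rf_decisiveness == pytest.approx(7 / 8)

    def test_no_disagreements_reports_missing_decisiveness(self):
        rep = consensus_report([self._assignment(0, "L1", "L1")])
        assert rep.rf_decisiveness is None and rep.agreement_rate == 1.0


class TestTraining:
    def test_separable_geometry_high_cv_accuracy(self):
        site = simulate_site(
            SyntheticSiteConfig(
                levels=(LevelSpec(0, 50, 250, "L1"), LevelSpec(60, 30, 250, "L2"))
            ),
            seed=5,
        )
        bands = propose_levels(site)
        model = train_consensus(site, bands, seed=5, n_estimators=100)
        assert model.cv_accuracy["rf"] >= 0.99
        assert model.cv_accuracy["svm"] >= 0.99

    def test_shuffled_labels_drop_to_chance(self):
        site = simulate_site(
            SyntheticSiteConfig(
                levels=(LevelSpec(0, 50, 200, "L1"), LevelSpec(60, 30, 200, "L2"))
            ),
            seed=6,
        )
        rng = np.random.default_rng(6)
        bands = [LevelBand("L1", -10, 55), LevelBand("L2", 55.01, 100)]
        shuffled = rng.permutation(np.array(["L1"] * 200 + ["L2"] * 200, dtype=object))
        model = train_consensus(site, bands, seed=6, n_estimators=50, labels=shuffled)
        # permuted labels carry no spatial signal: accuracy near the
        # majority-class rate (0.5 here)
        assert 0.35 <= model.cv_accuracy["rf"] <= 0.65
        assert 0.35 <= model.cv_accuracy["svm"] <= 0.65

    def test_same_seed_identical_predictions(self):
        site = simulate_site(
            SyntheticSiteConfig(
                levels=(LevelSpec(0, 50, 150, "L1"), LevelSpec(60, 30, 150, "L2"))
            ),
            seed=7,
        )
        bands = propose_levels(site)
        a = train_consensus(site, bands, seed=7, n_estimators=50, evaluate=False)
        b = train_consensus(site, bands, seed=7, n_estimators=50, evaluate=False)
        pa, _ = classify_specimens(a, site)
        pb, _ = classify_specimens(b, site)
        assert [x.final_label for x in pa] == [x.final_label for x in pb]
        assert [x.rf_prob for x in pa] == [x.rf_prob for x in pb]

    def test_band_smaller_than_folds_rejected(self):
        site = simulate_site(
            SyntheticSiteConfig(levels=(LevelSpec(0, 50, 30, "L1"), LevelSpec(60, 30, 2, "L2"))),
            seed=8,
        )
        bands = [LevelBand("L1", -10, 55), LevelBand("L2", 56, 95)]
        with pytest.raises(ValueError, match="folds"):
            train_consensus(site, bands, cv_folds=5, seed=8)

    def test_threshold_monotone_in_indeterminate_count(self):
        site = simulate_site(
            SyntheticSiteConfig(
                levels=(LevelSpec(0, 50, 300, "L1"), LevelSpec(50.001, 40, 300, "L2")),
                gap_cm=0.0,
            ),
            seed=9,
        )
        bands = [LevelBand("L1", -10, 50), LevelBand("L2", 50.001, 100)]
        model = train_consensus(site, bands, seed=9, n_estimators=100, evaluate=False)
        counts = []
        for thr in (0.6, 0.8, 0.95, 0.999):
            asg, _ = classify_specimens(model, site, threshold=thr)
            counts.append(sum(a.indeterminate for a in asg))
        assert counts == sorted(counts)
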