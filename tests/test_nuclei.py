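"""Classification stage: split, tree, tuning, error matrix, binuclear cascade."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import hepatoscope as hs
from hepatoscope.nuclei import TreeModel, binary_label


def _toy_record(i, x, y, area, true_class, predicted=None, **kw):
    defaults = dict(
        perimeter=30.0,
        circularity=0.9,
        elongation=1.1,
        intensity_mean=100.0,
        intensity_sd=10.0,
        nn_distance=20.0,
        touching_count=0,
    )
    defaults.update(kw)
    return hs.NucleusRecord(
        id=i, x=x, y=y, area=area, true_class=true_class,
        predicted_class=predicted, **defaults,
    )


def _two_class_toy(n_per_class=40, seed=0):
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n_per_class):
        recs.append(
            _toy_record(i, float(i), 0.0, rng.normal(70, 1), hs.CLASS_HEPATOCYTE)
        )
    for i in range(n_per_class):
        recs.append(
            _toy_record(
                n_per_class + i, float(i), 100.0, rng.normal(25, 1), hs.CLASS_OTHER
            )
        )
    return recs


class TestStratifiedSplit:
    def test_per_class_rounding(self):
        recs = _two_class_toy(10)  # 10 + 10
        cfg = hs.TreeConfig(train_fraction=0.70, seed=0)
        train, test = hs.stratified_split(recs, cfg)
        assert len(train) == 14 and len(test) == 6
        for cls in (hs.CLASS_HEPATOCYTE, hs.CLASS_OTHER):
            assert sum(r.true_class == cls for r in train) == 7

    def test_large_counts_round_to_nearest(self):
        recs = []
        i = 0
        for _ in range(1746):
            recs.append(_toy_record(i, float(i % 50), float(i // 50), 70, hs.CLASS_HEPATOCYTE))
            i += 1
        for _ in range(1169):
            recs.append(_toy_record(i, float(i % 50), float(i // 50), 25, hs.CLASS_OTHER))
            i += 1
        train, _ = hs.stratified_split(recs, hs.TreeConfig(seed=1))
        n_hep = sum(r.true_class == hs.CLASS_HEPATOCYTE for r in train)
        n_oth = sum(r.true_class == hs.CLASS_OTHER for r in train)
        assert (n_hep, n_oth) == (1222, 818)  # round(0.7 * n) per class

    def test_small_class_rejected(self):
        recs = _two_class_toy(5)[:5] + [_toy_record(99, 0.0, 0.0, 25.0, hs.CLASS_OTHER)]
        with pytest.raises(ValueError, match="fewer than 2"):
            hs.stratified_split(recs, hs.TreeConfig())

    def test_seed_reproducible(self):
        recs = _two_class_toy(20)
        a = hs.stratified_split(recs, hs.TreeConfig(seed=9))
        b = hs.stratified_split(recs, hs.TreeConfig(seed=9))
        assert [r.id for r in a[0]] == [r.id for r in b[0]]


class TestTrainTree:
    def test_separable_toy_perfect(self):
        recs = _two_class_toy()
        model = hs.train_tree(recs, hs.TreeConfig(seed=0))
        pred = model.predict(recs)
        assert all(r.predicted_class == binary_label(r.true_class) for r in pred)

    def test_single_class_rejected(self):
        recs = [_toy_record(i, float(i), 0.0, 70, hs.CLASS_HEPATOCYTE) for i in range(10)]
        with pytest.raises(ValueError, match="both binary classes"):
            hs.train_tree(recs, hs.TreeConfig())

    def test_depth_constraint_respected(self, nuclei_default):
        cfg = hs.TreeConfig(max_depth=4, seed=0)
        train, _ = hs.stratified_split(nuclei_default, cfg)
        model = hs.train_tree(train, cfg)
        assert model.estimator.get_depth() <= 4

    def test_depth_one_cannot_solve_xor(self):
        """Depth-1 stump on XOR-structured features stays near chance."""
        rng = np.random.default_rng(3)
        recs = []
        for i in range(200):
            a, b = rng.integers(0, 2), rng.integers(0, 2)
            cls = hs.CLASS_HEPATOCYTE if a ^ b else hs.CLASS_OTHER
            recs.append(
                _toy_record(
                    i, float(i), 0.0,
                    area=60.0 + 20.0 * a + rng.normal(0, 0.1),
                    true_class=cls,
                    intensity_mean=90.0 + 20.0 * b + rng.normal(0, 0.1),
                )
            )
        model = hs.train_tree(recs, hs.TreeConfig(max_depth=1, seed=0))
        pred = model.predict(recs)
        acc = np.mean(
            [r.predicted_class == binary_label(r.true_class) for r in pred]
        )
        assert acc <= 0.75


class TestIterativeTune:
    def test_single_config_grid(self, nuclei_default):
        cfg = hs.TreeConfig(max_depth=5, seed=0)
        train, test = hs.stratified_split(nuclei_default, cfg)
        chosen, report = hs.iterative_tune(train, test, [cfg])
        assert chosen == cfg and cfg in report

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            hs.iterative_tune([], [], [])

    def test_overfit_deep_config_rejected(self):
        """On noisy labels a depth-7 tree memorises the training set and its
        train/test statistics diverge; the shallow config is chosen."""
        rng = np.random.default_rng(7)
        recs = []
        for i in range(400):
            informative = rng.normal(0, 1)
            cls = hs.CLASS_HEPATOCYTE if informative + rng.normal(0, 0.8) > 0 else hs.CLASS_OTHER
            recs.append(
                _toy_record(
                    i, rng.uniform(0, 100), rng.uniform(0, 100),
                    area=60 + 10 * informative,
                    true_class=cls,
                    intensity_mean=rng.normal(100, 10),
                    intensity_sd=rng.normal(15, 3) + 5,
                    circularity=min(1.0, max(0.1, rng.normal(0.8, 0.1))),
                    elongation=1.0 + abs(rng.normal(0, 0.2)),
                    nn_distance=rng.uniform(5, 30),
                )
            )
        cfg3 = hs.TreeConfig(max_depth=3, seed=0)
        cfg7 = hs.TreeConfig(max_depth=7, seed=0)
        train, test = hs.stratified_split(recs, cfg3)
        chosen, report = hs.iterative_tune(train, test, [cfg3, cfg7])
        assert chosen.max_depth == 3
        assert report[cfg7]["balance"] >= report[cfg3]["balance"]


class TestErrorMatrix:
    def test_perfect_classifier(self):
        em = hs.error_matrix(
            ["Hepatocyte"] * 10 + ["nonHepatocyte"] * 10,
            ["Hepatocyte"] * 10 + ["nonHepatocyte"] * 10,
        )
        s = em.statistics()
        for k in ("PPV", "NPV", "sensitivity", "specificity", "accuracy"):
            assert s[k] == 1.0
        for k in ("FDR", "FNR", "FOR", "falsePos_over_realPos"):
            assert s[k] == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            hs.error_matrix(["Hepatocyte"], [])

    def test_undefined_ratio_flagged(self):
        em = hs.error_matrix(
            ["nonHepatocyte", "nonHepatocyte"], ["nonHepatocyte", "nonHepatocyte"]
        )
        assert math.isnan(em.PPV)
        assert "PPV" in em.flags

    @given(
        st.integers(0, 500), st.integers(0, 500),
        st.integers(0, 500), st.integers(0, 500),
    )
    def test_complement_identities(self, tp, fp, fn, tn):
        """PPV+FDR = 1, sensitivity+FNR = 1, NPV+FOR = 1 whenever defined."""
        em = hs.ErrorMatrix(tp=tp, fp=fp, fn=fn, tn=tn)
        if tp + fp > 0:
            assert em.PPV + em.FDR == pytest.approx(1.0, abs=1e-12)
        if tp + fn > 0:
            assert em.sensitivity + em.FNR == pytest.approx(1.0, abs=1e-12)
        if tn + fn > 0:
            assert em.NPV + em.FOR == pytest.approx(1.0, abs=1e-12)
        if tp + fp + fn + tn > 0:
            assert em.accuracy == pytest.approx(
                (tp + tn) / (tp + fp + fn + tn), abs=1e-12
            )
            if tp + fn > 0:
                assert em.falsePos_over_realPos == pytest.approx(
                    fp / (tp + fn), abs=1e-12
                )


class TestReconstructConfusion:
    @pytest.mark.parametrize(
        "args,expected",
        [
            ((537, 340, 0.9274, 0.8794), (498, 39, 299, 41)),
            ((100, 100, 1.0, 1.0), (100, 0, 100, 0)),
            ((1209, 829, 0.9404, 0.953), (1137, 72, 790, 39)),
        ],
    )
    def test_rounding_arithmetic(self, args, expected):
        assert hs.reconstruct_confusion(*args) == expected

    def test_out_of_range_rate(self):
        with pytest.raises(ValueError):
            hs.reconstruct_confusion(10, 10, 1.2, 0.5)


class TestReclassifyBinuclear:
    def test_touching_pair_promoted(self):
        recs = [
            _toy_record(0, 0.0, 0.0, 70.0, hs.CLASS_BINUCLEAR, hs.CLASS_HEPATOCYTE),
            _toy_record(1, 8.0, 0.0, 70.0, hs.CLASS_BINUCLEAR, hs.CLASS_HEPATOCYTE),
        ]
        out, audit = hs.reclassify_binuclear(recs)
        assert all(r.predicted_class == hs.CLASS_BINUCLEAR for r in out)
        assert audit[-1]["nuclei"] == 2

    def test_isolated_hepatocyte_unchanged(self):
        recs = [
            _toy_record(0, 0.0, 0.0, 70.0, hs.CLASS_HEPATOCYTE, hs.CLASS_HEPATOCYTE),
            _toy_record(1, 500.0, 0.0, 70.0, hs.CLASS_HEPATOCYTE, hs.CLASS_HEPATOCYTE),
        ]
        out, _ = hs.reclassify_binuclear(recs)
        assert all(r.predicted_class == hs.CLASS_HEPATOCYTE for r in out)

    def test_combined_area_window_enforced(self):
        recs = [
            _toy_record(0, 0.0, 0.0, 30.0, hs.CLASS_OTHER, hs.CLASS_HEPATOCYTE),
            _toy_record(1, 8.0, 0.0, 30.0, hs.CLASS_OTHER, hs.CLASS_HEPATOCYTE),
        ]
        out, _ = hs.reclassify_binuclear(recs)  # combined 60 < 1.4 × 70
        assert all(r.predicted_class == hs.CLASS_HEPATOCYTE for r in out)

    def test_clique_members_excluded(self):
        recs = [
            _toy_record(0, 0.0, 0.0, 70.0, hs.CLASS_OTHER, hs.CLASS_HEPATOCYTE),
            _toy_record(1, 8.0, 0.0, 70.0, hs.CLASS_OTHER, hs.CLASS_HEPATOCYTE),
            _toy_record(2, 4.0, 6.0, 70.0, hs.CLASS_OTHER, hs.CLASS_HEPATOCYTE),
        ]
        out, audit = hs.reclassify_binuclear(recs)
        assert all(r.predicted_class == hs.CLASS_HEPATOCYTE for r in out)
        assert audit[2]["pairs"] == 0  # R3 removed everything

    def test_empty_input(self):
        out, audit = hs.reclassify_binuclear([])
        assert out == [] and audit == []

    def test_idempotent_on_population(self, nuclei_default):
        model = hs.train_tree(nuclei_default, hs.TreeConfig(seed=0))
        pred = model.predict(nuclei_default)
        once, _ = hs.reclassify_binuclear(pred)
        twice, audit2 = hs.reclassify_binuclear(once)
        assert [r.predicted_class for r in once] == [r.predicted_class for r in twice]
        assert audit2[-1]["nuclei"] == 0


class TestClassDensity:
    def test_counts_over_area(self):
        recs = [
            _toy_record(i, float(i), 0.0, 70.0, hs.CLASS_HEPATOCYTE) for i in range(200)
        ]
        dens = hs.class_density(recs, 2.0)
        assert dens[hs.CLASS_HEPATOCYTE] == 100.0
        assert dens[hs.CLASS_BINUCLEAR] == 0.0

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            hs.class_density([], 0.0)

    def test_density_conservation(self, nuclei_default):
        dens = hs.class_density(nuclei_default, 1.0, use="true")
        assert sum(dens.values()) == pytest.approx(len(nuclei_default))
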