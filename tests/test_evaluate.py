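import itertools
import math

import numpy as np
import pandas as pd
import pytest

from olipred.balance import BalancePlan
from olipred.evaluate import (
    ConfusionCounts,
    auc,
    compare_methods,
    confusion_at,
    cross_rbp_sensitivity,
    curves,
    information_gain,
    information_gain_ranking,
    mcc,
    negative_resampling_ci,
    precision_at,
    run_cv,
)
from olipred.exceptions import DomainError, ProtocolError
from olipred.model import GridSpec
from olipred.synthetic import (
    SyntheticSpec,
    generate,
    planted_sites_pssm_source,
)

FAST_GRID = GridSpec(c_values=(0.1, 1.0), inner_folds=3)


def brute_force_auc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == +1]
    neg = [s for s, l in zip(scores, labels) if l == -1]
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0
        for p, n in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, -1, -1]) == 1.0

    def test_all_scores_equal(self):
        assert auc([0.5] * 6, [1, 1, 1, -1, -1, -1]) == 0.5

    def test_four_point_toy(self):
        assert auc([0.9, 0.8, 0.7, 0.1], [1, -1, 1, -1]) == pytest.approx(0.75)

    def test_one_class_absent_rejected(self):
        with pytest.raises(DomainError):
            auc([0.5, 0.6], [1, 1])

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(10, 200))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            labels = rng.choice([-1, 1], size=n)
            if len(set(labels)) < 2:
                continue
            assert auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )


class TestPrecision:
    def test_perfect(self):
        assert precision_at([0.9, 0.8, 0.1], [1, 1, -1]).value == 1.0

    def test_no_positive_predictions_flagged(self):
        res = precision_at([0.1, 0.2], [1, -1])
        assert res.value == 0.0 and res.no_positive_predictions

    def test_toy_two_thirds(self):
        assert precision_at([0.9, 0.8, 0.7, 0.1], [1, -1, 1, -1]).value == pytest.approx(2 / 3)

    def test_bad_threshold_rejected(self):
        with pytest.raises(DomainError):
            precision_at([0.5], [1], threshold=1.5)


class TestMcc:
    def test_perfect(self):
        assert mcc(ConfusionCounts(50, 0, 50, 0)) == 1.0

    def test_uninformative(self):
        assert mcc(ConfusionCounts(tp=25, fp=25, tn=25, fn=25)) == 0.0

    def test_closed_form(self):
        c = ConfusionCounts(tp=40, fp=15, tn=35, fn=10)
        expected = (40 * 35 - 15 * 10) / math.sqrt(55 * 50 * 50 * 45)
        assert mcc(c) == pytest.approx(expected)

    def test_zero_denominator_convention(self):
        assert mcc(ConfusionCounts(tp=10, fp=0, tn=0, fn=0)) == 0.0

    def test_symmetric_under_class_swap(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            tp, fp, tn, fn = rng.integers(0, 50, size=4)
            a = mcc(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
            b = mcc(ConfusionCounts(tp=int(tn), fp=int(fn), tn=int(tp), fn=int(fp)))
            assert a == pytest.approx(b)


class TestCurves:
    def test_perfect_roc_passes_corner(self):
        roc, _ = curves([0.9, 0.8, 0.2, 0.1], [1, 1, -1, -1])
        assert any(np.allclose(pt, [0.0, 1.0]) for pt in roc)

    def test_trapezoid_area_equals_auc(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(20, 150))
            scores = rng.random(n).round(2)  # force ties
            labels = np.where(rng.random(n) < 0.4, 1, -1)
            if len(set(labels)) < 2:
                continue
            roc, _ = curves(scores, labels)
            area = np.trapezoid(roc[:, 1], roc[:, 0])
            assert area == pytest.approx(auc(scores, labels), abs=1e-9)

    def test_constant_scores_pr_flat_at_prevalence(self):
        labels = [1, 1, -1, -1, -1]
        _, pr = curves([0.5] * 5, labels)
        # the recall=1 end of the curve sits at the class prevalence
        assert pr[-1, 0] == 1.0 and pr[-1, 1] == pytest.approx(2 / 5)


class TestCompareMethods:
    def test_identical_lists_not_significant(self):
        a = [0.7] * 10
        stat, p, sig = compare_methods(a, a)
        assert p == 1.0 and not sig

    def test_uniform_shift_significant(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0.6, 0.8, size=15)
        stat, p, sig = compare_methods(a, a + 0.1, alpha=0.01)
        assert sig and p < 0.01

    def test_short_lists_rejected(self):
        with pytest.raises(DomainError):
            compare_methods([0.5] * 3, [0.6] * 3)


class TestInformationGain:
    def test_label_identical_feature_one_bit(self):
        x = np.array([0, 0, 0, 0, 1, 1, 1, 1], float)
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        assert information_gain(x, y) == pytest.approx(1.0)

    def test_constant_feature_zero(self):
        assert information_gain(np.ones(10), np.array([0, 1] * 5)) == 0.0

    def test_eight_sample_hand_computation(self):
        x = np.arange(1, 9, dtype=float)
        y = np.array([0, 0, 0, 0, 1, 1, 1, 0])
        # best split: x <= 4 | x > 4 -> IG = H(3/8) - 0.5*H(3/4)
        h38 = -(3 / 8 * math.log2(3 / 8) + 5 / 8 * math.log2(5 / 8))
        h34 = -(0.75 * math.log2(0.75) + 0.25 * math.log2(0.25))
        assert information_gain(x, y) == pytest.approx(h38 - 0.5 * h34)

    def test_ranking_sorted_descending_ties_by_name(self):
        y = [+1, +1, -1, -1]
        df = pd.DataFrame(
            {"b": [1.0, 1, 0, 0], "a": [1.0, 1, 0, 0], "c": [0.3, 0.3, 0.3, 0.3]}
        )
        ranked = information_gain_ranking(df, y)
        assert [name for name, _ in ranked] == ["a", "b", "c"]
        assert ranked[0][1] == pytest.approx(1.0) and ranked[2][1] == 0.0


class TestRunCv:
    def test_partition_and_audit(self, tiny_gen):
        report = run_cv(
            tiny_gen.dataset, "oli", folds=5, seed=2, grid=FAST_GRID,
            plan=BalancePlan(seed=2),
        )
        ids = [s.id for s in tiny_gen.dataset.sequences]
        assert sorted(report.oof["id"]) == sorted(ids)  # each exactly once
        assert len(report.fold_results) == 5
        covered = [i for f in report.fold_results for i in f.test_ids]
        assert sorted(covered) == sorted(ids)
        for entry in report.leakage_audit:
            assert not set(entry["test_ids"]) & set(entry["smote_input_ids"])

    def test_pssm_source_sees_training_positives_only(self, tiny_gen):
        seen: list[list[str]] = []
        base = planted_sites_pssm_source(tiny_gen)

        def spy(train_pos):
            seen.append([s.id for s in train_pos])
            return base(train_pos)

        report = run_cv(
            tiny_gen.dataset, "olimo", pssm_source=spy, folds=5, seed=2,
            grid=FAST_GRID, plan=BalancePlan(seed=2),
        )
        for fold, ids_seen in enumerate(seen):
            test_ids = set(report.fold_results[fold].test_ids)
            assert all(i.startswith("pos_") for i in ids_seen)
            assert not test_ids & set(ids_seen)

    def test_too_few_records_per_class_rejected(self, tiny_gen):
        with pytest.raises(DomainError):
            run_cv(tiny_gen.dataset, "oli", folds=50)

    def test_missing_pssm_source_rejected(self, tiny_gen):
        with pytest.raises(ProtocolError):
            run_cv(tiny_gen.dataset, "olimo", folds=5)

    def test_olimoss_uses_structures(self, tiny_gen):
        from olipred.structure import structure_features

        sf_map = {i: structure_features(r) for i, r in tiny_gen.structures.items()}
        report = run_cv(
            tiny_gen.dataset, "olimoss",
            pssm_source=planted_sites_pssm_source(tiny_gen),
            structures=sf_map, folds=5, seed=3, grid=FAST_GRID,
        )
        assert report.schema_name == "olimoss"
        assert 0.5 <= report.pooled_auc <= 1.0


class TestNegativeResampling:
    def test_disjoint_draws_and_positive_width(self, tiny_gen):
        ds = tiny_gen.dataset
        res = negative_resampling_ci(
            ds.positives()[:15], ds.negatives(), "oli",
            draws=3, draw_size=20, folds=3, seed=4, grid=FAST_GRID,
            plan=BalancePlan(seed=4),
        )
        assert len(res.draw_aucs) == 3 and not res.degenerate
        lo, hi = res.ci
        assert hi > lo
        assert lo <= res.mean_auc <= hi

    def test_single_draw_degenerate(self, tiny_gen):
        ds = tiny_gen.dataset
        with pytest.warns(UserWarning, match="degenerate"):
            res = negative_resampling_ci(
                ds.positives()[:12], ds.negatives(), "oli",
                draws=1, draw_size=24, folds=3, seed=5, grid=FAST_GRID,
            )
        assert res.degenerate

    def test_oversized_draw_rejected(self, tiny_gen):
        ds = tiny_gen.dataset
        with pytest.raises(DomainError):
            negative_resampling_ci(
                ds.positives(), ds.negatives(), "oli",
                draws=2, draw_size=10_000,
            )


@pytest.fixture(scope="module")
def two_proteins():
    """Two synthetic RBPs with disjoint planted motifs."""
    from olipred.encoding import encode_dataset
    from olipred.model import train

    specs = {
            "P1": SyntheticSpec(n_pos=40, n_neg=40, length_range=(80, 160),
                            motif="UGUAUAUA", seed=11),
        "P2": SyntheticSpec(n_pos=40, n_neg=40, length_range=(80, 160),
                            motif="GCGCCGCG", seed=12),
    }
    models, pos_feats = [], []
    for name, spec in specs.items():
        gen = generate(spec)
        feats = encode_dataset(gen.dataset.sequences, "oli")
        m = train(feats.to_numpy(), gen.dataset.labels, FAST_GRID,
                  protein=name, schema="oli")
        models.append(m)
        pos_feats.append(
            encode_dataset(gen.dataset.positives(), "oli").to_numpy()
        )
    return models, pos_feats


class TestCrossRbpSensitivity:
    def test_entries_in_unit_interval(self, two_proteins):
        models, pos_feats = two_proteins
        mat = cross_rbp_sensitivity(models, pos_feats)
        assert ((0.0 <= mat) & (mat <= 1.0)).all()

    def test_own_motif_beats_foreign(self, two_proteins):
        models, pos_feats = two_proteins
        mat = cross_rbp_sensitivity(models, pos_feats)
        assert mat[0, 0] > mat[0, 1]
        assert mat[1, 1] > mat[1, 0]

    def test_diagonal_override(self, two_proteins):
        models, pos_feats = two_proteins
        mat = cross_rbp_sensitivity(models, pos_feats, diagonal_oof=[0.42, 0.24])
        assert mat[0, 0] == 0.42 and mat[1, 1] == 0.24
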