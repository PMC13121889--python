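"""Evaluation metrics against brute-force oracles and hand examples."""

import numpy as np
import pytest
from scipy import stats

import cliffgnn as cg
from cliffgnn.evaluation import (
    DROPOUT_RATES,
    MCS_THRESHOLDS,
    coloring_metrics,
    directional_auroc,
    gdir_curve,
    global_direction,
    paired_tests,
    perturbation_stability,
    regression_metrics,
    spearman_alignment,
)
from cliffgnn.attribution import maps_for_pairs


def make_pair(n_i=4, n_j=4, delta=2.0, unc_i=(2, 3), unc_j=(1,),
              fr_i=0.6, fr_j=0.8, pid="p"):
    mu_i = np.zeros(n_i)
    mu_i[list(unc_i)] = 1
    mu_j = np.zeros(n_j)
    mu_j[list(unc_j)] = 1
    return cg.ACPair(
        pair_id=pid, i=f"{pid}_i", j=f"{pid}_j",
        y_i=6.0 + delta, y_j=6.0,
        mask_common_i=1 - mu_i, mask_uncommon_i=mu_i,
        mask_common_j=1 - mu_j, mask_uncommon_j=mu_j,
        shared_fraction_i=fr_i, shared_fraction_j=fr_j,
    )


def make_map(scores, cid="c"):
    return cg.AttributionMap(cid, "gradient_x_input",
                             np.asarray(scores, float), None)


class TestRegressionMetrics:
    def test_perfect(self):
        rmse, pcc = regression_metrics([1, 2, 3], [1, 2, 3])
        assert rmse == 0.0 and pcc == pytest.approx(1.0)

    def test_anticorrelated(self):
        y = np.array([-1.0, 0.0, 1.0])
        _, pcc = regression_metrics(-y, y)
        assert pcc == pytest.approx(-1.0)

    def test_hand_rmse(self):
        rmse, _ = regression_metrics([1, 2, 5], [1, 2, 3])
        assert rmse == pytest.approx(np.sqrt(4 / 3))

    def test_zero_variance_pcc_missing(self):
        rmse, pcc = regression_metrics([2, 2, 2], [1, 2, 3])
        assert pcc is None and rmse > 0


class TestGlobalDirection:
    def test_direction_preserved(self):
        p = make_pair(delta=2.0)
        m_i = make_map([0, 0, 2.0, 2.0])
        m_j = make_map([0, 1.0, 0, 0])
        assert global_direction(p, m_i, m_j) == 1

    def test_direction_violated(self):
        p = make_pair(delta=2.0)
        assert global_direction(p, make_map([0, 0, 1, 1]),
                                make_map([0, 2.0, 0, 0])) == 0

    def test_exact_tie_scores_zero(self):
        p = make_pair(delta=2.0)
        assert global_direction(p, make_map([0, 0, 1, 1]),
                                make_map([0, 1.0, 0, 0])) == 0

    def test_zero_delta_rejected(self):
        p = make_pair(delta=0.0)
        with pytest.raises(ValueError):
            global_direction(p, make_map([0] * 4), make_map([0] * 4))

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bruteforce_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(250):
            n_i, n_j = rng.integers(2, 8, size=2)
            unc_i = rng.choice(n_i, size=rng.integers(0, n_i), replace=False)
            unc_j = rng.choice(n_j, size=rng.integers(0, n_j), replace=False)
            if len(unc_i) == 0 and len(unc_j) == 0:
                continue
            delta = float(rng.choice([-2.0, 1.5, 3.0]))
            p = make_pair(n_i, n_j, delta, unc_i, unc_j)
            s_i, s_j = rng.normal(size=n_i), rng.normal(size=n_j)
            got = global_direction(p, make_map(s_i), make_map(s_j))
            r_i = s_i[list(unc_i)].mean() if len(unc_i) else 0.0
            r_j = s_j[list(unc_j)].mean() if len(unc_j) else 0.0
            want = int(np.sign(r_i - r_j) == np.sign(delta))
            assert got == want


class TestGdirCurve:
    def _fixture(self):
        pairs = [
            make_pair(fr_i=0.55, fr_j=0.60, pid="a"),   # correct
            make_pair(fr_i=0.80, fr_j=0.85, pid="b"),   # correct
            make_pair(fr_i=0.90, fr_j=0.95, pid="c"),   # wrong
            make_pair(fr_i=0.97, fr_j=0.99, pid="d"),   # correct
        ]
        maps = {
            "a": (make_map([0, 0, 2, 2]), make_map([0, 1, 0, 0])),
            "b": (make_map([0, 0, 2, 2]), make_map([0, 1, 0, 0])),
            "c": (make_map([0, 0, 0, 0]), make_map([0, 1, 0, 0])),
            "d": (make_map([0, 0, 2, 2]), make_map([0, 1, 0, 0])),
        }
        return pairs, maps

    def test_hand_filtered_means(self):
        pairs, maps = self._fixture()
        curve = gdir_curve(pairs, maps)
        assert curve[0.50] == pytest.approx(3 / 4)
        assert curve[0.60] == pytest.approx(2 / 3)  # pair a drops (fr_i 0.55)
        assert curve[0.85] == pytest.approx(1 / 2)  # pairs c, d remain
        assert curve[0.95] == pytest.approx(1.0)    # only pair d

    def test_all_correct_gives_ones(self):
        pairs, maps = self._fixture()
        maps["c"] = (make_map([0, 0, 2, 2]), make_map([0, 1, 0, 0]))
        curve = gdir_curve(pairs, maps)
        assert all(v == 1.0 for v in curve.values() if v is not None)

    def test_threshold_sets_are_nested(self):
        pairs, _ = self._fixture()
        sel = {
            t: {p.pair_id for p in pairs
                if p.shared_fraction_i >= t and p.shared_fraction_j >= t}
            for t in MCS_THRESHOLDS
        }
        for lo, hi in zip(MCS_THRESHOLDS, MCS_THRESHOLDS[1:]):
            assert sel[hi] <= sel[lo]

    def test_thresholds_are_the_ten_canonical_ones(self):
        assert MCS_THRESHOLDS == tuple(
            pytest.approx(v) for v in
            (0.50, 0.55, 0.60, 0.65, 0.70, 0.75, 0.80, 0.85, 0.90, 0.95))


def _single_pair_setup(scores_i, scores_j, delta=2.0):
    p = make_pair(delta=delta)
    col = cg.ground_truth_coloring(p)
    maps = {p.pair_id: (make_map(scores_i), make_map(scores_j))}
    return [p], maps, {p.pair_id: col}


class TestColoringMetrics:
    def test_perfect_signs(self):
        args = _single_pair_setup([0, 0, 1, 2], [0, -1, 0, 0])
        acc, f1 = coloring_metrics(*args)
        assert acc == 1.0 and f1 == 1.0

    def test_all_zero_scores_score_zero(self):
        args = _single_pair_setup([0, 0, 0, 0], [0, 0, 0, 0])
        acc, f1 = coloring_metrics(*args)
        assert acc == 0.0

    def test_three_class_variant_counts_common_atoms(self):
        p = make_pair()
        col = cg.ground_truth_coloring(p)
        # uncommon atoms scored correctly; common atoms near zero
        maps = {p.pair_id: (make_map([0.01, -0.02, 1.0, 2.0]),
                            make_map([0.0, -1.0, 0.03, 0.0]))}
        acc, f1 = coloring_metrics([p], maps, {p.pair_id: col},
                                   include_common=True, zero_threshold=0.05)
        assert acc == 1.0 and f1 == 1.0
        # with threshold 0 the small common-atom scores become +-1 calls
        acc0, _ = coloring_metrics([p], maps, {p.pair_id: col},
                                   include_common=True, zero_threshold=0.0)
        assert acc0 == pytest.approx(5 / 8)

    def test_three_of_four_hand_confusion(self):
        # labels (+,+,-): uncommon i atoms 2,3 -> +1; uncommon j atom 1 -> -1
        # plus a second pair to reach 4 labelled atoms
        p1 = make_pair(pid="p1")
        p2 = make_pair(unc_i=(0,), unc_j=(2,), pid="p2")
        cols = {p.pair_id: cg.ground_truth_coloring(p) for p in (p1, p2)}
        maps = {
            "p1": (make_map([0, 0, 1, 1]), make_map([0, 1, 0, 0])),  # j wrong
            "p2": (make_map([1, 0, 0, 0]), make_map([0, 0, -1, 0])),
        }
        acc, _ = coloring_metrics([p1, p2], maps, cols)
        assert acc == pytest.approx(4 / 5)


class TestSpearman:
    def test_positive_separation_is_max_attainable(self):
        args = _single_pair_setup([0, 0, 3, 2], [0, -1, 0, 0])
        rho = spearman_alignment(*args)
        scores = np.array([3, 2, -1.0])
        labels = np.array([1, 1, -1])
        assert rho == pytest.approx(stats.spearmanr(scores, labels)[0])
        assert rho > 0

    def test_hand_ranks_small_fixture(self):
        args = _single_pair_setup([0, 0, -1, 2], [0, 0.5, 0, 0])
        rho = spearman_alignment(*args)
        want = stats.spearmanr([-1, 2, 0.5], [1, 1, -1])[0]
        assert rho == pytest.approx(want)

    def test_single_class_missing(self):
        p = make_pair(unc_j=())
        col = cg.ground_truth_coloring(p)
        maps = {p.pair_id: (make_map([0, 0, 1, 2]), make_map([0] * 4))}
        assert spearman_alignment([p], maps, {p.pair_id: col}) is None


class TestDirectionalAUROC:
    def test_perfect_separation(self):
        args = _single_pair_setup([0, 0, 3, 2], [0, -1, 0, 0])
        pos, neg = directional_auroc(*args)
        assert pos == 1.0 and neg == 1.0

    def test_constant_scores_are_chance(self):
        args = _single_pair_setup([0, 0, 1, 1], [0, 1, 0, 0])
        pos, neg = directional_auroc(*args)
        assert pos == 0.5 and neg == 0.5

    def test_ordered_scores_hand_case(self):
        # scores (3,2) on +1 atoms, (1,) ... construct labels (+,+,-,-)
        p1 = make_pair(pid="q1")
        p2 = make_pair(unc_i=(0,), unc_j=(2,), pid="q2")
        cols = {p.pair_id: cg.ground_truth_coloring(p) for p in (p1, p2)}
        maps = {
            "q1": (make_map([0, 0, 3, 2]), make_map([0, 1, 0, 0])),
            "q2": (make_map([2.5, 0, 0, 0]), make_map([0, 0, 0.5, 0])),
        }
        pos, _ = directional_auroc([p1, p2], maps, cols)
        # labels: +1 scores {3,2,2.5}, -1 scores {1,0.5} -> wait 1 > 0.5
        want = np.mean([[s > t for t in (1.0, 0.5)] for s in (3, 2, 2.5)])
        assert pos == pytest.approx(want)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_bruteforce_pairwise_estimator(self, seed):
        """Both directional AUROCs equal the exhaustive pairwise-comparison
        estimator (correctly ordered pairs + half ties, normalized)."""
        rng = np.random.default_rng(seed)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            labels = rng.choice([-1, 1], size=n)
            if len(np.unique(labels)) < 2:
                continue
            scores = np.round(rng.normal(size=n), 1)  # force some ties
            p = make_pair(n_i=n, n_j=2, unc_i=(), unc_j=(0,))
            col = cg.GroundTruthColoring(p.pair_id, labels_i=labels,
                                         labels_j=np.zeros(2))
            maps = {p.pair_id: (make_map(scores), make_map([0.0, 0.0]))}
            pos, neg = directional_auroc([p], maps, {p.pair_id: col})

            def brute(pos_s, neg_s):
                cmp = [(1.0 if a > b else 0.5 if a == b else 0.0)
                       for a in pos_s for b in neg_s]
                return float(np.mean(cmp))

            assert pos == pytest.approx(
                brute(scores[labels == 1], scores[labels == -1]))
            assert neg == pytest.approx(
                brute(-scores[labels == -1], -scores[labels == 1]))


class TestPairedTests:
    def test_identical_vectors_convention(self):
        t_p, w_p = paired_tests([1, 2, 3], [1, 2, 3])
        assert t_p == 1.0 and w_p is None

    def test_five_positive_differences_exact_wilcoxon(self):
        t_p, w_p = paired_tests([2, 3, 4, 5, 6], [1, 1, 1, 1, 1])
        assert w_p == pytest.approx(2 / 32)

    def test_two_sided_symmetry(self):
        a = [1.0, 2.5, 3.0, 0.5, 4.0]
        b = [2.0, 2.0, 2.0, 2.0, 2.0]
        ta, wa = paired_tests(a, b)
        tb, wb = paired_tests(b, a)
        assert ta == pytest.approx(tb)
        assert wa == pytest.approx(wb)

    def test_length_guard(self):
        with pytest.raises(ValueError):
            paired_tests([1, 2], [1, 2])


class TestReportOutputs:
    def test_plot_and_csv_helpers(self, tmp_path):
        from cliffgnn.evaluation import (EvaluationReport, curves_to_csv,
                                         plot_curves)

        report = EvaluationReport(
            rmse=0.2, pcc=0.95,
            gdir_by_threshold={0.5: 0.9, 0.55: 0.8, 0.95: None},
            stability={0.0: 0.8, 0.3: 0.5},
        )
        fig = plot_curves(report, tmp_path / "curves.png")
        assert (tmp_path / "curves.png").exists()
        curves_to_csv(report, tmp_path / "curves.csv")
        text = (tmp_path / "curves.csv").read_text()
        assert "gdir_by_threshold" in text and "stability" in text


class TestPerturbationStability:
    def test_rate_zero_reproduces_unperturbed_rho(self, pair_data,
                                                  random_state):
        _, _, graphs, dataset = pair_data
        pairs = dataset.pairs[:5]
        cols = {p.pair_id: dataset.colorings[p.pair_id] for p in pairs}
        maps = maps_for_pairs(random_state, pairs, graphs,
                              "gradient_x_input")
        base = spearman_alignment(pairs, maps, cols)
        out = perturbation_stability(random_state, pairs, graphs, cols,
                                     rates=(0.0, 0.2), seed=3)
        assert out[0.0] == pytest.approx(base, abs=1e-12)
        assert set(out) == {0.0, 0.2}

    def test_canonical_rate_grid(self):
        assert DROPOUT_RATES == (0.0, 0.05, 0.10, 0.20, 0.30)

    def test_seeded_perturbations_reproducible(self, pair_data, random_state):
        _, _, graphs, dataset = pair_data
        pairs = dataset.pairs[:3]
        cols = {p.pair_id: dataset.colorings[p.pair_id] for p in pairs}
        a = perturbation_stability(random_state, pairs, graphs, cols,
                                   rates=(0.3,), seed=9)
        b = perturbation_stability(random_state, pairs, graphs, cols,
                                   rates=(0.3,), seed=9)
        assert a == b
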