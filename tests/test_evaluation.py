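"""The four usage metrics against brute-force oracles and their edge rules."""

import numpy as np
import pytest
from scipy import stats

from apanet.data import DataError
from apanet.evaluation import (allelic_difference_analysis, averaged_spearman,
                               comparison_accuracy, highest_usage_accuracy, mae,
                               random_baseline)


def random_genes(rng, n_genes, min_pas=2, max_pas=8):
    truths, preds = [], []
    for _ in range(n_genes):
        n = int(rng.integers(min_pas, max_pas + 1))
        truths.append(rng.dirichlet(np.ones(n)))
        preds.append(rng.dirichlet(np.ones(n)))
    return preds, truths


# -- brute-force oracles ------------------------------------------------

def oracle_mae(preds, truths):
    errs = []
    for p, t in zip(preds, truths):
        for pi, ti in zip(p, t):
            errs.append(abs(pi - ti))
    return sum(errs) / len(errs)


def oracle_comparison(preds, truths, thr=0.05):
    correct = total = 0
    for p, t in zip(preds, truths):
        for i in range(len(t)):
            for j in range(len(t)):
                if i < j and abs(t[i] - t[j]) > thr:
                    total += 1
                    hi, lo = (i, j) if t[i] > t[j] else (j, i)
                    correct += int(p[hi] > p[lo])
    return correct / total, total


def oracle_highest(preds, truths, margin=0.15):
    correct = total = 0
    for p, t in zip(preds, truths):
        s = sorted(t, reverse=True)
        if len(t) >= 2 and s[0] - s[1] >= margin:
            total += 1
            correct += int(max(range(len(p)), key=p.__getitem__)
                           == max(range(len(t)), key=t.__getitem__))
    return correct / total, total


def oracle_spearman(preds, truths):
    vals = []
    for p, t in zip(preds, truths):
        r = stats.spearmanr(p, t).statistic
        if not np.isnan(r):
            vals.append(r)
    return float(np.mean(vals)), len(vals)


class TestMetricExamples:
    def test_mae_zero_for_perfect_prediction(self):
        t = [np.array([0.2, 0.8])]
        assert mae(t, t) == 0.0

    def test_mae_hand_example(self):
        p = [np.array([0.6, 0.4]), np.array([0.5, 0.5])]
        t = [np.array([0.5, 0.5]), np.array([1.0, 0.0])]
        assert np.isclose(mae(p, t), 0.30)

    def test_perfect_predictor_comparison_accuracy_is_one(self):
        t = [np.array([0.7, 0.3]), np.array([0.1, 0.2, 0.7])]
        acc, n = comparison_accuracy(t, t)
        assert acc == 1.0 and n == 4

    def test_near_tie_contributes_no_pairs(self):
        with pytest.raises(DataError, match="0 eligible"):
            comparison_accuracy([np.array([0.9, 0.1])], [np.array([0.52, 0.48])])

    def test_highest_usage_margin_rule(self):
        eligible = [np.array([0.6, 0.3, 0.1])]   # 0.6-0.3 = 0.3 >= 0.15
        acc, n = highest_usage_accuracy(eligible, eligible)
        assert (acc, n) == (1.0, 1)
        with pytest.raises(DataError):
            highest_usage_accuracy([np.array([0.5, 0.4, 0.1])],
                                   [np.array([0.5, 0.4, 0.1])])

    def test_spearman_identity_and_reversal(self):
        t = [np.array([0.5, 0.3, 0.2]), np.array([0.6, 0.4])]
        assert averaged_spearman(t, t) == (1.0, 2)
        rev = [v[::-1] for v in t]
        assert averaged_spearman(rev, t) == (-1.0, 2)

    def test_spearman_hand_example(self):
        # ranks (3,2,1) vs (3,1,2): Pearson on ranks = 0.5
        r, n = averaged_spearman([np.array([0.5, 0.3, 0.2])],
                                 [np.array([0.5, 0.2, 0.3])])
        assert np.isclose(r, 0.5) and n == 1

    def test_spearman_excludes_constant_rank_genes(self):
        r, n = averaged_spearman([np.array([0.5, 0.5]), np.array([0.9, 0.1])],
                                 [np.array([0.6, 0.4]), np.array([0.8, 0.2])])
        assert n == 1 and r == 1.0


class TestOracleEquivalence:
    def test_all_metrics_match_brute_force_on_random_genes(self, rng):
        preds, truths = random_genes(rng, 60)
        assert abs(mae(preds, truths) - oracle_mae(preds, truths)) < 1e-12
        acc, n = comparison_accuracy(preds, truths)
        oacc, on = oracle_comparison(preds, truths)
        assert n == on and abs(acc - oacc) < 1e-12
        h, nh = highest_usage_accuracy(preds, truths)
        oh, onh = oracle_highest(preds, truths)
        assert nh == onh and abs(h - oh) < 1e-12
        s, ns = averaged_spearman(preds, truths)
        os_, ons = oracle_spearman(preds, truths)
        assert ns == ons and abs(s - os_) < 1e-12

    def test_spearman_with_ties_matches_scipy(self):
        preds = [np.array([0.4, 0.4, 0.2]), np.array([0.25, 0.25, 0.25, 0.25])]
        truths = [np.array([0.5, 0.3, 0.2]), np.array([0.4, 0.3, 0.2, 0.1])]
        # second gene's prediction ranks are constant -> excluded
        r, n = averaged_spearman(preds, truths)
        assert n == 1
        assert np.isclose(r, stats.spearmanr(preds[0], truths[0]).statistic)


class TestEligibilityProperties:
    def test_raising_pair_threshold_never_adds_pairs(self, rng):
        preds, truths = random_genes(rng, 40)
        ns = [comparison_accuracy(preds, truths, threshold=thr)[1]
              for thr in (0.0, 0.05, 0.1, 0.2)]
        assert ns == sorted(ns, reverse=True)

    def test_raising_margin_never_adds_genes(self, rng):
        preds, truths = random_genes(rng, 40)
        ns = [highest_usage_accuracy(preds, truths, margin=m)[1]
              for m in (0.0, 0.15, 0.3)]
        assert ns == sorted(ns, reverse=True)

    def test_rank_metrics_invariant_under_monotone_transform(self, rng):
        # logits and softmax usages order sites identically, so score-only
        # models can be compared on logits
        preds, truths = random_genes(rng, 40)
        logits = [np.log(p) * 3 + 7 for p in preds]
        assert comparison_accuracy(preds, truths) == comparison_accuracy(logits, truths)
        assert highest_usage_accuracy(preds, truths) == highest_usage_accuracy(logits, truths)
        assert averaged_spearman(preds, truths) == averaged_spearman(logits, truths)


class TestRandomBaseline:
    def test_comparison_baseline_is_half(self, rng):
        _, truths = random_genes(rng, 300)
        m, sd = random_baseline(truths, "comparison", n_reps=50, seed=5)
        assert abs(m - 0.5) < 0.02

    def test_highest_baseline_on_fixed_pas_count_is_one_over_n(self, rng):
        truths = [rng.dirichlet(np.ones(4) * 0.3) for _ in range(300)]
        m, _ = random_baseline(truths, "highest", n_reps=50, seed=5)
        assert abs(m - 0.25) < 0.04

    def test_deterministic_given_seed(self, rng):
        _, truths = random_genes(rng, 50)
        assert random_baseline(truths, "comparison", 10, seed=3) == \
            random_baseline(truths, "comparison", 10, seed=3)


class _IdentityModel:
    """Predicts exactly the stored usage of each gene (for analysis tests)."""

    def predict_one(self, gene):
        from apanet.network import Prediction
        u = gene.usage_vector
        return Prediction(usage=u, logits=np.log(np.clip(u, 1e-12, None)))


class TestAllelicDifference:
    def test_perfect_prediction_gives_pcc_one(self, small_dataset):
        ds, _ = small_dataset
        genes = ds.multi_pas()[:10]
        import copy
        pairs = []
        for g in genes:
            gb = copy.deepcopy(g)
            gb.allele = "B"
            u = gb.usage_vector.copy()
            u[0], u[-1] = u[-1], u[0]
            for r, ui in zip(gb.pas_list, u):
                r.usage = float(ui)
            pairs.append((g, gb))
        rows = allelic_difference_analysis(_IdentityModel(), pairs, thresholds=(0.0,))
        thr, pcc, p, n = rows[0]
        assert np.isclose(pcc, 1.0)

    def test_anti_prediction_gives_pcc_minus_one(self, small_dataset):
        ds, _ = small_dataset
        genes = ds.multi_pas()[:10]
        import copy
        pairs = []
        for g in genes:
            gb = copy.deepcopy(g)
            gb.allele = "B"
            u = gb.usage_vector.copy()
            u[0], u[-1] = u[-1], u[0]
            for r, ui in zip(gb.pas_list, u):
                r.usage = float(ui)
            pairs.append((g, gb))

        def measured(ga, gb):  # negated ground truth
            return gb.usage_vector - ga.usage_vector

        rows = allelic_difference_analysis(_IdentityModel(), pairs,
                                           thresholds=(0.0,), measured=measured)
        assert np.isclose(rows[0][1], -1.0)

    def test_sparse_threshold_reports_nan(self, small_dataset):
        ds, _ = small_dataset
        g = ds.multi_pas()[0]
        rows = allelic_difference_analysis(_IdentityModel(), [(g, g)],
                                           thresholds=(0.99,))
        assert np.isnan(rows[0][1]) and rows[0][3] == 0
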