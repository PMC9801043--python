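"""Evaluation metrics for joint PAS-usage prediction.

Four metrics are reported, pooled over a test set of multi-PAS genes:

* **MAE** — mean absolute error between predicted and true usage,
  pooled over all sites of all genes (undefined for comparison-trained
  models whose scores are not usages);
* **comparison accuracy** — over all within-gene site pairs whose true
  usage differs by strictly more than 5 percentage points, the fraction
  for which the higher-usage site gets the higher predicted score;
* **highest-usage accuracy** — over genes whose top site beats the
  runner-up by at least 15 points, the fraction where the predicted
  argmax matches the true argmax;
* **averaged Spearman** — per-gene rank correlation (Pearson on average
  ranks, so ties are handled) between predicted and true usage, averaged
  over genes where it is defined.

Comparison and highest-usage accuracy only use the ordering of the
predicted scores, so logits and usages give identical results — which is
why raw pre-softmax scores are a valid surrogate for score-only models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import DataError
from .network import eligible_pairs

PAIR_THRESHOLD = 0.05
HIGHEST_MARGIN = 0.15
DIFF_THRESHOLDS = (0.0, 0.1, 0.2, 0.3, 0.4, 0.6, 0.8)


@dataclass
class MetricsReport:
    mae: float                    # NaN when undefined (score-only models)
    comparison_accuracy: float
    highest_usage_accuracy: float
    avg_spearman: float
    n_pas: int
    n_pairs: int
    n_genes_highest: int
    n_genes_rank: int

    def __str__(self):
        mae = "N/A" if np.isnan(self.mae) else f"{100 * self.mae:.2f}%"
        return (f"MAE {mae} | comparison {100 * self.comparison_accuracy:.2f}% "
                f"({self.n_pairs} pairs) | highest-usage "
                f"{100 * self.highest_usage_accuracy:.2f}% ({self.n_genes_highest} genes) "
                f"| Spearman {self.avg_spearman:.4f} ({self.n_genes_rank} genes)")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _check_aligned(predictions, truths):
    if len(predictions) != len(truths):
        raise DataError("predictions and truths differ in gene count")
    for p, t in zip(predictions, truths):
        if len(p) != len(t):
            raise DataError("prediction/truth length mismatch within a gene")


def mae(predictions, truths) -> float:
    """Mean absolute usage error pooled over every site of every gene."""
    _check_aligned(predictions, truths)
    errs = np.concatenate([np.abs(np.asarray(p, float) - np.asarray(t, float))
                           for p, t in zip(predictions, truths)])
    if errs.size == 0:
        raise DataError("MAE undefined: no sites")
    return float(errs.mean())


def comparison_accuracy(scores, truths, threshold: float = PAIR_THRESHOLD,
                        ties_correct: bool = False) -> tuple:
    """Pairwise comparison accuracy and the number of eligible pairs.

    Pairs are enumerated within genes only; a pair is eligible when its
    true usage difference is strictly greater than `threshold`. Tied
    predicted scores count as incorrect unless `ties_correct`.
    """
    _check_aligned(scores, truths)
    correct = total = 0
    for s, t in zip(scores, truths):
        s = np.asarray(s, float)
        t = np.asarray(t, float)
        for hi, lo in eligible_pairs(t, threshold):
            total += 1
            if s[hi] > s[lo] or (ties_correct and s[hi] == s[lo]):
                correct += 1
    if total == 0:
        raise DataError("comparison accuracy undefined: 0 eligible pairs")
    return correct / total, total


def highest_usage_accuracy(scores, truths, margin: float = HIGHEST_MARGIN) -> tuple:
    """Fraction of eligible genes whose top site is correctly predicted.

    Eligible: >= 2 sites and top-1 usage exceeding top-2 by at least `margin`.
    """
    _check_aligned(scores, truths)
    correct = total = 0
    for s, t in zip(scores, truths):
        t = np.asarray(t, float)
        if len(t) < 2:
            continue
        top = np.sort(t)[::-1]
        if top[0] - top[1] < margin:
            continue
        total += 1
        if int(np.argmax(s)) == int(np.argmax(t)):
            correct += 1
    if total == 0:
        raise DataError("highest-usage accuracy undefined: 0 eligible genes")
    return correct / total, total


def _average_ranks(x: np.ndarray) -> np.ndarray:
    """Average ranks (1-based), ties sharing their mean rank."""
    x = np.asarray(x, float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def averaged_spearman(scores, truths) -> tuple:
    """Mean per-gene Pearson correlation of average ranks, plus gene count.

    Genes where either rank vector is constant (correlation undefined)
    are excluded and counted out.
    """
    _check_aligned(scores, truths)
    vals = []
    for s, t in zip(scores, truths):
        pr = _average_ranks(np.asarray(s, float))
        gr = _average_ranks(np.asarray(t, float))
        dp = pr - pr.mean()
        dg = gr - gr.mean()
        den = np.sqrt((dp ** 2).sum() * (dg ** 2).sum())
        if den == 0:
            continue
        vals.append(float((dp * dg).sum() / den))
    if not vals:
        raise DataError("averaged Spearman undefined: all genes excluded")
    return float(np.mean(vals)), len(vals)


def compute_report(truths, scores, usages=None) -> MetricsReport:
    """All four metrics from per-gene score vectors (and usages if available)."""
    comp, n_pairs = comparison_accuracy(scores, truths)
    high, n_high = highest_usage_accuracy(scores, truths)
    rank, n_rank = averaged_spearman(scores, truths)
    m = mae(usages, truths) if usages is not None else float("nan")
    n_pas = int(sum(len(t) for t in truths))
    return MetricsReport(m, comp, high, rank, n_pas, n_pairs, n_high, n_rank)


def random_baseline(truths, metric: str = "comparison", n_reps: int = 100,
                    seed: int = 0) -> tuple:
    """Monte-Carlo performance of i.i.d. uniform per-site scores.

    Comparison accuracy of such a predictor is 50% by exchangeability;
    the highest-usage baseline depends on the site-count distribution.
    Returns (mean, sd) over `n_reps` score redraws.
    """
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_reps):
        scores = [rng.random(len(t)) for t in truths]
        if metric == "comparison":
            vals.append(comparison_accuracy(scores, truths)[0])
        elif metric == "highest":
            vals.append(highest_usage_accuracy(scores, truths)[0])
        elif metric == "spearman":
            vals.append(averaged_spearman(scores, truths)[0])
        elif metric == "mae":
            usages = [np.diff(np.sort(np.concatenate([[0.0], rng.random(len(t) - 1), [1.0]])))
                      for t in truths]
            vals.append(mae(usages, truths))
        else:
            raise DataError(f"unknown metric {metric!r}")
    return float(np.mean(vals)), float(np.std(vals))


def allelic_difference_analysis(model, pairs, thresholds=DIFF_THRESHOLDS,
                                measured: str = "observed"):
    """Predicted vs measured per-site allelic usage differences.

    `pairs` is a list of (gene_allele_A, gene_allele_B) with aligned site
    lists. The measured difference is usage_A - usage_B from the genes'
    usage vectors (set `measured='callable'` and pass a function instead
    of a string to supply external ground truth). For each minimum
    absolute measured difference in `thresholds`, returns a row
    (threshold, PCC, p-value, n) over the surviving sites; thresholds
    with fewer than 3 surviving sites report NaN.
    """
    pred_diff, meas_diff = [], []
    for ga, gb in pairs:
        if ga.gene_id != gb.gene_id or ga.n_pas != gb.n_pas:
            raise DataError(f"misaligned allele pair {ga.gene_id}/{gb.gene_id}")
        pa = model.predict_one(ga).usage
        pb = model.predict_one(gb).usage
        pred_diff.append(pa - pb)
        if callable(measured):
            meas_diff.append(np.asarray(measured(ga, gb), float))
        else:
            meas_diff.append(ga.usage_vector - gb.usage_vector)
    pred = np.concatenate(pred_diff)
    meas = np.concatenate(meas_diff)
    rows = []
    for thr in thresholds:
        mask = np.abs(meas) >= thr
        if mask.sum() < 3:
            rows.append((thr, float("nan"), float("nan"), int(mask.sum())))
            continue
        r, p = stats.pearsonr(pred[mask], meas[mask])
        rows.append((thr, float(r), float(p), int(mask.sum())))
    return rows
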