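"""Gene-level cross-validation and functional wrappers over the estimator.

The unit of splitting is the gene: all sites (and alleles) of a gene land
in the same fold, so no sequence information leaks between training and
testing. Aggregation across folds reports mean +/- SD per metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import DataError
from .estimator import APAUsageRegressor
from .evaluation import MetricsReport, compute_report

logger = logging.getLogger(__name__)


@dataclass
class FoldSplit:
    assignment: dict  # gene_id -> fold index
    k: int

    def fold_of(self, gene_id: str) -> int:
        return self.assignment[gene_id]

    def genes_in_fold(self, fold: int) -> list:
        return sorted(g for g, f in self.assignment.items() if f == fold)


def split_folds(gene_ids, k: int = 5, seed: int = 0) -> FoldSplit:
    """Deterministic gene-level k-fold partition, fold sizes within +/- 1."""
    ids = sorted(set(gene_ids))
    if len(ids) < k:
        raise DataError(f"need at least {k} genes for {k}-fold CV, got {len(ids)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    assignment = {ids[int(i)]: int(pos % k) for pos, i in enumerate(perm)}
    return FoldSplit(assignment, k)


def train(train_genes, val_genes=None, **params) -> APAUsageRegressor:
    """Fit an estimator on an explicit train/validation split."""
    est = APAUsageRegressor(**params)
    est.fit(train_genes, val_genes=val_genes)
    return est


def fine_tune(pretrained: APAUsageRegressor, genes, val_genes=None,
              max_epochs=None) -> APAUsageRegressor:
    """Continue training a fitted estimator at lr / fine_tune_lr_divisor."""
    return pretrained.fine_tune(genes, val_genes=val_genes, max_epochs=max_epochs)


def cross_validate(genes, k: int = 5, seed: int = 0, **params):
    """Gene-level k-fold CV.

    Returns (results, aggregate) where results is a list of
    (fold, fitted estimator, MetricsReport on that fold's test genes) and
    aggregate maps metric -> (mean, sd) across folds.
    """
    split = split_folds([g.gene_id for g in genes], k=k, seed=seed)
    results = []
    for fold in range(k):
        test = [g for g in genes if split.fold_of(g.gene_id) == fold]
        tr = [g for g in genes if split.fold_of(g.gene_id) != fold]
        overlap = {g.gene_id for g in tr} & {g.gene_id for g in test}
        if overlap:  # contract: splitting is by gene, never by PAS
            raise DataError(f"fold {fold}: leaked genes {sorted(overlap)[:5]}")
        est = APAUsageRegressor(**{**params, "random_state":
                                   params.get("random_state", 0) + fold})
        est.fit(tr)
        test_multi = [g for g in test if g.n_pas >= 2]
        scores = est.predict_scores(test_multi)
        usages = None if est.spec_.interaction == "none_pairwise" \
            else est.predict(test_multi)
        report = compute_report([g.usage_vector for g in test_multi],
                                scores, usages)
        results.append((fold, est, report))
        logger.info("fold %d: %s", fold, report)
    aggregate = aggregate_reports([r for _, _, r in results])
    return results, aggregate


def aggregate_reports(reports) -> dict:
    """mean +/- SD across folds for each metric."""
    out = {}
    for name in ("mae", "comparison_accuracy", "highest_usage_accuracy",
                 "avg_spearman"):
        vals = np.array([getattr(r, name) for r in reports], dtype=float)
        vals = vals[~np.isnan(vals)]
        if len(vals):
            out[name] = (float(vals.mean()), float(vals.std()))
    return out
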