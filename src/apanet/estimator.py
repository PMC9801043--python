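"""Scikit-learn style estimator for joint PAS-usage prediction.

`APAUsageRegressor` wraps the network family behind a fit/predict
surface: `X` is a list of :class:`~apanet.data.Gene` objects (each
carrying its ordered site windows and observed usage), `predict` returns
one usage vector per gene. Genes are never padded — minibatches are
bucketed by site count, and the base-network parameters are shared
across all sites of a gene.

Training minimizes the cross entropy between predicted and observed
usage (or, for the comparison-trained ablation, a logistic pairwise loss
over site pairs whose usage differs by more than 5%) with Adam, weight
decay on convolution/fully-connected weight matrices, dropout on the
BiLSTM outputs, and early stopping on validation mean absolute error.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator

from . import network as net
from .data import DataError, Gene
from .features import MotifTable, apply_zscore, featurize_many, fit_zscore
from .network import ModelSpec, ModelState, Prediction

logger = logging.getLogger(__name__)


class _Adam:
    def __init__(self, params: dict, lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def step(self, grads: dict):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p.data -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


class APAUsageRegressor(BaseEstimator):
    """Joint usage predictor over the competing PASs of a gene.

    Parameters mirror the architecture and training protocol: choose a
    base network and an interaction layer, then fit on a list of genes.

    Attributes set by :meth:`fit`: ``spec_`` (architecture), ``state_``
    (learned parameters), ``history_`` (per-epoch train loss and
    validation MAE), ``best_epoch_``, ``n_epochs_``.
    """

    def __init__(self, base_net="multi_conv", interaction="bilstm",
                 conv1_filters=40, conv1_width=12, pool_width=3, pool_stride=3,
                 conv2_filters=40, conv2_width=10, base_out_dim=64,
                 lstm_hidden=64, fc_sizes=(64,), dropout_p=0.2,
                 weight_decay=1e-3, lr=3e-3, fine_tune_lr_divisor=100.0,
                 max_epochs=50, patience=5, batch_genes=16, val_fraction=0.1,
                 pair_threshold=0.05, motif_table=None, random_state=0,
                 verbose=False):
        self.base_net = base_net
        self.interaction = interaction
        self.conv1_filters = conv1_filters
        self.conv1_width = conv1_width
        self.pool_width = pool_width
        self.pool_stride = pool_stride
        self.conv2_filters = conv2_filters
        self.conv2_width = conv2_width
        self.base_out_dim = base_out_dim
        self.lstm_hidden = lstm_hidden
        self.fc_sizes = fc_sizes
        self.dropout_p = dropout_p
        self.weight_decay = weight_decay
        self.lr = lr
        self.fine_tune_lr_divisor = fine_tune_lr_divisor
        self.max_epochs = max_epochs
        self.patience = patience
        self.batch_genes = batch_genes
        self.val_fraction = val_fraction
        self.pair_threshold = pair_threshold
        self.motif_table = motif_table
        self.random_state = random_state
        self.verbose = verbose

    # -- plumbing ------------------------------------------------------

    def _build_spec(self, W: int, n_features: int = 0) -> ModelSpec:
        return ModelSpec(
            base_net=self.base_net, interaction=self.interaction, W=W,
            n_features=n_features, conv1_filters=self.conv1_filters,
            conv1_width=self.conv1_width, pool_width=self.pool_width,
            pool_stride=self.pool_stride, conv2_filters=self.conv2_filters,
            conv2_width=self.conv2_width, base_out_dim=self.base_out_dim,
            lstm_hidden=self.lstm_hidden, fc_sizes=tuple(self.fc_sizes),
            dropout_p=self.dropout_p, weight_decay=self.weight_decay)

    def _gene_features(self, gene: Gene) -> np.ndarray | None:
        if self.spec_.base_net != "feature_net":
            return None
        raw = featurize_many(gene.windows, self._motif_table_)
        return apply_zscore(raw, self._zstats_)

    def _check_genes(self, X, need_usage: bool):
        if not X:
            raise DataError("need at least one gene")
        for g in X:
            if not isinstance(g, Gene):
                raise DataError("X must be a list of Gene objects")
            if need_usage:
                g.validate_usage()

    # -- training ------------------------------------------------------

    def fit(self, X, y=None, val_genes=None):
        """Train from random initialization.

        X: list of Gene (usage vectors are the targets; single-PAS genes
        are ignored). `val_genes` overrides the internal validation
        split (a seeded gene-level fraction of X otherwise).
        """
        self._check_genes(X, need_usage=True)
        genes = [g for g in X if g.n_pas >= 2]
        n_single = len(X) - len(genes)
        if n_single:
            logger.info("excluding %d single-PAS genes from training", n_single)
        if not genes:
            raise DataError("no multi-PAS genes to train on")
        rng = np.random.default_rng(self.random_state)

        if val_genes is None:
            perm = rng.permutation(len(genes))
            n_val = max(1, int(round(self.val_fraction * len(genes))))
            val_genes = [genes[i] for i in perm[:n_val]]
            train_genes = [genes[i] for i in perm[n_val:]]
        else:
            val_genes = [g for g in val_genes if g.n_pas >= 2]
            train_genes = genes
        if not train_genes:
            raise DataError("empty training set after validation split")

        W = train_genes[0].W
        if self.base_net == "feature_net":
            self._motif_table_ = self.motif_table or MotifTable.default()
            raw = np.concatenate([featurize_many(g.windows, self._motif_table_)
                                  for g in train_genes])
            self._zstats_ = fit_zscore(raw)
            n_features = raw.shape[1]
        else:
            n_features = 0
        self.spec_ = self._build_spec(W, n_features)
        self.state_ = net.init_state(self.spec_, rng)
        if self.base_net == "feature_net":
            self.state_.aux["zscore_mean"] = self._zstats_.mean
            self.state_.aux["zscore_sd"] = self._zstats_.sd
        self._optimize(train_genes, val_genes, self.lr, rng, self.max_epochs)
        return self

    def fine_tune(self, X, y=None, val_genes=None, max_epochs=None):
        """Continue training from the fitted parameters at a ~100x smaller
        learning rate (transfer to a smaller related dataset, e.g. from a
        parental strain to F1-hybrid alleles)."""
        self._require_fitted()
        self._check_genes(X, need_usage=True)
        genes = [g for g in X if g.n_pas >= 2]
        if any(g.W != self.spec_.W for g in genes):
            raise DataError("fine_tune: window length differs from the fitted spec")
        rng = np.random.default_rng(self.random_state + 1)
        if val_genes is None:
            perm = rng.permutation(len(genes))
            n_val = max(1, int(round(self.val_fraction * len(genes))))
            val_genes = [genes[i] for i in perm[:n_val]]
            genes = [genes[i] for i in perm[n_val:]]
        epochs = self.max_epochs if max_epochs is None else max_epochs
        if epochs > 0:
            self._optimize(genes, val_genes, self.lr / self.fine_tune_lr_divisor,
                           rng, epochs)
        return self

    def _optimize(self, train_genes, val_genes, lr, rng, max_epochs):
        spec, state = self.spec_, self.state_
        opt = _Adam(state.params, lr)
        decayed = set(net.decayed_param_names(state))
        drop_rng = np.random.default_rng(rng.integers(2 ** 31))

        feats = {id(g): self._gene_features(g) for g in train_genes + val_genes} \
            if spec.base_net == "feature_net" else {}

        best = state.copy_arrays()
        best_val = np.inf
        best_epoch = 0
        history = []
        stale = 0
        order = np.arange(len(train_genes))
        for epoch in range(1, max_epochs + 1):
            rng.shuffle(order)
            buckets = {}
            for i in order:
                buckets.setdefault(train_genes[i].n_pas, []).append(train_genes[i])
            losses = []
            for n, bucket in sorted(buckets.items()):
                for lo in range(0, len(bucket), self.batch_genes):
                    batch = bucket[lo:lo + self.batch_genes]
                    loss = self._batch_loss(batch, feats, drop_rng)
                    if loss is None:
                        continue
                    if not np.isfinite(loss.data):
                        raise FloatingPointError(
                            f"non-finite training loss at epoch {epoch}")
                    for p in state.params.values():
                        p.grad = None
                    loss.backward()
                    grads = {}
                    for k, p in state.params.items():
                        g = p.grad if p.grad is not None else np.zeros_like(p.data)
                        if k in decayed and spec.weight_decay > 0:
                            g = g + spec.weight_decay * p.data
                        grads[k] = g
                    opt.step(grads)
                    losses.append(float(loss.data))
            val_mae = self._validation_mae(val_genes, feats)
            history.append({"epoch": epoch,
                            "train_loss": float(np.mean(losses)) if losses else np.nan,
                            "val_mae": val_mae})
            if self.verbose:
                logger.info("epoch %d: train loss %.4f, val MAE %.4f",
                            epoch, history[-1]["train_loss"], val_mae)
            if val_mae < best_val - 1e-9:
                best_val = val_mae
                best = state.copy_arrays()
                best_epoch = epoch
                stale = 0
            else:
                stale += 1
                if stale >= self.patience:
                    break
        state.load_arrays(best)
        self.history_ = history
        self.best_epoch_ = best_epoch
        self.best_val_mae_ = best_val
        self.n_epochs_ = len(history)

    def _batch_loss(self, batch, feats, drop_rng):
        spec, state = self.spec_, self.state_
        windows = [g.windows for g in batch]
        features = [feats[id(g)] for g in batch] if feats else None
        logits = net.forward_logits(spec, state, windows, features=features,
                                    dropout_rng=drop_rng)
        if spec.interaction == "none_pairwise":
            hi_idx, lo_idx = [], []
            for b, g in enumerate(batch):
                for i, j in net.eligible_pairs(g.usage_vector, self.pair_threshold):
                    hi_idx.append((b, i))
                    lo_idx.append((b, j))
            if not hi_idx:
                return None
            hi = net.ad.getitem(logits, tuple(np.array(hi_idx).T))
            lo = net.ad.getitem(logits, tuple(np.array(lo_idx).T))
            return net.pairwise_loss(hi, lo)
        truth = np.stack([g.usage_vector for g in batch])
        return net.batch_cross_entropy(logits, truth)

    def _validation_mae(self, val_genes, feats):
        """Early-stopping criterion: usage MAE, or mean pairwise loss for the
        comparison-trained ablation (whose scores are not usages)."""
        if not val_genes:
            return np.nan
        spec = self.spec_
        if spec.interaction == "none_pairwise":
            vals = []
            for g in val_genes:
                pred = self._predict_gene(g, feats.get(id(g)))
                for i, j in net.eligible_pairs(g.usage_vector, self.pair_threshold):
                    d = pred.logits[i] - pred.logits[j]
                    vals.append(float(np.log1p(np.exp(-abs(d))) + max(0.0, -d)))
            return float(np.mean(vals)) if vals else np.nan
        errs = []
        for g in val_genes:
            pred = self._predict_gene(g, feats.get(id(g)))
            errs.append(np.abs(pred.usage - g.usage_vector))
        return float(np.concatenate(errs).mean())

    # -- inference -----------------------------------------------------

    def _require_fitted(self):
        if not hasattr(self, "state_"):
            raise DataError("estimator is not fitted")

    def _predict_gene(self, gene: Gene, features=None) -> Prediction:
        if features is None and self.spec_.base_net == "feature_net":
            features = self._gene_features(gene)
        return net.predict_windows(self.spec_, self.state_, gene.windows,
                                   features=features)

    def predict_one(self, gene: Gene) -> Prediction:
        self._require_fitted()
        return self._predict_gene(gene)

    def predict(self, X):
        """Per-gene usage vectors (lists of arrays summing to 1)."""
        self._require_fitted()
        if self.spec_.interaction == "none_pairwise":
            raise DataError("comparison-trained model has no usage output; "
                            "use predict_scores")
        return [self._predict_gene(g).usage for g in X]

    def predict_scores(self, X):
        """Per-gene raw scores (pre-softmax logits); defined for every model."""
        self._require_fitted()
        return [self._predict_gene(g).logits for g in X]

    def score(self, X, y=None):
        """Negative usage MAE (sklearn convention: larger is better)."""
        preds = self.predict(X)
        errs = np.concatenate([np.abs(p - g.usage_vector) for p, g in zip(preds, X)])
        return -float(errs.mean())

    # -- persistence ---------------------------------------------------

    def save(self, path):
        self._require_fitted()
        self.state_.save(path)

    def load(self, path):
        """Load a fitted state saved with :meth:`save` into this estimator."""
        spec, state = ModelState.load(path)
        self.spec_ = spec
        self.state_ = state
        if spec.base_net == "feature_net":
            from .features import ZScoreStats
            self._motif_table_ = self.motif_table or MotifTable.default()
            self._zstats_ = ZScoreStats(state.aux["zscore_mean"], state.aux["zscore_sd"])
        self.history_ = []
        return self
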