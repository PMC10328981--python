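"""Heartbeat-segment detectors: a trainable 1-D CNN and a template oracle.

Both detectors consume prepared segments (length ``M``, centred, scaled to
[0, 1]) and expose the probability ``P(B)`` that the segment contains one
complete, roughly centred heartbeat.  They follow the scikit-learn
estimator protocol (``fit`` / ``predict_proba`` / ``get_params``) so they
compose with sklearn model selection; the windowing loop only relies on
``predict_beat_proba``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import _nn
from .prep import DEFAULT_M, AlignedVector


@dataclass
class TrainConfig:
    """Cross-validation training settings (record-wise folds)."""

    epochs: int = 15
    folds: int = 10
    batch_size: int = 256
    lr: float = 1e-3
    dropout: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


class BeatSegmentCNN(BaseEstimator, ClassifierMixin):
    """Five conv/ReLU/maxpool blocks, then dropout, a dense layer and softmax.

    The convolution stack halves the 512-sample input five times
    (512 -> 16 positions at 128 channels); dropout acts on the flattened
    features feeding the final dense layer.  Trained with Adam on
    cross-entropy.  Binary classes: 1 = valid beat (VB), 0 = non-valid.
    """

    def __init__(self, M: int = DEFAULT_M, filters=(8, 16, 32, 64, 128),
                 kernel: int = 7, pool: int = 2, dropout: float = 0.5,
                 lr: float = 1e-3, batch_size: int = 256, epochs: int = 15,
                 random_state: int = 0, verbose: bool = False):
        self.M = M
        self.filters = filters
        self.kernel = kernel
        self.pool = pool
        self.dropout = dropout
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.random_state = random_state
        self.verbose = verbose

    # -- construction ------------------------------------------------------
    def _build(self) -> None:
        if self.M < 32:
            raise ValueError("M must be >= 32")
        rng = np.random.default_rng(self.random_state)
        layers = []
        c_in = 1
        length = self.M
        for c_out in self.filters:
            layers.append(_nn.Conv1D(c_in, c_out, self.kernel, rng))
            layers.append(_nn.ReLU())
            layers.append(_nn.MaxPool1D(self.pool))
            length = -(-length // self.pool)
            c_in = c_out
        layers.append(_nn.Flatten())
        layers.append(_nn.Dropout(self.dropout, rng))
        layers.append(_nn.Dense(length * c_in, 2, rng))
        self.net_ = _nn.Sequential(layers)
        self._rng = rng
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = self.M

    def _check_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.M:
            raise ValueError(f"expected segments of length {self.M}, got {X.shape[1]}")
        return X[:, None, :]        # (B, 1, M)

    # -- sklearn interface -------------------------------------------------
    def fit(self, X, y):
        X3 = self._check_X(X)
        y = np.asarray(y, dtype=np.int64).ravel()
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be binary VB(1)/NVB(0)")
        if len(np.unique(y)) < 2:
            raise ValueError("training split must contain both classes")
        self._build()
        opt = _nn.Adam(self.net_.layers, lr=self.lr)
        n = X3.shape[0]
        self.loss_curve_ = []
        for epoch in range(self.epochs):
            order = self._rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                sel = order[start:start + self.batch_size]
                logits = self.net_.forward(X3[sel], train=True)
                probs = _nn.softmax(logits)
                loss, grad = _nn.cross_entropy_grad(probs, y[sel])
                self.net_.backward(grad)
                opt.step()
                losses.append(loss)
            self.loss_curve_.append(float(np.mean(losses)))
            if self.verbose:
                print(f"epoch {epoch + 1}/{self.epochs} loss {self.loss_curve_[-1]:.4f}")
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        X3 = self._check_X(X)
        out = np.empty((X3.shape[0], 2))
        for start in range(0, X3.shape[0], 1024):
            logits = self.net_.forward(X3[start:start + 1024], train=False)
            out[start:start + 1024] = _nn.softmax(logits)
        return out

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def predict_beat_proba(self, x) -> float:
        """P(B) for a single prepared segment."""
        if isinstance(x, AlignedVector):
            x = x.values
        return float(self.predict_proba(np.asarray(x)[None, :])[0, 1])

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        check_is_fitted(self, "net_")
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.net_.state_dict())
        meta = {"kind": "cnn", **{k: (list(v) if isinstance(v, tuple) else v)
                                  for k, v in self.get_params().items()}}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "BeatSegmentCNN":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        meta.pop("kind", None)
        if "filters" in meta:
            meta["filters"] = tuple(meta["filters"])
        model = cls(**meta)
        model._build()
        with np.load(path.with_suffix(".npz")) as data:
            model.net_.load_state_dict(dict(data))
        return model


def build_cnn(M: int = DEFAULT_M, **kwargs) -> BeatSegmentCNN:
    """An initialised (untrained) CNN whose predictions are valid softmax."""
    model = BeatSegmentCNN(M=M, **kwargs)
    model._build()
    return model


class OracleBeatDetector(BaseEstimator, ClassifierMixin):
    """Deterministic detector: gated, squashed template cross-correlation.

    The peak zero-normalised cross-correlation of the window against a
    noiseless beat template measures morphological evidence; a positional
    gate demands that the matching beat sit near the window centre
    (mirroring the CNN's preference for centred valid segments).  The peak
    correlation is squashed with a concave power so clean-but-imperfect
    matches clear the detection threshold while structureless windows
    do not.
    """

    def __init__(self, templates=None, M: int = DEFAULT_M,
                 core_frac: float = 0.10, gate_frac: float = 0.15,
                 gate_floor: float = 0.75, edge_penalty: float = 0.25,
                 squash_exp: float = 0.5, detrend: bool = True):
        self.templates = templates
        self.M = M
        self.core_frac = core_frac
        self.gate_frac = gate_frac
        self.gate_floor = gate_floor
        self.edge_penalty = edge_penalty
        self.squash_exp = squash_exp
        self.detrend = detrend

    def fit(self, X=None, y=None):
        if self.templates is None:
            raise ValueError("at least one beat template is required")
        tpls = self.templates
        if isinstance(tpls, (AlignedVector, np.ndarray)):
            tpls = [tpls]
        self.templates_ = []
        for t in tpls:
            if isinstance(t, AlignedVector):
                # same preprocessing the scorer applies to incoming windows,
                # so a window identical to the template correlates at 1.0
                xd = self._pre(np.asarray(t.values, dtype=float))
                lead = -(-(t.M - t.source_len) // 2)
                core = xd[lead:lead + t.source_len]
            else:
                core = np.asarray(t, dtype=float).ravel()
            if core.size < 2 or core.size > self.M:
                raise ValueError("template core must have length in [2, M]")
            core = core - core.mean()
            norm = np.linalg.norm(core)
            if norm == 0:
                raise ValueError("template is constant")
            self.templates_.append(core / norm)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = self.M
        return self

    def _gate(self, offset: float) -> float:
        a = abs(offset)
        core = self.core_frac * self.M
        gate = self.gate_frac * self.M
        if a <= core:
            return 1.0
        if a <= gate:
            frac = (a - core) / (gate - core)
            return 1.0 + frac * (self.gate_floor - 1.0)
        return self.edge_penalty

    def _pre(self, x: np.ndarray) -> np.ndarray:
        """Remove a linear trend (baseline-wander slope) when enabled."""
        if not self.detrend:
            return x
        n = np.arange(x.size)
        slope, icept = np.polyfit(n, x, 1)
        return x - (slope * n + icept)

    def _score(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float).ravel()
        if x.size != self.M:
            raise ValueError(f"expected prepared segments of length {self.M}")
        x = self._pre(x)
        csum = np.concatenate(([0.0], np.cumsum(x)))
        csum2 = np.concatenate(([0.0], np.cumsum(x * x)))
        best = 0.0
        for t in self.templates_:
            Lt = t.size
            dots = np.correlate(x, t, mode="valid")
            u = np.arange(dots.size)
            seg_sum = csum[u + Lt] - csum[u]
            seg_sq = csum2[u + Lt] - csum2[u]
            var = np.maximum(seg_sq - seg_sum ** 2 / Lt, 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                rho = np.where(var > 0, dots / np.sqrt(var), 0.0)
            u_star = int(np.argmax(rho))
            offset = (u_star + Lt / 2.0) - self.M / 2.0
            p = float(np.clip(rho[u_star], 0.0, 1.0)) ** self.squash_exp
            best = max(best, p * self._gate(offset))
        return min(best, 1.0)

    def predict_beat_proba(self, x) -> float:
        check_is_fitted(self, "templates_")
        if isinstance(x, AlignedVector):
            x = x.values
        return self._score(np.asarray(x))

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "templates_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        p = np.array([self._score(row) for row in X])
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def oracle_detector(templates, M: int = DEFAULT_M, **kwargs) -> OracleBeatDetector:
    """Convenience constructor returning a fitted oracle."""
    return OracleBeatDetector(templates=templates, M=M, **kwargs).fit()


def train_crossval(dataset, cfg: TrainConfig | None = None, **model_kwargs):
    """Record-wise k-fold training of the CNN.

    Returns ``(models, fold_reports)`` where ``fold_reports[f]`` holds the
    held-out confusion counts and derived metrics for fold ``f``.  Records
    never straddle the train/test boundary of any fold.
    """
    from .evaluation import classifier_metrics

    cfg = cfg or TrainConfig()
    folds = np.unique(dataset.fold)
    if folds.size < 2:
        raise ValueError("dataset must contain at least 2 folds")
    models, reports = [], []
    for f in folds:
        test_mask = dataset.fold == f
        train_mask = ~test_mask
        y_train = dataset.y[train_mask]
        if test_mask.sum() == 0 or len(np.unique(y_train)) < 2:
            raise ValueError(f"fold {f} leaves an empty or single-class split")
        model = BeatSegmentCNN(
            M=dataset.M, dropout=cfg.dropout, lr=cfg.lr,
            batch_size=cfg.batch_size, epochs=cfg.epochs,
            random_state=cfg.seed + int(f), **model_kwargs,
        )
        model.fit(dataset.X[train_mask], y_train)
        pred = model.predict(dataset.X[test_mask])
        y_test = dataset.y[test_mask]
        tp = int(np.sum((pred == 1) & (y_test == 1)))
        tn = int(np.sum((pred == 0) & (y_test == 0)))
        fp = int(np.sum((pred == 1) & (y_test == 0)))
        fn = int(np.sum((pred == 0) & (y_test == 1)))
        metrics = classifier_metrics(tp=tp, tn=tn, fp=fp, fn=fn)
        models.append(model)
        reports.append({"fold": int(f), "tp": tp, "tn": tn, "fp": fp, "fn": fn,
                        "metrics": metrics})
    return models, reports
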