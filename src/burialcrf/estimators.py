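"""Scikit-learn style estimators over the CRF engine.

``HighOrderCRF`` is the full segment-conditioned model (orders 1/3/4 on
helices, 1/2 on strands, 1 on coils); ``ChainCRF`` restricts every
segment to the coil potential (adjacent-pair coupling only);
``BurialLogistic`` drops label coupling entirely and classifies residues
independently with a logistic regression on the singlet features.  The
three form a strict nesting in expressiveness, which is the comparison
axis of the model study.

X is a list of :class:`~burialcrf.records.ProteinRecord`; y is an
optional list of per-residue 0/1 label arrays (records' own labels are
used when y is None).  All estimators are clonable and compose with
sklearn model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression

from . import training
from .inference import predict_record
from .model import CHAIN_ORDERS, SEGMENT_ORDERS, ModelDims, ModelParameters
from .records import ProteinRecord, as_labels

__all__ = ["HighOrderCRF", "ChainCRF", "BurialLogistic"]


def _with_labels(X: list[ProteinRecord], y) -> list[ProteinRecord]:
    if y is None:
        for r in X:
            if r.labels is None:
                raise ValueError(f"record {r.id!r} has no labels and y was not given")
        return X
    if len(y) != len(X):
        raise ValueError("y must have one label array per record")
    out = []
    for r, yy in zip(X, y):
        out.append(
            ProteinRecord(
                id=r.id,
                sequence=r.sequence,
                segmentation=r.segmentation,
                singlet_features=r.singlet_features,
                doublet_features=r.doublet_features,
                labels=as_labels(yy, r.length),
            )
        )
    return out


class _ColumnScaler:
    """Z-scores real-valued singlet columns; binary 0/1 columns pass through."""

    def fit(self, records: list[ProteinRecord]) -> "_ColumnScaler":
        X = np.vstack([r.singlet_features for r in records])
        binary = np.all((X == 0) | (X == 1), axis=0)
        mean = np.where(binary, 0.0, X.mean(axis=0))
        std = np.where(binary, 1.0, X.std(axis=0))
        std = np.where(std > 0, std, 1.0)
        self.mean_, self.std_ = mean, std
        return self

    def transform(self, records: list[ProteinRecord]) -> list[ProteinRecord]:
        out = []
        for r in records:
            out.append(
                ProteinRecord(
                    id=r.id,
                    sequence=r.sequence,
                    segmentation=r.segmentation,
                    singlet_features=(r.singlet_features - self.mean_) / self.std_,
                    doublet_features=r.doublet_features,
                    labels=r.labels,
                )
            )
        return out

    def to_dict(self) -> dict:
        return {"mean": self.mean_.tolist(), "std": self.std_.tolist()}

    @classmethod
    def from_dict(cls, data: dict) -> "_ColumnScaler":
        obj = cls()
        obj.mean_ = np.asarray(data["mean"], dtype=float)
        obj.std_ = np.asarray(data["std"], dtype=float)
        return obj


class HighOrderCRF(BaseEstimator, ClassifierMixin):
    """Segment-conditioned high-order CRF for burial-state sequences.

    Parameters
    ----------
    l2 : float
        Ridge strength on all weights (keeps the concave objective strictly
        concave and the maximizer unique).
    learning_rate, max_iter, tol : float
        Gradient-ascent controls; see :class:`burialcrf.training.TrainingConfig`.
    normalize : bool
        Z-score real-valued singlet columns using training statistics
        (stored with the model).
    random_state : int
        Seed for the (optional) mini-batch shuffling; the default
        full-batch fit is deterministic regardless.

    Attributes
    ----------
    params_ : ModelParameters
        Fitted weight vector Λ = (θ, λ, μ, γ, τ).
    trace_ : TrainingTrace
        Per-iteration objective, gradient norm and step size.
    n_iter_ : int
    """

    _segment_orders = SEGMENT_ORDERS

    def __init__(
        self,
        l2: float = 1.0,
        learning_rate: float = 1.0,
        max_iter: int = 200,
        tol: float = 1e-6,
        normalize: bool = True,
        optimizer: str = "gd",
        batch_size: int = 0,
        random_state: int = 0,
    ):
        self.l2 = l2
        self.learning_rate = learning_rate
        self.max_iter = max_iter
        self.tol = tol
        self.normalize = normalize
        self.optimizer = optimizer
        self.batch_size = batch_size
        self.random_state = random_state

    # -- estimator API -------------------------------------------------------

    def fit(self, X: list[ProteinRecord], y=None) -> "HighOrderCRF":
        records = _with_labels(X, y)
        if self.normalize:
            self.scaler_ = _ColumnScaler().fit(records)
            records = self.scaler_.transform(records)
        else:
            self.scaler_ = None
        cfg = training.TrainingConfig(
            learning_rate=self.learning_rate,
            l2=self.l2,
            max_iter=self.max_iter,
            tol=self.tol,
            seed=self.random_state,
            batch_size=self.batch_size,
            optimizer=self.optimizer,
        )
        params, trace = training.fit(
            records, cfg, segment_orders=dict(self._segment_orders)
        )
        if self.scaler_ is not None:
            params.normalization = self.scaler_.to_dict()
        self.params_ = params
        self.trace_ = trace
        self.n_iter_ = len(trace.objective)
        self.classes_ = np.array([0, 1])
        return self

    def _prepare(self, X: list[ProteinRecord]) -> list[ProteinRecord]:
        if getattr(self, "scaler_", None) is not None:
            return self.scaler_.transform(X)
        return X

    def predict_marginals(self, X: list[ProteinRecord]) -> list[np.ndarray]:
        """Per-record (L, 2) matrices of p(Y_i = y | X)."""
        self._check_fitted()
        return [predict_record(r, self.params_).marginals for r in self._prepare(X)]

    def predict(self, X: list[ProteinRecord]) -> list[np.ndarray]:
        """Marginal-decoded 0/1 labels per record (ties go to buried)."""
        self._check_fitted()
        return [predict_record(r, self.params_).decoded for r in self._prepare(X)]

    def score(self, X: list[ProteinRecord], y=None) -> float:
        """Q2: pooled per-residue accuracy."""
        from .evaluation import q2_accuracy

        truth = y if y is not None else [r.labels for r in X]
        return q2_accuracy(self.predict(X), truth)

    def log_likelihood(self, X: list[ProteinRecord], y=None) -> float:
        """Unpenalized conditional log-likelihood of labels under the fit."""
        self._check_fitted()
        records = self._prepare(_with_labels(X, y))
        return training.log_likelihood(records, self.params_, l2=0.0)

    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted")

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        self._check_fitted()
        self.params_.save(path)

    @classmethod
    def from_file(cls, path) -> "HighOrderCRF":
        params = ModelParameters.load(path)
        est = cls()
        est.params_ = params
        est.scaler_ = (
            _ColumnScaler.from_dict(params.normalization)
            if params.normalization
            else None
        )
        est.classes_ = np.array([0, 1])
        return est


class ChainCRF(HighOrderCRF):
    """First-order chain CRF baseline: every segment uses the coil potential.

    Same engine, with the order-2/3/4 weight blocks frozen at zero (they
    are simply never instantiated)."""

    _segment_orders = CHAIN_ORDERS


class BurialLogistic(BaseEstimator, ClassifierMixin):
    """Per-residue logistic regression on singlet features (no label coupling)."""

    def __init__(self, C: float = 1.0, max_iter: int = 1000, random_state: int = 0):
        self.C = C
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X: list[ProteinRecord], y=None) -> "BurialLogistic":
        records = _with_labels(X, y)
        mat = np.vstack([r.singlet_features for r in records])
        lab = np.concatenate([r.labels for r in records])
        if len(np.unique(lab)) < 2:
            raise ValueError("training labels are single-class")
        self.clf_ = LogisticRegression(
            C=self.C, max_iter=self.max_iter, random_state=self.random_state
        ).fit(mat, lab)
        self.classes_ = self.clf_.classes_
        return self

    def predict_marginals(self, X: list[ProteinRecord]) -> list[np.ndarray]:
        out = []
        for r in X:
            proba = self.clf_.predict_proba(r.singlet_features)
            cols = np.zeros((r.length, 2))
            for j, c in enumerate(self.clf_.classes_):
                cols[:, int(c)] = proba[:, j]
            out.append(cols)
        return out

    def predict(self, X: list[ProteinRecord]) -> list[np.ndarray]:
        from .inference import decode

        return [decode(m) for m in self.predict_marginals(X)]

    def score(self, X: list[ProteinRecord], y=None) -> float:
        from .evaluation import q2_accuracy

        truth = y if y is not None else [r.labels for r in X]
        return q2_accuracy(self.predict(X), truth)
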