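"""Maximum-likelihood training by gradient ascent with exact expectations.

The objective is the conditional log-likelihood of the training labels,

    L(Λ) = Σ_m [ score_Λ(Y^m | X^m) − log Z(X^m) ] − (ℓ2/2) ||Λ||²,

whose gradient per weight is the empirical feature count minus the
model-expected count (from forward–backward tuple marginals) minus the
ridge term.  The objective is concave, so plain full-batch ascent with a
backtracking line search converges from the all-zero start; no random
initialisation is involved and training is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

from .inference import SegmentTrellis
from .model import ModelDims, ModelParameters, pair_index, sequence_log_score
from .records import ProteinRecord

__all__ = [
    "TrainingConfig",
    "TrainingTrace",
    "log_likelihood",
    "gradient",
    "fit",
    "kfold_split",
]


@dataclass
class TrainingConfig:
    """Hyperparameters of the gradient-ascent fit.

    ``learning_rate`` is the initial step of the backtracking line search;
    ``l2`` the ridge strength; ``tol`` the stopping threshold on the
    relative change of the penalized objective.  ``batch_size`` 0 means
    full batch (the default and the only mode the convergence guarantees
    cover).
    """

    learning_rate: float = 1.0
    l2: float = 1.0
    max_iter: int = 200
    tol: float = 1e-6
    seed: int = 0
    batch_size: int = 0
    optimizer: str = "gd"  # "gd" (default) or "lbfgs" (quasi-Newton mode)

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.max_iter <= 0 or self.tol <= 0:
            raise ValueError("learning_rate, max_iter and tol must be positive")
        if self.l2 < 0 or self.batch_size < 0:
            raise ValueError("l2 and batch_size must be non-negative")
        if self.optimizer not in ("gd", "lbfgs"):
            raise ValueError("optimizer must be 'gd' or 'lbfgs'")


@dataclass
class TrainingTrace:
    objective: list[float] = field(default_factory=list)
    grad_norm: list[float] = field(default_factory=list)
    step_size: list[float] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "iteration": np.arange(1, len(self.objective) + 1),
                "objective": self.objective,
                "grad_norm": self.grad_norm,
                "step_size": self.step_size,
            }
        ).to_csv(path, sep="\t", index=False)


def _check_labeled(records: list[ProteinRecord]) -> None:
    for r in records:
        if r.labels is None:
            raise ValueError(f"record {r.id!r} has no labels")


def log_likelihood(
    records: list[ProteinRecord], params: ModelParameters, l2: float = 0.0
) -> float:
    """Penalized conditional log-likelihood Σ log p(Y|X) − (l2/2)||Λ||²."""
    _check_labeled(records)
    total = 0.0
    for r in records:
        log_z = sum(
            SegmentTrellis(params, r, seg, need_backward=False).log_z
            for seg in r.segmentation
        )
        total += sequence_log_score(params, r, r.labels) - log_z
    if l2 > 0:
        v = params.to_vector()
        total -= 0.5 * l2 * float(v @ v)
    return total


def empirical_counts(
    record: ProteinRecord, params: ModelParameters
) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Observed feature counts of the record's labels, per weight block."""
    y = record.labels
    C_theta = np.zeros_like(params.theta)
    C_w = {d: np.zeros_like(W) for d, W in params.doublet.items()}
    X = record.singlet_features
    for seg in record.segmentation:
        orders = params.segment_orders[seg.ss_type]
        for i in range(seg.start, seg.end + 1):
            C_theta[y[i]] += X[i]
            off = i - seg.start
            for d in orders:
                if off >= d:
                    C_w[d][pair_index(y[i - d], y[i])] += record.doublet_matrix(d)[i]
    return C_theta, C_w


def gradient(
    records: list[ProteinRecord], params: ModelParameters, l2: float = 0.0
) -> np.ndarray:
    """∇L as a flat vector conforming to ``params.to_vector()``.

    Per weight: empirical count − expected count − l2 · weight.
    """
    _check_labeled(records)
    G_theta = np.zeros_like(params.theta)
    G_w = {d: np.zeros_like(W) for d, W in params.doublet.items()}
    for r in records:
        C_theta, C_w = empirical_counts(r, params)
        G_theta += C_theta
        for d in C_w:
            G_w[d] += C_w[d]
        for seg in r.segmentation:
            t = SegmentTrellis(params, r, seg)
            sl = slice(seg.start, seg.end + 1)
            U = {d: r.doublet_matrix(d)[sl] for d in t.orders}
            E_theta, E_w = t.expected_counts(r.singlet_features[sl], U)
            G_theta -= E_theta
            for d in E_w:
                G_w[d] -= E_w[d]
    grad = ModelParameters(
        theta=G_theta, doublet=G_w, segment_orders=dict(params.segment_orders)
    ).to_vector()
    if l2 > 0:
        grad -= l2 * params.to_vector()
    return grad


class _Objective:
    """Penalized likelihood and gradient with cached empirical counts.

    The empirical feature counts do not depend on Λ, so they are computed
    once; every evaluation then needs only the forward (for the value) or
    forward–backward (for the gradient) passes.
    """

    def __init__(self, records, template: ModelParameters, l2: float):
        self.records = records
        self.template = template
        self.l2 = l2
        total_theta = np.zeros_like(template.theta)
        total_w = {d: np.zeros_like(W) for d, W in template.doublet.items()}
        for r in records:
            C_theta, C_w = empirical_counts(r, template)
            total_theta += C_theta
            for d in C_w:
                total_w[d] += C_w[d]
        self.counts_vec = ModelParameters(
            theta=total_theta, doublet=total_w,
            segment_orders=dict(template.segment_orders),
        ).to_vector()

    def value(self, v: np.ndarray, subset=None) -> float:
        params = self.template.with_vector(v)
        records = self.records if subset is None else subset
        log_z = sum(
            SegmentTrellis(params, r, seg, need_backward=False).log_z
            for r in records
            for seg in r.segmentation
        )
        return float(self.counts_vec @ v) - log_z - 0.5 * self.l2 * float(v @ v)

    def value_and_grad(self, v: np.ndarray) -> tuple[float, np.ndarray]:
        params = self.template.with_vector(v)
        G_theta = np.zeros_like(params.theta)
        G_w = {d: np.zeros_like(W) for d, W in params.doublet.items()}
        log_z = 0.0
        for r in self.records:
            for seg in r.segmentation:
                t = SegmentTrellis(params, r, seg)
                log_z += t.log_z
                sl = slice(seg.start, seg.end + 1)
                U = {d: r.doublet_matrix(d)[sl] for d in t.orders}
                E_theta, E_w = t.expected_counts(r.singlet_features[sl], U)
                G_theta += E_theta
                for d in E_w:
                    G_w[d] += E_w[d]
        expected = ModelParameters(
            theta=G_theta, doublet=G_w,
            segment_orders=dict(params.segment_orders),
        ).to_vector()
        obj = float(self.counts_vec @ v) - log_z - 0.5 * self.l2 * float(v @ v)
        grad = self.counts_vec - expected - self.l2 * v
        return obj, grad


def fit(
    records: list[ProteinRecord],
    config: TrainingConfig | None = None,
    dims: ModelDims | None = None,
    segment_orders: dict[str, tuple[int, ...]] | None = None,
    init: ModelParameters | None = None,
) -> tuple[ModelParameters, TrainingTrace]:
    """Maximize the penalized likelihood.

    The default optimizer is full-batch gradient ascent with a
    backtracking (Armijo) line search; ``optimizer="lbfgs"`` switches to
    scipy's L-BFGS-B as a quasi-Newton mode.  Both are deterministic:
    zero initialisation, no randomness (mini-batching, if requested,
    draws from a seeded generator).  Under the default rule the penalized
    objective is non-decreasing across iterations; the fit stops when its
    relative change drops below ``config.tol`` or after
    ``config.max_iter`` iterations.  A non-finite objective aborts with
    the trace attached to the exception.
    """
    if not records:
        raise ValueError("empty training set")
    _check_labeled(records)
    cfg = config or TrainingConfig()
    if init is not None:
        params = init
    else:
        from .model import SEGMENT_ORDERS

        so = dict(segment_orders or SEGMENT_ORDERS)
        dims = dims or ModelDims.for_records(records, so)
        params = ModelParameters.zeros(dims, so)

    objective = _Objective(records, params, cfg.l2)
    trace = TrainingTrace()

    if cfg.optimizer == "lbfgs":
        from scipy.optimize import minimize

        def neg(v):
            obj, grad = objective.value_and_grad(v)
            return -obj, -grad

        def cb(v):
            obj = objective.value(v)
            trace.objective.append(obj)
            trace.grad_norm.append(np.nan)
            trace.step_size.append(np.nan)

        res = minimize(
            neg,
            params.to_vector(),
            jac=True,
            method="L-BFGS-B",
            callback=cb,
            options={"maxiter": cfg.max_iter, "ftol": cfg.tol, "gtol": 1e-9},
        )
        if not np.isfinite(res.fun):
            raise FloatingPointError(f"training diverged; trace={trace.objective[-5:]}")
        return params.with_vector(res.x), trace

    rng = np.random.default_rng(cfg.seed)
    v = params.to_vector()
    obj = objective.value(v)
    step = cfg.learning_rate
    for _ in range(cfg.max_iter):
        if cfg.batch_size and cfg.batch_size < len(records):
            batch = [records[j] for j in rng.choice(len(records), cfg.batch_size, replace=False)]
            g = gradient(batch, params.with_vector(v), cfg.l2)
        else:
            _, g = objective.value_and_grad(v)
        gnorm = float(np.linalg.norm(g))
        # backtracking line search on the full objective (Armijo, c1 = 1e-4)
        accepted = False
        for _ in range(40):
            cand_v = v + step * g
            cand_obj = objective.value(cand_v)
            if np.isfinite(cand_obj) and (
                cand_obj >= obj + 1e-4 * step * gnorm**2 or cand_obj >= obj
            ):
                accepted = True
                break
            step *= 0.5
        if not accepted:
            trace.objective.append(obj)
            trace.grad_norm.append(gnorm)
            trace.step_size.append(step)
            break
        rel_change = abs(cand_obj - obj) / max(1.0, abs(obj))
        v, obj = cand_v, cand_obj
        trace.objective.append(obj)
        trace.grad_norm.append(gnorm)
        trace.step_size.append(step)
        step = min(step * 1.5, 64.0 * cfg.learning_rate)
        if rel_change < cfg.tol:
            break
    if not np.isfinite(obj):
        raise FloatingPointError(f"training diverged; trace={trace.objective[-5:]}")
    return params.with_vector(v), trace


def kfold_split(
    records: list[ProteinRecord], k: int = 5, seed: int = 0
) -> list[tuple[list[ProteinRecord], list[ProteinRecord]]]:
    """Seedable k-fold split (default 5-fold) over whole proteins."""
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    idx = np.arange(len(records))
    for train_idx, test_idx in kf.split(idx):
        folds.append(
            ([records[i] for i in train_idx], [records[i] for i in test_idx])
        )
    return folds
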