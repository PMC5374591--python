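"""The high-order CRF model: parameters and segment-structured potentials.

The label sequence Y (buried/exposed per residue) is scored segment by
segment.  Within a segment of secondary-structure type t, position i
contributes a singlet term θᵀf⁰(Y_i, i, X) plus one doublet term per
*active order* d: a helix couples labels at separations 1, 3 and 4, a
strand at separations 1 and 2, a coil at separation 1 only.  An order d
is active at i only when the partner position i−d lies inside the same
segment, so doublet terms never span a segment boundary and the model
factorises over segments; every position contributes its singlet term
exactly once regardless of segment length.

Doublet weights are indexed by the ordered label pair (Y_{i−d}, Y_i)
(4 combinations) and multiply an observation vector u_d(i): a bias for
order 1, [bias, MI, cosine, contact-map] for orders 2–4.

The full weight vector is Λ = (θ, λ, μ, γ, τ) for the singlet and
order-1/2/3/4 doublet terms respectively.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .records import ProteinRecord

#: active doublet orders per segment type (helix has no separation-2 term)
SEGMENT_ORDERS: dict[str, tuple[int, ...]] = {"H": (1, 3, 4), "E": (1, 2), "C": (1,)}

#: chain-CRF restriction: every segment treated with the coil potential
CHAIN_ORDERS: dict[str, tuple[int, ...]] = {"H": (1,), "E": (1,), "C": (1,)}

ORDER_NAMES = {1: "lambda", 2: "mu", 3: "gamma", 4: "tau"}


def pair_index(y_prev: int, y: int) -> int:
    """Index of the ordered label pair (Y_{i-d}, Y_i) in 0..3."""
    return 2 * int(y_prev) + int(y)


@dataclass
class ModelDims:
    """Shapes of the weight blocks: singlet width and per-order doublet widths."""

    n_singlet: int
    doublet: dict[int, int]  # order -> observation width (0 = order unused)

    @classmethod
    def for_records(
        cls, records: list[ProteinRecord], segment_orders: dict[str, tuple[int, ...]]
    ) -> "ModelDims":
        if not records:
            raise ValueError("no records")
        D = records[0].singlet_features.shape[1]
        orders = sorted({d for ds in segment_orders.values() for d in ds})
        doublet = {}
        for d in orders:
            ks = {r.doublet_dim(d) for r in records}
            if len(ks) != 1:
                raise ValueError(f"inconsistent doublet widths for order {d}: {ks}")
            doublet[d] = ks.pop()
        for r in records:
            if r.singlet_features.shape[1] != D:
                raise ValueError("inconsistent singlet widths across records")
        return cls(n_singlet=D, doublet=doublet)

    @property
    def orders(self) -> tuple[int, ...]:
        return tuple(sorted(self.doublet))

    @property
    def n_params(self) -> int:
        return 2 * self.n_singlet + sum(4 * k for k in self.doublet.values())


@dataclass
class ModelParameters:
    """The weight vector Λ = (θ, λ, μ, γ, τ) plus bookkeeping.

    ``theta`` has shape (2, D): row y holds the weights conjoining each
    singlet column with label y.  ``doublet[d]`` has shape (4, K_d): row
    ``pair_index(y_prev, y)`` holds the weights of the order-d observation
    vector.  ``normalization`` optionally stores per-column (mean, std)
    used to z-score real-valued singlet columns at fit time.
    """

    theta: np.ndarray
    doublet: dict[int, np.ndarray]
    segment_orders: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(SEGMENT_ORDERS)
    )
    registry: list | None = None
    normalization: dict | None = None

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.ndim != 2 or self.theta.shape[0] != 2:
            raise ValueError("theta must be (2, D)")
        for d, W in self.doublet.items():
            W = np.asarray(W, dtype=float)
            if W.shape[0] != 4:
                raise ValueError(f"doublet weights for order {d} must be (4, K)")
            self.doublet[d] = W
        if not np.isfinite(self.theta).all() or not all(
            np.isfinite(W).all() for W in self.doublet.values()
        ):
            raise ValueError("non-finite weights")

    # -- construction -------------------------------------------------------

    @classmethod
    def zeros(
        cls,
        dims: ModelDims,
        segment_orders: dict[str, tuple[int, ...]] | None = None,
    ) -> "ModelParameters":
        return cls(
            theta=np.zeros((2, dims.n_singlet)),
            doublet={d: np.zeros((4, k)) for d, k in dims.doublet.items()},
            segment_orders=dict(segment_orders or SEGMENT_ORDERS),
        )

    @property
    def dims(self) -> ModelDims:
        return ModelDims(
            n_singlet=self.theta.shape[1],
            doublet={d: W.shape[1] for d, W in self.doublet.items()},
        )

    # -- flat vector view (optimizer interface) -----------------------------

    def to_vector(self) -> np.ndarray:
        parts = [self.theta.ravel()]
        for d in sorted(self.doublet):
            parts.append(self.doublet[d].ravel())
        return np.concatenate(parts)

    def with_vector(self, vec: np.ndarray) -> "ModelParameters":
        vec = np.asarray(vec, dtype=float)
        out_theta = vec[: self.theta.size].reshape(self.theta.shape)
        off = self.theta.size
        out_doublet = {}
        for d in sorted(self.doublet):
            W = self.doublet[d]
            out_doublet[d] = vec[off: off + W.size].reshape(W.shape)
            off += W.size
        if off != vec.size:
            raise ValueError("vector length does not match parameter dims")
        return ModelParameters(
            theta=out_theta,
            doublet=out_doublet,
            segment_orders=dict(self.segment_orders),
            registry=self.registry,
            normalization=self.normalization,
        )

    # -- serialization (bit-exact JSON round trip) --------------------------

    def save(self, path: str | Path) -> None:
        payload = {
            "format": "burialcrf-model",
            "version": 1,
            "segment_orders": {t: list(ds) for t, ds in self.segment_orders.items()},
            "theta": self.theta.tolist(),
            "doublet": {str(d): W.tolist() for d, W in self.doublet.items()},
            "registry": self.registry,
            "normalization": self.normalization,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ModelParameters":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "burialcrf-model":
            raise ValueError(f"{path}: not a burialcrf model file")
        return cls(
            theta=np.asarray(payload["theta"]),
            doublet={int(d): np.asarray(W) for d, W in payload["doublet"].items()},
            segment_orders={
                t: tuple(ds) for t, ds in payload["segment_orders"].items()
            },
            registry=payload.get("registry"),
            normalization=payload.get("normalization"),
        )


# ---------------------------------------------------------------------------
# potentials
# ---------------------------------------------------------------------------

def singlet_term(params: ModelParameters, record: ProteinRecord, y: int, i: int) -> float:
    """θᵀ f⁰(y, i, X)."""
    return float(params.theta[y] @ record.singlet_features[i])


def doublet_term(
    params: ModelParameters, record: ProteinRecord, d: int, y_prev: int, y: int, i: int
) -> float:
    """Weight of the order-d pair (Y_{i-d}=y_prev, Y_i=y) times u_d(i)."""
    return float(params.doublet[d][pair_index(y_prev, y)] @ record.doublet_matrix(d)[i])


def phi_C(params, record, y_prev: int, y: int, i: int) -> float:
    """Coil log-potential: θᵀf⁰(Y_i) + λᵀf¹(Y_{i-1}, Y_i)."""
    return singlet_term(params, record, y, i) + doublet_term(params, record, 1, y_prev, y, i)


def phi_E(params, record, y_2: int, y_1: int, y: int, i: int) -> float:
    """Strand log-potential: θᵀf⁰ + λᵀf¹(Y_{i-1}, Y_i) + μᵀf²(Y_{i-2}, Y_i)."""
    return (
        singlet_term(params, record, y, i)
        + doublet_term(params, record, 1, y_1, y, i)
        + doublet_term(params, record, 2, y_2, y, i)
    )


def phi_H(params, record, y_4: int, y_3: int, y_2: int, y_1: int, y: int, i: int) -> float:
    """Helix log-potential: θᵀf⁰ + λᵀf¹(Y_{i-1}, Y_i) + γᵀf³(Y_{i-3}, Y_i)
    + τᵀf⁴(Y_{i-4}, Y_i).  There is no separation-2 term on helices."""
    return (
        singlet_term(params, record, y, i)
        + doublet_term(params, record, 1, y_1, y, i)
        + doublet_term(params, record, 3, y_3, y, i)
        + doublet_term(params, record, 4, y_4, y, i)
    )


def sequence_log_score(params: ModelParameters, record: ProteinRecord, y) -> float:
    """Unnormalized log-score of a full labeling.

    log p(Y|X) = sequence_log_score(Y) − log Z(X).  Deliberately written as
    a direct per-position sum (no dynamic programming) so it can serve as
    the independent scoring path for the enumeration oracle.
    """
    y = np.asarray(y, dtype=int)
    if y.shape[0] != record.length:
        raise ValueError("label / sequence length mismatch")
    total = 0.0
    for seg in record.segmentation:
        orders = params.segment_orders[seg.ss_type]
        for i in range(seg.start, seg.end + 1):
            total += singlet_term(params, record, int(y[i]), i)
            off = i - seg.start
            for d in orders:
                if off >= d:
                    total += doublet_term(params, record, d, int(y[i - d]), int(y[i]), i)
    return total


def active_orders_at(
    params: ModelParameters, record: ProteinRecord, i: int
) -> tuple[int, ...]:
    """Doublet orders contributing at position i (segment type and offset gated)."""
    for seg in record.segmentation:
        if seg.start <= i <= seg.end:
            off = i - seg.start
            return tuple(d for d in params.segment_orders[seg.ss_type] if off >= d)
    raise IndexError(i)
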