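"""Exact inference by dynamic programming over variable-order trellises.

Because doublet terms never span a segment boundary, the CRF factorises
over secondary-structure segments, and inference runs independently per
segment.  Within a segment of maximal order k (4 in helices, 2 in strands,
1 in coils) the DP state at position p is the tuple of the last
min(p+1, k) labels, encoded as an integer whose bit j holds the label of
position p−j.  Each position therefore carries at most 2^k ≤ 16 states
and each transition at most 2^(k+1) ≤ 32 label tuples.

All computation is in natural-log space with log-sum-exp; the partition
function from the forward pass must agree with the backward pass to
1e-9.  A brute-force enumeration oracle over all 2^L labelings defines
the normative semantics and cross-checks the DP in the test suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .model import ModelParameters, sequence_log_score
from .records import BURIED, EXPOSED, ProteinRecord, Segment


def _lse(a: np.ndarray) -> float:
    """log-sum-exp of a small 1-D array (scipy-free hot path)."""
    m = a.max()
    if not np.isfinite(m):
        return float(m)
    return float(m + np.log(np.exp(a - m).sum()))

__all__ = [
    "SegmentTrellis",
    "InferenceResult",
    "forward_backward",
    "position_marginals",
    "predict_record",
    "decode",
    "brute_force_reference",
]


_CACHE: dict = {}


def _newstate_map(n_old: int, width_new: int) -> np.ndarray:
    """(n_old, 2) integer map: state after appending label y to state o."""
    key = ("newmap", n_old, width_new)
    if key not in _CACHE:
        o = np.arange(n_old)[:, None]
        y = np.arange(2)[None, :]
        _CACHE[key] = ((o << 1) | y) & ((1 << width_new) - 1)
    return _CACHE[key]


def _pair_idx(d: int, n_old: int) -> np.ndarray:
    """(n_old, 2) index 2*Y_{p-d} + Y_p given old state and appended label."""
    key = ("pair", d, n_old)
    if key not in _CACHE:
        o = np.arange(n_old)[:, None]
        y = np.arange(2)[None, :]
        _CACHE[key] = 2 * ((o >> (d - 1)) & 1) + y
    return _CACHE[key]


def _merge_idx(k: int):
    """Predecessor pairs of each full-width state: (o0, o1, y) arrays."""
    key = ("merge", k)
    if key not in _CACHE:
        n = np.arange(1 << k)
        o0, y = n >> 1, n & 1
        o1 = o0 | (1 << (k - 1))
        _CACHE[key] = (o0, o1, y)
    return _CACHE[key]


def _pair_onehot(d: int, n_old: int) -> np.ndarray:
    """(2*n_old, 4) one-hot of _pair_idx over C-order flattened (o, y)."""
    key = ("onehot", d, n_old)
    if key not in _CACHE:
        idx = _pair_idx(d, n_old).ravel()
        M = np.zeros((2 * n_old, 4))
        M[np.arange(2 * n_old), idx] = 1.0
        _CACHE[key] = M
    return _CACHE[key]


class SegmentTrellis:
    """Forward–backward machinery for one secondary-structure segment."""

    def __init__(
        self,
        params: ModelParameters,
        record: ProteinRecord,
        segment: Segment,
        need_backward: bool = True,
    ) -> None:
        self.segment = segment
        self.orders = params.segment_orders[segment.ss_type]
        self.k = max(self.orders)
        self.m = len(segment)
        sl = slice(segment.start, segment.end + 1)
        # singlet log-potentials S[p, y] and per-order pair weights pw[d][p, pair]
        self.S = record.singlet_features[sl] @ params.theta.T  # (m, 2)
        self.pw = {
            d: record.doublet_matrix(d)[sl] @ params.doublet[d].T  # (m, 4)
            for d in self.orders
        }
        self._widths = [min(p + 1, self.k) for p in range(self.m)]
        self._build_transitions()
        self._forward()
        if need_backward:
            self._backward()
        else:
            self.log_z_backward = self.log_z

    # -- construction -------------------------------------------------------

    def _trans_at(self, p: int) -> np.ndarray:
        """(n_old, 2) log transition weights into position p (p >= 1)."""
        n_old = 1 << self._widths[p - 1]
        T = np.broadcast_to(self.S[p], (n_old, 2)).copy()
        for d in self.orders:
            if d <= p:
                T += self.pw[d][p, _pair_idx(d, n_old)]
        return T

    def _build_transitions(self) -> None:
        m, k = self.m, self.k
        self.trans: list[np.ndarray | None] = [None] * m
        head = min(k, m)
        for p in range(1, head):
            self.trans[p] = self._trans_at(p)
        if m > k:
            # constant-width tail, built in one vectorised block
            n_old = 1 << k
            T = np.repeat(self.S[k:, None, :], n_old, axis=1)  # (m-k, n_old, 2)
            for d in self.orders:
                T += self.pw[d][k:][:, _pair_idx(d, n_old)]
            for j, p in enumerate(range(k, m)):
                self.trans[p] = T[j]
        self.newmaps: list[np.ndarray | None] = [None] * m
        for p in range(1, m):
            self.newmaps[p] = _newstate_map(1 << self._widths[p - 1], self._widths[p])

    # -- passes --------------------------------------------------------------

    def _forward(self) -> None:
        self.alpha: list[np.ndarray] = [self.S[0].copy()]
        for p in range(1, self.m):
            flat = self.alpha[p - 1][:, None] + self.trans[p]
            if self._widths[p] == self._widths[p - 1] + 1:
                self.alpha.append(flat.ravel())
            else:  # full width: two predecessors per new state
                o0, o1, y = _merge_idx(self.k)
                self.alpha.append(np.logaddexp(flat[o0, y], flat[o1, y]))
        self.log_z = _lse(self.alpha[-1])

    def _backward(self) -> None:
        self.beta: list[np.ndarray] = [None] * self.m  # type: ignore[list-item]
        self.beta[self.m - 1] = np.zeros(1 << self._widths[self.m - 1])
        for p in range(self.m - 1, 0, -1):
            tmp = self.trans[p] + self.beta[p][self.newmaps[p]]
            self.beta[p - 1] = np.logaddexp(tmp[:, 0], tmp[:, 1])
        self.log_z_backward = _lse(self.S[0] + self.beta[0])

    # -- queries -------------------------------------------------------------

    def marginals(self) -> np.ndarray:
        """(m, 2) matrix: column y holds p(Y_p = y | X)."""
        out = np.empty((self.m, 2))
        for p in range(self.m):
            g = np.exp(self.alpha[p] + self.beta[p] - self.log_z)
            bit0 = np.arange(g.size) & 1
            out[p, 0] = g[bit0 == 0].sum()
            out[p, 1] = g[bit0 == 1].sum()
        return out

    def transition_joints(self, p: int) -> np.ndarray:
        """(n_old, 2) joint p(state_{p-1}=o, Y_p=y | X) for p >= 1."""
        J = (
            self.alpha[p - 1][:, None]
            + self.trans[p]
            + self.beta[p][self.newmaps[p]]
            - self.log_z
        )
        return np.exp(J)

    def expected_counts(self, X_seg: np.ndarray, U: dict[int, np.ndarray]):
        """Model-expected singlet and pair feature counts for this segment.

        Returns ``(E_theta, E_w)`` with ``E_theta`` of shape (2, D) and
        ``E_w[d]`` of shape (4, K_d), matching the weight block layouts.
        """
        m, k = self.m, self.k
        Ey = np.empty((m, 2))
        Ey[0] = np.exp(self.S[0] + self.beta[0] - self.log_z)
        pair_q = {d: np.zeros((m, 4)) for d in self.orders}
        head = min(k, m)
        for p in range(1, head):
            P = self.transition_joints(p)
            Ey[p] = P.sum(axis=0)
            for d in self.orders:
                if d <= p:
                    np.add.at(pair_q[d][p], _pair_idx(d, P.shape[0]).ravel(), P.ravel())
        if m > k:
            A = np.stack(self.alpha[k - 1: m - 1])           # (m-k, n_old)
            B = np.stack(self.beta[k:m])                      # (m-k, n_state)
            T = np.stack(self.trans[k:m])                     # (m-k, n_old, 2)
            newmap = self.newmaps[k]
            P = np.exp(A[:, :, None] + T + B[:, newmap] - self.log_z)
            Ey[k:] = P.sum(axis=1)
            n_old = 1 << k
            flatP = P.reshape(m - k, -1)
            for d in self.orders:
                pair_q[d][k:] = flatP @ _pair_onehot(d, n_old)
        E_theta = Ey.T @ X_seg
        E_w = {}
        for d in self.orders:
            rows = slice(d, m)
            E_w[d] = pair_q[d][rows].T @ U[d][rows]
        return E_theta, E_w

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Exact samples from p(Y_seg | X) by forward-filtering backward-sampling."""
        m, k = self.m, self.k
        labels = np.empty((size, m), dtype=np.int8)
        probs = np.exp(self.alpha[m - 1] - _lse(self.alpha[m - 1]))
        states = rng.choice(probs.size, size=size, p=probs)
        labels[:, m - 1] = states & 1
        for p in range(m - 1, 0, -1):
            if self._widths[p] == self._widths[p - 1] + 1:
                states = states >> 1
            else:
                o0 = states >> 1
                o1 = o0 | (1 << (k - 1))
                y = states & 1
                w0 = self.alpha[p - 1][o0] + self.trans[p][o0, y]
                w1 = self.alpha[p - 1][o1] + self.trans[p][o1, y]
                take1 = rng.random(size) < 1.0 / (1.0 + np.exp(w0 - w1))
                states = np.where(take1, o1, o0)
            labels[:, p - 1] = states & 1
        return labels

    def state_count(self) -> int:
        """Total number of trellis states (complexity audit)."""
        return sum(1 << w for w in self._widths)


# ---------------------------------------------------------------------------
# whole-protein inference
# ---------------------------------------------------------------------------

@dataclass
class InferenceResult:
    """Partition function, per-position marginals and decoded labels."""

    log_z: float
    marginals: np.ndarray  # (L, 2); column y = p(Y_i = y | X)
    decoded: np.ndarray

    def p_buried(self) -> np.ndarray:
        return self.marginals[:, BURIED]


def forward_backward(
    record: ProteinRecord, params: ModelParameters
) -> tuple[list[SegmentTrellis], float]:
    """Run the segment DPs; returns per-segment trellises and total log Z."""
    trellises = [SegmentTrellis(params, record, seg) for seg in record.segmentation]
    log_z = 0.0
    for t in trellises:
        if abs(t.log_z - t.log_z_backward) > 1e-9 * max(1.0, abs(t.log_z)):
            raise FloatingPointError(
                f"forward/backward log Z mismatch in segment {t.segment}"
            )
        log_z += t.log_z
    return trellises, log_z


def position_marginals(trellises: list[SegmentTrellis]) -> np.ndarray:
    return np.vstack([t.marginals() for t in trellises])


def decode(marginals: np.ndarray) -> np.ndarray:
    """Per-position argmax of the marginals; exact ties go to buried."""
    marginals = np.asarray(marginals, dtype=float)
    return np.where(marginals[:, BURIED] >= marginals[:, EXPOSED], BURIED, EXPOSED).astype(
        np.int8
    )


def predict_record(record: ProteinRecord, params: ModelParameters) -> InferenceResult:
    trellises, log_z = forward_backward(record, params)
    marg = position_marginals(trellises)
    return InferenceResult(log_z=log_z, marginals=marg, decoded=decode(marg))


def sample_labels_given_features(
    record: ProteinRecord,
    params: ModelParameters,
    rng: np.random.Generator,
    size: int = 1,
) -> np.ndarray:
    """Exact samples Y ~ p(Y | X; Λ), shape (size, L)."""
    trellises, _ = forward_backward(record, params)
    return np.hstack([t.sample(rng, size) for t in trellises])


def brute_force_reference(
    record: ProteinRecord, params: ModelParameters, max_length: int = 20
) -> InferenceResult:
    """Exact inference by enumeration over all 2^L labelings (test oracle).

    Scores every labeling with :func:`sequence_log_score` — a code path
    deliberately independent of the trellis machinery.
    """
    L = record.length
    if L > max_length:
        raise ValueError(f"enumeration limited to L <= {max_length}, got {L}")
    labelings = np.array(list(itertools.product((0, 1), repeat=L)), dtype=np.int8)
    scores = np.array(
        [sequence_log_score(params, record, y) for y in labelings]
    )
    log_z = _lse(scores)
    probs = np.exp(scores - log_z)
    marg = np.empty((L, 2))
    for i in range(L):
        marg[i, 0] = probs[labelings[:, i] == 0].sum()
        marg[i, 1] = probs[labelings[:, i] == 1].sum()
    return InferenceResult(log_z=log_z, marginals=marg, decoded=decode(marg))
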