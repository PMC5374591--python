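"""Core data model: protein records, secondary-structure segmentations, burial labels.

Conventions used throughout the package:

* labels are binary, **buried = 1**, **exposed = 0** (the hydrophobic core is
  the positive class);
* secondary structure is three-state, ``H`` (helix), ``E`` (strand),
  ``C`` (coil);
* file formats and user-facing reports are 1-based inclusive, internal
  arrays are 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

SS_TYPES = ("H", "E", "C")

#: label values
BURIED, EXPOSED = 1, 0

#: the 20 standard amino-acid one-letter codes, alphabetical
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: mapping from 8-state DSSP codes to 3 states
_DSSP8_TO_3 = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
    "T": "C", "S": "C", " ": "C", "-": "C", "C": "C",
}


@dataclass(frozen=True)
class Segment:
    """One secondary-structure segment: type and 0-based inclusive span."""

    ss_type: str
    start: int  # 0-based
    end: int    # 0-based inclusive

    def __post_init__(self) -> None:
        if self.ss_type not in SS_TYPES:
            raise ValueError(f"unknown SS type {self.ss_type!r}")
        if not 0 <= self.start <= self.end:
            raise ValueError(f"bad segment span [{self.start}, {self.end}]")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SSSegmentation:
    """Ordered, gap-free, non-overlapping cover of positions 0..L-1."""

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("empty segmentation")
        if self.segments[0].start != 0:
            raise ValueError("segmentation must start at position 0")
        for a, b in zip(self.segments, self.segments[1:]):
            if b.start != a.end + 1:
                raise ValueError("segments must tile the chain without gaps")

    @property
    def length(self) -> int:
        return self.segments[-1].end + 1

    def to_string(self) -> str:
        return "".join(s.ss_type * len(s) for s in self.segments)

    def ss_type_at(self, i: int) -> str:
        for s in self.segments:
            if s.start <= i <= s.end:
                return s.ss_type
        raise IndexError(i)

    def __iter__(self):
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)


def ss_string_to_segments(ss: str) -> SSSegmentation:
    """Convert a 3-state SS string into maximal same-type segments.

    Re-expanding the result with :meth:`SSSegmentation.to_string` reproduces
    the input exactly.
    """
    if not ss:
        raise ValueError("empty SS string")
    bad = set(ss) - set(SS_TYPES)
    if bad:
        raise ValueError(f"illegal SS characters {sorted(bad)}; expected H/E/C")
    segments = []
    start = 0
    for i in range(1, len(ss) + 1):
        if i == len(ss) or ss[i] != ss[start]:
            segments.append(Segment(ss[start], start, i - 1))
            start = i
    return SSSegmentation(tuple(segments))


def map_8to3(dssp8: str) -> str:
    """Collapse 8-state DSSP codes to 3 states: H,G,I→H; E,B→E; rest→C."""
    out = []
    for c in dssp8:
        if c not in _DSSP8_TO_3:
            warnings.warn(f"unknown DSSP code {c!r}, mapping to C", stacklevel=2)
            out.append("C")
        else:
            out.append(_DSSP8_TO_3[c])
    return "".join(out)


def as_labels(y, length: int | None = None) -> np.ndarray:
    """Validate and coerce a burial-label sequence to an int8 0/1 array."""
    arr = np.asarray(y, dtype=np.int8)
    if arr.ndim != 1:
        raise ValueError("labels must be one-dimensional")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("labels must be 0 (exposed) or 1 (buried)")
    if length is not None and arr.shape[0] != length:
        raise ValueError(f"expected {length} labels, got {arr.shape[0]}")
    return arr


@dataclass
class ProteinRecord:
    """One protein chain: sequence, segmentation, features and optional labels.

    Parameters
    ----------
    id : str
        Chain identifier.
    sequence : str
        Amino-acid sequence over the 20 standard letters plus ``X``.
    segmentation : SSSegmentation
        Three-state segmentation covering the whole chain.
    singlet_features : ndarray of shape (L, D)
        Per-residue observation matrix (one row per residue).
    doublet_features : dict[int, ndarray], optional
        For each separation ``d`` an ``(L, K_d)`` matrix; row ``i`` holds the
        observation vector of the residue pair ``(i-d, i)`` (rows ``i < d``
        are unused).  Separation 1 defaults to a bias column; separations
        2/3/4 default to ``[bias, MI, cosine, contact-map]``.
    labels : ndarray, optional
        Burial labels, buried=1 / exposed=0.
    """

    id: str
    sequence: str
    segmentation: SSSegmentation
    singlet_features: np.ndarray
    doublet_features: dict[int, np.ndarray] = field(default_factory=dict)
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        allowed = set(AMINO_ACIDS + "X")
        if not self.sequence or set(self.sequence) - allowed:
            raise ValueError(f"invalid sequence for {self.id!r}")
        L = len(self.sequence)
        if self.segmentation.length != L:
            raise ValueError(
                f"{self.id}: segmentation covers {self.segmentation.length} "
                f"positions, sequence has {L}"
            )
        self.singlet_features = np.asarray(self.singlet_features, dtype=float)
        if self.singlet_features.ndim != 2 or self.singlet_features.shape[0] != L:
            raise ValueError(f"{self.id}: singlet feature matrix must be (L, D)")
        if not np.isfinite(self.singlet_features).all():
            raise ValueError(f"{self.id}: non-finite singlet features")
        for d, U in self.doublet_features.items():
            U = np.asarray(U, dtype=float)
            if U.ndim != 2 or U.shape[0] != L:
                raise ValueError(f"{self.id}: doublet features for d={d} must be (L, K)")
            self.doublet_features[d] = U
        if self.labels is not None:
            self.labels = as_labels(self.labels, L)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def doublet_dim(self, d: int) -> int:
        """Width of the order-``d`` observation vector (1 = bias only)."""
        if d in self.doublet_features:
            return self.doublet_features[d].shape[1]
        return 1

    def doublet_matrix(self, d: int) -> np.ndarray:
        """The (L, K_d) observation matrix for separation ``d`` (bias default)."""
        if d in self.doublet_features:
            return self.doublet_features[d]
        return np.ones((self.length, 1))

    def ss_string(self) -> str:
        return self.segmentation.to_string()
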