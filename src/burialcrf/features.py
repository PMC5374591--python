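"""Feature engine: singlet feature matrices and profile-based doublet features.

Singlet features describe one residue (residue type, terminal flags,
profile frequencies, sequence conservation, predicted secondary-structure
probabilities, contact number, plus optional precomputed columns from
external predictors).  Doublet features describe a residue *pair* at
sequence separation d ∈ {2, 3, 4}: mutual information, cosine similarity
and an optional contact-map score, all derived from profile columns.

The singlet matrix layout is owned by a :class:`FeatureRegistry` so that
column meaning is never implicit; the model layer conjoins every column
with each of the two burial labels to form weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .pssm import SequenceProfile
from .records import AMINO_ACIDS, SS_TYPES

DOUBLET_KINDS = ("bias", "mi", "cosine", "cmap")
DOUBLET_SEPARATIONS = (2, 3, 4)


# ---------------------------------------------------------------------------
# scalar / per-position features
# ---------------------------------------------------------------------------

def sequence_conservation(profile: SequenceProfile) -> np.ndarray:
    """Per-position conservation: relative entropy (bits) of the profile
    column against the background distribution, with 0·log 0 := 0."""
    p = profile.frequencies
    q = profile.background
    if (q <= 0).any():
        raise ValueError("background must be strictly positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / q), 0.0)
    return terms.sum(axis=1)


def contact_number(
    coords: np.ndarray, radius: float = 8.0, min_sep: int = 5
) -> np.ndarray:
    """Contact number: residues within ``radius`` Å (strict <) and at least
    ``min_sep`` positions away in sequence.

    ``coords`` is an (L, 3) array of Cα coordinates; rows with any NaN are
    treated as missing and contribute no contacts.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (L, 3)")
    L = coords.shape[0]
    if L < min_sep + 1:
        return np.zeros(L, dtype=int)
    ok = np.isfinite(coords).all(axis=1)
    dist = cdist(coords, coords)
    i, j = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
    mask = (np.abs(i - j) >= min_sep) & (dist < radius) & ok[:, None] & ok[None, :]
    return mask.sum(axis=1).astype(int)


def mutual_information(joint: np.ndarray) -> float:
    """MI in bits of a joint distribution over two discrete variables."""
    joint = np.asarray(joint, dtype=float)
    if (joint < 0).any():
        raise ValueError("joint must be non-negative")
    total = joint.sum()
    if total <= 0:
        return 0.0
    joint = joint / total
    pr = joint.sum(axis=1, keepdims=True)
    pc = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(joint > 0, joint * np.log2(joint / (pr * pc)), 0.0)
    return max(float(terms.sum()), 0.0)  # clamp float round-off; MI >= 0


def mutual_information_doublet(
    profile: SequenceProfile, i: int, d: int, joint: np.ndarray | None = None
) -> float:
    """MI (bits) between profile columns ``i-d`` and ``i`` (0-based ``i``).

    A single profile supplies only the two marginals; by default the joint
    is their outer product, which makes the MI exactly 0.  Passing an
    alignment-derived pair-count ``joint`` gives a real MI.
    """
    if i - d < 0 or i >= profile.length:
        raise IndexError(f"positions ({i - d}, {i}) out of range")
    if joint is None:
        joint = np.outer(profile.column(i - d), profile.column(i))
    return mutual_information(joint)


def cosine_doublet(profile: SequenceProfile, i: int, d: int) -> float:
    """Cosine similarity of profile columns ``i-d`` and ``i``; zero-norm
    columns give 0."""
    if i - d < 0 or i >= profile.length:
        raise IndexError(f"positions ({i - d}, {i}) out of range")
    a, b = profile.column(i - d), profile.column(i)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


# ---------------------------------------------------------------------------
# singlet feature assembly
# ---------------------------------------------------------------------------

@dataclass
class FeatureRegistry:
    """Ordered registry of named singlet column groups."""

    groups: list[tuple[str, int]] = field(default_factory=list)

    def add(self, name: str, width: int) -> None:
        if width <= 0:
            raise ValueError("group width must be positive")
        if any(n == name for n, _ in self.groups):
            raise ValueError(f"duplicate group {name!r}")
        self.groups.append((name, width))

    @property
    def width(self) -> int:
        return sum(w for _, w in self.groups)

    def slice_of(self, name: str) -> slice:
        off = 0
        for n, w in self.groups:
            if n == name:
                return slice(off, off + w)
            off += w
        raise KeyError(name)

    def names(self) -> list[str]:
        return [n for n, _ in self.groups]

    def to_dict(self) -> list[list]:
        return [[n, w] for n, w in self.groups]

    @classmethod
    def from_dict(cls, data) -> "FeatureRegistry":
        return cls(groups=[(str(n), int(w)) for n, w in data])


@dataclass
class FeatureConfig:
    """Which singlet groups to build and how.

    ``window`` adds copies of the profile group for flanking offsets
    ±1..±window (zero-padded at the termini).  ``extras`` maps group names
    to per-residue matrices supplied from external predictors (disorder
    probability, binding-site probability, I-site score, SS end tendency,
    contact potentials, ...) — these are consumed, never computed here.
    """

    include_bias: bool = True
    include_onehot: bool = True
    include_terminal: bool = True
    include_profile: bool = True
    include_conservation: bool = True
    include_ss_probs: bool = True
    include_contact_number: bool = False
    window: int = 0
    extras: dict[str, np.ndarray] = field(default_factory=dict)


def _one_hot_sequence(sequence: str) -> np.ndarray:
    alphabet = AMINO_ACIDS + "X"
    mat = np.zeros((len(sequence), len(alphabet)))
    for i, aa in enumerate(sequence):
        mat[i, alphabet.index(aa)] = 1.0
    return mat


def assemble_singlet_features(
    sequence: str,
    profile: SequenceProfile | None = None,
    ss_probs: np.ndarray | None = None,
    ss_string: str | None = None,
    contact_numbers: np.ndarray | None = None,
    config: FeatureConfig | None = None,
) -> tuple[np.ndarray, FeatureRegistry]:
    """Assemble the (L, D) singlet matrix and its column registry.

    A deterministic, pure function of its inputs: identical inputs yield a
    bit-identical matrix.  Missing optional groups that the config enables
    are zero-filled and flagged in the registry with a ``:missing`` suffix.
    """
    cfg = config or FeatureConfig()
    L = len(sequence)
    registry = FeatureRegistry()
    blocks: list[np.ndarray] = []

    def add(name: str, block: np.ndarray) -> None:
        block = np.asarray(block, dtype=float)
        if block.ndim == 1:
            block = block[:, None]
        if block.shape[0] != L:
            raise ValueError(f"group {name!r} has {block.shape[0]} rows, expected {L}")
        registry.add(name, block.shape[1])
        blocks.append(block)

    if cfg.include_bias:
        add("bias", np.ones(L))
    if cfg.include_onehot:
        add("residue_onehot", _one_hot_sequence(sequence))
    if cfg.include_terminal:
        term = np.zeros((L, 2))
        term[0, 0] = 1.0
        term[-1, 1] = 1.0
        add("terminal", term)
    if cfg.include_profile:
        if profile is not None:
            add("profile", profile.frequencies)
            for off in range(1, cfg.window + 1):
                for sign in (-1, +1):
                    shifted = np.zeros_like(profile.frequencies)
                    if sign < 0:
                        shifted[off:] = profile.frequencies[:-off]
                    else:
                        shifted[:-off] = profile.frequencies[off:]
                    add(f"profile@{sign * off:+d}", shifted)
        else:
            add("profile:missing", np.zeros((L, 20)))
    if cfg.include_conservation:
        if profile is not None:
            add("conservation", sequence_conservation(profile))
        else:
            add("conservation:missing", np.zeros(L))
    if cfg.include_ss_probs:
        if ss_probs is not None:
            ss_probs = np.asarray(ss_probs, dtype=float)
            if ss_probs.shape != (L, 3):
                raise ValueError("ss_probs must be (L, 3) for H/E/C")
            add("ss_probs", ss_probs)
        elif ss_string is not None:
            onehot = np.zeros((L, 3))
            for i, c in enumerate(ss_string):
                onehot[i, SS_TYPES.index(c)] = 1.0
            add("ss_probs", onehot)
        else:
            add("ss_probs:missing", np.zeros((L, 3)))
    if cfg.include_contact_number:
        if contact_numbers is not None:
            add("contact_number", np.asarray(contact_numbers, dtype=float))
        else:
            add("contact_number:missing", np.zeros(L))
    for name, block in cfg.extras.items():
        add(name, block)

    X = np.hstack(blocks) if blocks else np.zeros((L, 0))
    assert X.shape[1] == registry.width
    return X, registry


# ---------------------------------------------------------------------------
# doublet feature assembly
# ---------------------------------------------------------------------------

def build_doublet_features(
    profile: SequenceProfile,
    cmap_scores: dict[int, np.ndarray] | None = None,
    pair_joints: dict[tuple[int, int], np.ndarray] | None = None,
) -> dict[int, np.ndarray]:
    """Build the nine doublet features as per-separation (L, 4) matrices.

    Row ``i`` of matrix ``d`` holds ``[bias, MI, cosine, cmap]`` for the
    pair ``(i-d, i)``; rows ``i < d`` are zero.  Contact-map scores come
    from an optional precomputed per-separation column (zero otherwise);
    MI uses an optional supplied pair joint, else the outer-product
    default (which is exactly 0).
    """
    L = profile.length
    out: dict[int, np.ndarray] = {1: np.ones((L, 1))}
    for d in DOUBLET_SEPARATIONS:
        U = np.zeros((L, len(DOUBLET_KINDS)))
        for i in range(d, L):
            joint = None
            if pair_joints is not None:
                joint = pair_joints.get((i - d, i))
            U[i, 0] = 1.0
            U[i, 1] = mutual_information_doublet(profile, i, d, joint=joint)
            U[i, 2] = cosine_doublet(profile, i, d)
        if cmap_scores is not None and d in cmap_scores:
            col = np.asarray(cmap_scores[d], dtype=float)
            if col.shape[0] != L:
                raise ValueError("cmap score column length mismatch")
            U[d:, 3] = col[d:]
        out[d] = U
    return out


# ---------------------------------------------------------------------------
# TSV readers for externally supplied per-residue columns
# ---------------------------------------------------------------------------

def read_feature_tsv(path: str | Path, length: int | None = None) -> np.ndarray:
    """Read a headered per-residue TSV (first column: 1-based position)."""
    df = pd.read_csv(path, sep="\t")
    df = df.sort_values(df.columns[0])
    mat = df.iloc[:, 1:].to_numpy(dtype=float)
    if length is not None and mat.shape[0] != length:
        raise ValueError(f"{path}: {mat.shape[0]} rows, expected {length}")
    return mat


def read_ss_probs_tsv(path: str | Path, length: int | None = None) -> np.ndarray:
    """Read SS probabilities as a TSV with columns position, pH, pE, pC."""
    mat = read_feature_tsv(path, length)
    if mat.shape[1] != 3:
        raise ValueError(f"{path}: expected 3 probability columns (pH, pE, pC)")
    return mat
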