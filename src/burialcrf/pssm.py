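"""PSI-BLAST ASCII PSSM parsing and sequence profiles.

A profile provides two views of the same positions: integer log-odds scores
and per-position amino-acid frequencies (the percentage block divided by
100).  When no PSSM is available a one-hot pseudo-profile built from the
sequence stands in, so downstream feature code never branches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .records import AMINO_ACIDS


@dataclass
class SequenceProfile:
    """Per-position amino-acid profile over the 20 standard letters.

    ``frequencies`` rows sum to 1; ``log_odds`` may be None for pseudo
    profiles.  Column order follows the PSSM header, stored in
    ``alphabet``.
    """

    frequencies: np.ndarray             # (L, 20)
    log_odds: np.ndarray | None = None  # (L, 20), integer scores
    alphabet: str = AMINO_ACIDS
    background: np.ndarray = field(default_factory=lambda: np.full(20, 0.05))

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.frequencies.ndim != 2 or self.frequencies.shape[1] != len(self.alphabet):
            raise ValueError("profile must be (L, |alphabet|)")
        sums = self.frequencies.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("frequency rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1")

    @property
    def length(self) -> int:
        return self.frequencies.shape[0]

    def column(self, i: int) -> np.ndarray:
        return self.frequencies[i]


def read_pssm(path: str | Path, sequence: str | None = None) -> SequenceProfile:
    """Read a PSI-BLAST ``-out_ascii_pssm`` file.

    Layout: two header lines, a column-header line naming 40 amino-acid
    columns (20 log-odds then 20 percentages), then one row per position:
    index, residue letter, 20 integers, 20 percentages, information
    content, relative weight.  Rows whose percentage block sums to zero
    get a uniform frequency row.
    """
    lines = Path(path).read_text().splitlines()
    header_idx = None
    for k, line in enumerate(lines):
        toks = line.split()
        if len(toks) >= 40 and all(t in AMINO_ACIDS for t in toks[:40]):
            header_idx = k
            break
    if header_idx is None:
        raise ValueError(f"{path}: no PSSM column header found")
    alphabet = "".join(lines[header_idx].split()[:20])

    log_odds, percents, letters = [], [], []
    for line in lines[header_idx + 1:]:
        toks = line.split()
        if len(toks) < 42 or not toks[0].isdigit():
            if letters:
                break
            continue
        letters.append(toks[1])
        vals = [float(t) for t in toks[2:42]]
        log_odds.append(vals[:20])
        percents.append(vals[20:])
    if not letters:
        raise ValueError(f"{path}: no PSSM rows parsed (truncated file?)")
    if sequence is not None and len(letters) != len(sequence):
        raise ValueError(
            f"{path}: PSSM has {len(letters)} rows, sequence has {len(sequence)}"
        )

    freq = np.asarray(percents) / 100.0
    zero = freq.sum(axis=1) <= 0
    freq[zero] = 1.0 / 20.0
    freq = freq / freq.sum(axis=1, keepdims=True)
    return SequenceProfile(
        frequencies=freq,
        log_odds=np.asarray(log_odds),
        alphabet=alphabet,
    )


def one_hot_profile(sequence: str, pseudocount: float = 0.0) -> SequenceProfile:
    """One-hot pseudo-profile for sequences without a PSSM.

    'X' residues get a uniform row.  A small pseudocount can soften the
    point masses.
    """
    L = len(sequence)
    freq = np.full((L, 20), pseudocount, dtype=float)
    for i, aa in enumerate(sequence):
        if aa == "X":
            freq[i] = 1.0
        else:
            freq[i, AMINO_ACIDS.index(aa)] += 1.0
    freq /= freq.sum(axis=1, keepdims=True)
    return SequenceProfile(frequencies=freq)
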