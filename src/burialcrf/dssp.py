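"""DSSP output parsing and derivation of burial labels.

Burial labels are derived in three steps: parse per-residue accessible
surface area (ASA) from a classic DSSP text file, normalise it by the
residue-type maximum ASA to obtain relative solvent accessibility (RSA),
and threshold RSA at 0.25 — residues with RSA below the threshold are
buried (1), residues at or above it are exposed (0).

Only the DSSP *format* is consumed here; DSSP itself is never run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .records import AMINO_ACIDS, BURIED, EXPOSED

#: default exposure threshold: RSA >= threshold is exposed
EXPOSURE_THRESHOLD = 0.25

_DATA_PACKAGE = "burialcrf.data"
DEFAULT_MAX_ASA = "max_asa_tien2013.tsv"


class DsspFormatError(ValueError):
    """Raised when a file does not follow the classic DSSP column layout."""


@dataclass
class DsspTable:
    """Per-residue content of one DSSP file.

    ``breaks`` holds the 0-based index of the residue *preceding* each
    chain-break marker ('!').
    """

    residues: pd.DataFrame  # columns: aa, ss8, asa, chain, resnum
    breaks: list[int]

    @property
    def sequence(self) -> str:
        return "".join(self.residues["aa"])

    @property
    def has_breaks(self) -> bool:
        return bool(self.breaks)


def parse_dssp(path: str | Path) -> DsspTable:
    """Parse a classic DSSP text file into a per-residue table.

    The fixed-width record layout is: residue letter at column 13, 8-state
    SS code at column 16, ASA in columns 34-38.  Lowercase letters in the
    AA column are SS-bridge cysteines and map to 'C'; '!' rows are chain
    breaks and are recorded as breaks, not residues.
    """
    lines = Path(path).read_text().splitlines()
    start = None
    for k, line in enumerate(lines):
        if line.lstrip().startswith("#  RESIDUE"):
            start = k + 1
            break
    if start is None:
        raise DsspFormatError(f"{path}: no '#  RESIDUE' header found")

    rows, breaks = [], []
    for line in lines[start:]:
        if len(line) < 38:
            continue
        aa = line[13]
        if aa == "!":
            if rows:
                breaks.append(len(rows) - 1)
            continue
        if aa.islower():  # SS-bridge cysteine pair labels a..z
            aa = "C"
        if aa not in AMINO_ACIDS:
            warnings.warn(f"unknown residue letter {aa!r}, using 'X'", stacklevel=2)
            aa = "X"
        ss8 = line[16]
        try:
            asa = float(line[34:38])
        except ValueError as exc:
            raise DsspFormatError(f"{path}: bad ASA field in line {line!r}") from exc
        chain = line[11] if len(line) > 11 else " "
        try:
            resnum = int(line[5:10])
        except ValueError:
            resnum = len(rows) + 1
        rows.append((aa, ss8, asa, chain, resnum))

    df = pd.DataFrame(rows, columns=["aa", "ss8", "asa", "chain", "resnum"])
    return DsspTable(residues=df, breaks=breaks)


def load_max_asa(path: str | Path | None = None) -> dict[str, float]:
    """Load a per-residue maximum-ASA table (Å²).

    The default ships with the package (Tien et al. 2013, theoretical).
    Any 2-column TSV with ``residue`` and ``max_asa`` headers can be
    substituted.  'X' maps to the table mean.
    """
    if path is None:
        with resources.files(_DATA_PACKAGE).joinpath(DEFAULT_MAX_ASA).open() as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    table = dict(zip(df["residue"], df["max_asa"].astype(float)))
    missing = set(AMINO_ACIDS) - set(table)
    if missing:
        raise ValueError(f"max-ASA table missing residues {sorted(missing)}")
    table["X"] = float(np.mean([table[a] for a in AMINO_ACIDS]))
    return table


def compute_rsa(
    asa,
    residue_types: str,
    max_asa_table: dict[str, float] | None = None,
    clip: bool = False,
) -> np.ndarray:
    """Relative solvent accessibility: ASA divided by residue-type max ASA.

    Values above 1 are retained unless ``clip`` is set.
    """
    asa = np.asarray(asa, dtype=float)
    if asa.ndim != 1 or asa.shape[0] != len(residue_types):
        raise ValueError("asa and residue_types must have matching lengths")
    if (asa < 0).any():
        raise ValueError("negative ASA")
    table = max_asa_table if max_asa_table is not None else load_max_asa()
    denom = np.array([table[a] for a in residue_types], dtype=float)
    rsa = np.divide(asa, denom, out=np.zeros_like(asa), where=denom > 0)
    if clip:
        rsa = np.minimum(rsa, 1.0)
    return rsa


def binarize_rsa(rsa, threshold: float = EXPOSURE_THRESHOLD) -> np.ndarray:
    """Threshold RSA into burial labels: rsa < threshold → buried (1).

    The boundary convention is fixed: RSA exactly equal to the threshold is
    exposed ("exposure threshold" read as minimum exposure).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    rsa = np.asarray(rsa, dtype=float)
    return np.where(rsa < threshold, BURIED, EXPOSED).astype(np.int8)


def labels_from_dssp(
    path: str | Path,
    max_asa_table: dict[str, float] | None = None,
    threshold: float = EXPOSURE_THRESHOLD,
    allow_breaks: bool = False,
) -> tuple[str, str, np.ndarray]:
    """Full labeling pipeline: DSSP file → (sequence, 3-state SS, labels).

    Proteins with chain breaks are rejected unless ``allow_breaks`` (training
    data excludes broken chains; prediction may keep them).
    """
    from .records import map_8to3

    table = parse_dssp(path)
    if table.has_breaks and not allow_breaks:
        raise ValueError(f"{path}: chain breaks at {table.breaks}; rejected for training")
    rsa = compute_rsa(table.residues["asa"].to_numpy(), table.sequence, max_asa_table)
    labels = binarize_rsa(rsa, threshold)
    ss3 = map_8to3("".join(table.residues["ss8"]))
    return table.sequence, ss3, labels


def write_labels_tsv(path: str | Path, labels) -> None:
    """Write labels as a two-column TSV: 1-based position, 0/1 label."""
    labels = np.asarray(labels, dtype=int)
    df = pd.DataFrame({"position": np.arange(1, len(labels) + 1), "label": labels})
    df.to_csv(path, sep="\t", index=False)


def read_labels_tsv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    df = df.sort_values("position")
    return df["label"].to_numpy(dtype=np.int8)
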