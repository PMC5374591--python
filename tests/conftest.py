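"""Shared fixture builders: random CRF instances and crafted file fixtures.

Everything is generated programmatically; no binary or stored data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from burialcrf import ModelParameters, ProteinRecord, ss_string_to_segments

SS_CHARS = ("H", "E", "C")


def random_ss_string(rng: np.random.Generator, L: int) -> str:
    return "".join(SS_CHARS[j] for j in rng.integers(0, 3, size=L))


def random_instance(
    rng: np.random.Generator,
    L: int | None = None,
    D: int = 3,
    K: int = 4,
    ss: str | None = None,
    weight_scale: float = 1.0,
    labeled: bool = False,
) -> tuple[ProteinRecord, ModelParameters]:
    """A random protein record plus random model parameters.

    Random segmentations routinely contain length-1 segments, which
    exercises the short-segment order gating.
    """
    if L is None:
        L = int(rng.integers(1, 13))
    ss = ss or random_ss_string(rng, L)
    U = {
        1: np.ones((L, 1)),
        2: rng.normal(size=(L, K)),
        3: rng.normal(size=(L, K)),
        4: rng.normal(size=(L, K)),
    }
    record = ProteinRecord(
        id="rand",
        sequence="A" * L,
        segmentation=ss_string_to_segments(ss),
        singlet_features=rng.normal(size=(L, D)),
        doublet_features=U,
    )
    if labeled:
        record.labels = rng.integers(0, 2, size=L).astype(np.int8)
    params = ModelParameters(
        theta=weight_scale * rng.normal(size=(2, D)),
        doublet={d: weight_scale * rng.normal(size=(4, U[d].shape[1])) for d in U},
    )
    return record, params


# ---------------------------------------------------------------------------
# DSSP fixture text
# ---------------------------------------------------------------------------

DSSP_HEADER = (
    "==== Secondary Structure Definition by the program DSSP ====\n"
    "REFERENCE ...\n"
    "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N\n"
)


def dssp_line(num: int, aa: str, ss8: str, asa: float) -> str:
    """One fixed-width DSSP record: AA at column 13, SS at 16, ASA at 34-38."""
    line = f"{num:5d}{num:5d} A {aa}  {ss8}"
    line = line.ljust(34) + f"{asa:4.0f}" + "   0, 0.0"
    return line


def dssp_break_line(num: int) -> str:
    return (f"{num:5d}" + " " * 8 + "!").ljust(45)


def write_dssp(path, rows, breaks_after=()) -> None:
    """rows: list of (aa, ss8, asa); breaks_after: residue indices (1-based)."""
    lines = [DSSP_HEADER.rstrip("\n")]
    num = 0
    for j, (aa, ss8, asa) in enumerate(rows, start=1):
        num += 1
        lines.append(dssp_line(num, aa, ss8, asa))
        if j in breaks_after:
            num += 1
            lines.append(dssp_break_line(num))
    path.write_text("\n".join(lines) + "\n")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
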