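"""Fully in-silico datasets: segmentations, features and exact CRF labels.

The generator emulates the structure of a real burial-state corpus —
proteins of 50–150 residues, alternating helix/strand/coil segments with
geometric lengths, per-residue observation matrices standing in for
profile/SS/conservation/contact-number features, and doublet observations
at separations 2/3/4 — while keeping the label law *exactly* known:
labels are drawn from p(Y | X; Λ*) by forward-filtering backward-sampling
on the same trellis the inference module uses, for a generating parameter
vector Λ* built from the config.

Composition presets mirror the four dataset classes of real benchmarks
(α-rich, β-rich, α/β mixed, α+β) via segment-type frequencies.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .inference import sample_labels_given_features
from .model import ModelParameters, pair_index
from .records import AMINO_ACIDS, ProteinRecord, Segment, SSSegmentation

__all__ = [
    "GeneratorConfig",
    "preset",
    "make_generating_params",
    "sample_segmentation",
    "sample_features",
    "sample_labels",
    "sample_record",
    "sample_dataset",
    "make_benchmark",
    "load_benchmark",
]


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic corpus.

    ``ss_freqs`` are the stationary segment-type frequencies; successive
    segments always differ in type (frequencies renormalized over the
    remaining two types).  ``mean_len`` are geometric segment-length means;
    the helix default of 8 keeps order-4 terms active in most helices.
    ``effect_size`` is the singlet weight magnitude on signal columns
    (0 ⇒ features carry no label information); ``coupling`` are the
    generating doublet bias weights, positive values favouring equal
    labels at that separation.
    """

    n_proteins: int = 100
    length_min: int = 50
    length_max: int = 150
    ss_freqs: dict[str, float] = field(
        default_factory=lambda: {"H": 0.40, "E": 0.25, "C": 0.35}
    )
    mean_len: dict[str, float] = field(
        default_factory=lambda: {"H": 8.0, "E": 5.0, "C": 4.0}
    )
    n_signal_cols: int = 4
    n_noise_cols: int = 4
    effect_size: float = 1.0
    noise_scale: float = 1.0
    coupling: dict[int, float] = field(
        default_factory=lambda: {1: 0.3, 2: 0.8, 3: 0.8, 4: 0.8}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.ss_freqs.values())
        if total <= 0:
            raise ValueError("ss_freqs must have positive mass")
        self.ss_freqs = {t: p / total for t, p in self.ss_freqs.items()}
        if any(v < 1 for v in self.mean_len.values()):
            raise ValueError("mean segment lengths must be >= 1")
        if self.length_min < 1 or self.length_max < self.length_min:
            raise ValueError("bad length range")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_PRESETS: dict[str, dict] = {
    # composition classes analogous to α, β, α/β and α+β benchmark sets
    "alpha": {"ss_freqs": {"H": 0.65, "E": 0.05, "C": 0.30}},
    "beta": {"ss_freqs": {"H": 0.05, "E": 0.55, "C": 0.40}},
    "alpha_beta": {"ss_freqs": {"H": 0.35, "E": 0.30, "C": 0.35}},
    "alpha_plus_beta": {"ss_freqs": {"H": 0.30, "E": 0.25, "C": 0.45}},
    # helix-rich corpus with strong long-range coupling and weak singlet
    # signal: the regime where high-order terms pay off
    "helix_coupled": {
        "ss_freqs": {"H": 0.70, "E": 0.05, "C": 0.25},
        "mean_len": {"H": 12.0, "E": 5.0, "C": 4.0},
        "effect_size": 0.6,
        "coupling": {1: 0.1, 2: 0.1, 3: 1.2, 4: 1.5},
    },
    "strand_coupled": {
        "ss_freqs": {"H": 0.05, "E": 0.60, "C": 0.35},
        "mean_len": {"H": 8.0, "E": 8.0, "C": 4.0},
        "effect_size": 0.6,
        "coupling": {1: 0.1, 2: 1.5, 3: 0.1, 4: 0.1},
    },
}


def preset(name: str, **overrides) -> GeneratorConfig:
    """Named study conditions; see ``_PRESETS`` for the catalogue."""
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    kwargs = {**_PRESETS[name], **overrides}
    return GeneratorConfig(**kwargs)


def make_generating_params(config: GeneratorConfig) -> ModelParameters:
    """Λ* implied by the config.

    θ* puts ±effect_size/2 on the signal columns (buried positive), zero
    on noise columns and bias.  Doublet weights put ±coupling_d on the
    bias observation (equal label pairs positive, unequal negative); the
    MI/cosine/contact-map observation columns carry zero generating
    weight, so any information in them is incidental.
    """
    D = 1 + config.n_signal_cols + config.n_noise_cols
    theta = np.zeros((2, D))
    for c in range(1, 1 + config.n_signal_cols):
        theta[1, c] = +config.effect_size / 2.0
        theta[0, c] = -config.effect_size / 2.0
    doublet = {}
    for d in (1, 2, 3, 4):
        K = 1 if d == 1 else 4
        W = np.zeros((4, K))
        c = config.coupling.get(d, 0.0)
        for yp in (0, 1):
            for y in (0, 1):
                W[pair_index(yp, y), 0] = c if yp == y else -c
        doublet[d] = W
    return ModelParameters(theta=theta, doublet=doublet)


def sample_segmentation(
    length: int, config: GeneratorConfig, rng: np.random.Generator
) -> SSSegmentation:
    """Alternating-type segments with geometric lengths, truncated to fit."""
    if length < 1:
        raise ValueError("length must be >= 1")
    types = [t for t in ("H", "E", "C") if config.ss_freqs.get(t, 0.0) > 0]
    probs = np.array([config.ss_freqs[t] for t in types])
    segments: list[Segment] = []
    pos, prev = 0, None
    while pos < length:
        if prev is None or len(types) == 1:
            t = types[rng.choice(len(types), p=probs)]
        else:
            mask = np.array([tt != prev for tt in types], dtype=float)
            p = probs * mask
            p /= p.sum()
            t = types[rng.choice(len(types), p=p)]
        mean = config.mean_len[t]
        seg_len = 1 + rng.geometric(1.0 / mean) - 1 if mean > 1 else 1
        seg_len = max(1, min(int(seg_len), length - pos))
        if segments and segments[-1].ss_type == t:  # only one type available
            segments[-1] = Segment(t, segments[-1].start, pos + seg_len - 1)
        else:
            segments.append(Segment(t, pos, pos + seg_len - 1))
        pos += seg_len
        prev = t
    return SSSegmentation(tuple(segments))


def sample_features(
    length: int,
    segmentation: SSSegmentation,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Observation matrices: bias + Gaussian signal/noise singlet columns,
    and doublet observations [bias, MI-like, cosine-like, 0] per separation."""
    D = 1 + config.n_signal_cols + config.n_noise_cols
    X = np.empty((length, D))
    X[:, 0] = 1.0
    X[:, 1:] = rng.normal(0.0, config.noise_scale, size=(length, D - 1))
    U: dict[int, np.ndarray] = {1: np.ones((length, 1))}
    for d in (2, 3, 4):
        Ud = np.zeros((length, 4))
        Ud[d:, 0] = 1.0
        Ud[d:, 1] = np.abs(rng.normal(0.0, 0.3, size=length - d))   # MI-like, >= 0
        Ud[d:, 2] = np.tanh(rng.normal(0.0, 1.0, size=length - d))  # cosine-like
        U[d] = Ud
    return X, U


def sample_labels(
    record: ProteinRecord, params: ModelParameters, rng: np.random.Generator
) -> np.ndarray:
    """Exact draw Y ~ p(Y | X; Λ*) via forward-filtering backward-sampling."""
    return sample_labels_given_features(record, params, rng, size=1)[0]


def sample_record(
    config: GeneratorConfig,
    params: ModelParameters,
    rng: np.random.Generator,
    rec_id: str = "synth",
) -> ProteinRecord:
    length = int(rng.integers(config.length_min, config.length_max + 1))
    segmentation = sample_segmentation(length, config, rng)
    X, U = sample_features(length, segmentation, config, rng)
    sequence = "".join(
        AMINO_ACIDS[j] for j in rng.integers(0, len(AMINO_ACIDS), size=length)
    )
    record = ProteinRecord(
        id=rec_id,
        sequence=sequence,
        segmentation=segmentation,
        singlet_features=X,
        doublet_features=U,
    )
    record.labels = sample_labels(record, params, rng)
    return record


def sample_dataset(
    config: GeneratorConfig, params: ModelParameters | None = None
) -> tuple[list[ProteinRecord], ModelParameters]:
    """Generate a labeled corpus; (config, seed) → bit-identical output."""
    params = params or make_generating_params(config)
    rng = np.random.default_rng(config.seed)
    records = [
        sample_record(config, params, rng, rec_id=f"synth{k:04d}")
        for k in range(config.n_proteins)
    ]
    return records, params


# ---------------------------------------------------------------------------
# on-disk benchmarks, in the same formats the real pipeline reads
# ---------------------------------------------------------------------------

def _write_record(record: ProteinRecord, outdir: Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(record.sequence), id=record.id, description="")],
        outdir / f"{record.id}.fasta",
        "fasta",
    )
    (outdir / f"{record.id}.ss").write_text(record.ss_string() + "\n")
    L = record.length
    pos = np.arange(1, L + 1)
    pd.DataFrame(
        np.column_stack([pos, record.singlet_features]),
        columns=["position"] + [f"x{j}" for j in range(record.singlet_features.shape[1])],
    ).to_csv(outdir / f"{record.id}.features.tsv", sep="\t", index=False)
    for d, U in record.doublet_features.items():
        if d == 1:
            continue
        pd.DataFrame(
            np.column_stack([pos, U]),
            columns=["position", "bias", "mi", "cosine", "cmap"],
        ).to_csv(outdir / f"{record.id}.doublet{d}.tsv", sep="\t", index=False)
    if record.labels is not None:
        pd.DataFrame({"position": pos, "label": record.labels}).to_csv(
            outdir / f"{record.id}.labels.tsv", sep="\t", index=False
        )


def make_benchmark(config: GeneratorConfig, outdir: str | Path, n_folds: int = 5) -> Path:
    """Write a labeled corpus split into equal folds; returns the directory.

    Deterministic given (config, seed); a manifest records the config and
    its hash so reruns can be verified.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, params = sample_dataset(config)
    rng = np.random.default_rng(config.seed + 1)
    order = rng.permutation(len(records))
    folds: list[list[str]] = [[] for _ in range(n_folds)]
    for j, idx in enumerate(order):
        r = records[idx]
        fold = j % n_folds
        folds[fold].append(r.id)
        fold_dir = outdir / f"fold{fold + 1}"
        fold_dir.mkdir(exist_ok=True)
        _write_record(r, fold_dir)
    params.save(outdir / "generating_model.json")
    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "n_folds": n_folds,
        "folds": {f"fold{k + 1}": sorted(ids) for k, ids in enumerate(folds)},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return outdir


def load_record(directory: Path, rec_id: str) -> ProteinRecord:
    from .records import ss_string_to_segments

    seq = str(next(SeqIO.parse(directory / f"{rec_id}.fasta", "fasta")).seq)
    ss = (directory / f"{rec_id}.ss").read_text().strip()
    feat = pd.read_csv(directory / f"{rec_id}.features.tsv", sep="\t")
    X = feat.sort_values("position").iloc[:, 1:].to_numpy(float)
    U: dict[int, np.ndarray] = {1: np.ones((len(seq), 1))}
    for d in (2, 3, 4):
        p = directory / f"{rec_id}.doublet{d}.tsv"
        if p.exists():
            df = pd.read_csv(p, sep="\t").sort_values("position")
            U[d] = df.iloc[:, 1:].to_numpy(float)
    labels = None
    lp = directory / f"{rec_id}.labels.tsv"
    if lp.exists():
        labels = (
            pd.read_csv(lp, sep="\t").sort_values("position")["label"].to_numpy(np.int8)
        )
    return ProteinRecord(
        id=rec_id,
        sequence=seq,
        segmentation=ss_string_to_segments(ss),
        singlet_features=X,
        doublet_features=U,
        labels=labels,
    )


def load_benchmark(directory: str | Path) -> dict[str, list[ProteinRecord]]:
    """Read back a benchmark directory into per-fold record lists."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    out = {}
    for fold, ids in manifest["folds"].items():
        out[fold] = [load_record(directory / fold, rid) for rid in ids]
    return out
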