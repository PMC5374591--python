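"""Scoring and diagnostics: Q2 accuracy, stratified accuracies, burial-state
mutual information by sequence separation, and the baseline comparisons."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import mutual_information
from .records import ProteinRecord, SSSegmentation

__all__ = [
    "q2_accuracy",
    "mi_vs_separation",
    "EvaluationReport",
    "evaluate_predictions",
    "baseline_logistic",
    "baseline_chain_crf",
]


def q2_accuracy(pred: list, truth: list) -> float:
    """Fraction of residues whose predicted burial state matches the truth,
    pooled over all residues of all proteins."""
    if len(pred) != len(truth):
        raise ValueError("prediction / truth list length mismatch")
    correct = total = 0
    for p, t in zip(pred, truth):
        p, t = np.asarray(p), np.asarray(t)
        if p.shape != t.shape:
            raise ValueError("per-protein label length mismatch")
        correct += int((p == t).sum())
        total += p.size
    if total == 0:
        raise ValueError("no residues to score")
    return correct / total


def mi_vs_separation(
    labels: list,
    segmentations: list[SSSegmentation],
    max_sep: int = 6,
    stratify_by_ss: bool = True,
) -> pd.DataFrame:
    """Plug-in mutual information (bits) of burial-state pairs (Y_i, Y_{i+d}).

    When stratified, a pair qualifies for SS type t only if both residues
    lie in the *same* segment of type t; unstratified pools all pairs.
    Separations with no qualifying pairs get NaN (missing, not zero).
    Returns a tidy frame (separation, ss_type, mi_bits, n_pairs).
    """
    if len(labels) != len(segmentations):
        raise ValueError("labels / segmentations length mismatch")
    strata = ("H", "E", "C") if stratify_by_ss else ("all",)
    counts = {
        (d, t): np.zeros((2, 2))
        for d in range(1, max_sep + 1)
        for t in strata
    }
    for y, segm in zip(labels, segmentations):
        y = np.asarray(y)
        if y.shape[0] != segm.length:
            raise ValueError("labels not aligned with segmentation")
        for d in range(1, max_sep + 1):
            if stratify_by_ss:
                for seg in segm:
                    for i in range(seg.start, seg.end + 1 - d):
                        counts[(d, seg.ss_type)][y[i], y[i + d]] += 1
            else:
                for i in range(y.shape[0] - d):
                    counts[(d, "all")][y[i], y[i + d]] += 1
    rows = []
    for (d, t), joint in sorted(counts.items()):
        n = joint.sum()
        mi = mutual_information(joint) if n > 0 else np.nan
        rows.append({"separation": d, "ss_type": t, "mi_bits": mi, "n_pairs": int(n)})
    return pd.DataFrame(rows)


@dataclass
class EvaluationReport:
    """Q2 and its stratifications for one model on one test set."""

    overall: float
    n_residues: int
    confusion: np.ndarray             # rows: truth (0/1), cols: prediction
    by_ss: dict[str, tuple[float, int]] = field(default_factory=dict)
    by_residue: dict[str, tuple[float, int]] = field(default_factory=dict)
    per_protein: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "overall_q2": self.overall,
            "n_residues": self.n_residues,
            "confusion": self.confusion.tolist(),
            "by_ss": {t: {"q2": a, "n": n} for t, (a, n) in self.by_ss.items()},
            "by_residue": {t: {"q2": a, "n": n} for t, (a, n) in self.by_residue.items()},
            "per_protein": self.per_protein,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    def summary(self) -> str:
        lines = [
            f"Q2 accuracy: {self.overall:.4f} over {self.n_residues} residues",
            f"confusion (rows truth 0/1, cols pred 0/1): {self.confusion.tolist()}",
        ]
        for t, (a, n) in sorted(self.by_ss.items()):
            lines.append(f"  SS {t}: Q2 {a:.4f} (n={n})")
        return "\n".join(lines)


def evaluate_predictions(
    records: list[ProteinRecord], predictions: list[np.ndarray]
) -> EvaluationReport:
    """Score predictions against the records' labels, with stratifications.

    Stratified accuracies recombine: Σ_strata count·accuracy equals the
    pooled correct count for every stratification.
    """
    confusion = np.zeros((2, 2))
    by_ss: dict[str, list[int]] = {}
    by_res: dict[str, list[int]] = {}
    per_protein = {}
    correct = total = 0
    for r, p in zip(records, predictions):
        if r.labels is None:
            raise ValueError(f"record {r.id!r} has no labels")
        p = np.asarray(p)
        eq = p == r.labels
        per_protein[r.id] = float(eq.mean())
        correct += int(eq.sum())
        total += r.length
        for t, yp in zip(r.labels, p):
            confusion[int(t), int(yp)] += 1
        ss = r.ss_string()
        for i in range(r.length):
            by_ss.setdefault(ss[i], [0, 0])
            by_ss[ss[i]][0] += int(eq[i])
            by_ss[ss[i]][1] += 1
            by_res.setdefault(r.sequence[i], [0, 0])
            by_res[r.sequence[i]][0] += int(eq[i])
            by_res[r.sequence[i]][1] += 1
    return EvaluationReport(
        overall=correct / total,
        n_residues=total,
        confusion=confusion,
        by_ss={t: (c / n, n) for t, (c, n) in by_ss.items()},
        by_residue={t: (c / n, n) for t, (c, n) in by_res.items()},
        per_protein=per_protein,
    )


def quantile_bins(values: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Quantile bin index per value (used for conservation / CN stratification)."""
    values = np.asarray(values, dtype=float)
    edges = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, values, side="right")


def accuracy_by_bins(
    values: np.ndarray, correct: np.ndarray, n_bins: int = 10
) -> pd.DataFrame:
    """Accuracy within quantile bins of a per-residue covariate."""
    bins = quantile_bins(values, n_bins)
    rows = []
    for b in range(bins.max() + 1):
        mask = bins == b
        if mask.any():
            rows.append(
                {"bin": b, "n": int(mask.sum()), "accuracy": float(correct[mask].mean())}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------

def baseline_logistic(
    train: list[ProteinRecord], test: list[ProteinRecord], seed: int = 0, C: float = 1.0
) -> EvaluationReport:
    """Coupling-free logistic regression on singlet features."""
    from .estimators import BurialLogistic

    clf = BurialLogistic(C=C, random_state=seed).fit(train)
    return evaluate_predictions(test, clf.predict(test))


def baseline_chain_crf(
    train: list[ProteinRecord],
    test: list[ProteinRecord],
    l2: float = 1.0,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> EvaluationReport:
    """First-order chain CRF (coil potential everywhere)."""
    from .estimators import ChainCRF

    clf = ChainCRF(l2=l2, max_iter=max_iter, tol=tol).fit(train)
    return evaluate_predictions(test, clf.predict(test))
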