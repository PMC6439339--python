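"""Genotype-call concordance between two assays.

Compares a test call set (e.g., an allele-specific PCR assay) against a
truth call set (e.g., sequencing-derived genotypes) over the three
effect-allele genotype classes — homozygous non-effect, heterozygous,
homozygous effect — as a 3x3 confusion matrix with rows indexed by the
truth class and columns by the test class. Overall accuracy is the
diagonal fraction; per-class sensitivity, specificity, and precision use
the standard one-vs-rest definitions. Samples missing from either call
set are excluded from the tabulation (and counted), not treated as
errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .model import MISSING, GenotypeMatrix

__all__ = [
    "CLASSES",
    "ConfusionMatrix",
    "build_confusion",
    "calls_from_matrix",
    "assay_metrics",
    "format_report",
]

#: Genotype classes in dosage order: 0, 1, 2 effect-allele copies.
CLASSES = ("hom_non_effect", "het", "hom_effect")

_CLASS_INDEX = {c: k for k, c in enumerate(CLASSES)}


@dataclass
class ConfusionMatrix:
    """3x3 genotype-class agreement counts (rows truth, columns test)."""

    counts: np.ndarray
    n_dropped: int = 0
    label: str = ""
    classes: tuple = field(default=CLASSES)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3, 3):
            raise ValueError("confusion matrix must be 3x3")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        if self.n == 0:
            raise ValueError("empty confusion matrix has no accuracy")
        return float(np.trace(self.counts)) / self.n

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.classes, name="truth"),
            columns=pd.Index(self.classes, name="test"),
        )


def build_confusion(
    truth_calls: Mapping[str, str],
    test_calls: Mapping[str, str],
    label: str = "",
) -> ConfusionMatrix:
    """Cross-tabulate two genotype call sets over shared samples.

    ``truth_calls`` and ``test_calls`` map sample id to a class name in
    ``CLASSES``. Samples present in only one set are dropped and counted
    in ``n_dropped``. An unknown class name is an error naming the
    sample.
    """
    counts = np.zeros((3, 3), dtype=np.int64)
    shared = [s for s in truth_calls if s in test_calls]
    n_dropped = (len(truth_calls) - len(shared)) + sum(
        1 for s in test_calls if s not in truth_calls
    )
    for s in shared:
        for which, call in (("truth", truth_calls[s]), ("test", test_calls[s])):
            if call not in _CLASS_INDEX:
                raise ValueError(
                    f"sample {s!r}: {which} call {call!r} not in {CLASSES}"
                )
        counts[_CLASS_INDEX[truth_calls[s]], _CLASS_INDEX[test_calls[s]]] += 1
    return ConfusionMatrix(counts, n_dropped=n_dropped, label=label)


def calls_from_matrix(gm: GenotypeMatrix, variant_id: str) -> dict[str, str]:
    """Extract per-sample class calls for one effect-oriented variant.

    Missing genotypes are omitted (they become dropped samples in
    :func:`build_confusion`).
    """
    j = {v.id: k for k, v in enumerate(gm.variants)}.get(variant_id)
    if j is None:
        raise KeyError(f"variant {variant_id!r} not in matrix")
    col = gm.dosage[:, j]
    return {
        s: CLASSES[int(d)] for s, d in zip(gm.samples, col) if d != MISSING
    }


def assay_metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """One-vs-rest sensitivity, specificity, and precision per class.

    A metric whose denominator is zero (e.g., sensitivity of a class
    never observed in the truth set) is reported as NaN, not 0.
    """
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    c = cm.counts.astype(float)
    n = c.sum()
    row = c.sum(axis=1)
    col = c.sum(axis=0)
    diag = np.diag(c)
    with np.errstate(divide="ignore", invalid="ignore"):
        sensitivity = np.where(row > 0, diag / row, np.nan)
        specificity = np.where(
            n - row > 0, (n - row - col + diag) / (n - row), np.nan
        )
        precision = np.where(col > 0, diag / col, np.nan)
    return pd.DataFrame(
        {
            "sensitivity": sensitivity,
            "specificity": specificity,
            "precision": precision,
            "n_truth": row.astype(int),
            "n_test": col.astype(int),
        },
        index=pd.Index(cm.classes, name="class"),
    )


def format_report(cm: ConfusionMatrix) -> str:
    """Human-readable assay report with accuracy as one-decimal percent."""
    lines = []
    if cm.label:
        lines.append(f"Assay: {cm.label}")
    lines.append(cm.to_frame().to_string())
    lines.append(f"n = {cm.n} (dropped {cm.n_dropped})")
    lines.append(f"accuracy = {100.0 * cm.accuracy:.1f}%")
    return "\n".join(lines)
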