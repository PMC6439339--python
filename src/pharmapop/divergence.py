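"""Between-population effect-allele divergence and the pharmaSNP screen.

For each pharmacogenomic variant with effect-allele frequencies f1 and
f2 in two populations, divergence is summarised by three numbers:

- R = log2(f1 / f2), the log frequency ratio, sensitive to relative
  differences at low frequencies;
- delta = f1 - f2, the frequency difference, sensitive to absolute
  differences at high frequencies;
- E = sqrt(R^2 + delta^2), the Euclidean distance from the origin when
  the two axes are plotted orthogonally — a composite between-population
  difference.

Frequencies of exactly 0 or 1 would make the ratio singular; for R only,
such frequencies are continuity-corrected by adding half an allele
count, f* = (2n f + 0.5) / (2n + 1), so rare population-private effect
alleles still rank instead of being discarded. delta always uses the raw
frequencies. The screen keeps variants at the requested evidence levels
with E strictly greater than the threshold, sorted by descending E
(ties broken by rsID for deterministic reports).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .model import GenotypeMatrix, PharmaAnnotation, PopulationManifest
from .popgen import compute_freq

logger = logging.getLogger(__name__)

__all__ = [
    "effect_allele_frequencies",
    "divergence",
    "screen_of_interest",
]


def effect_allele_frequencies(
    gm: GenotypeMatrix,
    manifest: PopulationManifest,
    pop1: str,
    pop2: str,
) -> pd.DataFrame:
    """Per-variant effect-allele frequency in each of two populations.

    ``gm`` must be effect-allele oriented. Returns a DataFrame indexed by
    variant id with columns ``f_pop1, f_pop2, n1, n2`` (called-sample
    counts). Populations must exist in the manifest.
    """
    out = {}
    for label, pop in (("1", pop1), ("2", pop2)):
        members = manifest.samples_of(pop)
        members = [s for s in members if s in set(gm.samples)]
        if not members:
            raise KeyError(f"population {pop!r} has no samples in the genotype matrix")
        tab = compute_freq(gm, members)
        out[f"f_pop{label}"] = tab["freq"]
        out[f"n{label}"] = tab["n_called"]
    return pd.DataFrame(out)


def _continuity_correct(f: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Replace boundary frequencies by (2nf + 0.5) / (2n + 1); leave the rest."""
    f = np.asarray(f, dtype=float)
    boundary = (f == 0.0) | (f == 1.0)
    if not boundary.any():
        return f
    n = np.asarray(n, dtype=float)
    if np.isnan(n[boundary]).any():
        raise ValueError(
            "frequency of exactly 0 or 1 requires the sample count n "
            "for continuity correction"
        )
    out = f.copy()
    out[boundary] = (2.0 * n[boundary] * f[boundary] + 0.5) / (2.0 * n[boundary] + 1.0)
    return out


def divergence(
    f_pop1,
    f_pop2,
    n1=None,
    n2=None,
    index: pd.Index | None = None,
    pop1: str = "pop1",
    pop2: str = "pop2",
) -> pd.DataFrame:
    """Divergence records from paired effect-allele frequencies.

    Accepts scalars or arrays. ``n1``/``n2`` (called-sample counts) are
    only needed when a frequency is exactly 0 or 1. Returns a DataFrame
    with columns ``f_pop1, f_pop2, log2_ratio, delta, euclidean,
    direction``; direction names the population with the higher
    effect-allele frequency (``"equal"`` on ties).
    """
    f1 = np.atleast_1d(np.asarray(f_pop1, dtype=float))
    f2 = np.atleast_1d(np.asarray(f_pop2, dtype=float))
    if f1.shape != f2.shape:
        raise ValueError("frequency arrays must have identical shape")
    for name, f in (("f_pop1", f1), ("f_pop2", f2)):
        if ((f < 0) | (f > 1)).any():
            raise ValueError(f"{name} outside [0, 1]")
    nan = np.full_like(f1, np.nan)
    n1 = nan if n1 is None else np.atleast_1d(np.asarray(n1, dtype=float))
    n2 = nan if n2 is None else np.atleast_1d(np.asarray(n2, dtype=float))

    f1c = _continuity_correct(f1, n1)
    f2c = _continuity_correct(f2, n2)
    R = np.log2(f1c / f2c)
    delta = f1 - f2
    E = np.sqrt(R ** 2 + delta ** 2)
    direction = np.where(delta > 0, pop1, np.where(delta < 0, pop2, "equal"))
    out = pd.DataFrame(
        {
            "f_pop1": f1,
            "f_pop2": f2,
            "log2_ratio": R,
            "delta": delta,
            "euclidean": E,
            "direction": direction,
        },
        index=index if index is not None else pd.RangeIndex(f1.size),
    )
    return out


DEFAULT_LEVELS = ("1A", "1B", "2A", "2B")


def screen_of_interest(
    records: pd.DataFrame,
    annotations: Sequence[PharmaAnnotation],
    e_threshold: float = 0.5,
    levels: Sequence[str] = DEFAULT_LEVELS,
) -> pd.DataFrame:
    """Rank pharmacogenomic variants by composite divergence.

    Joins divergence records (indexed by variant id) to their clinical
    annotations, keeps the requested evidence levels, and retains
    variants with ``euclidean`` strictly greater than ``e_threshold``
    (a record at exactly the threshold is excluded). Records without an
    annotation are excluded with a log entry. Sorted by descending E,
    ties by rsID.
    """
    ann_by_id = {a.id: a for a in annotations}
    unjoined = [vid for vid in records.index if vid not in ann_by_id]
    if unjoined:
        logger.warning("screen_of_interest: %d records without annotation "
                       "excluded: %s", len(unjoined), unjoined[:10])
    rows = []
    for vid, rec in records.iterrows():
        ann = ann_by_id.get(vid)
        if ann is None:
            continue
        if ann.evidence_level not in set(levels):
            continue
        if not rec["euclidean"] > e_threshold:
            continue
        rows.append({
            "id": vid,
            "gene": ann.gene,
            "drug": ann.drug,
            "category": ann.category,
            "evidence_level": ann.evidence_level,
            "effect_allele": ann.effect_allele,
            **rec[["f_pop1", "f_pop2", "log2_ratio", "delta", "euclidean",
                   "direction"]].to_dict(),
        })
    cols = ["id", "gene", "drug", "category", "evidence_level", "effect_allele",
            "f_pop1", "f_pop2", "log2_ratio", "delta", "euclidean", "direction"]
    out = pd.DataFrame(rows, columns=cols)
    out = out.sort_values(
        ["euclidean", "id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return out
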