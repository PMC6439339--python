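"""Readers and writers for VCF, annotation, and manifest files.

Allele-orientation semantics are explicit throughout: :func:`read_vcf`
records which allele each dosage counts, and
:func:`orient_to_effect_allele` re-codes dosages so they count the
annotated effect allele, dropping variants whose orientation cannot be
resolved without strand guessing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .model import (
    MISSING,
    NUCLEOTIDES,
    GenotypeMatrix,
    PharmaAnnotation,
    PopulationManifest,
    VariantRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "VcfParseError",
    "read_vcf",
    "write_vcf",
    "read_annotation",
    "write_annotation",
    "read_manifest",
    "write_manifest",
    "orient_to_effect_allele",
    "OrientationReport",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Strand-ambiguous allele pairs: identical on both strands.
AMBIGUOUS_PAIRS = (frozenset("AT"), frozenset("CG"))


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed into a genotype matrix."""


def _is_biallelic_snp(ref: str, alts: tuple | None) -> bool:
    if alts is None or len(alts) != 1:
        return False
    alt = alts[0]
    return (
        isinstance(alt, str)
        and ref in NUCLEOTIDES
        and alt in NUCLEOTIDES
    )


def read_vcf(path: str | Path, allele_policy: str = "alt") -> GenotypeMatrix:
    """Read GT fields of a VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNP records are kept; indels, multiallelic sites, and
    symbolic alleles are skipped with a log entry. Phased and unphased
    genotypes are treated identically; ``./.`` becomes missing.

    Parameters
    ----------
    path
        VCF 4.x file (plain or bgzipped).
    allele_policy
        Which allele the dosage counts: ``"alt"`` (default) or ``"ref"``.
    """
    if allele_policy not in ("ref", "alt"):
        raise ValueError(f"allele_policy must be 'ref' or 'alt', got {allele_policy!r}")
    path = Path(path)
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"{path}: cannot open as VCF: {exc}") from exc

    samples = list(vf.header.samples)
    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    seen: set[str] = set()
    n_skipped = 0
    try:
        for line_no, rec in enumerate(vf, start=1):
            if not _is_biallelic_snp(rec.ref, rec.alts):
                n_skipped += 1
                continue
            vid = rec.id if rec.id not in (None, ".") else f"{rec.chrom}:{rec.pos}"
            if vid in seen:
                raise VcfParseError(f"{path}: duplicate variant ID {vid!r}")
            seen.add(vid)
            variants.append(
                VariantRecord(id=vid, chrom=str(rec.chrom), pos=rec.pos,
                              ref=rec.ref, alt=rec.alts[0])
            )
            dos = np.empty(len(samples), dtype=np.int8)
            for i, s in enumerate(samples):
                gt = rec.samples[s].get("GT", (None,))
                if gt is None or any(a is None for a in gt):
                    dos[i] = MISSING
                else:
                    dos[i] = sum(1 for a in gt if a == 1)
            rows.append(dos)
    except VcfParseError:
        raise
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"{path}: malformed VCF record: {exc}") from exc
    finally:
        vf.close()

    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records in %s",
                    n_skipped, path)
    dosage = (np.stack(rows, axis=1) if rows
              else np.empty((len(samples), 0), dtype=np.int8))
    gm = GenotypeMatrix(samples, variants, dosage)
    if allele_policy == "ref":
        gm = _complement_dosage(gm, np.ones(gm.n_variants, dtype=bool))
    return gm


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT fields only.

    Dosages counting the ref allele are converted back to alt counts so
    the written genotypes follow the VCF convention. Round-trips through
    :func:`read_vcf` reproduce sample order, variant order, and dosage.
    """
    path = Path(path)
    alt_gm = gm
    flip = gm.counted == "ref"
    if flip.any():
        alt_gm = _complement_dosage(gm, flip)
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(v.chrom for v in alt_gm.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(alt_gm.samples) + "\n")
        for j, v in enumerate(alt_gm.variants):
            gts = "\t".join(gt_code[int(d)] for d in alt_gm.dosage[:, j])
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t{gts}\n")


def _complement_dosage(gm: GenotypeMatrix, which: np.ndarray) -> GenotypeMatrix:
    """Re-code dosage d -> 2 - d (missing preserved) for flagged variants."""
    dosage = gm.dosage.copy()
    cols = np.where(which)[0]
    for j in cols:
        col = dosage[:, j]
        ok = col != MISSING
        col[ok] = 2 - col[ok]
    counted = gm.counted.copy()
    counted[cols] = np.where(counted[cols] == "alt", "ref", "alt")
    return GenotypeMatrix(gm.samples, gm.variants, dosage, counted)


# ---------------------------------------------------------------------------
# Annotation and manifest tables
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ["id", "gene", "drug", "category", "evidence_level",
                      "effect_allele", "non_effect_allele"]


def read_annotation(path: str | Path) -> list[PharmaAnnotation]:
    """Read a pharmacogenomic clinical-annotation TSV.

    Expects the columns ``id, gene, drug, category, evidence_level,
    effect_allele, non_effect_allele``; rows are validated against the
    closed category and evidence-level vocabularies.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: annotation TSV missing columns {missing}")
    records = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(PharmaAnnotation(
                id=row.id, gene=row.gene, drug=row.drug, category=row.category,
                evidence_level=row.evidence_level,
                effect_allele=row.effect_allele,
                non_effect_allele=row.non_effect_allele,
            ))
        except ValueError as exc:
            raise ValueError(f"{path}, row {row_no}: {exc}") from exc
    logger.info("read_annotation: %d records from %s", len(records), path)
    return records


def write_annotation(records: Sequence[PharmaAnnotation], path: str | Path) -> None:
    df = pd.DataFrame([{c: getattr(r, c) for c in ANNOTATION_COLUMNS}
                       for r in records], columns=ANNOTATION_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> PopulationManifest:
    """Read a sample/population/role manifest TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return PopulationManifest(df)


def write_manifest(manifest: PopulationManifest, path: str | Path) -> None:
    manifest.assignments.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Effect-allele orientation
# ---------------------------------------------------------------------------

@dataclass
class OrientationReport:
    """Outcome of orienting a genotype matrix to annotated effect alleles."""

    n_oriented: int
    n_flipped: int
    dropped: dict  # variant id -> reason


def orient_to_effect_allele(
    gm: GenotypeMatrix,
    annotations: Sequence[PharmaAnnotation],
) -> tuple[GenotypeMatrix, OrientationReport]:
    """Re-code dosages so each annotated variant counts its effect allele.

    A variant is kept only when its VCF allele pair equals the annotation
    allele pair on the same strand. Mismatching pairs — including apparent
    strand flips and the intrinsically strand-ambiguous A/T and C/G pairs —
    are dropped with a log entry rather than flipped: guessing strand for
    ambiguous SNPs silently corrupts effect directions.

    Returns the oriented matrix restricted to resolvable annotated
    variants (input order preserved) and a report of what happened.
    """
    ann_by_id = {}
    for a in annotations:
        if a.id in ann_by_id:
            raise ValueError(f"duplicate annotation for {a.id}")
        ann_by_id[a.id] = a

    keep_idx: list[int] = []
    flip = []
    dropped: dict[str, str] = {}
    for j, v in enumerate(gm.variants):
        ann = ann_by_id.get(v.id)
        if ann is None:
            dropped[v.id] = "no annotation"
            continue
        ann_pair = frozenset((ann.effect_allele, ann.non_effect_allele))
        if ann_pair != v.alleles:
            flipped_pair = frozenset(_COMPLEMENT[a] for a in ann_pair)
            if flipped_pair == v.alleles:
                reason = ("unresolvable orientation: strand-flip candidate "
                          f"(annotation {''.join(sorted(ann_pair))} vs "
                          f"VCF {v.ref}/{v.alt})")
            else:
                reason = (f"allele mismatch (annotation "
                          f"{''.join(sorted(ann_pair))} vs VCF {v.ref}/{v.alt})")
            dropped[v.id] = reason
            logger.warning("orient_to_effect_allele: dropping %s: %s", v.id, reason)
            continue
        counted_nt = gm.counted_allele(j)
        flip.append(counted_nt != ann.effect_allele)
        keep_idx.append(j)

    sub = GenotypeMatrix(
        gm.samples,
        [gm.variants[j] for j in keep_idx],
        gm.dosage[:, keep_idx],
        gm.counted[keep_idx],
    )
    flip_arr = np.asarray(flip, dtype=bool)
    oriented = _complement_dosage(sub, flip_arr) if flip_arr.any() else sub
    report = OrientationReport(
        n_oriented=len(keep_idx),
        n_flipped=int(flip_arr.sum()),
        dropped=dropped,
    )
    return oriented, report
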