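"""Core data model: variants, dosage genotype matrices, annotations, manifests.

Genotypes are stored as allele-dosage counts in {0, 1, 2} with an explicit
per-variant record of *which* allele the dosage counts (``ref`` or ``alt``).
Keeping the counted allele on the matrix, rather than implicit in a
convention, is what makes effect-allele orientation a checked, reversible
operation instead of a silent source of sign errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "NUCLEOTIDES",
    "EVIDENCE_LEVELS",
    "CATEGORIES",
    "VariantRecord",
    "GenotypeMatrix",
    "PharmaAnnotation",
    "PopulationManifest",
]

#: Sentinel for a missing genotype in the int8 dosage matrix.
MISSING: int = -1

NUCLEOTIDES = frozenset("ACGT")

#: Closed vocabulary of clinical-annotation evidence tiers (1A strongest).
EVIDENCE_LEVELS = ("1A", "1B", "2A", "2B", "3", "4")

#: Closed vocabulary of drug-response phenotype categories.
CATEGORIES = ("efficacy", "dosage", "toxicity/ADR", "metabolism", "other")


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNP: rsID, 1-based position, and its two alleles."""

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in NUCLEOTIDES or self.alt not in NUCLEOTIDES:
            raise ValueError(
                f"{self.id}: alleles must be single nucleotides, "
                f"got ref={self.ref!r} alt={self.alt!r}"
            )
        if self.ref == self.alt:
            raise ValueError(f"{self.id}: ref and alt alleles are identical")
        if self.pos < 1:
            raise ValueError(f"{self.id}: position must be 1-based, got {self.pos}")

    @property
    def alleles(self) -> frozenset:
        return frozenset((self.ref, self.alt))


class GenotypeMatrix:
    """Samples x biallelic variants dosage matrix.

    Parameters
    ----------
    samples
        Ordered sample identifiers.
    variants
        Ordered :class:`VariantRecord` list.
    dosage
        ``(n_samples, n_variants)`` integer array with entries in
        ``{0, 1, 2, MISSING}``; entry ``(i, j)`` counts copies of the
        counted allele of variant ``j`` carried by sample ``i``.
    counted
        Per-variant flag, ``"ref"`` or ``"alt"``, naming the counted allele.
        Defaults to ``"alt"`` everywhere (the VCF convention).
    """

    def __init__(
        self,
        samples: Sequence[str],
        variants: Sequence[VariantRecord],
        dosage: np.ndarray,
        counted: Sequence[str] | None = None,
    ) -> None:
        self.samples = list(samples)
        self.variants = list(variants)
        dosage = np.asarray(dosage, dtype=np.int8)
        if dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"dosage contains values outside {{0,1,2,missing}}: "
                             f"{np.unique(dosage[bad])}")
        self.dosage = dosage
        if counted is None:
            counted = ["alt"] * len(self.variants)
        self.counted = np.asarray(counted, dtype="U3")
        if self.counted.shape != (len(self.variants),):
            raise ValueError("counted must have one entry per variant")
        if not np.isin(self.counted, ("ref", "alt")).all():
            raise ValueError("counted entries must be 'ref' or 'alt'")
        ids = [v.id for v in self.variants]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate variant IDs: {dup}")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample IDs")

    # -- basic introspection ------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def counted_allele(self, j: int) -> str:
        """Nucleotide counted by the dosage at variant index ``j``."""
        v = self.variants[j]
        return v.alt if self.counted[j] == "alt" else v.ref

    def dosage_float(self) -> np.ndarray:
        """Dosage as float64 with missing entries as NaN."""
        d = self.dosage.astype(np.float64)
        d[self.dosage == MISSING] = np.nan
        return d

    # -- slicing ------------------------------------------------------------

    def take_samples(self, names: Iterable[str]) -> "GenotypeMatrix":
        names = list(names)
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in names if s not in lookup]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        idx = [lookup[s] for s in names]
        return GenotypeMatrix(names, self.variants, self.dosage[idx, :], self.counted)

    def take_variants(self, ids: Iterable[str]) -> "GenotypeMatrix":
        ids = list(ids)
        lookup = {v.id: j for j, v in enumerate(self.variants)}
        missing = [i for i in ids if i not in lookup]
        if missing:
            raise KeyError(f"variants not in matrix: {missing}")
        idx = [lookup[i] for i in ids]
        return GenotypeMatrix(
            self.samples,
            [self.variants[j] for j in idx],
            self.dosage[:, idx],
            self.counted[idx],
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.samples), list(self.variants),
            self.dosage.copy(), self.counted.copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.variants == other.variants
            and np.array_equal(self.dosage, other.dosage)
            and np.array_equal(self.counted, other.counted)
        )

    def __repr__(self) -> str:
        return (f"GenotypeMatrix({self.n_samples} samples x "
                f"{self.n_variants} variants)")


@dataclass(frozen=True)
class PharmaAnnotation:
    """Clinical annotation of one pharmacogenomic SNP.

    ``effect_allele`` is the allele that increases the annotated drug
    response (efficacy, required dosage, or toxicity/adverse-reaction risk).
    """

    id: str
    gene: str
    drug: str
    category: str
    evidence_level: str
    effect_allele: str
    non_effect_allele: str

    def __post_init__(self) -> None:
        if self.evidence_level not in EVIDENCE_LEVELS:
            raise ValueError(
                f"{self.id}: unknown evidence level {self.evidence_level!r}; "
                f"expected one of {EVIDENCE_LEVELS}"
            )
        if self.category not in CATEGORIES:
            raise ValueError(
                f"{self.id}: unknown category {self.category!r}; "
                f"expected one of {CATEGORIES}"
            )
        for name, a in (("effect", self.effect_allele),
                        ("non-effect", self.non_effect_allele)):
            if a not in NUCLEOTIDES:
                raise ValueError(f"{self.id}: {name} allele {a!r} is not a nucleotide")
        if self.effect_allele == self.non_effect_allele:
            raise ValueError(f"{self.id}: effect and non-effect alleles are identical")


@dataclass
class PopulationManifest:
    """Assignment of every sample to a population and a role.

    Roles distinguish ``reference`` individuals (anchoring ancestral
    components) from ``study`` individuals (the admixed cohorts under
    analysis).
    """

    assignments: "pd.DataFrame" = field(default_factory=pd.DataFrame)

    ROLES = ("reference", "study")

    def __post_init__(self) -> None:
        df = self.assignments
        required = {"sample", "population", "role"}
        if not required.issubset(df.columns):
            raise ValueError(f"manifest needs columns {sorted(required)}")
        if df["sample"].duplicated().any():
            dup = df.loc[df["sample"].duplicated(), "sample"].tolist()
            raise ValueError(f"samples assigned more than once: {dup}")
        bad = ~df["role"].isin(self.ROLES)
        if bad.any():
            raise ValueError(f"unknown roles: {sorted(df.loc[bad, 'role'].unique())}")
        self.assignments = df.reset_index(drop=True)

    @property
    def populations(self) -> list[str]:
        return sorted(self.assignments["population"].unique())

    def samples_of(self, population: str, role: str | None = None) -> list[str]:
        df = self.assignments
        sel = df["population"] == population
        if role is not None:
            sel &= df["role"] == role
        out = df.loc[sel, "sample"].tolist()
        if not out and population not in set(df["population"]):
            raise KeyError(f"population {population!r} absent from manifest")
        return out

    def population_of(self) -> Mapping[str, str]:
        return dict(zip(self.assignments["sample"], self.assignments["population"]))

    def check_covers(self, gm: GenotypeMatrix) -> None:
        """Every sample of ``gm`` must be assigned exactly once."""
        assigned = set(self.assignments["sample"])
        unassigned = [s for s in gm.samples if s not in assigned]
        if unassigned:
            raise ValueError(f"samples missing from manifest: {unassigned}")
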