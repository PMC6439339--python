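"""Synthetic admixed cohorts with known ancestry truth.

The generator emulates the data a population-pharmacogenomics survey of
two neighbouring admixed populations needs: a reference panel of
per-component allele frequencies, admixed study cohorts with
individual-level ancestry drawn on the simplex, a pharmacogenomic
annotation table over a subset of the simulated variants, and
discordance-injected re-call sets for assay validation.

Model
-----
Ancestral component frequencies follow the Balding–Nichols model: for
variant *j* an ancestral mean frequency ``p_j`` is drawn (Uniform(0.05,
0.95) by default) and each component *k* gets

    f_kj ~ Beta(p_j (1-F)/F, (1-p_j)(1-F)/F),

so that E[f_kj] = p_j and Var[f_kj] = F p_j (1-p_j): the single
parameter ``F`` is the expected between-component fixation index.
Individuals in cohort *c* draw ancestry fractions q_i ~ Dirichlet(α_c)
and genotypes g_ij ~ Binomial(2, Σ_k q_ik f_kj). Variants are simulated
unlinked; linkage-disequilibrium pruning is exercised on separately
constructed correlated fixtures, not on simulator output.

The default cohorts mirror two Colombian populations with distinct
three-way admixture: an Antioquia-like cohort (mean ancestry 7% African,
61% European, 32% Native American) and a Chocó-like cohort (76% African,
11% European, 13% Native American), each with Dirichlet concentration 50
around those means so individual ancestry varies realistically while
remaining recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import MISSING, GenotypeMatrix, PharmaAnnotation, PopulationManifest, VariantRecord
from . import io as pio

__all__ = [
    "COMPONENTS",
    "CohortSpec",
    "SimulationConfig",
    "simulate_reference_panel",
    "simulate_cohort",
    "make_annotations",
    "inject_discordance",
    "simulate_study",
    "write_study",
]

#: Fixed component order used throughout the package.
COMPONENTS = ("African", "European", "NativeAmerican")


@dataclass(frozen=True)
class CohortSpec:
    """One admixed cohort: name, size, and Dirichlet α over components."""

    name: str
    n: int
    alpha: tuple

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"cohort {self.name}: n must be >= 1")
        if any(a <= 0 for a in self.alpha):
            raise ValueError(f"cohort {self.name}: Dirichlet alpha must be > 0")

    @property
    def mean(self) -> np.ndarray:
        a = np.asarray(self.alpha, dtype=float)
        return a / a.sum()


def _default_cohorts() -> tuple:
    # African, European, NativeAmerican order; concentration 50.
    return (
        CohortSpec("Antioquia", 100, (0.07 * 50, 0.61 * 50, 0.32 * 50)),
        CohortSpec("Choco", 100, (0.76 * 50, 0.11 * 50, 0.13 * 50)),
    )


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, driven by a single seed."""

    K: int = 3
    M: int = 2000
    cohorts: tuple = field(default_factory=_default_cohorts)
    diff: float = 0.15  # Balding–Nichols F per ancestral component
    base_freq_range: tuple = (0.05, 0.95)
    pharma_fraction: float = 0.05
    discordance_rate: float = 0.023
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.diff < 1):
            raise ValueError("diff (Balding–Nichols F) must satisfy 0 <= F < 1")
        if not (0 <= self.discordance_rate <= 1):
            raise ValueError("discordance_rate must be in [0, 1]")
        if not (0 < self.pharma_fraction <= 1):
            raise ValueError("pharma_fraction must be in (0, 1]")
        self.cohorts = tuple(
            c if isinstance(c, CohortSpec) else CohortSpec(**c) for c in self.cohorts
        )
        for c in self.cohorts:
            if len(c.alpha) != self.K:
                raise ValueError(
                    f"cohort {c.name}: alpha length {len(c.alpha)} != K={self.K}"
                )

    @property
    def component_names(self) -> tuple:
        if self.K == len(COMPONENTS):
            return COMPONENTS
        return tuple(f"component{k + 1}" for k in range(self.K))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "cohorts" in raw:
            raw["cohorts"] = tuple(
                CohortSpec(c["name"], c["n"], tuple(c["alpha"])) for c in raw["cohorts"]
            )
        for key in ("base_freq_range",):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def simulate_reference_panel(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw the (K, M) matrix of per-component allele frequencies.

    With ``F = 0`` every component shares the ancestral mean exactly.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    lo, hi = cfg.base_freq_range
    p = rng.uniform(lo, hi, size=cfg.M)
    if cfg.diff == 0:
        return np.tile(p, (cfg.K, 1))
    scale = (1.0 - cfg.diff) / cfg.diff
    return rng.beta(p * scale, (1.0 - p) * scale, size=(cfg.K, cfg.M))


def _simulate_variants(cfg: SimulationConfig, rng: np.random.Generator) -> list:
    """Invent rsIDs, positions, and allele pairs for M unlinked SNPs."""
    nts = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, size=cfg.M)
    alt_off = rng.integers(1, 4, size=cfg.M)
    alt_i = (ref_i + alt_off) % 4
    return [
        VariantRecord(
            id=f"rs{1_000_000 + j}",
            chrom="1",
            pos=1 + 1000 * j,
            ref=str(nts[ref_i[j]]),
            alt=str(nts[alt_i[j]]),
        )
        for j in range(cfg.M)
    ]


def simulate_cohort(
    cfg: SimulationConfig,
    panel: np.ndarray,
    rng: np.random.Generator | None = None,
    variants: list | None = None,
) -> tuple[GenotypeMatrix, PopulationManifest, pd.DataFrame]:
    """Draw admixed genotypes for every cohort in the config.

    Returns the genotype matrix (dosage counts the alt allele, whose
    per-component frequency is the panel entry), a manifest labelling
    each individual with its cohort, and the truth table of simulated
    ancestry fractions q_i for recovery tests.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if panel.shape != (cfg.K, cfg.M):
        raise ValueError(f"panel shape {panel.shape} != (K={cfg.K}, M={cfg.M})")
    if variants is None:
        variants = _simulate_variants(cfg, rng)

    samples: list[str] = []
    rows_manifest = []
    q_rows = []
    dosage_blocks = []
    for c in cfg.cohorts:
        q = rng.dirichlet(np.asarray(c.alpha, dtype=float), size=c.n)  # (n, K)
        p = q @ panel  # (n, M) individual alt-allele frequencies
        dosage_blocks.append(rng.binomial(2, p).astype(np.int8))
        for i in range(c.n):
            samples.append(f"{c.name}_{i:04d}")
        rows_manifest.extend(
            {"sample": f"{c.name}_{i:04d}", "population": c.name, "role": "study"}
            for i in range(c.n)
        )
        q_rows.append(q)

    gm = GenotypeMatrix(samples, variants, np.vstack(dosage_blocks))
    manifest = PopulationManifest(pd.DataFrame(rows_manifest))
    truth = pd.DataFrame(
        np.vstack(q_rows), index=pd.Index(samples, name="sample"),
        columns=list(cfg.component_names),
    )
    return gm, manifest, truth


def make_annotations(
    cfg: SimulationConfig,
    gm: GenotypeMatrix,
    rng: np.random.Generator | None = None,
) -> list[PharmaAnnotation]:
    """Annotate a random ``pharma_fraction`` of variants as pharmacogenomic.

    The effect allele is the ref or alt allele with equal probability, so
    downstream effect-allele orientation is genuinely exercised.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    n_pharma = max(1, int(round(cfg.pharma_fraction * gm.n_variants)))
    idx = np.sort(rng.choice(gm.n_variants, size=n_pharma, replace=False))
    genes = ("CYP2C9", "CYP3A5", "VKORC1", "SLCO1B1", "CYP2C19", "DPYD", "TPMT")
    drugs = ("warfarin", "tacrolimus", "simvastatin", "clopidogrel",
             "metformin", "fluorouracil", "azathioprine")
    categories = ("efficacy", "dosage", "toxicity/ADR", "metabolism")
    levels = ("1A", "1B", "2A", "2B", "3", "4")
    records = []
    for j in idx:
        v = gm.variants[j]
        effect_is_alt = bool(rng.integers(0, 2))
        effect, non_effect = (v.alt, v.ref) if effect_is_alt else (v.ref, v.alt)
        k = int(rng.integers(0, len(genes)))
        records.append(PharmaAnnotation(
            id=v.id, gene=genes[k], drug=drugs[k],
            category=str(categories[rng.integers(0, len(categories))]),
            evidence_level=str(levels[rng.integers(0, len(levels))]),
            effect_allele=effect, non_effect_allele=non_effect,
        ))
    return records


def inject_discordance(
    gm: GenotypeMatrix, rate: float, seed: int
) -> tuple[GenotypeMatrix, int]:
    """Corrupt genotype calls to emulate an imperfect re-genotyping assay.

    Each non-missing genotype is independently replaced, with probability
    ``rate``, by one of the two other genotype classes (chosen uniformly).
    Returns the corrupted matrix and the number of changed cells.
    """
    if not (0 <= rate <= 1):
        raise ValueError("discordance rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    dosage = gm.dosage.copy()
    callable_mask = dosage != MISSING
    hit = callable_mask & (rng.random(dosage.shape) < rate)
    # replace d by one of the two other classes, uniformly
    shift = rng.integers(1, 3, size=dosage.shape)
    dosage[hit] = (dosage[hit] + shift[hit]) % 3
    return GenotypeMatrix(gm.samples, gm.variants, dosage, gm.counted.copy()), int(hit.sum())


def simulate_study(cfg: SimulationConfig) -> dict:
    """Run the whole generator: panel, cohorts, annotations, re-calls.

    All randomness flows from ``cfg.seed``; identical configs give
    bit-identical outputs.
    """
    rng = np.random.default_rng(cfg.seed)
    panel = simulate_reference_panel(cfg, rng)
    gm, manifest, truth = simulate_cohort(cfg, panel, rng)
    annotations = make_annotations(cfg, gm, rng)
    recalled, n_changed = inject_discordance(
        gm, cfg.discordance_rate, seed=cfg.seed + 2
    )
    return {
        "config": cfg,
        "panel": panel,
        "genotypes": gm,
        "manifest": manifest,
        "truth": truth,
        "annotations": annotations,
        "recalled": recalled,
        "n_discordant_injected": n_changed,
    }


def write_study(study: dict, out_dir: str | Path) -> dict:
    """Write a simulated study to disk (VCF + TSVs); returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg: SimulationConfig = study["config"]
    paths = {
        "vcf": out / "genotypes.vcf",
        "recalled_vcf": out / "genotypes_recalled.vcf",
        "manifest": out / "manifest.tsv",
        "annotation": out / "annotations.tsv",
        "truth": out / "ancestry_truth.tsv",
        "panel": out / "reference_panel.tsv",
    }
    pio.write_vcf(study["genotypes"], paths["vcf"])
    pio.write_vcf(study["recalled"], paths["recalled_vcf"])
    pio.write_manifest(study["manifest"], paths["manifest"])
    pio.write_annotation(study["annotations"], paths["annotation"])
    study["truth"].to_csv(paths["truth"], sep="\t")
    panel_df = pd.DataFrame(
        study["panel"].T,
        index=pd.Index(study["genotypes"].variant_ids, name="id"),
        columns=list(cfg.component_names),
    )
    panel_df.to_csv(paths["panel"], sep="\t")
    return {k: str(v) for k, v in paths.items()}
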