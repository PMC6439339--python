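"""Curated reference values for the Colombian pharmacogenomics worked example.

These small tables hold published summary data for two Colombian
populations with distinct admixture profiles — Antioquia (mainly
European ancestry with Native American admixture) and Chocó (mainly
African ancestry): effect-allele frequencies and ancestry-association
coefficients for 13 clinically actionable pharmacogenomic SNPs, the
PharmGKB-style variant-annotation counts, and the validation counts of
three allele-specific PCR genotyping assays scored against exome
sequencing in a 132-patient cohort. They serve as inputs to worked
examples and consistency checks; all derived quantities (divergence
composites, screen membership, assay accuracies) are recomputed from
them by the package.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "colombia_pharmasnps",
    "PHARMGKB_SNP_COUNT",
    "PHARMGKB_VARIANT_COUNT",
    "ASSAY_COHORT_SIZE",
    "ASSAY_DISCORDANT_CALLS",
    "ASSAY_EFFECT_FREQ_ANTIOQUIA",
]

#: Individual-SNP clinical annotations out of all variant annotations in
#: the knowledgebase snapshot the survey used.
PHARMGKB_SNP_COUNT = 1995
PHARMGKB_VARIANT_COUNT = 2144

#: Patients genotyped by both exome sequencing and allele-specific PCR.
ASSAY_COHORT_SIZE = 132

#: Discordant (off-diagonal) calls per validated PCR assay, exome calls
#: taken as truth.
ASSAY_DISCORDANT_CALLS = {
    "rs4149056": 3,  # SLCO1B1*5, simvastatin toxicity
    "rs1799853": 2,  # CYP2C9*2, warfarin dosage
    "rs1057910": 0,  # CYP2C9*3, warfarin dosage
}

#: Approximate effect-allele frequencies in Antioquia for the assayed
#: SNPs, used to lay out realistic genotype-class counts in
#: reconstructions of the assay cohort.
ASSAY_EFFECT_FREQ_ANTIOQUIA = {
    "rs4149056": 0.18,
    "rs1799853": 0.12,  # non-effect allele frequency 0.88 for the C>T effect
    "rs1057910": 0.06,
}

# id, drug-response effect, effect-allele frequency in each population,
# ancestry-association slope and P per component, and an opaque flag
# carried from the source table.
_TABLE_ROWS = [
    ("rs776746", "Tacrolimus metabolism", 0.81, 0.32,
     0.31, 4.00e-22, -0.24, 2.20e-21, -0.06, 1.10e-08, True),
    ("rs1799853", "Warfarin dosage", 0.88, 0.97,
     -0.25, 4.20e-04, 0.21, 2.50e-04, 0.04, 8.40e-02, False),
    ("rs9923231", "Warfarin dosage", 0.57, 0.88,
     0.24, 1.00e-10, -0.19, 1.00e-10, -0.04, 2.90e-04, True),
    ("rs4149056", "Simvastatin toxicity", 0.18, 0.05,
     -0.22, 2.80e-04, 0.18, 1.80e-04, 0.00, 6.20e-02, True),
    ("rs4244285", "Clopidogrel efficacy", 0.90, 0.84,
     0.09, 1.36e-01, -0.06, 1.87e-01, -0.02, 1.67e-01, False),
    ("rs2740574", "Tacrolimus metabolism", 0.10, 0.59,
     0.32, 1.20e-22, -0.24, 2.20e-21, -0.06, 1.00e-09, False),
    ("rs11615", "Platin toxicity", 0.48, 0.07,
     -0.30, 9.80e-18, 0.25, 2.50e-19, 0.04, 1.10e-04, False),
    ("rs11212617", "Metformin efficacy", 0.33, 0.74,
     0.28, 5.30e-16, -0.21, 8.30e-15, -0.06, 2.70e-07, False),
    ("rs6977820", "Antipsychotic drug toxicity", 0.25, 0.68,
     0.28, 5.30e-16, -0.19, 1.70e-12, -0.07, 1.20e-11, False),
    ("rs3812718", "Antiepileptic treatment resistance", 0.55, 0.27,
     -0.27, 2.00e-06, 0.21, 8.40e-06, 0.05, 7.74e-04, False),
    ("rs7793837", "Salbutamol efficacy", 0.69, 0.24,
     0.21, 4.30e-17, 0.21, 2.90e-16, 0.05, 2.80e-07, False),
    ("rs1954787", "Antidepressant efficacy", 0.62, 0.21,
     -0.24, 3.00e-13, 0.18, 6.80e-12, 0.05, 4.20e-07, False),
    ("rs1719247", "Simvastatin adverse reaction", 0.54, 0.27,
     -0.21, 3.90e-08, 0.17, 3.50e-08, 0.04, 2.00e-03, False),
]


def colombia_pharmasnps() -> pd.DataFrame:
    """Published pharmaSNPs of interest for Antioquia versus Chocó.

    Indexed by rsID; columns ``effect`` (drug-response label),
    ``f_antioquia``/``f_choco`` (effect-allele frequencies),
    ``beta_*``/``p_*`` per ancestry component, and ``flagged`` (an
    opaque marker carried from the source table).
    """
    cols = ["id", "effect", "f_antioquia", "f_choco",
            "beta_african", "p_african", "beta_european", "p_european",
            "beta_native_american", "p_native_american", "flagged"]
    df = pd.DataFrame(_TABLE_ROWS, columns=cols).set_index("id")
    return df
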