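"""Supervised ancestry estimation and ancestry-association regression.

Ancestry fractions are estimated per individual against a reference
panel of per-component allele frequencies by maximising the binomial
log-likelihood

    L(q) = sum_j [ g_j log p_j(q) + (2 - g_j) log(1 - p_j(q)) ],
    p_j(q) = sum_k q_k f_kj,

over the probability simplex with the multiplicative EM update

    q_k <- (q_k / 2M') sum_j [ g_j f_kj / p_j + (2 - g_j)(1 - f_kj) / (1 - p_j) ],

where M' is the number of non-missing variants. The update keeps q on
the simplex and never decreases L. This is the supervised analogue of
model-based admixture clustering with the ancestral components anchored
by labelled reference frequencies, so component identity (African,
European, Native American) is fixed by the panel rather than recovered
by label switching.

Ancestry association regresses an individual's ancestry fraction y for
one component on the effect-allele dosage x in {0, 1, 2} of one variant,
y = a + b x + e; the slope b (ancestry fraction per effect-allele copy)
is tested with t = b / SE_b on n - 2 degrees of freedom. b > 0 means
carrying the effect allele is associated with more of that ancestry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import GenotypeMatrix

__all__ = [
    "AncestryEstimate",
    "estimate_ancestry",
    "ancestry_association",
]

#: Panel frequencies are clipped to this open interval so the
#: log-likelihood stays finite at fixed sites.
PANEL_CLIP = 1e-6

#: Minimum variants shared between genotypes and panel.
MIN_SHARED_VARIANTS = 10


@dataclass
class AncestryEstimate:
    """Per-individual ancestry fractions with optimisation diagnostics."""

    fractions: pd.DataFrame  # samples x components, rows on the simplex
    loglik: pd.Series  # log-likelihood at the optimum
    n_iter: pd.Series  # EM iterations used
    trace: dict | None = None  # sample -> log-likelihood trajectory

    def __post_init__(self) -> None:
        q = self.fractions.to_numpy()
        if (q < -1e-12).any():
            raise ValueError("ancestry fractions must be non-negative")
        if not np.allclose(q.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("ancestry fractions must sum to 1")


def _em_one(
    g: np.ndarray, F: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, float, int, list[float]]:
    """EM for one individual. g: (M',) dosages; F: (K, M') frequencies."""
    K, Mp = F.shape
    q = np.full(K, 1.0 / K)
    ll_trace: list[float] = []
    ll_prev = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        p = q @ F
        ll = float(np.sum(g * np.log(p) + (2.0 - g) * np.log1p(-p)))
        if not np.isfinite(ll):
            j = int(np.nonzero(~np.isfinite(g * np.log(p) + (2.0 - g) * np.log1p(-p)))[0][0])
            raise FloatingPointError(
                f"non-finite log-likelihood at variant index {j} (p={p[j]})"
            )
        ll_trace.append(ll)
        if ll - ll_prev < tol and it > 1:
            break
        ll_prev = ll
        w = (g / p)[None, :] * F + ((2.0 - g) / (1.0 - p))[None, :] * (1.0 - F)
        q = q * w.sum(axis=1) / (2.0 * Mp)
        q = q / q.sum()  # guard float drift; update is simplex-preserving
    return q, ll_trace[-1], it, ll_trace


def estimate_ancestry(
    gm: GenotypeMatrix,
    panel: pd.DataFrame,
    tol: float = 1e-6,
    max_iter: int = 2000,
    keep_trace: bool = False,
) -> AncestryEstimate:
    """Maximum-likelihood ancestry fractions against a reference panel.

    Parameters
    ----------
    gm
        Genotype matrix; dosages must count the allele whose frequencies
        the panel reports (for simulator output, the alt allele).
    panel
        Variants x components frequency table indexed by variant id.
        Frequencies are clipped to ``[1e-6, 1 - 1e-6]``.
    tol
        EM stops when the log-likelihood gain falls below ``tol``.
    keep_trace
        Record the per-iteration log-likelihood for every individual
        (used to verify EM monotonicity).
    """
    shared = [vid for vid in gm.variant_ids if vid in panel.index]
    if len(shared) < MIN_SHARED_VARIANTS:
        raise ValueError(
            f"only {len(shared)} variants shared between genotypes and panel "
            f"(need >= {MIN_SHARED_VARIANTS})"
        )
    sub = gm.take_variants(shared)
    F_all = np.clip(panel.loc[shared].to_numpy(dtype=float).T, PANEL_CLIP, 1.0 - PANEL_CLIP)
    d = sub.dosage_float()

    rows, lls, its = [], [], []
    trace: dict[str, list[float]] = {}
    for i, s in enumerate(sub.samples):
        ok = ~np.isnan(d[i])
        if ok.sum() < MIN_SHARED_VARIANTS:
            raise ValueError(f"sample {s!r}: fewer than {MIN_SHARED_VARIANTS} called variants")
        q, ll, it, tr = _em_one(d[i, ok], F_all[:, ok], tol, max_iter)
        rows.append(q)
        lls.append(ll)
        its.append(it)
        if keep_trace:
            trace[s] = tr

    index = pd.Index(sub.samples, name="sample")
    return AncestryEstimate(
        fractions=pd.DataFrame(np.vstack(rows), index=index, columns=list(panel.columns)),
        loglik=pd.Series(lls, index=index, name="loglik"),
        n_iter=pd.Series(its, index=index, name="n_iter"),
        trace=trace if keep_trace else None,
    )


def ancestry_association(
    gm: GenotypeMatrix,
    fractions: pd.DataFrame,
    component: str | None = None,
) -> pd.DataFrame:
    """Regress ancestry fractions on effect-allele dosage, per variant.

    ``gm`` must already be oriented so the dosage counts the effect
    allele. With ``component=None`` all panel components are tested.

    Returns one row per (variant, component) with columns ``beta``,
    ``se``, ``t``, ``p``, ``n``, ``flag``. Degenerate cases:

    - constant genotype: slope undefined, row flagged ``constant_x``;
    - constant ancestry fraction: beta 0, p 1 (``constant_y``);
    - perfect non-constant fit (zero residuals): p 0, flagged
      ``degenerate_fit`` rather than dividing by a zero standard error.
    """
    if component is None:
        components = list(fractions.columns)
    else:
        if component not in fractions.columns:
            raise KeyError(f"component {component!r} not in fractions table")
        components = [component]
    common = [s for s in gm.samples if s in fractions.index]
    if len(common) < 3:
        raise ValueError("need at least 3 samples with both genotype and ancestry")
    sub = gm.take_samples(common)
    d = sub.dosage_float()

    rows = []
    for j, vid in enumerate(sub.variant_ids):
        x_all = d[:, j]
        ok = ~np.isnan(x_all)
        n = int(ok.sum())
        for comp in components:
            y = fractions.loc[common, comp].to_numpy(dtype=float)[ok]
            x = x_all[ok]
            rows.append(_ols_row(vid, comp, x, y, n))
    out = pd.DataFrame(
        rows, columns=["id", "component", "beta", "se", "t", "p", "n", "flag"]
    )
    return out


def _ols_row(vid: str, comp: str, x: np.ndarray, y: np.ndarray, n: int) -> tuple:
    if n < 3:
        raise ValueError(f"{vid}: fewer than 3 non-missing genotypes")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        return (vid, comp, np.nan, np.nan, np.nan, np.nan, n, "constant_x")
    if np.ptp(y) == 0.0:
        return (vid, comp, 0.0, 0.0, np.nan, 1.0, n, "constant_y")
    beta = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    resid = y - (y.mean() + beta * (x - x.mean()))
    sse = float(np.sum(resid ** 2))
    df = n - 2
    if sse <= 0.0 or np.isclose(sse, 0.0, atol=1e-30):
        return (vid, comp, beta, 0.0, np.inf, 0.0, n, "degenerate_fit")
    se = float(np.sqrt(sse / df / sxx))
    t = beta / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return (vid, comp, beta, se, t, p, n, "")
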