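"""Allele-frequency statistics, LD pruning, IBS distances, and classical MDS.

F_ST here is Wright's fixation index computed directly from population
allele frequencies, F_ST = sigma^2 / (p-bar (1 - p-bar)), with sigma^2 the
variance of the per-population frequencies around their unweighted mean
p-bar. The population (divide-by-N) variance convention is the default;
the sample (N-1) convention is available via ``ddof=1``. Variants fixed or
absent in every population have an undefined F_ST and are excluded from
set averages.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from skbio import DistanceMatrix

from .model import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "compute_freq",
    "compute_maf",
    "population_frequencies",
    "compute_fst",
    "mean_fst",
    "ld_prune",
    "ibs_distance",
    "classical_mds",
]


def compute_freq(gm: GenotypeMatrix, samples: Sequence[str] | None = None) -> pd.DataFrame:
    """Counted-allele frequency and MAF per variant.

    Missing genotypes are excluded from numerator and denominator alike.
    Variants with no called genotype among the selected samples get NaN
    frequencies and ``defined=False``.

    Returns a DataFrame indexed by variant id with columns
    ``freq`` (counted-allele frequency), ``maf`` (folded to <= 0.5),
    ``n_called``, ``defined``.
    """
    sub = gm if samples is None else gm.take_samples(samples)
    d = sub.dosage_float()
    n_called = np.sum(~np.isnan(d), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        counted = np.nansum(d, axis=0)
        freq = np.where(n_called > 0, counted / (2.0 * np.maximum(n_called, 1)), np.nan)
    maf = np.minimum(freq, 1.0 - freq)
    out = pd.DataFrame(
        {
            "freq": freq,
            "maf": maf,
            "n_called": n_called.astype(int),
            "defined": n_called > 0,
        },
        index=pd.Index(sub.variant_ids, name="id"),
    )
    n_undef = int((~out["defined"]).sum())
    if n_undef:
        logger.warning("compute_freq: %d variants entirely missing", n_undef)
    return out


def compute_maf(gm: GenotypeMatrix, samples: Sequence[str] | None = None) -> pd.Series:
    """Minor allele frequency per variant (folded counted-allele frequency)."""
    return compute_freq(gm, samples)["maf"].rename("maf")


def population_frequencies(
    gm: GenotypeMatrix, sample_groups: Mapping[str, Sequence[str]], folded: bool = False
) -> pd.DataFrame:
    """Per-population counted-allele frequency (or MAF if ``folded``).

    ``sample_groups`` maps population name to its member samples. Returns
    a variants x populations DataFrame.
    """
    cols = {}
    for pop, members in sample_groups.items():
        tab = compute_freq(gm, members)
        cols[pop] = tab["maf"] if folded else tab["freq"]
    return pd.DataFrame(cols)


def compute_fst(freqs: pd.DataFrame | np.ndarray, ddof: int = 0) -> pd.DataFrame:
    """Wright's F_ST per variant from per-population allele frequencies.

    Parameters
    ----------
    freqs
        Variants x populations frequency table (NaN = population
        undefined at that variant; such populations are excluded
        variant-wise).
    ddof
        0 (default) for the population variance convention, 1 for the
        sample variance.

    Returns a DataFrame with columns ``p_mean`` (unweighted mean across
    populations), ``p_var``, ``fst``, ``n_pops``, ``defined``. F_ST is
    undefined (NaN, ``defined=False``) where the mean frequency is 0 or 1.
    """
    arr = np.asarray(freqs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("need frequencies for at least two populations")
    n_pops = np.sum(~np.isnan(arr), axis=1)
    if (n_pops < 2).any():
        bad = int((n_pops < 2).sum())
        logger.warning("compute_fst: %d variants with <2 defined populations", bad)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p_mean = np.nanmean(arr, axis=1)
        p_var = np.nanvar(arr, axis=1, ddof=ddof)
    denom = p_mean * (1.0 - p_mean)
    defined = (n_pops >= 2) & (denom > 0)
    fst = np.full(arr.shape[0], np.nan)
    fst[defined] = p_var[defined] / denom[defined]
    index = freqs.index if isinstance(freqs, pd.DataFrame) else pd.RangeIndex(arr.shape[0])
    return pd.DataFrame(
        {"p_mean": p_mean, "p_var": p_var, "fst": fst,
         "n_pops": n_pops.astype(int), "defined": defined},
        index=index,
    )


def mean_fst(fst_table: pd.DataFrame, variant_ids: Iterable[str] | None = None) -> float:
    """Average F_ST over a variant set, skipping undefined variants."""
    tab = fst_table if variant_ids is None else fst_table.loc[list(variant_ids)]
    vals = tab.loc[tab["defined"], "fst"]
    if vals.empty:
        raise ValueError("no variant with defined F_ST in the requested set")
    return float(vals.mean())


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _pairwise_r2(d: np.ndarray, i: int, j: int) -> float:
    """Squared dosage correlation over samples non-missing in both."""
    ok = ~np.isnan(d[:, i]) & ~np.isnan(d[:, j])
    if ok.sum() < 2:
        return 0.0
    x, y = d[ok, i], d[ok, j]
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0  # zero-variance variant: r2 defined as 0
    r = np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy)
    return float(r * r)


def _greedy_prune(
    d: np.ndarray, maf: np.ndarray, pos: np.ndarray, active: list[int], threshold: float
) -> set[int]:
    """Remove members of pairs with r2 > threshold; returns removed indices.

    Repeatedly drops from the currently worst pair (largest r2; ties by
    scan order) the variant with the lower MAF, breaking MAF ties toward
    the later position. Deterministic.
    """
    removed: set[int] = set()
    alive = [k for k in active if k not in removed]
    r2 = {}
    for a in range(len(alive)):
        for b in range(a + 1, len(alive)):
            r2[(alive[a], alive[b])] = _pairwise_r2(d, alive[a], alive[b])
    while True:
        best, best_pair = threshold, None
        for (i, j), v in r2.items():
            if i in removed or j in removed:
                continue
            if v > best:
                best, best_pair = v, (i, j)
        if best_pair is None:
            return removed
        i, j = best_pair
        if maf[i] < maf[j]:
            removed.add(i)
        elif maf[j] < maf[i]:
            removed.add(j)
        else:
            removed.add(i if pos[i] > pos[j] else j)


def ld_prune(
    gm: GenotypeMatrix,
    r2_threshold: float = 0.5,
    window: int = 50,
    step: int = 5,
) -> list[str]:
    """Greedy windowed linkage-disequilibrium pruning.

    Within each ``window``-variant window (slid by ``step`` variants),
    pairs of retained variants with squared dosage correlation above
    ``r2_threshold`` are reduced by dropping the lower-MAF member
    (position tie-break). Variants must be ordered by (chrom, pos).
    Returns the retained variant ids in input order.
    """
    order = [(v.chrom, v.pos) for v in gm.variants]
    if order != sorted(order):
        raise ValueError("variants must be sorted by (chrom, pos) before pruning")
    d = gm.dosage_float()
    maf = compute_maf(gm).to_numpy()
    pos = np.array([v.pos for v in gm.variants])
    M = gm.n_variants
    removed: set[int] = set()
    start = 0
    while True:
        end = min(start + window, M)
        active = [k for k in range(start, end) if k not in removed]
        removed |= _greedy_prune(d, maf, pos, active, r2_threshold)
        if end >= M:
            break
        start += step
    return [gm.variants[k].id for k in range(M) if k not in removed]


# ---------------------------------------------------------------------------
# IBS distances and classical MDS
# ---------------------------------------------------------------------------

def ibs_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """1 - identity-by-state distance between every pair of genomes.

    d(a, b) = sum_j |g_aj - g_bj| / (2 * number of variants called in
    both). Dosage differences count shared alleles: identical genotypes
    contribute 0, opposite homozygotes contribute 2. Pairs sharing no
    called variant are an error.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least two samples for a distance matrix")
    d = gm.dosage_float()
    called = ~np.isnan(d)
    d0 = np.nan_to_num(d)
    n = gm.n_samples
    dist = np.zeros((n, n))
    for a in range(n):
        both = called[a] & called
        diff = np.abs(d0[a] - d0) * both
        shared = both.sum(axis=1)
        if (shared[np.arange(n) != a] == 0).any():
            b = int(np.nonzero((shared == 0) & (np.arange(n) != a))[0][0])
            raise ValueError(
                f"samples {gm.samples[a]!r} and {gm.samples[b]!r} share no called variant"
            )
        dist[a] = diff.sum(axis=1) / (2.0 * shared)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # exact symmetry against float noise
    return DistanceMatrix(dist, ids=gm.samples)


def classical_mds(
    dm: DistanceMatrix, dims: int = 2, neg_eig_tol: float = 1e-8
) -> pd.DataFrame:
    """Torgerson (classical metric) multidimensional scaling.

    Double-centres the squared distance matrix, takes the top ``dims``
    eigenvectors scaled by the square root of their eigenvalues, orders
    axes by descending eigenvalue, and fixes signs so the first non-zero
    loading of each axis is positive. Negative eigenvalues beyond
    tolerance trigger a warning and are clamped to zero.
    """
    D = dm.data
    n = D.shape[0]
    if dims < 1 or dims > n:
        raise ValueError(f"dims must be in [1, {n}]")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = eigh(B)  # ascending
    vals, vecs = vals[::-1], vecs[:, ::-1]
    sel_vals = vals[:dims].copy()
    scale = max(1.0, float(np.abs(vals).max()))
    if (sel_vals < -neg_eig_tol * scale).any():
        warnings.warn(
            "classical_mds: negative eigenvalue among requested axes; "
            "distances are not Euclidean-embeddable in this dimension",
            RuntimeWarning,
            stacklevel=2,
        )
    sel_vals = np.clip(sel_vals, 0.0, None)
    coords = vecs[:, :dims] * np.sqrt(sel_vals)
    for ax in range(dims):
        col = coords[:, ax]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            coords[:, ax] = -col
    return pd.DataFrame(
        coords,
        index=pd.Index(list(dm.ids), name="sample"),
        columns=[f"axis{k + 1}" for k in range(dims)],
    )
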