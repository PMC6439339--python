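"""Frequency statistics, LD pruning, IBS distance, and classical MDS."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa

from pharmapop.model import MISSING
from pharmapop.popgen import (
    classical_mds,
    compute_freq,
    compute_fst,
    compute_maf,
    ibs_distance,
    ld_prune,
    mean_fst,
    population_frequencies,
)

from conftest import make_gm


class TestMaf:
    @pytest.mark.parametrize(
        "dosages,expected_freq,expected_maf",
        [
            ([0, 1, 2], 0.5, 0.5),
            ([2, 2, 2], 1.0, 0.0),
            ([2, 1, MISSING], 0.75, 0.25),  # missing excluded from both sides
            ([0, 0, 0], 0.0, 0.0),
        ],
    )
    def test_hand_counts(self, dosages, expected_freq, expected_maf):
        gm = make_gm(np.array(dosages, dtype=np.int8)[:, None])
        tab = compute_freq(gm)
        assert tab["freq"].iloc[0] == pytest.approx(expected_freq)
        assert tab["maf"].iloc[0] == pytest.approx(expected_maf)

    def test_entirely_missing_variant_flagged(self):
        gm = make_gm(np.array([[MISSING, 0], [MISSING, 1]], dtype=np.int8))
        tab = compute_freq(gm)
        assert not tab["defined"].iloc[0]
        assert np.isnan(tab["maf"].iloc[0])
        assert tab["defined"].iloc[1]

    def test_sample_subset(self):
        gm = make_gm(np.array([[0], [2], [2]], dtype=np.int8))
        assert compute_maf(gm, samples=["S2", "S3"]).iloc[0] == 0.0


class TestFst:
    @pytest.mark.parametrize(
        "freqs,expected",
        [
            ((0.3, 0.3, 0.3), 0.0),
            ((0.0, 1.0), 1.0),
            ((0.2, 0.4), 0.01 / 0.21),
        ],
    )
    def test_wright_formula_analytic_cases(self, freqs, expected):
        tab = compute_fst(np.array([freqs]))
        assert tab["fst"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_undefined_when_globally_fixed(self):
        tab = compute_fst(np.array([[0.0, 0.0], [1.0, 1.0], [0.5, 0.5]]))
        assert not tab["defined"].iloc[0]
        assert not tab["defined"].iloc[1]
        assert tab["fst"].iloc[2] == 0.0

    def test_single_population_rejected(self):
        with pytest.raises(ValueError, match="two populations"):
            compute_fst(np.array([[0.5]]))

    def test_sample_variance_option(self):
        pop = compute_fst(np.array([[0.2, 0.4]]), ddof=0)["fst"].iloc[0]
        samp = compute_fst(np.array([[0.2, 0.4]]), ddof=1)["fst"].iloc[0]
        assert samp == pytest.approx(2 * pop)

    def test_mean_fst_skips_undefined(self):
        tab = compute_fst(pd.DataFrame([[0.0, 0.0], [0.2, 0.4]],
                                       index=["rsA", "rsB"]))
        assert mean_fst(tab) == pytest.approx(0.01 / 0.21)

    @given(st.lists(st.floats(0.01, 0.99), min_size=2, max_size=6),
           st.randoms(use_true_random=False))
    def test_invariant_to_relabeling_and_complement(self, freqs, rnd):
        arr = np.array([freqs])
        base = compute_fst(arr)["fst"].iloc[0]
        shuffled = list(freqs)
        rnd.shuffle(shuffled)
        assert compute_fst(np.array([shuffled]))["fst"].iloc[0] == \
            pytest.approx(base, rel=1e-9)
        assert compute_fst(1.0 - arr)["fst"].iloc[0] == pytest.approx(base, rel=1e-9)

    def test_mean_fst_monotone_in_simulator_differentiation(self):
        # two pure-component cohorts: more drift -> more differentiation
        from pharmapop.simulate import CohortSpec, SimulationConfig, simulate_cohort, simulate_reference_panel

        means = []
        for F in (0.01, 0.05, 0.2):
            cfg = SimulationConfig(
                M=2000, seed=31, diff=F,
                cohorts=(CohortSpec("p1", 60, (500.0, 0.01, 0.01)),
                         CohortSpec("p2", 60, (0.01, 500.0, 0.01))),
            )
            rng = np.random.default_rng(cfg.seed)
            panel = simulate_reference_panel(cfg, rng)
            gm, manifest, _ = simulate_cohort(cfg, panel, rng)
            groups = {p: manifest.samples_of(p) for p in ("p1", "p2")}
            tab = compute_fst(population_frequencies(gm, groups))
            means.append(mean_fst(tab))
        assert means[0] < means[1] < means[2]


def brute_force_prune(gm, threshold):
    """All-pairs greedy pruning oracle, windowless, written independently."""
    d = gm.dosage_float()
    maf = compute_maf(gm).to_numpy()
    alive = list(range(gm.n_variants))

    def r2(i, j):
        ok = ~np.isnan(d[:, i]) & ~np.isnan(d[:, j])
        x, y = d[ok, i], d[ok, j]
        if x.std() == 0 or y.std() == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1] ** 2)

    while True:
        worst, pair = threshold, None
        for i, j in itertools.combinations(alive, 2):
            v = r2(i, j)
            if v > worst:
                worst, pair = v, (i, j)
        if pair is None:
            break
        i, j = pair
        if maf[i] != maf[j]:
            drop = i if maf[i] < maf[j] else j
        else:
            drop = max(i, j, key=lambda k: gm.variants[k].pos)
        alive.remove(drop)
    return [gm.variants[k].id for k in alive]


class TestLdPrune:
    def test_single_variant_retained(self):
        gm = make_gm(np.array([[0], [1], [2]], dtype=np.int8))
        assert ld_prune(gm) == ["rs1"]

    def test_duplicated_variant_keeps_higher_maf_copy(self):
        # rs1 and rs2 perfectly correlated; rs2 has higher MAF
        col1 = np.array([0, 0, 0, 2, 2, 0])
        col2 = np.array([0, 1, 1, 2, 2, 1])
        gm = make_gm(np.stack([col1, col2], axis=1).astype(np.int8))
        kept = ld_prune(gm, r2_threshold=0.5)
        assert "rs2" in kept and "rs1" not in kept

    def test_equal_maf_tie_drops_later_position(self):
        col = np.array([0, 1, 1, 2], dtype=np.int8)
        gm = make_gm(np.stack([col, col], axis=1))
        assert ld_prune(gm) == ["rs1"]

    def test_zero_variance_variant_never_pruned_by_r2(self):
        mono = np.zeros(6, dtype=np.int8)
        poly = np.array([0, 1, 2, 0, 1, 2], dtype=np.int8)
        gm = make_gm(np.stack([mono, poly], axis=1))
        assert ld_prune(gm) == ["rs1", "rs2"]

    def test_windowed_prune_matches_brute_force_oracle(self):
        # 60 variants incl. one mutually correlated triple inside a window
        rng = np.random.default_rng(17)
        n = 80
        base = rng.integers(0, 3, size=(n, 60)).astype(np.int8)
        src = rng.binomial(2, 0.4, size=n)
        for k, at in enumerate((10, 12, 14)):
            col = src.copy()
            flip = rng.random(n) < 0.03  # r2 ~ 0.9 within the triple
            col[flip] = rng.integers(0, 3, size=flip.sum())
            base[:, at] = col
        gm = make_gm(base)
        assert ld_prune(gm, r2_threshold=0.5, window=50, step=5) == \
            brute_force_prune(gm, 0.5)


class TestIbsDistance:
    def test_identical_genomes_at_zero(self):
        g = np.array([[0, 1, 2], [0, 1, 2]], dtype=np.int8)
        dm = ibs_distance(make_gm(g))
        assert dm[0, 1] == 0.0

    def test_opposite_homozygotes_at_one(self):
        g = np.array([[0, 0], [2, 2]], dtype=np.int8)
        assert ibs_distance(make_gm(g))[0, 1] == 1.0

    def test_hand_count(self):
        g = np.array([[0, 1, 2], [1, 1, 0]], dtype=np.int8)
        assert ibs_distance(make_gm(g))[0, 1] == pytest.approx(0.5)

    def test_missing_excluded_pairwise(self):
        g = np.array([[0, MISSING, 2], [2, 1, 2]], dtype=np.int8)
        # shared variants: rs1, rs3 -> (2 + 0) / 4
        assert ibs_distance(make_gm(g))[0, 1] == pytest.approx(0.5)

    def test_no_shared_variant_is_error(self):
        g = np.array([[0, MISSING], [MISSING, 2]], dtype=np.int8)
        with pytest.raises(ValueError, match="share no called variant"):
            ibs_distance(make_gm(g))


class TestClassicalMds:
    def test_zero_distances_give_zero_coordinates(self):
        dm = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        coords = classical_mds(dm)
        assert np.allclose(coords.to_numpy(), 0.0)

    def test_equilateral_triangle_distances_recovered(self):
        dm = DistanceMatrix(np.ones((3, 3)) - np.eye(3), ids=list("abc"))
        coords = classical_mds(dm, dims=2).to_numpy()
        for i, j in itertools.combinations(range(3), 2):
            d = np.linalg.norm(coords[i] - coords[j])
            assert d == pytest.approx(1.0, abs=1e-9)

    def test_euclidean_configuration_reproduced(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(7, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        coords = classical_mds(DistanceMatrix(D, ids=[str(i) for i in range(7)]))
        D2 = np.linalg.norm(coords.to_numpy()[:, None] - coords.to_numpy()[None, :],
                            axis=-1)
        assert np.allclose(D, D2, atol=1e-9)

    def test_agrees_with_skbio_pcoa(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(9, 3))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        dm = DistanceMatrix(D, ids=[str(i) for i in range(9)])
        ours = classical_mds(dm, dims=2).to_numpy()
        theirs = pcoa(dm, number_of_dimensions=2).samples.to_numpy()
        for ax in range(2):
            col = theirs[:, ax]
            nz = np.nonzero(np.abs(col) > 1e-12)[0]
            if nz.size and col[nz[0]] < 0:
                theirs[:, ax] = -col
        assert np.allclose(ours, theirs, atol=1e-8)

    def test_non_euclidean_input_warns(self):
        # violates the triangle inequality strongly
        D = np.array([[0, 1, 1, 1], [1, 0, 1, 1], [1, 1, 0, 1], [1, 1, 1, 0]],
                     dtype=float)
        D[0, 1] = D[1, 0] = 3.0
        dm = DistanceMatrix(D, ids=list("abcd"))
        with pytest.warns(RuntimeWarning, match="negative eigenvalue"):
            classical_mds(dm, dims=4)

    def test_simulated_cohorts_separate_in_two_dimensions(self, small_study):
        from sklearn.metrics import silhouette_score

        gm = small_study["genotypes"]
        labels = small_study["manifest"].assignments.set_index("sample").loc[
            gm.samples, "population"]
        coords = classical_mds(ibs_distance(gm), dims=2)
        assert silhouette_score(coords.to_numpy(), labels.to_numpy()) > 0
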