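"""Effect-allele divergence statistics and the pharmaSNP screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pharmapop.datasets import colombia_pharmasnps
from pharmapop.divergence import divergence, effect_allele_frequencies, screen_of_interest
from pharmapop.model import MISSING, PharmaAnnotation, PopulationManifest

from conftest import make_gm


def oracle(f1, f2):
    """Independent arithmetic for the three divergence statistics."""
    import math

    R = math.log2(f1 / f2)
    delta = f1 - f2
    return R, delta, math.hypot(R, delta)


def manifest_for(samples, pops):
    return PopulationManifest(pd.DataFrame(
        {"sample": samples, "population": pops, "role": ["study"] * len(samples)}
    ))


class TestEffectAlleleFrequencies:
    def test_hand_counts(self):
        gm = make_gm(np.array([[1], [2], [0], [0]], dtype=np.int8))
        mf = manifest_for(gm.samples, ["P1", "P1", "P2", "P2"])
        eff = effect_allele_frequencies(gm, mf, "P1", "P2")
        assert eff["f_pop1"].iloc[0] == pytest.approx(0.75)
        assert eff["f_pop2"].iloc[0] == 0.0
        assert eff["n1"].iloc[0] == 2

    def test_missing_genotypes_excluded(self):
        gm = make_gm(np.array([[2], [MISSING], [0], [1]], dtype=np.int8))
        mf = manifest_for(gm.samples, ["P1", "P1", "P2", "P2"])
        eff = effect_allele_frequencies(gm, mf, "P1", "P2")
        assert eff["f_pop1"].iloc[0] == 1.0 and eff["n1"].iloc[0] == 1

    def test_unknown_population_is_error(self):
        gm = make_gm(np.array([[1], [1]], dtype=np.int8))
        mf = manifest_for(gm.samples, ["P1", "P1"])
        with pytest.raises(KeyError):
            effect_allele_frequencies(gm, mf, "P1", "P9")

    def test_simulated_frequencies_match_admixture_expectation(self, small_study):
        gm = small_study["genotypes"]
        truth = small_study["truth"]
        panel = small_study["panel"]
        mf = small_study["manifest"]
        eff = effect_allele_frequencies(gm, mf, "Antioquia", "Choco")
        ant = [s for s in gm.samples if s.startswith("Antioquia")]
        q_mean = truth.loc[ant].mean().to_numpy()
        expected = q_mean @ panel
        n = len(ant)
        se = np.sqrt(expected * (1 - expected) / (2 * n))
        ok = np.abs(eff["f_pop1"].to_numpy() - expected) <= 3 * np.maximum(se, 1e-3)
        assert ok.mean() > 0.97  # 3-sigma band

class TestDivergence:
    @pytest.mark.parametrize("rsid", list(colombia_pharmasnps().index))
    def test_published_colombian_rows_match_arithmetic_oracle(self, rsid):
        row = colombia_pharmasnps().loc[rsid]
        out = divergence(row["f_antioquia"], row["f_choco"]).iloc[0]
        R, delta, E = oracle(row["f_antioquia"], row["f_choco"])
        assert out["log2_ratio"] == pytest.approx(R, abs=1e-9)
        assert out["delta"] == pytest.approx(delta, abs=1e-9)
        assert out["euclidean"] == pytest.approx(E, abs=1e-9)

    def test_tacrolimus_snp_worked_example(self):
        out = divergence(0.81, 0.32).iloc[0]
        assert out["delta"] == pytest.approx(0.49)
        assert out["log2_ratio"] == pytest.approx(1.3399, abs=1e-4)
        assert out["euclidean"] == pytest.approx(1.4267, abs=1e-4)

    def test_simvastatin_snp_worked_example(self):
        out = divergence(0.18, 0.05).iloc[0]
        assert out["log2_ratio"] == pytest.approx(np.log2(3.6), abs=1e-9)
        assert out["euclidean"] == pytest.approx(1.8526, abs=1e-4)

    def test_equal_frequencies_at_origin(self):
        out = divergence(0.4, 0.4).iloc[0]
        assert out["log2_ratio"] == 0.0 and out["delta"] == 0.0
        assert out["euclidean"] == 0.0 and out["direction"] == "equal"

    def test_boundary_frequency_continuity_corrected(self):
        out = divergence(0.0, 0.5, n1=10, n2=10).iloc[0]
        fstar = 0.5 / 21.0  # (2*10*0 + 0.5) / (2*10 + 1)
        assert out["log2_ratio"] == pytest.approx(np.log2(fstar / 0.5))
        assert out["delta"] == -0.5  # delta uses the raw frequency
        assert np.isfinite(out["euclidean"])

    def test_boundary_without_sample_count_is_error(self):
        with pytest.raises(ValueError, match="continuity"):
            divergence(1.0, 0.5)

    @given(st.floats(0.01, 0.99), st.floats(0.01, 0.99))
    def test_interior_frequencies_never_corrected(self, f1, f2):
        out = divergence(f1, f2).iloc[0]
        R, delta, E = oracle(f1, f2)
        assert out["log2_ratio"] == pytest.approx(R, abs=1e-12)
        assert out["euclidean"] == pytest.approx(E, abs=1e-12)

    @given(st.floats(0.01, 0.99), st.floats(0.01, 0.99))
    def test_population_swap_antisymmetry(self, f1, f2):
        a = divergence(f1, f2, pop1="P", pop2="Q").iloc[0]
        b = divergence(f2, f1, pop1="Q", pop2="P").iloc[0]
        assert a["log2_ratio"] == pytest.approx(-b["log2_ratio"], abs=1e-12)
        assert a["delta"] == pytest.approx(-b["delta"], abs=1e-12)
        assert a["euclidean"] == pytest.approx(b["euclidean"], abs=1e-12)
        if f1 != f2:
            assert a["direction"] == b["direction"]

    @given(st.floats(0.05, 0.95), st.floats(0.05, 0.95), st.floats(0.05, 0.95))
    def test_composite_dominates_components(self, f1, f2, f3):
        out = divergence(f1, f2).iloc[0]
        assert out["euclidean"] >= max(abs(out["log2_ratio"]), abs(out["delta"])) - 1e-12


def ann(vid, level="1A"):
    return PharmaAnnotation(vid, "GENE", "drug", "dosage", level, "A", "G")


class TestScreen:
    def records(self, e_values, ids=None):
        ids = ids or [f"rs{i}" for i in range(len(e_values))]
        return pd.DataFrame(
            {
                "f_pop1": 0.5, "f_pop2": 0.5,
                "log2_ratio": 0.0, "delta": 0.0,
                "euclidean": e_values,
                "direction": "equal",
            },
            index=pd.Index(ids, name="id"),
        )

    def test_exactly_at_threshold_excluded(self):
        rec = self.records([0.5])
        assert screen_of_interest(rec, [ann("rs0")]).empty

    def test_filters_levels_and_sorts_descending(self):
        rng = np.random.default_rng(0)
        e = list(rng.uniform(0, 2, size=10))
        levels = ["1A", "2B", "3", "4", "1A", "2B", "3", "4", "1A", "2B"]
        rec = self.records(e)
        anns = [ann(f"rs{i}", lv) for i, lv in enumerate(levels)]
        out = screen_of_interest(rec, anns, e_threshold=0.5,
                                 levels=("1A", "1B", "2A", "2B"))
        # brute-force filter oracle
        expect = sorted(
            (i for i in range(10) if e[i] > 0.5 and levels[i] in {"1A", "2B"}),
            key=lambda i: (-e[i], f"rs{i}"),
        )
        assert out["id"].tolist() == [f"rs{i}" for i in expect]
        assert (out["euclidean"].diff().dropna() <= 0).all()

    def test_unannotated_records_excluded(self, caplog):
        rec = self.records([1.0, 1.0], ids=["rsA", "rsB"])
        out = screen_of_interest(rec, [ann("rsA")])
        assert out["id"].tolist() == ["rsA"]

    def test_screen_on_published_colombian_rows_matches_oracle(self):
        # the published table mixes divergence-selected and clinically
        # selected SNPs: the screen must keep exactly the rows whose
        # recomputed composite exceeds the threshold
        tab = colombia_pharmasnps()
        div = divergence(tab["f_antioquia"].to_numpy(),
                         tab["f_choco"].to_numpy(), index=tab.index)
        anns = [ann(vid) for vid in tab.index]
        out = screen_of_interest(div, anns)
        expected = {vid for vid in tab.index
                    if oracle(tab.loc[vid, "f_antioquia"],
                              tab.loc[vid, "f_choco"])[2] > 0.5}
        assert set(out["id"]) == expected
        assert len(expected) == 11  # two low-divergence, assay-motivated rows
        assert (out["euclidean"] > 0.5).all()
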