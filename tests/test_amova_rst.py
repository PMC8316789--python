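"""AMOVA variance components, Rst closed forms, permutation test."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ystrkit.amova_rst import (
    DistanceMatrix,
    RepeatDistanceConfig,
    amova_pair,
    haplotype_squared_distance,
    pairwise_rst,
    permutation_pvalue,
)
from ystrkit.haplotype_io import (
    AlleleValue,
    Haplotype,
    LocusGenotype,
    LocusPanel,
    PopulationDataset,
)
from ystrkit.synthetic_data import two_population_fixture

from conftest import single_locus_dataset

TWO_MARKERS = LocusPanel(name="two", markers=(("DYS998", 1), ("DYS385a/b", 2)))


def hap(sid, single, pair):
    return Haplotype(
        sample_id=sid,
        genotypes=(
            LocusGenotype("DYS998", (AlleleValue(single * 10),)),
            LocusGenotype(
                "DYS385a/b", tuple(AlleleValue(a * 10) for a in pair)
            ),
        ),
    )


class TestSquaredDistance:
    def test_identity_is_zero(self):
        a = hap("a", 13, (13, 17))
        assert haplotype_squared_distance(a, a, TWO_MARKERS) == 0.0

    def test_single_copy_difference(self):
        a, b = hap("a", 13, (13, 17)), hap("b", 16, (13, 17))
        assert haplotype_squared_distance(a, b, TWO_MARKERS) == 9.0

    def test_rank_matched_multi_copy(self):
        a, b = hap("a", 13, (13, 17)), hap("b", 13, (14, 17))
        assert haplotype_squared_distance(a, b, TWO_MARKERS) == 1.0

    def test_exclude_multi_copy_mode(self):
        cfg = RepeatDistanceConfig(multi_copy_mode="exclude")
        a, b = hap("a", 13, (13, 17)), hap("b", 15, (20, 25))
        assert haplotype_squared_distance(a, b, TWO_MARKERS, cfg) == 4.0

    def test_microvariant_modes(self):
        p = LocusPanel(name="m", markers=(("DYS458", 1),))
        a = Haplotype("a", (LocusGenotype("DYS458", (AlleleValue(172),)),))
        b = Haplotype("b", (LocusGenotype("DYS458", (AlleleValue(170),)),))
        numeric = haplotype_squared_distance(a, b, p)
        assert math.isclose(numeric, 0.2**2, abs_tol=1e-12)
        trunc = haplotype_squared_distance(
            a, b, p, RepeatDistanceConfig(microvariant_mode="truncate")
        )
        assert trunc == 0.0

    def test_unequal_copy_number_marker_skipped(self):
        a = hap("a", 13, (13, 17))
        b = Haplotype(
            "b",
            (
                LocusGenotype("DYS998", (AlleleValue(150),)),
                LocusGenotype("DYS385a/b", (AlleleValue(140),)),  # one copy only
            ),
        )
        # multi-copy marker unusable for this pair -> only DYS998 contributes
        assert haplotype_squared_distance(a, b, TWO_MARKERS) == 4.0

    def test_disjoint_usable_markers_error(self):
        p = LocusPanel(name="m", markers=(("DYS458", 1),))
        a = Haplotype("a", (None,))
        b = Haplotype("b", (LocusGenotype("DYS458", (AlleleValue(170),)),))
        with pytest.raises(ValueError, match="no usable marker"):
            haplotype_squared_distance(a, b, p)


class TestAmovaPair:
    def test_duplicated_population_rst_zero(self, one_marker_panel):
        a = single_locus_dataset("A", [10, 11, 12, 13], one_marker_panel)
        b = single_locus_dataset("B", [10, 11, 12, 13], one_marker_panel)
        assert amova_pair(a, b).rst == 0.0

    def test_fixed_disjoint_rst_one(self, one_marker_panel):
        a = single_locus_dataset("A", [10] * 5, one_marker_panel)
        b = single_locus_dataset("B", [20] * 5, one_marker_panel)
        assert amova_pair(a, b).rst == 1.0

    def test_hand_computed_variance_components(self, one_marker_panel):
        """Frozen one-way ANOVA oracle on alleles (10,10,11 | 13,14,14):
        SS_among=50/3, SS_within=4/3, s2a=49/9, s2w=1/3, Rst=49/52."""
        a = single_locus_dataset("A", [10, 10, 11], one_marker_panel)
        b = single_locus_dataset("B", [13, 14, 14], one_marker_panel)
        r = amova_pair(a, b)
        assert math.isclose(r.ss_among, 50 / 3, abs_tol=1e-9)
        assert math.isclose(r.ss_within, 4 / 3, abs_tol=1e-9)
        assert (r.df_among, r.df_within) == (1, 4)
        assert math.isclose(r.sigma2_among, 49 / 9, abs_tol=1e-9)
        assert math.isclose(r.sigma2_within, 1 / 3, abs_tol=1e-9)
        assert math.isclose(r.rst, 49 / 52, abs_tol=1e-12)

    def test_group_mean_anova_oracle_random(self, one_marker_panel):
        """Pairwise-distance route equals the classical group-mean ANOVA
        route on haploid single-locus data (they are algebraically equal)."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            n1, n2 = rng.integers(2, 6, size=2)
            x1 = rng.integers(8, 20, size=n1)
            x2 = rng.integers(8, 20, size=n2)
            r = amova_pair(
                single_locus_dataset("A", x1, one_marker_panel),
                single_locus_dataset("B", x2, one_marker_panel),
                RepeatDistanceConfig(negative_rst="report_raw"),
            )
            x = np.concatenate([x1, x2]).astype(float)
            ss_a = n1 * (x1.mean() - x.mean()) ** 2 + n2 * (x2.mean() - x.mean()) ** 2
            ss_w = ((x1 - x1.mean()) ** 2).sum() + ((x2 - x2.mean()) ** 2).sum()
            assert math.isclose(r.ss_among, ss_a, abs_tol=1e-9)
            assert math.isclose(r.ss_within, ss_w, abs_tol=1e-9)

    @settings(derandomize=True, max_examples=60)
    @given(
        x1=st.lists(st.integers(5, 30), min_size=2, max_size=8),
        x2=st.lists(st.integers(5, 30), min_size=2, max_size=8),
        shift=st.integers(-5, 5),
    )
    def test_ss_conservation_and_shift_invariance(self, x1, x2, shift, one_marker_panel):
        cfg = RepeatDistanceConfig(negative_rst="report_raw")
        a = single_locus_dataset("A", x1, one_marker_panel)
        b = single_locus_dataset("B", x2, one_marker_panel)
        r = amova_pair(a, b, cfg)
        # SS conservation against the total computed directly
        x = np.array(x1 + x2, dtype=float)
        ss_total = ((x - x.mean()) ** 2).sum()
        assert math.isclose(r.ss_among + r.ss_within, ss_total, rel_tol=1e-9,
                            abs_tol=1e-9)
        # global allele shift leaves everything unchanged
        a2 = single_locus_dataset("A", [v + shift + 10 for v in x1], one_marker_panel)
        b2 = single_locus_dataset("B", [v + shift + 10 for v in x2], one_marker_panel)
        r2 = amova_pair(a2, b2, cfg)
        assert math.isclose(r.rst, r2.rst, abs_tol=1e-12) or (
            math.isnan(r.rst) and math.isnan(r2.rst)
        )

    def test_scaling_differences_leaves_rst_unchanged(self, one_marker_panel):
        a1 = single_locus_dataset("A", [10, 10, 11, 12], one_marker_panel)
        b1 = single_locus_dataset("B", [13, 14, 14, 15], one_marker_panel)
        # triple every deviation from 10
        a3 = single_locus_dataset("A", [10, 10, 13, 16], one_marker_panel)
        b3 = single_locus_dataset("B", [19, 22, 22, 25], one_marker_panel)
        r1, r3 = amova_pair(a1, b1), amova_pair(a3, b3)
        assert math.isclose(r3.ss_among, 9 * r1.ss_among, rel_tol=1e-12)
        assert math.isclose(r3.ss_within, 9 * r1.ss_within, rel_tol=1e-12)
        assert math.isclose(r1.rst, r3.rst, abs_tol=1e-12)

    def test_sample_reordering_invariance(self, one_marker_panel):
        a = single_locus_dataset("A", [10, 12, 11, 10], one_marker_panel)
        a_r = single_locus_dataset("A", [10, 10, 11, 12], one_marker_panel, prefix="r")
        b = single_locus_dataset("B", [14, 13, 15, 13], one_marker_panel)
        assert math.isclose(
            amova_pair(a, b).rst, amova_pair(a_r, b).rst, abs_tol=1e-12
        )

    def test_small_population_rejected(self, one_marker_panel):
        a = single_locus_dataset("A", [10], one_marker_panel)
        b = single_locus_dataset("B", [12, 13], one_marker_panel)
        with pytest.raises(ValueError, match="n >= 2"):
            amova_pair(a, b)

    def test_zero_total_variance_gives_zero(self, one_marker_panel):
        a = single_locus_dataset("A", [10, 10], one_marker_panel)
        b = single_locus_dataset("B", [10, 10], one_marker_panel)
        assert amova_pair(a, b).rst == 0.0


class TestPairwiseMatrix:
    def test_symmetry_and_duplicates(self, one_marker_panel):
        a = single_locus_dataset("A", [10, 11, 12], one_marker_panel)
        a2 = single_locus_dataset("Acopy", [10, 11, 12], one_marker_panel)
        b = single_locus_dataset("B", [15, 16, 17], one_marker_panel)
        m = pairwise_rst([a, a2, b])
        assert m[("A", "Acopy")] == 0.0
        assert m[("A", "B")] == m[("Acopy", "B")]
        assert np.allclose(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 0)

    def test_two_datasets(self, one_marker_panel):
        a = single_locus_dataset("A", [10, 10, 11], one_marker_panel)
        b = single_locus_dataset("B", [13, 14, 14], one_marker_panel)
        m = pairwise_rst([a, b])
        assert m.values.shape == (2, 2)
        assert math.isclose(m[("A", "B")], 49 / 52, abs_tol=1e-12)

    def test_needs_two_populations(self, one_marker_panel):
        with pytest.raises(ValueError):
            pairwise_rst([single_locus_dataset("A", [10, 11], one_marker_panel)])

    def test_tsv_and_phylip_round_trip(self, tmp_path, one_marker_panel):
        a = single_locus_dataset("A", [10, 10, 11], one_marker_panel)
        b = single_locus_dataset("B", [13, 14, 14], one_marker_panel)
        c = single_locus_dataset("C", [20, 21, 22], one_marker_panel)
        m = pairwise_rst([a, b, c])
        t = tmp_path / "m.tsv"
        m.write_tsv(t)
        back = DistanceMatrix.read_tsv(t)
        assert back.labels == m.labels
        assert np.allclose(back.values, m.values, atol=1e-12)
        p = tmp_path / "m.phy"
        m.write_phylip(p)
        back_p = DistanceMatrix.read_phylip(p)
        assert back_p.labels == m.labels
        assert np.allclose(back_p.values, m.values, atol=1e-6)


class TestPermutation:
    def test_same_seed_same_p(self, one_marker_panel):
        rng = np.random.default_rng(3)
        a = single_locus_dataset("A", rng.integers(10, 14, 8), one_marker_panel)
        b = single_locus_dataset("B", rng.integers(12, 16, 8), one_marker_panel)
        p1 = permutation_pvalue(a, b, n_perm=199, seed=7)
        p2 = permutation_pvalue(a, b, n_perm=199, seed=7)
        assert p1 == p2

    def test_disjoint_fixed_populations_significant(self):
        a, b = two_population_fixture(3, n_per_pop=10)
        assert permutation_pvalue(a, b, n_perm=999, seed=1) <= 0.01

    def test_null_p_values_not_significant(self, one_marker_panel):
        """Identical generating process: p should rarely be small."""
        rng = np.random.default_rng(11)
        big = 0
        runs = 10
        for i in range(runs):
            pool = rng.integers(10, 18, size=24)
            a = single_locus_dataset("A", pool[:12], one_marker_panel)
            b = single_locus_dataset("B", pool[12:], one_marker_panel)
            p = permutation_pvalue(a, b, n_perm=199, seed=100 + i)
            big += p > 0.05
        assert big >= runs - 1

    def test_minimum_permutations_enforced(self, one_marker_panel):
        a = single_locus_dataset("A", [10, 11], one_marker_panel)
        b = single_locus_dataset("B", [12, 13], one_marker_panel)
        with pytest.raises(ValueError):
            permutation_pvalue(a, b, n_perm=50)
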