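"""Relatedness estimation: core-site selection, genomic similarity,
pooling, and the FST-like coefficient."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gutkin.errors import DataError, UndefinedRelatednessError
from gutkin.relatedness import (
    build_relatedness_table,
    genomic_similarity,
    pooled_frequencies,
    relatedness,
    select_core_sites,
)
from gutkin.simulate import IslandModelParams, simulate_island_model

from conftest import make_panel


def brute_force_similarity(freqs):
    """Independent oracle: average pairwise identity over all ordered
    haplotype pairs drawn with replacement from the per-site frequency
    distribution (sites unlinked)."""
    freqs = np.asarray(freqs, dtype=float)
    n_sites = freqs.shape[0]
    haplotypes = list(itertools.product(range(4), repeat=n_sites))
    probs = np.array(
        [np.prod([freqs[s, a] for s, a in enumerate(h)]) for h in haplotypes]
    )
    total = 0.0
    for (hi, pi), (hj, pj) in itertools.product(zip(haplotypes, probs), repeat=2):
        if pi == 0 or pj == 0:
            continue
        s_ij = np.mean([a == b for a, b in zip(hi, hj)])
        total += pi * pj * s_ij
    return total


class TestCoreSites:
    def test_strict_prevalence_threshold(self, panel_factory):
        # 10 hosts; site 0 present in all, site 1 in 9/10 (exactly 0.90, dropped)
        freqs = np.zeros((10, 2, 4))
        freqs[:, :, 0] = 1.0
        presence = np.ones((10, 2), dtype=bool)
        presence[0, 1] = False
        panel = panel_factory(freqs, presence=presence)
        mask = select_core_sites(panel, 0.90)
        assert mask.tolist() == [True, False]

    def test_zero_threshold_keeps_any_present_site(self, panel_factory):
        freqs = np.zeros((4, 3, 4))
        freqs[:, :, 0] = 1.0
        presence = np.zeros((4, 3), dtype=bool)
        presence[0, 0] = True
        presence[:, 1] = True
        panel = panel_factory(freqs, presence=presence)
        assert select_core_sites(panel, 0.0).tolist() == [True, True, False]


class TestGenomicSimilarity:
    @pytest.mark.parametrize(
        "freqs, expected",
        [
            ([[1, 0, 0, 0]], 1.0),
            ([[0.25, 0.25, 0.25, 0.25]], 0.25),
            ([[0.8, 0.2, 0, 0], [0.5, 0.5, 0, 0]], 0.59),
        ],
    )
    def test_hand_examples(self, freqs, expected):
        assert genomic_similarity(np.array(freqs)) == pytest.approx(expected)

    def test_matches_bruteforce_pair_enumeration(self):
        # haplotype-pair identity (definition) == mean of sum(p^2) (site form)
        rng = np.random.default_rng(11)
        for _ in range(5):
            freqs = rng.dirichlet(np.ones(4) * 0.7, size=3)
            assert genomic_similarity(freqs) == pytest.approx(
                brute_force_similarity(freqs), abs=1e-12
            )

    def test_empty_mask_rejected(self):
        with pytest.raises(DataError):
            genomic_similarity(np.array([[1.0, 0, 0, 0]]), np.array([False]))

    def test_bias_corrected_removes_self_pairing(self):
        # two individuals of ten carry the alternative allele
        freqs = np.array([[0.8, 0.2, 0.0, 0.0]])
        plain = genomic_similarity(freqs)
        corrected = genomic_similarity(freqs, depth=np.array([10.0]), bias_corrected=True)
        assert plain == pytest.approx(0.68)
        assert corrected == pytest.approx((10 * 0.68 - 1) / 9)
        assert corrected < plain


class TestPooling:
    def test_equal_depth_symmetry(self, panel_factory):
        freqs = np.zeros((2, 1, 4))
        freqs[0, 0, 0] = 1.0
        freqs[1, 0, 1] = 1.0
        pooled, _ = pooled_frequencies(panel_factory(freqs))
        assert pooled[0, 0] == pytest.approx(0.5)

    def test_depth_weighting(self, panel_factory):
        freqs = np.zeros((2, 1, 4))
        freqs[0, 0, 0] = 1.0
        freqs[1, 0, 1] = 1.0
        depth = np.array([[3.0], [1.0]])
        pooled, _ = pooled_frequencies(panel_factory(freqs, depth=depth))
        assert pooled[0, 0] == pytest.approx(0.75)
        unweighted, _ = pooled_frequencies(
            panel_factory(freqs, depth=depth), depth_weighted=False
        )
        assert unweighted[0, 0] == pytest.approx(0.5)

    def test_single_present_host_is_identity(self, panel_factory):
        freqs = np.zeros((2, 1, 4))
        freqs[0, 0] = [0.6, 0.4, 0, 0]
        freqs[1, 0] = [1.0, 0, 0, 0]
        presence = np.array([[True], [False]])
        pooled, _ = pooled_frequencies(panel_factory(freqs, presence=presence))
        assert pooled[0].tolist() == pytest.approx([0.6, 0.4, 0, 0])


class TestRelatednessCoefficient:
    @pytest.mark.parametrize(
        "s_w, s_a, expected",
        [(1.0, 0.5, 1.0), (0.7, 0.7, 0.0), (0.8, 0.6, 0.5)],
    )
    def test_hand_examples(self, s_w, s_a, expected):
        assert relatedness(s_w, s_a) == pytest.approx(expected)

    def test_global_monomorphism_is_undefined(self):
        with pytest.raises(UndefinedRelatednessError):
            relatedness(1.0, 1.0)

    @given(
        st.floats(0.0, 1.0),
        st.floats(0.0, 0.999),
    )
    @settings(max_examples=50, derandomize=True)
    def test_never_exceeds_one(self, s_w, s_a):
        assert relatedness(s_w, s_a) <= 1.0 + 1e-12


class TestInvariances:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_allele_relabeling_and_site_order(self, seed):
        """r is unchanged by permuting allele labels per panel and by
        reordering sites."""
        rng = np.random.default_rng(seed)
        freqs = rng.dirichlet(np.ones(4), size=(4, 6))
        panel = make_panel(freqs)
        base = build_relatedness_table([panel], min_core_sites=1).table

        perm_alleles = rng.permutation(4)
        perm_sites = rng.permutation(6)
        shuffled = make_panel(freqs[:, perm_sites][:, :, perm_alleles])
        out = build_relatedness_table([shuffled], min_core_sites=1).table
        np.testing.assert_allclose(out["r"], base["r"], atol=1e-12)

    def test_identical_hosts_give_zero(self):
        freqs = np.tile(
            np.array([[0.6, 0.4, 0.0, 0.0], [0.3, 0.3, 0.2, 0.2]]), (3, 1, 1)
        )
        table = build_relatedness_table([make_panel(freqs)], min_core_sites=1).table
        np.testing.assert_allclose(table["r"], 0.0, atol=1e-12)

    def test_host_matching_pool_has_zero_r(self):
        # two hosts symmetric around the pool plus one host at the pooled
        # frequency: the matching host's r is 0
        freqs = np.zeros((3, 2, 4))
        freqs[0, :, :2] = [0.8, 0.2]
        freqs[1, :, :2] = [0.2, 0.8]
        freqs[2, :, :2] = [0.5, 0.5]
        table = build_relatedness_table([make_panel(freqs)], min_core_sites=1).table
        assert table.loc[table["host"] == "h2", "r"].iloc[0] == pytest.approx(0.0, abs=1e-12)


class TestBuildTable:
    def test_single_host_species_dropped(self, panel_factory):
        freqs = np.zeros((1, 5, 4))
        freqs[:, :, 0] = 1.0
        result = build_relatedness_table(
            [panel_factory(freqs, species="lonely")], min_core_sites=1, min_hosts=2
        )
        assert result.table.empty
        assert result.dropped and result.dropped[0][0] == "lonely"

    def test_small_core_genome_dropped(self, panel_factory):
        rng = np.random.default_rng(0)
        freqs = rng.dirichlet(np.ones(4), size=(3, 10))
        result = build_relatedness_table([panel_factory(freqs)], min_core_sites=50)
        assert result.table.empty
        assert "core sites" in result.dropped[0][1]

    def test_monomorphic_pool_dropped_with_reason(self, panel_factory):
        freqs = np.zeros((3, 5, 4))
        freqs[:, :, 0] = 1.0
        result = build_relatedness_table([panel_factory(freqs)], min_core_sites=1)
        assert result.table.empty
        assert "monomorphic" in result.dropped[0][1]


class TestIslandModelBehaviour:
    def test_full_mixing_relatedness_near_zero(self):
        panel = simulate_island_model(
            IslandModelParams(
                n_demes=20, deme_size=50, migration=1.0, mutation=1e-4,
                n_sites=300, n_generations=30, burn_in=50, seed=5,
            )
        )
        res = build_relatedness_table([panel], min_core_sites=1, bias_corrected=True)
        assert abs(res.summary["mean_r"].iloc[0]) < 0.02

    def test_mean_relatedness_decreases_with_migration(self):
        """Equilibrium relatedness is monotone decreasing over a
        migration grid, averaged over replicate simulations."""
        grid = [0.01, 0.05, 0.2]
        means = []
        for m in grid:
            reps = []
            for rep in range(10):
                panel = simulate_island_model(
                    IslandModelParams(
                        n_demes=10, deme_size=10, migration=m, mutation=1e-4,
                        n_sites=120, n_generations=20, seed=1000 + rep,
                    )
                )
                res = build_relatedness_table(
                    [panel], min_core_sites=1, bias_corrected=True
                )
                reps.append(res.summary["mean_r"].iloc[0])
            means.append(np.mean(reps))
        assert means[0] > means[1] > means[2]
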