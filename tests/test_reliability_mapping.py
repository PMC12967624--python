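import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from thorson.reliability_mapping import (
    OccurrenceTable,
    chao1,
    band_summary,
    latitude_bands,
    n_min,
    proportion_permutation_test,
    reference_proportion,
    reliability_mask,
    stack_proportions,
)

STUDY_POOL = np.array(["non_pelagic"] * 33 + ["planktotrophic"] * 51
                      + ["lecithotrophic"] * 10)


class TestStackProportions:
    def test_counting(self):
        masks = [np.array([[True]]), np.array([[True]]),
                 np.array([[True]]), np.array([[True]])]
        modes = ["non_pelagic", "non_pelagic", "planktotrophic", "planktotrophic"]
        pm = stack_proportions(masks, modes)
        assert pm.richness[0, 0] == 4
        assert pm.prop_np[0, 0] == 0.5 and pm.prop_pt[0, 0] == 0.5
        assert pm.prop_lc[0, 0] == 0.0

    def test_single_species_pixel_and_empty_pixel(self):
        masks = [np.array([[True, False]])]
        pm = stack_proportions(masks, ["lecithotrophic"])
        assert pm.prop_lc[0, 0] == 1.0
        assert np.isnan(pm.prop_lc[0, 1])

    def test_proportions_sum_to_one_where_occupied(self, world):
        pm = stack_proportions(world.dists, world.species["mode"].to_numpy())
        occ = pm.richness > 0
        total = pm.prop_np[occ] + pm.prop_pt[occ] + pm.prop_lc[occ]
        assert np.allclose(total, 1.0, atol=1e-9)

    def test_unknown_mode_errors(self):
        with pytest.raises(ValueError, match="mode"):
            stack_proportions([np.array([[True]])], ["benthic"])


def test_reference_proportion_of_study_pool():
    assert reference_proportion(STUDY_POOL) == pytest.approx(33 / 94)


class TestNmin:
    def test_study_conditions_give_twenty(self):
        assert n_min(0.351, 0.30, 0.05, 0.8) == 20

    def test_half_half_case(self):
        # ((1.95996+0.84162)/0.5)^2 * 0.25 = 7.85 -> ceil 8
        assert n_min(0.5, 0.5, 0.05, 0.8) == 8

    def test_degenerate_proportions(self):
        assert n_min(0.0, 0.3) == 0
        assert n_min(1.0, 0.3) == 0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            n_min(0.3, 0.0)
        with pytest.raises(ValueError):
            n_min(1.2, 0.3)

    @settings(max_examples=40)
    @given(st.floats(0.05, 0.95), st.floats(0.05, 0.45), st.floats(0.05, 0.45))
    def test_monotone_in_deltap_and_maximised_at_half(self, P, d1, d2):
        lo, hi = sorted((d1, d2))
        assert n_min(P, lo) >= n_min(P, hi)
        assert n_min(0.5, lo) >= n_min(P, lo)


class TestChao1:
    def test_examples(self):
        assert chao1(10, 4, 2) == 14.0
        assert chao1(5, 3, 0) == 8.0  # f2 = 0 fallback f1(f1-1)/2
        assert chao1(7, 0, 0) == 7.0

    def test_against_skbio_oracle_on_abundance_vectors(self, rng):
        from skbio.diversity.alpha import chao1 as skbio_chao1
        for _ in range(500):
            counts = rng.poisson(rng.uniform(0.2, 3.0),
                                 size=rng.integers(5, 60))
            if counts.sum() == 0:
                continue
            s_obs = int((counts > 0).sum())
            f1 = int((counts == 1).sum())
            f2 = int((counts == 2).sum())
            ours = chao1(s_obs, f1, f2)
            theirs = float(skbio_chao1(counts, bias_corrected=False))
            assert ours == pytest.approx(theirs)

    def test_never_below_observed(self, rng):
        for _ in range(200):
            s = int(rng.integers(1, 50))
            f1 = int(rng.integers(0, s + 1))
            f2 = int(rng.integers(0, s - f1 + 1))
            est = chao1(s, f1, f2)
            assert est >= s
            if f1 == 0:
                assert est == s

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            chao1(5, -1, 0)


class TestReliabilityMask:
    def make_occ(self, counts):
        counts = np.asarray(counts)
        lats = 25.25 + 0.5 * np.arange(counts.shape[1])
        lons = 0.25 + 0.5 * np.arange(counts.shape[2])
        return OccurrenceTable(counts, lats, lons)

    def test_flags(self):
        # pixel 0: every species seen 3 times (complete); pixel 1: all singletons
        counts = np.zeros((10, 1, 2), dtype=int)
        counts[:, 0, 0] = 3
        counts[:, 0, 1] = 1
        occ = self.make_occ(counts)
        richness = np.array([[25, 25]])
        mask = reliability_mask(occ, richness, nmin=20)
        assert mask.rel_chao[0, 0] == 1.0 and mask.passes_survey[0, 0]
        assert not mask.passes_survey[0, 1]  # rel-chao blows up on singletons

    def test_nmin_boundary(self):
        counts = np.zeros((5, 1, 2), dtype=int)
        counts[:, 0, :] = 3
        occ = self.make_occ(counts)
        mask = reliability_mask(occ, np.array([[19, 20]]), nmin=20)
        assert not mask.passes_nmin[0, 0] and mask.passes_nmin[0, 1]

    def test_unsurveyed_pixel_fails_not_errors(self):
        counts = np.zeros((5, 1, 1), dtype=int)
        occ = self.make_occ(counts)
        mask = reliability_mask(occ, np.array([[30]]), nmin=20)
        assert not mask.passes_survey[0, 0]


class TestOccurrenceBinning:
    def test_from_records_round_trip(self):
        lats = np.array([25.25, 25.75])
        lons = np.array([0.25, 0.75])
        records = pd.DataFrame({
            "species": ["a", "a", "b", "b", "b"],
            "decimalLatitude": [25.1, 25.2, 25.6, 25.6, 25.9],
            "decimalLongitude": [0.1, 0.2, 0.6, 0.6, 0.9],
        })
        occ = OccurrenceTable.from_records(records, lats, lons)
        assert occ.counts.sum() == 5
        assert occ.S_obs[0, 0] == 1  # species a twice in the SW pixel
        assert occ.f2[0, 0] == 1
        assert occ.counts[:, 1, 1].sum() == 3  # all b records in the NE pixel

    def test_invariants_on_world(self, world):
        occ = world.occurrences
        assert np.all(occ.S_obs >= occ.f1 + occ.f2)
        total = occ.counts.sum(axis=0)
        assert np.all(occ.f1 + 2 * occ.f2 <= total)


class TestBandSummary:
    def test_homogeneous_world_methods_agree(self):
        # every species occupies every pixel: all methods give the pool share
        ny, nx = 90, 4
        masks = [np.ones((ny, nx), bool)] * 6
        modes = ["non_pelagic"] * 3 + ["planktotrophic"] * 3
        lats = 25.25 + 0.5 * np.arange(ny)
        pm = stack_proportions(masks, modes, lats=lats,
                               lons=0.25 + 0.5 * np.arange(nx))
        pooled = band_summary(pm, "pooled", dists=masks, modes=modes)
        pixel = band_summary(pm, "pixel_mean")
        for table in (pooled, pixel):
            np_rows = table[table["mode"] == "non_pelagic"]
            assert np.allclose(np_rows["proportion"], 0.5)

    def test_pooled_proportions_sum_to_one(self, world):
        modes = world.species["mode"].to_numpy()
        pm = stack_proportions(world.dists, modes, lats=world.grid.lats,
                               lons=world.grid.lons)
        pooled = band_summary(pm, "pooled", dists=world.dists, modes=modes)
        sums = pooled.groupby("band_lo")["proportion"].sum()
        assert np.allclose(sums.dropna(), 1.0)

    def test_pooled_vs_pixel_mean_divergence(self):
        # one pixel of pure non-pelagic among many pure-planktotrophic pixels
        ny, nx = 10, 10
        m_np = np.zeros((ny, nx), bool)
        m_np[0, 0] = True
        m_pt = np.ones((ny, nx), bool)
        m_pt[0, 0] = False
        lats = np.full(ny, 27.0) + 0.1 * np.arange(ny)
        pm = stack_proportions([m_np, m_pt], ["non_pelagic", "planktotrophic"],
                               lats=lats, lons=np.arange(nx, dtype=float))
        bands = [(25.0, 30.0)]
        pooled = band_summary(pm, "pooled", dists=[m_np, m_pt],
                              modes=["non_pelagic", "planktotrophic"],
                              bands=bands)
        pixel = band_summary(pm, "pixel_mean", bands=bands)
        p_pool = pooled[pooled["mode"] == "non_pelagic"]["proportion"].iloc[0]
        p_pix = pixel[pixel["mode"] == "non_pelagic"]["proportion"].iloc[0]
        assert p_pool == pytest.approx(0.5)
        assert p_pix == pytest.approx(1 / 100)

    def test_empty_bands_reported_not_dropped(self, world):
        modes = world.species["mode"].to_numpy()
        pm = stack_proportions(world.dists, modes, lats=world.grid.lats,
                               lons=world.grid.lons)
        table = band_summary(pm, "pixel_mean")
        assert len(table) == len(latitude_bands()) * 3


class TestPermutationTest:
    def test_observed_at_reference_gives_p_one(self):
        ref = reference_proportion(STUDY_POOL)
        p = proportion_permutation_test(20, ref, STUDY_POOL, seed=0)
        assert p == 1.0

    def test_whole_pool_subset_is_degenerate(self):
        p = proportion_permutation_test(len(STUDY_POOL),
                                        reference_proportion(STUDY_POOL),
                                        STUDY_POOL, seed=0)
        assert p == 1.0

    def test_extreme_pixel_detected(self):
        # 20 species, all non-pelagic, from a 35%-non-pelagic pool
        p = proportion_permutation_test(20, 1.0, STUDY_POOL, seed=1)
        tail = stats.hypergeom.sf(19, 94, 33, 20)  # oracle: ~1e-10
        assert tail < 1e-6
        assert p < 0.05

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            proportion_permutation_test(20, 0.5, STUDY_POOL, n_perm=0)
        with pytest.raises(ValueError):
            proportion_permutation_test(100, 0.5, STUDY_POOL)
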