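"""Methylation-state scoring, levels, contexts, filters and markers."""

import numpy as np
import pytest

from msapop import (
    BandMatrix,
    MethylationState,
    SampleMetadata,
    SiteFilterFlag,
    build_marker_matrix,
    call_site,
    context_fractions,
    filter_genetic_sites,
    filter_tmd_transposition,
    methylation_level,
    methylation_profile,
    population_mean_level,
    qc_exclude_samples,
    score_matrix,
)
from msapop.errors import AssayMismatchError, UndefinedStatisticError
from msapop.scoring import MethylationCallMatrix

from conftest import random_band_matrix


def calls_from_states(states, assay="MSAP", te_family=None):
    states = np.asarray(states, dtype=np.int8)
    return MethylationCallMatrix(
        band_ids=[f"b{i}" for i in range(states.shape[0])],
        sample_ids=[f"s{j}" for j in range(states.shape[1])],
        states=states,
        assay=assay,
        te_family=te_family,
    )


class TestTruthTable:
    @pytest.mark.parametrize("h,m,state", [
        (1, 1, MethylationState.UNMETHYLATED),
        (0, 1, MethylationState.CG_INTERNAL),
        (1, 0, MethylationState.CHG_HEMI),
        (0, 0, MethylationState.UNINFORMATIVE),
    ])
    def test_exhaustive(self, h, m, state):
        assert call_site(h, m) is state

    @pytest.mark.parametrize("h,m", [(-1, 1), (1, -1), (-1, -1)])
    def test_missing_lane_gives_missing_state(self, h, m):
        assert call_site(h, m) is None

    def test_score_matrix_agrees_with_per_cell_calls(self, rng):
        bands = random_band_matrix(rng, n_bands=50, n_samples=100,
                                   missing_frac=0.1)
        calls = score_matrix(bands)
        for i in range(bands.n_bands):
            for j in range(bands.n_samples):
                expected = call_site(bands.h[i, j], bands.m[i, j])
                got = calls.states[i, j]
                assert (got == -1) if expected is None else (got == expected)

    def test_state_counts_are_conserved(self, rng):
        bands = random_band_matrix(rng, n_bands=40, n_samples=9,
                                   missing_frac=0.2)
        s = score_matrix(bands).states
        total = sum(int((s == v).sum()) for v in (-1, 0, 1, 2, 3))
        assert total == bands.n_bands * bands.n_samples

    def test_all_missing_lane_gives_all_missing_states(self):
        bands = BandMatrix(["b1", "b2"], ["s1"], [[-1], [-1]], [[1], [0]])
        assert (score_matrix(bands).states == -1).all()


class TestMethylationLevel:
    def test_half_methylated(self):
        calls = calls_from_states([[0], [1], [2], [0]])
        assert methylation_level(calls, "s0") == 0.5

    def test_all_unmethylated_is_zero(self):
        calls = calls_from_states([[0]] * 5)
        assert methylation_level(calls, "s0") == 0.0

    def test_all_chg_is_one(self):
        calls = calls_from_states([[2]] * 5)
        assert methylation_level(calls, "s0") == 1.0

    def test_zero_scored_sites_is_an_error(self):
        calls = calls_from_states([[-1], [3]])
        with pytest.raises(UndefinedStatisticError):
            methylation_level(calls, "s0")

    def test_profile_identity(self):
        calls = calls_from_states([[0], [1], [2], [2], [3]])
        prof = methylation_profile(calls, "s0")
        assert prof.n_methylation_polymorphic == prof.n_cg + prof.n_chg == 3
        assert prof.level == prof.n_methylation_polymorphic / prof.n_scored_sites
        assert prof.n_scored_sites == 4  # (0,0) excluded by default

    def test_including_uninformative_never_increases_level(self, rng):
        states = rng.integers(0, 4, size=(60, 1)).astype(np.int8)
        calls = calls_from_states(states)
        strict = methylation_level(calls, "s0")
        loose = methylation_level(calls, "s0", include_uninformative=True)
        assert loose <= strict
        assert 0.0 <= loose <= strict <= 1.0


class TestContextFractions:
    def test_hand_counts(self):
        calls = calls_from_states([[2], [2], [2], [1]])
        assert context_fractions(calls) == (0.75, 0.25)

    def test_cg_only(self):
        calls = calls_from_states([[1]] * 5)
        chg, cg = context_fractions(calls)
        assert (chg, cg) == (0.0, 1.0)

    def test_fractions_sum_to_one(self, rng):
        states = rng.integers(0, 4, size=(80, 6)).astype(np.int8)
        chg, cg = context_fractions(calls_from_states(states))
        assert chg + cg == pytest.approx(1.0)

    def test_no_polymorphic_sites_is_an_error(self):
        calls = calls_from_states([[0], [3]])
        with pytest.raises(UndefinedStatisticError):
            context_fractions(calls)


class TestGeneticFilter:
    def test_concordant_presence_absence_is_genetic(self):
        # (1,1),(0,0),(1,1): presence varies, never H != M
        calls = calls_from_states([[0, 3, 0]])
        assert filter_genetic_sites(calls)[0] == SiteFilterFlag.GENETIC_AFLP

    def test_lane_polymorphism_is_retained(self):
        calls = calls_from_states([[0, 2]])
        assert filter_genetic_sites(calls)[0] == SiteFilterFlag.RETAINED

    def test_monomorphic_unmethylated_is_retained(self):
        calls = calls_from_states([[0, 0, 0]])
        assert filter_genetic_sites(calls)[0] == SiteFilterFlag.RETAINED

    def test_never_flags_a_site_with_methylation_calls(self, rng):
        states = rng.integers(0, 4, size=(200, 8)).astype(np.int8)
        calls = calls_from_states(states)
        flags = filter_genetic_sites(calls)
        has_meth = ((states == 1) | (states == 2)).any(axis=1)
        assert not (flags[has_meth] == SiteFilterFlag.GENETIC_AFLP).any()


class TestTmdFilter:
    def test_transposition_pattern_excluded(self):
        calls = calls_from_states([[0, 3]], assay="TMD", te_family="Veju")
        flag = filter_tmd_transposition(calls)[0]
        assert flag == SiteFilterFlag.TRANSPOSITION_NO_METH

    def test_methylation_polymorphism_retained(self):
        calls = calls_from_states([[1, 0]], assay="TMD", te_family="Veju")
        assert filter_tmd_transposition(calls)[0] == SiteFilterFlag.RETAINED

    def test_monomorphic_site_retained(self):
        calls = calls_from_states([[0, 0]], assay="TMD", te_family="Thalos")
        assert filter_tmd_transposition(calls)[0] == SiteFilterFlag.RETAINED

    def test_msap_matrix_is_an_assay_mismatch(self):
        calls = calls_from_states([[0, 3]])
        with pytest.raises(AssayMismatchError):
            filter_tmd_transposition(calls)


class TestSampleQc:
    def test_clean_sample_retained(self):
        calls = calls_from_states([[0], [1], [2]])
        assert qc_exclude_samples(calls, max_missing=0.2) == {"s0": False}

    def test_half_missing_excluded_at_default_threshold(self):
        calls = calls_from_states([[0, 0], [-1, 1], [-1, 2], [1, 3]])
        flags = qc_exclude_samples(calls, max_missing=0.2)
        assert flags == {"s0": True, "s1": False}

    def test_threshold_one_excludes_nobody(self, rng):
        states = rng.integers(-1, 4, size=(30, 5)).astype(np.int8)
        flags = qc_exclude_samples(calls_from_states(states), max_missing=1.0)
        assert not any(flags.values())


class TestMarkerMatrix:
    def test_two_lanes_per_retained_site(self, tiny_bands):
        markers = build_marker_matrix(tiny_bands)
        assert len(markers.marker_ids) == 4
        assert markers.values.shape == (4, 3)

    def test_excluded_sites_contribute_no_markers(self, tiny_bands):
        flags = np.array([SiteFilterFlag.RETAINED,
                          SiteFilterFlag.GENETIC_AFLP], dtype=np.int8)
        markers = build_marker_matrix(tiny_bands, flags)
        assert markers.marker_ids == ["b1_H", "b1_M"]

    def test_marker_values_equal_lane_presence(self, rng):
        bands = random_band_matrix(rng, n_bands=15, n_samples=5,
                                   missing_frac=0.1)
        markers = build_marker_matrix(bands)
        for k, mid in enumerate(markers.marker_ids):
            band, lane = mid.rsplit("_", 1)
            i = bands.band_ids.index(band)
            src = bands.lane(lane)[i].astype(float)
            src[bands.lane(lane)[i] == -1] = np.nan
            np.testing.assert_array_equal(markers.values[k], src)

    def test_no_retained_sites_is_an_error(self, tiny_bands):
        flags = np.full(2, SiteFilterFlag.GENETIC_AFLP, dtype=np.int8)
        with pytest.raises(UndefinedStatisticError):
            build_marker_matrix(tiny_bands, flags)


class TestPopulationMeans:
    def test_mean_of_two_members(self):
        calls = calls_from_states([
            [2, 2, 0],
            [2, 2, 0],
            [2, 2, 2],
            [2, 0, 0],
            [2, 0, 2],
            [0, 2, 0],
            [2, 0, 0],
            [0, 0, 0],
            [2, 0, 0],
            [0, 0, 0],
        ])
        profiles = [methylation_profile(calls, s)
                    for s in ("s0", "s1", "s2")]
        meta = SampleMetadata.from_records(
            ["s0", "s1", "s2"], ["west", "west", "east"]
        )
        means = population_mean_level(profiles, meta)
        assert means["west"] == pytest.approx((0.7 + 0.4) / 2)
        assert means["east"] == pytest.approx(0.2)  # singleton: its own level

    def test_mean_equals_pooled_recomputation_when_denominators_match(self):
        # both members scored over the same 10 sites -> mean of levels
        # equals pooled counts / pooled denominator
        calls = calls_from_states(np.array([[2] * 2] * 4 + [[0] * 2] * 6))
        profiles = [methylation_profile(calls, s) for s in ("s0", "s1")]
        meta = SampleMetadata.from_records(["s0", "s1"], ["p", "p"])
        pooled = sum(p.n_methylation_polymorphic for p in profiles) / sum(
            p.n_scored_sites for p in profiles
        )
        assert population_mean_level(profiles, meta)["p"] == pytest.approx(pooled)

    def test_empty_population_error_names_it(self):
        calls = calls_from_states([[2], [0]])
        profiles = [methylation_profile(calls, "s0")]
        meta = SampleMetadata.from_records(
            ["s0", "ghost"], ["here", "nowhere"]
        )
        with pytest.raises(UndefinedStatisticError, match="nowhere"):
            population_mean_level(profiles, meta)
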