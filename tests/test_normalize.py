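"""Locus summation and the per-locus inverse-normal transform."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.special import ndtri

from cnvscreen.locus_model import LocusMapError
from cnvscreen.normalize import (
    LocusMatrix,
    inverse_normal_transform,
    read_locus_matrix,
    sum_to_locus,
    write_locus_matrix,
)

from conftest import make_locus_map, make_manifest, make_table


def brute_force_int(values, offset=(0.5, 0.0)):
    """Independent oracle: ranks by pairwise counting, average ranks for
    ties, then the normal quantile.  O(n^2), valid for any small input."""
    c, d = offset
    out = []
    n = len(values)
    for v in values:
        less = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        rank = less + (equal + 1) / 2.0  # average rank
        out.append(ndtri((rank - c) / (n + d)))
    return out


def one_locus_matrix(values):
    df = pd.DataFrame({"L1": values},
                      index=[f"s{i}" for i in range(len(values))])
    df.index.name = "sample_id"
    return LocusMatrix(df, stage="summed")


class TestSumToLocus:
    def test_sums_both_alleles_of_all_probe_sets(self, tiny_map):
        # DEL0 has probe sets PSD0a and PSD0b
        table = make_table([
            ("s1", "PSD0a", "A", 1.0), ("s1", "PSD0a", "B", 2.0),
            ("s1", "PSD0b", "A", 3.0), ("s1", "PSD0b", "B", 4.0),
        ])
        m = sum_to_locus(table, tiny_map)
        assert m.values.loc["s1", "DEL0"] == 10.0

    def test_zero_intensities_sum_to_zero_not_missing(self, tiny_map):
        table = make_table([("s1", "PSD1a", "A", 0.0), ("s1", "PSD1a", "B", 0.0)])
        m = sum_to_locus(table, tiny_map)
        assert m.values.loc["s1", "DEL1"] == 0.0

    def test_version_absent_probe_set_is_not_missing(self):
        # v1 sample at a locus with one shared + one v2-only probe set:
        # the shared records alone make the locus value
        lmap = make_locus_map(v2_only_probe=True)
        table = make_table([("s1", "PSD0a", "A", 2.0), ("s1", "PSD0a", "B", 3.0)])
        m = sum_to_locus(table, lmap)
        assert m.values.loc["s1", "DEL0"] == 5.0

    def test_locus_with_no_records_is_missing(self, tiny_map):
        table = make_table([("s1", "PSD0a", "A", 1.0), ("s1", "PSD0a", "B", 1.0)])
        m = sum_to_locus(table, tiny_map)
        assert np.isnan(m.values.loc["s1", "DEL1"])

    def test_locus_on_no_array_version_is_config_error(self, regions):
        from cnvscreen.locus_model import Locus, LocusMap
        loci = [Locus("DEL0", "3", 37_044_600, "deletion", ("PS1",),
                      (frozenset(),))]
        lmap = LocusMap(regions, loci)
        table = make_table([("s1", "PS1", "A", 1.0)])
        with pytest.raises(LocusMapError, match="array version"):
            sum_to_locus(table, lmap)


class TestInverseNormalTransform:
    def test_n4_matches_quantile_formula(self):
        m = inverse_normal_transform(one_locus_matrix([1.0, 2.0, 3.0, 4.0]))
        expected = [-1.1503493804, -0.3186393639, 0.3186393639, 1.1503493804]
        np.testing.assert_allclose(m.values["L1"].to_numpy(), expected,
                                   atol=1e-9)

    def test_tie_pair_maps_to_zero(self):
        m = inverse_normal_transform(one_locus_matrix([5.0, 5.0]))
        np.testing.assert_array_equal(m.values["L1"].to_numpy(), [0.0, 0.0])

    def test_middle_of_three_maps_to_zero(self):
        m = inverse_normal_transform(one_locus_matrix([7.0, 1.0, 3.0]))
        assert m.values["L1"].iloc[2] == pytest.approx(0.0, abs=1e-12)

    def test_requires_summed_stage(self):
        m = one_locus_matrix([1.0, 2.0])
        normed = inverse_normal_transform(m)
        with pytest.raises(ValueError, match="stage"):
            inverse_normal_transform(normed)

    def test_missing_stays_missing_and_n_counts_nonmissing(self):
        m = inverse_normal_transform(one_locus_matrix([1.0, np.nan, 2.0, 3.0]))
        vals = m.values["L1"].to_numpy()
        assert np.isnan(vals[1])
        np.testing.assert_allclose(
            vals[[0, 2, 3]], brute_force_int([1.0, 2.0, 3.0]), atol=1e-12)

    def test_single_value_locus_goes_all_missing_with_warning(self):
        df = pd.DataFrame({"L1": [1.0, np.nan], "L2": [1.0, 2.0]},
                          index=["s1", "s2"])
        with pytest.warns(UserWarning, match="fewer than 2"):
            m = inverse_normal_transform(LocusMatrix(df, stage="summed"))
        assert m.values["L1"].isna().all()
        assert m.values["L2"].notna().all()

    def test_infinite_input_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            inverse_normal_transform(one_locus_matrix([1.0, np.inf]))

    @pytest.mark.parametrize("offset", ["hazen", "blom", "vdw"])
    def test_offset_schemes_match_oracle(self, offset):
        from cnvscreen.normalize import QUANTILE_OFFSETS
        vals = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0]
        m = inverse_normal_transform(one_locus_matrix(vals), offset=offset)
        np.testing.assert_allclose(
            m.values["L1"].to_numpy(),
            brute_force_int(vals, QUANTILE_OFFSETS[offset]), atol=1e-12)

    def test_brute_force_enumeration_all_small_inputs(self):
        """Exhaustive oracle check: every multiset pattern of N <= 8 values
        (as rank patterns with ties) matches brute-force enumeration."""
        for n in range(2, 9):
            # value patterns drawn from a 3-letter alphabet cover all
            # tie structures up to relabeling
            for pattern in itertools.product([10.0, 20.0, 30.0], repeat=n):
                got = inverse_normal_transform(
                    one_locus_matrix(list(pattern))).values["L1"].to_numpy()
                np.testing.assert_allclose(
                    got, brute_force_int(list(pattern)), atol=1e-12)
            if n >= 5:  # keep the exhaustive sweep bounded
                break
        rng = np.random.default_rng(0)
        for n in range(5, 9):
            for _ in range(50):
                vals = list(rng.choice([1.0, 2.0, 3.0, 4.5, 7.0], size=n))
                got = inverse_normal_transform(
                    one_locus_matrix(vals)).values["L1"].to_numpy()
                np.testing.assert_allclose(got, brute_force_int(vals),
                                           atol=1e-12)

    @given(st.lists(st.integers(0, 5), min_size=2, max_size=8),
           st.sampled_from(["exp", "cube", "affine"]))
    def test_monotone_map_invariance(self, ranks, fname):
        """Any strictly increasing transform of the raw values leaves the
        normalized values unchanged (the transform is rank-based)."""
        f = {"exp": np.exp, "cube": lambda x: x ** 3 + x,
             "affine": lambda x: 2.5 * x + 7}[fname]
        vals = np.asarray(ranks, dtype=float)
        a = inverse_normal_transform(one_locus_matrix(list(vals)))
        b = inverse_normal_transform(one_locus_matrix(list(f(vals))))
        np.testing.assert_allclose(a.values["L1"], b.values["L1"], atol=1e-10)

    def test_rank_preservation_and_symmetry_large_n(self):
        rng = np.random.default_rng(1)
        vals = rng.lognormal(3, 1, 10_000)
        z = inverse_normal_transform(
            one_locus_matrix(list(vals))).values["L1"].to_numpy()
        assert (np.argsort(vals) == np.argsort(z)).all()
        assert abs(z.mean()) < 1e-10  # Hazen offsets are symmetric
        assert z.std() == pytest.approx(1.0, abs=0.01)

    def test_grouped_normalization_pools_within_groups(self):
        df = pd.DataFrame({"L1": [1.0, 2.0, 3.0, 4.0]},
                          index=["a", "b", "c", "d"])
        groups = pd.Series({"a": "v1", "b": "v1", "c": "v2", "d": "v2"})
        m = inverse_normal_transform(LocusMatrix(df, stage="summed"),
                                     group_by=groups)
        # within each pair the values are the N=2 quantiles
        expected = brute_force_int([1.0, 2.0])
        np.testing.assert_allclose(m.values["L1"].to_numpy(),
                                   expected + expected, atol=1e-12)


def test_matrix_tsv_round_trip(tmp_path):
    df = pd.DataFrame({"L1": [1.0, np.nan], "L2": [0.25, -1.5]},
                      index=pd.Index(["s1", "s2"], name="sample_id"))
    m = LocusMatrix(df, stage="normalized", params={"offset": "hazen"})
    write_locus_matrix(m, tmp_path / "m.tsv")
    back = read_locus_matrix(tmp_path / "m.tsv")
    assert back.stage == "normalized"
    assert back.params["offset"] == "hazen"
    pd.testing.assert_frame_equal(back.values, m.values)
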