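"""Ensemble statistics: deciles, FCC aggregation, pattern clustering."""

import numpy as np
import pandas as pd
import pytest

from cbbkin.postprocess import (
    aggregate_fcc,
    cluster_control_patterns,
    cut_clusters,
    decile_indices,
    decile_location_test,
    stability_decile_density,
)


def _frame(values, mets=("m1",)):
    df = pd.DataFrame(values, columns=list(mets))
    df.index.name = "fmcs_index"
    return df


class TestDeciles:
    def test_requires_twenty_fmcs(self):
        frac = pd.Series(np.linspace(0, 1, 19))
        with pytest.raises(ValueError, match=">= 20"):
            decile_indices(frac)

    def test_tie_break_is_permutation_invariant(self):
        rng = np.random.default_rng(0)
        frac = pd.Series(rng.choice([0.4, 0.5, 0.6], size=40))
        top1, bot1 = decile_indices(frac)
        perm = rng.permutation(40)
        top2, bot2 = decile_indices(frac.iloc[perm])
        np.testing.assert_array_equal(top1, top2)
        np.testing.assert_array_equal(bot1, bot2)

    def test_identical_fractions_yield_coincident_densities(self):
        rng = np.random.default_rng(1)
        conc = _frame(10 ** rng.normal(0, 0.5, size=(40, 1)))
        frac = pd.Series(np.full(40, 0.5))
        dens = stability_decile_density(conc, frac)["m1"]
        # deterministic tie-break: top = highest indices, bottom = lowest;
        # both groups are draws from the same distribution
        assert dens["top"].shape == dens["bottom"].shape
        top, bot = decile_indices(frac)
        np.testing.assert_array_equal(top, np.arange(36, 40))
        np.testing.assert_array_equal(bot, np.arange(4))

    def test_planted_negative_association_shifts_top_decile_left(self):
        rng = np.random.default_rng(2)
        conc = 10 ** rng.normal(0, 0.6, size=(200, 1))
        # stability forced to anti-correlate with the metabolite level
        frac = pd.Series(1.0 / (1.0 + conc[:, 0]))
        conc = _frame(conc)
        dens = stability_decile_density(conc, frac)["m1"]
        top, bot = decile_indices(frac)
        mean_top = np.log10(conc.loc[top, "m1"]).mean()
        mean_bot = np.log10(conc.loc[bot, "m1"]).mean()
        assert mean_top < mean_bot
        test = decile_location_test(conc, frac, "m1", alternative="less")
        assert test["p_value"] < 1e-6


class TestSaturationSplit:
    def test_tidy_split_carries_stability_flags(
        self, cbb_model, calibrated_ensemble
    ):
        from cbbkin.kinetics import saturation_profile
        from cbbkin.postprocess import saturation_split
        from cbbkin.stability import classify_ensemble

        s, x0, ens = calibrated_ensemble
        prof = saturation_profile(cbb_model, ens, x0)
        # saturation strictly inside (0, 1) for every binding constant
        assert (prof["saturation"] > 0).all()
        assert (prof["saturation"] < 1).all()
        cls = classify_ensemble(cbb_model, ens, x0)
        df = saturation_split(prof, cls["stable"])
        assert df["stable"].sum() == int(cls["stable"].sum()) * (
            len(prof) // ens.n_sets
        )
        np.testing.assert_allclose(
            df["log10_s_over_km"], np.log10(df["s_over_km"])
        )


class TestAggregateFcc:
    def test_single_set_median_is_itself_and_mad_zero(self):
        fcc = np.arange(4.0).reshape(1, 2, 2)
        med, mad = aggregate_fcc(fcc, ["a", "b"])
        np.testing.assert_array_equal(med.to_numpy(), fcc[0])
        np.testing.assert_array_equal(mad.to_numpy(), np.zeros((2, 2)))

    def test_hand_computed_median_and_mad(self):
        vals = np.array([1.0, 2.0, 100.0])
        fcc = vals[:, None, None] * np.ones((3, 1, 1))
        med, mad = aggregate_fcc(fcc, ["r"])
        assert med.iloc[0, 0] == 2.0
        assert mad.iloc[0, 0] == 1.0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            aggregate_fcc(np.empty((0, 2, 2)), ["a", "b"])


class TestTidyFccRecords:
    def test_records_match_tensor_entries(self):
        from cbbkin.postprocess import fcc_tidy_frame

        rng = np.random.default_rng(0)
        fcc = rng.standard_normal((3, 2, 2))
        df = fcc_tidy_frame(fcc, ["u", "w"], [5, 5, 6], [0, 1, 0])
        assert len(df) == 12
        row = df[(df["fmcs_index"] == 6) & (df["effector"] == "w")
                 & (df["target"] == "u")]
        assert float(row["value"].iloc[0]) == fcc[2, 0, 1]


class TestClustering:
    def _planted_tensor(self, n_sets=40, noise=0.05, seed=0):
        """Two effector blocks with distinct control signatures."""
        rng = np.random.default_rng(seed)
        n = 8
        base_a = np.array([1.0, 1.0, 1.0, 1.0, 0.0, 0.0, 0.0, 0.0])
        base_b = 1.0 - base_a
        fcc = np.empty((n_sets, n, n))
        for e in range(n):
            pattern = base_a if e < 4 else base_b
            fcc[:, :, e] = pattern[None, :] + noise * rng.standard_normal(
                (n_sets, n)
            )
        return fcc, [f"r{i}" for i in range(n)]

    def test_small_values_round_to_exact_zero_then_asinh(self):
        fcc = np.full((2, 2, 2), 1e-7)
        fcc[0, 0, 0] = 1.0
        X = np.where(np.abs(fcc) < 1e-6, 0.0, fcc)
        assert np.arcsinh(X).min() == 0.0
        assert np.arcsinh(0.0) == 0.0

    def test_duplicated_patterns_merge_at_zero_with_full_support(self):
        fcc, labels = self._planted_tensor(noise=0.05)
        fcc[:, :, 1] = fcc[:, :, 0]  # exact duplicate effector
        res = cluster_control_patterns(
            fcc, labels, axis="effector", subsample_fraction=0.5,
            n_bootstrap=50, seed=0,
        )
        pair = frozenset({labels.index("r0"), labels.index("r1")})
        # the duplicate pair is an original cluster with full support
        assert pair in res.support
        assert res.support[pair] == 1.0
        # and it merges at (numerically) zero height
        assert res.linkage[0][2] < 1e-10

    def test_planted_two_block_structure_recovered_with_high_support(self):
        fcc, labels = self._planted_tensor()
        res = cluster_control_patterns(
            fcc, labels, axis="effector", subsample_fraction=0.5,
            n_bootstrap=100, seed=0,
        )
        block_a = frozenset(range(4))
        block_b = frozenset(range(4, 8))
        assert res.support.get(block_a, 0.0) >= 0.95
        assert res.support.get(block_b, 0.0) >= 0.95
        flat = cut_clusters(res, 2)
        assert len({flat[f"r{i}"] for i in range(4)}) == 1
        assert len({flat[f"r{i}"] for i in range(4, 8)}) == 1

    def test_same_seed_gives_identical_dendrograms(self):
        fcc, labels = self._planted_tensor()
        a = cluster_control_patterns(fcc, labels, n_bootstrap=20, seed=3,
                                     subsample_fraction=0.5)
        b = cluster_control_patterns(fcc, labels, n_bootstrap=20, seed=3,
                                     subsample_fraction=0.5)
        np.testing.assert_array_equal(a.linkage, b.linkage)
        assert a.newick == b.newick
        assert a.support == b.support

    def test_newick_contains_all_labels(self):
        fcc, labels = self._planted_tensor()
        res = cluster_control_patterns(fcc, labels, n_bootstrap=10, seed=0,
                                       subsample_fraction=0.5)
        for lab in labels:
            assert lab in res.newick
        assert res.newick.endswith(";")
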