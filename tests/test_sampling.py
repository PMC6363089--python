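"""Metabolome sampling: log-uniform draws, Gibbs filter, feasibility."""

import numpy as np
import pytest
from scipy.stats import kstest

from cbbkin.model import R_GAS, load_cbb_model
from cbbkin.sampling import (
    ConcentrationRangeTable,
    InfeasibleConfiguration,
    generate_fmcs,
    gibbs_energy,
    sample_log_uniform,
    verify_fmcs,
)


def _ranges(mets, lo, hi, **kw):
    return ConcentrationRangeTable(list(mets), np.asarray(lo), np.asarray(hi), **kw)


class TestLogUniform:
    def test_degenerate_range_is_constant(self):
        r = _ranges(["A"], [0.7], [0.7])
        draws = sample_log_uniform(r, 50, seed=0)
        assert np.all(draws == 0.7)

    def test_log10_uniformity(self):
        r = _ranges(["A"], [0.01], [100.0])
        draws = np.log10(sample_log_uniform(r, 10_000, seed=3)[:, 0])
        stat = kstest(draws, "uniform", args=(-2.0, 4.0))
        assert stat.pvalue > 0.01

    def test_seed_determinism(self):
        r = _ranges(["A", "B"], [0.1, 1.0], [10.0, 2.0])
        a = sample_log_uniform(r, 100, seed=5)
        b = sample_log_uniform(r, 100, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_positive_bounds_required(self):
        with pytest.raises(ValueError):
            _ranges(["A"], [0.0], [1.0])

    def test_multiplier_must_exceed_one(self):
        with pytest.raises(ValueError):
            _ranges(["A"], [0.1], [1.0], ppool_multiplier_range=(0.9, 5.0))


class TestGibbsEnergy:
    def test_zero_at_equilibrium(self, cbb_model):
        rxn = cbb_model.reaction("tpi")  # GAP <-> DHAP
        conc = {"GAP": 1.0, "DHAP": 1.0 * rxn.keq}
        assert gibbs_energy(rxn, conc) == pytest.approx(0.0, abs=1e-9)

    def test_equal_concentrations_give_minus_rt_log_keq(self):
        from cbbkin.model import build_network

        rt = R_GAS * 298.15
        dg0 = -rt * np.log(10.0)  # Keq = 10
        model = build_network(
            {
                "metabolites": [
                    {"id": "A", "role": "balanced", "conc_range_mM": [0.1, 1]},
                    {"id": "B", "role": "balanced", "conc_range_mM": [0.1, 1]},
                ],
                "reactions": [
                    {
                        "id": "R",
                        "stoichiometry": {"A": -1, "B": 1},
                        "rate_law": "reversible-MM",
                        "dG0_prime_kJ_mol": dg0,
                    }
                ],
            }
        )
        dg = gibbs_energy(model.reaction("R"), {"A": 1.0, "B": 1.0})
        assert dg == pytest.approx(-rt * np.log(10.0), rel=1e-12)
        assert dg == pytest.approx(-5.708, abs=5e-3)  # kJ/mol at 298.15 K

    def test_doubling_product_adds_rt_log_two(self, cbb_model):
        rxn = cbb_model.reaction("tpi")
        base = gibbs_energy(rxn, {"GAP": 0.5, "DHAP": 0.2})
        doubled = gibbs_energy(rxn, {"GAP": 0.5, "DHAP": 0.4})
        assert doubled - base == pytest.approx(
            R_GAS * 298.15 * np.log(2.0), rel=1e-12
        )

    def test_sink_reactions_not_checkable(self, cbb_model):
        with pytest.raises(ValueError, match="not thermodynamically checkable"):
            gibbs_energy(cbb_model.reaction("sink_PYR"), {"PYR": 1.0})


class TestGenerateFmcs:
    def test_known_feasible_point_accepts_everything(self, cbb_model, small_fmcs):
        point = small_fmcs.samples[0].concentrations
        table = ConcentrationRangeTable.from_model(cbb_model)
        lo = point[table.metabolites].to_numpy()
        collapsed = ConcentrationRangeTable(
            table.metabolites, lo, lo,
            table.cofactor_ratio_bounds, table.ppool_multiplier_range,
            table.total_cap_mM,
        )
        res = generate_fmcs(cbb_model, collapsed, max_rounds=256, target=256, seed=0)
        assert res.acceptance_rate == 1.0

    def test_infeasible_point_names_the_reaction(self, cbb_model, small_fmcs):
        point = small_fmcs.samples[0].concentrations.copy()
        point["BPG"] = 0.1  # push the phosphoglycerate kinase step uphill
        point["3PG"] = 0.1
        table = ConcentrationRangeTable.from_model(cbb_model)
        lo = point[table.metabolites].to_numpy()
        collapsed = ConcentrationRangeTable(
            table.metabolites, lo, lo,
            table.cofactor_ratio_bounds, table.ppool_multiplier_range,
            table.total_cap_mM,
        )
        with pytest.raises(InfeasibleConfiguration) as exc:
            generate_fmcs(cbb_model, collapsed, max_rounds=64, target=1, seed=0)
        assert exc.value.rejection_tally["gibbs_by_reaction"]["pgk"] > 0

    def test_filter_soundness_reverification(self, cbb_model, small_fmcs):
        table = ConcentrationRangeTable.from_model(cbb_model)
        for s in small_fmcs.samples:
            assert verify_fmcs(cbb_model, table, s) == []

    def test_gibbs_rate_law_sign_consistency(self, cbb_model, small_fmcs):
        # dG < 0 in the flux direction must mean Q/Keq < 1, the same
        # displacement term that sets the sign of the reversible rate laws
        from cbbkin.kinetics import _gamma, compile_kinetics
        from cbbkin.sampling import full_concentration_vector

        compiled = compile_kinetics(cbb_model)
        for s in small_fmcs.samples:
            x = full_concentration_vector(cbb_model, s)
            for cr in compiled:
                if cr.kind == "reversible-MM":
                    assert _gamma(cr, x) < 1.0

    def test_tightening_a_range_against_thermodynamics_lowers_acceptance(
        self, cbb_model
    ):
        # Acetyl-CoA appears only as a *product* of thermodynamically
        # checked reactions (pdh, pta) and in no other constraint, so
        # restricting its range upward is monotone draw-by-draw: with the
        # shared seed stream, every other coordinate of every candidate is
        # unchanged while the acetyl-CoA value can only rise, which can
        # only push dG(pdh)/dG(pta) further uphill.
        wide = ConcentrationRangeTable.from_model(cbb_model)
        i = wide.index("ACCOA")
        hi_min = wide.min_mM.copy()
        hi_min[i] = np.sqrt(wide.min_mM[i] * wide.max_mM[i])
        narrow = ConcentrationRangeTable(
            wide.metabolites, hi_min, wide.max_mM,
            wide.cofactor_ratio_bounds, wide.ppool_multiplier_range,
            wide.total_cap_mM,
        )
        n = 400_000
        res_wide = generate_fmcs(cbb_model, wide, max_rounds=n, target=n, seed=11)
        try:
            res_narrow = generate_fmcs(
                cbb_model, narrow, max_rounds=n, target=n, seed=11
            )
            narrow_rate = res_narrow.acceptance_rate
        except InfeasibleConfiguration:
            narrow_rate = 0.0
        assert narrow_rate <= res_wide.acceptance_rate

    def test_determinism_same_seed(self, cbb_model):
        a = generate_fmcs(cbb_model, max_rounds=400_000, target=3, seed=21)
        b = generate_fmcs(cbb_model, max_rounds=400_000, target=3, seed=21)
        assert a.accepted == b.accepted
        for sa, sb in zip(a.samples, b.samples):
            np.testing.assert_array_equal(
                sa.concentrations.to_numpy(), sb.concentrations.to_numpy()
            )
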