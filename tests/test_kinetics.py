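"""Rate laws, constant sampling, Vmax calibration and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cbbkin.kinetics import (
    CalibrationError,
    calibrate_vmax,
    rate,
    sample_parameter_ensemble,
    sample_parameter_set,
    saturation_fraction,
)
from cbbkin.model import R_GAS, build_network
from cbbkin.sampling import full_concentration_vector


def _ab_model(keq=2.0):
    rt = R_GAS * 298.15
    return build_network(
        {
            "metabolites": [
                {"id": "A", "role": "balanced", "conc_range_mM": [0.01, 100]},
                {"id": "B", "role": "balanced", "conc_range_mM": [0.01, 100]},
            ],
            "reactions": [
                {
                    "id": "R",
                    "stoichiometry": {"A": -1, "B": 1},
                    "rate_law": "reversible-MM",
                    "dG0_prime_kJ_mol": -rt * np.log(keq),
                }
            ],
        }
    )


def _pset(model, conc, seed=0):
    import pandas as pd

    from cbbkin.sampling import MetabolomeSample

    fmcs = MetabolomeSample(
        concentrations=pd.Series(conc, dtype=float),
        ppool_multiple=1.0,
        dG=pd.Series(dtype=float),
        feasible=True,
        index=0,
    )
    return sample_parameter_set(model, fmcs, seed), fmcs


class TestSaturationFraction:
    def test_tight_binding_is_99_percent(self):
        assert 100 * saturation_fraction(1.0, 0.01) == pytest.approx(99.0, abs=0.01)

    def test_weak_binding_is_1_percent(self):
        assert 100 * saturation_fraction(1.0, 100.0) == pytest.approx(0.99, abs=0.001)

    def test_half_saturation_at_km(self):
        assert saturation_fraction(3.0, 3.0) == 0.5

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            saturation_fraction(0.0, 1.0)


class TestRateLaw:
    def _manual_rate(self, model, km_a, km_b, keq, vmax, a, b):
        return (
            vmax * (a / km_a) * (1 - b / (a * keq)) / (1 + a / km_a + b / km_b)
        )

    def test_textbook_example(self):
        # A=1, B=0.5, K_A=K_B=1, Keq=2, Vmax=1 -> 1*(1)*(1-0.25)/(2.5)=0.3
        model = _ab_model(keq=2.0)
        pset, fmcs = _pset(model, {"A": 1.0, "B": 0.5})
        pset.ensemble.K[:] = 1.0
        pset.ensemble.vmax = np.ones((1, 1))
        # Keq in the law is molar-based; for a 1:1 conversion the unit
        # factors cancel, so the mM evaluation matches the hand result
        v = rate(model.reaction("R"), pset, {"A": 1.0, "B": 0.5})
        assert v == pytest.approx(0.3, rel=1e-12)

    def test_zero_rate_at_equilibrium(self):
        model = _ab_model(keq=2.0)
        pset, _ = _pset(model, {"A": 1.0, "B": 2.0})
        pset.ensemble.vmax = np.ones((1, 1))
        v = rate(model.reaction("R"), pset, {"A": 1.0, "B": 2.0})
        assert v == pytest.approx(0.0, abs=1e-14)

    def test_saturation_limit_reaches_vmax(self):
        model = _ab_model(keq=1e6)
        pset, _ = _pset(model, {"A": 1.0, "B": 1.0})
        pset.ensemble.K[:] = 1.0
        pset.ensemble.vmax = np.full((1, 1), 7.0)
        v = rate(model.reaction("R"), pset, {"A": 1e9, "B": 1e-6})
        assert v == pytest.approx(7.0, rel=1e-5)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        a=st.floats(0.01, 100.0),
        b=st.floats(0.01, 100.0),
        km_a=st.floats(0.01, 100.0),
        km_b=st.floats(0.01, 100.0),
        keq=st.floats(0.05, 20.0),
    )
    def test_rate_sign_matches_thermodynamic_displacement(
        self, a, b, km_a, km_b, keq
    ):
        model = _ab_model(keq=keq)
        pset, _ = _pset(model, {"A": a, "B": b})
        pset.ensemble.K[0] = [km_a, km_b]
        pset.ensemble.vmax = np.ones((1, 1))
        v = rate(model.reaction("R"), pset, {"A": a, "B": b})
        displacement = 1.0 - b / (a * model.reaction("R").keq)
        assert np.sign(v) == np.sign(displacement) or v == displacement == 0

    def test_competitive_inhibitor_reduces_rate_monotonically(self):
        model = build_network(
            {
                "metabolites": [
                    {"id": "A", "role": "balanced", "conc_range_mM": [0.01, 100]},
                    {"id": "B", "role": "balanced", "conc_range_mM": [0.01, 100]},
                    {"id": "I", "role": "balanced", "conc_range_mM": [0.01, 100]},
                ],
                "reactions": [
                    {
                        "id": "R",
                        "stoichiometry": {"A": -1, "B": 1},
                        "rate_law": "reversible-MM",
                        "dG0_prime_kJ_mol": -10.0,
                        "regulators": [
                            {"metabolite": "I", "mode": "competitive-inhibitor"}
                        ],
                    }
                ],
            }
        )
        pset, _ = _pset(model, {"A": 1.0, "B": 0.1, "I": 1.0})
        pset.ensemble.vmax = np.ones((1, 1))
        rates = [
            rate(model.reaction("R"), pset, {"A": 1.0, "B": 0.1, "I": i})
            for i in (0.01, 0.1, 1.0, 10.0)
        ]
        assert all(np.diff(rates) < 0)

    def test_allosteric_activator_increases_rate(self):
        model = build_network(
            {
                "metabolites": [
                    {"id": "A", "role": "balanced", "conc_range_mM": [0.01, 100]},
                    {"id": "B", "role": "balanced", "conc_range_mM": [0.01, 100]},
                    {"id": "X", "role": "balanced", "conc_range_mM": [0.01, 100]},
                ],
                "reactions": [
                    {
                        "id": "R",
                        "stoichiometry": {"A": -1, "B": 1},
                        "rate_law": "reversible-MM",
                        "dG0_prime_kJ_mol": -10.0,
                        "regulators": [
                            {"metabolite": "X", "mode": "allosteric-activator"}
                        ],
                    }
                ],
            }
        )
        pset, _ = _pset(model, {"A": 1.0, "B": 0.1, "X": 1.0})
        pset.ensemble.vmax = np.ones((1, 1))
        rates = [
            rate(model.reaction("R"), pset, {"A": 1.0, "B": 0.1, "X": x})
            for x in (0.01, 0.1, 1.0, 10.0)
        ]
        assert all(np.diff(rates) > 0)


class TestParameterSampling:
    def test_draws_span_the_prescribed_window(self, cbb_model, small_fmcs):
        s = small_fmcs.samples[0]
        ens = sample_parameter_ensemble(cbb_model, s, 500, seed=2)
        x = full_concentration_vector(cbb_model, s)
        for j, p in enumerate(cbb_model.sampled_parameters):
            ref = x[cbb_model.met_index(p.metabolite)]
            factors = ens.K[:, j] / ref
            assert factors.min() >= 0.01
            assert factors.max() <= 100.0
        # log10 factors cover the window roughly uniformly
        factors = ens.K / np.array(
            [x[cbb_model.met_index(p.metabolite)] for p in cbb_model.sampled_parameters]
        )
        logs = np.log10(factors).ravel()
        assert logs.min() < -1.9 and logs.max() > 1.9

    def test_promiscuity_shared_constant_is_one_draw(self, cbb_model, small_fmcs):
        # the bisphosphatase cross-inhibition references the partner's K_M:
        # the SBP binding constant of SBPase appears as the inhibition
        # constant of SBP in the FBPase law
        s = small_fmcs.samples[0]
        pset = sample_parameter_set(cbb_model, s, seed=4)
        km_sbp = pset.km("SBPase")["SBP"]
        ki_fbpase = pset.ki("FBPase")["SBP"]
        assert km_sbp == ki_fbpase

    def test_same_seed_identical_sets(self, cbb_model, small_fmcs):
        s = small_fmcs.samples[0]
        a = sample_parameter_ensemble(cbb_model, s, 10, seed=9)
        b = sample_parameter_ensemble(cbb_model, s, 10, seed=9)
        np.testing.assert_array_equal(a.K, b.K)


class TestTidySerialization:
    def test_streamed_tsv_roundtrips_values(self, tmp_path, calibrated_ensemble):
        import pandas as pd

        from cbbkin.kinetics import write_parameter_tsv

        s, x0, ens = calibrated_ensemble
        path = tmp_path / "params.tsv"
        write_parameter_tsv(ens, path)
        df = pd.read_csv(path, sep="\t")
        n_const = ens.K.shape[1]
        n_rxn = ens.vmax.shape[1]
        assert len(df) == ens.n_sets * (n_const + n_rxn)
        sym0 = ens.symbols[0]
        got = df[(df["set_index"] == 3) & (df["constant"] == sym0)]["value"]
        # values are serialized with 12 significant digits
        assert float(got.iloc[0]) == pytest.approx(ens.K[3, 0], rel=1e-11)


class TestCalibration:
    def test_vmax_equals_flux_over_normalized_rate(self):
        # f = 0.3 at the reference state and v0 = 0.06 give Vmax = 0.2
        model = _ab_model(keq=2.0)
        pset, fmcs = _pset(model, {"A": 1.0, "B": 0.5})
        pset.ensemble.K[:] = 1.0
        model.reaction("R").v0 = 0.06
        x0 = full_concentration_vector(model, fmcs)
        vmax = calibrate_vmax(model.reaction("R"), pset, x0)
        assert vmax == pytest.approx(0.06 / 0.3, rel=1e-12)

    def test_fully_saturated_irreversible_gives_vmax_equal_v0(self):
        model = build_network(
            {
                "metabolites": [
                    {"id": "A", "role": "boundary-unbalanced", "conc_fixed_mM": 1e9},
                    {"id": "SINK", "role": "sink-pool", "conc_fixed_mM": 1.0},
                ],
                "reactions": [
                    {
                        "id": "R",
                        "stoichiometry": {"A": -1, "SINK": 1},
                        "rate_law": "irreversible-MM",
                    }
                ],
            }
        )
        import pandas as pd

        from cbbkin.sampling import MetabolomeSample

        fmcs = MetabolomeSample(
            pd.Series(dtype=float), 1.0, pd.Series(dtype=float), True, index=0
        )
        pset = sample_parameter_set(model, fmcs, seed=0)
        pset.ensemble.K[:] = 1.0  # K << A: fully saturated, f -> 1
        x0 = full_concentration_vector(model, fmcs)
        vmax = calibrate_vmax(model.reaction("R"), pset, x0, v0=0.5)
        assert vmax == pytest.approx(0.5, rel=1e-6)

    def test_rubisco_rate_reproduces_input_flux(
        self, cbb_model, cbb_flux, calibrated_ensemble
    ):
        s, x0, ens = calibrated_ensemble
        rubisco = cbb_model.reaction("Rubisco")
        j = cbb_model.rxn_index("Rubisco")
        for i in range(5):
            v = rate(rubisco, ens[i], x0)
            assert v == pytest.approx(cbb_flux[j], rel=1e-10)

    def test_steady_state_residual_after_calibration(
        self, cbb_model, cbb_flux, calibrated_ensemble
    ):
        from cbbkin.kinetics import rates

        s, x0, ens = calibrated_ensemble
        v = rates(cbb_model, ens, x0)
        resid = np.abs(cbb_model.S @ v.T).max()
        assert resid < 1e-9 * np.abs(cbb_flux).max()

    def test_equilibrium_state_fails_calibration(self):
        model = _ab_model(keq=2.0)
        pset, fmcs = _pset(model, {"A": 1.0, "B": 2.0})  # Q = Keq
        x0 = full_concentration_vector(model, fmcs)
        with pytest.raises(CalibrationError):
            calibrate_vmax(model.reaction("R"), pset, x0, v0=1.0)
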