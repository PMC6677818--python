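"""Single-site ITC model/fitter and Michaelis-Menten fitting."""

import io

import numpy as np
import pytest
from scipy.optimize import brentq

from cnslim.binding import (
    ItcExperiment,
    absorbance_to_concentration,
    default_schedule,
    derive_thermo,
    fit_itc,
    fit_michaelis_menten,
    michaelis_menten,
    read_itc_csv,
    read_pnpp_csv,
    wiseman_heats,
    write_itc_csv,
    write_pnpp_csv,
)
from cnslim.synthetic import gen_itc, gen_pnpp

# thermodynamic parameter sets of the titrations exercised throughout:
# (label, K_D molar, dH kcal/mol, cell M, syringe M)
TITRATIONS = [
    ("WT", 59e-9, -12.0, 5e-6, 50e-6),
    ("ATAP", 4800e-9, -4.5, 10e-6, 100e-6),
    ("AVATAA", 2400e-9, -7.6, 10e-6, 100e-6),
    ("D92", 21e-9, -8.5, 5e-6, 50e-6),
    ("P782A", 48e-9, -2.8, 5e-6, 50e-6),
]


def schedule_for(cell, syringe):
    return default_schedule(cell_concentration=cell, syringe_concentration=syringe)


def equilibrium_heats_oracle(n, K_D, dH, exp):
    """Independent forward model: per-injection bookkeeping done from
    scratch, with the binding equilibrium solved numerically (brentq on the
    free-titrant concentration) instead of via the closed-form quadratic."""
    V0 = exp.cell_volume
    heats = []
    m_tot, x_tot, prev_b = exp.cell_concentration, 0.0, 0.0
    for v in exp.injection_volumes:
        d = 1.0 - v / V0
        m_tot *= d
        x_tot = x_tot * d + exp.syringe_concentration * v / V0
        sites = n * m_tot

        def free_titrant(xf):
            return xf + sites * xf / (K_D + xf) - x_tot

        xf = brentq(free_titrant, 0.0, x_tot, xtol=1e-30, rtol=1e-15)
        bound = sites * xf / (K_D + xf)
        heats.append(dH * 1e9 * V0 * (bound - prev_b * d))
        prev_b = bound
    return np.array(heats)


class TestWisemanModel:
    def test_zero_enthalpy_means_zero_heat(self):
        sched = default_schedule()
        assert np.allclose(wiseman_heats(1.0, 59e-9, 0.0, sched), 0.0)

    def test_saturating_cumulative_heat_equals_mass_balance_limit(self):
        # tight binder saturated by the first injection: every site binds at
        # once, so the cumulative heat is n*dH*V0*[M] at that composition
        n = 1.3
        sched = default_schedule(cell_concentration=1e-6, syringe_concentration=1e-3)
        heats = wiseman_heats(n, 1e-13, -10.0, sched)
        M, X = sched.compositions()
        assert X[0] > n * M[0]  # saturated immediately
        expected = n * -10.0 * 1e9 * sched.cell_volume * M[0]
        assert heats.sum() == pytest.approx(expected, rel=1e-4)

    def test_matches_numerical_equilibrium_solver(self, rng):
        for _ in range(100):
            n = rng.uniform(0.5, 2.0)
            K_D = 10 ** rng.uniform(-9.5, -4.5)
            dH = rng.uniform(-20.0, 10.0)
            cell = 10 ** rng.uniform(-6.5, -4.5)
            sched = default_schedule(cell_concentration=cell,
                                     syringe_concentration=cell * 10)
            got = wiseman_heats(n, K_D, dH, sched)
            want = equilibrium_heats_oracle(n, K_D, dH, sched)
            scale = np.max(np.abs(want)) or 1.0
            assert np.max(np.abs(got - want)) / scale < 1e-9

    def test_nonphysical_inputs_rejected(self):
        sched = default_schedule()
        with pytest.raises(ValueError):
            wiseman_heats(1.0, -1e-9, -10.0, sched)
        with pytest.raises(ValueError):
            wiseman_heats(0.0, 1e-9, -10.0, sched)


class TestItcFit:
    @pytest.mark.parametrize("label, K_D, dH, cell, syringe", TITRATIONS,
                             ids=[t[0] for t in TITRATIONS])
    def test_noiseless_recovery(self, label, K_D, dH, cell, syringe):
        exp, _ = gen_itc(1.0, K_D, dH, schedule=schedule_for(cell, syringe), seed=0)
        fit = fit_itc(exp)
        assert fit.converged
        assert fit.n == pytest.approx(1.0, rel=1e-4)
        assert fit.K_D == pytest.approx(K_D, rel=1e-4)
        assert fit.dH == pytest.approx(dH, rel=1e-4)

    def test_thermodynamic_identities_hold_exactly(self):
        exp, _ = gen_itc(1.0, 59e-9, -12.0, seed=0)
        fit = fit_itc(exp)
        dG_expected = 1.987e-3 * exp.temperature * np.log(fit.K_D)
        assert fit.dG == pytest.approx(dG_expected, rel=1e-12)
        assert fit.TdS == pytest.approx(fit.dH - fit.dG, rel=1e-12)

    @pytest.mark.parametrize(
        "K_D, dH, cell, syringe",
        [(59e-9, -12.0, 5e-6, 50e-6), (4800e-9, -4.5, 10e-6, 100e-6)],
        ids=["nM_scale_c~100", "uM_scale_c~2"],
    )
    def test_noisy_recovery_median_under_10pct(self, K_D, dH, cell, syringe):
        sched = schedule_for(cell, syringe)
        clean = wiseman_heats(1.0, K_D, dH, sched)
        sigma = 0.02 * np.max(np.abs(clean))
        errors = []
        for rep in range(100):
            exp, _ = gen_itc(1.0, K_D, dH, schedule=sched, noise_sd=sigma,
                             seed=50_000 + rep)
            fit = fit_itc(exp)
            errors.append(abs(fit.K_D - K_D) / K_D)
        assert np.median(errors) < 0.10

    def test_too_few_injections_rejected(self):
        sched = default_schedule(n_injections=5)
        exp, _ = gen_itc(1.0, 59e-9, -12.0, schedule=sched, seed=0)
        with pytest.raises(ValueError, match="10 injections"):
            fit_itc(exp)

    def test_c_value_warning_outside_informative_range(self, caplog):
        exp, _ = gen_itc(1.0, 1e-12, -12.0, seed=0)
        with caplog.at_level("WARNING"):
            fit_itc(exp)
        assert "c-value" in caplog.text


class TestThermo:
    def test_reference_state(self):
        dG, TdS = derive_thermo(1.0, -5.0)
        assert dG == pytest.approx(0.0)
        assert TdS == pytest.approx(-5.0)

    def test_nhe1_wt_values(self):
        dG, TdS = derive_thermo(59e-9, -12.0, 298.15)
        assert dG == pytest.approx(-9.86, abs=0.02)
        assert TdS == pytest.approx(-2.14, abs=0.05)

    def test_tighter_binding_is_more_favorable(self):
        dG_tight, _ = derive_thermo(1e-9, -10.0)
        dG_loose, _ = derive_thermo(1e-6, -10.0)
        assert dG_tight < dG_loose


class TestPnpp:
    def test_beer_lambert(self):
        assert absorbance_to_concentration(0.0) == 0.0
        assert absorbance_to_concentration(0.54) == pytest.approx(1.0e-4)
        assert absorbance_to_concentration(1.0) == pytest.approx(
            2 * absorbance_to_concentration(0.5)
        )

    def test_negative_absorbance_clipped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert absorbance_to_concentration(-0.01) == 0.0
        assert "clipped" in caplog.text

    def test_rate_at_km_is_half_vmax(self):
        assert michaelis_menten(0.5e-3, 2e-6, 0.5e-3) == pytest.approx(1e-6)

    def test_noiseless_recovery(self):
        S, v, _ = gen_pnpp(Km=0.5e-3, Vmax=1e-6, seed=0)
        fit = fit_michaelis_menten(S, v, enzyme_total=0.5e-6)
        assert fit.Km == pytest.approx(0.5e-3, rel=1e-6)
        assert fit.Vmax == pytest.approx(1e-6, rel=1e-6)
        assert fit.kcat == pytest.approx(fit.Vmax / 0.5e-6, rel=1e-12)

    def test_all_zero_rates_flagged(self, caplog):
        S = np.array([0, 1e-4, 1e-3, 4e-3, 8e-3])
        with caplog.at_level("WARNING"):
            fit = fit_michaelis_menten(S, np.zeros(5), enzyme_total=0.5e-6)
        assert not fit.converged
        assert fit.Vmax == pytest.approx(0.0, abs=1e-9)


class TestCsv:
    def test_itc_roundtrip(self):
        exp, _ = gen_itc(1.0, 59e-9, -12.0, noise_sd=0.5, seed=2)
        buf = io.StringIO()
        write_itc_csv(exp, buf)
        buf.seek(0)
        again = read_itc_csv(buf)
        assert again.cell_concentration == pytest.approx(exp.cell_concentration)
        assert again.temperature == pytest.approx(exp.temperature)
        assert np.allclose(again.injection_volumes, exp.injection_volumes)
        assert np.allclose(again.heats, exp.heats)

    def test_pnpp_roundtrip(self):
        S, v, _ = gen_pnpp(0.5e-3, 1e-6, noise_sd=0.01, seed=2)
        buf = io.StringIO()
        write_pnpp_csv(S, v, buf)
        buf.seek(0)
        S2, v2 = read_pnpp_csv(buf)
        assert np.allclose(S2, S)
        assert np.allclose(v2, v)

    def test_missing_header_rejected(self):
        with pytest.raises(ValueError, match="header missing"):
            read_itc_csv(io.StringIO("injection_index,injection_volume_uL,heat_ucal\n1,10,-5\n"))
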