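"""Binding-heat model, mass balance, fitting, and derived thermodynamics."""

import math

import numpy as np
import pytest

from tfdna import (
    BindingParams,
    Isotherm,
    SiteClass,
    TitrationProtocol,
    derive_thermo,
    fit_isotherm,
    model_heats,
    read_isotherm_csv,
    simulate_itc,
    subtract_dilution,
    write_isotherm_csv,
)
from tfdna.itc import _free_ligand, _total_concentrations


class TestModelHeats:
    def test_zero_enthalpy_gives_zero_heats(self, protocol):
        p = BindingParams.two_site(0.3, 1e-7, 0.0, 0.2, 1e-8, 0.0)
        assert np.allclose(model_heats(p, protocol), 0.0)

    def test_linearity_in_enthalpy(self, protocol):
        base = BindingParams.one_site(0.5, 1e-7, -4.0)
        doubled = BindingParams.one_site(0.5, 1e-7, -8.0)
        assert np.allclose(2 * model_heats(base, protocol), model_heats(doubled, protocol))

    def test_tight_binding_saturation_limit(self, protocol):
        # c = K * M >> 1000: each injection fully bound pre-equivalence,
        # nothing after; total integrated heat = n * dH * M0 * V0
        n, dh = 0.5, -10.0
        p = BindingParams.one_site(n, 1e-13, dh)
        heats = model_heats(p, protocol)
        assert np.all(heats[:5] == pytest.approx(dh, abs=0.05))
        assert heats[-1] == pytest.approx(0.0, abs=0.05)
        # exact saturating oracle: cumulative Q_i = V0*dH*min(X_i, n*M_i),
        # pushed through the same displacement bookkeeping
        m_tot, x_tot = _total_concentrations(protocol)
        v0_l = protocol.cell_volume_ul * 1e-6
        q = v0_l * dh * np.minimum(x_tot, n * m_tot)
        q_prev = np.concatenate([[0.0], q[:-1]])
        dv = np.array(protocol.injection_volumes_ul) / protocol.cell_volume_ul
        moles = np.array(protocol.injection_volumes_ul) * 1e-6 * protocol.syringe_concentration_uM * 1e-6
        oracle = (q - q_prev + dv * (q + q_prev) / 2.0) / moles
        # agreement everywhere except the single equivalence-crossing injection
        err = np.abs(heats - oracle)
        assert np.sum(err > 1e-3) <= 1
        assert float(np.sum(heats * moles)) == pytest.approx(float(np.sum(oracle * moles)), rel=1e-4)

    def test_two_site_collapses_to_one_site_when_degenerate(self, protocol):
        two = BindingParams.two_site(0.3, 2e-7, -8.0, 0.25, 2e-7, -8.0)
        one = BindingParams.one_site(0.55, 2e-7, -8.0)
        assert np.abs(model_heats(two, protocol) - model_heats(one, protocol)).max() < 1e-9

    def test_mass_balance_residual_on_random_draws(self, rng):
        for _ in range(1000):
            n_sites = int(rng.integers(1, 3))
            sites = tuple(
                SiteClass(
                    n=float(rng.uniform(0.1, 2.0)),
                    K=float(10 ** rng.uniform(4, 9)),
                    dH=float(rng.uniform(-30, 30)),
                )
                for _ in range(n_sites)
            )
            x_tot = float(10 ** rng.uniform(-7, -4))
            m_tot = float(10 ** rng.uniform(-7, -4))
            x_free = _free_ligand(x_tot, m_tot, sites)
            bound = sum(s.n * m_tot * s.K * x_free / (1 + s.K * x_free) for s in sites)
            assert abs(x_free + bound - x_tot) <= 1e-10 * x_tot


class TestFitIsotherm:
    def test_one_site_recovery_from_noise_free_data(self, protocol):
        truth = BindingParams.one_site(0.52, 200e-9, -10.1)
        fit = fit_isotherm(simulate_itc(truth, protocol), "one-site", n_starts=10, seed=2)
        s = fit.params.sites[0]
        assert s.Kd == pytest.approx(200e-9, rel=1e-3)
        assert s.dH == pytest.approx(-10.1, rel=1e-3)
        assert s.n == pytest.approx(0.52, rel=1e-3)

    def test_two_site_ordered_weakest_first(self, protocol):
        truth = BindingParams.two_site(0.26, 330e-9, -25.8, 0.23, 33e-9, 15.5)
        fit = fit_isotherm(simulate_itc(truth, protocol), "two-site", n_starts=30, seed=2)
        s1, s2 = fit.params.sites
        assert s1.K < s2.K
        assert s1.Kd == pytest.approx(330e-9, rel=0.01)
        assert s2.Kd == pytest.approx(33e-9, rel=0.01)

    def test_self_consistency_over_random_parameter_draws(self, protocol, rng):
        for _ in range(15):
            truth = BindingParams.one_site(
                n=float(rng.uniform(0.3, 1.5)),
                Kd_M=float(10 ** rng.uniform(-9, -5)),
                dH=float(rng.choice([-1.0, 1.0]) * rng.uniform(1, 30)),
            )
            fit = fit_isotherm(simulate_itc(truth, protocol), "one-site", n_starts=8, seed=7)
            got = fit.params.sites[0]
            want = truth.sites[0]
            assert got.Kd == pytest.approx(want.Kd, rel=0.01)
            assert got.dH == pytest.approx(want.dH, rel=0.01)
            assert got.n == pytest.approx(want.n, rel=0.01)

    def test_confidence_interval_coverage_under_noise(self, protocol):
        # 95% Wald interval on ln K should cover the generating value in at
        # least 90% of noisy replicates
        truth = BindingParams.one_site(0.52, 200e-9, -10.1)
        lnk_true = math.log(1.0 / 200e-9)
        covered = 0
        n_rep = 50
        for seed in range(n_rep):
            iso = simulate_itc(truth, protocol, noise_sd=0.3, seed=seed)
            fit = fit_isotherm(iso, "one-site", n_starts=8, seed=seed)
            se = fit.stderr["lnK"]
            assert se is not None
            if abs(math.log(fit.params.sites[0].K) - lnk_true) <= 1.96 * se:
                covered += 1
        assert covered >= 0.9 * n_rep

    def test_drop_first_recovers_despite_corrupted_first_injection(self, protocol):
        truth = BindingParams.one_site(0.52, 200e-9, -10.1)
        iso = simulate_itc(truth, protocol)
        iso.heats[0] *= 0.4  # typical first-injection heat loss
        fit = fit_isotherm(iso, "one-site", n_starts=8, seed=4, drop_first=True)
        assert fit.params.sites[0].Kd == pytest.approx(200e-9, rel=1e-3)

    def test_too_few_injections_rejected(self):
        proto = TitrationProtocol(injection_volumes_ul=(1.5,) * 5)
        iso = simulate_itc(BindingParams.one_site(0.5, 1e-7, -8.0), proto)
        with pytest.raises(ValueError):
            fit_isotherm(iso, "two-site")


class TestSubtractDilution:
    def test_zero_blank_is_identity(self, protocol):
        iso = simulate_itc(BindingParams.one_site(0.5, 1e-7, -8.0), protocol)
        blank = Isotherm(protocol=protocol, heats=np.zeros(protocol.n_injections))
        assert np.array_equal(subtract_dilution(iso, blank).heats, iso.heats)

    def test_sample_equals_blank_gives_zero(self, protocol):
        iso = simulate_itc(BindingParams.one_site(0.5, 1e-7, -8.0), protocol)
        assert np.allclose(subtract_dilution(iso, iso).heats, 0.0)

    def test_constant_offset_shifts_heats(self, protocol):
        iso = simulate_itc(BindingParams.one_site(0.5, 1e-7, -8.0), protocol)
        blank = Isotherm(protocol=protocol, heats=np.full(protocol.n_injections, 0.25))
        assert np.allclose(subtract_dilution(iso, blank).heats, iso.heats - 0.25)

    def test_length_mismatch_rejected(self, protocol):
        iso = simulate_itc(BindingParams.one_site(0.5, 1e-7, -8.0), protocol)
        short = Isotherm(
            protocol=TitrationProtocol(injection_volumes_ul=(1.5,) * 10),
            heats=np.zeros(10),
        )
        with pytest.raises(ValueError):
            subtract_dilution(iso, short)


class TestDeriveThermo:
    def test_unit_association_constant_gives_zero_free_energy(self):
        th = derive_thermo(BindingParams(sites=(SiteClass(n=1.0, K=1.0, dH=-5.0),)), 298.15)[0]
        assert th["dG"] == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_at_200_nanomolar(self):
        th = derive_thermo(BindingParams.one_site(0.52, 200e-9, -10.1), 298.15)[0]
        assert th["dG"] == pytest.approx(-1.9872e-3 * 298.15 * math.log(1.0 / 200e-9), abs=1e-9)
        assert th["dG"] == pytest.approx(-9.14, abs=0.01)
        # TdS follows as dH - dG
        assert th["TdS"] == pytest.approx(-10.1 + 9.139, abs=0.01)

    def test_enthalpy_entropy_combination(self):
        # dH = -10.1 kcal/mol and dS = -2.7 cal/mol/K recombine to
        # dH - T dS ~ -9.30 kcal/mol at 298.15 K
        dG = -10.1 - 298.15 * (-2.7e-3)
        assert dG == pytest.approx(-9.295, abs=0.005)


class TestIsothermCsv:
    def test_round_trip(self, protocol, tmp_path):
        iso = simulate_itc(BindingParams.one_site(0.5, 1e-7, -8.0), protocol, 0.2, seed=3)
        path = tmp_path / "iso.csv"
        write_isotherm_csv(iso, path)
        back = read_isotherm_csv(path, protocol)
        assert np.allclose(back.heats, iso.heats, atol=1e-9)
        assert back.protocol.injection_volumes_ul == protocol.injection_volumes_ul

    def test_bad_header_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b,c\n1,2,3\n")
        with pytest.raises(ValueError):
            read_isotherm_csv(path)
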