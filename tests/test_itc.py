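"""ITC bookkeeping, one-site model behaviour, and parameter recovery."""

import numpy as np
import pytest

from quadbind.binding import Thermodynamics
from quadbind.datasets import itc_thermodynamics_table
from quadbind.itc import (
    InjectionSchedule,
    OneSiteItcModel,
    build_isotherm,
    correct_heat_of_dilution,
    derive_thermodynamics,
    fit_one_site,
    one_site_heats,
)
from quadbind.simulate import ItcSimConfig, gen_itc_experiment

STUDY_SCHEDULE = InjectionSchedule(
    cell_volume=200.0, cell_conc=5.0, syringe_conc=200.0,
    injections=(2.0,) * 20,
)


def exact_dilution_oracle(schedule):
    """Exact stepwise overflow dilution: add dv of syringe, mix, overflow dv."""
    v0 = schedule.cell_volume
    x, m = 0.0, schedule.cell_conc
    xs, ms = [], []
    for dv in schedule.injections:
        x = (x * v0 + schedule.syringe_conc * dv) / (v0 + dv)
        m = m * v0 / (v0 + dv)
        xs.append(x)
        ms.append(m)
    return np.array(xs), np.array(ms)


class TestBuildIsotherm:
    def test_concentrations_match_exact_dilution_oracle_within_1pct(self):
        iso = build_isotherm(STUDY_SCHEDULE, np.ones(20))
        x_exact, m_exact = exact_dilution_oracle(STUDY_SCHEDULE)
        np.testing.assert_allclose(iso.titrant_cell, x_exact, rtol=0.01)
        np.testing.assert_allclose(iso.macromol_cell, m_exact, rtol=0.01)

    def test_molar_ratio_strictly_increasing(self):
        iso = build_isotherm(STUDY_SCHEDULE, np.zeros(20))
        assert np.all(np.diff(iso.molar_ratio) > 0)

    def test_vanishing_injection_volume_leaves_cell_unchanged(self):
        tiny = InjectionSchedule(
            cell_volume=200.0, cell_conc=5.0, syringe_conc=200.0,
            injections=(1e-9,) * 6,
        )
        iso = build_isotherm(tiny, np.zeros(6))
        np.testing.assert_allclose(iso.macromol_cell, 5.0, rtol=1e-10)
        np.testing.assert_allclose(iso.titrant_cell, 0.0, atol=1e-6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="one heat per injection"):
            build_isotherm(STUDY_SCHEDULE, np.ones(7))

    def test_overfill_warns_but_builds(self, caplog):
        big = InjectionSchedule(
            cell_volume=30.0, cell_conc=5.0, syringe_conc=200.0,
            injections=(2.0,) * 20,
        )
        with caplog.at_level("WARNING", logger="quadbind.itc"):
            build_isotherm(big, np.zeros(20))
        assert "exceeds cell volume" in caplog.text


class TestOneSiteHeats:
    def test_zero_enthalpy_gives_pure_baseline(self):
        ndh = one_site_heats(STUDY_SCHEDULE, n=1.0, kd=1.0, dH=0.0, baseline=0.3)
        np.testing.assert_allclose(ndh, 0.3, atol=1e-12)

    def test_stoichiometric_limit_steps_at_molar_ratio_n(self):
        # kd -> 0: every injected mole binds until sites fill, then nothing
        n = 0.8
        ndh = one_site_heats(STUDY_SCHEDULE, n=n, kd=1e-6, dH=-40.0)
        iso = build_isotherm(STUDY_SCHEDULE, np.zeros(20))
        pre = iso.molar_ratio < n - 0.1
        post = iso.molar_ratio > n + 0.2
        np.testing.assert_allclose(ndh[pre], -40.0, rtol=0.01)
        np.testing.assert_allclose(ndh[post], 0.0, atol=0.4)

    def test_sigmoid_inflection_near_stoichiometry(self):
        # steepest descent of the study-parameter isotherm sits near n
        ndh = one_site_heats(STUDY_SCHEDULE, n=0.82, kd=0.92, dH=-41.88)
        iso = build_isotherm(STUDY_SCHEDULE, np.zeros(20))
        slopes = np.diff(ndh) / np.diff(iso.molar_ratio)
        mid = (iso.molar_ratio[1:] + iso.molar_ratio[:-1]) / 2
        assert mid[np.argmax(np.abs(slopes))] == pytest.approx(0.82, abs=0.3)

    def test_total_heat_conservation_at_saturation(self):
        n, dh = 0.9, -30.0
        ndh = one_site_heats(STUDY_SCHEDULE, n=n, kd=0.05, dH=dh)
        dv = np.asarray(STUDY_SCHEDULE.injections)
        total_ucal = np.sum(ndh * STUDY_SCHEDULE.syringe_conc * dv * 1e-3)
        expected = n * STUDY_SCHEDULE.cell_conc * STUDY_SCHEDULE.cell_volume * dh * 1e-3
        assert total_ucal == pytest.approx(expected, rel=0.02)


class TestFitOneSite:
    def test_noise_free_recovery_is_exact(self):
        schedule, heats = gen_itc_experiment(
            ItcSimConfig(seed=0, n=1.04, kd=2.37, dH=-19.7,
                         noise_frac=0.0, noise_floor=0.0)
        )
        fit = fit_one_site(build_isotherm(schedule, heats))
        assert fit.ok
        assert fit.n == pytest.approx(1.04, rel=1e-4)
        assert fit.kd == pytest.approx(2.37, rel=1e-4)
        assert fit.dH == pytest.approx(-19.7, rel=1e-4)

    def test_recovery_within_reported_bands_at_2pct_noise(self):
        kds, ns = [], []
        for seed in range(50):
            schedule, heats = gen_itc_experiment(ItcSimConfig(seed=100 + seed))
            fit = fit_one_site(build_isotherm(schedule, heats))
            kds.append(fit.kd)
            ns.append(fit.n)
        assert np.median(kds) == pytest.approx(0.92, abs=0.17)
        assert np.median(ns) == pytest.approx(0.82, abs=0.04)

    def test_low_c_experiment_is_flagged(self):
        # weak-binding parameters: c = 1.06 * 5 / 9 ~ 0.6
        schedule, heats = gen_itc_experiment(
            ItcSimConfig(seed=1, n=1.06, kd=9.0, dH=-0.67,
                         noise_frac=0.0, noise_floor=0.0)
        )
        fit = fit_one_site(build_isotherm(schedule, heats))
        assert fit.c == pytest.approx(1.06 * 5.0 / 9.0, rel=0.3)
        assert "low_c" in fit.flags

    def test_discard_first_drops_artifact_point(self):
        schedule, heats = gen_itc_experiment(
            ItcSimConfig(seed=2, noise_frac=0.0, noise_floor=0.0)
        )
        heats = heats.copy()
        heats[0] *= 0.4  # classic short first injection
        fit = fit_one_site(build_isotherm(schedule, heats), discard_first=True)
        assert fit.kd == pytest.approx(0.92, rel=1e-3)
        assert fit.n == pytest.approx(0.82, rel=1e-3)

    def test_fit_invariant_to_heat_unit_rescaling(self):
        schedule, heats = gen_itc_experiment(ItcSimConfig(seed=3))
        fit_ucal = fit_one_site(build_isotherm(schedule, heats))
        # same run recorded in mcal with concentrations in mM: dH and the
        # normalized heats are unchanged, kd scales with the unit
        schedule_m = InjectionSchedule(
            cell_volume=schedule.cell_volume,
            cell_conc=schedule.cell_conc * 1e3,
            syringe_conc=schedule.syringe_conc * 1e3,
            injections=schedule.injections,
        )
        model = OneSiteItcModel(kd_bounds=(1e-4, 1e7))
        model.fit(build_isotherm(schedule_m, heats * 1e3))
        assert model.kd_ / 1e3 == pytest.approx(fit_ucal.kd, rel=1e-3)
        assert model.n_ == pytest.approx(fit_ucal.n, rel=1e-3)

    def test_too_few_injections_rejected(self):
        short = InjectionSchedule(
            cell_volume=200.0, cell_conc=5.0, syringe_conc=200.0,
            injections=(2.0,) * 5,
        )
        with pytest.raises(ValueError, match="6 usable"):
            fit_one_site(build_isotherm(short, np.ones(5)))

    def test_round_trip_all_reference_parameter_sets(self):
        # simulate -> fit at every protein-RNA reference row (2% noise,
        # 5 seeds each); recovered medians stay within 3 Monte-Carlo SDs
        table = itc_thermodynamics_table()
        for row in table.itertuples():
            kds = []
            for s in range(5):
                schedule, heats = gen_itc_experiment(
                    ItcSimConfig(seed=1000 + 10 * row.Index + s,
                                 n=row.n, kd=row.kd_uM, dH=row.dH_kcal)
                )
                kds.append(fit_one_site(build_isotherm(schedule, heats)).kd)
            spread = max(np.std(kds, ddof=1), 0.02 * row.kd_uM)
            assert abs(np.median(kds) - row.kd_uM) < 3 * spread, row.experiment


class TestDilutionCorrection:
    def test_subtracting_zero_control_is_identity(self):
        schedule, heats = gen_itc_experiment(ItcSimConfig(seed=4))
        iso = build_isotherm(schedule, heats)
        ctrl = build_isotherm(schedule, np.zeros(20))
        out = correct_heat_of_dilution(iso, "control_titration", control=ctrl)
        np.testing.assert_allclose(out.normalized_heats, iso.normalized_heats)

    def test_tail_average_zeroes_saturated_heats(self):
        schedule, heats = gen_itc_experiment(
            ItcSimConfig(seed=5, dilution_heat=-0.8,
                         noise_frac=0.0, noise_floor=0.0)
        )
        out = correct_heat_of_dilution(build_isotherm(schedule, heats))
        assert np.abs(out.normalized_heats[-3:]).max() < 0.05

    def test_control_and_tail_modes_agree_for_constant_dilution_heat(self):
        # tight binding so the tail is fully saturated: tail_average then
        # removes exactly the constant dilution heat, like the control run
        cfg = ItcSimConfig(seed=6, kd=0.05, dilution_heat=-0.8,
                           noise_frac=0.0, noise_floor=0.0)
        schedule, heats = gen_itc_experiment(cfg)
        iso = build_isotherm(schedule, heats)
        ctrl_heats = (
            -0.8 * schedule.syringe_conc * np.asarray(schedule.injections) * 1e-3
        )
        ctrl = build_isotherm(schedule, ctrl_heats)
        by_control = correct_heat_of_dilution(iso, "control_titration", control=ctrl)
        by_tail = correct_heat_of_dilution(iso, "tail_average")
        np.testing.assert_allclose(
            by_control.normalized_heats, by_tail.normalized_heats, atol=0.05
        )

    def test_control_length_mismatch_rejected(self):
        schedule, heats = gen_itc_experiment(ItcSimConfig(seed=7))
        iso = build_isotherm(schedule, heats)
        short = InjectionSchedule(
            cell_volume=200.0, cell_conc=5.0, syringe_conc=200.0,
            injections=(2.0,) * 10,
        )
        ctrl = build_isotherm(short, np.zeros(10))
        with pytest.raises(ValueError, match="lengths differ"):
            correct_heat_of_dilution(iso, "control_titration", control=ctrl)


class TestThermogramIntegration:
    def make_thermogram(self, heats, spacing=180.0, tau=15.0, dt=0.5,
                        drift=(0.5, 0.001)):
        """Exponential injection pulses of known area on a linear baseline."""
        from quadbind.itc import integrate_thermogram

        inj_times = 60.0 + spacing * np.arange(len(heats))
        t = np.arange(0.0, inj_times[-1] + spacing, dt)
        p = drift[0] + drift[1] * t
        for ti, q in zip(inj_times, heats):
            mask = t >= ti
            p[mask] += (q / tau) * np.exp(-(t[mask] - ti) / tau)
        return t, p, inj_times, integrate_thermogram(t, p, inj_times)

    def test_recovers_known_pulse_areas(self):
        truth = np.array([-5.0, -4.1, -2.7, -1.2, -0.4, -0.1, 0.3, -0.05])
        *_, heats = self.make_thermogram(truth)
        np.testing.assert_allclose(heats, truth, atol=0.05)

    def test_injections_outside_trace_rejected(self):
        from quadbind.itc import integrate_thermogram

        t = np.arange(0.0, 100.0, 0.5)
        with pytest.raises(ValueError, match="inside the trace"):
            integrate_thermogram(t, np.zeros(len(t)), [150.0])

    def test_thermogram_file_path_matches_integrated_heats(self, tmp_path):
        from quadbind.io import read_itc_thermogram

        truth = np.array([-6.0, -3.0, -1.5, -0.7, -0.3, -0.1])
        t, p, inj_times, _ = self.make_thermogram(truth)
        data = tmp_path / "trace.csv"
        data.write_text(
            "# cell_volume_ul: 200\n# cell_conc_uM: 5\n# syringe_conc_uM: 200\n"
            + "time_s,power_ucal_per_s\n"
            + "\n".join(f"{a},{b:.6g}" for a, b in zip(t, p))
            + "\n"
        )
        side = tmp_path / "inj.csv"
        side.write_text(
            "time_s,injection_ul\n"
            + "\n".join(f"{ti},2.0" for ti in inj_times) + "\n"
        )
        schedule, heats = read_itc_thermogram(data, side)
        assert schedule.injections == (2.0,) * 6
        np.testing.assert_allclose(heats, truth, atol=0.05)


class TestDerivedThermodynamics:
    def test_completes_fit_with_identities(self):
        schedule, heats = gen_itc_experiment(
            ItcSimConfig(seed=8, n=1.04, kd=2.37, dH=-19.7,
                         noise_frac=0.0, noise_floor=0.0)
        )
        fit = fit_one_site(build_isotherm(schedule, heats))
        thermo = derive_thermodynamics(fit, 298.15)
        assert isinstance(thermo, Thermodynamics)
        assert thermo.dG == pytest.approx(-7.67, abs=0.02)
        assert thermo.TdS == pytest.approx(-12.03, abs=0.03)
        r1, r2 = thermo.identity_residuals()
        assert abs(r1) < 1e-10 and abs(r2) < 1e-10
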