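"""Synthetic-cohort generator: distributions, determinism, physiology."""

import json

import numpy as np
import pytest
from scipy import stats as sps

from cuffcomfort import (DEFAULT_POPULATION, CohortDesign, Epoch,
                         PopulationParams, SimConfig, SimulationError,
                         StimulusSchedule, build_schedule, compute_sto2,
                         draw_scr_events, sample_subject, simulate_cohort,
                         simulate_eda, simulate_nirs, simulate_vas)
from cuffcomfort.simulate import bateman_kernel

from conftest import pressure_epoch, quiet_profile


# ---------------------------------------------------------------------------
# subject sampling
# ---------------------------------------------------------------------------

class TestSampleSubject:
    def test_zero_dispersion_returns_population_means(self):
        fields = {k: (m, 0.0) for k, (m, _) in DEFAULT_POPULATION.fields.items()}
        prof = sample_subject(PopulationParams(fields=fields), 0)
        for name, (mean, _) in fields.items():
            got = getattr(prof, name)
            if name == "sto2_drop_max_pct":  # clipped against the baseline
                assert got == min(mean, fields["sto2_baseline_pct"][0] - 2.0)
            else:
                assert got == pytest.approx(mean)

    def test_same_rng_state_gives_identical_profiles(self):
        p1 = sample_subject(DEFAULT_POPULATION, 42)
        p2 = sample_subject(DEFAULT_POPULATION, 42)
        assert p1 == p2

    def test_negative_dispersion_rejected(self):
        bad = dict(DEFAULT_POPULATION.fields)
        bad["scr_amp_median_uS"] = (0.3, -0.1)
        with pytest.raises(SimulationError, match="dispersion"):
            PopulationParams(fields=bad)

    def test_amp_median_sample_mean_matches_population(self):
        """10,000 draws land within 3 standard errors of the stated mean."""
        mean, sd = DEFAULT_POPULATION.fields["scr_amp_median_uS"]
        rng = np.random.default_rng(7)
        draws = np.array([
            sample_subject(DEFAULT_POPULATION, rng).scr_amp_median_uS
            for _ in range(10_000)])
        assert abs(draws.mean() - mean) < 3 * sd / np.sqrt(draws.size)


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------

class TestSchedule:
    def test_overlapping_epochs_rejected(self):
        with pytest.raises(SimulationError, match="overlap"):
            StimulusSchedule(epochs=[Epoch(10, 60, 10), Epoch(50, 60, 20)])

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(SimulationError, match="duration"):
            StimulusSchedule(epochs=[Epoch(10, 0, 10)])

    def test_builder_layout(self):
        s = build_schedule([20, 10, 30], 60, rest_s=100, pre_s=50)
        assert [e.label for e in s.epochs] == ["anchor"] + ["pressure"] * 3
        assert [e.pressure_kPa for e in s.pressure_epochs] == [20, 10, 30]
        gaps = np.diff([e.onset_s for e in s.epochs[1:]])
        assert np.allclose(gaps, 160.0)


# ---------------------------------------------------------------------------
# EDA simulator
# ---------------------------------------------------------------------------

class TestSimulateEDA:
    def test_silent_subject_constant_trace(self, profile, schedule, noise_free):
        rec = simulate_eda(profile, schedule, noise_free, seed=0)
        assert np.allclose(rec.eda_uS, 5.0, atol=1e-12)

    def test_unit_peak_kernel_normalization(self, profile, noise_free):
        """A single forced unit event raises the trace by exactly its
        amplitude (1 kHz grid resolves the kernel peak)."""
        sched = StimulusSchedule(epochs=[], total_duration_s=60.0)
        cfg = SimConfig(fs_eda_hz=1000.0, eda_noise_sd_uS=0.0)
        rec = simulate_eda(profile, sched, cfg, seed=0, events=[(10.0, 1.0)])
        assert rec.eda_uS.max() - 5.0 == pytest.approx(1.0, abs=1e-6)

    def test_kernel_shape(self):
        t = np.arange(0, 60, 1e-3)
        k = bateman_kernel(t, 0.75, 4.0)
        assert k.max() == pytest.approx(1.0, abs=1e-6)
        assert k[0] == 0.0 and bateman_kernel(np.array([-1.0]), 0.75, 4.0)[0] == 0.0

    def test_poisson_event_count_oracle(self):
        """Empirical mean event count over seeded replicates matches lambda*T
        within 3 standard errors of the Poisson mean."""
        lam_per_min, window_s = 6.0, 600.0
        prof = quiet_profile(scr_rate_base_per_min=lam_per_min)
        sched = StimulusSchedule(epochs=[], total_duration_s=window_s)
        rng = np.random.default_rng(11)
        n_rep = 500
        counts = [len(draw_scr_events(prof, sched, rng)) for _ in range(n_rep)]
        expected = lam_per_min * window_s / 60.0
        se = np.sqrt(expected / n_rep)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_seeded_reproducibility(self, profile, schedule):
        cfg = SimConfig(fs_eda_hz=25.0)
        r1 = simulate_eda(profile, schedule, cfg, seed=3)
        r2 = simulate_eda(profile, schedule, cfg, seed=3)
        assert np.array_equal(r1.eda_uS, r2.eda_uS)


# ---------------------------------------------------------------------------
# NIRS simulator
# ---------------------------------------------------------------------------

class TestSimulateNIRS:
    def test_no_epochs_constant_baseline(self, profile, noise_free):
        sched = StimulusSchedule(epochs=[], total_duration_s=200.0)
        rec = simulate_nirs(profile, sched, noise_free, seed=0)
        sto2 = compute_sto2(rec)
        assert np.allclose(sto2.sto2_pct, 70.0, atol=1e-9)

    @pytest.mark.parametrize("factor", [1.0, 1.5])
    def test_occlusion_plateau(self, noise_free, factor):
        """At and above the occlusion pressure the asymptote is identical."""
        prof = quiet_profile(sto2_drop_exponent=2.0)
        p = 20.0 * factor
        sched = StimulusSchedule(epochs=[Epoch(50.0, 900.0, p)],
                                 total_duration_s=1000.0)
        rec = simulate_nirs(prof, sched, noise_free, seed=0)
        sto2 = compute_sto2(rec)
        i = np.searchsorted(rec.time_s, 949.0)
        assert sto2.sto2_pct[i] == pytest.approx(10.0, abs=1e-3)

    def test_closed_form_asymptote_linear_exponent(self, noise_free):
        """P=10, P_occ=20, drop 60 from 70, gamma=1 -> terminal 40%."""
        prof = quiet_profile(sto2_drop_exponent=1.0, sto2_tau_s=30.0)
        sched = StimulusSchedule(epochs=[Epoch(50.0, 600.0, 10.0)],
                                 total_duration_s=700.0)
        rec = simulate_nirs(prof, sched, noise_free, seed=0)
        sto2 = compute_sto2(rec)
        i = np.searchsorted(rec.time_s, 649.0)
        assert sto2.sto2_pct[i] == pytest.approx(40.0, abs=0.01)

    def test_hemoglobin_conservation_and_roundtrip(self, profile, schedule,
                                                   noise_free):
        rec = simulate_nirs(profile, schedule, noise_free, seed=0)
        total = rec.oxyHb_au + rec.deoxyHb_au
        assert np.allclose(total, noise_free.total_hb_au, atol=1e-12)
        sto2 = compute_sto2(rec)
        assert np.allclose(sto2.sto2_pct, rec.meta["latent_sto2_pct"], atol=1e-9)


# ---------------------------------------------------------------------------
# VAS simulator
# ---------------------------------------------------------------------------

class TestSimulateVAS:
    def test_anchor_clips_at_ceiling(self, schedule):
        prof = quiet_profile(vas_sensitivity=1.0)
        cfg = SimConfig(vas_noise_sd=0.0)
        doc = simulate_vas(prof, schedule, seed=0, config=cfg)
        assert doc["anchor"]["vas_raw"] == 10.0

    def test_monotone_in_pressure_without_noise(self):
        prof = quiet_profile(vas_sensitivity=0.8)
        sched = build_schedule([10, 20, 30], 60, rest_s=60, pre_s=30)
        doc = simulate_vas(prof, sched, seed=0, config=SimConfig(vas_noise_sd=0.0))
        by_p = {r["pressure_kPa"]: r["vas_raw"] for r in doc["ratings"]}
        assert by_p[10] < by_p[20] < by_p[30]

    def test_clipped_mean_matches_censored_normal_oracle(self, schedule):
        """Empirical mean of clip(N(mu, sd), 0, 10) at 20 kPa vs closed form."""
        prof = quiet_profile(vas_sensitivity=0.9)
        sched = build_schedule([20.0], 60, rest_s=60, pre_s=30)
        sd = 0.5
        cfg = SimConfig(vas_noise_sd=sd)
        draws = np.array([
            simulate_vas(prof, sched, seed=s, config=cfg)["ratings"][0]["vas_raw"]
            for s in range(1000)])
        mu = 0.9 * 20.0 / 6.0
        a, b = (0 - mu) / sd, (10 - mu) / sd  # censoring points
        expected = (mu * (sps.norm.cdf(b) - sps.norm.cdf(a))
                    + sd * (sps.norm.pdf(a) - sps.norm.pdf(b))
                    + 0.0 * sps.norm.cdf(a) + 10.0 * sps.norm.sf(b))
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - expected) < 3 * se


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def small_design(**kw):
    base = dict(n_subjects=13, epoch_duration_s=60.0, measure_nirs=False,
                rest_s=90.0, pre_s=40.0, tail_s=30.0,
                sim_config=SimConfig(fs_eda_hz=20.0))
    base.update(kw)
    return CohortDesign(**base)


class TestSimulateCohort:
    def test_layout_13_subjects(self, tmp_path):
        out = tmp_path / "cohort"
        simulate_cohort(small_design(), seed=5, out_dir=out)
        dirs = sorted(d for d in out.iterdir() if d.is_dir())
        assert len(dirs) == 13
        for d in dirs:
            lines = [l for l in (d / "events.tsv").read_text().splitlines()
                     if l and not l.startswith("#")][1:]
            labels = [l.split("\t")[3] for l in lines]
            assert labels.count("pressure") == 3 and labels.count("anchor") == 1

    def test_manifest_byte_identical(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        simulate_cohort(small_design(), seed=9, out_dir=a)
        simulate_cohort(small_design(), seed=9, out_dir=b)
        assert (a / "manifest.json").read_bytes() == (b / "manifest.json").read_bytes()
        eda_a = (a / "S07" / "eda.csv").read_bytes()
        assert eda_a == (b / "S07" / "eda.csv").read_bytes()

    def test_output_collision_raises(self, tmp_path):
        out = tmp_path / "c"
        simulate_cohort(small_design(n_subjects=2), seed=1, out_dir=out)
        with pytest.raises(FileExistsError):
            simulate_cohort(small_design(n_subjects=2), seed=2, out_dir=out)

    def test_randomized_order_varies_across_subjects(self):
        cohort = simulate_cohort(small_design(), seed=3)
        orders = {tuple(e.pressure_kPa for e in sd.schedule.pressure_epochs)
                  for sd in cohort.subjects}
        assert len(orders) > 1

    def test_design_validation(self):
        with pytest.raises(SimulationError):
            CohortDesign(n_subjects=1)
        with pytest.raises(SimulationError):
            CohortDesign(n_subjects=5, pressures_kPa=(10.0, 10.0, 30.0))

    def test_cohort_mean_scr_counts_increase_with_pressure(self):
        """Across a 20-seed sweep, cohort-mean SCR counts order
        10 < 20 < 30 kPa in at least 18 of 20 cohorts."""
        from cuffcomfort.pipeline import extract_features

        hits = 0
        for seed in range(20):
            cohort = simulate_cohort(small_design(), seed=1000 + seed)
            tab = extract_features(cohort)
            m = tab.groupby("pressure_kPa")["scr_count"].mean()
            hits += bool(m[10.0] < m[20.0] < m[30.0])
        assert hits >= 18
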