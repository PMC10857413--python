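"""Synthetic cuff-pressure cohorts: EDA, NIRS, and VAS generators.

Emulates within-subject pressure-cuff experiments on the thigh: pressure
epochs at 10/20/30 kPa (1-min or 5-min), applied in randomized order with
rest periods in between, preceded by a brief 60 kPa anchor stimulus used to
normalize the discomfort ratings.

Signal models
-------------
EDA (sampled at ``fs_eda_hz``) is a sum of

* a tonic level: subject baseline + optional linear drift
  + a pressure-coupled rise (``tonic_gain_uS_per_kPa * P``, smoothed at the
  epoch edges by a raised-cosine ramp)
  - an epoch-locked adaptation dip that relaxes toward
  ``scl_dip_uS + scl_dip_gain_uS_per_kPa * P`` with time constant
  ``scl_dip_tau_s`` during pressure and recovers during rest (tonic skin
  conductance habituates under a sustained stimulus);
* a phasic SCR train: an inhomogeneous Poisson process whose rate is
  ``scr_rate_base_per_min`` at rest and grows linearly with pressure during
  epochs; each event contributes a unit-peak Bateman kernel
  ``b(t) = A (e^{-t/tau_d} - e^{-t/tau_r})`` scaled by a lognormal amplitude
  whose median grows linearly with pressure;
* white Gaussian measurement noise.

NIRS (5 Hz) follows a latent first-order tissue-oxygen-saturation
trajectory: at epoch onset StO2 relaxes toward an asymptote

    S_inf(P) = baseline - drop_max * (min(P, P_occ) / P_occ) ** gamma

— constant above the occlusion pressure ``P_occ`` (vessels already fully
occluded) and convex below it — with an effective time constant that
shortens as pressure grows (stronger compression occludes faster), and
recovers toward baseline during rest.  Oxy/deoxy-hemoglobin are derived
from the saturation at constant total hemoglobin, plus noise.

VAS is a clipped linear map of pressure, ``clip(k * P / 6 + noise, 0, 10)``,
with a per-subject sensitivity ``k``; the anchor rating is generated by the
same stochastic rule at 60 kPa.

Seeding: one master seed; per-subject, per-signal substreams are derived as
``SeedSequence(master_seed, spawn_key=(subject_index, stream))`` with
streams 0=profile, 1=order, 2=EDA, 3=NIRS, 4=VAS.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .eda import EDARecording
from .nirs import NIRSRecording

# substream identifiers for the seeding contract
_STREAM_PROFILE, _STREAM_ORDER, _STREAM_EDA, _STREAM_NIRS, _STREAM_VAS = range(5)


class SimulationError(ValueError):
    """Raised for invalid simulation parameters or schedules."""


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Epoch:
    """One pressure application, half-open [onset_s, onset_s + duration_s)."""

    onset_s: float
    duration_s: float
    pressure_kPa: float
    label: str = "pressure"

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class StimulusSchedule:
    """Ordered, non-overlapping pressure epochs plus the anchor stimulus."""

    epochs: list[Epoch]
    rest_s: float = 300.0
    anchor_pressure_kPa: float = 60.0
    anchor_duration_s: float = 5.0
    total_duration_s: float | None = None

    def __post_init__(self) -> None:
        prev_end = -np.inf
        prev_onset = -np.inf
        for ep in self.epochs:
            if ep.duration_s <= 0:
                raise SimulationError(f"epoch at {ep.onset_s}s has non-positive duration")
            if ep.pressure_kPa <= 0:
                raise SimulationError(f"epoch at {ep.onset_s}s has non-positive pressure")
            if ep.onset_s <= prev_onset:
                raise SimulationError("epoch onsets must be strictly increasing")
            if ep.onset_s < prev_end:
                raise SimulationError(f"epoch at {ep.onset_s}s overlaps the previous one")
            prev_onset, prev_end = ep.onset_s, ep.offset_s
        if self.total_duration_s is None:
            self.total_duration_s = prev_end + 60.0
        elif self.total_duration_s < prev_end:
            raise SimulationError("total_duration_s shorter than the last epoch")

    @property
    def pressure_epochs(self) -> list[Epoch]:
        return [e for e in self.epochs if e.label == "pressure"]


def build_schedule(
    pressures_kPa: Sequence[float],
    epoch_duration_s: float,
    rest_s: float = 300.0,
    pre_s: float = 60.0,
    tail_s: float = 60.0,
    anchor_pressure_kPa: float = 60.0,
    anchor_duration_s: float = 5.0,
) -> StimulusSchedule:
    """Standard session layout: rest, anchor, rest, then the pressure epochs
    separated by ``rest_s`` of recovery, in the order given."""
    epochs = [Epoch(pre_s, anchor_duration_s, anchor_pressure_kPa, label="anchor")]
    t = pre_s + anchor_duration_s + rest_s
    for p in pressures_kPa:
        epochs.append(Epoch(t, epoch_duration_s, float(p)))
        t += epoch_duration_s + rest_s
    total = epochs[-1].offset_s + tail_s
    return StimulusSchedule(epochs=epochs, rest_s=rest_s,
                            anchor_pressure_kPa=anchor_pressure_kPa,
                            anchor_duration_s=anchor_duration_s,
                            total_duration_s=total)


# ---------------------------------------------------------------------------
# configuration and subject profiles
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Instrument-level simulation settings."""

    fs_eda_hz: float = 1000.0
    fs_nirs_hz: float = 5.0
    eda_noise_sd_uS: float = 0.003
    nirs_noise_sd_au: float = 1.0
    scr_tau_rise_s: float = 0.75
    scr_tau_decay_s: float = 4.0
    scr_amp_cap_uS: float = 2.0  # physiological ceiling on single-SCR size
    total_hb_au: float = 100.0
    occlusion_pressure_kPa: float = 20.0
    vas_noise_sd: float = 0.5
    ramp_s: float = 2.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.fs_eda_hz <= 0 or self.fs_nirs_hz <= 0:
            raise SimulationError("sampling rates must be positive")
        if not 0 < self.scr_tau_rise_s < self.scr_tau_decay_s:
            raise SimulationError("need scr_tau_decay_s > scr_tau_rise_s > 0")
        if self.total_hb_au <= 0 or self.occlusion_pressure_kPa <= 0:
            raise SimulationError("total_hb_au and occlusion pressure must be positive")


@dataclass
class SubjectProfile:
    """Per-subject physiological parameters (the cohort heterogeneity model)."""

    subject_id: str
    scl_baseline_uS: float
    scr_rate_base_per_min: float
    scr_rate_gain_per_kPa: float   # per minute per kPa
    scr_amp_median_uS: float
    scr_amp_gain_per_kPa: float    # multiplicative, per kPa
    tonic_gain_uS_per_kPa: float
    sto2_baseline_pct: float
    sto2_drop_max_pct: float
    sto2_tau_s: float
    vas_sensitivity: float
    # adaptation / shape parameters beyond the minimal model
    scl_drift_uS_per_s: float = 0.0
    scl_dip_uS: float = 0.0
    scl_dip_gain_uS_per_kPa: float = 0.0
    scl_dip_pow: float = 1.0        # Stevens-type power-law pressure coupling
    scl_dip_tau_s: float = 30.0
    scr_amp_sigma_log: float = 0.85
    sto2_drop_exponent: float = 1.0
    sto2_recovery_tau_s: float = 25.0  # reactive hyperemia is fast

    def validate(self) -> "SubjectProfile":
        nonneg = ["scr_rate_base_per_min", "scr_rate_gain_per_kPa",
                  "scr_amp_gain_per_kPa", "tonic_gain_uS_per_kPa",
                  "scl_dip_uS", "scl_dip_gain_uS_per_kPa"]
        for name in nonneg:
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be non-negative")
        positive = ["scl_baseline_uS", "scr_amp_median_uS", "sto2_tau_s",
                    "vas_sensitivity", "scl_dip_tau_s", "scl_dip_pow",
                    "scr_amp_sigma_log", "sto2_drop_exponent",
                    "sto2_recovery_tau_s"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be positive")
        if not 0 < self.sto2_baseline_pct <= 100:
            raise SimulationError("sto2_baseline_pct must lie in (0, 100]")
        if not 0 <= self.sto2_drop_max_pct <= 100:
            raise SimulationError("sto2_drop_max_pct must lie in [0, 100]")
        if self.sto2_baseline_pct - self.sto2_drop_max_pct < 0:
            raise SimulationError("sto2 drop may not exceed the baseline")
        return self


@dataclass
class PopulationParams:
    """Mean/SD table for each :class:`SubjectProfile` field.

    Fields are drawn independently from normal distributions truncated at a
    per-field physiological floor (default dispersions are small relative to
    their means, so the truncation is essentially inactive).
    """

    fields: Mapping[str, tuple[float, float]]

    _FLOORS = {
        "scl_baseline_uS": 0.5, "scr_rate_base_per_min": 0.2,
        "scr_rate_gain_per_kPa": 0.0, "scr_amp_median_uS": 0.02,
        "scr_amp_gain_per_kPa": 0.0, "tonic_gain_uS_per_kPa": 0.0,
        "sto2_baseline_pct": 40.0, "sto2_drop_max_pct": 5.0,
        "sto2_tau_s": 20.0, "vas_sensitivity": 0.2,
        "scl_drift_uS_per_s": None,  # may be negative (habituation)
        "scl_dip_uS": 0.0, "scl_dip_gain_uS_per_kPa": 0.0,
        "scl_dip_tau_s": 5.0, "scl_dip_pow": 0.5, "scr_amp_sigma_log": 0.1,
        "sto2_drop_exponent": 0.5, "sto2_recovery_tau_s": 5.0,
    }

    def __post_init__(self) -> None:
        for name, (_, sd) in self.fields.items():
            if name not in self._FLOORS:
                raise SimulationError(f"unknown profile field {name!r}")
            if sd < 0:
                raise SimulationError(f"negative dispersion for {name!r}")


#: Default population, calibrated so that cohort-level feature summaries land
#: in the physiological reference range for both the 1-min and 5-min designs.
DEFAULT_POPULATION = PopulationParams(fields={
    "scl_baseline_uS": (6.0, 1.5),
    "scl_drift_uS_per_s": (0.0, 0.0),
    "scl_dip_uS": (0.185, 0.02),
    "scl_dip_gain_uS_per_kPa": (0.0035, 0.0002),
    "scl_dip_pow": (1.38, 0.0),
    "scl_dip_tau_s": (30.0, 0.0),
    "scr_rate_base_per_min": (1.0, 0.3),
    "scr_rate_gain_per_kPa": (0.40, 0.05),
    "scr_amp_median_uS": (0.13, 0.025),
    "scr_amp_sigma_log": (0.85, 0.0),
    "scr_amp_gain_per_kPa": (0.030, 0.005),
    "tonic_gain_uS_per_kPa": (0.002, 0.0003),
    "sto2_baseline_pct": (70.0, 4.0),
    "sto2_drop_max_pct": (62.0, 12.0),
    "sto2_drop_exponent": (2.0, 0.3),
    "sto2_tau_s": (120.0, 20.0),
    "sto2_recovery_tau_s": (25.0, 5.0),
    "vas_sensitivity": (0.85, 0.15),
})


def sample_subject(
    population_params: PopulationParams,
    rng_state: np.random.Generator | int,
    subject_id: str = "S01",
) -> SubjectProfile:
    """Draw one subject profile; deterministic given the generator state."""
    rng = np.random.default_rng(rng_state) if isinstance(rng_state, int) else rng_state
    values: dict[str, float] = {}
    # iterate in a fixed order so the draw sequence is reproducible
    for name in sorted(population_params.fields):
        mean, sd = population_params.fields[name]
        v = float(rng.normal(mean, sd)) if sd > 0 else float(mean)
        floor = PopulationParams._FLOORS[name]
        if floor is not None:
            v = max(v, floor)
        values[name] = v
    # the drop may not exceed the subject's own baseline
    if "sto2_drop_max_pct" in values and "sto2_baseline_pct" in values:
        values["sto2_drop_max_pct"] = min(values["sto2_drop_max_pct"],
                                          values["sto2_baseline_pct"] - 2.0)
    return SubjectProfile(subject_id=subject_id, **values).validate()


# ---------------------------------------------------------------------------
# signal-building primitives
# ---------------------------------------------------------------------------

def bateman_kernel(t: np.ndarray, tau_rise_s: float, tau_decay_s: float) -> np.ndarray:
    """Unit-peak Bateman SCR kernel, zero for t < 0."""
    t = np.asarray(t, dtype=float)
    t_peak = (tau_rise_s * tau_decay_s / (tau_decay_s - tau_rise_s)) \
        * np.log(tau_decay_s / tau_rise_s)
    peak = np.exp(-t_peak / tau_decay_s) - np.exp(-t_peak / tau_rise_s)
    out = np.where(t >= 0,
                   np.exp(-np.maximum(t, 0) / tau_decay_s)
                   - np.exp(-np.maximum(t, 0) / tau_rise_s), 0.0)
    return out / peak


def _relax_piecewise(
    time_s: np.ndarray,
    segments: Iterable[tuple[float, float, float, float]],
    y0: float,
) -> np.ndarray:
    """Exact first-order relaxation through (t0, t1, target, tau) segments.

    Within each segment y(t) = target + (y(t0) - target) exp(-(t-t0)/tau);
    the state is carried continuously across segment boundaries.
    """
    y = np.full(time_s.shape, y0, dtype=float)
    state = y0
    for t0, t1, target, tau in segments:
        m = (time_s >= t0) & (time_s < t1)
        if m.any():
            y[m] = target + (state - target) * np.exp(-(time_s[m] - t0) / tau)
        state = target + (state - target) * np.exp(-(t1 - t0) / tau)
        y[time_s >= t1] = state
    return y


def _pressure_segments(schedule: StimulusSchedule) -> list[tuple[float, float, float]]:
    """(t0, t1, pressure) tiling of the whole session; rest has pressure 0."""
    segs: list[tuple[float, float, float]] = []
    t = 0.0
    for ep in schedule.epochs:
        if ep.onset_s > t:
            segs.append((t, ep.onset_s, 0.0))
        segs.append((ep.onset_s, ep.offset_s, ep.pressure_kPa))
        t = ep.offset_s
    if schedule.total_duration_s > t:
        segs.append((t, schedule.total_duration_s, 0.0))
    return segs


def draw_scr_events(
    profile: SubjectProfile,
    schedule: StimulusSchedule,
    rng: np.random.Generator,
    amp_cap_uS: float | None = 2.0,
) -> list[tuple[float, float]]:
    """Sample the (time, amplitude) SCR train for one session.

    Piecewise-homogeneous Poisson process: rate ``base + gain * P`` during
    epochs and ``base`` at rest (per minute); amplitudes are lognormal with
    median ``scr_amp_median_uS * (1 + scr_amp_gain_per_kPa * P)``, capped
    at ``amp_cap_uS`` (single responses beyond ~2 uS are not physiological).
    """
    events: list[tuple[float, float]] = []
    for t0, t1, p in _pressure_segments(schedule):
        rate_per_s = (profile.scr_rate_base_per_min
                      + profile.scr_rate_gain_per_kPa * p) / 60.0
        n = rng.poisson(rate_per_s * (t1 - t0))
        times = np.sort(rng.uniform(t0, t1, size=n))
        median = profile.scr_amp_median_uS * (1.0 + profile.scr_amp_gain_per_kPa * p)
        amps = median * np.exp(profile.scr_amp_sigma_log * rng.standard_normal(n))
        if amp_cap_uS is not None:
            amps = np.minimum(amps, amp_cap_uS)
        events.extend(zip(times.tolist(), amps.tolist()))
    events.sort()
    return events


def _epoch_envelope(time_s: np.ndarray, schedule: StimulusSchedule,
                    ramp_s: float) -> np.ndarray:
    """Pressure envelope (kPa) with raised-cosine edges of width ramp_s."""
    env = np.zeros_like(time_s)
    for ep in schedule.epochs:
        r = min(ramp_s, ep.duration_s / 2.0)
        up = (time_s >= ep.onset_s) & (time_s < ep.onset_s + r)
        hold = (time_s >= ep.onset_s + r) & (time_s < ep.offset_s - r)
        down = (time_s >= ep.offset_s - r) & (time_s < ep.offset_s)
        env[up] += ep.pressure_kPa * 0.5 * (1 - np.cos(np.pi * (time_s[up] - ep.onset_s) / r))
        env[hold] += ep.pressure_kPa
        env[down] += ep.pressure_kPa * 0.5 * (1 - np.cos(np.pi * (ep.offset_s - time_s[down]) / r))
    return env


# ---------------------------------------------------------------------------
# simulators
# ---------------------------------------------------------------------------

def simulate_eda(
    profile: SubjectProfile,
    schedule: StimulusSchedule,
    config: SimConfig | None = None,
    seed: int | np.random.Generator | None = None,
    events: Sequence[tuple[float, float]] | None = None,
) -> EDARecording:
    """Simulate one EDA session; ground-truth SCR events are kept in
    ``recording.meta['scr_events']``.

    ``events`` overrides the Poisson draw with an explicit (time, amplitude)
    train, e.g. for detector validation.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    profile.validate()
    n = int(round(schedule.total_duration_s * config.fs_eda_hz))
    t = np.arange(n) / config.fs_eda_hz

    # tonic: baseline + drift + smoothed pressure coupling - adaptation dip
    tonic = profile.scl_baseline_uS + profile.scl_drift_uS_per_s * t
    tonic = tonic + profile.tonic_gain_uS_per_kPa * _epoch_envelope(t, schedule, config.ramp_s)
    dip_segments = []
    for t0, t1, p in _pressure_segments(schedule):
        target = (profile.scl_dip_uS
                  + profile.scl_dip_gain_uS_per_kPa * p ** profile.scl_dip_pow) \
            if p > 0 else 0.0
        dip_segments.append((t0, t1, target, profile.scl_dip_tau_s))
    tonic = tonic - _relax_piecewise(t, dip_segments, 0.0)

    if events is None:
        events = draw_scr_events(profile, schedule, rng,
                                 amp_cap_uS=config.scr_amp_cap_uS)
    else:
        events = sorted((float(et), float(ea)) for et, ea in events)

    x = tonic.copy()
    support = int(round(15.0 * config.scr_tau_decay_s * config.fs_eda_hz))
    kernel_t = np.arange(support) / config.fs_eda_hz
    kernel = bateman_kernel(kernel_t, config.scr_tau_rise_s, config.scr_tau_decay_s)
    for et, amp in events:
        i0 = int(np.ceil(et * config.fs_eda_hz))
        if i0 >= n:
            continue
        frac = i0 / config.fs_eda_hz - et
        k = amp * bateman_kernel(kernel_t + frac, config.scr_tau_rise_s,
                                 config.scr_tau_decay_s) if frac > 0 else amp * kernel
        stop = min(n, i0 + support)
        x[i0:stop] += k[: stop - i0]

    if config.eda_noise_sd_uS > 0:
        x = x + rng.normal(0.0, config.eda_noise_sd_uS, size=n)

    return EDARecording(time_s=t, eda_uS=x, fs_hz=config.fs_eda_hz,
                        meta={"scr_events": list(events),
                              "subject_id": profile.subject_id})


def latent_sto2(
    profile: SubjectProfile,
    schedule: StimulusSchedule,
    time_s: np.ndarray,
    occlusion_pressure_kPa: float = 20.0,
) -> np.ndarray:
    """Noise-free latent StO2 trajectory (%) on the given time grid."""
    p_occ = occlusion_pressure_kPa
    segments = []
    for t0, t1, p in _pressure_segments(schedule):
        if p > 0:
            frac = (min(p, p_occ) / p_occ) ** profile.sto2_drop_exponent
            target = profile.sto2_baseline_pct - profile.sto2_drop_max_pct * frac
            tau = profile.sto2_tau_s * p_occ / p  # faster occlusion at higher P
        else:
            target, tau = profile.sto2_baseline_pct, profile.sto2_recovery_tau_s
        segments.append((t0, t1, target, tau))
    return _relax_piecewise(time_s, segments, profile.sto2_baseline_pct)


def simulate_nirs(
    profile: SubjectProfile,
    schedule: StimulusSchedule,
    config: SimConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> NIRSRecording:
    """Simulate one NIRS session at constant total hemoglobin."""
    config = config or SimConfig()
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    profile.validate()
    n = int(round(schedule.total_duration_s * config.fs_nirs_hz))
    t = np.arange(n) / config.fs_nirs_hz
    sto2 = latent_sto2(profile, schedule, t, config.occlusion_pressure_kPa)
    oxy = config.total_hb_au * sto2 / 100.0
    deoxy = config.total_hb_au - oxy
    if config.nirs_noise_sd_au > 0:
        oxy = oxy + rng.normal(0.0, config.nirs_noise_sd_au, size=n)
        deoxy = deoxy + rng.normal(0.0, config.nirs_noise_sd_au, size=n)
    return NIRSRecording(time_s=t, oxyHb_au=oxy, deoxyHb_au=deoxy,
                         fs_hz=config.fs_nirs_hz,
                         meta={"latent_sto2_pct": sto2,
                               "subject_id": profile.subject_id})


def simulate_vas(
    profile: SubjectProfile,
    schedule: StimulusSchedule,
    seed: int | np.random.Generator | None = None,
    config: SimConfig | None = None,
) -> dict:
    """Per-epoch raw VAS ratings plus the 60 kPa anchor rating.

    Rating model: ``clip(sensitivity * P / 6 + noise, 0, 10)`` — the
    anchor pressure of 60 kPa maps to ``10 * sensitivity`` before noise.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(seed if seed is not None else config.seed)

    def rating(p: float) -> float:
        raw = profile.vas_sensitivity * p / 6.0 + rng.normal(0.0, config.vas_noise_sd)
        return float(np.clip(raw, 0.0, 10.0))

    # draw in schedule order (anchor occurs first in the session)
    ratings = []
    anchor = None
    for ep in schedule.epochs:
        if ep.label == "anchor":
            anchor = {"pressure_kPa": ep.pressure_kPa, "vas_raw": rating(ep.pressure_kPa)}
        else:
            ratings.append({"pressure_kPa": ep.pressure_kPa,
                            "onset_s": ep.onset_s,
                            "vas_raw": rating(ep.pressure_kPa)})
    if anchor is None:
        anchor = {"pressure_kPa": schedule.anchor_pressure_kPa,
                  "vas_raw": rating(schedule.anchor_pressure_kPa)}
    return {"subject_id": profile.subject_id, "ratings": ratings, "anchor": anchor}


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortDesign:
    """Experimental design for a simulated cohort.

    The two standard designs: 13 subjects x 1-min epochs (EDA only) and
    10 subjects x 5-min epochs (EDA + NIRS), pressures {10, 20, 30} kPa in
    per-subject randomized order with 5-min rests.
    """

    n_subjects: int
    epoch_duration_s: float = 60.0
    pressures_kPa: tuple[float, ...] = (10.0, 20.0, 30.0)
    randomize_order: bool = True
    measure_nirs: bool = True
    rest_s: float = 300.0
    pre_s: float = 60.0
    tail_s: float = 60.0
    population: PopulationParams = field(default_factory=lambda: DEFAULT_POPULATION)
    sim_config: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise SimulationError("need at least 2 subjects")
        if len(set(self.pressures_kPa)) != len(self.pressures_kPa) \
                or any(p <= 0 for p in self.pressures_kPa):
            raise SimulationError("pressures must be distinct and positive")
        if self.epoch_duration_s <= 0:
            raise SimulationError("epoch duration must be positive")


@dataclass
class SubjectData:
    profile: SubjectProfile
    schedule: StimulusSchedule
    eda: EDARecording
    nirs: NIRSRecording | None
    vas: dict


@dataclass
class Cohort:
    design: CohortDesign
    seed: int
    subjects: list[SubjectData]
    manifest: dict


def _substream(master_seed: int, subject_index: int, stream: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=master_seed,
                                spawn_key=(subject_index, stream))
    return np.random.default_rng(ss)


def simulate_cohort(
    design: CohortDesign,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> Cohort:
    """Simulate a full cohort; optionally write the on-disk layout.

    Each subject gets an independently permuted condition order (when
    ``randomize_order``) and independent RNG substreams, so the cohort is a
    pure function of ``(design, seed)``.  With ``out_dir``, one directory
    per subject is written (``eda.csv``, ``nirs.csv``, ``events.tsv``,
    ``vas.json``) plus a cohort ``manifest.json``.
    """
    if seed is None:
        seed = design.sim_config.seed
    if seed is None:
        raise SimulationError("a master seed is required")
    seed = int(seed)

    subjects: list[SubjectData] = []
    manifest_subjects = []
    for i in range(design.n_subjects):
        sid = f"S{i + 1:02d}"
        profile = sample_subject(design.population,
                                 _substream(seed, i, _STREAM_PROFILE), sid)
        order = list(design.pressures_kPa)
        if design.randomize_order:
            order = [order[j] for j in
                     _substream(seed, i, _STREAM_ORDER).permutation(len(order))]
        schedule = build_schedule(order, design.epoch_duration_s,
                                  rest_s=design.rest_s, pre_s=design.pre_s,
                                  tail_s=design.tail_s)
        eda = simulate_eda(profile, schedule, design.sim_config,
                           _substream(seed, i, _STREAM_EDA))
        nirs = None
        if design.measure_nirs:
            nirs = simulate_nirs(profile, schedule, design.sim_config,
                                 _substream(seed, i, _STREAM_NIRS))
        vas = simulate_vas(profile, schedule,
                           _substream(seed, i, _STREAM_VAS), design.sim_config)
        subjects.append(SubjectData(profile, schedule, eda, nirs, vas))
        prof_dict = {k: v for k, v in asdict(profile).items()}
        manifest_subjects.append({
            "subject_id": sid,
            "condition_order_kPa": [float(p) for p in order],
            "profile": prof_dict,
            "seed_spawn_keys": {"profile": [i, _STREAM_PROFILE],
                                "order": [i, _STREAM_ORDER],
                                "eda": [i, _STREAM_EDA],
                                "nirs": [i, _STREAM_NIRS],
                                "vas": [i, _STREAM_VAS]},
        })

    design_dict = asdict(design)
    design_dict["population"] = {k: list(v) for k, v in design.population.fields.items()}
    manifest = {
        "format": "cuffcomfort-cohort/1",
        "master_seed": seed,
        "design": design_dict,
        "units": {"time": "s", "pressure": "kPa", "conductance": "uS",
                  "hemoglobin": "arbitrary", "epochs": "half-open [onset, offset)"},
        "subjects": manifest_subjects,
    }
    cohort = Cohort(design=design, seed=seed, subjects=subjects, manifest=manifest)
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


_HEADER = ("# cuffcomfort: times in seconds; epochs half-open [onset_s, offset_s); "
           "pressures in kPa; conductance in uS\n")


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write the documented per-subject directory layout and manifest."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()):
        raise FileExistsError(f"output directory {out} exists and is not empty")
    out.mkdir(parents=True, exist_ok=True)
    for sd in cohort.subjects:
        d = out / sd.profile.subject_id
        d.mkdir()
        with open(d / "eda.csv", "w") as fh:
            fh.write(_HEADER)
            fh.write("time_s,eda_uS\n")
            np.savetxt(fh, np.column_stack([sd.eda.time_s, sd.eda.eda_uS]),
                       fmt=["%.4f", "%.6f"], delimiter=",")
        if sd.nirs is not None:
            with open(d / "nirs.csv", "w") as fh:
                fh.write(_HEADER)
                fh.write("time_s,oxyHb_au,deoxyHb_au\n")
                np.savetxt(fh, np.column_stack([sd.nirs.time_s, sd.nirs.oxyHb_au,
                                                sd.nirs.deoxyHb_au]),
                           fmt=["%.4f", "%.6f", "%.6f"], delimiter=",")
        with open(d / "events.tsv", "w") as fh:
            fh.write(_HEADER)
            fh.write("onset_s\toffset_s\tpressure_kPa\tlabel\n")
            for ep in sd.schedule.epochs:
                fh.write(f"{ep.onset_s:.3f}\t{ep.offset_s:.3f}\t"
                         f"{ep.pressure_kPa:g}\t{ep.label}\n")
        with open(d / "vas.json", "w") as fh:
            json.dump(sd.vas, fh, indent=2, sort_keys=True)
            fh.write("\n")
    with open(out / "manifest.json", "w") as fh:
        json.dump(cohort.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


__all__ = [
    "SimulationError", "Epoch", "StimulusSchedule", "build_schedule",
    "SimConfig", "SubjectProfile", "PopulationParams", "DEFAULT_POPULATION",
    "sample_subject", "bateman_kernel", "draw_scr_events", "latent_sto2",
    "simulate_eda", "simulate_nirs", "simulate_vas",
    "CohortDesign", "SubjectData", "Cohort", "simulate_cohort", "write_cohort",
]
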