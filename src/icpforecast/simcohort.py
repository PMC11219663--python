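"""Synthetic neuromonitoring cohorts with known ground truth.

Real ICU recordings of intracranial pressure (ICP), mean arterial pressure
(MAP) and ICP pulse amplitude (AMP) are not publicly shareable, so every
downstream stage of this package is exercised on simulated patients whose
outcome (intracranial hypertension, IH; severe IH, SIH) is planted by
construction.

The per-patient signal model, at the sample level (default 1 Hz), is

    ICP(t) = b_icp + slow(t) + sigma_icp * fast_icp(t) + episode(t)
    MAP(t) = b_map + slow_map(t) + sigma_cpp * fast_map(t)
    AMP(t) = b_amp + k * (ICP(t) - b_icp) + sigma_amp * e_amp(t)

where ``slow`` mixes a plateau-level process (random ICP levels held for
tens of minutes with smoothed transitions, emulating the locally flat,
occasionally shifting character of slow ICP) with B-wave-band AR(1)
fluctuations (tau ~ 60 s).  The MAP slow component shares the ICP slow
component with weight ``rho`` (the PRx coupling target) and mixes in an
independent process with weight sqrt(1 - rho^2), so the slow-band ICP-MAP
correlation is rho by construction.  ``fast_*`` are short-memory AR(1) processes whose innovation
scales control the irregularity (sample entropy / Lempel-Ziv complexity) of
the epoch-averaged series.  Planted IH/SIH episodes are trapezoidal
excursions above the 22 mmHg treatment threshold, starting strictly after
the 6-h feature-extraction window; background fluctuations are damped
during an episode (plateau waves suppress variability) so a planted episode
is never fragmented by noise.

Group effect directions follow the clinical pattern reported for IH-positive
TBI patients: higher baseline ICP, stronger ICP-MAP coupling (PRx), more
irregular CPP, *less* irregular ICP, lower admission GCS, and (for SIH)
higher age.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

__all__ = [
    "GroupEffect",
    "SimConfig",
    "GroundTruth",
    "RawRecording",
    "draw_ground_truths",
    "simulate_patient",
    "simulate_cohort",
    "simulate_pulse_icp",
]


@dataclass(frozen=True)
class GroupEffect:
    """A simulator parameter that differs between outcome groups.

    ``sih`` defaults to the positive-group value; it lets severe-IH patients
    carry a stronger effect (e.g. baseline ICP 14 vs 12 mmHg) without a
    separate configuration axis.
    """

    negative: float
    positive: float
    sih: float | None = None

    def value(self, is_ih: bool, is_sih: bool) -> float:
        if is_sih:
            return self.positive if self.sih is None else self.sih
        return self.positive if is_ih else self.negative


@dataclass(frozen=True)
class SimConfig:
    """Cohort- and signal-level simulation settings.

    Defaults emulate the study conditions this package replicates: a cohort
    with 62.3% IH prevalence of whom ~70% progress to SIH, 24-h recordings at
    1 Hz, graded group-mean baseline ICP 9 / 10.5 / 14 mmHg (negative / mild
    IH / SIH) with 4-mmHg between-patient spread,
    and event onsets drawn log-normally after the 6-h feature window with
    median latencies near 9.8 h (IH) and 11.2 h (SIH).
    """

    n_patients: int = 69
    prevalence_ih: float = 0.623
    prevalence_sih_given_ih: float = 30 / 43
    record_hours: float = 24.0
    sample_period_s: float = 1.0
    seed: int = 0

    # group-dependent effects (reported clinical contrast directions)
    icp_baseline_mmHg: GroupEffect = GroupEffect(9.0, 10.5, 14.0)
    icp_baseline_sd_mmHg: float = 4.0
    prx_coupling_sd: float = 0.12
    irregularity_log_sd: float = 0.35
    dwell_log_sd: float = 0.30
    prx_coupling: GroupEffect = GroupEffect(0.18, 0.30, 0.68)
    cpp_irregularity: GroupEffect = GroupEffect(0.50, 0.58, 0.85)
    icp_irregularity: GroupEffect = GroupEffect(0.10, 0.07, 0.025)
    age_mean_years: GroupEffect = GroupEffect(50.0, 54.0, 59.0)
    gcs_mean: GroupEffect = GroupEffect(9.0, 7.2, 6.8)

    # group-independent signal scales (mmHg unless noted)
    map_baseline_mmHg: float = 88.0
    map_baseline_sd_mmHg: float = 9.0
    level_sd_mmHg: float = 2.0
    level_dwell_s: GroupEffect = GroupEffect(800.0, 1100.0, 1800.0)
    level_trans_s: float = 300.0
    slow_amp_icp: GroupEffect = GroupEffect(0.16, 0.13, 0.09)
    slow_tau_s: float = 60.0
    slow_amp_map: float = 3.0
    fast_tau_s: float = 15.0
    amp_baseline_mmHg: float = 1.5
    amp_icp_coupling: float = 0.12
    amp_noise_mmHg: float = 0.25
    amp_noise_tau_s: float = 30.0

    # planted episodes
    ih_onset_hours_range: tuple[float, float] = (7.0, 22.0)
    ih_latency_median_h: float = 9.8
    sih_latency_median_h: float = 11.2
    latency_log_sd: float = 1.0
    ih_duration_min_range: tuple[float, float] = (8.0, 30.0)
    sih_duration_min_range: tuple[float, float] = (70.0, 150.0)
    episode_peak_mmHg: float = 29.0
    episode_ramp_s: float = 2.0
    episode_noise_damp: float = 0.25
    icp_ceiling_mmHg: float = 21.5
    ceiling_softness_mmHg: float = 0.5

    # demographics
    male_fraction: float = 0.667
    age_sd_years: float = 12.0
    gcs_sd: float = 2.4

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("prevalence_ih", "prevalence_sih_given_ih"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.record_hours < 18.0:
            raise ValueError("record_hours must be >= 18")
        if self.sample_period_s <= 0:
            raise ValueError("sample_period_s must be positive")
        lo, hi = self.ih_onset_hours_range
        if not 6.0 < lo < hi:
            raise ValueError("ih_onset_hours_range must lie entirely after hour 6")
        if self.ih_duration_min_range[0] <= 5.0:
            raise ValueError("planted IH durations must exceed 5 min")
        if self.sih_duration_min_range[0] <= 60.0:
            raise ValueError("planted SIH durations must exceed 60 min")


@dataclass(frozen=True)
class GroundTruth:
    """Planted outcome and effect sizes for one simulated patient."""

    patient_id: str
    is_ih: bool
    is_sih: bool
    planted_onset_hours: float | None = None
    planted_duration_min: float | None = None
    planted_group_params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.is_sih and not self.is_ih:
            raise ValueError("is_sih implies is_ih")
        if self.is_ih:
            if self.planted_duration_min is None or self.planted_duration_min <= 5.0:
                raise ValueError("planted IH episodes must last > 5 min")
            if self.is_sih and self.planted_duration_min <= 60.0:
                raise ValueError("planted SIH episodes must last > 60 min")


@dataclass
class RawRecording:
    """Uniformly sampled ICP / MAP / AMP channels for one patient."""

    patient_id: str
    sample_period_s: float
    icp: np.ndarray
    abp_mean: np.ndarray
    amp: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.icp) == len(self.abp_mean) == len(self.amp)):
            raise ValueError("all channels must have equal length")

    @property
    def duration_hours(self) -> float:
        return len(self.icp) * self.sample_period_s / 3600.0


def _patient_rng(seed: int, patient_id: str) -> np.random.Generator:
    # substream keyed by a hash of the id: cohort composition is invariant
    # to generation order
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(patient_id.encode("utf8"))])
    )


def _ar1(rng: np.random.Generator, n: int, tau_s: float, dt: float) -> np.ndarray:
    """Stationary unit-variance AR(1) process with correlation time tau_s."""
    phi = float(np.exp(-dt / tau_s))
    burn = int(5 * tau_s / dt)
    e = rng.standard_normal(n + burn) * np.sqrt(1.0 - phi * phi)
    x = lfilter([1.0], [1.0, -phi], e)
    return x[burn:]


def _levels(
    rng: np.random.Generator, n: int, dwell_s: float, trans_s: float, dt: float
) -> np.ndarray:
    """Plateau-level process: unit-SD random levels held for ~dwell_s each.

    Transitions are smoothed over ``trans_s`` (moving average).  This
    reproduces the locally flat, occasionally shifting character of slow
    intracranial pressure, which is what keeps the epoch-series sample
    entropy and Lempel-Ziv complexity low.
    """
    x = np.empty(n)
    i = 0
    min_dwell = int(60.0 / dt)
    while i < n:
        d = int(rng.exponential(dwell_s / dt)) + min_dwell
        x[i : i + d] = rng.normal(0.0, 1.0)
        i += d
    k = max(int(trans_s / dt), 1)
    kern = np.ones(k) / k
    return np.convolve(x, kern, mode="same")


def draw_ground_truths(config: SimConfig) -> list[GroundTruth]:
    """Draw outcome flags, episode placement and per-patient effect sizes.

    Cheap (no signals); ``simulate_cohort`` builds on this.  Deterministic:
    each patient uses a substream derived from (seed, patient_id).
    """
    config.validate()
    truths: list[GroundTruth] = []
    for i in range(config.n_patients):
        pid = f"P{i + 1:04d}"
        rng = _patient_rng(config.seed, pid)
        is_ih = bool(rng.random() < config.prevalence_ih)
        is_sih = bool(is_ih and rng.random() < config.prevalence_sih_given_ih)
        onset = duration = None
        if is_ih:
            lo_d, hi_d = (
                config.sih_duration_min_range if is_sih else config.ih_duration_min_range
            )
            duration = float(rng.uniform(lo_d, hi_d))
            median = (
                config.sih_latency_median_h if is_sih else config.ih_latency_median_h
            )
            latency = float(
                np.exp(np.log(median) + config.latency_log_sd * rng.standard_normal())
            )
            lo, hi = config.ih_onset_hours_range
            hi = min(hi, config.record_hours - duration / 60.0 - 0.25)
            onset = float(np.clip(6.0 + latency, lo, hi))
        # per-patient effect sizes: group means with between-patient spread,
        # matching the reported within-group dispersion (so the prediction
        # tasks have realistic, overlapping feature distributions)
        jitter = lambda mu, sd_log: float(mu * np.exp(sd_log * rng.standard_normal()))
        params = {
            "icp_baseline_mmHg": float(
                np.clip(
                    rng.normal(
                        config.icp_baseline_mmHg.value(is_ih, is_sih),
                        config.icp_baseline_sd_mmHg,
                    ),
                    4.0,
                    17.0,
                )
            ),
            "prx_coupling": float(
                np.clip(
                    rng.normal(
                        config.prx_coupling.value(is_ih, is_sih), config.prx_coupling_sd
                    ),
                    0.02,
                    0.92,
                )
            ),
            "cpp_irregularity": jitter(
                config.cpp_irregularity.value(is_ih, is_sih), config.irregularity_log_sd
            ),
            "icp_irregularity": jitter(
                config.icp_irregularity.value(is_ih, is_sih), config.irregularity_log_sd
            ),
            "level_dwell_s": jitter(
                config.level_dwell_s.value(is_ih, is_sih), config.dwell_log_sd
            ),
            "slow_amp_icp": jitter(
                config.slow_amp_icp.value(is_ih, is_sih), config.irregularity_log_sd
            ),
        }
        truths.append(
            GroundTruth(
                patient_id=pid,
                is_ih=is_ih,
                is_sih=is_sih,
                planted_onset_hours=onset,
                planted_duration_min=duration,
                planted_group_params=params,
            )
        )
    return truths


def simulate_patient(
    config: SimConfig, patient_id: str, outcome: GroundTruth
) -> RawRecording:
    """Simulate one patient's ICP/MAP/AMP recording.

    Deterministic given ``(config.seed, patient_id)``.  The first 6 h never
    contain a qualifying hypertensive run (so the patient always passes the
    early-persistent-IH exclusion filter); if ``outcome.is_ih`` the recording
    contains exactly one planted excursion above 22 mmHg of the stated
    duration, starting at ``outcome.planted_onset_hours``.
    """
    config.validate()
    if outcome.is_sih and not outcome.is_ih:
        raise ValueError("inconsistent outcome: is_sih without is_ih")
    if outcome.is_ih and (
        outcome.planted_onset_hours is None or outcome.planted_onset_hours <= 6.0
    ):
        raise ValueError("planted onset must lie strictly after hour 6")

    dt = config.sample_period_s
    n = int(round(config.record_hours * 3600.0 / dt))
    rng = _patient_rng(config.seed, patient_id)
    map_b = float(
        np.clip(
            rng.normal(config.map_baseline_mmHg, config.map_baseline_sd_mmHg),
            65.0,
            110.0,
        )
    )

    p = dict(outcome.planted_group_params)
    b_icp = p.get("icp_baseline_mmHg", config.icp_baseline_mmHg.value(outcome.is_ih, outcome.is_sih))
    rho = p.get("prx_coupling", config.prx_coupling.value(outcome.is_ih, outcome.is_sih))
    sig_cpp = p.get("cpp_irregularity", config.cpp_irregularity.value(outcome.is_ih, outcome.is_sih))
    sig_icp = p.get("icp_irregularity", config.icp_irregularity.value(outcome.is_ih, outcome.is_sih))
    dwell = p.get("level_dwell_s", config.level_dwell_s.value(outcome.is_ih, outcome.is_sih))
    bw_amp = p.get("slow_amp_icp", config.slow_amp_icp.value(outcome.is_ih, outcome.is_sih))

    # slow structure: plateau levels (vasogenic drift) + B-wave-band AR(1);
    # the whole slow part is shared with MAP at weight rho, so the slow-band
    # ICP-MAP correlation (hence PRx) is controlled by rho
    lev_i = _levels(rng, n, dwell, config.level_trans_s, dt)
    s_i = _ar1(rng, n, config.slow_tau_s, dt)
    lev_m = _levels(rng, n, dwell, config.level_trans_s, dt)
    s_m = _ar1(rng, n, config.slow_tau_s, dt)
    a_v, a_s = config.level_sd_mmHg, bw_amp
    slow_icp = a_v * lev_i + a_s * s_i
    norm = float(np.std(slow_icp)) or 1.0
    z_icp = slow_icp / norm
    z_own_raw = a_v * lev_m + a_s * s_m
    z_own = z_own_raw / (float(np.std(z_own_raw)) or 1.0)
    slow_map = config.slow_amp_map * (rho * z_icp + np.sqrt(1.0 - rho * rho) * z_own)

    fast_i = _ar1(rng, n, config.fast_tau_s, dt)
    fast_m = _ar1(rng, n, config.fast_tau_s, dt)
    e_amp = _ar1(rng, n, config.amp_noise_tau_s, dt)

    fluct_icp = slow_icp + sig_icp * fast_i
    fluct_map = slow_map + sig_cpp * fast_m

    # soft ceiling: background ICP saturates below the 22-mmHg treatment
    # threshold, so only planted episodes can cross it (keeps planted labels
    # exact and the early-persistent-IH exclusion inert by construction)
    c, soft = config.icp_ceiling_mmHg, config.ceiling_softness_mmHg
    background = b_icp + fluct_icp
    background = c - soft * np.logaddexp(0.0, (c - background) / soft)

    # planted episode: trapezoid to a fixed plateau with damped background
    # noise; the ramps are placed so ICP crosses 22 mmHg at exactly the
    # planted onset and again at onset + duration
    episode = np.zeros(n)
    if outcome.is_ih:
        t = np.arange(n) * dt
        t0 = outcome.planted_onset_hours * 3600.0
        t1 = t0 + outcome.planted_duration_min * 60.0
        ramp = config.episode_ramp_s
        rise = config.episode_peak_mmHg - b_icp
        cross = float(np.clip((22.0 - b_icp) / rise, 0.05, 0.95))
        up = np.clip((t - (t0 - ramp * cross)) / ramp, 0.0, 1.0)
        down = np.clip(((t1 + ramp * (1.0 - cross)) - t) / ramp, 0.0, 1.0)
        prof = np.minimum(up, down)
        episode = rise * prof
        # plateau waves suppress background variability during the episode
        background = b_icp + (background - b_icp) * (
            1.0 - (1.0 - config.episode_noise_damp) * prof
        )

    icp = background + episode
    map_ = map_b + fluct_map
    amp = (
        config.amp_baseline_mmHg
        + config.amp_icp_coupling * (icp - b_icp)
        + config.amp_noise_mmHg * e_amp
    )

    n_neg = int((icp < 0).sum() + (map_ < 0).sum() + (amp < 0).sum())
    if n_neg:
        import warnings

        warnings.warn(
            f"{patient_id}: clipped {n_neg} negative pressure samples", stacklevel=2
        )
    icp = np.clip(icp, 0.0, None)
    map_ = np.clip(map_, 0.0, None)
    amp = np.clip(amp, 0.0, None)

    return RawRecording(
        patient_id=patient_id,
        sample_period_s=dt,
        icp=icp,
        abp_mean=map_,
        amp=amp,
    )


def _draw_baseline(
    config: SimConfig, rng: np.random.Generator, truth: GroundTruth
) -> dict[str, float]:
    age_mu = config.age_mean_years.value(truth.is_ih, truth.is_sih)
    gcs_mu = config.gcs_mean.value(truth.is_ih, truth.is_sih)
    age = int(np.clip(round(rng.normal(age_mu, config.age_sd_years)), 18, 90))
    gcs = int(np.clip(round(rng.normal(gcs_mu, config.gcs_sd)), 3, 15))
    sex = int(rng.random() < config.male_fraction)  # 1 = male, 0 = female
    return {"age": age, "sex": sex, "gcs": gcs}


def draw_baselines(config: SimConfig, truths: Sequence[GroundTruth]) -> pd.DataFrame:
    """Baseline covariate table (age, sex, GCS) with group shifts."""
    rows = []
    for truth in truths:
        rng = _patient_rng(config.seed + 1_000_003, truth.patient_id)
        row = {"patient_id": truth.patient_id}
        row.update(_draw_baseline(config, rng, truth))
        row["is_ih"] = int(truth.is_ih)
        row["is_sih"] = int(truth.is_sih)
        row["onset_hours"] = (
            np.nan if truth.planted_onset_hours is None else truth.planted_onset_hours
        )
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_cohort(
    config: SimConfig,
) -> tuple[list[RawRecording], list[GroundTruth], pd.DataFrame]:
    """Simulate a full cohort: recordings, ground truths and baseline table.

    Outcome flags are Bernoulli draws matching the configured prevalences in
    expectation; fully reproducible from ``config.seed``.
    """
    config.validate()
    if config.n_patients < 2:
        raise ValueError("a cohort needs n_patients >= 2")
    truths = draw_ground_truths(config)
    recordings = [simulate_patient(config, t.patient_id, t) for t in truths]
    baselines = draw_baselines(config, truths)
    return recordings, truths, baselines


def simulate_pulse_icp(
    duration_s: float,
    sample_rate_hz: float = 100.0,
    heart_rate_hz: float = 1.2,
    pulse_amp_mmHg: float = 2.0,
    baseline_mmHg: float = 12.0,
    drift_amp_mmHg: float = 0.0,
    drift_period_s: float = 60.0,
    seed: int = 0,
) -> np.ndarray:
    """Short pulse-resolved ICP segment (cardiac sine + optional slow drift).

    Used only to exercise the pulse-amplitude extraction path; the cohort
    simulator itself emits AMP directly at the sample level.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    phase = 2 * np.pi * rng.random()
    pulse = (pulse_amp_mmHg / 2.0) * np.sin(2 * np.pi * heart_rate_hz * t + phase)
    drift = drift_amp_mmHg * np.sin(2 * np.pi * t / drift_period_s)
    return baseline_mmHg + pulse + drift


def with_coupling(config: SimConfig, rho: float) -> SimConfig:
    """Convenience: a copy of ``config`` with a uniform PRx coupling target."""
    return replace(config, prx_coupling=GroupEffect(rho, rho, rho))
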