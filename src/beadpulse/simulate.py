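"""Forward simulation of multifrequency bead-transit waveforms.

Emulates a lock-in-amplifier acquisition: magnitude and phase of the
aperture impedance sampled at 57,000 samples/s at six carrier frequencies
(45 kHz - 35 MHz).  Each bead transit is a symmetric Gaussian-bell
occupancy pulse ``s(t)`` driving the circuit models in
:mod:`beadpulse.circuits`; additive Gaussian channel noise and a slow
sinusoidal baseline drift emulate instrument imperfections (and justify the
high-pass filter in the detection stage).

Two output levels are provided:

* :func:`synthesize_trial` -- full waveform synthesis plus the ground-truth
  event list, for exercising the detection stage end to end;
* :func:`synthesize_bead_records` -- per-bead peak records drawn directly
  from the circuit models plus measurement noise, a fast path for
  metric/dose-level studies where the waveform stage is not under test.

Both are pure functions of their arguments including the seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import circuits
from .circuits import (
    ApertureModel,
    BeadModel,
    BindingParams,
    ShellLink,
    dose_to_metallization,
)
from .errors import ConfigError

__all__ = [
    "DEFAULT_FREQS",
    "AcquisitionConfig",
    "MultiFreqTimeSeries",
    "TransitEvent",
    "TrialSpec",
    "default_transit_tau",
    "ground_truth_frame",
    "synthesize_bead_records",
    "synthesize_trial",
]

#: Default carrier frequencies (Hz), 45 kHz to 35 MHz.
DEFAULT_FREQS = (45e3, 150e3, 380e3, 2e6, 11e6, 35e6)

#: Gaussian FWHM / sigma.
_FWHM = 2.355

#: Minimum event spacing, in units of tau.
_MIN_GAP_TAU = 10.0


def default_transit_tau(
    aperture: ApertureModel,
    bead_diameter: float = 8.2e-6,
    flow_rate_ul_min: float = 10.0,
) -> float:
    """Transit-pulse FWHM (s) from the volumetric flow through the aperture.

    10 uL/min through a 30 um square cross-section gives ~0.185 m/s, so an
    8.2 um bead crosses the ~38 um sensing region in ~0.2 ms.
    """
    area = aperture.side_length**2
    velocity = flow_rate_ul_min * 1e-9 / 60.0 / area
    return (aperture.sensing_length + bead_diameter) / velocity


@dataclass(frozen=True)
class AcquisitionConfig:
    """Lock-in acquisition parameters."""

    sample_rate: float = 57000.0
    freqs: tuple[float, ...] = DEFAULT_FREQS
    duration: float = 1.5
    noise_sd_mag: float = 10.0
    noise_sd_phase: float = 0.5
    drift_amp: float = 200.0
    drift_freq: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ConfigError("sample_rate must be positive")
        if len(self.freqs) != 6:
            raise ConfigError("exactly 6 carrier frequencies are required")
        f = np.asarray(self.freqs)
        if np.any(f <= 0) or np.any(np.diff(f) <= 0):
            raise ConfigError("freqs must be positive and strictly increasing")
        if self.duration <= 0:
            raise ConfigError("duration must be positive")
        for name in ("noise_sd_mag", "noise_sd_phase", "drift_amp"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")


@dataclass(frozen=True)
class TransitEvent:
    """Ground truth for one bead transit."""

    t0: float  # apex time (s)
    tau: float  # pulse FWHM (s)
    amp_scale: float  # off-centre positioning factor
    bead: BeadModel

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ConfigError("tau must be positive")
        if not 0 < self.amp_scale <= 1.2:
            raise ConfigError("amp_scale must lie in (0, 1.2]")


@dataclass(frozen=True)
class TrialSpec:
    """One synthetic assay trial (a bead population at one concentration)."""

    n_beads: int = 60
    probe_concentration: float = 0.0  # nM
    binding_params: BindingParams = field(default_factory=BindingParams)
    heterogeneity_sd: float = 0.6  # lognormal sd of per-bead m_density
    bead_diameter: float = 8.2e-6
    amp_scale_sd: float = 0.05
    tau: float | None = None  # default derived from the flow rate
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_beads <= 0:
            raise ConfigError("n_beads must be positive")
        if self.probe_concentration < 0:
            raise ConfigError("probe_concentration must be non-negative")
        if self.heterogeneity_sd < 0 or self.amp_scale_sd < 0:
            raise ConfigError("spread parameters must be non-negative")
        if self.tau is not None and self.tau <= 0:
            raise ConfigError("tau must be positive")


@dataclass
class MultiFreqTimeSeries:
    """Synchronized magnitude/phase traces at the six carriers.

    ``mag`` and ``phase`` have shape (6, n_samples); ``t`` is uniformly
    spaced at ``1/sample_rate``.
    """

    t: np.ndarray
    mag: np.ndarray  # ohm
    phase: np.ndarray  # degrees
    config: AcquisitionConfig

    def __post_init__(self) -> None:
        n = len(self.t)
        if self.mag.shape != (6, n) or self.phase.shape != (6, n):
            raise ConfigError("mag and phase must have shape (6, len(t))")

    @property
    def n_samples(self) -> int:
        return len(self.t)


def _rng(spec_seed: int, acq_seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec_seed, acq_seed]))


def _draw_metallization(
    spec: TrialSpec, rng: np.random.Generator
) -> np.ndarray:
    """Per-bead metallization: lognormal spread around the dose mean."""
    mean = dose_to_metallization(spec.probe_concentration, spec.binding_params)
    sd = spec.heterogeneity_sd
    # mean-preserving (pre-clip) lognormal multiplier
    factors = np.exp(rng.normal(-0.5 * sd**2, sd, size=spec.n_beads))
    return np.clip(mean * factors, 0.0, 1.0)


def _build_beads(
    spec: TrialSpec,
    aperture: ApertureModel,
    rng: np.random.Generator,
    link: ShellLink | None = None,
) -> list[BeadModel]:
    m = _draw_metallization(spec, rng)
    return [
        BeadModel.metallized(spec.bead_diameter, mi, aperture, link=link)
        for mi in m
    ]


def _place_events(
    n: int, duration: float, min_gap: float, tau: float, sample_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Apex times with pairwise spacing >= min_gap, snapped to the grid."""
    margin = 3.0 * tau  # keep pulses clear of the trace edges
    slack = duration - 2 * margin - (n - 1) * min_gap
    if slack <= 0:
        raise ConfigError(
            f"cannot place {n} events with spacing {min_gap:.2g} s in a "
            f"{duration:.2g} s trial; increase the acquisition duration"
        )
    offsets = np.sort(rng.uniform(0.0, slack, size=n))
    t0 = margin + offsets + min_gap * np.arange(n)
    return np.round(t0 * sample_rate) / sample_rate


def synthesize_trial(
    spec: TrialSpec,
    aperture: ApertureModel,
    config: AcquisitionConfig,
    link: ShellLink | None = None,
) -> tuple[MultiFreqTimeSeries, list[TransitEvent]]:
    """Simulate one trial's waveforms and return the ground-truth events.

    Pulses are superimposed on the baseline spectrum, then sinusoidal drift
    (magnitude channels) and i.i.d. Gaussian noise (all channels) are added.
    Deterministic for fixed ``(spec, aperture, config)``.
    """
    rng = _rng(spec.seed, config.seed)
    tau = spec.tau or default_transit_tau(aperture, spec.bead_diameter)
    sigma = tau / _FWHM
    freqs = np.asarray(config.freqs)
    n = int(round(config.duration * config.sample_rate))
    t = np.arange(n) / config.sample_rate

    beads = _build_beads(spec, aperture, rng, link=link)
    t0s = _place_events(
        spec.n_beads, config.duration, _MIN_GAP_TAU * tau, tau,
        config.sample_rate, rng,
    )
    amps = np.clip(
        rng.normal(1.0, spec.amp_scale_sd, size=spec.n_beads), 0.5, 1.2
    )
    events = [
        TransitEvent(t0=float(t0), tau=tau, amp_scale=float(a), bead=b)
        for t0, a, b in zip(t0s, amps, beads)
    ]

    z_base = circuits.baseline_spectrum(aperture, freqs)
    mag = np.tile(np.abs(z_base)[:, None], (1, n))
    phase = np.tile(np.degrees(np.angle(z_base))[:, None], (1, n))

    half = int(np.ceil(5 * sigma * config.sample_rate))
    for ev in events:
        i0 = int(round(ev.t0 * config.sample_rate))
        lo, hi = max(0, i0 - half), min(n, i0 + half + 1)
        s = ev.amp_scale * np.exp(
            -((t[lo:hi] - ev.t0) ** 2) / (2.0 * sigma**2)
        )
        db = circuits.bead_element(ev.bead, aperture, freqs)
        for k, f in enumerate(freqs):
            z = circuits.total_impedance(aperture, db[k], s, f)
            mag[k, lo:hi] += np.abs(z) - np.abs(z_base[k])
            phase[k, lo:hi] += np.degrees(np.angle(z) - np.angle(z_base[k]))

    if config.drift_amp > 0:
        mag += config.drift_amp * np.sin(2 * np.pi * config.drift_freq * t)
    if config.noise_sd_mag > 0:
        mag += rng.normal(0.0, config.noise_sd_mag, size=mag.shape)
    if config.noise_sd_phase > 0:
        phase += rng.normal(0.0, config.noise_sd_phase, size=phase.shape)

    return MultiFreqTimeSeries(t=t, mag=mag, phase=phase, config=config), events


def synthesize_bead_records(
    spec: TrialSpec,
    aperture: ApertureModel,
    config: AcquisitionConfig,
    link: ShellLink | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fast path: per-bead peak records without waveform synthesis.

    Each record carries the noise-free peak signature of the bead (scaled by
    its off-centre factor) plus Gaussian measurement noise at the channel
    noise levels.  Returns ``(records, ground_truth)`` frames in the same
    column dialects as the detection stage and :func:`ground_truth_frame`.
    """
    rng = _rng(spec.seed, config.seed)
    tau = spec.tau or default_transit_tau(aperture, spec.bead_diameter)
    freqs = np.asarray(config.freqs)
    beads = _build_beads(spec, aperture, rng, link=link)
    t0s = np.sort(
        rng.uniform(0.0, config.duration, size=spec.n_beads)
    )
    amps = np.clip(
        rng.normal(1.0, spec.amp_scale_sd, size=spec.n_beads), 0.5, 1.2
    )
    rows = []
    for t0, a, bead in zip(t0s, amps, beads):
        dzp, dphip = circuits.peak_spectrum(bead, aperture, freqs, s=a)
        dzp = dzp + rng.normal(0.0, config.noise_sd_mag, size=6)
        dphip = dphip + rng.normal(0.0, config.noise_sd_phase, size=6)
        rows.append((t0, dzp, dphip))
    from .pulses import BeadRecord, records_to_frame  # local import: no cycle at module load

    records = [
        BeadRecord(timestamp=t0, dzp=dzp, dphip=dphip)
        for t0, dzp, dphip in rows
    ]
    gt = ground_truth_frame(
        [
            TransitEvent(t0=float(t0), tau=tau, amp_scale=float(a), bead=b)
            for t0, a, b in zip(t0s, amps, beads)
        ]
    )
    return records_to_frame(records, freqs), gt


def ground_truth_frame(events: list[TransitEvent]) -> pd.DataFrame:
    """Ground-truth event list as a data frame (CSV dialect of the docs)."""
    return pd.DataFrame(
        {
            "t0": [ev.t0 for ev in events],
            "tau": [ev.tau for ev in events],
            "diameter_um": [ev.bead.diameter * 1e6 for ev in events],
            "m_density": [ev.bead.m_density for ev in events],
            "kind": [ev.bead.kind for ev in events],
        }
    )
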