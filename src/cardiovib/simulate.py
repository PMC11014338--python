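"""Synthetic multi-frequency cardiac vibration generator.

The composite chest-wall vibration is modeled as a DC offset plus a weighted
sum of band-limited quasi-periodic modes plus additive noise::

    vibration(t) = a0 + sum_n a_n * mode_n(t) + baseline(t) + noise(t)

Each mode is a train of Gabor atoms (Gaussian-windowed cosines) anchored at
per-cycle cardiac event times.  Three modes are synthesized by default,
occupying the 1-5 Hz (volume change), 5-30 Hz (valve/contraction) and
20-200 Hz (heart sound) bands.  A synchronized reference ECG channel with one
dominant R spike per cycle is generated alongside, and every recording keeps
its ground-truth event schedule and per-mode component traces so downstream
stages can be validated against exact truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "EVENT_SEQUENCE",
    "ALL_EVENTS",
    "EXTRACTION_TARGETS",
    "DEFAULT_TEMPLATE",
    "CardiacEventSchedule",
    "GaborAtom",
    "ModeSpec",
    "SimulationConfig",
    "SyntheticRecording",
    "default_mode_specs",
    "make_event_schedule",
    "synthesize_mode",
    "synthesize_ecg",
    "synthesize_recording",
]

#: Physiological ordering of the SCG fiducials within one cycle.
EVENT_SEQUENCE = ("AS", "MC", "IM", "AO", "IC", "RE", "AC", "MO", "RF")

#: Every annotated event, including the heart sounds and the ULF crest/trough.
ALL_EVENTS = EVENT_SEQUENCE + ("S1", "S2", "WC", "WT")

#: The ten localization targets (WT and AS are annotated but never targets).
EXTRACTION_TARGETS = ("MC", "IM", "AO", "IC", "RE", "AC", "MO", "RF", "S1", "S2")

#: Reference period (s) at which the default template times are defined.
TEMPLATE_PERIOD = 0.8

#: Default event times (s from cycle onset) at the reference period.  These
#: are plumbing defaults, fully overridable through configuration.
DEFAULT_TEMPLATE: dict[str, float] = {
    "AS": 0.015,
    "MC": 0.035,
    "IM": 0.055,
    "AO": 0.080,
    "IC": 0.105,
    "RE": 0.150,
    "AC": 0.350,
    "MO": 0.400,
    "RF": 0.470,
    "S1": 0.060,
    "S2": 0.360,
    "WC": 0.100,
    "WT": 0.330,
}

# Events whose latency from the R wave scales weakly with the period; the
# remaining (diastolic) events absorb most of the period change.
_SYSTOLIC_EVENTS = ("AS", "MC", "IM", "AO", "IC", "RE", "S1", "WC", "WT")
_DIASTOLIC_EVENTS = ("MO", "RF")
SYSTOLIC_EXPONENT = 0.3

_S2_AC_TOLERANCE = 0.040  # |S2 - AC| bound, seconds


@dataclass(frozen=True)
class CardiacEventSchedule:
    """Ground-truth event times for one cardiac cycle.

    Times are seconds from cycle onset (the R-wave sample).
    """

    cycle_index: int
    period_T: float
    event_times: dict[str, float]

    def validate(self) -> None:
        t = self.event_times
        missing = set(ALL_EVENTS) - set(t)
        if missing:
            raise ValueError(f"schedule missing events: {sorted(missing)}")
        for name, v in t.items():
            if not (0.0 < v < self.period_T):
                raise ValueError(
                    f"event {name}={v:.4f}s outside (0, {self.period_T:.4f})"
                )
        seq = [t[e] for e in EVENT_SEQUENCE]
        if any(a >= b for a, b in zip(seq, seq[1:])):
            raise ValueError(f"event ordering violated: {seq}")
        if not (t["MC"] <= t["S1"] <= t["IC"]):
            raise ValueError("S1 must lie in [MC, IC]")
        if abs(t["S2"] - t["AC"]) > _S2_AC_TOLERANCE:
            raise ValueError("S2 must lie within 40 ms of AC")
        if t["WC"] >= t["WT"]:
            raise ValueError("WC must precede WT")

    def is_valid(self) -> bool:
        try:
            self.validate()
        except ValueError:
            return False
        return True


def _scale_template(period_T: float, template: dict[str, float]) -> dict[str, float]:
    """Scale the reference template to an arbitrary period.

    Systolic latencies scale as (T/T0)**SYSTOLIC_EXPONENT; AC (and the tied
    S2 offset) scale the same way; MO/RF keep their fractional position in
    the remaining diastole so that diastole absorbs most of the change.
    """
    s = (period_T / TEMPLATE_PERIOD) ** SYSTOLIC_EXPONENT
    times: dict[str, float] = {}
    for e in _SYSTOLIC_EVENTS:
        times[e] = template[e] * s
    ac = template["AC"] * s
    times["AC"] = ac
    times["S2"] = ac + (template["S2"] - template["AC"]) * s
    t0_diastole = TEMPLATE_PERIOD - template["AC"]
    diastole = period_T - ac
    for e in _DIASTOLIC_EVENTS:
        times[e] = ac + (template[e] - template["AC"]) * diastole / t0_diastole
    return times


def make_event_schedule(
    period_T: float,
    jitter: float | dict[str, float] | None = 0.0,
    rng: np.random.Generator | None = None,
    cycle_index: int = 0,
    template: dict[str, float] | None = None,
    max_redraws: int = 100,
) -> CardiacEventSchedule:
    """Draw one cycle's event schedule.

    ``jitter`` is a per-event Gaussian SD in seconds (scalar applies to every
    event); draws are truncated at +/-2 SD and the whole schedule is redrawn
    if the ordering invariants are violated, so every returned schedule is
    valid.  With zero jitter the schedule is the deterministic scaled
    template.
    """
    if not (0.4 <= period_T <= 2.0):
        raise ValueError(
            f"period_T={period_T} s outside [0.4, 2.0]; the ordered event "
            "sequence cannot be hosted reliably outside this range"
        )
    template = dict(DEFAULT_TEMPLATE if template is None else template)
    base = _scale_template(period_T, template)
    if jitter is None:
        jitter = 0.0
    if np.isscalar(jitter):
        jitter_map = {e: float(jitter) for e in ALL_EVENTS}
    else:
        jitter_map = {e: float(jitter.get(e, 0.0)) for e in ALL_EVENTS}
    if all(v == 0.0 for v in jitter_map.values()):
        sched = CardiacEventSchedule(cycle_index, period_T, base)
        sched.validate()
        return sched
    if rng is None:
        rng = np.random.default_rng()
    for _ in range(max_redraws):
        times = {}
        for e in ALL_EVENTS:
            sd = jitter_map[e]
            dt = float(np.clip(rng.normal(0.0, sd), -2.0 * sd, 2.0 * sd)) if sd else 0.0
            times[e] = base[e] + dt
        # keep the tied constraints by construction
        eps = 1e-4
        times["S1"] = float(np.clip(times["S1"], times["MC"] + eps, times["IC"] - eps))
        times["S2"] = float(
            np.clip(
                times["S2"],
                times["AC"] - _S2_AC_TOLERANCE + eps,
                times["AC"] + _S2_AC_TOLERANCE - eps,
            )
        )
        sched = CardiacEventSchedule(cycle_index, period_T, times)
        if sched.is_valid():
            return sched
    raise RuntimeError(
        f"could not draw a valid schedule in {max_redraws} attempts; "
        "jitter SDs are too large for the inter-event gaps"
    )


@dataclass(frozen=True)
class GaborAtom:
    """Gaussian-windowed cosine anchored at one event time."""

    event: str
    frequency_hz: float
    width_s: float
    amplitude: float
    phase: float = 0.0


@dataclass(frozen=True)
class ModeSpec:
    """One band-limited vibration mode: a coefficient, a band and its atoms."""

    index: int
    coefficient: float
    band: tuple[float, float]
    atoms: tuple[GaborAtom, ...]

    #: Permissible band envelope per mode index.
    MODE_BANDS = {1: (1.0, 5.0), 2: (5.0, 30.0), 3: (20.0, 200.0)}

    def validate(self) -> None:
        if self.index < 1:
            raise ValueError("mode index must be >= 1")
        lo, hi = self.band
        if not (0 < lo < hi):
            raise ValueError(f"invalid band {self.band}")
        if self.index in self.MODE_BANDS:
            blo, bhi = self.MODE_BANDS[self.index]
            if lo < blo or hi > bhi:
                raise ValueError(
                    f"mode {self.index} band {self.band} outside [{blo}, {bhi}] Hz"
                )
        for atom in self.atoms:
            if not (lo <= atom.frequency_hz <= hi):
                raise ValueError(
                    f"atom at {atom.event}: carrier {atom.frequency_hz} Hz "
                    f"outside mode band {self.band}"
                )


def default_mode_specs() -> tuple[ModeSpec, ...]:
    """Default three-mode parameterization.

    Mode 1 (1-5 Hz) carries the volume-change crest/trough; mode 2 (5-30 Hz)
    carries the eight SCG fiducials, with deliberately broad low-amplitude
    atoms at RE and RF; mode 3 (20-200 Hz) carries the two heart sounds.
    """
    mode1 = ModeSpec(
        index=1,
        coefficient=1.0,
        band=(1.0, 5.0),
        atoms=(
            GaborAtom("WC", 3.0, 0.09, 1.0),
            GaborAtom("WT", 3.0, 0.09, -1.0),
        ),
    )
    mode2 = ModeSpec(
        index=2,
        coefficient=1.0,
        band=(5.0, 30.0),
        atoms=(
            GaborAtom("AS", 10.0, 0.030, 0.30),
            GaborAtom("MC", 12.0, 0.035, 0.80),
            GaborAtom("IM", 13.0, 0.035, -0.90),
            GaborAtom("AO", 13.0, 0.035, 1.00),
            GaborAtom("IC", 12.0, 0.035, -0.80),
            GaborAtom("RE", 9.5, 0.055, 0.45),
            GaborAtom("AC", 13.0, 0.035, 0.90),
            GaborAtom("MO", 11.0, 0.035, -0.70),
            GaborAtom("RF", 9.0, 0.060, 0.40),
        ),
    )
    mode3 = ModeSpec(
        index=3,
        coefficient=1.0,
        band=(20.0, 200.0),
        atoms=(
            GaborAtom("S1", 50.0, 0.045, 2.00),
            GaborAtom("S2", 60.0, 0.040, 1.70),
        ),
    )
    for m in (mode1, mode2, mode3):
        m.validate()
    return (mode1, mode2, mode3)


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce one synthetic recording bit-for-bit."""

    sampling_rate: float = 2000.0
    n_cycles: int = 60
    mean_heart_rate_bpm: float = 75.0
    heart_rate_jitter_bpm: float = 2.0
    event_jitter_s: float | dict[str, float] = 0.005
    noise_sd: float = 0.05
    baseline_amplitude: float = 0.2
    baseline_freq_hz: float = 0.25
    seed: int = 0
    a0: float = 0.0
    ecg_noise_sd: float = 0.01
    lead_in_s: float = 0.25
    modes: tuple[ModeSpec, ...] | None = None
    template: dict[str, float] | None = None
    quantize_bits: int | None = None

    def validate(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        modes = self.modes if self.modes is not None else default_mode_specs()
        top = max(m.band[1] for m in modes)
        if self.sampling_rate <= 2.0 * top:
            raise ValueError(
                f"sampling_rate {self.sampling_rate} Hz must exceed twice the "
                f"highest mode band edge ({top} Hz)"
            )


@dataclass
class SyntheticRecording:
    """Synthesized ECG + composite vibration with full ground truth."""

    ecg: np.ndarray
    vibration: np.ndarray
    sampling_rate: float
    schedules: list[CardiacEventSchedule]
    r_peak_times: np.ndarray  # seconds, absolute
    components: dict[str, np.ndarray]  # mode1/mode2/mode3/baseline/noise
    a0: float
    config: SimulationConfig | None = None
    mode_coefficients: dict[str, float] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.vibration.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def cycle_start_samples(self) -> np.ndarray:
        """Absolute sample index of each cycle onset (exact, from truth)."""
        return np.round(self.r_peak_times * self.sampling_rate).astype(int)

    def reconstruct(self) -> np.ndarray:
        """Sum stored components back into the vibration channel."""
        out = np.full(self.n_samples, self.a0, dtype=float)
        for name, trace in self.components.items():
            out = out + self.mode_coefficients.get(name, 1.0) * trace
        return out

    def annotations(self) -> list[tuple[int, str, int]]:
        """(cycle_index, event, sample index relative to cycle onset)."""
        fs = self.sampling_rate
        rows = []
        for sched in self.schedules:
            for event in ALL_EVENTS:
                rows.append(
                    (sched.cycle_index, event, int(round(sched.event_times[event] * fs)))
                )
        return rows


def synthesize_mode(
    schedule: CardiacEventSchedule,
    mode: ModeSpec,
    sampling_rate: float,
) -> np.ndarray:
    """Render one mode for one cycle as a sum of Gabor atoms.

    The trace has ``round(period_T * sampling_rate)`` samples; each atom is
    ``amp * exp(-(t-tc)^2 / (2 w^2)) * cos(2 pi f (t-tc) + phase)`` with tc
    the atom's event time.
    """
    mode.validate()
    for atom in mode.atoms:
        if atom.event not in schedule.event_times:
            raise ValueError(f"atom references unknown event {atom.event!r}")
    n = int(round(schedule.period_T * sampling_rate))
    t = np.arange(n) / sampling_rate
    trace = np.zeros(n)
    for atom in mode.atoms:
        if atom.amplitude == 0.0:
            continue
        tc = schedule.event_times[atom.event]
        dt = t - tc
        trace += (
            atom.amplitude
            * np.exp(-0.5 * (dt / atom.width_s) ** 2)
            * np.cos(2.0 * math.pi * atom.frequency_hz * dt + atom.phase)
        )
    return trace


def _render_mode_timeline(
    schedules: list[CardiacEventSchedule],
    onset_samples: np.ndarray,
    mode: ModeSpec,
    sampling_rate: float,
    n: int,
) -> np.ndarray:
    """Render a mode over the whole record with atoms at absolute event times.

    Unlike the per-cycle :func:`synthesize_mode`, atom tails spill across
    cycle boundaries instead of being clipped, so wide atoms stay smooth.
    """
    mode.validate()
    fs = sampling_rate
    trace = np.zeros(n)
    t = np.arange(n) / fs
    for onset, sched in zip(onset_samples, schedules):
        t0 = onset / fs
        for atom in mode.atoms:
            if atom.amplitude == 0.0:
                continue
            tc = t0 + sched.event_times[atom.event]
            lo = max(0, int((tc - 5 * atom.width_s) * fs))
            hi = min(n, int((tc + 5 * atom.width_s) * fs) + 1)
            if lo >= hi:
                continue
            dt = t[lo:hi] - tc
            trace[lo:hi] += (
                atom.amplitude
                * np.exp(-0.5 * (dt / atom.width_s) ** 2)
                * np.cos(2.0 * math.pi * atom.frequency_hz * dt + atom.phase)
            )
    return trace


def synthesize_ecg(
    schedules: list[CardiacEventSchedule],
    sampling_rate: float,
    lead_in_s: float = 0.25,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Reference ECG: one dominant R spike per cycle plus P/T humps.

    Returns ``(trace, r_peak_times)`` where the R times are absolute seconds.
    The R spike amplitude is >= 3x every other deflection by construction.
    """
    fs = sampling_rate
    onsets = lead_in_s + np.concatenate(
        ([0.0], np.cumsum([s.period_T for s in schedules[:-1]]))
    )
    total = lead_in_s * 2 + sum(s.period_T for s in schedules)
    n = int(round(total * fs))
    t = np.arange(n) / fs
    trace = np.zeros(n)

    def bump(center: float, amp: float, width: float) -> None:
        lo = max(0, int((center - 5 * width) * fs))
        hi = min(n, int((center + 5 * width) * fs) + 1)
        dt = t[lo:hi] - center
        trace[lo:hi] += amp * np.exp(-0.5 * (dt / width) ** 2)

    for onset, sched in zip(onsets, schedules):
        bump(onset, 1.0, 0.008)  # R
        bump(onset - 0.025, -0.08, 0.006)  # Q
        bump(onset + 0.030, -0.10, 0.007)  # S
        bump(onset + sched.event_times["AC"] - 0.060, 0.18, 0.045)  # T
        bump(onset + sched.period_T - 0.160, 0.12, 0.035)  # next P
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        trace = trace + rng.normal(0.0, noise_sd, n)
    return trace, onsets


def synthesize_recording(config: SimulationConfig) -> SyntheticRecording:
    """Render a full multi-cycle recording from a configuration.

    Deterministic given the config (including seed): identical configs yield
    bitwise-identical recordings.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    modes = config.modes if config.modes is not None else default_mode_specs()

    # Heart periods; quantized to the sample grid so cycle onsets are exact.
    hr = config.mean_heart_rate_bpm + rng.normal(
        0.0, config.heart_rate_jitter_bpm, config.n_cycles
    )
    periods = np.clip(60.0 / hr, 0.4, 2.0)
    periods = np.round(periods * fs) / fs

    schedules = [
        make_event_schedule(
            float(T), config.event_jitter_s, rng, cycle_index=i, template=config.template
        )
        for i, T in enumerate(periods)
    ]

    lead = int(round(config.lead_in_s * fs))
    cycle_lens = [int(round(s.period_T * fs)) for s in schedules]
    n = lead * 2 + sum(cycle_lens)

    onsets = lead + np.concatenate(([0], np.cumsum(cycle_lens[:-1])))
    components: dict[str, np.ndarray] = {}
    coeffs: dict[str, float] = {}
    for mode in modes:
        key = f"mode{mode.index}"
        components[key] = _render_mode_timeline(schedules, onsets, mode, fs, n)
        coeffs[key] = mode.coefficient

    t = np.arange(n) / fs
    baseline = config.baseline_amplitude * np.sin(
        2.0 * math.pi * config.baseline_freq_hz * t
    )
    components["baseline"] = baseline
    coeffs["baseline"] = 1.0
    noise = (
        rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else np.zeros(n)
    )
    components["noise"] = noise
    coeffs["noise"] = 1.0

    vibration = np.full(n, config.a0)
    for key, trace in components.items():
        vibration = vibration + coeffs[key] * trace

    ecg, r_times = synthesize_ecg(
        schedules, fs, lead_in_s=config.lead_in_s, noise_sd=config.ecg_noise_sd, rng=rng
    )
    # synthesize_ecg derives its own grid from the same periods; lengths match
    # because both quantize identically.
    if ecg.shape[0] != n:  # pragma: no cover - defensive
        m = min(ecg.shape[0], n)
        ecg = ecg[:m]
        vibration = vibration[:m]
        components = {k: v[:m] for k, v in components.items()}

    if config.quantize_bits is not None:
        vibration = _quantize(vibration, config.quantize_bits)

    return SyntheticRecording(
        ecg=ecg,
        vibration=vibration,
        sampling_rate=fs,
        schedules=schedules,
        r_peak_times=r_times,
        components=components,
        a0=config.a0,
        config=config,
        mode_coefficients=coeffs,
    )


def _quantize(x: np.ndarray, bits: int) -> np.ndarray:
    """Mid-rise uniform quantizer over the signal's own range (ADC stand-in)."""
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        return x.copy()
    levels = 2**bits - 1
    q = np.round((x - lo) / (hi - lo) * levels)
    return q / levels * (hi - lo) + lo


def with_noise_free(config: SimulationConfig) -> SimulationConfig:
    """Convenience: same config with all stochastic nuisance terms disabled."""
    return replace(
        config,
        noise_sd=0.0,
        baseline_amplitude=0.0,
        ecg_noise_sd=0.0,
        heart_rate_jitter_bpm=0.0,
        event_jitter_s=0.0,
    )
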