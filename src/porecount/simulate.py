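"""Synthetic nanopore signal generation.

Emulates the statistical structure of single-channel solid-state nanopore
recordings of a DNA sample: an open-pore current baseline with Gaussian
noise, square translocation pulses whose dwell times carry exponential
tails, and class-specific in-event current fluctuations.  Native mtDNA is
modelled with a bursty (telegraph-like) blocked-current fluctuation that
produces a per-event RMS population roughly six-fold above that of clean
linear dsDNA of the same length; enzymatically fragmented gDNA produces
short, shallow events.

The generator is the ground-truth source for every downstream stage:
event detection, feature extraction, SVM classification, digital-count
ratiometry and electro-optical synchrony all have exact per-event truth
available through :class:`GroundTruth` tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EventClassParams",
    "TraceSpec",
    "IonTrace",
    "DEFAULT_CLASSES",
    "PCDNA_PRESET",
    "DEFAULT_MIXTURE",
    "sample_event_features",
    "synth_trace",
    "synth_spikein_series",
    "synth_photon_trace",
    "telegraph_wave",
    "lognormal_from_moments",
]

CLASS_LABELS = ("fragment", "mtDNA", "linear_dsDNA")
#: integer codes used throughout classification (fragments 0, mtDNA 1, syDNA 2)
CLASS_CODES = {"fragment": 0, "mtDNA": 1, "linear_dsDNA": 2}

FEATURE_COLUMNS = ("I_B", "t_D_us", "i_rms_nA", "label")


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed or an existing Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class EventClassParams:
    """Population parameters of one translocation-event class.

    Dwell times are drawn as ``dwell_min_us + Exp(dwell_tail_us - dwell_min_us)``
    so that the mean dwell equals the characteristic tail time; fractional
    blockage I_B = i_b/i_o is truncated-normal on (0, 1); the per-event
    blocked-level RMS is log-normal with the stated population moments.
    ``fluctuation`` selects how the target per-event RMS is realised inside
    a simulated pulse: "gaussian" adds white in-event noise, "telegraph"
    adds a symmetric two-state switching process (the bursty signature of
    protein-complexed mtDNA), "none" leaves only the baseline noise.
    """

    label: str
    dwell_tail_us: float
    ib_mean: float
    ib_sd: float
    irms_mean_nA: float
    irms_sd_nA: float
    dwell_min_us: float = 20.0
    fluctuation: str = "gaussian"
    telegraph_rate_hz: float = 5000.0

    def __post_init__(self):
        if not 0.0 < self.ib_mean < 1.0:
            raise ValueError(f"ib_mean must lie in (0, 1), got {self.ib_mean}")
        if not self.dwell_tail_us > self.dwell_min_us > 0:
            raise ValueError(
                "require dwell_tail_us > dwell_min_us > 0, got "
                f"{self.dwell_tail_us} / {self.dwell_min_us}"
            )
        if self.irms_mean_nA < 0 or self.irms_sd_nA < 0:
            raise ValueError("i_rms population moments must be nonnegative")
        if self.fluctuation not in ("none", "gaussian", "telegraph"):
            raise ValueError(f"unknown fluctuation model {self.fluctuation!r}")


#: Default class populations.  Dwell tails and i_rms moments for mtDNA and
#: 17 kbp linear dsDNA are the measured population values (1,280 us / 680 us /
#: 57 us tails; i_rms 1.1 +- 0.8 nA vs 0.16 +- 0.04 nA).  Fractional-blockage
#: means for fragments and mtDNA are free parameters chosen to respect the
#: observed ordering (fragments shallowest, mtDNA deepest); see docs/methods.md.
DEFAULT_CLASSES: dict[str, EventClassParams] = {
    "fragment": EventClassParams(
        label="fragment",
        dwell_tail_us=57.0,
        ib_mean=0.92,
        ib_sd=0.03,
        irms_mean_nA=0.12,
        irms_sd_nA=0.04,
    ),
    "mtDNA": EventClassParams(
        label="mtDNA",
        dwell_tail_us=1280.0,
        ib_mean=0.70,
        ib_sd=0.05,
        irms_mean_nA=1.1,
        irms_sd_nA=0.8,
        fluctuation="telegraph",
    ),
    "linear_dsDNA": EventClassParams(
        label="linear_dsDNA",
        dwell_tail_us=680.0,
        ib_mean=0.81,
        ib_sd=0.03,
        irms_mean_nA=0.16,
        irms_sd_nA=0.04,
    ),
}

#: Linearized pcDNA3.1 plasmid preset (5,428 bp): measured dwell 546 us,
#: I_B 0.81 +- 0.03, i_rms 0.2 +- 0.07 nA.
PCDNA_PRESET = EventClassParams(
    label="linear_dsDNA",
    dwell_tail_us=546.0,
    ib_mean=0.81,
    ib_sd=0.03,
    irms_mean_nA=0.2,
    irms_sd_nA=0.07,
)

#: Steady-state ExoV digestion leaves a fragment background roughly 10-fold
#: more abundant than the mtDNA copies.
DEFAULT_MIXTURE = {"fragment": 10.0 / 11.0, "mtDNA": 1.0 / 11.0}


@dataclass(frozen=True)
class TraceSpec:
    """Acquisition parameters of one simulated recording.

    Defaults model an Axopatch-style recording digitised at 500 kHz
    (comfortably above the 100 kHz low-pass analog filter), a 10 nA
    open-pore current and 0.03 nA baseline noise.
    """

    duration_s: float
    event_rate_hz: float
    class_mixture: dict = field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    open_pore_current_nA: float = 10.0
    baseline_noise_sd_nA: float = 0.03
    sampling_rate_hz: float = 500_000.0
    voltage_mV: float = 150.0
    seed: int = 0

    def __post_init__(self):
        fracs = np.asarray(list(self.class_mixture.values()), dtype=float)
        if (fracs < 0).any():
            raise ValueError("mixture fractions must be nonnegative")
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ValueError(f"mixture fractions must sum to 1, got {fracs.sum()}")
        if self.sampling_rate_hz <= 0 or self.duration_s <= 0:
            raise ValueError("sampling_rate_hz and duration_s must be positive")


@dataclass
class IonTrace:
    """A uniformly sampled ion-current record (nA) with acquisition metadata."""

    samples: np.ndarray
    sampling_rate_hz: float
    voltage_mV: float = 0.0
    source: str = "synthetic"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if not np.isfinite(self.samples).all():
            raise ValueError("trace contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate_hz


GROUND_TRUTH_COLUMNS = (
    "label", "start_idx", "end_idx", "dwell_us", "i_b_nA", "I_B", "i_rms_nA",
)


def lognormal_from_moments(mean: float, sd: float, n: int, rng) -> np.ndarray:
    """Draw n log-normal variates with the given arithmetic mean and SD."""
    if mean < 0 or sd < 0:
        raise ValueError("moments must be nonnegative")
    if mean == 0:
        return np.zeros(n)
    if sd == 0:
        return np.full(n, float(mean))
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), n)


def _truncated_normal_01(mean, sd, n, rng, max_rounds=100):
    """Normal(mean, sd) conditioned on (0, 1) by rejection."""
    out = rng.normal(mean, sd, n)
    bad = (out <= 0.0) | (out >= 1.0)
    rounds = 0
    while bad.any():
        rounds += 1
        if rounds > max_rounds:
            raise ValueError(
                "fractional blockage parameters place almost no mass in (0,1); "
                f"mean={mean}, sd={sd}"
            )
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out <= 0.0) | (out >= 1.0)
    return out


def sample_event_features(params: EventClassParams, n: int, seed) -> pd.DataFrame:
    """Draw n per-event feature rows (I_B, t_D_us, i_rms_nA, label) for one class.

    This is the event-level shortcut around full trace simulation: it samples
    directly from the class population that the trace-level path realises
    physically, and the two paths are required to agree (tested).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = as_rng(seed)
    dwell = params.dwell_min_us + rng.exponential(
        params.dwell_tail_us - params.dwell_min_us, n
    )
    ib = _truncated_normal_01(params.ib_mean, params.ib_sd, n, rng)
    irms = lognormal_from_moments(params.irms_mean_nA, params.irms_sd_nA, n, rng)
    return pd.DataFrame(
        {"I_B": ib, "t_D_us": dwell, "i_rms_nA": irms, "label": params.label}
    )


def telegraph_wave(n: int, rate_hz: float, sampling_rate_hz: float, depth: float,
                   rng) -> np.ndarray:
    """Symmetric two-state telegraph signal of n samples, levels +-depth/2.

    Each state flips with per-direction rate ``rate_hz``; for rate*duration
    large the sample SD converges to depth/2.
    """
    p_flip = 1.0 - math.exp(-rate_hz / sampling_rate_hz)
    flips = rng.random(n) < p_flip
    state = np.cumsum(flips) % 2          # 0/1 alternating at flip points
    if rng.random() < 0.5:
        state = 1 - state
    return (state - 0.5) * depth


#: stationary fraction of the telegraph process spent at the shallow level;
#: the skew keeps upward excursions small so deep sub-blockades never push
#: the in-pulse current back across the detection threshold
TELEGRAPH_UP_OCCUPANCY = 0.8


def _skewed_telegraph(n, rate_hz, sampling_rate_hz, sd, rng,
                      q=TELEGRAPH_UP_OCCUPANCY):
    """Zero-mean two-state process: shallow level (occupancy q) and deep
    sub-blockade level, with stationary SD ``sd`` and mean switching rate
    ``rate_hz``."""
    up_level = sd * math.sqrt((1.0 - q) / q)
    down_level = -sd * math.sqrt(q / (1.0 - q))
    p_leave_up = 1.0 - math.exp(-2.0 * rate_hz * (1.0 - q) / sampling_rate_hz)
    p_leave_down = 1.0 - math.exp(-2.0 * rate_hz * q / sampling_rate_hz)
    u = rng.random(n)
    out = np.empty(n)
    state_up = rng.random() < q
    for i in range(n):
        out[i] = up_level if state_up else down_level
        if u[i] < (p_leave_up if state_up else p_leave_down):
            state_up = not state_up
    return out


def _in_event_fluctuation(params: EventClassParams, n: int, target_sd: float,
                          sampling_rate_hz: float, rng,
                          lo: float = -np.inf, hi: float = np.inf) -> np.ndarray:
    """Zero-mean in-pulse fluctuation with sample SD ~= target_sd.

    ``lo``/``hi`` bound the admissible excursion around the blocked level
    (the current must stay physical and below the detection band).  The
    telegraph branch solves for the amplitude at which the *clipped* wave
    reaches the target SD, so large sub-blockade events keep their RMS
    rather than losing it to saturation; calibration uses the pulse
    interior (10% edge trim), the convention under which blocked-level
    statistics are measured.  An event too short to visit both telegraph
    levels falls back to Gaussian fluctuation of the same SD.
    """
    if target_sd <= 0 or params.fluctuation == "none":
        return np.zeros(n)
    if params.fluctuation == "telegraph" and n >= 2:
        trim = int(0.1 * n)
        core = slice(trim, n - trim) if n - 2 * trim >= 2 else slice(0, n)
        bounded = np.isfinite(lo) and np.isfinite(hi) and lo < 0 < hi

        def two_point(up):
            """Level assignment for a state sequence: exactly zero mean and
            the target SD over the pulse interior, the majority state at a
            small upward offset and the minority state at the deep
            sub-blockade level.  Returns (wave, feasible)."""
            p_hat = float(up[core].mean())
            if not 0.0 < p_hat < 1.0:
                return None, False
            maj = up if p_hat >= 0.5 else ~up
            a = 1.0 - max(p_hat, 1.0 - p_hat)  # minority occupancy
            x = target_sd * math.sqrt(a / (1.0 - a))   # majority, up
            y = target_sd * math.sqrt((1.0 - a) / a)   # minority, deep
            if x <= hi and y <= -lo:
                return np.where(maj, x, -y), True
            # saturate at the largest zero-mean SD this duty cycle allows
            sep = min(hi / a, -lo / (1.0 - a))
            return np.where(maj, a * sep, -(1.0 - a) * sep), False

        # shallow-level occupancy follows the available headroom: deep
        # sub-blockades have ~i_b of room below, upward excursions only the
        # narrow band up to the detection ceiling
        q = float(np.clip(-lo / (hi - lo), 0.55, 0.9)) if bounded \
            else TELEGRAPH_UP_OCCUPANCY
        raw = _skewed_telegraph(n, params.telegraph_rate_hz, sampling_rate_hz,
                                1.0, rng, q=q)
        wave, ok = two_point(raw > 0)
        if ok:
            return wave
        if bounded:
            # the target RMS cannot ride on this duty cycle; redraw the
            # switching sequence at the variance-optimal duty cycle, fast
            # enough that even short pulses realise it (~10 sojourns)
            a_opt = float(np.clip(hi / (hi - lo), 0.15, 0.5))
            rate2 = max(params.telegraph_rate_hz, 10.0 * sampling_rate_hz / n)
            raw2 = _skewed_telegraph(n, rate2, sampling_rate_hz, 1.0, rng,
                                     q=1.0 - a_opt)
            wave2, _ = two_point(raw2 > 0)
            if wave2 is not None:
                return wave2
        if wave is not None:
            return wave
    g = rng.normal(0.0, target_sd, n)
    return np.clip(g, lo, hi)


def _schedule_events(spec: TraceSpec, classes: dict, rng) -> pd.DataFrame:
    """Poisson event schedule thinned to forbid overlap, with class truth."""
    labels = list(spec.class_mixture.keys())
    fracs = np.asarray([spec.class_mixture[k] for k in labels], dtype=float)
    mean_dwell_s = sum(
        spec.class_mixture[k] * classes[k].dwell_tail_us * 1e-6 for k in labels
    )
    if spec.event_rate_hz * mean_dwell_s > 0.5:
        raise ValueError(
            "requested pore occupancy exceeds 0.5; lower event_rate_hz or dwell"
        )
    fs = spec.sampling_rate_hz
    n_samples = int(round(spec.duration_s * fs))
    rows = []
    t = 0.0
    guard_s = 10.0 / fs  # a few samples of open pore between events
    while True:
        t += rng.exponential(1.0 / spec.event_rate_hz)
        if t >= spec.duration_s:
            break
        label = labels[rng.choice(len(labels), p=fracs)]
        p = classes[label]
        dwell_us = p.dwell_min_us + rng.exponential(p.dwell_tail_us - p.dwell_min_us)
        start = int(round(t * fs))
        end = start + max(1, int(round(dwell_us * 1e-6 * fs)))
        if rows and start <= rows[-1]["end_idx"] + guard_s * fs:
            continue  # thinning: drop events that would overlap
        if end >= n_samples - 1 or start <= 0:
            continue
        ib = float(_truncated_normal_01(p.ib_mean, p.ib_sd, 1, rng)[0])
        irms = float(lognormal_from_moments(p.irms_mean_nA, p.irms_sd_nA, 1, rng)[0])
        rows.append(
            {
                "label": label,
                "start_idx": start,
                "end_idx": end,
                "dwell_us": (end - start) / fs * 1e6,
                "i_b_nA": ib * spec.open_pore_current_nA,
                "I_B": ib,
                "i_rms_nA": irms,
            }
        )
    return pd.DataFrame(rows, columns=list(GROUND_TRUTH_COLUMNS))


def synth_trace(spec: TraceSpec, classes=None, rng=None):
    """Simulate one recording; returns (IonTrace, ground-truth DataFrame).

    Events are square pulses down to i_b = I_B * i_o with the class
    fluctuation process superimposed inside the pulse, placed by a Poisson
    process thinned to forbid overlap.  The ground-truth table uses 0-based
    half-open sample intervals.
    """
    if classes is None:
        classes = DEFAULT_CLASSES
    if isinstance(classes, (list, tuple)):
        classes = {p.label: p for p in classes}
    missing = set(spec.class_mixture) - set(classes)
    if missing:
        raise ValueError(f"class_mixture labels without parameters: {missing}")
    rng = as_rng(spec.seed if rng is None else rng)
    fs = spec.sampling_rate_hz
    n_samples = int(round(spec.duration_s * fs))

    truth = (
        _schedule_events(spec, classes, rng)
        if spec.event_rate_hz > 0
        else pd.DataFrame(columns=list(GROUND_TRUTH_COLUMNS))
    )

    current = np.full(n_samples, spec.open_pore_current_nA, dtype=np.float64)
    if spec.baseline_noise_sd_nA > 0:
        current += rng.normal(0.0, spec.baseline_noise_sd_nA, n_samples)
    base_var = spec.baseline_noise_sd_nA ** 2
    for row in truth.itertuples(index=False):
        s, e = int(row.start_idx), int(row.end_idx)
        p = classes[row.label]
        # split the target per-event RMS between baseline noise (already in
        # the trace) and the class fluctuation process
        fluct_sd = math.sqrt(max(row.i_rms_nA ** 2 - base_var, 0.0))
        depth = spec.open_pore_current_nA - row.i_b_nA
        # blocked current stays physical (>= 0) and below the detection band
        ceiling = spec.open_pore_current_nA - max(
            8.0 * spec.baseline_noise_sd_nA, 1e-3 * spec.open_pore_current_nA
        )
        guard = 3.0 * spec.baseline_noise_sd_nA  # headroom for baseline noise
        fluct = _in_event_fluctuation(
            p, e - s, fluct_sd, fs, rng,
            lo=-row.i_b_nA + guard, hi=ceiling - row.i_b_nA - guard,
        )
        current[s:e] += fluct - depth
        np.clip(current[s:e], 0.0, ceiling, out=current[s:e])

    trace = IonTrace(current, fs, spec.voltage_mV, source="synthetic")
    return trace, truth


def synth_spikein_series(n_endo: float, n_gdna: float, masses_ng,
                         events_per_run: int, mt_length_bp: int = 16_569,
                         seed=0):
    """Simulate a spike-in calibration series with binomial counting noise.

    For each spiked mass the true nanopore ratio follows the saturating
    spike-in model; the observed mtDNA event count is Binomial(events, r).
    Returns a :class:`porecount.quantify.SpikeInSeries`.
    """
    from .quantify import SpikeInSeries, spikein_model

    if n_endo < 0 or n_gdna < 0:
        raise ValueError("copy numbers must be nonnegative")
    masses = np.asarray(masses_ng, dtype=float)
    if (masses < 0).any():
        raise ValueError("masses must be nonnegative")
    if events_per_run < 100:
        raise ValueError("events_per_run must be >= 100")
    rng = as_rng(seed)
    r_true = np.array(
        [spikein_model(m, n_endo, n_gdna, mt_length_bp) for m in masses]
    )
    n_mt = rng.binomial(events_per_run, r_true)
    return SpikeInSeries(
        masses_ng=masses,
        observed_R=n_mt / events_per_run,
        events_per_run=np.full(masses.size, events_per_run, dtype=int),
        mt_length_bp=mt_length_bp,
    )


def synth_photon_trace(ground_truth: pd.DataFrame, sampling_rate_hz: float,
                       duration_s: float, labeled_fraction: float = 1.0,
                       burst_mean_counts: float = 400.0,
                       background_mean: float = 100.0,
                       background_sd: float = 30.0,
                       frame_rate_hz: float = 1000.0,
                       jitter_ms=(0.5, 3.0), seed=0):
    """Simulate the synchronous 1 kHz photon-count channel.

    Frames are Gaussian background (floored at 0 counts); each labeled event
    elevates every frame overlapping [start - jitter, end] by Poisson
    burst counts, the jitter letting the optical burst precede the electrical
    translocation start (a molecule dwelling at the pore mouth fluoresces
    before threading).  Returns a :class:`porecount.optical.PhotonTrace`.
    """
    from .optical import PhotonTrace

    if frame_rate_hz <= 0:
        raise ValueError("frame_rate_hz must be positive")
    if not 0.0 <= labeled_fraction <= 1.0:
        raise ValueError("labeled_fraction must lie in [0, 1]")
    rng = as_rng(seed)
    n_frames = math.ceil(duration_s * frame_rate_hz)
    counts = np.maximum(rng.normal(background_mean, background_sd, n_frames), 0.0)
    for row in ground_truth.itertuples(index=False):
        if rng.random() >= labeled_fraction:
            continue
        t0 = row.start_idx / sampling_rate_hz
        t1 = row.end_idx / sampling_rate_hz
        jit = rng.uniform(*jitter_ms) * 1e-3
        f0 = max(0, int(math.floor((t0 - jit) * frame_rate_hz)))
        f1 = min(n_frames, int(math.ceil(t1 * frame_rate_hz)))
        if f1 > f0:
            counts[f0:f1] += rng.poisson(burst_mean_counts, f1 - f0)
    return PhotonTrace(
        frame_counts=counts,
        frame_rate_hz=frame_rate_hz,
        background_mean=background_mean,
        background_rms=background_sd,
    )
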