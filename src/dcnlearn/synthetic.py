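"""Synthetic cohorts of nerve-evoked DCN surface recordings.

The generator emulates the statistical structure of in-vivo dorsal column
nuclei (DCN) surface potentials evoked by stimulating the four hindlimb
nerves (right/left sural and peroneal: RSN, LSN, RPN, LPN), so that every
downstream stage — feature extraction, learnability, input minimization,
mapping, statistics — can be exercised with known ground truth.

Each trial is built from four components, all attenuated per electrode by
exp(-d / attenuation_length) where d is the distance from the electrode to
the stimulated nerve's cortical-surface "hotspot":

1. a brief stimulus artifact at t = 0 (damped oscillation);
2. a smooth biphasic low-frequency wave: a positive P1 lobe followed by a
   larger negative N1 lobe (raised-cosine lobes with compact, non-overlapping
   support, so the injected peak times/amplitudes are exactly the extrema);
3. a high-frequency multiunit burst: homogeneous-Poisson point events in the
   15-55 ms window convolved with a ~1 ms biphasic kernel whose energy lies
   in the 550-3300 Hz band;
4. additive white Gaussian noise per channel.

Nerve identity is encoded the way the recordings motivate: nerve *type*
(sural vs peroneal) shifts latencies, amplitudes and burst rates; body
*side* moves the hotspot to the corresponding half of the map.  An
``asymmetry_scale`` dial pulls right-side hotspots toward the midline and
biases right-side amplitudes, emulating the right-side dominance seen at
midline electrodes; with ``effect_scale = 0`` all four nerves are generated
from identical parameters (an exact null).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy.stats import norm

from .features import RawTrace, SF_NAMES, hf_bandpass_sos, HF_WINDOW_MS
from .mapping import ElectrodeLayout, DEFAULT_LAYOUT

__all__ = [
    "NERVES",
    "GeneratorConfig",
    "AnimalModel",
    "TrialSet",
    "make_cohort",
    "synthesize_trial",
    "generate_dataset",
    "ground_truth_features",
    "channel_gains",
]

#: Canonical nerve label order (right/left sural, right/left peroneal).
NERVES = ("RSN", "LSN", "RPN", "LPN")

_SIDE = {"R": 1.0, "L": -1.0}


def _nerve_side_type(nerve: str) -> tuple[float, str]:
    if nerve not in NERVES:
        raise ValueError(f"unknown nerve label {nerve!r}; expected one of {NERVES}")
    return _SIDE[nerve[0]], nerve[1:]  # 'SN' or 'PN'


# Cohort-mean generative parameters and the nerve-type offsets applied at
# effect_scale = 1.  Peroneal responses have shorter latencies, larger N1 and
# denser/hotter HF bursts than sural; chosen so the default cohort is
# cleanly separable by the five features.
_BASE = {
    "p1_latency_ms": 10.0,
    "n1_latency_ms": 20.0,
    "p1_amplitude_uv": 60.0,
    "n1_amplitude_uv": -120.0,
    "hf_rate_per_ms": 0.4,
    "hf_amplitude_uv": 12.0,
}
_TYPE_OFFSET = {  # sural gets +offset, peroneal gets -offset
    "p1_latency_ms": 1.0,
    "n1_latency_ms": 3.0,
    "p1_amplitude_uv": -10.0,
    "n1_amplitude_uv": 20.0,
    "hf_rate_per_ms": -0.2,
    "hf_amplitude_uv": -3.0,
}
# Hotspot geometry (mm) at effect_scale = 1: lateral displacement by nerve
# type, rostro-caudal separation of sural vs peroneal territories.
_HOTSPOT_LATERAL = {"SN": 0.5, "PN": 0.4}
_HOTSPOT_ROSTRAL = {"SN": 0.3, "PN": -0.3}
# Fraction by which asymmetry_scale = 1 pulls right hotspots toward the
# midline (and pushes left hotspots away), and the right-side amplitude bias.
_ASYM_HOTSPOT_FRACTION = 0.4
_ASYM_AMPLITUDE_BIAS = 0.15

_ATTENUATION_LENGTH_MM = 0.8

# HF event kernel: one Gabor cycle at 1.5 kHz, ~1 ms support, unit peak.
_KERNEL_F0_HZ = 1500.0
_KERNEL_SIGMA_MS = 0.2
_KERNEL_HALFSPAN_MS = 0.6

# Stimulus artifact: damped 2.5 kHz oscillation, ~1 ms decay.
_ARTIFACT_F0_HZ = 2500.0
_ARTIFACT_TAU_MS = 0.4


@dataclass(frozen=True)
class GeneratorConfig:
    """Study design and noise/effect dials for one synthetic cohort.

    Defaults reproduce the in-vivo design scale: 7 animals, 20 stimulus sets
    of 11 trials per nerve (880 trials/animal, 6160 total) sampled at
    40 kHz on a [-20, +80] ms window around the stimulus.
    """

    n_animals: int = 7
    n_sets: int = 20
    trials_per_set: int = 11
    sample_rate: float = 40_000.0
    trace_window_ms: tuple[float, float] = (20.0, 80.0)  # (pre, post)
    noise_sd: float = 16.0         # uV, white noise per channel
    artifact_amplitude: float = 500.0  # uV
    effect_scale: float = 1.0      # scales all nerve-dependent differences
    asymmetry_scale: float = 0.5   # scales left/right hotspot displacement
    animal_variability_sd: float = 0.1  # fractional, per animal
    electrode_shift_sd: float = 150.0   # um, per-animal array placement
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if self.n_sets < 1 or self.trials_per_set < 1:
            raise ValueError("n_sets and trials_per_set must be >= 1")
        if self.sample_rate <= 2 * 3300.0:
            raise ValueError("sample_rate must exceed twice the HF band edge")
        pre, post = self.trace_window_ms
        if pre < 15.0 or post < 55.0:
            raise ValueError("trace window must cover [-15, 55] ms")
        for name in ("effect_scale", "asymmetry_scale"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_sd < 0 or self.animal_variability_sd < 0:
            raise ValueError("noise and variability SDs must be non-negative")
        if self.electrode_shift_sd < 0:
            raise ValueError("electrode_shift_sd must be non-negative")

    @property
    def trials_per_nerve(self) -> int:
        return self.n_sets * self.trials_per_set

    @property
    def trials_per_animal(self) -> int:
        return self.trials_per_nerve * len(NERVES)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["trace_window_ms"] = list(self.trace_window_ms)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "trace_window_ms" in d:
            d["trace_window_ms"] = tuple(d["trace_window_ms"])
        return cls(**d)


@dataclass
class AnimalModel:
    """Per-animal generative parameters (ground truth for one animal)."""

    animal_id: str
    hotspots: dict[str, tuple[float, float]]       # nerve -> (x, y) mm
    lf_params: dict[str, dict[str, float]]         # nerve -> P1/N1 latency & amp
    hf_params: dict[str, dict[str, float]]         # nerve -> rate, amplitude
    attenuation_length_mm: float
    electrode_shift_um: tuple[float, float]        # (lateral, rostro-caudal)


def _nerve_params(
    nerve: str,
    effect: float,
    asym: float,
    amp_factor: float,
    lat_factor: float,
    rate_factor: float,
) -> tuple[tuple[float, float], dict[str, float], dict[str, float]]:
    side, ntype = _nerve_side_type(nerve)
    sgn = 1.0 if ntype == "SN" else -1.0
    p = {k: _BASE[k] + sgn * effect * _TYPE_OFFSET[k] for k in _BASE}
    # Right-side magnitude bias at asymmetry > 0 (scaled by effect so the
    # effect_scale = 0 cohort is an exact null).
    bias = 1.0 + side * effect * asym * _ASYM_AMPLITUDE_BIAS
    lf = {
        "p1_latency_ms": p["p1_latency_ms"] * lat_factor,
        "n1_latency_ms": p["n1_latency_ms"] * lat_factor,
        "p1_amplitude_uv": p["p1_amplitude_uv"] * amp_factor * bias,
        "n1_amplitude_uv": p["n1_amplitude_uv"] * amp_factor * bias,
    }
    hf = {
        "rate_per_ms": p["hf_rate_per_ms"] * rate_factor,
        "amplitude_uv": p["hf_amplitude_uv"] * amp_factor * bias,
    }
    x = side * effect * _HOTSPOT_LATERAL[ntype] * (
        1.0 - side * asym * _ASYM_HOTSPOT_FRACTION
    )
    y = effect * _HOTSPOT_ROSTRAL[ntype]
    return (x, y), lf, hf


def make_cohort(config: GeneratorConfig) -> list[AnimalModel]:
    """Draw a cohort of animal models around the cohort means.

    Per-animal variability is applied as shared multiplicative factors
    (amplitudes, latencies, burst rates) so nerve-type orderings are
    preserved within every animal; the electrode array shift is a per-animal
    zero-mean lateral/rostro-caudal offset.  Deterministic given
    ``config.rng_seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.rng_seed, 0xC0)))
    animals = []
    sd = config.animal_variability_sd
    for a in range(config.n_animals):
        amp_factor = float(np.clip(1.0 + sd * rng.standard_normal(), 0.5, 1.5))
        lat_factor = float(np.clip(1.0 + sd * rng.standard_normal(), 0.7, 1.3))
        rate_factor = float(np.clip(1.0 + sd * rng.standard_normal(), 0.5, 1.5))
        shift = rng.normal(0.0, config.electrode_shift_sd, size=2)
        hotspots, lf_params, hf_params = {}, {}, {}
        for nerve in NERVES:
            hs, lf, hf = _nerve_params(
                nerve,
                config.effect_scale,
                config.asymmetry_scale,
                amp_factor,
                lat_factor,
                rate_factor,
            )
            hotspots[nerve] = hs
            lf_params[nerve] = lf
            hf_params[nerve] = hf
        animals.append(
            AnimalModel(
                animal_id=f"a{a + 1}",
                hotspots=hotspots,
                lf_params=lf_params,
                hf_params=hf_params,
                attenuation_length_mm=_ATTENUATION_LENGTH_MM,
                electrode_shift_um=(float(shift[0]), float(shift[1])),
            )
        )
    return animals


def channel_gains(
    animal: AnimalModel, nerve: str, layout: ElectrodeLayout = DEFAULT_LAYOUT
) -> np.ndarray:
    """Per-electrode gain exp(-d / attenuation_length) for one nerve."""
    positions = layout.shifted(*animal.electrode_shift_um)
    hotspot = np.asarray(animal.hotspots[nerve])
    d = np.linalg.norm(positions - hotspot, axis=1)
    return np.exp(-d / animal.attenuation_length_mm)


def _raised_cos_lobe(t_ms: np.ndarray, centre: float, halfwidth: float) -> np.ndarray:
    u = (t_ms - centre) / halfwidth
    out = np.zeros_like(t_ms)
    mask = np.abs(u) < 1.0
    out[mask] = np.cos(0.5 * np.pi * u[mask]) ** 2
    return out


def lf_waveform(t_ms: np.ndarray, lf: dict[str, float]) -> np.ndarray:
    """Biphasic slow wave with exact extrema at the injected parameters.

    The P1 and N1 lobes are raised-cosine bumps whose supports meet but do
    not overlap (P1 takes 40% of the P1-N1 gap, N1 60%), so the waveform's
    maximum is exactly (t_p1, p1_amplitude) and its minimum exactly
    (t_n1, n1_amplitude).
    """
    tp, tn = lf["p1_latency_ms"], lf["n1_latency_ms"]
    gap = tn - tp
    if gap <= 0:
        raise ValueError("N1 latency must exceed P1 latency")
    wave = lf["p1_amplitude_uv"] * _raised_cos_lobe(t_ms, tp, 0.4 * gap)
    wave += lf["n1_amplitude_uv"] * _raised_cos_lobe(t_ms, tn, 0.6 * gap)
    return wave


@lru_cache(maxsize=8)
def _hf_kernel(sample_rate: float) -> np.ndarray:
    """Biphasic ~1 ms event kernel, unit positive peak, 550-3300 Hz energy."""
    dt = 1000.0 / sample_rate
    t = np.arange(-_KERNEL_HALFSPAN_MS, _KERNEL_HALFSPAN_MS + dt / 2, dt)
    k = np.sin(2 * np.pi * _KERNEL_F0_HZ * t / 1000.0) * np.exp(
        -(t**2) / (2 * _KERNEL_SIGMA_MS**2)
    )
    return k / k.max()


def synthesize_trial(
    animal: AnimalModel,
    nerve: str,
    config: GeneratorConfig,
    seed: int,
) -> RawTrace:
    """One 7-channel evoked trial for the given animal and nerve."""
    _nerve_side_type(nerve)  # validates the label
    rng = np.random.default_rng(seed)
    fs = config.sample_rate
    pre, post = config.trace_window_ms
    t0 = int(round(pre * fs / 1000.0))
    n = t0 + int(round(post * fs / 1000.0))
    t_ms = (np.arange(n) - t0) * 1000.0 / fs

    common = lf_waveform(t_ms, animal.lf_params[nerve])

    hf = animal.hf_params[nerve]
    w0, w1 = HF_WINDOW_MS
    n_events = rng.poisson(hf["rate_per_ms"] * (w1 - w0))
    if n_events > 0 and hf["amplitude_uv"] != 0.0:
        kernel = _hf_kernel(fs)
        half = len(kernel) // 2
        event_t = rng.uniform(w0, w1, size=n_events)
        idx = t0 + np.floor(event_t * fs / 1000.0).astype(int)
        for i in idx:
            lo, hi = i - half, i - half + len(kernel)
            klo, khi = max(0, -lo), len(kernel) - max(0, hi - n)
            common[max(lo, 0) : min(hi, n)] += (
                hf["amplitude_uv"] * kernel[klo:khi]
            )

    if config.artifact_amplitude != 0.0:
        span = t_ms >= 0
        ta = t_ms[span]
        common[span] += (
            config.artifact_amplitude
            * np.sin(2 * np.pi * _ARTIFACT_F0_HZ * ta / 1000.0)
            * np.exp(-ta / _ARTIFACT_TAU_MS)
        )

    gains = channel_gains(animal, nerve)
    samples = gains[:, None] * common[None, :]
    if config.noise_sd > 0:
        samples = samples + rng.normal(0.0, config.noise_sd, size=samples.shape)
    return RawTrace(samples=samples, sample_rate=fs, t0_index=t0)


def trial_seed(config: GeneratorConfig, animal_idx: int, nerve: str, trial: int) -> int:
    """Deterministic per-trial seed derived from the cohort seed."""
    ss = np.random.SeedSequence(
        (config.rng_seed, animal_idx, NERVES.index(nerve), trial)
    )
    return int(ss.generate_state(1)[0])


@dataclass
class TrialSet:
    """A cohort's worth of trials, synthesized lazily.

    ``labels`` holds one row per trial (animal, nerve, trial, seed);
    :meth:`iter_traces` synthesizes each trace on demand so the full default
    cohort (6160 trials) never needs to sit in memory at once.
    """

    config: GeneratorConfig
    animals: list[AnimalModel]
    labels: pd.DataFrame = field(repr=False)

    def __len__(self) -> int:
        return len(self.labels)

    def iter_traces(self):
        """Yield ``(trace, animal_id, nerve, trial_idx, seed)`` per trial."""
        by_id = {a.animal_id: a for a in self.animals}
        for row in self.labels.itertuples(index=False):
            trace = synthesize_trial(
                by_id[row.animal], row.nerve, self.config, row.seed
            )
            yield trace, row.animal, row.nerve, row.trial, row.seed


def generate_dataset(config: GeneratorConfig) -> TrialSet:
    """Full balanced design: every animal gets n_sets x trials_per_set trials
    of each of the four nerves, with per-trial seeds derived deterministically
    from ``config.rng_seed``."""
    animals = make_cohort(config)
    rows = []
    for a_idx, animal in enumerate(animals):
        for nerve in NERVES:
            for k in range(config.trials_per_nerve):
                rows.append(
                    {
                        "animal": animal.animal_id,
                        "nerve": nerve,
                        "trial": k,
                        "seed": trial_seed(config, a_idx, nerve, k),
                    }
                )
    return TrialSet(config=config, animals=animals, labels=pd.DataFrame(rows))


# --------------------------------------------------------------------------
# Closed-form ground-truth feature expectations
# --------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _filter_noise_stats(sample_rate: float) -> tuple[float, float, float]:
    """Gaussian-process statistics of unit-SD white noise after the
    zero-phase band-pass: ``(sd_ratio, nu_max, eps)``.

    ``sd_ratio`` is the output/input noise SD; ``nu_max`` the expected rate
    of local maxima per second ((1/2pi) sqrt(m4/m2)); ``eps`` the spectral
    width parameter sqrt(1 - m2^2/(m0 m4)) of the Cartwright–Longuet-Higgins
    peak-height distribution.  Moments m_k = int (2 pi f)^k S(f) df are
    computed by quadrature of the realized response (the forward-backward
    pass contributes |H|^2 in amplitude, |H|^4 in power).
    """
    sos = hf_bandpass_sos(sample_rate)
    f, h = _signal.sosfreqz(sos, worN=16384, fs=sample_rate)
    p = np.abs(h) ** 4  # power transfer of filtfilt
    w = 2 * np.pi * f
    m0 = np.trapezoid(p, f)
    m2 = np.trapezoid(w**2 * p, f)
    m4 = np.trapezoid(w**4 * p, f)
    sd_ratio = math.sqrt(m0 / (sample_rate / 2.0))
    nu_max = math.sqrt(m4 / m2) / (2 * np.pi)
    eps = math.sqrt(max(1.0 - m2**2 / (m0 * m4), 1e-12))
    return sd_ratio, nu_max, eps


def _peak_exceedance(u: float, eps: float) -> float:
    """P(height of a local maximum > u*sigma) for a Gaussian process with
    spectral width ``eps`` (Cartwright–Longuet-Higgins)."""
    root = math.sqrt(max(1.0 - eps**2, 0.0))
    return float(
        norm.sf(u / eps)
        + root * math.exp(-(u**2) / 2.0) * norm.cdf(u * root / eps)
    )


@lru_cache(maxsize=8)
def _filtered_kernel(sample_rate: float) -> np.ndarray:
    """The HF event kernel as it appears after the zero-phase band-pass."""
    kernel = _hf_kernel(sample_rate)
    padded = np.zeros(4096)
    padded[2048 - len(kernel) // 2 : 2048 - len(kernel) // 2 + len(kernel)] = kernel
    return _signal.sosfiltfilt(hf_bandpass_sos(sample_rate), padded)


@lru_cache(maxsize=8)
def _kernel_lobe_values(sample_rate: float) -> tuple[float, ...]:
    """Heights of the positive local maxima of the filtered unit kernel
    (each lobe can become a counted peak if it rises above threshold)."""
    k = _filtered_kernel(sample_rate)
    interior = np.arange(1, len(k) - 1)
    is_max = (k[interior] > k[interior - 1]) & (k[interior] > k[interior + 1])
    vals = np.sort(k[interior][is_max & (k[interior] > 1e-3)])[::-1]
    return tuple(float(v) for v in vals)


@lru_cache(maxsize=512)
def _pair_area_correction(sample_rate: float, max_sep_ms: float = 6.0) -> float:
    """Second-order Poisson cluster correction for the rectified area.

    Two filtered events separated by ``tau`` partially cancel when
    rectified: |k(t) + k(t - tau)| integrates to less than twice the
    single-event area.  Integrating that deficit over the Poisson
    pair-separation density (lambda^2 per unit separation per window) gives
    an additive correction ``rate^2 * window * d_area`` to the expected
    integral; the deficit is linear in the event amplitude, so it is
    computed here for a unit-amplitude kernel.  Valid in the sparse regime
    where triple overlaps are rare; higher-order clusters (and the
    analogous peak-count interactions, which are not pairwise-dominated)
    are neglected.
    """
    dt_ms = 1000.0 / sample_rate
    k = _filtered_kernel(sample_rate)
    single_area = np.sum(np.abs(k)) * dt_ms
    max_shift = int(round(max_sep_ms / dt_ms))
    d_area = 0.0
    for shift in range(1, max_shift + 1):
        s = np.concatenate([k, np.zeros(shift)]) + np.concatenate(
            [np.zeros(shift), k]
        )
        pair_area = np.sum(np.abs(s)) * dt_ms
        # ordered pairs at +/-tau -> factor 2, halved for unordered pairs
        d_area += (pair_area - 2.0 * single_area) * dt_ms
    return float(d_area)


def ground_truth_features(
    animal: AnimalModel,
    nerve: str,
    layout: ElectrodeLayout = DEFAULT_LAYOUT,
    config: GeneratorConfig | None = None,
) -> pd.DataFrame:
    """Expected per-electrode SF values under the generative model.

    Low-frequency features are exact (the slow wave's extrema are the
    injected parameters scaled by each electrode's gain).  High-frequency
    expectations model the filtered noise as a Gaussian process:

    - peak count = rate x window x (expected suprathreshold lobes of one
      filtered event) + a false-positive term from the
      Cartwright–Longuet-Higgins peak-height distribution of the noise;
    - integral = rate x window x the expected rectified-minus-baseline area
      of one filtered event, using the exact Gaussian identity
      E|s + n| - E|n| pointwise along the kernel.

    Event overlap is neglected, so the HF expectations are accurate in the
    sparse regime (rate x kernel width << 1); the low-frequency ones are
    exact whenever the burst does not ride on the N1 trough (rate -> 0).

    Returns a DataFrame indexed e1..e7 with the five SF columns.
    """
    cfg = config or GeneratorConfig()
    gains = channel_gains(animal, nerve, layout)
    lf = animal.lf_params[nerve]
    hf = animal.hf_params[nerve]
    w0, w1 = HF_WINDOW_MS
    window_ms = w1 - w0

    sd_ratio, nu_max, eps = _filter_noise_stats(cfg.sample_rate)
    sigma_hf = cfg.noise_sd * sd_ratio
    from .features import MIN_PEAK_UV, PEAK_THRESHOLD_SD

    threshold = max(PEAK_THRESHOLD_SD * sigma_hf, MIN_PEAK_UV)

    amp = (lf["n1_amplitude_uv"] - lf["p1_amplitude_uv"]) * gains
    gap = lf["n1_latency_ms"] - lf["p1_latency_ms"]

    lobes = np.array(_kernel_lobe_values(cfg.sample_rate))
    kernel = _filtered_kernel(cfg.sample_rate)
    dt_ms = 1000.0 / cfg.sample_rate
    event_amp = np.abs(hf["amplitude_uv"]) * gains  # per electrode

    counts = np.empty(7)
    integrals = np.empty(7)
    for i, a in enumerate(event_amp):
        lobe_heights = a * lobes
        if sigma_hf > 0:
            peaks_per_event = float(
                np.sum(norm.cdf((lobe_heights - threshold) / sigma_hf))
            )
        else:
            peaks_per_event = float(np.sum(lobe_heights > threshold))
        s = np.abs(a * kernel)
        if sigma_hf > 0:
            rect = s * (2.0 * norm.cdf(s / sigma_hf) - 1.0) + sigma_hf * math.sqrt(
                2.0 / math.pi
            ) * (np.exp(-(s**2) / (2.0 * sigma_hf**2)) - 1.0)
        else:
            rect = s
        rate = hf["rate_per_ms"]
        counts[i] = rate * window_ms * peaks_per_event
        integrals[i] = rate * window_ms * float(np.sum(rect) * dt_ms)
        if a > 0 and rate > 0:
            integrals[i] += (
                rate**2 * window_ms * a * _pair_area_correction(cfg.sample_rate)
            )
    if sigma_hf > 0:
        counts += (
            (window_ms / 1000.0)
            * nu_max
            * _peak_exceedance(threshold / sigma_hf, eps)
        )

    return pd.DataFrame(
        {
            "n1_latency": np.full(7, lf["n1_latency_ms"]),
            "p1n1_slope": amp / gap,
            "p1n1_amplitude": amp,
            "hf_peak_count": counts,
            "hf_integral": integrals,
        },
        index=[f"e{i}" for i in range(1, 8)],
    )[list(SF_NAMES)]
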