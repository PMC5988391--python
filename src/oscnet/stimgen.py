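"""Cloud-of-sweeps acoustic textures and balanced trial designs.

The stimuli modeled here are brief acoustic textures: 400-ms sounds built
from 72 overlapping frequency-modulated (FM) sine sweeps of 100 ms each.
Sweep onsets and start frequencies are uniformly distributed across time
and log frequency.  Two stimulus dimensions are manipulated factorially:

* **spectral center** — the texture's overall pitch placement, one of
  eight values deviating ±2, ±1, ±0.5 or ±0.25 semitones from a mean
  center frequency of 707.1 Hz;
* **coherence** — the fraction (25/50/75/100 %) of sweeps sharing one
  signed frequency slope (±3.3 octaves/s); the remaining sweeps get a
  randomly signed slope.

The module also generates the balanced block design in which the stimuli
are presented: blocks of 128 trials containing each direction × coherence
× spectral-center cell exactly twice, with the task (pitch vs. direction
judgment) alternating from block to block.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Semitone deviations of the eight spectral-center levels.
SEMITONE_DEVIATIONS = (-2.0, -1.0, -0.5, -0.25, 0.25, 0.5, 1.0, 2.0)

#: Fractions of sweeps sharing the coherent slope.
COHERENCE_LEVELS = (0.25, 0.5, 0.75, 1.0)

DEFAULT_MEAN_CENTER_HZ = 707.1
DEFAULT_SLOPE_OCT_PER_S = 3.3

TASKS = ("pitch", "direction")
DIRECTIONS = ("up", "down")

#: Trials per block with 2 repeats of each of the 2 x 4 x 8 condition cells.
TRIALS_PER_BLOCK = 2 * len(COHERENCE_LEVELS) * len(SEMITONE_DEVIATIONS) * 2


def spectral_centers(
    mean_freq: float = DEFAULT_MEAN_CENTER_HZ,
    deviations=SEMITONE_DEVIATIONS,
) -> np.ndarray:
    """Spectral-center frequencies for semitone deviations around a mean.

    Each deviation ``d`` (in semitones) maps to ``mean_freq * 2**(d/12)``.

    Parameters
    ----------
    mean_freq : float
        Mean center frequency in Hz; must be positive.
    deviations : sequence of float
        Deviations in semitones.

    Returns
    -------
    numpy.ndarray
        Center frequencies in Hz, ascending.
    """
    if mean_freq <= 0:
        raise ValueError(f"mean_freq must be positive, got {mean_freq}")
    dev = np.asarray(deviations, dtype=float)
    return np.sort(mean_freq * 2.0 ** (dev / 12.0))


@dataclass(frozen=True)
class TextureSpec:
    """Parameters of one acoustic texture.

    Attributes
    ----------
    duration : float
        Total stimulus duration in seconds.
    n_sweeps : int
        Number of FM sweeps in the texture.
    sweep_duration : float
        Duration of each sweep in seconds.
    mean_center_freq : float
        Mean center frequency in Hz from which the spectral center deviates.
    semitone_deviation : float
        Deviation of this texture's spectral center, in semitones.
    coherence : float
        Fraction of sweeps sharing the coherent slope, in (0, 1].
    coherent_direction : {"up", "down"}
        Sign of the coherent slope.
    slope_magnitude : float
        Magnitude of the frequency slope in octaves/second.
    freq_span_octaves : float
        Half-width of the uniform log-frequency span of sweep start
        frequencies around the spectral center.
    continuous_slopes : bool
        If True, incoherent sweeps draw slopes uniformly from
        ``[-slope_magnitude, +slope_magnitude]`` instead of a random sign
        at full magnitude.
    """

    duration: float = 0.4
    n_sweeps: int = 72
    sweep_duration: float = 0.1
    mean_center_freq: float = DEFAULT_MEAN_CENTER_HZ
    semitone_deviation: float = 0.0
    coherence: float = 1.0
    coherent_direction: str = "up"
    slope_magnitude: float = DEFAULT_SLOPE_OCT_PER_S
    freq_span_octaves: float = 1.5
    continuous_slopes: bool = False

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not (0 < self.sweep_duration <= self.duration):
            raise ValueError("sweep_duration must be in (0, duration]")
        if not (0 < self.coherence <= 1):
            raise ValueError("coherence must be in (0, 1]")
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")
        if self.mean_center_freq <= 0:
            raise ValueError("mean_center_freq must be positive")
        if self.coherent_direction not in DIRECTIONS:
            raise ValueError(f"coherent_direction must be one of {DIRECTIONS}")
        if self.slope_magnitude <= 0:
            raise ValueError("slope_magnitude must be positive")

    @property
    def center_freq(self) -> float:
        """Spectral center of this texture in Hz."""
        return self.mean_center_freq * 2.0 ** (self.semitone_deviation / 12.0)

    @property
    def n_coherent(self) -> int:
        """Number of sweeps carrying the coherent slope (nearest-integer)."""
        return int(round(self.coherence * self.n_sweeps))


@dataclass(frozen=True)
class TextureStimulus:
    """One realized texture: per-sweep onsets, start frequencies and slopes."""

    spec: TextureSpec
    onsets: np.ndarray  # seconds
    start_freqs: np.ndarray  # Hz
    slopes: np.ndarray  # octaves/second
    is_coherent: np.ndarray  # bool

    def __len__(self) -> int:
        return len(self.onsets)

    @property
    def sweeps(self) -> list[tuple[float, float, float, bool]]:
        """Sweeps as ``(onset, start_freq, slope, is_coherent)`` tuples."""
        return [
            (float(o), float(f), float(s), bool(c))
            for o, f, s, c in zip(
                self.onsets, self.start_freqs, self.slopes, self.is_coherent
            )
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_s": self.onsets,
                "start_freq_hz": self.start_freqs,
                "slope_oct_per_s": self.slopes,
                "is_coherent": self.is_coherent,
            }
        )


def make_texture(spec: TextureSpec, seed) -> TextureStimulus:
    """Draw one texture stimulus from a spec.

    Onsets are uniform on ``[0, duration - sweep_duration]`` so every sweep
    completes within the stimulus.  Start frequencies are uniform in log2
    frequency over ``center_freq * 2**(+-freq_span_octaves)``.  Exactly
    ``round(coherence * n_sweeps)`` sweeps share the coherent signed slope.

    Parameters
    ----------
    spec : TextureSpec
    seed : int or numpy.random.Generator

    Returns
    -------
    TextureStimulus
        Deterministic for a fixed ``(spec, seed)``.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_sweeps
    onsets = rng.uniform(0.0, spec.duration - spec.sweep_duration, size=n)
    log_c = math.log2(spec.center_freq)
    start_freqs = 2.0 ** rng.uniform(
        log_c - spec.freq_span_octaves, log_c + spec.freq_span_octaves, size=n
    )

    coherent_sign = 1.0 if spec.coherent_direction == "up" else -1.0
    is_coherent = np.zeros(n, dtype=bool)
    idx = rng.choice(n, size=spec.n_coherent, replace=False)
    is_coherent[idx] = True

    slopes = np.empty(n)
    slopes[is_coherent] = coherent_sign * spec.slope_magnitude
    n_inc = n - spec.n_coherent
    if spec.continuous_slopes:
        slopes[~is_coherent] = rng.uniform(
            -spec.slope_magnitude, spec.slope_magnitude, size=n_inc
        )
    else:
        slopes[~is_coherent] = (
            rng.choice([-1.0, 1.0], size=n_inc) * spec.slope_magnitude
        )
    return TextureStimulus(spec, onsets, start_freqs, slopes, is_coherent)


def _sweep_phase(f0: float, slope: float, t: np.ndarray) -> np.ndarray:
    # Instantaneous frequency f(t) = f0 * 2**(slope*t); phase is its integral.
    if slope == 0.0:
        return 2.0 * np.pi * f0 * t
    return 2.0 * np.pi * f0 * (2.0 ** (slope * t) - 1.0) / (slope * math.log(2.0))


def synthesize_audio(
    stim: TextureStimulus,
    sample_rate: float = 44100.0,
    ramp_duration: float = 0.005,
) -> np.ndarray:
    """Render a texture to a mono waveform.

    Each sweep is a sine with exponentially gliding frequency
    ``f(t) = f0 * 2**(slope * t)``, gated by raised-cosine on/off ramps to
    avoid clicks.  The summed waveform is peak-normalized to ``|x| <= 1``.

    Parameters
    ----------
    stim : TextureStimulus
    sample_rate : float
        Output sample rate in Hz; must be >= 8000.
    ramp_duration : float
        On/off ramp length in seconds.

    Returns
    -------
    numpy.ndarray of shape ``(round(duration * sample_rate),)``
    """
    if sample_rate < 8000:
        raise ValueError("sample_rate must be >= 8000 Hz")
    spec = stim.spec
    n_total = int(round(spec.duration * sample_rate))
    out = np.zeros(n_total)
    if len(stim) == 0:
        return out

    f_end = stim.start_freqs * 2.0 ** (
        np.maximum(stim.slopes, 0.0) * spec.sweep_duration
    )
    f_max = float(np.max(np.maximum(stim.start_freqs, f_end)))
    if f_max > sample_rate / 2:
        logger.warning(
            "highest instantaneous frequency %.1f Hz exceeds Nyquist (%.1f Hz)",
            f_max,
            sample_rate / 2,
        )

    n_sweep = int(round(spec.sweep_duration * sample_rate))
    t = np.arange(n_sweep) / sample_rate
    n_ramp = max(1, min(int(round(ramp_duration * sample_rate)), n_sweep // 2))
    window = np.ones(n_sweep)
    ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
    window[:n_ramp] = ramp
    window[-n_ramp:] = ramp[::-1]

    for onset, f0, slope in zip(stim.onsets, stim.start_freqs, stim.slopes):
        start = int(round(onset * sample_rate))
        stop = min(start + n_sweep, n_total)
        seg = np.sin(_sweep_phase(f0, slope, t)) * window
        out[start:stop] += seg[: stop - start]

    peak = np.max(np.abs(out))
    if peak > 0:
        out /= peak
    return out


def write_wav(path, waveform: np.ndarray, sample_rate: float = 44100.0) -> None:
    """Write a waveform to a 16-bit PCM WAV file."""
    from scipy.io import wavfile

    clipped = np.clip(waveform, -1.0, 1.0)
    wavfile.write(path, int(sample_rate), (clipped * 32767).astype(np.int16))


def make_design(
    n_blocks: int,
    seed,
    n_repeats: int = 2,
    tasks=TASKS,
) -> pd.DataFrame:
    """Build the balanced, randomized trial design.

    Every block contains ``n_repeats`` trials of each direction x coherence
    x spectral-center cell (128 trials for the default two repeats), in
    randomized order.  The task alternates from block to block; which task
    comes first is randomized.  The mapping of decision labels to the two
    response buttons is randomized per trial.

    Parameters
    ----------
    n_blocks : int
        Number of blocks; must be >= 1.
    seed : int or numpy.random.Generator
    n_repeats : int
        Repeats of each condition cell per block.

    Returns
    -------
    pandas.DataFrame
        One row per trial with columns ``trial``, ``block``,
        ``trial_in_block``, ``task``, ``direction``, ``coherence``,
        ``spectral_center_semitones``, ``repeat``, ``button_map``.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = np.random.default_rng(seed)
    first = int(rng.integers(len(tasks)))

    cells = list(
        itertools.product(
            DIRECTIONS, COHERENCE_LEVELS, SEMITONE_DEVIATIONS, range(1, n_repeats + 1)
        )
    )
    blocks = []
    for b in range(n_blocks):
        order = rng.permutation(len(cells))
        rows = [cells[i] for i in order]
        frame = pd.DataFrame(
            rows,
            columns=["direction", "coherence", "spectral_center_semitones", "repeat"],
        )
        frame.insert(0, "trial_in_block", np.arange(len(frame)))
        frame.insert(0, "block", b)
        frame.insert(2, "task", tasks[(first + b) % len(tasks)])
        frame["button_map"] = rng.integers(0, 2, size=len(frame))
        blocks.append(frame)
    design = pd.concat(blocks, ignore_index=True)
    design.insert(0, "trial", np.arange(len(design)))
    return design


def texture_spec_for_trial(row, **overrides) -> TextureSpec:
    """TextureSpec for one design row (a trial of :func:`make_design`)."""
    params = dict(
        semitone_deviation=float(row["spectral_center_semitones"]),
        coherence=float(row["coherence"]),
        coherent_direction=str(row["direction"]),
    )
    params.update(overrides)
    return TextureSpec(**params)
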