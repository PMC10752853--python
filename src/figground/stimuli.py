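"""Psychophysical stimulus synthesis.

Three stimulus classes used to probe cochlear-implant listeners:

* stochastic figure-ground (SFG) tone clouds — 4-s sequences of 50-ms chords
  drawn from a dense log-frequency grid; on "figure" trials a subset of
  components repeats across the second half, creating a groupable object;
* spectral ripple noise — broadband noise whose log-magnitude envelope is a
  sinusoid in log-frequency, indexing spectral resolution;
* five-component amplitude-modulated complexes — indexing temporal-envelope
  resolution at a 20-Hz modulation rate.

Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .audio import (
    DEFAULT_SAMPLE_RATE,
    Waveform,
    linear_ramp,
    peak_normalize,
    raised_cosine_ramp,
    rms_equalize,
)


class InfeasibleConstraintError(ValueError):
    """Raised when a separation constraint cannot be satisfied."""


class ClippedModulationError(ValueError):
    """Raised when a requested modulation depth exceeds m = 1."""


# ---------------------------------------------------------------------------
# frequency grid
# ---------------------------------------------------------------------------

def make_frequency_grid(low_hz: float, high_hz: float, steps_per_octave: int) -> np.ndarray:
    """Geometric frequency grid from ``low_hz`` upward in steps of
    2**(1/steps_per_octave), including every step <= ``high_hz``.

    For an exact-octave span the grid has floor(steps*log2(high/low)) + 1
    members (e.g. 1–8 kHz at 48 steps/octave -> 145 components).
    """
    if low_hz <= 0 or high_hz <= 0:
        raise ValueError("frequencies must be positive")
    if low_hz > high_hz:
        raise ValueError("low_hz must not exceed high_hz")
    if steps_per_octave < 1:
        raise ValueError("steps_per_octave must be >= 1")
    # tolerance absorbs float error so an exact top edge is included
    n_steps = int(np.floor(steps_per_octave * np.log2(high_hz / low_hz) + 1e-9))
    return low_hz * 2.0 ** (np.arange(n_steps + 1) / steps_per_octave)


# ---------------------------------------------------------------------------
# stochastic figure-ground
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SFGStimulusSpec:
    """Construction recipe for a stochastic figure-ground trial."""

    segment_ms: float = 50.0
    n_segments_per_half: int = 40
    components_per_segment: int = 8
    n_figure_components: int = 6
    grid_low_hz: float = 1000.0
    grid_high_hz: float = 8000.0
    grid_steps_per_octave: int = 48
    min_figure_separation_octaves: float = 0.5
    pip_ramp_ms: float = 5.0
    sample_rate: int = DEFAULT_SAMPLE_RATE
    level_db_spl: float = 70.0

    def __post_init__(self) -> None:
        if self.n_figure_components > self.components_per_segment:
            raise ValueError("n_figure_components must not exceed components_per_segment")
        if self.grid_low_hz >= self.grid_high_hz:
            raise ValueError("grid_low_hz must be below grid_high_hz")
        if self.segment_ms <= 0 or self.n_segments_per_half <= 0:
            raise ValueError("durations must be positive")

    @property
    def n_segments(self) -> int:
        return 2 * self.n_segments_per_half

    @property
    def duration_s(self) -> float:
        return self.n_segments * self.segment_ms / 1000.0

    def grid(self) -> np.ndarray:
        return make_frequency_grid(
            self.grid_low_hz, self.grid_high_hz, self.grid_steps_per_octave
        )


@dataclass
class SFGStimulus:
    """A realized tone-cloud trial with its ground/figure label."""

    spec: SFGStimulusSpec
    is_figure: bool
    figure_frequencies: np.ndarray
    segment_frequencies: list[np.ndarray]
    seed: int
    waveform: Waveform | None = None


def _draw_figure_frequencies(spec: SFGStimulusSpec, grid: np.ndarray, rng) -> np.ndarray:
    """Draw figure components uniformly among all grid subsets with pairwise
    separation >= min_figure_separation_octaves.

    Uses the gap bijection: sorted indices x_1 < ... < x_k with
    x_{i+1} - x_i >= g correspond one-to-one to k distinct values from a
    grid shortened by (k-1)(g-1), so the draw is exact (no rejection).
    """
    k = spec.n_figure_components
    # minimum index gap on the log-spaced grid
    g = int(np.ceil(spec.min_figure_separation_octaves * spec.grid_steps_per_octave - 1e-9))
    n_reduced = grid.size - (k - 1) * (g - 1)
    if n_reduced < k:
        span = np.log2(spec.grid_high_hz / spec.grid_low_hz)
        raise InfeasibleConstraintError(
            f"cannot place {k} components with pairwise separation "
            f">= {spec.min_figure_separation_octaves} octaves in a "
            f"{span:.3g}-octave grid"
        )
    y = np.sort(rng.choice(n_reduced, size=k, replace=False))
    idx = y + np.arange(k) * (g - 1)
    return grid[idx]


def _render_segments(
    spec: SFGStimulusSpec, segments: list[np.ndarray], rng
) -> Waveform:
    fs = spec.sample_rate
    n_seg_samp = int(round(spec.segment_ms * 1e-3 * fs))
    t = np.arange(n_seg_samp) / fs
    chunks = []
    for freqs in segments:
        phases = rng.uniform(0.0, 2.0 * np.pi, size=freqs.size)
        pips = np.sin(2.0 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])
        chord = pips.sum(axis=0) / freqs.size
        chunks.append(raised_cosine_ramp(chord, fs, spec.pip_ramp_ms))
    samples = peak_normalize(np.concatenate(chunks))
    return Waveform(samples=samples, sample_rate=fs,
                    nominal_level_db_spl=spec.level_db_spl)


def generate_sfg_stimulus(
    spec: SFGStimulusSpec,
    is_figure: bool,
    seed: int,
    render: bool = True,
) -> SFGStimulus:
    """Synthesize one SFG trial.

    Every 50-ms chord holds ``components_per_segment`` grid frequencies:
    ``n_figure_components`` of them mutually separated by at least the
    half-octave minimum plus the remainder drawn freely. In the first half
    (and throughout ground trials) the separated subset is redrawn every
    segment; on figure trials the second half freezes one separated subset —
    the figure — and only the remaining components change. Same seed ->
    bit-identical waveform.

    Set ``render=False`` to plan the frequency content without synthesizing
    audio (the frequency draws are identical either way).
    """
    rng = np.random.default_rng(seed)
    grid = spec.grid()
    m = spec.components_per_segment
    k = spec.n_figure_components

    figure_freqs = (
        _draw_figure_frequencies(spec, grid, rng) if is_figure else np.empty(0)
    )

    def one_segment(fixed: np.ndarray | None) -> np.ndarray:
        """One chord: k mutually separated components (fresh, or the frozen
        figure set) plus m - k free components drawn from the rest of the
        grid. Every segment of every trial class has the same within-segment
        statistics, so neither acoustic energy nor encoded current can cue
        the class."""
        sep = fixed if fixed is not None else _draw_figure_frequencies(spec, grid, rng)
        pool = np.delete(np.arange(grid.size), np.searchsorted(grid, sep))
        free = grid[rng.choice(pool, size=m - k, replace=False)]
        return np.sort(np.concatenate([sep, free]))

    segments: list[np.ndarray] = []
    for _ in range(spec.n_segments_per_half):
        segments.append(one_segment(None))
    for _ in range(spec.n_segments_per_half):
        segments.append(one_segment(figure_freqs if is_figure else None))

    waveform = _render_segments(spec, segments, rng) if render else None
    return SFGStimulus(
        spec=spec,
        is_figure=bool(is_figure),
        figure_frequencies=figure_freqs,
        segment_frequencies=segments,
        seed=int(seed),
        waveform=waveform,
    )


def generate_sfg_session(
    spec: SFGStimulusSpec,
    n_trials: int = 120,
    seed: int = 0,
    render: bool = True,
) -> list[SFGStimulus]:
    """Pre-generate a session of unique SFG stimuli, half of them containing
    a figure, in seed-randomized order."""
    if n_trials % 2 != 0:
        raise ValueError("n_trials must be even (half figure, half ground)")
    rng = np.random.default_rng(seed)
    labels = np.array([True] * (n_trials // 2) + [False] * (n_trials // 2))
    rng.shuffle(labels)
    # independent per-trial streams derived from the session seed
    trial_seeds = np.random.SeedSequence(seed).generate_state(n_trials) >> 1
    return [
        generate_sfg_stimulus(spec, bool(lab), int(s), render=render)
        for lab, s in zip(labels, trial_seeds)
    ]


# ---------------------------------------------------------------------------
# spectral ripple
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RippleSpec:
    """Rippled-noise recipe: sinusoidal log-magnitude envelope in
    log-frequency. ``depth_db`` is the peak-to-trough spectral contrast."""

    density_ripples_per_octave: float = 1.25
    depth_db: float = 20.0
    phase: float = 0.0
    band_low_hz: float = 100.0
    band_high_hz: float = 8000.0
    duration_ms: float = 500.0
    ramp_ms: float = 50.0
    sample_rate: int = DEFAULT_SAMPLE_RATE
    level_db_spl: float = 70.0

    def __post_init__(self) -> None:
        if self.depth_db < 0:
            raise ValueError("depth_db must be non-negative")
        if self.density_ripples_per_octave <= 0:
            raise ValueError("ripple density must be positive")


def generate_ripple(spec: RippleSpec, invert_phase: bool = False, seed: int = 0) -> Waveform:
    """Synthesize band-limited noise with a sinusoidal spectral ripple.

    The log-magnitude envelope is (depth_db/2)*sin(2*pi*density*octaves + phase)
    dB, so peak-to-trough contrast equals ``depth_db``; ``invert_phase`` adds
    pi (the oddball construction).
    """
    fs = spec.sample_rate
    n = int(round(spec.duration_ms * 1e-3 * fs))
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(n)
    spectrum = np.fft.rfft(noise)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    phase = spec.phase + (np.pi if invert_phase else 0.0)
    in_band = (freqs >= spec.band_low_hz) & (freqs <= spec.band_high_hz)
    gain = np.zeros_like(freqs)
    octaves = np.zeros_like(freqs)
    octaves[in_band] = np.log2(freqs[in_band] / spec.band_low_hz)
    gain_db = (spec.depth_db / 2.0) * np.sin(
        2.0 * np.pi * spec.density_ripples_per_octave * octaves + phase
    )
    gain[in_band] = 10.0 ** (gain_db[in_band] / 20.0)
    shaped = np.fft.irfft(spectrum * gain, n=n)
    samples = peak_normalize(linear_ramp(shaped, fs, spec.ramp_ms))
    return Waveform(samples=samples, sample_rate=fs,
                    nominal_level_db_spl=spec.level_db_spl)


# ---------------------------------------------------------------------------
# temporal modulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TMSpec:
    """Five-component complex, sinusoidally amplitude modulated at 20 Hz.

    ``depth_db`` encodes modulation depth m in [0, 1] as 20*log10(m) <= 0 —
    the scale the adaptive procedure operates on.
    """

    carrier_freqs_hz: tuple[float, ...] = (1515.0, 2350.0, 3485.0, 5045.0, 6990.0)
    am_rate_hz: float = 20.0
    depth_db: float = 0.0
    duration_ms: float = 500.0
    ramp_ms: float = 50.0
    sample_rate: int = DEFAULT_SAMPLE_RATE
    level_db_spl: float = 70.0

    @property
    def modulation_index(self) -> float:
        return float(10.0 ** (self.depth_db / 20.0))


def generate_tm(spec: TMSpec, modulated: bool = True, seed: int = 0) -> Waveform:
    """Synthesize the amplitude-modulation stimulus (or its unmodulated
    standard). Carrier phases are randomized by seed."""
    m = spec.modulation_index
    if m > 1.0 + 1e-12:
        raise ClippedModulationError(
            f"modulation index m={m:.3f} > 1 (depth_db must be <= 0)"
        )
    fs = spec.sample_rate
    n = int(round(spec.duration_ms * 1e-3 * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)
    carriers = np.zeros(n)
    for f in spec.carrier_freqs_hz:
        carriers += np.sin(2.0 * np.pi * f * t + rng.uniform(0.0, 2.0 * np.pi))
    carriers /= len(spec.carrier_freqs_hz)
    if modulated:
        envelope = 1.0 + m * np.sin(2.0 * np.pi * spec.am_rate_hz * t)
        carriers = carriers * envelope / (1.0 + m)
    samples = peak_normalize(linear_ramp(carriers, fs, spec.ramp_ms))
    return Waveform(samples=samples, sample_rate=fs,
                    nominal_level_db_spl=spec.level_db_spl)


# ---------------------------------------------------------------------------
# oddball trial assembly
# ---------------------------------------------------------------------------

def prepare_oddball_triplet(
    standard_gen,
    oddball_gen,
    rove_db: tuple[float, float] | None = (-3.0, 3.0),
    seed: int = 0,
    target_rms: float = 0.05,
) -> tuple[list[Waveform], int]:
    """Assemble a 3-interval oddball trial.

    ``standard_gen`` / ``oddball_gen`` are callables taking a seed and
    returning a Waveform. The three intervals are RMS-equalized, then each is
    independently level-roved uniformly over ``rove_db`` (so loudness is not
    a reliable cue); the oddball position is uniform over the three slots.

    Returns (waveforms in presentation order, oddball index).
    """
    if rove_db is not None:
        lo, hi = rove_db
        if not np.isclose(lo, -hi):
            raise ValueError("rove range must be symmetric about 0 dB")
    rng = np.random.default_rng(seed)
    seeds = np.random.SeedSequence(seed).generate_state(4) >> 1
    waves = [
        standard_gen(int(seeds[0])),
        standard_gen(int(seeds[1])),
        oddball_gen(int(seeds[2])),
    ]
    waves = rms_equalize(waves, target_rms=target_rms)
    if rove_db is not None:
        offsets = rng.uniform(rove_db[0], rove_db[1], size=3)
        waves = [w.scaled(10.0 ** (o / 20.0)) for w, o in zip(waves, offsets)]
    oddball_index = int(rng.integers(3))
    order = [0, 1]
    order.insert(oddball_index, 2)
    return [waves[i] for i in order], oddball_index


def make_ripple_trial(
    depth_db: float,
    seed: int = 0,
    spec: RippleSpec | None = None,
    rove_db: tuple[float, float] | None = (-3.0, 3.0),
) -> tuple[list[Waveform], int]:
    """One spectral-ripple oddball trial: both standards share one random
    ripple phase, the oddball carries the inverted phase, all at the same
    depth."""
    base = spec or RippleSpec()
    rng = np.random.default_rng(seed)
    trial_phase = rng.uniform(0.0, 2.0 * np.pi)
    sspec = RippleSpec(**{**base.__dict__, "depth_db": depth_db, "phase": trial_phase})

    def std(s: int) -> Waveform:
        return generate_ripple(sspec, invert_phase=False, seed=s)

    def odd(s: int) -> Waveform:
        return generate_ripple(sspec, invert_phase=True, seed=s)

    return prepare_oddball_triplet(std, odd, rove_db=rove_db, seed=int(rng.integers(2**31)))


def make_tm_trial(
    depth_db: float,
    seed: int = 0,
    spec: TMSpec | None = None,
    rove_db: tuple[float, float] | None = (-3.0, 3.0),
) -> tuple[list[Waveform], int]:
    """One temporal-modulation oddball trial. Half of trials present two
    modulated standards with an unmodulated oddball; the other half the
    reverse."""
    base = spec or TMSpec()
    rng = np.random.default_rng(seed)
    sspec = TMSpec(**{**base.__dict__, "depth_db": depth_db})
    standards_modulated = bool(rng.integers(2))

    def std(s: int) -> Waveform:
        return generate_tm(sspec, modulated=standards_modulated, seed=s)

    def odd(s: int) -> Waveform:
        return generate_tm(sspec, modulated=not standards_modulated, seed=s)

    return prepare_oddball_triplet(std, odd, rove_db=rove_db, seed=int(rng.integers(2**31)))
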