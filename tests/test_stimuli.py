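"""Stimulus synthesis: frequency grid, figure-ground construction, ripple
and modulation spectra, oddball trial assembly."""

import numpy as np
import pytest
from scipy import signal as sps
from scipy.stats import kstest

import figground as fg
from figground.stimuli import _draw_figure_frequencies


# ---------------------------------------------------------------------------
# frequency grid
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "low, high, steps, expected_n, first, last",
    [
        (1000.0, 8000.0, 48, 145, 1000.0, 8000.0),
        (1000.0, 2000.0, 1, 2, 1000.0, 2000.0),
        (440.0, 440.0, 48, 1, 440.0, 440.0),
    ],
)
def test_grid_examples(low, high, steps, expected_n, first, last):
    grid = fg.make_frequency_grid(low, high, steps)
    assert grid.size == expected_n
    assert grid[0] == pytest.approx(first)
    assert grid[-1] == pytest.approx(last)


@pytest.mark.parametrize("low, octaves, steps", [(200.0, 2, 12), (1000.0, 3, 48), (55.0, 5, 7)])
def test_grid_matches_brute_force_multiplication(low, octaves, steps):
    high = low * 2.0**octaves
    grid = fg.make_frequency_grid(low, high, steps)
    # independent oracle: repeated multiplication until the top edge
    ratio = 2.0 ** (1.0 / steps)
    expected, f = [], low
    while f <= high * (1 + 1e-12):
        expected.append(f)
        f *= ratio
    assert grid.size == len(expected) == octaves * steps + 1
    np.testing.assert_allclose(grid, expected, rtol=1e-9)


def test_grid_invalid_arguments():
    with pytest.raises(ValueError):
        fg.make_frequency_grid(-1.0, 8000.0, 48)
    with pytest.raises(ValueError):
        fg.make_frequency_grid(2000.0, 1000.0, 48)
    with pytest.raises(ValueError):
        fg.make_frequency_grid(1000.0, 8000.0, 0)


def test_grid_truncates_non_integer_span():
    grid = fg.make_frequency_grid(1000.0, 2500.0, 1)
    np.testing.assert_allclose(grid, [1000.0, 2000.0])


# ---------------------------------------------------------------------------
# figure-ground stimuli
# ---------------------------------------------------------------------------

def test_figure_trial_components_persist_and_are_separated(sfg_spec):
    stim = fg.generate_sfg_stimulus(sfg_spec, is_figure=True, seed=7, render=False)
    assert stim.figure_frequencies.size == 6
    gaps = np.diff(np.log2(stim.figure_frequencies))
    assert np.all(gaps >= 0.5 - 1e-9)
    for seg in stim.segment_frequencies[40:]:
        assert set(stim.figure_frequencies) <= set(seg)


def test_ground_trial_has_no_persistent_component(sfg_spec):
    stim = fg.generate_sfg_stimulus(sfg_spec, is_figure=False, seed=7, render=False)
    assert stim.figure_frequencies.size == 0
    common = set(stim.segment_frequencies[40])
    for seg in stim.segment_frequencies[41:]:
        common &= set(seg)
    assert not common


def test_waveform_duration_and_segments(sfg_spec):
    stim = fg.generate_sfg_stimulus(sfg_spec, is_figure=True, seed=3)
    assert stim.waveform.n_samples == int(4.0 * sfg_spec.sample_rate)
    assert len(stim.segment_frequencies) == 80
    assert all(len(s) == 8 for s in stim.segment_frequencies)
    grid = set(sfg_spec.grid())
    assert all(set(seg) <= grid for seg in stim.segment_frequencies)


def test_stimulus_determinism_bit_identical(sfg_spec):
    a = fg.generate_sfg_stimulus(sfg_spec, True, seed=11)
    b = fg.generate_sfg_stimulus(sfg_spec, True, seed=11)
    assert np.array_equal(a.waveform.samples, b.waveform.samples)
    c = fg.generate_sfg_stimulus(sfg_spec, True, seed=12)
    assert not np.array_equal(a.waveform.samples, c.waveform.samples)


def test_separation_constraint_infeasibility_is_reported():
    spec = fg.SFGStimulusSpec(grid_low_hz=1000.0, grid_high_hz=2000.0,
                              n_figure_components=6)
    with pytest.raises(fg.InfeasibleConstraintError, match="octave"):
        fg.generate_sfg_stimulus(spec, is_figure=True, seed=0, render=False)


def test_figure_sampler_uniform_marginal_and_exact(sfg_spec):
    # every draw satisfies the constraint; extremes of the grid reachable
    grid = sfg_spec.grid()
    rng = np.random.default_rng(0)
    seen_lo = seen_hi = False
    for _ in range(300):
        f = _draw_figure_frequencies(sfg_spec, grid, rng)
        assert np.all(np.diff(np.log2(f)) >= 0.5 - 1e-9)
        seen_lo |= f[0] == grid[0]
        seen_hi |= f[-1] == grid[-1]
    assert seen_lo and seen_hi


@pytest.mark.parametrize("n_trials", [2, 120])
def test_session_composition(sfg_spec, n_trials):
    sess = fg.generate_sfg_session(sfg_spec, n_trials=n_trials, seed=9, render=False)
    labels = [s.is_figure for s in sess]
    assert sum(labels) == n_trials // 2
    # all stimuli unique
    keys = {tuple(map(tuple, s.segment_frequencies)) for s in sess}
    assert len(keys) == n_trials


def test_session_determinism(sfg_spec):
    a = fg.generate_sfg_session(sfg_spec, 10, seed=4, render=False)
    b = fg.generate_sfg_session(sfg_spec, 10, seed=4, render=False)
    assert [s.is_figure for s in a] == [s.is_figure for s in b]
    for x, y in zip(a, b):
        assert all(np.array_equal(u, v) for u, v in
                   zip(x.segment_frequencies, y.segment_frequencies))


def test_session_rejects_odd_trial_count(sfg_spec):
    with pytest.raises(ValueError):
        fg.generate_sfg_session(sfg_spec, n_trials=3, seed=0, render=False)


def test_peak_amplitude_identical_across_classes(rendered_session):
    peaks = {np.round(np.max(np.abs(s.waveform.samples)), 12) for s in rendered_session}
    assert len(peaks) == 1


def test_acoustic_energy_control_between_classes(rendered_session, sfg_spec):
    """Total acoustic energy in the 2-4 s window must not differ between
    ground-only and figure+ground stimuli (the stimulus-level analogue of
    the electrodogram current control)."""
    from scipy.stats import mannwhitneyu

    fs = sfg_spec.sample_rate
    energy = {True: [], False: []}
    for s in rendered_session:
        x = s.waveform.samples[2 * fs:4 * fs]
        energy[s.is_figure].append(np.sum(x * x))
    p = mannwhitneyu(energy[False], energy[True], alternative="two-sided").pvalue
    assert p > 0.05


# ---------------------------------------------------------------------------
# spectral ripple
# ---------------------------------------------------------------------------

def _octave_band_spectrum_db(w, n_bands=8, f_lo=300.0, f_hi=7000.0):
    f, pxx = sps.welch(w.samples, fs=w.sample_rate, nperseg=2048)
    edges = np.geomspace(f_lo, f_hi, int(np.log2(f_hi / f_lo) * n_bands) + 1)
    out = []
    for a, b in zip(edges[:-1], edges[1:]):
        m = (f >= a) & (f < b)
        out.append(10 * np.log10(np.mean(pxx[m])))
    return np.array(out)


def test_ripple_zero_depth_standard_equals_oddball_spectrally():
    # long rendition for a well-averaged spectral estimate; the envelope
    # rule does not depend on duration
    spec = fg.RippleSpec(depth_db=0.0, duration_ms=8000.0)
    std = fg.generate_ripple(spec, invert_phase=False, seed=21)
    odd = fg.generate_ripple(spec, invert_phase=True, seed=22)
    # compare spectral shapes; absolute level is set by RMS equalization
    # at trial assembly, not by the ripple envelope
    a = _octave_band_spectrum_db(std)
    b = _octave_band_spectrum_db(odd)
    d = (a - a.mean()) - (b - b.mean())
    assert np.sqrt(np.mean(d * d)) < 1.0


def test_ripple_phase_inversion_anticorrelates_envelopes():
    spec = fg.RippleSpec(depth_db=20.0, phase=0.7, duration_ms=4000.0)
    std = fg.generate_ripple(spec, invert_phase=False, seed=5)
    odd = fg.generate_ripple(spec, invert_phase=True, seed=6)
    a = _octave_band_spectrum_db(std)
    b = _octave_band_spectrum_db(odd)
    r = np.corrcoef(a - a.mean(), b - b.mean())[0, 1]
    assert r < -0.8


def test_ripple_duration_and_ramps():
    spec = fg.RippleSpec(depth_db=12.0)
    w = fg.generate_ripple(spec, seed=3)
    assert w.n_samples == int(0.5 * w.sample_rate)
    n_ramp = int(0.05 * w.sample_rate)
    # linear ramps: coarse windowed RMS rises/falls monotonically (coarse
    # windows so noise fluctuations cannot mask the 20%-per-step ramp gain)
    hop = n_ramp // 5
    rms_on = [np.sqrt(np.mean(w.samples[i:i + hop] ** 2))
              for i in range(0, n_ramp, hop)]
    rms_off = [np.sqrt(np.mean(w.samples[len(w.samples) - i - hop:len(w.samples) - i] ** 2))
               for i in range(0, n_ramp, hop)]
    assert np.all(np.diff(rms_on) > 0)
    assert np.all(np.diff(rms_off) > 0)  # traversed from the end inward


def test_ripple_rejects_negative_depth():
    with pytest.raises(ValueError):
        fg.RippleSpec(depth_db=-1.0)


# ---------------------------------------------------------------------------
# temporal modulation
# ---------------------------------------------------------------------------

def _slow_envelope(w):
    env = np.abs(sps.hilbert(w.samples))
    b, a = sps.butter(4, 60.0 / (w.sample_rate / 2))
    return sps.filtfilt(b, a, env)


def test_tm_unmodulated_has_no_20hz_envelope_component():
    w = fg.generate_tm(fg.TMSpec(depth_db=0.0), modulated=False, seed=8)
    fs = w.sample_rate
    env = _slow_envelope(w)[int(0.1 * fs):-int(0.1 * fs)]
    spectrum = np.abs(np.fft.rfft(env - env.mean()))
    freqs = np.fft.rfftfreq(env.size, 1 / fs)
    at20 = spectrum[np.argmin(np.abs(freqs - 20.0))]
    assert at20 < 0.01 * env.mean() * env.size / 2


def test_tm_full_depth_envelope_excursion():
    w = fg.generate_tm(fg.TMSpec(depth_db=0.0), modulated=True, seed=8)
    fs = w.sample_rate
    env = _slow_envelope(w)[int(0.1 * fs):-int(0.1 * fs)]
    assert env.min() < 0.05 * env.mean()
    assert env.max() == pytest.approx(2.0 * env.mean(), rel=0.05)


def test_tm_spectrum_has_the_five_carriers():
    spec = fg.TMSpec(depth_db=0.0)
    w = fg.generate_tm(spec, modulated=False, seed=2)
    mag = np.abs(np.fft.rfft(w.samples))
    freqs = np.fft.rfftfreq(w.n_samples, 1 / w.sample_rate)
    peaks, _ = sps.find_peaks(mag, height=0.1 * mag.max())
    peak_freqs = freqs[peaks]
    assert len(peak_freqs) == 5
    df = freqs[1] - freqs[0]
    for f in spec.carrier_freqs_hz:
        assert np.min(np.abs(peak_freqs - f)) <= df


def test_tm_overmodulation_raises():
    with pytest.raises(fg.ClippedModulationError):
        fg.generate_tm(fg.TMSpec(depth_db=1.0), modulated=True, seed=0)


# ---------------------------------------------------------------------------
# oddball triplet assembly
# ---------------------------------------------------------------------------

def _tiny_gen(seed):
    rng = np.random.default_rng(seed)
    return fg.Waveform(rng.standard_normal(256) * 0.1, 44100)


def test_triplet_rms_equalization_without_rove():
    waves, _ = fg.prepare_oddball_triplet(_tiny_gen, _tiny_gen, rove_db=None, seed=1)
    rms = [w.rms() for w in waves]
    assert max(rms) / min(rms) - 1 < 1e-6


def test_triplet_rejects_asymmetric_rove():
    with pytest.raises(ValueError):
        fg.prepare_oddball_triplet(_tiny_gen, _tiny_gen, rove_db=(-2.0, 3.0), seed=1)


def test_triplet_oddball_position_uniform_and_rove_distribution():
    n = 10_000
    positions = np.empty(n, dtype=int)
    roves = []
    for i in range(n):
        waves, odd = fg.prepare_oddball_triplet(
            _tiny_gen, _tiny_gen, rove_db=(-3.0, 3.0), seed=i
        )
        positions[i] = odd
        roves.extend(20 * np.log10(w.rms() / 0.05) for w in waves)
    counts = np.bincount(positions, minlength=3) / n
    assert np.all(np.abs(counts - 1 / 3) < 0.02)
    assert kstest(roves, "uniform", args=(-3.0, 6.0)).pvalue > 0.01
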