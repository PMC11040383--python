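"""Homodyne (lock-in) detection of a tone buried in noise.

A unit-amplitude 30 kHz oscillation with additive white noise of the same
magnitude is unrecoverable frame by frame; projecting the 1000-sample record
onto the single carrier-frequency Fourier bin recovers amplitude and phase to
a few percent and improves the SNR by more than an order of magnitude.
"""

import numpy as np

import strobomech as sm

config = sm.PulseTrainConfig(f0=30e3, alpha=10e3, n_pulses=1000)
t = sm.strobe_schedule(config).sample_times[:1000]
rng = np.random.default_rng(0)

amplitude, phase = 1.0, -0.6
signal = amplitude * np.cos(2 * np.pi * config.f0 * t + phase)
noisy = signal + 1.0 * rng.standard_normal(t.size)

coef = sm.homodyne_coefficient(noisy, t, config.f0)
print(f"true amplitude / phase      : {amplitude:.3f} / {phase:.3f} rad")
print(f"recovered amplitude / phase : {abs(coef):.3f} / {np.angle(coef):.3f} rad")

gain = sm.homodyne_snr_gain(t, config.f0, amplitude=1.0, noise_sigma=1.0,
                            n_reps=200, rng=rng)
print(f"SNR gain over raw readout   : {gain:.1f}x  (theory sqrt(N/2) ~ 22 for N = 1000)")
# This single-bin projection is what turns noisy per-frame DIC and bead
# displacements into clean complex phasor maps at the drive frequency.
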