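"""Acoustic drive pulses and the stroboscopic acquisition schedule.

Builds the standard drive: Gaussian-windowed 30 kHz bursts repeated at 1 kHz,
and the detuned frame rate that makes N = 1000 frames sweep exactly one full
oscillation period on the reconstructed time base.
"""

import numpy as np

import strobomech as sm

config = sm.PulseTrainConfig(f0=30e3, alpha=10e3, n_pulses=1000, f_repet=1000.0)
schedule = sm.strobe_schedule(config)

t = np.arange(0, 1.0 / config.f_repet, 1.0 / config.drive_sampling)
pulse = sm.synth_pulse(config, t)

print(f"carrier f0            : {config.f0 / 1e3:.0f} kHz")
print(f"envelope centre t0    : {config.t0 * 1e3:.2f} ms (middle of the period)")
print(f"pulse peak |f(t)|     : {np.abs(pulse).max():.3f} (envelope maximum is 1)")
print(f"strobe frame rate     : {schedule.f_strob:.6f} Hz (just below f_repet)")
print(f"effective sample step : {schedule.dt_effective * 1e6:.3f} us")
print(f"effective sample rate : {1e-6 / schedule.dt_effective:.1f} MHz "
      f"(>= {2 * config.f0 / 1e3:.0f} kHz needed for Nyquist)")
print(f"frames acquired       : {config.n_frames} ({config.n_pulses} oscillating "
      f"+ {config.n_frames - config.n_pulses} at rest for the reference image)")
# The detuned frame rate aliases the 30 kHz motion into a slow sweep: each of
# the N frames samples the oscillation 1 us later on the reconstructed time
# base, so one frame per pulse reconstructs the full waveform.
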