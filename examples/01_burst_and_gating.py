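"""Synthesize one AC burst and build an ECG-gated burst train.

The therapy waveform is a 100-us, 100-kHz bipolar square burst (ten
oscillations) delivered once per heartbeat, 50-75 ms after the R wave.
"""

import numpy as np

from pfasim import BurstSpec, synthesize_burst, duty_power_factor
from pfasim import detect_r_peaks, schedule_bursts
from pfasim.synthetic import gen_ecg

# the atrial setting: 900 V, 60 bursts
spec = BurstSpec(amplitude_volts=900.0, n_bursts=60)
t, v = synthesize_burst(spec, sample_rate_hz=10e6)
nz = v[v != 0]
cycles = (np.sum(np.sign(nz[1:]) != np.sign(nz[:-1])) + 1) / 2
print(f"burst: {v.size} samples, {cycles:.0f} bipolar cycles, extrema {v.min():.0f}/{v.max():.0f} V")
print(f"net charge (sum of samples): {np.sum(v):.1f}  -> charge balanced")
print(f"duty power factor: {duty_power_factor(spec):.2f}  (fraction of continuous-wave heating)")

# gate the train on a noisy synthetic ECG at the study's resting rhythm
t_ecg, ecg, truth = gen_ecg(bpm=75.0, duration_s=60.0, noise_sd=0.05, seed=1)
r_peaks = detect_r_peaks(ecg, threshold=0.5, sample_rate_hz=1000.0)
sched = schedule_bursts(r_peaks, delay_ms=60.0, n_bursts=spec.n_bursts)
print(f"detected {r_peaks.size} R peaks; scheduled {sched.burst_times_s.size} bursts")
print(f"mean inter-burst interval: {sched.mean_interburst_s*1000:.0f} ms (75 bpm -> 800 ms)")
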