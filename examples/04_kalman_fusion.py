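"""Fuse noisy displacement and acceleration into displacement + velocity.

The Kalman filter uses the per-sample COM acceleration as the control
input of a constant-velocity state model and the per-sample COM
displacement as the observation.  The payoff over simply differentiating
the noisy displacement is dramatic, and because the recursion is strictly
causal with no appreciable lag it is usable for real-time COM display.
"""

import numpy as np

import swaycom as sc

rng = np.random.default_rng(0)
fs = 100.0
t = np.arange(4000) / fs
w0 = 2 * np.pi * 0.5                       # 0.5 Hz sway
x = 0.02 * np.sin(w0 * t)                  # 20 mm amplitude
v = 0.02 * w0 * np.cos(w0 * t)
a = -0.02 * w0**2 * np.sin(w0 * t)

y = x + rng.normal(0, 1e-3, t.size)        # 1 mm displacement noise
u = a + rng.normal(0, 1e-2, t.size)        # 10 mm/s^2 acceleration noise

disp, vel = sc.kalman_fuse(y, u, sc.KalmanConfig(dt=1 / fs))

w = slice(200, None)
kf = np.sqrt(np.mean((vel[w] - v[w]) ** 2))
naive = np.sqrt(np.mean((sc.differentiate(y, fs)[w] - v[w]) ** 2))
print(f"velocity RMSE, differentiated noisy displacement: {naive * 1e3:7.2f} mm/s")
print(f"velocity RMSE, Kalman fusion:                     {kf * 1e3:7.2f} mm/s")
print(f"improvement factor: {naive / kf:.1f}x")
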