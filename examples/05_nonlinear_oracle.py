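"""Validate the small-angle inversion against exact nonlinear dynamics.

The estimators invert linearised equations of motion.  To know how much
that costs, this script generates plate and head signals from the exact
(trigonometric) Newton-Euler dynamics of the double pendulum -- derived
symbolically, an entirely separate code path -- and measures the COM
error of the linear inversion as the sway amplitude shrinks.  The error
collapses much faster than linearly: at ordinary postural amplitudes the
small-angle approximation is irrelevant next to sensor noise.
"""

import numpy as np

import swaycom as sc
from swaycom.nonlinear import inverse_dynamics_nonlinear
from swaycom.series import HeadAcceleration

subject = sc.SubjectDescriptor(mass=70.0, height=1.75)
params = sc.derive_segment_parameters(subject)
inertias = sc.composite_inertias(params)

for deg in (2.0, 1.0, 0.5):
    spec = sc.MotionSpec(motion="ankle_AP", amplitude=np.deg2rad(deg),
                         seed=5, background_rms=0.0)
    truth = sc.make_trajectories(spec)
    plate, imu, support = inverse_dynamics_nonlinear(truth, params, subject)
    head = HeadAcceleration(t=truth.t, acc_x=truth.head_acc,
                            acc_y=np.zeros_like(truth.t))
    est = sc.estimate_method2("ap", plate, head, support, params, inertias, subject)
    err = sc.rmse_windowed(est.disp, truth.com, 100.0)
    print(f"sway amplitude {deg:3.1f} deg: COM RMSE of the linear inversion "
          f"= {err * 1e6:8.3f} um")
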