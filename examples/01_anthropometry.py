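"""Scale the segment-parameter table to a subject.

Every pendulum model in the package is parameterised by regression on the
subject's mass M and height H: masses scale with M, lengths with H and
moments of inertia with M*H^2.  The printed mass coefficients close
exactly (lower + upper body mass equals the whole pendulum mass), which
the estimators rely on.
"""

import swaycom as sc

subject = sc.SubjectDescriptor(mass=83.0, height=1.80)
p = sc.derive_segment_parameters(subject)
c = sc.composite_inertias(p)

print(f"subject: M = {subject.mass} kg, H = {subject.height} m")
print(f"pendulum (body) mass m_b   = {p.m_b:.3f} kg")
print(f"body COM height l_b        = {p.l_b:.4f} m above the ankle")
print(f"lower/upper masses         = {p.m_1:.3f} + {p.m_2:.3f} "
      f"= {p.m_1 + p.m_2:.3f} kg (closure exact)")
print(f"sagittal composite inertias J_x1 = {c.J_x1:.3f}, J_x2 = {c.J_x2:.3f} kg.m")
print(f"frontal  composite inertias J_y1 = {c.J_y1:.3f}, J_y2 = {c.J_y2:.3f}, "
      f"J_yb = {c.J_yb:.3f} kg.m")
print(f"single-pendulum moment coefficient C_sag = {c.C_sag:.3f} kg.m")
# the frontal loop collapses exactly onto its constrained single pendulum:
lhs = c.J_y1 * p.l_l + c.J_y2 * (p.L_l + p.l_u)
print(f"constrained-frontal identity: J_y1*l_l + J_y2*(L_l+l_u) = {lhs:.6f} "
      f"vs J_yb*l_b = {c.J_yb * p.l_b:.6f}")
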