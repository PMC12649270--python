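"""Rigid registration of an implanted bead cloud (the marker-tracking core).

Builds a 7-bead cloud, moves it by a known rigid transform plus 0.05 mm of
measurement noise, and recovers the transform with the Kabsch fit.
"""

import numpy as np

from bvrkin import PointSet, RigidTransform, kabsch_fit

rng = np.random.default_rng(0)
labels = tuple(f"b{i}" for i in range(7))
beads = PointSet(labels, rng.uniform(-35, 35, (7, 3)), frame="CT")

truth = RigidTransform.from_rotvec([0.1, -0.3, 0.2], [12.0, -4.0, 30.0])
measured = truth.apply(beads.coordinates) + rng.normal(0, 0.05, (7, 3))

fit, rms = kabsch_fit(beads, PointSet(labels, measured, frame="lab"))
rot_err = np.degrees((fit.inverse() @ truth).rotation_angle())
trans_err = np.linalg.norm(fit.translation - truth.translation)

print(f"rms residual       : {rms:.4f} mm")
print(f"rotation error     : {rot_err:.4f} deg")
print(f"translation error  : {trans_err:.4f} mm")
print("The residual sits at the injected noise level and the recovered pose")
print("is within a few hundredths of a degree/millimetre of the truth —")
print("this is why implanted beads serve as the gold standard.")
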