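"""Room-scale accuracy contour with Fresnel symmetry, plus a distance fit.

Sensing accuracy measured on a grid covering one side of the Tx-Rx line is
interpolated and mirrored across the line-of-sight centerline (a single
link's Fresnel zones are symmetric about it).  An OLS fit quantifies how
accuracy decays with distance from the link.

The measured accuracies here are synthetic stand-ins generated from a
smooth distance model plus noise, not physical measurements.
"""

import numpy as np

from csimotion import MirrorAxis, build_accuracy_contour, fit_accuracy_vs_distance

rng = np.random.default_rng(0)
# synthetic measured points on the left half (x < 0) of a 4.2 x 7.9 m room
xs, ys = np.meshgrid(np.arange(-2.0, 0.0, 1.0), np.arange(-3.0, 3.5, 1.0))
pts = np.column_stack([xs.ravel(), ys.ravel()])
acc = 96.0 - 1.7 * np.abs(pts[:, 1]) - 0.8 * np.abs(pts[:, 0]) + rng.normal(0, 0.3, len(pts))

axis = MirrorAxis(point=(0.0, 0.0), direction=(0.0, 1.0))  # LoS centerline
val_pts = np.array([[1.5, 0.5], [1.5, -2.0]])              # right half
val_acc = 96.0 - 1.7 * np.abs(val_pts[:, 1]) - 0.8 * np.abs(val_pts[:, 0])
model = build_accuracy_contour(pts, acc, axis=axis,
                               validation_points=val_pts,
                               validation_accuracy=val_acc)

print("accuracy at (-1.5, 0.0):", f"{model.predict([[-1.5, 0.0]])[0]:.1f}%")
print("mirrored  at (+1.5, 0.0):", f"{model.predict([[1.5, 0.0]])[0]:.1f}%")
print("validation discrepancies:",
      ", ".join(f"{d:.2f}%" for d in model.validation_discrepancies))

fit = fit_accuracy_vs_distance(np.abs(pts[:, 1]), acc)
print(f"accuracy vs |d_y|: slope {fit.slope:.2f} %/m, "
      f"intercept {fit.intercept:.2f}%, R^2 = {fit.r_squared:.2f}")
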