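"""Checkerboard camera calibration on synthetic corner views.

Projects a 6x9 checkerboard through a known pinhole camera from 12 poses
and recovers the intrinsics with the planar-homography method, reporting
the RMS reprojection error.
"""

import numpy as np

from camgaze.geometry import (CameraIntrinsics, Checkerboard, calibrate_camera,
                              checkerboard_object_points, euler_to_matrix,
                              project_points)

true = CameraIntrinsics(600.0, 605.0, 320.0, 240.0, 640, 480)
board = Checkerboard(rows=6, cols=9, square_mm=25.0)
obj = checkerboard_object_points(board)

rng = np.random.default_rng(7)
views = []
for _ in range(12):
    R = euler_to_matrix(*rng.uniform(-25, 25, 3))
    t = np.array([rng.uniform(-40, 40), rng.uniform(-30, 30),
                  rng.uniform(380, 600)]) - R @ obj.mean(axis=0)
    views.append(project_points(obj @ R.T + t, true))

result = calibrate_camera(views, board, (640, 480))
intr = result.intrinsics
print(f"true focal:      fx = 600.000, fy = 605.000 px")
print(f"recovered focal: fx = {intr.focal_x:.3f}, fy = {intr.focal_y:.3f} px")
print(f"principal point: ({intr.principal_x:.3f}, {intr.principal_y:.3f}) px")
print(f"RMS reprojection error: {result.rms_px:.2e} px on "
      f"{len(views)} views x {board.n_corners} corners")
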