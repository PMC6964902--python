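"""Numerical tolerances and simulator defaults, collected in one place.

Translations and 3D points are in millimetres throughout the package;
image coordinates are in pixels (origin at the top-left corner, pixel
centres at integer coordinates, 0-based; the camera looks along +z).
"""

# --- rigid-transform algebra ---------------------------------------------
ORTHONORMALITY_TOL = 1e-9       # max deviation of R R^T from I, det from +1
COMPOSE_DRIFT_TOL = 1e-12       # re-orthonormalize a product only beyond this
ROTATION_ROUNDTRIP_TOL = 1e-10  # matrix <-> quaternion <-> axis-angle

# --- camera model ---------------------------------------------------------
UNDISTORT_TOL = 1e-12           # fixed-point convergence, normalized coords
UNDISTORT_MAX_ITER = 200

# --- calibration / pose estimation ---------------------------------------
MIN_CALIBRATION_VIEWS = 3
CALIB_DEGENERACY_RATIO = 1e-8   # singular-value ratio flagging fronto-parallel sets
P3P_COLLINEARITY_TOL = 1e-6     # min normalized triangle area
REFINE_FTOL = 1e-15
REFINE_MAX_ITER = 200

# --- tracking -------------------------------------------------------------
MIN_TRACKING_MARKERS = 3
COLLINEARITY_SV_RATIO = 1e-9    # point sets flatter than this are degenerate

# --- evaluation -----------------------------------------------------------
MATCH_MAX_DISTANCE_PX = 50.0
SPHERE_DIAMETER_MM = 2.0        # steel spheres of the accuracy grid
HEATMAP_BINS = 8

# --- simulated endoscope --------------------------------------------------
# Image size is the physical sensor of the rig (2590x1942 px at 15 fps);
# focal length and distortion are plausible defaults for a wide-angle
# endoscope with a 35 mm coupler, not measured values.
SENSOR_WIDTH = 2590
SENSOR_HEIGHT = 1942
DEFAULT_FX = 1300.0
DEFAULT_FY = 1300.0
DEFAULT_K1 = -0.20
DEFAULT_K2 = 0.05
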