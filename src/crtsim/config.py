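"""Default configuration: numerical constants, calibrated scales and
physiological parameter tables, plus YAML round-tripping.

``DIFFUSIVITY_SCALE`` converts the nominal tissue conductivities
(sigma_L = 0.5 S/m, sigma_T = 0.1 S/m) into the effective monodomain
diffusivity D = scale * sigma (mm^2/ms).  The surface-to-volume ratio
and membrane capacitance of the monodomain equation are folded into this
single knob, which is calibrated once so that a planar wavefront on the
0.4 mm calibration slab propagates at 0.61 m/s along fibers (and, via
the square-root law, 0.29 m/s across them).
"""

from __future__ import annotations

import copy

import yaml

# --- calibrated constants (see docs/methods.md) ---------------------------
# Frozen by the one-off slab calibration: with these values the
# 20 x 20 mm, 0.4 mm slab at dt = 0.02 ms propagates at 0.61 m/s along
# fibers and 0.29 m/s across them for sigma_L/sigma_T = 0.5/0.1 S/m.
DIFFUSIVITY_SCALE = 0.50304     # mm^2/ms per S/m (longitudinal)
# The coarse grid under-resolves the narrow transverse wavefront, which
# slows it more than the longitudinal one; this factor multiplies the
# transverse diffusivity to compensate at the working resolution.
TRANSVERSE_CORRECTION = 1.6415
# 1D Stewart cable diffusivity giving 2.5 m/s at dx = 0.4 mm
PURKINJE_CABLE_DIFFUSIVITY = 1.1423
# Heart-failure diffusivity multiplier exponent: hf_scale = (1-r)^gamma.
# gamma = 2 is the continuum square-root law; the calibrated value makes
# the measured 0.4 mm slab CV fall by exactly r (the slowed front is
# narrower and loses extra speed to the grid).
HF_SCALE_EXPONENT = 1.49066

SIGMA_L = 0.5                   # S/m, longitudinal tissue conductivity
SIGMA_T = 0.1                   # S/m, transverse tissue conductivity
PURKINJE_CV = 2.5               # m/s, conduction-system target velocity
HF_CV_REDUCTION = 0.5           # heart failure halves conduction velocity

# Organ conductivities of the reference heterogeneous torso (mS/cm).
# Retained as metadata only: the forward ECG here uses an unbounded
# homogeneous volume-conductor surrogate (see ecg module), but a future
# FEM backend can consume this table.
TORSO_CONDUCTIVITY_MS_PER_CM = {
    "myocardium": 4.589,
    "bones": 0.200,
    "liver": 0.277,
    "lungs": 0.389,
    "muscle": 2.390,
    "blood": 7.0,
}


def default_config() -> dict:
    """Full parameter tree with every default the pipeline consumes."""
    return copy.deepcopy({
        "geometry": {
            "lv_semi_axes": [30.0, 30.0, 45.0],
            "lv_wall": 9.0,
            "rv_wall": 4.0,
            "edge_mm": 0.8,
            "layer_fractions": [0.17, 0.41, 0.42],
            "endo_helix_deg": 60.0,
            "epi_helix_deg": -60.0,
        },
        "monodomain": {
            "sigma_l": SIGMA_L,
            "sigma_t": SIGMA_T,
            "diffusivity_scale": DIFFUSIVITY_SCALE,
            "transverse_correction": TRANSVERSE_CORRECTION,
            "dt_ms": 0.02,
            "sample_dt_ms": 1.0,
            "activation_threshold_mv": -10.0,
            "stimulus_amplitude": 400.0,   # uA/uF
            "stimulus_duration_ms": 2.0,
        },
        "purkinje": {
            "cv_m_per_s": PURKINJE_CV,
            "cable_diffusivity": PURKINJE_CABLE_DIFFUSIVITY,
            "pmj_delay_antero_ms": 5.0,
            "pmj_delay_retro_ms": 3.0,
            "pmj_density_per_mm2": 0.03,
            "seed": 20190211,
        },
        "protocols": {
            "atrial_conduction_ms": 100,
            "av_node_delay_ms": 80,
            "avd_ms": [100, 140],
            "vvd_ms": [0, 30],
            "hf_cv_reduction": HF_CV_REDUCTION,
        },
        "ecg": {
            "sample_rate_khz": 1.0,
            "gain": 1.0,
            "torso_conductivity_ms_per_cm": dict(TORSO_CONDUCTIVITY_MS_PER_CM),
        },
        "delineation": {
            "slope_threshold_frac": 0.05,
            "smooth_samples": 5,
            "area_fraction": 0.95,
        },
    })


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def load_config(path) -> dict:
    """Load a config file, filling unspecified sections with defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config()
    for section, values in user.items():
        if section in cfg and isinstance(values, dict):
            cfg[section].update(values)
        else:
            cfg[section] = values
    return cfg
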