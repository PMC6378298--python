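"""Shared fixtures.

Simulation-backed fixtures are session-scoped and sized for a desk run:
slab experiments use the 0.4 mm calibration geometry (thin, planar CV is
thickness-invariant); whole-heart runs use a 0.35-scaled biventricle at
0.8 mm / dt 0.04 ms, which preserves the physiological orderings the
tests check while keeping the suite fast.
"""

import numpy as np
import pytest

from crtsim import geometry as G
from crtsim.cells import IonicModelParams
from crtsim.monodomain import ConductivityField, apply_hf, slab_cv
from crtsim.pipeline import run_config
from crtsim.protocols import PacingConfig
from crtsim.purkinje import GrowthParams, grow_tree

SEED = 20190211

#: CRT sweep used for ordering/correlation checks (3 RV sites x mixed LV
#: segments/surfaces x all four delay settings)
SWEEP_CONFIGS = [
    ("RV_APEX", "LV_POSTERIOR_MID_ENDO", 140, 0),
    ("RV_APEX", "LV_POSTERIOR_MID_EPI", 100, 30),
    ("RV_APEX", "LV_ANTERIOR_BASAL_ENDO", 100, 0),
    ("RV_MID", "LV_LATERAL_MID_ENDO", 140, 0),
    ("RV_MID", "LV_POSTERIOR_MID_EPI", 140, 30),
    ("RV_MID", "LV_ANTERIOR_MID_EPI", 100, 0),
    ("RV_UPPER", "LV_POSTERIOR_MID_ENDO", 140, 30),
    ("RV_UPPER", "LV_LATERAL_MID_EPI", 140, 0),
    ("RV_UPPER", "LV_LATERAL_APICAL_ENDO", 100, 30),
    ("RV_UPPER", "LV_ANTERIOR_BASAL_EPI", 100, 0),
]


@pytest.fixture(scope="session")
def tiny_heart():
    """Small biventricle + Purkinje tree for simulation tests."""
    params = G.BiventricleParams().scaled(0.35, 0.8)
    mesh = G.build_biventricle(params)
    G.assign_fibers_streeter(mesh)
    G.assign_transmural_layers(mesh)
    G.segment_lv_free_wall(mesh)
    # denser junctions compensate the reduced endocardial area, keeping
    # the absolute PMJ count in the physiological study range
    tree = grow_tree(mesh, seed=SEED,
                     params=GrowthParams(pmj_density_per_mm2=0.12))
    return mesh, tree


@pytest.fixture(scope="session")
def default_mesh():
    """Full desk-scale biventricle (geometry only, no simulation)."""
    mesh = G.build_biventricle()
    G.assign_fibers_streeter(mesh)
    G.assign_transmural_layers(mesh)
    G.segment_lv_free_wall(mesh)
    return mesh


@pytest.fixture(scope="session")
def slab_cvs():
    """Measured conduction velocities on the 0.4 mm calibration slab:
    longitudinal, transverse, and longitudinal under HF scaling."""
    cv_l = slab_cv("L")
    cv_t = slab_cv("T")
    cv_hf = slab_cv("L", cond=apply_hf(ConductivityField(), 0.5))
    return {"L": cv_l, "T": cv_t, "HF_L": cv_hf}


@pytest.fixture(scope="session")
def pipeline_results(tiny_heart):
    """Healthy, HF+LBBB baseline and the ten-configuration CRT sweep."""
    mesh, tree = tiny_heart
    out = {}
    out["HEALTHY"] = run_config(mesh, tree, PacingConfig("HEALTHY"), dt=0.04)
    out["BASELINE"] = run_config(mesh, tree,
                                 PacingConfig("HF_LBBB_BASELINE"), dt=0.04)
    out["CRT"] = [
        run_config(mesh, tree, PacingConfig("CRT", rv, lv, avd, vvd),
                   dt=0.04)
        for rv, lv, avd, vvd in SWEEP_CONFIGS
    ]
    return out
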