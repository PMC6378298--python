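"""CRT pacing protocols: the AVD/VVD timing model with His-bundle
fusion, enumeration of the lead-placement grid, and per-scenario
stimulus schedules.

The atrioventricular delay (AVD) is measured from sinoatrial activation
to the ventricular lead stimulus.  Without atria in the model, intrinsic
conduction is represented by stimulating the His bundle at
atrial-conduction (100 ms) + AV-node delay (80 ms) = 180 ms on the
sinoatrial clock; pacing the leads at AVD therefore means the His
stimulus arrives 180 - AVD ms after the leads (80 ms at AVD = 100,
40 ms at AVD = 140).  The interventricular delay (VVD) delays the RV
lead relative to the LV lead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .geometry import (Mesh, RV_LEAD_LABELS, lv_lead_labels, place_lead)
from .monodomain import ConductivityField, StimulusSpec, apply_hf

ATRIAL_CONDUCTION_MS = 100
AV_NODE_DELAY_MS = 80

SCENARIOS = ("HEALTHY", "HF_LBBB_BASELINE", "CRT")
AVD_GRID = (100, 140)
VVD_GRID = (0, 30)


@dataclass(frozen=True)
class StimulusSchedule:
    """Stimulus instants on the sinoatrial clock (t = 0 at SA firing)."""

    lv_time: float
    rv_time: float
    his_time: float
    atrial_conduction: float = ATRIAL_CONDUCTION_MS
    av_node_delay: float = AV_NODE_DELAY_MS

    @property
    def his_offset(self) -> float:
        """His stimulus relative to (LV) lead activation; positive means
        the His fires after the leads."""
        return self.his_time - self.lv_time


def timing_model(AVD: float, VVD: float,
                 atrial_conduction: float = ATRIAL_CONDUCTION_MS,
                 av_node_delay: float = AV_NODE_DELAY_MS
                 ) -> StimulusSchedule:
    """Exact stimulus arithmetic for one delay setting (integer-safe)."""
    if AVD < 0 or VVD < 0:
        raise ValueError("AVD and VVD must be nonnegative")
    return StimulusSchedule(
        lv_time=AVD,
        rv_time=AVD + VVD,
        his_time=atrial_conduction + av_node_delay,
        atrial_conduction=atrial_conduction,
        av_node_delay=av_node_delay,
    )


@dataclass(frozen=True)
class PacingConfig:
    """One scenario: lead sites plus delay settings (CRT) or none."""

    scenario: str
    rv_site: Optional[str] = None
    lv_site: Optional[str] = None
    AVD: Optional[int] = None
    VVD: Optional[int] = None

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "CRT":
            if self.rv_site is None or self.lv_site is None \
                    or self.AVD is None or self.VVD is None:
                raise ValueError("CRT configs carry both leads and delays")
            if self.rv_site not in RV_LEAD_LABELS:
                raise ValueError(f"unknown RV site {self.rv_site!r}")
            if self.lv_site not in lv_lead_labels():
                raise ValueError(f"unknown LV site {self.lv_site!r}")
        elif any(v is not None
                 for v in (self.rv_site, self.lv_site, self.AVD, self.VVD)):
            raise ValueError(f"{self.scenario} configs carry no leads")

    @property
    def config_id(self) -> str:
        if self.scenario != "CRT":
            return self.scenario
        return f"{self.rv_site}|{self.lv_site}|AVD{self.AVD}|VVD{self.VVD}"


def enumerate_configs(mode: str = "LOCATIONS_ONLY",
                      fixed_avd: int = 140, fixed_vvd: int = 0
                      ) -> list[PacingConfig]:
    """The study grid: 54 lead-location configurations (3 RV x 18 LV),
    optionally crossed with the 2 x 2 delay grid (216 configs)."""
    if mode not in ("LOCATIONS_ONLY", "FULL_GRID"):
        raise ValueError("mode must be LOCATIONS_ONLY or FULL_GRID")
    delays = [(fixed_avd, fixed_vvd)] if mode == "LOCATIONS_ONLY" else \
        [(a, v) for a in AVD_GRID for v in VVD_GRID]
    out = []
    for rv in RV_LEAD_LABELS:
        for lv in lv_lead_labels():
            for avd, vvd in delays:
                out.append(PacingConfig("CRT", rv, lv, avd, vvd))
    return out


@dataclass
class ScenarioBuild:
    """Everything run_simulation needs for one configuration.

    Stimulus times are on the run clock, which starts at the earliest
    stimulus; add ``clock_shift`` to recover the sinoatrial clock.
    """

    tree: object
    cond: ConductivityField
    stimuli: list
    tree_sources: list
    clock_shift: float


def build_scenario(config: PacingConfig, mesh: Mesh, tree,
                   cond: Optional[ConductivityField] = None,
                   stim_amplitude: float = 400.0,
                   stim_duration: float = 2.0,
                   hf_cv_reduction: float = 0.5) -> ScenarioBuild:
    """Compose pathology and stimuli for one pacing configuration.

    HEALTHY: intact tree, baseline conductivity, His stimulus only.
    HF_LBBB_BASELINE: lesioned tree + HF conductivity, His stimulus only.
    CRT: lesioned tree + HF conductivity, LV/RV lead stimuli and the His
    fusion stimulus per the timing model.
    """
    from .purkinje import apply_lbbb

    cond = cond or ConductivityField()
    if config.scenario == "HEALTHY":
        return ScenarioBuild(tree=tree, cond=cond, stimuli=[],
                             tree_sources=[(tree.his_node, 0.0)],
                             clock_shift=ATRIAL_CONDUCTION_MS
                             + AV_NODE_DELAY_MS)
    lesioned = apply_lbbb(tree)
    hf_cond = apply_hf(cond, hf_cv_reduction)
    if config.scenario == "HF_LBBB_BASELINE":
        return ScenarioBuild(tree=lesioned, cond=hf_cond, stimuli=[],
                             tree_sources=[(lesioned.his_node, 0.0)],
                             clock_shift=ATRIAL_CONDUCTION_MS
                             + AV_NODE_DELAY_MS)

    sched = timing_model(config.AVD, config.VVD)
    shift = min(sched.lv_time, sched.rv_time, sched.his_time)
    lv = place_lead(mesh, config.lv_site)
    rv = place_lead(mesh, config.rv_site)

    from .monodomain import stimulus_cluster

    lv_nodes, lv_amp = stimulus_cluster(mesh, lv.node_set, stim_amplitude)
    rv_nodes, rv_amp = stimulus_cluster(mesh, rv.node_set, stim_amplitude)
    stimuli = [
        StimulusSpec(node_set=lv_nodes, amplitude=lv_amp,
                     start=sched.lv_time - shift, duration=stim_duration),
        StimulusSpec(node_set=rv_nodes, amplitude=rv_amp,
                     start=sched.rv_time - shift, duration=stim_duration),
    ]
    tree_sources = [(lesioned.his_node, sched.his_time - shift)]
    return ScenarioBuild(tree=lesioned, cond=hf_cond, stimuli=stimuli,
                         tree_sources=tree_sources, clock_shift=shift)
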