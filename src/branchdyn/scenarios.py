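"""Canonical synthetic study conditions for the branching pipeline.

These builders fix the simulated "ground truth" the pipeline is validated
against: a 7-stage branching trajectory (four pre-branch stages, one
branch-point stage, one stage per post-branch segment — mirroring a typical
early-embryo trajectory), per-gene two-state kinetics or Gamma-mixture laws
per stage, programmed burst-size ramps, branch-shifted marker genes and a
pseudotime-ramped regulator->target coupling.  Tests, examples and the
acceptance study all draw their inputs from here, so the conditions are
stated once.
"""

from __future__ import annotations

import numpy as np

from .simulate import (GammaMixtureSpec, SimulationConfig, StageSchedule,
                       StageSpec, TwoStateParams, couple_target_to_regulator,
                       simulate_branching_dataset)

__all__ = ["modality_config", "burst_trend_config", "marker_screen_config",
           "regulation_ramp_dataset", "BIMODAL_COMPONENTS", "TRIMODAL_COMPONENTS",
           "UNIMODAL_BURSTY"]

#: Well-separated mixture laws used for programmed modality (modes near 10/20/30).
BIMODAL_COMPONENTS = ((0.5, 100.0, 10.0, 0.0), (0.5, 900.0, 30.0, 0.0))
TRIMODAL_COMPONENTS = ((1 / 3, 100.0, 10.0, 0.0), (1 / 3, 400.0, 20.0, 0.0),
                       (1 / 3, 900.0, 30.0, 0.0))
#: A moderately bursty two-state gene (mean ~8.3, burst size 10).
UNIMODAL_BURSTY = TwoStateParams(k_on=1.0, k_off=5.0, k_syn=50.0)


def _seven_stages(genes_per_stage, cells_per_stage: int) -> StageSchedule:
    """4 pre + 1 branch_point + 1 branch1 + 1 branch2 stages."""
    branches = ["pre", "pre", "pre", "pre", "branch_point", "branch1", "branch2"]
    return StageSchedule([
        StageSpec(i + 1, b, cells_per_stage, genes_per_stage[i])
        for i, b in enumerate(branches)
    ])


def modality_config(cells_per_stage: int = 200, seed: int = 0) -> SimulationConfig:
    """A gene programmed bimodal pre-branch, unimodal at the branch point and
    trimodal on branch2 (bimodal on branch1), alongside a plain bursty gene."""
    bi = GammaMixtureSpec(BIMODAL_COMPONENTS)
    tri = GammaMixtureSpec(TRIMODAL_COMPONENTS)
    # the branch-point stage is specified as a single Gamma component (mean
    # ~16.7) so the programmed law is exactly unimodal in the fitted family
    uni = GammaMixtureSpec([(1.0, 30.0, 1.8, 0.0)])
    per_stage = []
    for branch in ["pre", "pre", "pre", "pre", "branch_point", "branch1", "branch2"]:
        law = {"pre": bi, "branch_point": uni, "branch1": bi, "branch2": tri}[branch]
        per_stage.append({"Gata3": law, "Ctrl": UNIMODAL_BURSTY})
    return SimulationConfig(_seven_stages(per_stage, cells_per_stage), seed=seed)


def burst_trend_config(cells_per_stage: int = 1200, seed: int = 0,
                       bs_pre=(12.0, 6.0), bs_branch1=(6.0, 14.0),
                       bs_branch2=(6.0, 3.0), n_stages_per_branch: int = 4,
                       k_on: float = 0.5, k_off: float = 10.0) -> SimulationConfig:
    """Burst-size schedules: decreasing pre-branch, increasing on branch1,
    decreasing on branch2 (the qualitative post-branch asymmetry of real
    lineages).  Burst size is ramped linearly via k_syn at fixed k_on, k_off.
    """
    def ramp(lo_hi, n):
        return np.linspace(lo_hi[0], lo_hi[1], n)

    stages = []
    sid = 0
    for branch, bs_range, n in (("pre", bs_pre, n_stages_per_branch),
                                ("branch_point", None, 1),
                                ("branch1", bs_branch1, n_stages_per_branch),
                                ("branch2", bs_branch2, n_stages_per_branch)):
        if bs_range is None:
            bs_values = [bs_pre[1]]
        else:
            bs_values = ramp(bs_range, n)
        for bs in bs_values:
            sid += 1
            genes = {"Gene": TwoStateParams(k_on=k_on, k_off=k_off, k_syn=bs * k_off)}
            # near-constitutive housekeeping genes keep per-cell totals
            # positive so size factors are estimable
            for h in range(2):
                genes[f"hk{h}"] = TwoStateParams(k_on=20.0, k_off=1.0, k_syn=50.0)
            stages.append(StageSpec(sid, branch, cells_per_stage, genes))
    return SimulationConfig(StageSchedule(stages), seed=seed)


def marker_screen_config(n_flat: int = 50, n_shifted: int = 5,
                         cells_per_stage: int = 60, seed: int = 0) -> SimulationConfig:
    """``n_shifted`` stage-switched genes among ``n_flat`` stage-independent ones.

    The programmed markers alternate between a low (mean ~8) and a high
    (mean 25) expression state across the pre-branch stages — which makes
    them genuinely highly variable — settle high on branch1 and low on
    branch2, so their distribution changes across the branch on both
    segments.  Flat genes keep one bursty law everywhere.
    """
    # background genes: moderately expressed, mildly bursty, stage-independent
    flat_law = TwoStateParams(k_on=3.0, k_off=3.0, k_syn=17.0)  # mean 8.5
    flat = {f"flat{i:02d}": flat_law for i in range(n_flat)}
    low = TwoStateParams(k_on=1.0, k_off=5.0, k_syn=50.0)     # mean ~8.3
    high = TwoStateParams(k_on=4.0, k_off=2.0, k_syn=37.5)    # mean 25
    stage_law = {0: low, 1: high, 2: low, 3: high,            # pre stages
                 4: low,                                      # branch point
                 5: high, 6: low}                             # branch1 / branch2
    per_stage = []
    for k in range(7):
        genes = dict(flat)
        for i in range(n_shifted):
            genes[f"shift{i:02d}"] = stage_law[k]
        per_stage.append(genes)
    return SimulationConfig(_seven_stages(per_stage, cells_per_stage), seed=seed)


def regulation_ramp_dataset(seed: int = 0, cells_per_stage: int = 200,
                            n_background: int = 8, max_strength: float = 0.8,
                            coupled: bool = True):
    """Dataset where the target tracks the regulator with a coupling that
    ramps linearly in pseudotime (zero at t=0).  With ``coupled=False`` the
    target stays independent — the null for importance calibration.
    Returns (matrix, annotation).
    """
    genes = {"Reg": TwoStateParams(k_on=2.0, k_off=2.0, k_syn=30.0),
             "Tgt": UNIMODAL_BURSTY}
    for i in range(n_background):
        genes[f"bg{i:02d}"] = UNIMODAL_BURSTY
    per_stage = [dict(genes) for _ in range(7)]
    config = SimulationConfig(_seven_stages(per_stage, cells_per_stage), seed=seed)
    matrix, annotation = simulate_branching_dataset(config)
    if coupled:
        matrix = couple_target_to_regulator(
            matrix, annotation, "Reg", "Tgt",
            strength=lambda t: max_strength * t, seed=seed + 1)
    return matrix, annotation
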