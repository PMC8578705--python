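"""Synthetic plate-reader ER Ca2+ traces from the forward model.

Generates everything the inverse pipeline consumes without any recorded
data: luminal fluorescence time series with the canonical
load-inhibit-stimulate shape (SERCA loading to a ~500 uM plateau, a slow
IP3-independent leak after SERCA inhibition, stimulus-evoked release driven
by the stochastic C4/O4/I4 gating model), sampled at the plate reader's
1.44 s interval with additive Gaussian noise, plus dose-response tables for
fit-recovery tests. Every generated artifact carries its ground truth
(true open-receptor and luminal Ca2+ time courses, all parameters, seed)
and regenerates bit-for-bit from the same seed.

Population wells are simulated with the exact-distribution multinomial
ensemble engine (2e10 receptors per well cannot be looped individually)
and the luminal equation is integrated on the per-cell average open count,
so fractional store depletion matches the single-cell equation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from quantalca.gating import AdditionProtocol, GatingRates, simulate_protocol
from quantalca.er import ERParams, integrate_er
from quantalca.analysis import FluorescenceTrace
from quantalca.occupancy import (
    HillFit, LigandParams, OccupancyModel, concentration_for_count,
    hill_response,
)

__all__ = [
    "NoiseModel", "ExperimentTemplate", "GroundTruth", "generate_trace",
    "paper_protocols", "generate_binding_dataset",
]

IP3_KD_NM = 794.0            # IP3 affinity under functional-assay conditions
RECEPTORS_PER_WELL = 2e10    # 4e5 HEK-IP3R1 cells/well
CELLS_PER_WELL = 4e5
RECEPTORS_HEK_IP3R1 = 49146  # per HEK-IP3R1 cell
RECEPTORS_WT_HEK = 9101      # per wild-type HEK cell
SAMPLE_INTERVAL_S = 1.44


@dataclass(frozen=True)
class NoiseModel:
    """Additive white measurement noise.

    additive_sd is expressed as a fraction of the clean trace's dynamic
    range (max - min), so the same setting means the same signal-to-noise
    across templates.
    """

    additive_sd: float = 0.01
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.additive_sd < 0:
            raise ValueError("additive_sd must be >= 0")


@dataclass(frozen=True)
class ExperimentTemplate:
    """A complete recipe for one synthetic recording.

    The timeline is: ATP at ``t_atp`` starts SERCA loading from
    ``load_start_content``; the SERCA inhibitor at ``t_cpa`` (if not
    None) freezes refill, leaving the bare leak; ``schedule`` lists
    (time_s, final_concentration_nM) ligand additions; ``antagonist_time``
    (if set) zeroes the release rate from that point on.
    """

    template_id: str
    receptors_total: float
    cells: float = 1.0
    K_D: float = IP3_KD_NM
    rates: GatingRates = field(default_factory=GatingRates)
    er: ERParams = field(default_factory=lambda: ERParams(
        C_ER_init=150.0, serca_active=True))
    schedule: Sequence[tuple[float, float]] = ()
    t_atp: float = 0.0
    t_cpa: float | None = 300.0
    antagonist_time: float | None = None
    sample_interval: float = SAMPLE_INTERVAL_S
    duration: float = 1100.0
    load_start_content: float = 150.0
    calibration: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        for t, _ in self.schedule:
            if not (0 <= t <= self.duration):
                raise ValueError("schedule times must lie within the record")
        if self.cells <= 0:
            raise ValueError("cells must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Everything needed to score a recovery against a generated trace."""

    times: np.ndarray            # trace sampling grid, s
    O4_per_cell: np.ndarray      # true mean open receptors per cell
    C_ER: np.ndarray             # true luminal free Ca2+, uM
    releasable: np.ndarray       # remaining releasable pool, uM
    injected_totals: tuple[int, ...]  # tetra-liganded totals per addition
    template: ExperimentTemplate
    noise: NoiseModel
    seed: int


def _build_er_params(template: ExperimentTemplate) -> ERParams:
    return replace(template.er, C_ER_init=template.load_start_content,
                   serca_active=True)


def generate_trace(template: ExperimentTemplate,
                   noise: NoiseModel | None = None,
                   seed: int = 0) -> tuple[FluorescenceTrace, GroundTruth]:
    """Run the forward model and emit a noisy fluorescence trace.

    The gating chain and the measurement noise draw from independent
    streams spawned from ``seed`` (``noise.seed`` overrides the noise
    stream), so the same seed regenerates the identical file.
    """
    noise = noise or NoiseModel()
    ss = np.random.SeedSequence(seed)
    gate_seed, noise_seed = [int(s.generate_state(1)[0] % (2**31))
                             for s in ss.spawn(2)]
    if noise.seed is not None:
        noise_seed = noise.seed

    protocol = AdditionProtocol(
        events=tuple(template.schedule), K_D=template.K_D,
        receptors_total=template.receptors_total, duration=template.duration,
    )
    gating = simulate_protocol(protocol, template.rates, seed=gate_seed)
    o4_per_cell = gating["O4"].to_numpy(dtype=float) / template.cells

    er_params = _build_er_params(template)
    traj = integrate_er(
        o4_per_cell, er_params, dt=template.rates.dt,
        serca_off_time=template.t_cpa,
        antagonist_time=template.antagonist_time,
    )

    grid = np.arange(0.0, template.duration + 1e-9, template.sample_interval)
    c_er = np.interp(grid, traj.times, traj.C_ER)
    releasable = np.interp(grid, traj.times, traj.releasable_remaining)
    o4_grid = np.interp(grid, traj.times, o4_per_cell)

    a, b = template.calibration
    clean = a * c_er + b
    rng = np.random.default_rng(noise_seed)
    dyn = clean.max() - clean.min()
    values = clean + rng.normal(0.0, noise.additive_sd * dyn, size=clean.shape)

    annotations: dict = {"ATP": template.t_atp}
    if template.t_cpa is not None:
        annotations["CPA"] = template.t_cpa
    if template.schedule:
        annotations["stimulus"] = [t for t, _ in template.schedule]
    if template.antagonist_time is not None:
        annotations["antagonist"] = template.antagonist_time

    trace = FluorescenceTrace(times=grid, values=values,
                              annotations=annotations,
                              calibration=template.calibration)
    truth = GroundTruth(
        times=grid, O4_per_cell=o4_grid, C_ER=c_er, releasable=releasable,
        injected_totals=tuple(protocol.target_counts()),
        template=template, noise=noise, seed=seed,
    )
    return trace, truth


def _single_cell_schedule(first_count: float, t0: float, spacing: float,
                          n_receptors: int = RECEPTORS_WT_HEK,
                          fold_changes: tuple[float, ...] = (4.41, 2.76),
                          kd: float = IP3_KD_NM) -> tuple[tuple[float, float], ...]:
    """Additions driving a single cell to first_count, then x4.41, x2.76."""
    model = OccupancyModel(LigandParams("IP3", kd), n_receptors)
    counts = [first_count]
    for f in fold_changes:
        counts.append(counts[-1] * f)
    return tuple((t0 + i * spacing, concentration_for_count(c, model))
                 for i, c in enumerate(counts))


def paper_protocols() -> dict[str, ExperimentTemplate]:
    """Ready-made templates with the study's printed parameters.

    - population_96well: 96-well population (2e10 receptors, 4e5 cells per
      well), SERCA inhibited, sequential 60/90/120 nM additions.
    - population_direct: as above with a single 120 nM addition at the time
      of the final sequential one.
    - single_cell: one wild-type HEK cell (9,101 receptors); first addition
      forms 5 tetra-liganded receptors (143 nM), then two further additions
      raise the count 4.41- and 2.76-fold.
    - incremental: population well stimulated around the Ca2+-release EC50
      (120/186/300 nM) — stronger evoked fluxes suited to the inverse
      reconstruction.
    - antagonist: SERCAs stay active; a maximal stimulus is followed by a
      competitive antagonist (release rate set to 0), letting the store
      refill toward its plateau.
    - leak_only: loading then SERCA inhibition, no stimulus.
    """
    pop = dict(receptors_total=RECEPTORS_PER_WELL, cells=CELLS_PER_WELL)
    templates = {
        "population_96well": ExperimentTemplate(
            template_id="population_96well", **pop,
            schedule=((800.0, 60.0), (900.0, 90.0), (1000.0, 120.0)),
        ),
        "population_direct": ExperimentTemplate(
            template_id="population_direct", **pop,
            schedule=((1000.0, 120.0),),
        ),
        "single_cell": ExperimentTemplate(
            template_id="single_cell", receptors_total=RECEPTORS_WT_HEK,
            cells=1.0,
            schedule=_single_cell_schedule(5.0, t0=800.0, spacing=100.0),
        ),
        "incremental": ExperimentTemplate(
            template_id="incremental", **pop,
            schedule=((800.0, 120.0), (900.0, 186.0), (1000.0, 300.0)),
        ),
        "antagonist": ExperimentTemplate(
            template_id="antagonist", **pop,
            t_cpa=None, duration=900.0,
            schedule=((400.0, 1000.0),),
            antagonist_time=600.0,
        ),
        "leak_only": ExperimentTemplate(
            template_id="leak_only", **pop, schedule=(),
        ),
    }
    return templates


def generate_binding_dataset(true_fit: HillFit, concentrations,
                             noise_sd: float = 0.0,
                             seed: int = 0) -> tuple[pd.DataFrame, HillFit]:
    """Dose-response table drawn from a Hill curve with Gaussian noise.

    Returns the table (columns ``concentration_nM``, ``response``) and the
    generating parameters for recovery scoring. ``noise_sd`` is in
    response units (absolute).
    """
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    resp = np.asarray(hill_response(conc, true_fit), dtype=float)
    if noise_sd > 0:
        resp = resp + rng.normal(0.0, noise_sd, size=resp.shape)
    df = pd.DataFrame({"concentration_nM": conc, "response": resp})
    return df, true_fit
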