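"""Deterministic ER luminal Ca2+ dynamics driven by open IP3 receptors.

Luminal free Ca2+ (C_ER, uM) declines through an IP3-independent leak and
through open IP3R channels, each flux proportional to the luminal-cytosolic
gradient (the cytosolic level C is clamped by the buffered medium):

    dC_ER/dt = -(k_leak + k_rel * O4) * (C_ER - C)            (SERCA off)
    dC_ER/dt = ... + (500 - C_ER) / tau_SERCA                 (SERCA on)

where O4 is the open-receptor count from the gating simulation, k_leak is
the leak rate constant and k_rel the per-open-channel release rate
constant. With SERCA pumps active the store refills toward its 500 uM
loading plateau with time constant tau_SERCA.

Only a fraction of the store (default 80%) is releasable through IP3Rs:
C_ER is partitioned at t = 0 into releasable and non-releasable pools; the
k_rel*O4 term draws exclusively on the releasable pool while the leak acts
on the total (apportioned between pools by their share of the content),
and SERCA refill enters the releasable pool. Reported C_ER is the sum.

Integration is explicit Euler locked to the gating-trace step (default
12.5 ms), which is deeply stable for the default rates; convergence is
checked by property test. The module also carries the cell-geometry
arithmetic: total ER Ca2+ content of a cell, the fraction a single open
channel releases, and a first-principles estimate of k_rel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

AVOGADRO = 6.02214076e23

SERCA_TARGET_UM = 500.0  # refill plateau of the loading phase, uM

__all__ = [
    "ERParams", "CellGeometry", "ERTrajectory", "integrate_er",
    "simulate_antagonist", "er_calcium_content", "single_channel_depletion",
    "estimate_k_rel", "leak_only_solution",
]


@dataclass(frozen=True)
class ERParams:
    """Parameters of the luminal Ca2+ balance.

    k_leak : IP3-independent leak rate constant, /s.
    k_rel : per-open-receptor release rate constant, /s.
    C_cyt : clamped cytosolic free Ca2+, uM.
    C_ER_init : initial luminal free Ca2+, uM.
    tau_SERCA : refill time constant toward the 500 uM plateau, s.
    releasable_fraction : share of the store accessible to IP3Rs.
    serca_active : whether the refill term is on.
    """

    k_leak: float = 1.8e-4
    k_rel: float = 0.0008
    C_cyt: float = 0.22
    C_ER_init: float = 500.0
    tau_SERCA: float = 100.0
    releasable_fraction: float = 0.8
    serca_active: bool = False

    def __post_init__(self) -> None:
        if self.k_leak < 0 or self.k_rel < 0:
            raise ValueError("rate constants must be >= 0")
        if self.tau_SERCA <= 0:
            raise ValueError("tau_SERCA must be positive")
        if not (0 < self.releasable_fraction <= 1):
            raise ValueError("releasable_fraction must lie in (0, 1]")
        if self.C_ER_init <= self.C_cyt:
            raise ValueError("C_ER_init must exceed C_cyt")


@dataclass(frozen=True)
class CellGeometry:
    """Cell/ER geometry and single-channel flux used for content arithmetic."""

    cell_volume: float = 1.1e-12       # L
    nuclear_fraction: float = 0.10
    er_fraction_of_cytoplasm: float = 0.35
    buffer_ratio: float = 5.0          # total/free luminal Ca2+
    free_luminal_Ca: float = 500.0     # uM
    channel_flux: float = 5e5          # Ca2+ ions/s per open channel

    def __post_init__(self) -> None:
        if self.cell_volume <= 0 or self.buffer_ratio <= 0:
            raise ValueError("cell_volume and buffer_ratio must be positive")
        for name in ("nuclear_fraction", "er_fraction_of_cytoplasm"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.free_luminal_Ca < 0 or self.channel_flux < 0:
            raise ValueError("free_luminal_Ca and channel_flux must be >= 0")

    @property
    def er_volume(self) -> float:
        """ER volume in litres: cell volume minus nucleus, times ER share."""
        return (self.cell_volume * (1.0 - self.nuclear_fraction)
                * self.er_fraction_of_cytoplasm)


@dataclass(frozen=True)
class ERTrajectory:
    """Time course of luminal Ca2+ and the remaining releasable pool."""

    times: np.ndarray            # s
    C_ER: np.ndarray             # uM (total free luminal Ca2+)
    releasable_remaining: np.ndarray  # uM
    annotations: dict | None = None

    def percent_of_initial(self) -> np.ndarray:
        return 100.0 * self.C_ER / self.C_ER[0]


def leak_only_solution(t, params: ERParams) -> np.ndarray:
    """Closed-form C_ER(t) for O4 = 0 and SERCA off: pure leak decay."""
    t = np.asarray(t, dtype=float)
    c = params.C_cyt
    return c + (params.C_ER_init - c) * np.exp(-params.k_leak * t)


def integrate_er(o4_trace, params: ERParams, dt: float,
                 t0: float = 0.0,
                 serca_off_time: float | None = None,
                 antagonist_time: float | None = None) -> ERTrajectory:
    """Integrate the luminal Ca2+ balance along an open-receptor trace.

    Parameters
    ----------
    o4_trace : sequence of float
        Open-receptor counts at times t0, t0+dt, ... (need not be
        integer: population runs may pass per-cell averages).
    params : ERParams
        Rates and pools; ``params.serca_active`` sets the refill term.
    dt : float
        Sampling step of the trace, s; also the Euler step.
    serca_off_time : float, optional
        Time at which SERCA pumps are inhibited (refill term switched
        off); only meaningful when ``params.serca_active``.
    antagonist_time : float, optional
        Time from which k_rel = 0 (competitive IP3R antagonist).

    Returns
    -------
    ERTrajectory with the same sampling as the input trace.
    """
    o4 = np.asarray(o4_trace, dtype=float)
    if o4.ndim != 1 or len(o4) < 2:
        raise ValueError("o4_trace must be a 1-D sequence of length >= 2")
    if np.any(o4 < 0):
        raise ValueError("open-receptor counts must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be positive")

    n = len(o4)
    times = t0 + dt * np.arange(n)
    rel = np.empty(n)
    nonrel = np.empty(n)
    rel[0] = params.releasable_fraction * params.C_ER_init
    nonrel[0] = (1.0 - params.releasable_fraction) * params.C_ER_init

    c = params.C_cyt
    for i in range(n - 1):
        total = rel[i] + nonrel[i]
        grad = total - c
        leak = params.k_leak * grad if grad > 0 else 0.0
        k_rel = params.k_rel
        if antagonist_time is not None and times[i] >= antagonist_time:
            k_rel = 0.0
        release = k_rel * o4[i] * grad if grad > 0 else 0.0
        serca_on = params.serca_active and (
            serca_off_time is None or times[i] < serca_off_time
        )
        refill = (SERCA_TARGET_UM - total) / params.tau_SERCA if serca_on else 0.0
        # leak apportioned by pool share; release and refill act on the
        # releasable pool only
        if total > 0:
            leak_rel = leak * rel[i] / total
        else:
            leak_rel = 0.0
        leak_non = leak - leak_rel
        # refill split by the releasable fraction so the pool ratio set at
        # t=0 is preserved through a SERCA loading phase
        f = params.releasable_fraction
        d_rel = (-leak_rel - release + f * refill) * dt
        d_non = (-leak_non + (1.0 - f) * refill) * dt
        rel[i + 1] = max(rel[i] + d_rel, 0.0)
        nonrel[i + 1] = max(nonrel[i] + d_non, 0.0)

    return ERTrajectory(times=times, C_ER=rel + nonrel,
                        releasable_remaining=rel)


def simulate_antagonist(o4_trace, params: ERParams, dt: float,
                        antagonist_time: float,
                        t0: float = 0.0,
                        serca_off_time: float | None = None) -> ERTrajectory:
    """Integrate with k_rel set to 0 from ``antagonist_time`` onwards.

    Emulates addition of a competitive IP3R antagonist (e.g. heparin)
    that abolishes release without touching the leak or SERCA refill.
    """
    n = len(np.asarray(o4_trace))
    if not (t0 <= antagonist_time <= t0 + dt * (n - 1)):
        raise ValueError("antagonist_time must lie within the trace span")
    return integrate_er(o4_trace, params, dt, t0=t0,
                        serca_off_time=serca_off_time,
                        antagonist_time=antagonist_time)


def er_calcium_content(geometry: CellGeometry) -> float:
    """Total ER Ca2+ content of one cell, in mol.

    free luminal Ca2+ x buffer ratio (total/free) x ER volume.
    """
    total_conc_m = geometry.free_luminal_Ca * 1e-6 * geometry.buffer_ratio
    return total_conc_m * geometry.er_volume


def single_channel_depletion(geometry: CellGeometry,
                             open_duration: float) -> float:
    """Fraction of ER Ca2+ content lost through one open channel.

    Assumes the channel conducts at its unitary flux for the whole
    duration (an upper bound: the real flux falls with the gradient).
    """
    if open_duration < 0:
        raise ValueError("open_duration must be >= 0")
    content = er_calcium_content(geometry)
    if content == 0:
        raise ValueError("ER content is zero; depletion fraction undefined")
    mol_released = geometry.channel_flux * open_duration / AVOGADRO
    return mol_released / content


def estimate_k_rel(geometry: CellGeometry) -> float:
    """First-principles per-open-channel release rate constant, /s.

    The unitary flux (ions/s) expressed as free-Ca2+ molarity change per
    second in the ER volume, divided by the buffer ratio (only 1/ratio of
    released Ca2+ comes off the free pool) and by the free luminal
    concentration:

        k_rel = (flux / N_A / buffer) / (free_Ca * V_ER)
    """
    free_m = geometry.free_luminal_Ca * 1e-6
    if free_m <= 0 or geometry.er_volume <= 0:
        raise ValueError("free_luminal_Ca and er_volume must be positive")
    molar_flux = geometry.channel_flux / AVOGADRO / geometry.buffer_ratio
    return molar_flux / (free_m * geometry.er_volume)
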