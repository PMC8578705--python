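"""Stochastic C4/O4/I4 gating of tetra-liganded IP3 receptors.

A receptor whose four subunits have all bound IP3 moves among three stable
states: closed (C4), open (O4) and inactivated (I4). The scheme is
triangular with one irreversible edge — direct C4 -> I4 transitions are
forbidden — so activation proceeds C4 -> O4 -> I4 with slow recovery
I4 -> C4 and 100-fold slower reverse steps O4 -> C4 and I4 -> O4:

    C4 --k1--> O4        O4 --k1/f--> C4
    O4 --k2--> I4        I4 --k2/f--> O4
    I4 --k3--> C4        C4 --x--> I4 forbidden

Defaults k1 = 0.4, k2 = 0.2, k3 = 0.004 /s with reverse factor f = 100
give mean residences of 2.5 s (closed), ~4.9 s (open) and ~4.9 min
(inactivated): a receptor opens quickly once tetra-liganded, inactivates
within seconds, and recovers only slowly.

Ligand binding equilibrates much faster than gating, so each IP3 addition
is modelled as an instantaneous injection of new tetra-liganded receptors
into C4 (the expected count from :mod:`quantalca.occupancy`). The chain is
advanced on a fixed step dt (default 12.5 ms); each receptor takes exit i
with probability k_i * dt per step. Receptors are exchangeable, so the
default engine advances per-state counts with binomial/multinomial draws —
distributionally identical to looping over receptors, which is retained as
a literal per-receptor mode for validation. A matrix-exponential
master-equation solver provides the deterministic mean-field counterpart.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm

from quantalca.occupancy import LigandParams, OccupancyModel, tetra_count

__all__ = [
    "GatingRates", "ReceptorEnsemble", "AdditionProtocol", "step",
    "inject_tetraliganded", "simulate_protocol", "meanfield_occupancies",
    "dwell_time_sample", "rate_matrix", "stationary_distribution",
]

STATES = ("C4", "O4", "I4")


@dataclass(frozen=True)
class GatingRates:
    """Rate constants of the three-state scheme.

    k1: C4->O4 (/s); k2: O4->I4 (/s); k3: I4->C4 recovery (/s).
    reverse_factor f sets the slow reverse steps k_-1 = k1/f (O4->C4)
    and k_-2 = k2/f (I4->O4); ``f = inf`` disables them. dt is the
    stochastic update step in seconds. The C4->I4 rate is identically
    zero (the scheme's irreversible step).
    """

    k1: float = 0.4
    k2: float = 0.2
    k3: float = 0.004
    reverse_factor: float = 100.0
    dt: float = 0.0125

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.reverse_factor <= 0:
            raise ValueError("reverse_factor must be positive (may be inf)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        rates = [self.k1, self.k2, self.k3, self.k_rev1, self.k_rev2]
        if max(rates) * self.dt >= 0.1:
            raise ValueError(
                "max(rate)*dt must stay below 0.1 for the fixed-step scheme"
            )

    @property
    def k_rev1(self) -> float:
        """O4 -> C4 rate, k1/reverse_factor."""
        return 0.0 if np.isinf(self.reverse_factor) else self.k1 / self.reverse_factor

    @property
    def k_rev2(self) -> float:
        """I4 -> O4 rate, k2/reverse_factor."""
        return 0.0 if np.isinf(self.reverse_factor) else self.k2 / self.reverse_factor


@dataclass(frozen=True)
class ReceptorEnsemble:
    """Integer counts of tetra-liganded receptors in each state."""

    C4: int = 0
    O4: int = 0
    I4: int = 0
    time: float = 0.0

    def __post_init__(self) -> None:
        for name in STATES:
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.C4 + self.O4 + self.I4

    def as_array(self) -> np.ndarray:
        return np.array([self.C4, self.O4, self.I4], dtype=np.int64)


@dataclass(frozen=True)
class AdditionProtocol:
    """A schedule of ligand additions for an ensemble of receptors.

    events: ordered (time_s, concentration_nM) pairs; concentrations are
    final (cumulative) levels and must be non-decreasing. K_D and
    receptors_total convert each concentration into the expected number
    of tetra-liganded receptors (rounded to the nearest integer).
    """

    events: Sequence[tuple[float, float]]
    K_D: float
    receptors_total: float
    duration: float

    def __post_init__(self) -> None:
        times = [t for t, _ in self.events]
        concs = [c for _, c in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        if any(c2 < c1 for c1, c2 in zip(concs, concs[1:])):
            raise ValueError("concentration decreases are unsupported")
        if any(c < 0 for c in concs):
            raise ValueError("concentrations must be >= 0")
        if times and (times[0] < 0 or times[-1] > self.duration):
            raise ValueError("event times must lie within [0, duration]")

    def target_counts(self) -> list[int]:
        """Expected tetra-liganded totals after each event, nearest-integer."""
        model = OccupancyModel(
            ligand=LigandParams(name="ligand", K_D=self.K_D),
            receptors_per_cell=int(round(self.receptors_total)),
        )
        return [max(0, int(round(tetra_count(c, model)))) for _, c in self.events]


def rate_matrix(rates: GatingRates) -> np.ndarray:
    """Generator matrix Q (columns: from-state; Q[i, j] = rate j -> i)."""
    k1, k2, k3 = rates.k1, rates.k2, rates.k3
    km1, km2 = rates.k_rev1, rates.k_rev2
    q = np.array([
        [-(k1), km1, k3],
        [k1, -(k2 + km1), km2],
        [0.0, k2, -(k3 + km2)],
    ])
    return q


def stationary_distribution(rates: GatingRates) -> np.ndarray:
    """Stationary state probabilities (null space of the generator)."""
    q = rate_matrix(rates)
    w, v = np.linalg.eig(q)
    idx = np.argmin(np.abs(w))
    pi = np.real(v[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def _exit_probs(rates: GatingRates) -> dict[str, list[tuple[str, float]]]:
    dt = rates.dt
    return {
        "C4": [("O4", rates.k1 * dt)],
        "O4": [("I4", rates.k2 * dt), ("C4", rates.k_rev1 * dt)],
        "I4": [("C4", rates.k3 * dt), ("O4", rates.k_rev2 * dt)],
    }


def step(ensemble: ReceptorEnsemble, rates: GatingRates,
         rng: np.random.Generator) -> ReceptorEnsemble:
    """Advance the ensemble one step of dt with multinomial count updates.

    Each receptor takes allowed exit i with probability k_i*dt, staying
    put otherwise; at most one transition per receptor per step. Counts
    are conserved.
    """
    counts = {s: getattr(ensemble, s) for s in STATES}
    delta = {s: 0 for s in STATES}
    for src, exits in _exit_probs(rates).items():
        n = counts[src]
        if n == 0:
            continue
        probs = [p for _, p in exits]
        stay = 1.0 - sum(probs)
        moved = rng.multinomial(n, probs + [stay])
        for (dst, _), m in zip(exits, moved[:-1]):
            delta[src] -= int(m)
            delta[dst] += int(m)
    return ReceptorEnsemble(
        C4=counts["C4"] + delta["C4"],
        O4=counts["O4"] + delta["O4"],
        I4=counts["I4"] + delta["I4"],
        time=ensemble.time + rates.dt,
    )


def step_per_receptor(ensemble: ReceptorEnsemble, rates: GatingRates,
                      rng: np.random.Generator) -> ReceptorEnsemble:
    """Literal per-receptor update: one uniform draw per receptor.

    The unit interval is partitioned into sub-intervals of length k_i*dt
    per allowed exit; a draw falling in interval i takes that exit.
    Distributionally identical to :func:`step`; kept for validation and
    only practical for small ensembles.
    """
    exit_probs = _exit_probs(rates)
    counts = {s: getattr(ensemble, s) for s in STATES}
    new_counts = {s: 0 for s in STATES}
    for src in STATES:
        exits = exit_probs[src]
        for _ in range(counts[src]):
            x = rng.uniform()
            lo = 0.0
            dest = src
            for dst, p in exits:
                if lo <= x < lo + p:
                    dest = dst
                    break
                lo += p
            new_counts[dest] += 1
    return ReceptorEnsemble(time=ensemble.time + rates.dt, **new_counts)


def inject_tetraliganded(ensemble: ReceptorEnsemble,
                         new_total: int) -> ReceptorEnsemble:
    """Raise the tetra-liganded total to ``new_total``, adding to C4 only.

    Models an instantaneous IP3 addition: binding equilibrates fast, so
    the increment appears in the closed state; O4 and I4 are untouched.
    """
    increment = int(new_total) - ensemble.total
    if increment < 0:
        raise ValueError(
            f"new_total {new_total} below current total {ensemble.total}; "
            "concentration decreases are unsupported"
        )
    return replace(ensemble, C4=ensemble.C4 + increment)


def simulate_protocol(protocol: AdditionProtocol, rates: GatingRates,
                      seed: int, record_every: int = 1,
                      per_receptor: bool = False) -> pd.DataFrame:
    """Simulate a ligand-addition protocol; return a state-count table.

    The ensemble starts empty; at each event time the tetra-liganded
    total jumps to the occupancy-model expectation for that
    concentration. Returns a DataFrame with columns ``time_s, C4, O4,
    I4`` sampled every ``record_every`` steps (row 0 is t = 0 after any
    t = 0 injection). Deterministic given (protocol, rates, seed).
    """
    if record_every < 1:
        raise ValueError("record_every must be >= 1")
    rng = np.random.default_rng(seed)
    stepper = step_per_receptor if per_receptor else step
    n_steps = int(round(protocol.duration / rates.dt))
    targets = protocol.target_counts()
    # event times snapped to the step grid
    event_steps = {int(round(t / rates.dt)): tgt
                   for (t, _), tgt in zip(protocol.events, targets)}
    if len(event_steps) < len(protocol.events):
        raise ValueError("events closer than one dt step overlap on the grid")

    ens = ReceptorEnsemble()
    rows = []
    for i in range(n_steps + 1):
        if i in event_steps:
            ens = inject_tetraliganded(ens, max(event_steps[i], ens.total))
        if i % record_every == 0:
            rows.append((i * rates.dt, ens.C4, ens.O4, ens.I4))
        if i < n_steps:
            ens = stepper(ens, rates, rng)
    return pd.DataFrame(rows, columns=["time_s", "C4", "O4", "I4"])


def meanfield_occupancies(initial, rates: GatingRates, t: float) -> np.ndarray:
    """Exact master-equation state probabilities at time ``t``.

    Solves dp/dt = Q p by matrix exponential for the (C4, O4, I4)
    probability vector. ``initial`` must be non-negative and sum to 1.
    """
    p0 = np.asarray(initial, dtype=float)
    if p0.shape != (3,):
        raise ValueError("initial must be a length-3 probability vector")
    if np.any(p0 < 0):
        raise ValueError("probabilities must be non-negative")
    if abs(p0.sum() - 1.0) > 1e-8:
        raise ValueError("probabilities must sum to 1")
    if t < 0:
        raise ValueError("t must be >= 0")
    p = expm(rate_matrix(rates) * t) @ p0
    p = np.clip(p, 0.0, 1.0)
    return p / p.sum()


def dwell_time_sample(state: str, rates: GatingRates, n: int,
                      seed: int) -> np.ndarray:
    """Sample ``n`` continuous-time residence times (s) in ``state``.

    Residence in a state is exponential with rate = sum of exit rates;
    a state with zero total exit rate has infinite dwell and returns an
    array of ``inf``.
    """
    if state not in STATES:
        raise ValueError(f"state must be one of {STATES}")
    if n < 1:
        raise ValueError("n must be >= 1")
    total_exit = {
        "C4": rates.k1,
        "O4": rates.k2 + rates.k_rev1,
        "I4": rates.k3 + rates.k_rev2,
    }[state]
    if total_exit == 0:
        return np.full(n, np.inf)
    rng = np.random.default_rng(seed)
    return rng.exponential(1.0 / total_exit, size=n)
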