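"""Equilibrium occupancy and pharmacology of the tetrameric IP3 receptor.

The IP3 receptor (IP3R) is a tetramer that opens only when all four subunits
have bound IP3. With four independent, identical sites (per-site Hill
coefficient 1), the fraction of sites occupied at ligand concentration L is
the Langmuir isotherm

    alpha = (L / K_D) / (1 + L / K_D)

and the fraction of receptors with all four sites occupied is alpha**4.
Because alpha**4 rises much more steeply than alpha at sub-K_D
concentrations, small increments in IP3 produce large fold-changes in the
number of tetra-liganded (open-eligible) receptors — the arithmetic that
underlies quantal, incremental Ca2+ release.

This module also provides the supporting pharmacology: Hill (4-parameter
logistic) dose-response fitting, the Cheng-Prusoff IC50 -> K_D correction
for competition binding, the Schild dose-ratio estimate of a competitive
antagonist's K_D, partial-agonist binding energetics (DDG = DG_IBC - DG_NT
with DG = -RT ln K_D), and the B_max-based receptors-per-cell calibration.

Concentrations are in nM throughout; p-values (pEC50, pK_D, ...) are
-log10 of the molar value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

GAS_CONSTANT = 8.31446261815324  # J/(mol K)

__all__ = [
    "LigandParams", "OccupancyModel", "HillFit", "EnergeticsResult",
    "fractional_occupancy", "tetra_fraction", "tetra_count",
    "tetra_fold_change", "concentration_for_count", "hill_response",
    "fit_hill", "kd_from_ic50", "kd_from_dose_ratio", "delta_delta_g",
    "receptors_per_cell_from_bmax", "HillFitError",
]


class HillFitError(RuntimeError):
    """Raised when a dose-response fit cannot be performed or fails."""


def _p_value(conc_nm: float) -> float:
    """-log10 of a concentration given in nM."""
    return -math.log10(conc_nm * 1e-9)


@dataclass(frozen=True)
class LigandParams:
    """Equilibrium binding parameters of a ligand.

    Parameters
    ----------
    name : str
        Label, e.g. ``"IP3"``.
    K_D : float
        Equilibrium dissociation constant in nM. Must be positive.
    assay_context : str, optional
        Free-text assay conditions (medium, temperature) under which the
        K_D was measured, e.g. ``"CLM 22C"``.
    """

    name: str
    K_D: float
    assay_context: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.K_D) and self.K_D > 0):
            raise ValueError(f"K_D must be finite and positive, got {self.K_D}")

    @property
    def pK_D(self) -> float:
        """-log10 of the molar K_D."""
        return _p_value(self.K_D)


@dataclass(frozen=True)
class OccupancyModel:
    """A ligand plus the number of receptors per cell (or per well)."""

    ligand: LigandParams
    receptors_per_cell: int

    def __post_init__(self) -> None:
        if self.receptors_per_cell < 0:
            raise ValueError("receptors_per_cell must be non-negative")


@dataclass(frozen=True)
class HillFit:
    """Parameters of a 4-parameter logistic (Hill) dose-response curve."""

    midpoint: float          # EC50 or IC50, nM
    hill_coefficient: float  # h
    top: float
    bottom: float
    rss: float = 0.0         # residual sum of squares of the fit

    def __post_init__(self) -> None:
        if not (np.isfinite(self.midpoint) and self.midpoint > 0):
            raise ValueError("midpoint must be finite and positive")
        if self.top < self.bottom:
            raise ValueError("top must be >= bottom")

    @property
    def p_midpoint(self) -> float:
        """pEC50/pIC50: -log10 of the molar midpoint."""
        return _p_value(self.midpoint)


@dataclass(frozen=True)
class EnergeticsResult:
    """Binding free energies of a ligand for two receptor constructs.

    ``delta_delta_G = delta_G_IBC - delta_G_NT`` reports the binding energy
    diverted into conformational change of the N-terminal construct.
    All energies in J/mol.
    """

    delta_G_IBC: float
    delta_G_NT: float
    temperature: float
    delta_delta_G: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "delta_delta_G", self.delta_G_IBC - self.delta_G_NT
        )


def fractional_occupancy(L, K_D: float):
    """Fraction of binding sites occupied at ligand concentration ``L``.

    alpha = (L/K_D) / (1 + L/K_D). Accepts scalar or array ``L`` (nM).
    """
    L = np.asarray(L, dtype=float)
    if not np.all(np.isfinite(L)) or np.any(L < 0):
        raise ValueError("ligand concentration must be finite and >= 0")
    if not (np.isfinite(K_D) and K_D > 0):
        raise ValueError("K_D must be finite and positive")
    alpha = L / (L + K_D)
    return float(alpha) if alpha.ndim == 0 else alpha


def tetra_fraction(alpha):
    """Fraction of tetramers with all four sites occupied: alpha**4."""
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha < 0) or np.any(alpha > 1):
        raise ValueError("alpha must lie in [0, 1]")
    out = alpha ** 4
    return float(out) if out.ndim == 0 else out


def tetra_count(L, model: OccupancyModel):
    """Expected number of tetra-liganded receptors per cell at ``L`` nM."""
    alpha = fractional_occupancy(L, model.ligand.K_D)
    return model.receptors_per_cell * tetra_fraction(alpha)


def tetra_fold_change(L1: float, L2: float, K_D: float) -> float:
    """Ratio alpha^4(L2) / alpha^4(L1) for a step from L1 to L2 nM."""
    if L1 <= 0 or L2 <= 0:
        raise ValueError("both concentrations must be positive")
    a1 = fractional_occupancy(L1, K_D)
    a2 = fractional_occupancy(L2, K_D)
    return (a2 / a1) ** 4


def concentration_for_count(target_count: float, model: OccupancyModel) -> float:
    """Ligand concentration (nM) giving an expected tetra-liganded count.

    Inverts N * alpha(L)**4 = target_count:
    alpha = (target/N)**(1/4), L = K_D * alpha / (1 - alpha).
    """
    n = model.receptors_per_cell
    if target_count <= 0:
        raise ValueError("target_count must be positive")
    if target_count >= n:
        raise ValueError(
            f"target_count {target_count} must be below receptors_per_cell {n}"
        )
    alpha = (target_count / n) ** 0.25
    return model.ligand.K_D * alpha / (1.0 - alpha)


def hill_response(L, fit: HillFit):
    """Evaluate a Hill curve: bottom + (top-bottom) L^h / (L^h + EC50^h)."""
    if fit.hill_coefficient == 0:
        raise ValueError("hill_coefficient must be nonzero")
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise ValueError("concentration must be >= 0")
    h, m = fit.hill_coefficient, fit.midpoint
    with np.errstate(divide="ignore"):
        # L=0 handled explicitly: response -> bottom for h > 0
        frac = np.where(L > 0, 1.0 / (1.0 + (m / np.where(L > 0, L, 1.0)) ** h), 0.0)
    out = fit.bottom + (fit.top - fit.bottom) * frac
    return float(out) if out.ndim == 0 else out


def fit_hill(concentrations, responses) -> HillFit:
    """Least-squares fit of a 4-parameter Hill curve to dose-response data.

    Initialization from the data: bottom = min response, top = max
    response, midpoint = concentration nearest the half-range response,
    h = 1. Degenerate (constant-response) data raise :class:`HillFitError`
    rather than returning a silent default.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("concentrations and responses must be 1-D, same length")
    if len(np.unique(x)) < 4:
        raise HillFitError("need >= 4 distinct concentrations")
    span = y.max() - y.min()
    if span <= 0 or not np.isfinite(span):
        raise HillFitError("responses are constant; Hill fit is degenerate")

    half = y.min() + span / 2.0
    pos = x > 0
    mid0 = x[pos][np.argmin(np.abs(y[pos] - half))] if pos.any() else 1.0
    p0 = [mid0, 1.0, y.max(), y.min()]

    def model(L, midpoint, h, top, bottom):
        with np.errstate(divide="ignore", over="ignore"):
            frac = np.where(
                L > 0, 1.0 / (1.0 + (midpoint / np.where(L > 0, L, 1.0)) ** h), 0.0
            )
        return bottom + (top - bottom) * frac

    try:
        popt, _ = curve_fit(
            model, x, y, p0=p0,
            bounds=([1e-12, 1e-6, -np.inf, -np.inf], [np.inf] * 4),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - optimizer failure path
        raise HillFitError(f"Hill fit did not converge: {exc}") from exc
    midpoint, h, top, bottom = popt
    if top < bottom:
        # re-express an inverted fit in canonical top >= bottom form
        raise HillFitError("fitted top below bottom; data not sigmoid in L")
    rss = float(np.sum((model(x, *popt) - y) ** 2))
    return HillFit(midpoint=float(midpoint), hill_coefficient=float(h),
                   top=float(top), bottom=float(bottom), rss=rss)


def kd_from_ic50(ic50: float, radioligand_conc: float,
                 radioligand_kd: float) -> float:
    """Cheng-Prusoff correction: K_D = IC50 / (1 + [L*]/K_D*).

    Converts the half-maximal inhibitory concentration from a competition
    binding assay into the competitor's equilibrium dissociation constant,
    given the radioligand concentration [L*] and its own K_D*. All in nM.
    """
    for name, v in (("ic50", ic50), ("radioligand_conc", radioligand_conc),
                    ("radioligand_kd", radioligand_kd)):
        if not (np.isfinite(v) and v > 0):
            raise ValueError(f"{name} must be finite and positive, got {v}")
    return ic50 / (1.0 + radioligand_conc / radioligand_kd)


def kd_from_dose_ratio(antagonist_conc: float, dose_ratio: float) -> float:
    """Schild relation for a competitive antagonist: K_D = [B]/(DR - 1)."""
    if antagonist_conc <= 0:
        raise ValueError("antagonist_conc must be positive")
    if dose_ratio <= 1:
        raise ValueError("dose_ratio must exceed 1 (no rightward shift)")
    return antagonist_conc / (dose_ratio - 1.0)


def delta_delta_g(kd_ibc: float, kd_nt: float,
                  temperature: float = 277.15) -> EnergeticsResult:
    """Binding-energy difference between two constructs.

    DG = -RT ln K_D (K_D in molar); DDG = DG_IBC - DG_NT. The default
    temperature corresponds to a 4 degC binding assay.
    """
    if kd_ibc <= 0 or kd_nt <= 0:
        raise ValueError("both K_D values must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    rt = GAS_CONSTANT * temperature
    dg_ibc = -rt * math.log(kd_ibc * 1e-9)
    dg_nt = -rt * math.log(kd_nt * 1e-9)
    return EnergeticsResult(delta_G_IBC=dg_ibc, delta_G_NT=dg_nt,
                            temperature=temperature)


def receptors_per_cell_from_bmax(bmax_per_volume: float,
                                 cells_per_volume: float,
                                 signal_ratio: float) -> float:
    """Receptors per cell from a B_max-calibrated immunoblot comparison.

    A lysate of known cell density is compared against a standard whose
    receptor density (B_max, receptors/uL) is known from saturation
    binding; ``signal_ratio`` is (lysate band intensity per uL) /
    (standard band intensity per uL), assumed linear in receptor number.
    """
    if bmax_per_volume <= 0 or cells_per_volume <= 0:
        raise ValueError("bmax_per_volume and cells_per_volume must be positive")
    if signal_ratio < 0:
        raise ValueError("signal_ratio must be >= 0")
    return signal_ratio * bmax_per_volume / cells_per_volume
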