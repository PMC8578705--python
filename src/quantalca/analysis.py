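"""Inverse analysis of ER luminal Ca2+ fluorescence traces.

Plate-reader recordings of a low-affinity luminal Ca2+ indicator are
approximately linear in ER free [Ca2+]. After SERCA inhibition the store
declines through an IP3-independent leak; a mono-exponential fitted to this
window defines the leak flux J_leak(t) (the negative derivative of the
fit), and the J_leak-vs-content relationship (second-degree polynomial by
default, exponential optionally) lets the leak be subtracted at matched
content throughout the record:

    evoked_flux(t) = -dF/dt - J_leak(content(t))

The evoked flux is integrated to reconstruct the luminal Ca2+ time course,
and dividing each instantaneous evoked rate by the luminal-cytosolic
gradient yields the time course of open receptors in arbitrary units
(proportional to the true open count by the unknown per-channel rate
constant k_rel):

    open_au(t) = evoked_flux(t) / (C_ER(t) - C_cyt)

Derivatives in the stimulus window use central finite differences after
optional Savitzky-Golay smoothing (default window 7 samples, polynomial
order 2); the leak window uses the analytic derivative of the fitted
exponential. Negative evoked-flux samples (noise) are kept in the flux
output but clipped at zero for the open-receptor estimate, and samples
where the gradient falls below a configurable floor (default 2% of the
initial content) are masked rather than divided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter

__all__ = [
    "FluorescenceTrace", "LeakModel", "ReconstructionResult", "LeakFitError",
    "fit_leak", "subtract_leak", "reconstruct_caer", "open_receptors",
    "estimate_k_leak", "analyze_trace",
]


class LeakFitError(RuntimeError):
    """Raised when the leak window cannot be fitted by a decaying exponential."""


@dataclass
class FluorescenceTrace:
    """A uniformly sampled luminal Ca2+ proxy time series for one well/cell.

    annotations maps event names (``"ATP"``, ``"CPA"``, ``"stimulus"``,
    ``"antagonist"``, ...) to times in s; ``"stimulus"`` may be a list of
    times for incremental additions. calibration, if given, is (a, b)
    mapping fluorescence to uM via C = (F - b)/a.
    """

    times: np.ndarray
    values: np.ndarray
    annotations: dict = field(default_factory=dict)
    calibration: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D and equal length")
        d = np.diff(self.times)
        if np.any(d <= 0):
            raise ValueError("times must be strictly increasing")
        if len(d) and (d.max() - d.min()) > 0.01 * d.mean():
            raise ValueError("sampling must be uniform within 1%")
        for name, t in self.annotations.items():
            for ti in np.atleast_1d(t):
                if not (self.times[0] <= ti <= self.times[-1]):
                    raise ValueError(f"annotation {name!r} at t={ti} outside record")

    @property
    def dt(self) -> float:
        return float(np.mean(np.diff(self.times)))

    def content(self) -> np.ndarray:
        """Values mapped to uM if calibrated, else raw fluorescence units."""
        if self.calibration is None:
            return self.values
        a, b = self.calibration
        return (self.values - b) / a

    def stimulus_times(self) -> list[float]:
        t = self.annotations.get("stimulus", [])
        return [float(x) for x in np.atleast_1d(t)]


@dataclass(frozen=True)
class LeakModel:
    """Fitted leak: mono-exponential decay plus J_leak-vs-content relation.

    The decay model is content(t) = offset + amplitude * exp(-rate *
    (t - t_start)). jleak_coeffs parameterize J_leak(content): polynomial
    coefficients (highest power first) for family ``"poly2"``, or
    (A, k) with J = A*exp(k*content) for family ``"exp"``.
    """

    amplitude: float
    rate: float
    offset: float
    t_start: float
    jleak_coeffs: tuple
    family: Literal["poly2", "exp"] = "poly2"
    content_range: tuple[float, float] = (0.0, np.inf)

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("leak rate must be positive (decaying window)")

    def decay(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.offset + self.amplitude * np.exp(-self.rate * (t - self.t_start))

    def j_leak_at_time(self, t) -> np.ndarray:
        """Leak flux -d(decay)/dt at time t: amplitude*rate*exp(...)."""
        t = np.asarray(t, dtype=float)
        return self.amplitude * self.rate * np.exp(-self.rate * (t - self.t_start))

    def j_leak(self, content) -> np.ndarray:
        """Leak flux at matched content, from the fitted relation."""
        content = np.asarray(content, dtype=float)
        lo, hi = self.content_range
        if np.any(content < lo - 0.1 * (hi - lo)) or \
           np.any(content > hi + 0.1 * (hi - lo)):
            warnings.warn("J_leak evaluated well outside its fitted content "
                          "range; extrapolation", stacklevel=2)
        if self.family == "poly2":
            out = np.polyval(self.jleak_coeffs, content)
        else:
            a, k = self.jleak_coeffs
            out = a * np.exp(k * content)
        return np.clip(out, 0.0, None)


def fit_leak(trace: FluorescenceTrace, window: tuple[float, float] | None = None,
             offset: float | None = None,
             family: Literal["poly2", "exp"] = "poly2") -> LeakModel:
    """Fit the IP3-independent leak on the post-SERCA-inhibition window.

    ``window`` defaults to (CPA annotation, first stimulus annotation or
    end of record). ``offset`` fixes the decay asymptote (e.g. to the
    clamped cytosolic level, known in permeabilized-cell experiments);
    when None all three exponential parameters are fitted, which is exact
    on clean data but poorly conditioned when the window covers only a
    small part of the decay.
    """
    if window is None:
        t_cpa = trace.annotations.get("CPA", trace.times[0])
        stims = trace.stimulus_times()
        t_end = min(stims) if stims else trace.times[-1]
        window = (float(t_cpa), float(t_end))
    lo, hi = window
    mask = (trace.times >= lo) & (trace.times < hi)
    if mask.sum() < 10:
        raise LeakFitError("leak window must contain at least 10 samples")
    t = trace.times[mask]
    y = trace.content()[mask]
    t0 = t[0]

    span = y.max() - y.min()
    if span <= 0:
        raise LeakFitError("constant trace in leak window; zero leak rate")
    # crude rate initialization from the end-to-end log ratio
    y_ref = offset if offset is not None else y.min() - span
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = (y[-1] - y_ref) / (y[0] - y_ref)
    k0 = -np.log(ratio) / (t[-1] - t0) if 0 < ratio < 1 else 1e-4

    try:
        if offset is None:
            popt, _ = curve_fit(
                lambda tt, a, k, c: c + a * np.exp(-k * (tt - t0)),
                t, y, p0=[y[0] - y_ref, max(k0, 1e-8), y_ref], maxfev=20000,
            )
            amplitude, rate, off = popt
        else:
            popt, _ = curve_fit(
                lambda tt, a, k: offset + a * np.exp(-k * (tt - t0)),
                t, y, p0=[y[0] - offset, max(k0, 1e-8)], maxfev=20000,
            )
            amplitude, rate = popt
            off = offset
    except RuntimeError as exc:
        raise LeakFitError(f"leak fit did not converge: {exc}") from exc
    if rate <= 0 or amplitude <= 0:
        raise LeakFitError("leak window does not decay (rate <= 0)")

    # pair the leak flux with time-matched content and fit the relation
    content_fit = off + amplitude * np.exp(-rate * (t - t0))
    jleak = amplitude * rate * np.exp(-rate * (t - t0))
    if family == "poly2":
        coeffs = tuple(np.polyfit(content_fit, jleak, 2))
    elif family == "exp":
        # initialize from the log-linear regression of J on content
        k0, ln_a0 = np.polyfit(content_fit, np.log(jleak), 1)
        popt, _ = curve_fit(
            lambda cc, a, k: a * np.exp(k * cc),
            content_fit, jleak, p0=[np.exp(ln_a0), k0], maxfev=20000,
        )
        coeffs = tuple(popt)
    else:
        raise ValueError(f"unknown family {family!r}")
    return LeakModel(
        amplitude=float(amplitude), rate=float(rate), offset=float(off),
        t_start=float(t0), jleak_coeffs=coeffs, family=family,
        content_range=(float(content_fit.min()), float(content_fit.max())),
    )


def _derivative(times: np.ndarray, values: np.ndarray,
                smooth_window: int = 7, smooth_order: int = 2) -> np.ndarray:
    """Central-difference derivative after optional Savitzky-Golay smoothing."""
    if smooth_window and smooth_window >= 3 and len(values) >= smooth_window:
        values = savgol_filter(values, smooth_window, smooth_order)
    return np.gradient(values, times)


def subtract_leak(trace: FluorescenceTrace, leak: LeakModel,
                  smooth_window: int = 7, smooth_order: int = 2) -> np.ndarray:
    """Stimulus-evoked Ca2+ flux: total efflux minus the content-matched leak.

    Returns evoked_flux(t) = -dF/dt - J_leak(content(t)) over the whole
    record, in content-units per second. On a leak-only trace the result
    is ~0 everywhere (self-subtraction).
    """
    content = trace.content()
    dfdt = _derivative(trace.times, content, smooth_window, smooth_order)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        jleak = leak.j_leak(content)
    return -dfdt - jleak


def reconstruct_caer(evoked_flux, times, initial_content: float) -> np.ndarray:
    """Reconstruct luminal Ca2+ by integrating the evoked flux.

    content(t) = initial - cumulative trapezoid of evoked_flux. Flags
    (warns) if the reconstruction crosses zero.
    """
    times = np.asarray(times, dtype=float)
    flux = np.asarray(evoked_flux, dtype=float)
    dt = np.diff(times)
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (flux[1:] + flux[:-1]) * dt)])
    content = initial_content - cum
    if np.any(content < 0):
        warnings.warn("reconstructed content fell below zero", stacklevel=2)
    return content


def open_receptors(evoked_flux, reconstructed_c_er, c_cyt: float,
                   gradient_floor_fraction: float = 0.02,
                   clip: bool = True) -> np.ndarray:
    """Open-receptor time course in arbitrary units.

    open_au = max(evoked_flux, 0) / (C_ER - C_cyt); proportional to the
    true open count by the unknown k_rel. Samples whose gradient is below
    ``gradient_floor_fraction`` of the initial gradient are returned as
    NaN (masked) instead of being divided. ``clip=False`` keeps
    noise-induced negative samples, giving a signed, mean-unbiased
    estimate (useful for null checks on unstimulated traces).
    """
    flux = np.asarray(evoked_flux, dtype=float)
    if clip:
        flux = np.clip(flux, 0.0, None)
    c_er = np.asarray(reconstructed_c_er, dtype=float)
    grad = c_er - c_cyt
    floor = gradient_floor_fraction * (c_er[0] - c_cyt)
    out = np.full_like(flux, np.nan)
    ok = grad > floor
    out[ok] = flux[ok] / grad[ok]
    return out


def estimate_k_leak(leak: LeakModel, reference_content: float,
                    c_cyt: float = 0.0) -> float:
    """Leak rate constant from the J_leak-vs-content relation.

    k_leak = J_leak(reference) / (reference - C_cyt), evaluated at a
    reference content (e.g. the 500 uM loading plateau, in the trace's
    content units). Warns if the reference lies far outside the fitted
    content range.
    """
    if reference_content <= c_cyt:
        raise ValueError("reference_content must exceed C_cyt (zero gradient)")
    lo, hi = leak.content_range
    if not (0.5 * lo <= reference_content <= 2.0 * max(hi, lo)):
        warnings.warn("reference content far outside fitted range", stacklevel=2)
    j = float(leak.j_leak(reference_content))
    return j / (reference_content - c_cyt)


@dataclass(frozen=True)
class ReconstructionResult:
    """Full inverse-analysis output for one trace."""

    times: np.ndarray
    evoked_flux: np.ndarray
    reconstructed_C_ER: np.ndarray
    open_receptors_au: np.ndarray
    leak: LeakModel
    k_leak_estimate: float


def analyze_trace(trace: FluorescenceTrace,
                  offset: float | None = None,
                  family: Literal["poly2", "exp"] = "poly2",
                  reference_content: float | None = None,
                  c_cyt: float = 0.0,
                  smooth_window: int = 7,
                  smooth_order: int = 2) -> ReconstructionResult:
    """Run the full inverse pipeline on one trace.

    Fits the leak on the CPA-to-stimulus window, subtracts it, restricts
    the reconstruction to the post-first-stimulus segment (starting from
    the content at the first stimulus), and divides by the gradient to
    obtain open receptors in arbitrary units. ``reference_content``
    defaults to the content at the start of the leak window.
    """
    leak = fit_leak(trace, offset=offset, family=family)
    stims = trace.stimulus_times()
    t_from = min(stims) if stims else leak.t_start
    mask = trace.times >= t_from

    evoked = subtract_leak(trace, leak, smooth_window, smooth_order)[mask]
    times = trace.times[mask]
    initial = float(trace.content()[mask][0])
    c_er = reconstruct_caer(evoked, times, initial)
    open_au = open_receptors(evoked, c_er, c_cyt)
    if reference_content is None:
        reference_content = leak.decay(leak.t_start)
    k_leak = estimate_k_leak(leak, float(reference_content), c_cyt)
    return ReconstructionResult(
        times=times, evoked_flux=evoked, reconstructed_C_ER=c_er,
        open_receptors_au=open_au, leak=leak, k_leak_estimate=k_leak,
    )
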