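"""Supporting statistical models: stage-transition survival curves,
constrained dose-response fits, FCS-based molecular densities, and
z-stack surface-area estimation.

Survival analysis (Kaplan-Meier with exponential-Greenwood confidence
intervals, log-rank comparison) is delegated to ``lifelines``; dose-response
and FCS autocorrelation fits use non-linear least squares.  The FCS density
chain converts a fitted autocorrelation amplitude G(0) and transit time
tau_D into molecules per square micrometre via N = 1/G(0) and the
observation-spot diameter d = sqrt(8 ln2 * D * tau_D), with D the literature
diffusion coefficient of the calibration dye.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import ndimage, optimize


# ---------------------------------------------------------------- survival


@dataclass
class KMEstimate:
    times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    at_risk: np.ndarray
    observed: np.ndarray

    def cdf(self) -> np.ndarray:
        """Cumulative fraction transitioned (1 - S), the quantity plotted
        for stage transitions."""
        return 1.0 - self.survival


def km_estimate(durations, observed=None, alpha: float = 0.05) -> KMEstimate:
    """Product-limit survival estimate with exponential Greenwood
    (log(-log)) confidence intervals."""
    durations = np.asarray(durations, float)
    if durations.size == 0:
        raise ValueError("need at least one duration")
    if np.any(durations < 0):
        raise ValueError("durations must be non-negative")
    observed = (np.ones_like(durations, bool) if observed is None
                else np.asarray(observed, bool))
    if not observed.any() and np.all(durations == 0):
        raise ValueError("all subjects censored at time 0")
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(durations, event_observed=observed)
    t = kmf.survival_function_.index.to_numpy()
    s = kmf.survival_function_.iloc[:, 0].to_numpy()
    ci = kmf.confidence_interval_
    ev = kmf.event_table
    return KMEstimate(
        times=t,
        survival=s,
        ci_lower=ci.iloc[:, 0].to_numpy(),
        ci_upper=ci.iloc[:, 1].to_numpy(),
        at_risk=ev["at_risk"].to_numpy(),
        observed=ev["observed"].to_numpy(),
    )


@dataclass
class LogRankResult:
    statistic: float
    p_value: float


def logrank_test(durations_a, durations_b, observed_a=None, observed_b=None) -> LogRankResult:
    """Two-sample log-rank test (chi-square, 1 df)."""
    a = np.asarray(durations_a, float)
    b = np.asarray(durations_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    observed_a = np.ones_like(a, bool) if observed_a is None else np.asarray(observed_a, bool)
    observed_b = np.ones_like(b, bool) if observed_b is None else np.asarray(observed_b, bool)
    if not observed_a.any() and not observed_b.any():
        raise ValueError("no events in either group")
    res = _ll_logrank(a, b, event_observed_A=observed_a, event_observed_B=observed_b)
    return LogRankResult(float(res.test_statistic), float(res.p_value))


# ------------------------------------------------------------ dose-response


@dataclass
class DoseResponseFit:
    bottom: float
    top: float
    ec50: float
    hill: float
    constrained: dict = field(default_factory=dict)
    residuals: np.ndarray = None

    def predict(self, dose):
        return _four_pl(np.asarray(dose, float), self.bottom, self.top, self.ec50, self.hill)


def _four_pl(dose, bottom, top, ec50, hill):
    dose = np.asarray(dose, float)
    out = np.full(dose.shape, bottom, float)
    pos = dose > 0
    out[pos] = bottom + (top - bottom) / (1 + (ec50 / dose[pos]) ** hill)
    return out


def fit_dose_response(
    doses,
    responses,
    bottom: float | None = None,
    top: float | None = None,
    hill: float | None = None,
) -> DoseResponseFit:
    """Four-parameter logistic fit on log-dose.

    Constrained parameters (typically the bottom, pinned to the response to
    non-cognate pMHC) are honoured exactly.  Zero-dose points are handled by
    the constrained bottom.  EC50 is reported in dose units.
    """
    doses = np.asarray(doses, float)
    responses = np.asarray(responses, float)
    if np.ptp(responses) == 0:
        raise ValueError("flat responses: dose-response fit is unidentifiable")
    free = [name for name, v in (("bottom", bottom), ("top", top), ("hill", hill)) if v is None]
    n_params = 1 + len(free)
    if len(np.unique(doses)) < n_params:
        raise ValueError(f"need at least {n_params} dose levels for {n_params} free parameters")

    pos = doses > 0
    log_ec50_0 = np.log10(np.median(doses[pos])) if pos.any() else 0.0

    def unpack(theta):
        vals = {"bottom": bottom, "top": top, "hill": hill}
        i = 1
        for name in free:
            vals[name] = theta[i]
            i += 1
        return 10.0 ** theta[0], vals["bottom"], vals["top"], vals["hill"]

    def resid(theta):
        ec50, b, t, h = unpack(theta)
        return _four_pl(doses, b, t, ec50, h) - responses

    p0 = [log_ec50_0]
    defaults = {"bottom": float(responses.min()), "top": float(responses.max()), "hill": 1.0}
    p0 += [defaults[name] for name in free]
    sol = optimize.least_squares(resid, p0, method="lm", max_nfev=20000)
    if not sol.success:
        raise RuntimeError(f"dose-response fit failed: {sol.message}")
    ec50, b, t, h = unpack(sol.x)
    constrained = {k: v for k, v in (("bottom", bottom), ("top", top), ("hill", hill))
                   if v is not None}
    return DoseResponseFit(b, t, ec50, h, constrained, sol.fun)


# ---------------------------------------------------------------------- FCS


@dataclass
class FCSFit:
    g0: float
    tau_d_s: float
    triplet_fraction: float
    triplet_tau_s: float
    offset: float
    n_particles: float
    spot_diameter_um: float
    spot_area_um2: float
    density_per_um2: float


def fcs_autocorrelation(
    lags_s: np.ndarray,
    g0: float,
    tau_d_s: float,
    offset: float = 0.0,
    triplet_fraction: float = 0.0,
    triplet_tau_s: float = 1e-5,
    model: str = "2d",
) -> np.ndarray:
    """Model autocorrelation G(tau) = G0 * GD(tau) * GT(tau) + Off.

    GD is the 2-D free-diffusion term 1/(1 + tau/tauD) (appropriate for a
    supported bilayer); the 3-D term adds an axial factor for solution
    calibration.  GT is the optional triplet-blinking term.
    """
    tau = np.asarray(lags_s, float)
    gd = 1.0 / (1.0 + tau / tau_d_s)
    if model == "3d":
        gd = gd / np.sqrt(1.0 + tau / (25.0 * tau_d_s))
    gt = np.ones_like(tau)
    if triplet_fraction > 0:
        gt = 1.0 + triplet_fraction / (1.0 - triplet_fraction) * np.exp(-tau / triplet_tau_s)
    return g0 * gd * gt + offset


def fcs_density(
    lags_s,
    g,
    diffusion_um2_s: float,
    fit_triplet: bool = False,
    model: str = "2d",
) -> FCSFit:
    """Fit an autocorrelation curve and convert to molecular surface density.

    ``diffusion_um2_s`` is the literature diffusion coefficient of the
    calibration dye; the observation-spot diameter follows from
    D = d^2 / (8 ln2 tauD), the particle number from N = 1/G0, and the
    density from N / (pi (d/2)^2).
    """
    lags = np.asarray(lags_s, float)
    g = np.asarray(g, float)
    if lags.size < 4:
        raise ValueError("autocorrelation curve too short to fit")

    g0_guess = max(g.max() - g.min(), 1e-6)
    tau_guess = lags[np.argmin(np.abs(g - (g.min() + g0_guess / 2)))]
    tau_guess = max(tau_guess, lags[lags > 0].min())

    if fit_triplet:
        def modelf(tau, g0, tau_d, off, tf, tt):
            return fcs_autocorrelation(tau, g0, tau_d, off, tf, tt, model)
        p0 = [g0_guess, tau_guess, g.min(), 0.1, tau_guess / 100]
        bounds = ([0, 0, -np.inf, 0, 0], [np.inf, np.inf, np.inf, 0.99, np.inf])
    else:
        def modelf(tau, g0, tau_d, off):
            return fcs_autocorrelation(tau, g0, tau_d, off, model=model)
        p0 = [g0_guess, tau_guess, g.min()]
        bounds = ([0, 0, -np.inf], [np.inf, np.inf, np.inf])
    popt, _ = optimize.curve_fit(modelf, lags, g, p0=p0, bounds=bounds, maxfev=20000)
    g0, tau_d = float(popt[0]), float(popt[1])
    off = float(popt[2])
    tf, tt = (float(popt[3]), float(popt[4])) if fit_triplet else (0.0, 0.0)
    if g0 <= 0 or tau_d <= 0:
        raise RuntimeError("FCS fit converged to a non-physical amplitude or transit time")

    n = 1.0 / g0
    d_um = float(np.sqrt(8.0 * np.log(2.0) * diffusion_um2_s * tau_d))
    area = np.pi * (d_um / 2) ** 2
    return FCSFit(g0, tau_d, tf, tt, off, n, d_um, area, n / area)


# ------------------------------------------------------------ standard curve


@dataclass
class StandardCurve:
    slope: float  # molecules/um^2 per concentration unit
    composition: str = ""

    def extrapolate(self, concentration: float) -> float:
        return self.slope * concentration


def standard_curve(densities, concentrations, composition: str = "") -> StandardCurve:
    """Least-squares line through the origin relating measured density to
    incubation concentration; used to extrapolate densities below the pFCS
    detection floor (~1 molecule/um^2)."""
    y = np.asarray(densities, float)
    x = np.asarray(concentrations, float)
    if np.all(x == 0):
        raise ValueError("all concentrations are zero")
    slope = float(np.dot(x, y) / np.dot(x, x))
    if slope <= 0:
        raise ValueError("non-positive calibration slope")
    return StandardCurve(slope, composition)


# ------------------------------------------------------------- surface area


def surface_area_from_zstack(
    zstack: np.ndarray,
    pixel_size_um: float,
    slice_depth_um: float = 0.2,
    threshold: float | None = None,
) -> float:
    """Cell surface area from a membrane-stained confocal z-stack.

    Each slice is thresholded (Otsu by default), the perimeter of the outer
    membrane contour measured (Crofton estimator, which corrects the
    staircase bias of pixel counting), multiplied by the slice depth and
    summed over the stack.  Empty slices contribute nothing.
    """
    from skimage.filters import threshold_otsu
    from skimage.measure import perimeter_crofton

    stack = np.asarray(zstack, float)
    if stack.ndim == 2:
        stack = stack[None]
    total = 0.0
    any_contour = False
    for sl in stack:
        thr = threshold_otsu(sl) if threshold is None else threshold
        mask = sl > thr
        if not mask.any():
            continue
        # keep the outer contour only: fill holes, largest component
        mask = ndimage.binary_fill_holes(mask)
        lab, n = ndimage.label(mask)
        if n > 1:
            sizes = np.bincount(lab.ravel())
            sizes[0] = 0
            mask = lab == sizes.argmax()
        any_contour = True
        total += perimeter_crofton(mask, directions=4) * pixel_size_um * slice_depth_um
    if not any_contour:
        raise ValueError("no membrane contour found in any slice")
    return float(total)
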