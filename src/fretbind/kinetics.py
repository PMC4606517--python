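"""Kinetic estimators for single-molecule binding data.

Two observables drive the analysis:

* **Association** — the time from sample injection (flow start) to each
  molecule's first binding event.  The accumulated fraction of targets that
  have bound by time t is fit with the single-exponential growth curve
  ``A (1 - exp(-k t))``; the apparent per-concentration association rate is
  kon_obs = k / [protein].

* **Dissociation** — the dwell time of each binding event.  The dwell-time
  distribution is fit with a single- or double-exponential decay.  For a
  double-exponential fit with per-bin density amplitudes A1, A2 and time
  constants tau1, tau2, the share of *events* in component i is
  ``p_i = A_i tau_i / (A1 tau1 + A2 tau2)`` and the average dwell time is the
  event-weighted mean ``p1 tau1 + p2 tau2``.

Two fitting routes are provided.  Histogram least squares (``method="ls"``)
mirrors the classic procedure: bin the dwells, normalize by the total event
count, drop the first bin (events at the camera's time resolution limit are
unreliable), and fit the decay to the remaining bin heights.  Truncated
maximum likelihood (``method="mle"``, the default) is bin-free: it maximizes
the exponential-mixture likelihood left-truncated at the same cutoff, which
is the principled analogue of dropping the first bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .traces import BindingEventSet

__all__ = [
    "ArrivalCurve",
    "ArrivalRateFit",
    "DwellHistogram",
    "ExponentialMixtureFit",
    "ModelSelection",
    "accumulate_first_bindings",
    "fit_arrival_curve",
    "build_dwell_histogram",
    "fit_dwell_distribution",
    "population_fractions",
    "average_dwell_time",
    "select_model",
]

# Collapse a 2-component fit to 1 component when the time constants are
# this close (ratio); such fits are not identifiable.
_TAU_COLLAPSE_RATIO = 1.05


@dataclass
class ArrivalCurve:
    """Cumulative fraction of targets bound by time t, on the frame grid."""

    time: np.ndarray
    cumulative_fraction: np.ndarray
    n_targets: int
    n_arrivals: int


@dataclass
class ArrivalRateFit:
    """Result of fitting A(1 - exp(-k t)) to an accumulated-arrival curve."""

    amplitude: float
    k: float                    # s^-1
    kon_obs: float              # s^-1 nM^-1
    concentration: float        # nM
    amplitude_se: float
    k_se: float
    kon_obs_se: float
    r_squared: float
    n_molecules: int
    success: bool = True
    message: str = ""


@dataclass
class DwellHistogram:
    """Event-normalized dwell-time histogram with uniform bins from zero."""

    bin_edges: np.ndarray       # length n_bins + 1, starting at 0
    normalized_counts: np.ndarray
    excluded_first_bin: bool
    n_events: int

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def fit_mask(self) -> np.ndarray:
        """Bins that enter the fit (first bin dropped when excluded)."""
        mask = np.ones(self.normalized_counts.size, dtype=bool)
        if self.excluded_first_bin:
            mask[0] = False
        return mask

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left_s": self.bin_edges[:-1],
                "bin_right_s": self.bin_edges[1:],
                "normalized_count": self.normalized_counts,
                "excluded_flag": ~self.fit_mask,
            }
        )


@dataclass
class ExponentialMixtureFit:
    """One- or two-component exponential fit of a dwell-time distribution.

    ``taus`` ascend; ``fractions`` are event-count shares summing to 1;
    ``average_dwell`` is the event-weighted mean dwell.  ``amplitudes`` are
    per-bin density scales in LS mode and untruncated component weights in
    MLE mode.  ``standard_errors`` maps parameter names to asymptotic SEs.
    """

    order: int
    amplitudes: tuple[float, ...]
    taus: tuple[float, ...]
    fractions: tuple[float, ...]
    average_dwell: float
    method: str                       # "ls" or "mle"
    n_events: int
    r_squared: Optional[float] = None
    log_likelihood: Optional[float] = None
    truncation_s: float = 0.0
    standard_errors: dict[str, float] = field(default_factory=dict)
    success: bool = True
    message: str = ""

    @property
    def bic(self) -> Optional[float]:
        if self.log_likelihood is None:
            return None
        n_par = 1 if self.order == 1 else 3
        return n_par * np.log(self.n_events) - 2.0 * self.log_likelihood

    @property
    def rss(self) -> Optional[float]:
        return self._rss

    _rss: Optional[float] = None
    _n_fit_points: Optional[int] = None


@dataclass
class ModelSelection:
    """Comparison of nested 1- vs 2-component dwell fits."""

    chosen_order: int
    rule: str                       # "f-test", "bic", or "collapse"
    statistic: Optional[float]
    p_value: Optional[float]
    r_squared_1: Optional[float]
    r_squared_2: Optional[float]
    bic_1: Optional[float] = None
    bic_2: Optional[float] = None


# ---------------------------------------------------------------------------
# association


def accumulate_first_bindings(
    first_arrivals: Sequence[float] | np.ndarray,
    n_targets: int,
    frame_interval: float = 0.1,
    duration: Optional[float] = None,
) -> ArrivalCurve:
    """Accumulated first-binding curve, normalized by the number of targets.

    The curve is the step function count(arrival <= t) / n_targets evaluated
    on the frame grid, so it saturates below 1 when some targets never bind
    within the observation window.
    """
    arrivals = np.sort(np.asarray(first_arrivals, dtype=float))
    if arrivals.size and arrivals[0] < 0:
        raise ValueError("first arrivals must be non-negative")
    if n_targets < arrivals.size:
        raise ValueError("n_targets must be >= the number of arrivals")
    if arrivals.size == 0:
        warnings.warn("no arrivals: accumulated curve is identically zero")
        t_end = duration if duration is not None else 10 * frame_interval
    else:
        t_end = duration if duration is not None else float(arrivals[-1])
    n_frames = int(np.ceil(t_end / frame_interval)) + 1
    time = np.arange(n_frames) * frame_interval
    counts = np.searchsorted(arrivals, time, side="right")
    return ArrivalCurve(
        time=time,
        cumulative_fraction=counts / n_targets,
        n_targets=int(n_targets),
        n_arrivals=int(arrivals.size),
    )


def fit_arrival_curve(curve: ArrivalCurve, concentration: float) -> ArrivalRateFit:
    """Least-squares fit of A(1 - exp(-k t)); kon_obs = k / concentration."""
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    t = curve.time
    y = curve.cumulative_fraction
    if np.any(np.diff(y) < 0):
        raise ValueError("accumulated curve must be nondecreasing")
    if not np.any(y > 0):
        return ArrivalRateFit(
            amplitude=np.nan, k=0.0, kon_obs=0.0, concentration=concentration,
            amplitude_se=np.nan, k_se=np.nan, kon_obs_se=np.nan,
            r_squared=np.nan, n_molecules=curve.n_targets,
            success=False, message="degenerate curve: no arrivals",
        )

    a0 = float(y[-1])
    half = a0 / 2.0
    i_half = int(np.searchsorted(y, half))
    t_half = float(t[min(i_half, t.size - 1)]) or float(t[-1]) / 2.0
    k0 = np.log(2.0) / max(t_half, t[1] if t.size > 1 else 1.0)

    def model(tt, a, k):
        return a * (1.0 - np.exp(-k * tt))

    popt, pcov = optimize.curve_fit(
        model, t, y, p0=[a0, k0],
        bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=20000,
    )
    a_hat, k_hat = popt
    perr = np.sqrt(np.diag(pcov))
    resid = y - model(t, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return ArrivalRateFit(
        amplitude=float(a_hat),
        k=float(k_hat),
        kon_obs=float(k_hat / concentration),
        concentration=float(concentration),
        amplitude_se=float(perr[0]),
        k_se=float(perr[1]),
        kon_obs_se=float(perr[1] / concentration),
        r_squared=r2,
        n_molecules=curve.n_targets,
    )


# ---------------------------------------------------------------------------
# dissociation: histogram


def build_dwell_histogram(
    data: BindingEventSet | Sequence[float] | np.ndarray,
    bin_width: float = 0.5,
    exclude_first_bin: bool = True,
) -> DwellHistogram:
    """Histogram dwell times into uniform bins from zero, normalized by the
    total event count.

    The first bin holds events at the camera's time-resolution limit; it is
    flagged for exclusion from fitting by default.  Right-censored events are
    excluded from the histogram (their dwells are lower bounds, not dwells).
    """
    if isinstance(data, BindingEventSet):
        if bin_width < data.frame_interval:
            raise ValueError("bin_width must be >= frame_interval")
        dwells = data.dwells()
        if data.n_events and dwells.size == 0:
            raise ValueError("all events are censored; no dwells to histogram")
    else:
        dwells = np.asarray(data, dtype=float)
    if dwells.size == 0:
        raise ValueError("need at least one uncensored dwell")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(np.ceil(dwells.max() / bin_width))
    n_bins = max(n_bins, 1)
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(dwells, bins=edges)
    return DwellHistogram(
        bin_edges=edges,
        normalized_counts=counts / dwells.size,
        excluded_first_bin=exclude_first_bin,
        n_events=int(dwells.size),
    )


# ---------------------------------------------------------------------------
# dissociation: population formulas


def population_fractions(
    a1: float, tau1: float, a2: float, tau2: float
) -> tuple[float, float]:
    """Event-count fractions from density amplitudes and time constants.

    p1 = A1*tau1 / (A1*tau1 + A2*tau2), p2 = 1 - p1.  A_i*tau_i is the area
    under component i of the fitted density, i.e. its share of events.
    """
    if a1 < 0 or a2 < 0:
        raise ValueError("amplitudes must be non-negative")
    if tau1 <= 0 or tau2 <= 0:
        raise ValueError("time constants must be positive")
    w1, w2 = a1 * tau1, a2 * tau2
    total = w1 + w2
    if total == 0:
        raise ValueError("at least one amplitude must be positive")
    p1 = w1 / total
    return p1, 1.0 - p1


def average_dwell_time(a1: float, tau1: float, a2: float, tau2: float) -> float:
    """Event-weighted mean dwell (A1*tau1^2 + A2*tau2^2)/(A1*tau1 + A2*tau2)."""
    p1, p2 = population_fractions(a1, tau1, a2, tau2)
    return p1 * tau1 + p2 * tau2


# ---------------------------------------------------------------------------
# dissociation: fitting


def _ls_fit(
    hist: DwellHistogram, order: int
) -> ExponentialMixtureFit:
    t = hist.bin_centers[hist.fit_mask]
    y = hist.normalized_counts[hist.fit_mask]
    mean_dwell = float(np.sum(hist.bin_centers * hist.normalized_counts)
                       / max(np.sum(hist.normalized_counts), 1e-12))
    mean_dwell = max(mean_dwell, hist.bin_width)

    if order == 1:
        def model(tt, a, tau):
            return a * np.exp(-tt / tau)

        # counts are normalized, so no bin (hence no extrapolated amplitude)
        # can meaningfully exceed 1; the cap also blocks quasi-delta
        # components hiding below the excluded first bin
        p0 = [max(y.max(), 1e-6), mean_dwell]
        popt, pcov = optimize.curve_fit(
            model, t, y, p0=p0, bounds=([0, 1e-9], [1.5, np.inf]),
            maxfev=20000,
        )
        a_hat, tau_hat = map(float, popt)
        perr = np.sqrt(np.diag(pcov))
        yhat = model(t, *popt)
        amplitudes, taus = (a_hat,), (tau_hat,)
        fractions = (1.0,)
        avg = tau_hat
        ses = {"A1": float(perr[0]), "tau1": float(perr[1])}
    else:
        def model(tt, a1, tau1, a2, tau2):
            return a1 * np.exp(-tt / tau1) + a2 * np.exp(-tt / tau2)

        p0 = [min(y.max(), 1.4), 0.5 * mean_dwell,
              min(0.25 * y.max(), 1.4), 3.0 * mean_dwell]
        popt, pcov = optimize.curve_fit(
            model, t, y, p0=p0,
            bounds=([0, 1e-9, 0, 1e-9], [1.5, np.inf, 1.5, np.inf]),
            maxfev=40000,
        )
        perr = np.sqrt(np.diag(pcov))
        pars = list(zip([popt[0], popt[2]], [popt[1], popt[3]],
                        [perr[0], perr[2]], [perr[1], perr[3]]))
        # tau ascending; ties broken by larger amplitude first
        pars.sort(key=lambda q: (q[1], -q[0]))
        (a1, tau1, a1se, t1se), (a2, tau2, a2se, t2se) = pars
        if tau2 / tau1 < _TAU_COLLAPSE_RATIO:
            fit1 = _ls_fit(hist, 1)
            fit1.message = "two-component fit not identifiable (tau1 ~ tau2); collapsed to one component"
            return fit1
        if hist.excluded_first_bin and tau1 < hist.bin_width:
            # most of such a component's events would sit inside the
            # excluded first bin; its weight is pure extrapolation, so the
            # fit is not identifiable at this binning
            fit1 = _ls_fit(hist, 1)
            fit1.message = (
                "two-component fit not identifiable (short tau below the "
                "excluded-bin boundary); collapsed to one component"
            )
            return fit1
        yhat = model(t, *popt)
        amplitudes, taus = (float(a1), float(a2)), (float(tau1), float(tau2))
        fractions = population_fractions(a1, tau1, a2, tau2)
        avg = average_dwell_time(a1, tau1, a2, tau2)
        ses = {"A1": float(a1se), "tau1": float(t1se),
               "A2": float(a2se), "tau2": float(t2se)}

    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    fit = ExponentialMixtureFit(
        order=order,
        amplitudes=amplitudes,
        taus=taus,
        fractions=tuple(float(f) for f in fractions),
        average_dwell=float(avg),
        method="ls",
        n_events=hist.n_events,
        r_squared=r2,
        truncation_s=hist.bin_width if hist.excluded_first_bin else 0.0,
        standard_errors=ses,
    )
    fit._rss = ss_res
    fit._n_fit_points = int(t.size)
    return fit


def _component_prob(d: np.ndarray, tau: float, dt: float) -> np.ndarray:
    """Per-event likelihood contribution of one exponential component.

    With ``dt == 0`` this is the density exp(-d/tau)/tau.  With ``dt > 0``
    dwells are treated as interval-censored to the frame grid: an observed
    dwell d stands for a true dwell in [d - dt/2, d + dt/2), whose
    probability is S(d - dt/2) - S(d + dt/2).  The interval form keeps the
    likelihood bounded on quantized data (a pure density would diverge by
    shrinking tau onto the atom at the shortest observed dwell).
    """
    if dt <= 0:
        return np.exp(-d / tau) / tau
    lo = np.clip(d - 0.5 * dt, 0.0, None)
    return np.exp(-lo / tau) - np.exp(-(d + 0.5 * dt) / tau)


def _survival_at_truncation(tau: float, t0: float, dt: float) -> float:
    lo = max(t0 - 0.5 * dt, 0.0) if dt > 0 else t0
    return float(np.exp(-lo / tau))


def _mixture_nll(
    theta: np.ndarray,
    d: np.ndarray,
    t0: float,
    dt: float,
    cens: Optional[np.ndarray] = None,
) -> float:
    """Negative log-likelihood of the left-truncated 2-exponential mixture.

    theta = (logit w1, log tau1, log tau2); w1 is the *untruncated*
    event-count weight of component 1, so the fitted weight estimates the
    same quantity as the histogram percentage formula.  Events flagged in
    ``cens`` are right-censored and contribute survival terms S(d) instead
    of probabilities (the dwell is only a lower bound).
    """
    w1 = 1.0 / (1.0 + np.exp(-theta[0]))
    tau1, tau2 = np.exp(theta[1]), np.exp(theta[2])
    if cens is None:
        cens = np.zeros(d.size, dtype=bool)
    obs = d[~cens]
    f = (w1 * _component_prob(obs, tau1, dt)
         + (1 - w1) * _component_prob(obs, tau2, dt))
    z = (w1 * _survival_at_truncation(tau1, t0, dt)
         + (1 - w1) * _survival_at_truncation(tau2, t0, dt))
    if z <= 0 or np.any(f <= 0):
        return 1e300
    nll = float(-np.sum(np.log(f)) + d.size * np.log(z))
    if cens.any():
        c = d[cens]
        s = w1 * np.exp(-c / tau1) + (1 - w1) * np.exp(-c / tau2)
        if np.any(s <= 0):
            return 1e300
        nll -= float(np.sum(np.log(s)))
    return nll


def _numeric_hessian(fun, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = x.size
    h = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            h[i, j] = h[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej)
                - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4 * eps * eps)
    return h


def _mle_fit(
    dwells: np.ndarray,
    order: int,
    truncation: float,
    resolution: float = 0.0,
    censored: Optional[np.ndarray] = None,
) -> ExponentialMixtureFit:
    if censored is None:
        censored = np.zeros(dwells.size, dtype=bool)
    keep = dwells >= truncation
    d = dwells[keep]
    cens = censored[keep]
    n = int(d.size)
    n_obs = int(n - cens.sum())
    if n_obs == 0:
        raise ValueError("no uncensored dwells beyond the truncation point")

    if order == 1:
        if resolution > 0:
            # interval-censored likelihood; 1-D search started from the
            # continuous closed form
            tau0 = max(float(np.sum(d - truncation) / n_obs), resolution / 4)

            def nll1(log_tau: float) -> float:
                tau = float(np.exp(log_tau))
                f = _component_prob(d[~cens], tau, resolution)
                z = _survival_at_truncation(tau, truncation, resolution)
                if z <= 0 or np.any(f <= 0):
                    return 1e300
                nll = float(-np.sum(np.log(f)) + n * np.log(z))
                if cens.any():
                    nll += float(np.sum(d[cens]) / tau)
                return nll

            res = optimize.minimize_scalar(
                nll1, bracket=(np.log(tau0 * 0.5), np.log(tau0 * 2.0))
            )
            tau = float(np.exp(res.x))
            ll = -float(res.fun)
        else:
            # Memorylessness: uncensored d - t0 ~ Exp(tau), and censored
            # events add pure exposure, so the MLE is total observed time
            # beyond t0 over the number of completed events.
            tau = float(np.sum(d - truncation) / n_obs)
            ll = float(-n_obs * np.log(tau) - np.sum(d - truncation) / tau)
        fit = ExponentialMixtureFit(
            order=1,
            amplitudes=(1.0,),
            taus=(tau,),
            fractions=(1.0,),
            average_dwell=tau,
            method="mle",
            n_events=n,
            log_likelihood=ll,
            truncation_s=truncation,
            standard_errors={"tau1": tau / np.sqrt(n_obs)},
        )
        return fit

    # two-component: multi-start L-BFGS-B on (logit w1, log tau1, log tau2)
    shifted_mean = float(np.sum(d - truncation) / n_obs)
    q25, q75 = np.quantile(d - truncation, [0.25, 0.75])
    starts = [
        np.array([0.0, np.log(max(0.4 * shifted_mean, 1e-3)),
                  np.log(3.0 * shifted_mean)]),
        np.array([0.0, np.log(max(q25, 1e-3)), np.log(max(2.0 * q75, 1e-2))]),
        np.array([np.log(0.25 / 0.75), np.log(max(0.7 * shifted_mean, 1e-3)),
                  np.log(5.0 * shifted_mean)]),
    ]
    best = None
    bounds = [(-20.0, 20.0), (np.log(1e-4), np.log(1e5)), (np.log(1e-4), np.log(1e5))]
    for x0 in starts:
        res = optimize.minimize(
            _mixture_nll, x0, args=(d, truncation, resolution, cens),
            method="L-BFGS-B", bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    w1 = 1.0 / (1.0 + np.exp(-best.x[0]))
    tau1, tau2 = float(np.exp(best.x[1])), float(np.exp(best.x[2]))
    # order components by ascending tau; ties: larger weight first
    comps = sorted([(tau1, w1), (tau2, 1.0 - w1)], key=lambda q: (q[0], -q[1]))
    (tau1, w1), (tau2, w2) = comps

    if tau2 / tau1 < _TAU_COLLAPSE_RATIO:
        fit1 = _mle_fit(dwells, 1, truncation, resolution, censored)
        fit1.message = "two-component fit not identifiable (tau1 ~ tau2); collapsed to one component"
        return fit1

    # asymptotic SEs: inverse Hessian of the NLL, delta method back to
    # (w1, tau1, tau2)
    ses: dict[str, float] = {}
    try:
        hess = _numeric_hessian(
            lambda x: _mixture_nll(x, d, truncation, resolution, cens), best.x
        )
        cov_theta = np.linalg.inv(hess)
        s = 1.0 / (1.0 + np.exp(-best.x[0]))
        jac = np.diag([s * (1 - s), np.exp(best.x[1]), np.exp(best.x[2])])
        cov = jac @ cov_theta @ jac.T
        var = np.clip(np.diag(cov), 0.0, None)
        raw = {"w": np.sqrt(var[0]), "t1": np.sqrt(var[1]), "t2": np.sqrt(var[2])}
        # map back respecting the component reordering
        swapped = np.exp(best.x[1]) > np.exp(best.x[2])
        ses = {
            "p1": float(raw["w"]),
            "tau1": float(raw["t2"] if swapped else raw["t1"]),
            "tau2": float(raw["t1"] if swapped else raw["t2"]),
        }
    except np.linalg.LinAlgError:
        ses = {}

    fit = ExponentialMixtureFit(
        order=2,
        amplitudes=(float(w1), float(w2)),
        taus=(tau1, tau2),
        fractions=(float(w1), float(w2)),
        average_dwell=float(w1 * tau1 + w2 * tau2),
        method="mle",
        n_events=n,
        log_likelihood=float(-best.fun),
        truncation_s=truncation,
        standard_errors=ses,
    )
    return fit


def fit_dwell_distribution(
    data: DwellHistogram | Sequence[float] | np.ndarray,
    order: int = 2,
    method: str = "mle",
    bin_width: float = 0.5,
    exclude_first_bin: bool = True,
    truncation: Optional[float] = None,
    resolution: float = 0.0,
    censored: Optional[np.ndarray] = None,
) -> ExponentialMixtureFit:
    """Fit a one- or two-component exponential decay to dwell times.

    ``method="ls"`` needs (or builds) a :class:`DwellHistogram` and fits the
    decay to normalized bin heights with unweighted least squares, first bin
    excluded.  ``method="mle"`` needs raw dwells and maximizes the mixture
    likelihood left-truncated at ``truncation`` (default: one bin width when
    the first bin is excluded, else 0) — the same cutoff, without binning.
    For dwells quantized to a frame grid, pass the frame interval as
    ``resolution`` so the MLE uses interval probabilities instead of
    densities (bounded likelihood on gridded data).  A boolean ``censored``
    mask marks right-censored dwells, which enter the MLE as survival terms
    (LS cannot use them; they must be excluded there).

    Fractions always refer to event counts of the untruncated mixture, so LS
    and MLE estimate the same quantities.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if method not in ("ls", "mle"):
        raise ValueError("method must be 'ls' or 'mle'")

    if method == "ls":
        hist = (
            data
            if isinstance(data, DwellHistogram)
            else build_dwell_histogram(data, bin_width, exclude_first_bin)
        )
        if order == 2 and hist.n_events < 20:
            return ExponentialMixtureFit(
                order=2, amplitudes=(), taus=(), fractions=(),
                average_dwell=np.nan, method="ls", n_events=hist.n_events,
                success=False,
                message=f"two-component fit needs >= 20 events, got {hist.n_events}",
            )
        return _ls_fit(hist, order)

    if isinstance(data, DwellHistogram):
        raise ValueError("MLE mode requires raw dwell times, not a histogram")
    dwells = np.asarray(data, dtype=float)
    if truncation is None:
        truncation = bin_width if exclude_first_bin else 0.0
    if order == 2 and dwells.size < 20:
        return ExponentialMixtureFit(
            order=2, amplitudes=(), taus=(), fractions=(),
            average_dwell=np.nan, method="mle", n_events=int(dwells.size),
            success=False,
            message=f"two-component fit needs >= 20 events, got {dwells.size}",
        )
    return _mle_fit(dwells, order, float(truncation), float(resolution),
                    censored)


def select_model(
    fit1: ExponentialMixtureFit, fit2: ExponentialMixtureFit, alpha: float = 0.01
) -> ModelSelection:
    """Choose between one- and two-component dwell fits of the same data.

    LS mode: extra-sum-of-squares F-test (2 extra parameters).  MLE mode:
    BIC, with the likelihood-ratio statistic reported alongside.  A
    two-component fit that collapsed (tau1 ~ tau2) or failed selects order 1
    by parsimony.
    """
    if fit1.method != fit2.method:
        raise ValueError("fits use different methods")
    if fit1.n_events != fit2.n_events:
        raise ValueError("fits are not on the same data")
    if not fit2.success or fit2.order == 1:
        return ModelSelection(
            chosen_order=1, rule="collapse", statistic=None, p_value=None,
            r_squared_1=fit1.r_squared, r_squared_2=fit2.r_squared,
        )

    if fit1.method == "ls":
        rss1, rss2 = fit1.rss, fit2.rss
        npts = fit2._n_fit_points or 0
        df2 = npts - 4
        if rss1 is None or rss2 is None or df2 <= 0 or rss2 <= 0:
            raise ValueError("LS fits lack residual information")
        f_stat = ((rss1 - rss2) / 2.0) / (rss2 / df2)
        p = float(stats.f.sf(max(f_stat, 0.0), 2, df2))
        chosen = 2 if p < alpha else 1
        return ModelSelection(
            chosen_order=chosen, rule="f-test", statistic=float(f_stat),
            p_value=p, r_squared_1=fit1.r_squared, r_squared_2=fit2.r_squared,
        )

    # MLE: BIC decides; LRT reported for reference
    lrt = 2.0 * (fit2.log_likelihood - fit1.log_likelihood)  # type: ignore[operator]
    p = float(stats.chi2.sf(max(lrt, 0.0), 2))
    bic1, bic2 = fit1.bic, fit2.bic
    chosen = 2 if (bic2 is not None and bic1 is not None and bic2 < bic1) else 1
    return ModelSelection(
        chosen_order=chosen, rule="bic", statistic=float(lrt), p_value=p,
        r_squared_1=fit1.r_squared, r_squared_2=fit2.r_squared,
        bic_1=bic1, bic_2=bic2,
    )
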