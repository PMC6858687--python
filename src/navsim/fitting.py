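"""Patch-clamp curve analysis.

Boltzmann fits of activation/availability curves, single/double
exponential fits of recovery-from-inactivation curves, the relative
persistent-current measure (end-pulse / peak), an extrapolated-plateau
estimator of the persistent fraction, drug-effect ratios, peak current
density, the series-resistance voltage-error QC rule and unpaired
two-sample comparisons with the conventional star labelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .trace import Trace
from .vclamp import END_PULSE_WINDOW_MS, measure_end_pulse, measure_peak

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Boltzmann fits
# ---------------------------------------------------------------------------


@dataclass
class BoltzmannFit:
    Vhalf_mV: float
    slope_mV: float
    amplitude: float
    floor: float
    stderr: dict[str, float] = field(default_factory=dict)
    rms: float = float("nan")
    converged: bool = True

    def __call__(self, V):
        V = np.asarray(V, dtype=float)
        return self.floor + (self.amplitude - self.floor) / (
            1.0 + np.exp((V - self.Vhalf_mV) / self.slope_mV)
        )


def _boltzmann_model(V, Vhalf, k, amplitude, floor):
    return floor + (amplitude - floor) / (1.0 + np.exp((V - Vhalf) / k))


def _boltzmann_init(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Initial guess: midpoint from the half-crossing of the (monotone)
    interpolated data, slope from the 25–75% width."""
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    hi = float(ys[0])
    lo = float(ys[-1])
    decreasing = hi >= lo
    if not decreasing:
        hi, lo = lo, hi
    span = hi - lo
    if span <= 0:
        return float(np.median(xs)), 6.0, float(ys[0]), float(ys[-1])

    def crossing(level: float) -> float:
        # first crossing of the level in the monotone envelope of the data
        yy = ys if decreasing else ys[::-1]
        xx = xs if decreasing else xs[::-1]
        env = np.minimum.accumulate(yy)  # enforce monotone non-increasing
        idx = np.nonzero(env <= level)[0]
        if len(idx) == 0:
            return float(xx[-1])
        i = idx[0]
        if i == 0:
            return float(xx[0])
        x0, x1 = xx[i - 1], xx[i]
        y0, y1 = env[i - 1], env[i]
        if y1 == y0:
            return float(x1)
        return float(x0 + (level - y0) * (x1 - x0) / (y1 - y0))

    v50 = crossing(lo + 0.5 * span)
    v25 = crossing(lo + 0.75 * span)  # 25% of the way down
    v75 = crossing(lo + 0.25 * span)
    width = abs(v75 - v25)
    k = max(width / (2 * np.log(3.0)), 0.5)
    if not decreasing:
        k = -k
    amplitude = float(ys[0])
    floor = float(ys[-1])
    return v50, k, amplitude, floor


def fit_boltzmann(x, y) -> BoltzmannFit:
    """Least-squares Boltzmann fit floor+(amp−floor)/(1+exp((V−V½)/k)).

    Non-convergence is flagged (``converged=False``) rather than raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 points spanning the transition")
    p0 = _boltzmann_init(x, y)
    try:
        popt, pcov = optimize.curve_fit(_boltzmann_model, x, y, p0=p0, maxfev=20000)
        perr = np.sqrt(np.diag(pcov))
        resid = y - _boltzmann_model(x, *popt)
        return BoltzmannFit(
            Vhalf_mV=float(popt[0]),
            slope_mV=float(popt[1]),
            amplitude=float(popt[2]),
            floor=float(popt[3]),
            stderr={
                "Vhalf_mV": float(perr[0]),
                "slope_mV": float(perr[1]),
                "amplitude": float(perr[2]),
                "floor": float(perr[3]),
            },
            rms=float(np.sqrt(np.mean(resid**2))),
            converged=True,
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        logger.warning("Boltzmann fit did not converge: %s", exc)
        return BoltzmannFit(*p0, rms=float("nan"), converged=False)


# ---------------------------------------------------------------------------
# Exponential recovery fits
# ---------------------------------------------------------------------------


@dataclass
class ExpFit:
    n_components: int
    taus_ms: tuple[float, ...]
    amplitude_fractions: tuple[float, ...]
    asymptote: float
    total_amplitude: float
    rms: float
    converged: bool = True

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        y = np.full_like(t, self.asymptote)
        for tau, frac in zip(self.taus_ms, self.amplitude_fractions):
            y = y - self.total_amplitude * frac * np.exp(-t / tau)
        return y


def _varpro_init(t: np.ndarray, y: np.ndarray, n: int) -> list[float]:
    """Grid-searched initial guess: candidate time constants on a log grid,
    amplitudes and offset by linear least squares (variable projection)."""
    grid = np.geomspace(max(t[t > 0].min() / 3.0, 1e-4), t.max() * 3.0, 14)
    best: tuple[float, list[float]] | None = None
    if n == 1:
        combos = [(tau,) for tau in grid]
    else:
        combos = [(grid[i], grid[j]) for i in range(len(grid)) for j in range(i + 1, len(grid))]
    for taus in combos:
        A = np.column_stack([np.ones_like(t)] + [-np.exp(-t / tau) for tau in taus])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        if np.any(coef[1:] < 0):
            continue
        sse = float(np.sum((A @ coef - y) ** 2))
        if best is None or sse < best[0]:
            params = [float(coef[0])]
            for a, tau in zip(coef[1:], taus):
                params.extend([float(a), float(tau)])
            best = (sse, params)
    if best is not None:
        return best[1]
    # all-amplitudes-negative fallback: crude single-scale guess
    tau0 = max(float(np.median(t)), 1e-3)
    a0 = max(float(np.ptp(y)), 1e-6)
    out = [float(np.max(y))]
    for k in range(n):
        out.extend([a0 / n, tau0 * 10.0**k])
    return out


def _fit_exp_n(t: np.ndarray, y: np.ndarray, n: int) -> ExpFit | None:
    """Rising saturating fit y = c − Σ a_i exp(−t/τ_i) with n components."""
    # time constants beyond ~10x the observation window are not
    # identifiable; cap them so drift cannot masquerade as a component
    tau_max = 10.0 * float(np.max(t))
    if n == 1:
        def model(t, c, a, tau):
            return c - a * np.exp(-t / tau)

        bounds = ([-np.inf, 0, 1e-6], [np.inf, np.inf, tau_max])
    else:
        def model(t, c, a1, tau1, a2, tau2):
            return c - a1 * np.exp(-t / tau1) - a2 * np.exp(-t / tau2)

        bounds = ([-np.inf, 0, 1e-6, 0, 1e-6], [np.inf, np.inf, tau_max, np.inf, tau_max])
    p0 = _varpro_init(t, y, n)
    p0 = np.clip(p0, [b + 1e-12 if np.isfinite(b) else b for b in bounds[0]], bounds[1])
    try:
        popt, _ = optimize.curve_fit(model, t, y, p0=p0, bounds=bounds, maxfev=40000)
    except (RuntimeError, ValueError) as exc:
        logger.warning("%d-exponential fit failed: %s", n, exc)
        return None
    resid = y - model(t, *popt)
    rms = float(np.sqrt(np.mean(resid**2)))
    if n == 1:
        taus = (float(popt[2]),)
        amps = (float(popt[1]),)
    else:
        pairs = sorted([(float(popt[2]), float(popt[1])), (float(popt[4]), float(popt[3]))])
        taus = (pairs[0][0], pairs[1][0])
        amps = (pairs[0][1], pairs[1][1])
    total = sum(amps)
    fracs = tuple(a / total for a in amps) if total > 0 else tuple(1.0 / n for _ in amps)
    return ExpFit(
        n_components=n,
        taus_ms=taus,
        amplitude_fractions=fracs,
        asymptote=float(popt[0]),
        total_amplitude=float(total),
        rms=rms,
    )


def fit_recovery(
    intervals_ms,
    fractions,
    rms_improvement: float = 0.20,
    min_fraction: float = 0.05,
    n_components: int | None = None,
) -> ExpFit:
    """Fit a recovery curve with 1 and 2 exponential components.

    The double-exponential description is retained only when it improves
    the residual RMS by more than ``rms_improvement`` (default 20%) and
    both amplitude fractions exceed ``min_fraction`` (default 5%);
    otherwise the single-exponential fit is reported.  Pass
    ``n_components`` to force one model instead of selecting.
    """
    t = np.asarray(intervals_ms, dtype=float)
    y = np.asarray(fractions, dtype=float)
    if len(t) < 8:
        raise ValueError("need at least 8 recovery intervals")
    if n_components is not None:
        if n_components not in (1, 2):
            raise ValueError("n_components must be 1 or 2")
        fit = _fit_exp_n(t, y, n_components)
        if fit is None:
            raise RuntimeError(f"{n_components}-exponential fit failed")
        return fit
    fit1 = _fit_exp_n(t, y, 1)
    fit2 = _fit_exp_n(t, y, 2)
    if fit1 is None and fit2 is None:
        raise RuntimeError("both exponential fits failed on degenerate data")
    if fit1 is None:
        fit2.converged = False  # flagged: single fit failed, double kept
        return fit2
    if (
        fit2 is not None
        and fit2.rms < (1.0 - rms_improvement) * fit1.rms
        and min(fit2.amplitude_fractions) > min_fraction
    ):
        return fit2
    return fit1


# ---------------------------------------------------------------------------
# Trace-derived scalar measures
# ---------------------------------------------------------------------------


@dataclass
class PersistentRatio:
    percent: float
    peak_pA: float
    end_pulse_pA: float
    reliable: bool = True


def persistent_ratio(
    trace: Trace,
    pulse_end_ms: float,
    pulse_start_ms: float = 0.0,
    noise_floor_sd: float = 3.0,
) -> PersistentRatio:
    """Relative persistent current: mean of the final 2 ms of the pulse
    divided by the signed peak, as a percentage.

    When a pre-pulse baseline exists, a peak smaller than
    ``noise_floor_sd`` × baseline SD marks the result unreliable.
    """
    peak = measure_peak(trace, pulse_start_ms, pulse_end_ms)
    end = measure_end_pulse(trace, pulse_end_ms)
    reliable = True
    if pulse_start_ms > trace.t[0]:
        base = trace.slice(trace.t[0], pulse_start_ms)
        if len(base.y) >= 4:
            sd = float(np.std(base.y))
            if abs(peak) < noise_floor_sd * sd:
                reliable = False
                logger.warning(
                    "peak %.3g pA below %gx baseline SD (%.3g pA); ratio unreliable",
                    peak,
                    noise_floor_sd,
                    sd,
                )
    if peak == 0:
        raise ZeroDivisionError("zero peak current; persistent ratio undefined")
    return PersistentRatio(
        percent=100.0 * end / peak, peak_pA=peak, end_pulse_pA=end, reliable=reliable
    )


def estimate_persistent_fraction(
    trace: Trace,
    step_start_ms: float,
    step_end_ms: float,
    fit_start_offset_ms: float = 0.5,
    fit_window_ms: float = 8.0,
) -> float:
    """Persistent fraction from the fast-inactivation decay itself.

    Fits I(t) = I_ss + A·exp(−(t−t0)/τ) over an early window of the step
    (after activation has settled) and returns I_ss / (I_ss + A), i.e.
    the plateau relative to the zero-time extrapolated full amplitude.
    Unlike the raw end-pulse/peak ratio this is unbiased by the partial
    inactivation already incurred at the time of the observed peak.
    """
    t0 = step_start_ms + fit_start_offset_ms
    sub = trace.slice(t0, min(step_start_ms + fit_window_ms, step_end_ms))
    t = sub.t - t0
    y = sub.y

    def model(t, iss, a, tau):
        return iss + a * np.exp(-t / tau)

    a0 = y[0] - y[-1]
    p0 = [y[-1], a0, max((sub.t[-1] - sub.t[0]) / 4, 0.05)]
    popt, _ = optimize.curve_fit(model, t, y, p0=p0, maxfev=20000)
    iss, a, tau = popt
    full = iss + a * np.exp(fit_start_offset_ms / tau)  # extrapolate to step onset
    if full == 0:
        raise ZeroDivisionError("zero extrapolated amplitude")
    return float(iss / full)


def drug_effect_ratio(before: Trace, after: Trace) -> tuple[float, float]:
    """(peak ratio, end-pulse ratio) = I_after / I_before for one sweep."""
    for key in ("protocol", "sweep_value"):
        if before.meta.get(key) != after.meta.get(key):
            raise ValueError(
                f"mismatched protocols: {key} differs "
                f"({before.meta.get(key)!r} vs {after.meta.get(key)!r})"
            )
    lo = before.meta["step_start_ms"]
    hi = before.meta["step_end_ms"]
    peak_ratio = measure_peak(after, lo, hi) / measure_peak(before, lo, hi)
    end_ratio = measure_end_pulse(after, hi) / measure_end_pulse(before, hi)
    return float(peak_ratio), float(end_ratio)


def current_density(peak_pA: float, capacitance_pF: float) -> float:
    """Peak current density in pA/pF."""
    if capacitance_pF <= 0:
        raise ValueError("capacitance must be positive")
    return peak_pA / capacitance_pF


@dataclass
class QCResult:
    error_mV: float
    passed: bool


def qc_series_resistance(peak_nA: float, Rs_MOhm: float, max_error_mV: float = 5.0) -> QCResult:
    """Series-resistance voltage-error rule: error = |I|·Rs; pass iff
    error ≤ the accepted maximum (2.5 nA × 2 MΩ = 5 mV)."""
    error = abs(peak_nA) * Rs_MOhm
    return QCResult(error_mV=float(error), passed=bool(error <= max_error_mV))


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------


@dataclass
class GroupStats:
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    n_a: int
    n_b: int
    t: float
    p: float
    stars: str


def star_label(p: float) -> str:
    """Significance stars: *** p<0.001, ** p<0.01, * p<0.05, else 'ns'
    (p = 0.05 is not significant)."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(a, b, equal_var: bool = True) -> GroupStats:
    """Two-sided unpaired Student t-test (Welch variant via equal_var=False)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_ind(a, b, equal_var=equal_var)
        t_stat, p = float(t_stat), float(p)
    return GroupStats(
        mean_a=float(np.mean(a)),
        mean_b=float(np.mean(b)),
        sem_a=float(stats.sem(a)),
        sem_b=float(stats.sem(b)),
        n_a=int(len(a)),
        n_b=int(len(b)),
        t=t_stat,
        p=p,
        stars=star_label(p),
    )
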