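"""Fiber-photometry trace processing.

Raw fluorescence is debleached by subtracting a fitted mono- or
bi-exponential decay (model chosen by corrected AIC), z-scored against a
baseline window, optionally LOESS-smoothed for display, and summarized as
trapezoidal AUC over analysis windows.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "PhotometryTrace",
    "BleachFit",
    "ProcessedTrace",
    "AUCResult",
    "SessionConfig",
    "fit_bleach",
    "debleach",
    "zscore_baseline",
    "loess_smooth",
    "auc",
    "process_session",
]


@dataclass
class PhotometryTrace:
    """A fluorescence time series sampled at a nominally constant rate.

    ``t`` (seconds) must be strictly increasing; ``fs`` defaults to the
    reciprocal of the median sampling interval and must agree with it to 1%.
    """

    t: np.ndarray
    F: np.ndarray
    fs: float | None = None
    baseline_window: tuple | None = None
    stim_onsets: tuple = ()

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.F.shape:
            raise ValueError("t and F must be 1-D arrays of equal length")
        if len(self.t) < 2:
            raise ValueError("trace needs at least 2 samples")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValueError("t must be strictly increasing")
        med = float(np.median(dt))
        if self.fs is None:
            self.fs = 1.0 / med
        elif abs(self.fs * med - 1.0) > 0.01:
            raise ValueError(
                f"fs={self.fs} inconsistent with median sampling interval {med}"
            )
        if self.baseline_window is not None:
            t0, t1 = self.baseline_window
            if not (self.t[0] <= t0 < t1 <= self.t[-1]):
                raise ValueError("baseline_window must lie within the trace span")
        for s in self.stim_onsets:
            if not (self.t[0] <= s <= self.t[-1]):
                raise ValueError(f"stim onset {s} outside trace span")

    @property
    def span(self) -> tuple:
        return float(self.t[0]), float(self.t[-1])


def _mono(t, A, tau, C):
    return A * np.exp(-t / tau) + C


def _bi(t, A1, tau1, A2, tau2, C):
    return A1 * np.exp(-t / tau1) + A2 * np.exp(-t / tau2) + C


@dataclass
class BleachFit:
    """Fitted photobleaching decay. Bi-exponential parameters are stored with
    tau1 <= tau2."""

    model: str  # "mono" | "bi"
    params: dict
    rss: float
    aicc: float

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        p = self.params
        if self.model == "mono":
            return _mono(t, p["A"], p["tau"], p["C"])
        return _bi(t, p["A1"], p["tau1"], p["A2"], p["tau2"], p["C"])


def _aicc(rss: float, n: int, k: int) -> float:
    rss = max(rss, n * 1e-300)  # guard log(0) on perfect fits
    aic = n * math.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return aic


def _fit_model(t, F, model: str) -> BleachFit:
    span = t[-1] - t[0]
    amp = F[0] - F[-1]
    offs = F[-1]
    fmax = max(abs(F).max(), 1.0)
    if model == "mono":
        p0 = [amp, span / 3.0, offs]
        lo = [-10 * fmax, 1e-9, -10 * fmax]
        hi = [10 * fmax, np.inf, 10 * fmax]
        popt, _ = curve_fit(_mono, t, F, p0=p0, bounds=(lo, hi), maxfev=20000,
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        resid = F - _mono(t, *popt)
        rss = float((resid**2).sum())
        params = {"A": popt[0], "tau": popt[1], "C": popt[2]}
        return BleachFit("mono", params, rss, _aicc(rss, len(t), 3))
    p0 = [amp / 2.0, span / 10.0, amp / 2.0, span / 2.0, offs]
    lo = [-10 * fmax, 1e-9, -10 * fmax, 1e-9, -10 * fmax]
    hi = [10 * fmax, np.inf, 10 * fmax, np.inf, 10 * fmax]
    popt, _ = curve_fit(_bi, t, F, p0=p0, bounds=(lo, hi), maxfev=40000,
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    A1, tau1, A2, tau2, C = popt
    if tau1 > tau2:
        A1, tau1, A2, tau2 = A2, tau2, A1, tau1
    resid = F - _bi(t, A1, tau1, A2, tau2, C)
    rss = float((resid**2).sum())
    params = {"A1": A1, "tau1": tau1, "A2": A2, "tau2": tau2, "C": C}
    return BleachFit("bi", params, rss, _aicc(rss, len(t), 5))


def fit_bleach(trace: PhotometryTrace, model: str | None = None) -> BleachFit:
    """Fit the photobleaching decay.

    Fits ``A e^{-t/tau} + C`` and ``A1 e^{-t/tau1} + A2 e^{-t/tau2} + C`` by
    nonlinear least squares with deterministic initialization and keeps the
    model with lower corrected AIC. ``model`` forces "mono" or "bi".
    """
    if len(trace.t) < 20:
        raise ValueError("fit_bleach requires at least 20 samples")
    candidates = [model] if model in ("mono", "bi") else ["mono", "bi"]
    if model is not None and model not in ("mono", "bi"):
        raise ValueError(f"model must be 'mono' or 'bi', got {model!r}")
    fits, errors = [], []
    for name in candidates:
        try:
            fits.append(_fit_model(trace.t, trace.F, name))
        except (RuntimeError, ValueError) as e:  # pragma: no cover - rare
            errors.append(f"{name}: {e}")
    if not fits:
        raise RuntimeError("bleach fit failed for all models: " + "; ".join(errors))
    return min(fits, key=lambda f: f.aicc)


def debleach(trace: PhotometryTrace, fit: BleachFit | None = None) -> PhotometryTrace:
    """Subtract the fitted bleach curve, returning the residual trace."""
    if fit is None:
        fit = fit_bleach(trace)
    resid = trace.F - fit.predict(trace.t)
    return PhotometryTrace(
        t=trace.t,
        F=resid,
        fs=trace.fs,
        baseline_window=trace.baseline_window,
        stim_onsets=trace.stim_onsets,
    )


@dataclass
class ProcessedTrace:
    """Z-scored (and optionally smoothed) trace with processing provenance."""

    t: np.ndarray
    z: np.ndarray
    z_smooth: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)


@dataclass
class AUCResult:
    window: tuple
    auc: float  # z * seconds
    n_samples: int = 0


def _window_index(t: np.ndarray, window) -> np.ndarray:
    t0, t1 = window
    if not (t[0] <= t0 and t1 <= t[-1]):
        raise ValueError(f"window {window} outside trace span ({t[0]}, {t[-1]})")
    return np.flatnonzero((t >= t0) & (t <= t1))


def zscore_baseline(
    trace: PhotometryTrace,
    baseline_window: tuple | None = None,
    sd_source: str = "baseline",
    min_samples: int = 10,
) -> ProcessedTrace:
    """Z-score a (debleached) trace against its baseline window.

    z_t = (F_t - mu_b) / sigma_b with mu_b the baseline mean and sigma_b the
    baseline standard deviation (ddof=1); ``sd_source="full"`` uses the sd of
    the whole trace instead.
    """
    window = baseline_window or trace.baseline_window
    if window is None:
        raise ValueError("no baseline window given")
    idx = _window_index(trace.t, window)
    if idx.size < max(min_samples, 2):
        raise ValueError(
            f"baseline window holds {idx.size} samples; need >= {max(min_samples, 2)}"
        )
    base = trace.F[idx]
    mu = float(base.mean())
    if sd_source == "baseline":
        sd = float(base.std(ddof=1))
    elif sd_source == "full":
        sd = float(trace.F.std(ddof=1))
    else:
        raise ValueError("sd_source must be 'baseline' or 'full'")
    if sd == 0:
        raise ValueError("zero baseline variance; cannot z-score")
    z = (trace.F - mu) / sd
    return ProcessedTrace(
        t=trace.t,
        z=z,
        provenance={"baseline_window": tuple(window), "mu_b": mu, "sigma_b": sd,
                    "sd_source": sd_source},
    )


def loess_smooth(y, x=None, frac: float = 0.1) -> np.ndarray:
    """LOESS: locally weighted linear regression with tricube weights.

    The local window holds ``ceil(frac * n)`` nearest neighbours (contiguous,
    since x must be sorted). Exactly linear input is reproduced; constant
    input is returned unchanged.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError("loess_smooth needs at least 10 points")
    if not (0 < frac <= 1):
        raise ValueError(f"frac must be in (0, 1], got {frac}")
    x = np.arange(n, dtype=float) if x is None else np.asarray(x, dtype=float)
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")
    k = int(math.ceil(frac * n))
    if k < 2:
        raise ValueError(f"local window of {k} point(s) is too small; raise frac")

    out = np.empty(n)
    lo = 0
    for i in range(n):
        # slide the k-point window so it holds the nearest neighbours of x[i]
        while lo + k < n and x[lo + k] - x[i] < x[i] - x[lo]:
            lo += 1
        xs = x[lo : lo + k]
        ys = y[lo : lo + k]
        d = np.abs(xs - x[i])
        dmax = d.max()
        if dmax == 0:
            w = np.ones(k)
        else:
            w = (1.0 - (d / dmax) ** 3) ** 3
            w[w < 0] = 0.0
        if np.count_nonzero(w) < 2:
            w = np.ones(k)
        sw = w.sum()
        xw = (w * xs).sum() / sw
        yw = (w * ys).sum() / sw
        dxs = xs - xw
        denom = (w * dxs * dxs).sum()
        if denom <= 0:
            out[i] = yw
        else:
            slope = (w * dxs * (ys - yw)).sum() / denom
            out[i] = yw + slope * (x[i] - xw)
    return out


def auc(processed: ProcessedTrace, window: tuple, use_smooth: bool = False) -> AUCResult:
    """Trapezoidal integral of the z-score over a time window (z * seconds).

    Window endpoints snap to the nearest samples; the snapped endpoints are
    included in the trapezoid. A window capturing fewer than two samples is
    an error.
    """
    t = processed.t
    t0, t1 = window
    if t0 >= t1:
        raise ValueError(f"empty window {window}")
    dt = float(np.median(np.diff(t)))  # one-sample slack for endpoint snapping
    if t0 < t[0] - dt or t1 > t[-1] + dt:
        raise ValueError(f"window {window} outside trace span ({t[0]}, {t[-1]})")
    i0 = int(np.argmin(np.abs(t - t0)))
    i1 = int(np.argmin(np.abs(t - t1)))
    if i1 <= i0:
        raise ValueError(f"window {window} snaps to fewer than two samples")
    z = processed.z_smooth if use_smooth else processed.z
    if z is None:
        raise ValueError("no smoothed series available")
    val = float(np.trapezoid(z[i0 : i1 + 1], t[i0 : i1 + 1]))
    return AUCResult(window=(float(t[i0]), float(t[i1])), auc=val, n_samples=i1 - i0 + 1)


@dataclass
class SessionConfig:
    """Processing configuration for one recording session.

    ``windows`` maps window names (e.g. pre/during/post) to (start, end)
    seconds. ``zscore_first=False`` smooths the residual before z-scoring.
    """

    baseline_window: tuple
    windows: dict = field(default_factory=dict)
    frac: float = 0.1
    model: str | None = None
    smooth: bool = True
    zscore_first: bool = True
    sd_source: str = "baseline"


def process_session(trace: PhotometryTrace, config: SessionConfig):
    """Full pipeline: fit bleach -> debleach -> z-score -> smooth -> AUCs.

    Returns ``(ProcessedTrace, {window_name: AUCResult})``. AUCs integrate
    the unsmoothed z-score; smoothing is for display.
    """

    def _stage(name, fn, *a, **kw):
        try:
            return fn(*a, **kw)
        except Exception as e:
            raise RuntimeError(f"process_session failed at stage {name!r}: {e}") from e

    fit = _stage("fit_bleach", fit_bleach, trace, model=config.model)
    resid = _stage("debleach", debleach, trace, fit)
    if config.zscore_first:
        proc = _stage("zscore_baseline", zscore_baseline, resid,
                      config.baseline_window, sd_source=config.sd_source)
        if config.smooth:
            proc.z_smooth = _stage("loess_smooth", loess_smooth, proc.z,
                                   x=proc.t, frac=config.frac)
    else:
        smoothed = _stage("loess_smooth", loess_smooth, resid.F,
                          x=resid.t, frac=config.frac) if config.smooth else resid.F
        sm_trace = PhotometryTrace(t=resid.t, F=smoothed, fs=resid.fs)
        proc = _stage("zscore_baseline", zscore_baseline, sm_trace,
                      config.baseline_window, sd_source=config.sd_source)
        proc.z_smooth = proc.z
    proc.provenance.update(
        {"model": fit.model, "bleach_params": dict(fit.params),
         "aicc": fit.aicc, "rss": fit.rss}
    )
    aucs = {
        name: _stage(f"auc[{name}]", auc, proc, win)
        for name, win in config.windows.items()
    }
    return proc, aucs
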