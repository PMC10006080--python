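"""FRAP recovery analysis: double normalization, averaging, kinetics, class.

Fluorescence recovery after photobleaching distinguishes liquid-like
condensates (fast, near-complete recovery) from solid-like aggregates
(little recovery).  Raw ROI traces are double-normalized as

    N(t) = [ (Ibleach(t) − Ibg(t)) / (Ibleach(t0) − Ibg(t0)) ]
         / [ (Itotal(t)  − Ibg(t)) / (Itotal(t0)  − Ibg(t0)) ]

where Itotal is the whole cellular structure, Ibleach the bleach ROI and
Ibg the camera-offset background; the Itotal denominator cancels
acquisition photobleaching that affects both ROIs equally.  t0 quantities
are means over the pre-bleach frames, so N ≡ 1 before the bleach by
construction.  Replicate curves are averaged to mean ± SEM, the post-bleach
recovery is fitted with a single exponential (double exponential behind a
flag), and foci are classified liquid-like or solid-like by the mobile
fraction reached within a time horizon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit

__all__ = [
    "FrapTrace",
    "FrapFit",
    "FrapResult",
    "normalize_trace",
    "average_curves",
    "FrapRecoveryModel",
    "fit_recovery",
    "classify_mobility",
    "analyze_trace",
    "read_trace_csv",
]


@dataclass
class FrapTrace:
    """Raw ROI intensity traces of one photobleaching experiment.

    ``pre_bleach`` holds the frame indices before the bleach event; all
    later frames are post-bleach.  The bleach and whole-structure ROIs may
    differ in area, so no ordering between the channels is assumed.
    """

    time_s: np.ndarray
    i_bleach: np.ndarray
    i_total: np.ndarray
    i_background: np.ndarray
    pre_bleach: np.ndarray

    def __post_init__(self) -> None:
        for attr in ("time_s", "i_bleach", "i_total", "i_background"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=float))
        self.pre_bleach = np.asarray(self.pre_bleach, dtype=int)
        n = self.time_s.size
        for attr in ("i_bleach", "i_total", "i_background"):
            if getattr(self, attr).size != n:
                raise ValueError(f"{attr} length does not match time axis")
        if self.pre_bleach.size < 1:
            raise ValueError("need at least one pre-bleach frame")
        for attr in ("i_bleach", "i_total", "i_background"):
            if np.any(getattr(self, attr) < 0):
                raise ValueError(f"{attr} has negative intensities")

    @property
    def post_bleach(self) -> np.ndarray:
        first_post = int(self.pre_bleach.max()) + 1
        return np.arange(first_post, self.time_s.size)


def normalize_trace(trace: FrapTrace) -> np.ndarray:
    """Double-normalized recovery curve N(t).

    Reference (t0) intensities are the means of each channel over the
    pre-bleach frames.  Raises on a vanishing reference, naming the ROI.
    """
    pre = trace.pre_bleach
    bleach0 = float((trace.i_bleach[pre] - trace.i_background[pre]).mean())
    total0 = float((trace.i_total[pre] - trace.i_background[pre]).mean())
    if bleach0 <= 0:
        raise ValueError("pre-bleach bleach-ROI intensity does not exceed "
                         "background (Ibleach(t0) - Ibg(t0) <= 0)")
    if total0 <= 0:
        raise ValueError("pre-bleach whole-structure intensity does not "
                         "exceed background (Itotal(t0) - Ibg(t0) <= 0)")
    total = trace.i_total - trace.i_background
    if np.any(total == 0):
        raise ValueError("whole-structure ROI equals background at some "
                         "frame; normalization denominator vanishes")
    num = (trace.i_bleach - trace.i_background) / bleach0
    den = total / total0
    return num / den


def average_curves(curves: Sequence[np.ndarray]
                   ) -> tuple[np.ndarray, np.ndarray | None]:
    """Pointwise mean ± SEM over replicate normalized curves.

    Curves must share the time base (resample beforehand otherwise).  A
    single curve has no dispersion: SEM is returned as None.
    """
    arr = np.asarray(list(curves), dtype=float)
    if arr.ndim != 2:
        raise ValueError("curves must share a common time base")
    mean = arr.mean(axis=0)
    if arr.shape[0] < 2:
        return mean, None
    sem = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
    return mean, sem


@dataclass
class FrapFit:
    """Recovery-kinetics fit of one normalized curve.

    ``mobile_fraction`` = (N∞ − N₊)/(1 − N₊) with the pre-bleach level
    fixed at 1; ``half_time_s`` = τ·ln 2 for the single-exponential model.
    ``flat`` marks non-recovering curves whose τ is unconstrained (half
    time absent, mobile fraction ≈ 0).
    """

    mobile_fraction: float
    half_time_s: float | None
    tau_s: float | None
    n_plus: float
    n_inf: float
    mobile_fraction_stderr: float = np.nan
    tau_stderr: float = np.nan
    flat: bool = False
    model: str = "single"

    def summary(self) -> str:
        if self.flat:
            return (f"no recovery: mobile fraction ≈ "
                    f"{self.mobile_fraction:.3f}, half-time undetermined")
        return (f"{self.model}-exponential recovery: mobile fraction = "
                f"{self.mobile_fraction:.3f} ± {self.mobile_fraction_stderr:.3f}, "
                f"half-time = {self.half_time_s:.2f} s")


class FrapRecoveryModel:
    """Fit the post-bleach recovery of a normalized FRAP curve.

    Single-exponential model N(t) = N∞ − (N∞ − N₊)·exp(−t/τ) on the
    post-bleach points (t measured from the first post-bleach frame);
    ``model="double"`` adds a second exponential component.
    """

    FLAT_SPAN = 1e-3   # recovery amplitude below which a curve is flat

    def __init__(self, time_s: np.ndarray, n_curve: np.ndarray,
                 post_bleach: np.ndarray,
                 pre_bleach: np.ndarray | None = None):
        post = np.asarray(post_bleach, dtype=int)
        if post.size < 10:
            raise ValueError("need at least 10 post-bleach points")
        self.t = np.asarray(time_s, dtype=float)[post]
        self.t = self.t - self.t[0]
        self.n = np.asarray(n_curve, dtype=float)[post]
        # relative uncertainty of the t0 normalization reference, estimated
        # from the pre-bleach scatter of N around 1; it acts as a common
        # scale factor on the whole curve and is propagated into the
        # mobile-fraction error (the fit covariance alone cannot see it)
        self.ref_sigma = 0.0
        if pre_bleach is not None:
            pre = np.asarray(n_curve, dtype=float)[np.asarray(pre_bleach,
                                                              dtype=int)]
            if pre.size > 1:
                self.ref_sigma = float(pre.std(ddof=1) / np.sqrt(pre.size))

    def fit(self, model: str = "single") -> FrapFit:
        n_plus = float(self.n[0])
        span = float(self.n[-5:].mean() - n_plus)
        if span < self.FLAT_SPAN:
            mf = (float(self.n.mean()) - n_plus) / (1.0 - n_plus) \
                if n_plus < 1.0 else 0.0
            return FrapFit(mobile_fraction=max(mf, 0.0), half_time_s=None,
                           tau_s=None, n_plus=n_plus,
                           n_inf=float(self.n.mean()), flat=True, model=model)
        if model == "single":
            return self._fit_single(n_plus)
        if model == "double":
            return self._fit_double(n_plus)
        raise ValueError(f"unknown model {model!r}")

    def _fit_single(self, n_plus0: float) -> FrapFit:
        def f(t, n_inf, n_plus, tau):
            return n_inf - (n_inf - n_plus) * np.exp(-t / tau)

        tau0 = max(self.t[-1] / 5.0, self.t[1] - self.t[0])
        p0 = (float(self.n[-5:].mean()), n_plus0, tau0)
        popt, pcov = curve_fit(f, self.t, self.n, p0=p0, maxfev=20000)
        n_inf, n_plus, tau = popt
        mf = (n_inf - n_plus) / (1.0 - n_plus)
        # delta-method error on the mobile fraction from the (n_inf, n_plus)
        # block; grad wrt (n_inf, n_plus)
        g = np.array([1.0 / (1.0 - n_plus),
                      (n_inf - 1.0) / (1.0 - n_plus) ** 2])
        mf_var = float(g @ pcov[:2, :2] @ g)
        # reference-scale systematic: a relative error eps in the t0
        # reference rescales the curve, shifting mf by ~ mf/(1-n_plus)*eps
        mf_var += (mf / (1.0 - n_plus) * self.ref_sigma) ** 2
        return FrapFit(mobile_fraction=float(mf),
                       half_time_s=float(tau * np.log(2.0)),
                       tau_s=float(tau), n_plus=float(n_plus),
                       n_inf=float(n_inf),
                       mobile_fraction_stderr=float(np.sqrt(max(mf_var, 0.0))),
                       tau_stderr=float(np.sqrt(pcov[2, 2])),
                       model="single")

    def _fit_double(self, n_plus0: float) -> FrapFit:
        def f(t, n_inf, a1, tau1, a2, tau2):
            return n_inf - a1 * np.exp(-t / tau1) - a2 * np.exp(-t / tau2)

        span = float(self.n[-5:].mean() - n_plus0)
        p0 = (float(self.n[-5:].mean()), 0.7 * span, self.t[-1] / 10.0,
              0.3 * span, self.t[-1] / 2.0)
        popt, pcov = curve_fit(f, self.t, self.n, p0=p0, maxfev=40000)
        n_inf, a1, tau1, a2, tau2 = popt
        n_plus = n_inf - a1 - a2
        mf = (n_inf - n_plus) / (1.0 - n_plus)
        half = n_plus + 0.5 * (n_inf - n_plus)

        def root(t):
            return f(t, *popt) - half

        t_half = None
        if root(0.0) < 0 < root(self.t[-1] * 10.0):
            t_half = float(brentq(root, 0.0, self.t[-1] * 10.0))
        return FrapFit(mobile_fraction=float(mf), half_time_s=t_half,
                       tau_s=float(max(tau1, tau2)), n_plus=float(n_plus),
                       n_inf=float(n_inf), model="double")


def fit_recovery(time_s: np.ndarray, n_curve: np.ndarray,
                 post_bleach: np.ndarray, model: str = "single",
                 pre_bleach: np.ndarray | None = None) -> FrapFit:
    """Convenience wrapper: build the model and fit in one call."""
    return FrapRecoveryModel(time_s, n_curve, post_bleach,
                             pre_bleach).fit(model)


def classify_mobility(fit: FrapFit, threshold: float = 0.5,
                      horizon_s: float = 120.0) -> str:
    """'liquid-like' iff the fraction recovered within the horizon reaches
    the threshold (inclusive); non-recovering curves are solid-like."""
    if fit.flat or fit.tau_s is None:
        return "solid-like"
    recovered = fit.mobile_fraction * (1.0 - np.exp(-horizon_s / fit.tau_s))
    return "liquid-like" if recovered >= threshold else "solid-like"


@dataclass
class FrapResult:
    """Normalized curve plus kinetics fit and mobility class for one focus."""

    time_s: np.ndarray
    normalized: np.ndarray
    fit: FrapFit
    mobility: str

    def summary(self) -> str:
        return f"{self.fit.summary()}; classified {self.mobility}"


def analyze_trace(trace: FrapTrace, model: str = "single",
                  threshold: float = 0.5,
                  horizon_s: float = 120.0) -> FrapResult:
    """Normalize, fit and classify a single trace."""
    n = normalize_trace(trace)
    fit = fit_recovery(trace.time_s, n, trace.post_bleach, model,
                       pre_bleach=trace.pre_bleach)
    return FrapResult(time_s=trace.time_s, normalized=n, fit=fit,
                      mobility=classify_mobility(fit, threshold, horizon_s))


def read_trace_csv(path) -> FrapTrace:
    """Read a trace CSV with columns time_s, i_bleach, i_total,
    i_background, phase (pre|post)."""
    df = pd.read_csv(path)
    required = {"time_s", "i_bleach", "i_total", "i_background", "phase"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    pre = np.nonzero((df["phase"] == "pre").to_numpy())[0]
    return FrapTrace(time_s=df["time_s"].to_numpy(),
                     i_bleach=df["i_bleach"].to_numpy(),
                     i_total=df["i_total"].to_numpy(),
                     i_background=df["i_background"].to_numpy(),
                     pre_bleach=pre)
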