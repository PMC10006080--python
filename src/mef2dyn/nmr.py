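"""NMR-derived backbone dynamics: shifts, relaxation, spectral densities, DOSY.

Four measurement families describe the 37-residue peptide models:

* Chemical shifts (Cα, Cβ, Hα) are converted to secondary shifts against a
  random-coil reference, then to Random Coil Indices (RCI) and backbone
  order parameters S² in [0, 1] (1 = rigid, 0 = fully flexible).
* ¹⁵N relaxation intensity-vs-delay series are fitted to a monoexponential
  decay, giving per-residue T1 and T2, the rates R1 = 1/T1, R2 = 1/T2 and
  the exchange-sensitive ratio R2/R1.  Only labelled residues (leucines in
  the study design) carry data, so coverage is sparse by construction.
* R1, R2 and the heteronuclear NOE are mapped to the reduced spectral
  densities J(0), J(ωN) and J(0.87 ωH).
* DOSY gradient decays are fitted with the Stejskal–Tanner equation
  I(g) = I0 · exp(−D (γ g δ)² (Δ − δ/3)) for the translational diffusion
  coefficient D (m²/s); fast diffusion indicates compact conformations.

The fits follow the Model → fit() → Results pattern: construct a model from
data, call ``fit()``, read estimates, standard errors and ``summary()`` off
the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "RCI_WEIGHTS",
    "NitrogenConstants",
    "ShiftTable",
    "secondary_shifts",
    "rci_s2",
    "ExponentialDecayModel",
    "DecayFitResult",
    "RelaxationSeries",
    "fit_relaxation_series",
    "relaxation_summary",
    "r2_over_r1",
    "reduced_spectral_density",
    "DosyDecay",
    "StejskalTannerModel",
    "DiffusionResult",
    "dosy_gradient_schedule",
    "T1_DELAYS_MS",
    "T2_DELAYS_MS",
]

#: Longitudinal (T1) relaxation delay schedule, ms.
T1_DELAYS_MS = np.array([10, 20, 40, 80, 120, 160, 200, 300, 400, 600,
                         1200, 2400], dtype=float)
#: Transverse (T2) CPMG pulse-train durations, ms.
T2_DELAYS_MS = np.array([17, 34, 51, 68, 85, 102, 119, 153, 204, 254, 305],
                        dtype=float)

# Package-default per-nucleus weights for the RCI combination and the
# RCI -> S2 map parameters.  The weights reflect the relative sensitivity
# of each nucleus' secondary shift to backbone order (carbons more
# order-sensitive than Halpha); they are configuration, not physics, and
# any alternative set may be passed to rci_s2.  The S2 map gain is chosen
# so the log map stays non-degenerate over the RCI range the floor allows
# (RCI in [~0.3, 1/floor]): S2 spans ~[0.28, 1) rather than saturating.
RCI_WEIGHTS: dict[str, float] = {"CA": 0.74, "CB": 0.72, "HA": 0.20}
_RCI_FLOOR_PPM = 0.02      # floor on the weighted shift before inversion
_S2_SCALE = 0.4            # S2 = 1 - _S2_SCALE * ln(1 + _S2_GAIN * RCI)
_S2_GAIN = 0.1


@dataclass(frozen=True)
class NitrogenConstants:
    """Physical constants of the ¹⁵N-¹H spin pair used in the J mapping."""

    gamma_h: float = 2.6752218744e8     # rad s-1 T-1
    gamma_n: float = -2.7116e7          # rad s-1 T-1 (negative for 15N)
    r_nh: float = 1.02e-10              # m
    csa_ppm: float = -160.0             # 15N chemical-shift anisotropy

    @property
    def dipolar(self) -> float:
        """Dipolar coupling constant d = mu0 hbar gH gN / (4 pi r^3)."""
        mu0_over_4pi = 1.0e-7
        hbar = 1.054571817e-34
        return (mu0_over_4pi * hbar * self.gamma_h * abs(self.gamma_n)
                / self.r_nh ** 3)

    def omegas(self, field_mhz: float) -> tuple[float, float]:
        """(ωH, ωN) angular frequencies in rad/s at the given ¹H field."""
        omega_h = 2.0 * np.pi * field_mhz * 1e6
        omega_n = omega_h * abs(self.gamma_n) / self.gamma_h
        return omega_h, omega_n


N15 = NitrogenConstants()


# ---------------------------------------------------------------------------
# Chemical shifts -> S2


@dataclass
class ShiftTable:
    """Observed and random-coil reference shifts aligned on residues.

    Both frames are indexed by residue number with nucleus columns (a
    subset of CA/CB/HA); missing observations are NaN and stay absent —
    they are never imputed as zero.
    """

    observed: pd.DataFrame
    reference: pd.DataFrame

    def __post_init__(self) -> None:
        common = [c for c in self.observed.columns
                  if c in self.reference.columns]
        if not common:
            raise ValueError("observed and reference share no nucleus columns")
        self.observed = self.observed[common].astype(float)
        self.reference = self.reference.reindex(
            self.observed.index)[common].astype(float)


def secondary_shifts(table: ShiftTable) -> pd.DataFrame:
    """Per-residue secondary shifts Δδ = observed − reference, per nucleus.

    A single scalar offset per nucleus (the median of observed − reference
    over residues with both values) is removed first, so a global
    referencing error leaves Δδ unchanged.  Residues without a reference
    stay NaN.
    """
    raw = table.observed - table.reference
    offsets = raw.median(axis=0, skipna=True)
    return raw - offsets


def rci_s2(secondary: pd.DataFrame,
           weights: Mapping[str, float] | None = None,
           smooth_window: int = 3,
           floor_ppm: float = _RCI_FLOOR_PPM) -> pd.DataFrame:
    """Random Coil Index and order parameter S² from secondary shifts.

    The weighted mean absolute secondary shift of each residue (weights per
    nucleus, NaNs excluded) is smoothed over ``smooth_window`` consecutive
    reported residues, floored at ``floor_ppm`` and inverted to give the
    RCI; S² = 1 − a·ln(1 + b·RCI) (module-level a, b), clamped to [0, 1],
    so S² is monotone non-increasing in RCI.  Residues with no nucleus
    observed are dropped from the output.

    Returns a frame indexed by residue with columns ``rci`` and ``s2``.
    """
    weights = dict(weights or RCI_WEIGHTS)
    cols = [c for c in secondary.columns if c in weights]
    if not cols:
        raise ValueError("no weighted nuclei present in the secondary shifts")
    w = np.array([weights[c] for c in cols])
    absd = secondary[cols].abs().to_numpy()
    mask = ~np.isnan(absd)
    wsum = (mask * w).sum(axis=1)
    keep = wsum > 0
    combined = np.where(keep,
                        np.nansum(absd * w, axis=1) / np.where(keep, wsum, 1.0),
                        np.nan)
    residues = secondary.index[keep]
    values = combined[keep]
    if smooth_window > 1 and values.size > 1:
        half = smooth_window // 2
        smoothed = np.array([values[max(0, i - half):i + half + 1].mean()
                             for i in range(values.size)])
    else:
        smoothed = values
    rci = 1.0 / np.maximum(smoothed, floor_ppm)
    s2 = np.clip(1.0 - _S2_SCALE * np.log1p(_S2_GAIN * rci), 0.0, 1.0)
    return pd.DataFrame({"rci": rci, "s2": s2}, index=residues)


# ---------------------------------------------------------------------------
# Monoexponential relaxation fits


@dataclass
class DecayFitResult:
    """Result of a monoexponential intensity-decay fit.

    ``t`` is the time constant in the units of the input delays (ms here);
    ``success`` is False for degenerate or non-decaying data, in which case
    ``t`` and its error are NaN — never silently clamped.
    """

    t: float
    t_stderr: float
    i0: float
    success: bool
    message: str = ""
    n_points: int = 0

    @property
    def rate(self) -> float:
        """Decay rate in s⁻¹ when delays were in ms."""
        return 1000.0 / self.t

    def summary(self) -> str:
        if not self.success:
            return f"monoexponential fit FAILED: {self.message}"
        return (f"monoexponential fit: T = {self.t:.2f} ± {self.t_stderr:.2f} "
                f"ms  (I0 = {self.i0:.3g}, n = {self.n_points})")


class ExponentialDecayModel:
    """I(t) = I0 · exp(−t / T), fitted by nonlinear least squares.

    Starting values come from a log-linear regression; data that do not
    decay (non-negative log-slope) are flagged as failures.
    """

    def __init__(self, delays_ms: np.ndarray, intensities: np.ndarray):
        self.delays = np.asarray(delays_ms, dtype=float)
        self.intensities = np.asarray(intensities, dtype=float)
        if self.delays.size < 3:
            raise ValueError("need at least 3 delay points")
        if self.delays.size != self.intensities.size:
            raise ValueError("delays and intensities differ in length")
        if np.any(self.delays <= 0) or np.unique(self.delays).size != self.delays.size:
            raise ValueError("delays must be positive and distinct")

    @staticmethod
    def _model(t, i0, tau):
        return i0 * np.exp(-t / tau)

    def fit(self) -> DecayFitResult:
        t, y = self.delays, self.intensities
        # starting values from the positive portion of the trace; noisy
        # near-zero tails (long delays) may legitimately dip below zero
        pos = y > 0
        if pos.sum() < 3:
            return DecayFitResult(np.nan, np.nan, np.nan, False,
                                  "fewer than 3 positive intensities",
                                  t.size)
        slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
        if slope >= 0:
            return DecayFitResult(np.nan, np.nan, np.nan, False,
                                  "intensities do not decay", t.size)
        p0 = (float(np.exp(intercept)), float(-1.0 / slope))
        try:
            popt, pcov = curve_fit(self._model, t, y, p0=p0, maxfev=10000)
        except RuntimeError as err:
            return DecayFitResult(np.nan, np.nan, np.nan, False, str(err),
                                  t.size)
        i0, tau = popt
        if tau <= 0:
            return DecayFitResult(np.nan, np.nan, np.nan, False,
                                  "fit diverged to non-positive T", t.size)
        stderr = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else np.nan
        return DecayFitResult(float(tau), stderr, float(i0), True, "",
                              t.size)


@dataclass
class RelaxationSeries:
    """Per-residue intensity-vs-delay series for one experiment kind.

    ``intensities`` maps residue number -> intensity array aligned with
    ``delays_ms``.  ``kind`` is "T1" or "T2"; ``noe`` optionally carries
    per-residue heteronuclear NOE ratios.
    """

    delays_ms: np.ndarray
    intensities: dict
    kind: str = "T1"
    field_mhz: float = 700.0
    noe: dict | None = None

    def __post_init__(self) -> None:
        self.delays_ms = np.asarray(self.delays_ms, dtype=float)
        if self.delays_ms.size < 3:
            raise ValueError("need at least 3 delay points")
        if self.kind not in ("T1", "T2"):
            raise ValueError("kind must be 'T1' or 'T2'")


def fit_relaxation_series(series: RelaxationSeries) -> dict:
    """Fit every residue's decay; returns residue -> DecayFitResult."""
    return {res: ExponentialDecayModel(series.delays_ms, y).fit()
            for res, y in series.intensities.items()}


def r2_over_r1(t1_ms: float, t2_ms: float) -> float:
    """R2/R1 = T1/T2 — unitless, invariant to intensity scaling."""
    if t1_ms <= 0 or t2_ms <= 0:
        raise ValueError("time constants must be positive")
    return t1_ms / t2_ms


def reduced_spectral_density(r1: float, r2: float, noe: float,
                             field_mhz: float = 700.0,
                             constants: NitrogenConstants = N15
                             ) -> tuple[float, float, float]:
    """Map (R1, R2, NOE) to J(0), J(ωN), J(0.87 ωH), in s/rad.

    Standard three-point reduced mapping: the high-frequency terms
    J(ωH ± ωN) are collapsed onto J(0.87 ωH).  With the cross-relaxation
    rate σ = (NOE − 1) · R1 · γN/γH,

        J(0.87 ωH) = 4σ / (5 d²)
        J(ωN)      = (R1 − 7 d²/4 · J(0.87 ωH)) / (3 d²/4 + c²)
        J(0)       = (R2 − 3(d²/8 + c²/6)·J(ωN) − 13 d²/8 · J(0.87 ωH))
                     / (d²/2 + 2 c²/3)

    where d is the ¹⁵N-¹H dipolar constant and c = ωN·Δσ/√3 the CSA term.
    Negative outputs are physically impossible and indicate inconsistent
    rates; they are reported as-is for the caller to flag.
    """
    if r1 <= 0 or r2 <= 0:
        raise ValueError("relaxation rates must be positive")
    d = constants.dipolar
    _, omega_n = constants.omegas(field_mhz)
    c = omega_n * abs(constants.csa_ppm) * 1e-6 / np.sqrt(3.0)
    d2, c2 = d * d, c * c
    sigma = (noe - 1.0) * r1 * constants.gamma_n / constants.gamma_h
    j_h = 4.0 * sigma / (5.0 * d2)
    j_n = (r1 - 7.0 * d2 / 4.0 * j_h) / (3.0 * d2 / 4.0 + c2)
    j_0 = ((r2 - 3.0 * (d2 / 8.0 + c2 / 6.0) * j_n - 13.0 * d2 / 8.0 * j_h)
           / (d2 / 2.0 + 2.0 * c2 / 3.0))
    return float(j_0), float(j_n), float(j_h)


def relaxation_summary(t1_fits: Mapping[int, DecayFitResult],
                       t2_fits: Mapping[int, DecayFitResult],
                       noe: Mapping[int, float] | None = None,
                       field_mhz: float = 700.0) -> pd.DataFrame:
    """Combine per-residue T1/T2 fits into rates, ratios and J values.

    Residues missing either fit (or whose fit failed) are dropped; J values
    require the NOE and stay NaN without it.  Times are ms, rates s⁻¹,
    spectral densities s/rad.
    """
    rows = []
    for res in sorted(set(t1_fits) & set(t2_fits)):
        f1, f2 = t1_fits[res], t2_fits[res]
        if not (f1.success and f2.success):
            continue
        r1, r2 = f1.rate, f2.rate
        row = dict(residue=res, t1_ms=f1.t, t1_stderr=f1.t_stderr,
                   t2_ms=f2.t, t2_stderr=f2.t_stderr, r1=r1, r2=r2,
                   r2_over_r1=r2_over_r1(f1.t, f2.t),
                   j0=np.nan, j_wn=np.nan, j_wh=np.nan)
        if noe is not None and res in noe:
            row["j0"], row["j_wn"], row["j_wh"] = reduced_spectral_density(
                r1, r2, noe[res], field_mhz)
        rows.append(row)
    return pd.DataFrame(rows).set_index("residue") if rows else pd.DataFrame()


# ---------------------------------------------------------------------------
# DOSY


def dosy_gradient_schedule(n_increments: int = 32,
                           g_max_gcm: float = 57.7,
                           lo: float = 0.05, hi: float = 0.95) -> np.ndarray:
    """Linear gradient-strength ramp (G/cm), 5–95 % of the probe maximum."""
    return np.linspace(lo * g_max_gcm, hi * g_max_gcm, n_increments)


@dataclass
class DosyDecay:
    """Signal intensity versus gradient strength for one species.

    ``delta_s`` is the gradient-pulse length δ, ``big_delta_s`` the
    diffusion delay Δ (seconds); ``gamma`` the gyromagnetic ratio of the
    observed nucleus (rad s⁻¹ T⁻¹, ¹H by default).
    """

    gradients_gcm: np.ndarray
    intensities: np.ndarray
    delta_s: float = 2e-3
    big_delta_s: float = 75e-3
    gamma: float = N15.gamma_h

    def __post_init__(self) -> None:
        self.gradients_gcm = np.asarray(self.gradients_gcm, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.gradients_gcm.size != self.intensities.size:
            raise ValueError("gradients and intensities differ in length")
        if np.any(np.diff(self.gradients_gcm) <= 0):
            raise ValueError("gradient strengths must be strictly increasing")
        if np.any(self.intensities <= 0):
            raise ValueError("intensities must be positive")

    def b_values(self) -> np.ndarray:
        """Stejskal–Tanner b = (γ g δ)² (Δ − δ/3) in s/m²  (g: G/cm → T/m)."""
        g_tm = self.gradients_gcm * 1e-2
        return ((self.gamma * g_tm * self.delta_s) ** 2
                * (self.big_delta_s - self.delta_s / 3.0))


@dataclass
class DiffusionResult:
    """Fitted translational diffusion coefficient."""

    d: float                  # m^2/s
    d_stderr: float
    i0: float
    success: bool
    method: str = "log"
    message: str = ""

    def summary(self) -> str:
        if not self.success:
            return f"Stejskal-Tanner fit FAILED: {self.message}"
        return (f"Stejskal-Tanner fit ({self.method}): "
                f"D = {self.d:.3e} ± {self.d_stderr:.2e} m^2/s")


class StejskalTannerModel:
    """Fit I(g) = I0 · exp(−D·b(g)) for the diffusion coefficient D.

    The default fit works in the log-intensity domain by weighted least
    squares (weights ∝ I², the correct propagation of additive intensity
    noise); ``method="nonlinear"`` performs the raw-domain fit instead.
    """

    def __init__(self, decay: DosyDecay):
        if decay.gradients_gcm.size < 5:
            raise ValueError("need at least 5 gradient points")
        self.decay = decay

    def fit(self, method: str = "log") -> DiffusionResult:
        b = self.decay.b_values()
        y = self.decay.intensities
        if method == "log":
            return self._fit_log(b, y)
        if method == "nonlinear":
            return self._fit_nonlinear(b, y)
        raise ValueError(f"unknown method {method!r}")

    def _fit_log(self, b: np.ndarray, y: np.ndarray) -> DiffusionResult:
        ly = np.log(y)
        w = y ** 2
        X = np.column_stack([np.ones_like(b), -b])
        WX = X * w[:, None]
        xtx = X.T @ WX
        beta = np.linalg.solve(xtx, WX.T @ ly)
        resid = ly - X @ beta
        dof = max(b.size - 2, 1)
        sigma2 = float((w * resid ** 2).sum() / dof)
        cov = sigma2 * np.linalg.inv(xtx)
        d_hat = float(beta[1])
        stderr = float(np.sqrt(cov[1, 1]))
        if d_hat <= 0:
            return DiffusionResult(np.nan, np.nan, np.nan, False, "log",
                                   "decay fits to non-positive D")
        return DiffusionResult(d_hat, stderr, float(np.exp(beta[0])), True,
                               "log")

    def _fit_nonlinear(self, b: np.ndarray, y: np.ndarray) -> DiffusionResult:
        log_fit = self._fit_log(b, y)
        if not log_fit.success:
            return DiffusionResult(np.nan, np.nan, np.nan, False, "nonlinear",
                                   log_fit.message)
        p0 = (log_fit.i0, log_fit.d)
        try:
            popt, pcov = curve_fit(lambda bb, i0, d: i0 * np.exp(-d * bb),
                                   b, y, p0=p0, maxfev=10000)
        except RuntimeError as err:
            return DiffusionResult(np.nan, np.nan, np.nan, False, "nonlinear",
                                   str(err))
        i0, d_hat = popt
        if d_hat <= 0:
            return DiffusionResult(np.nan, np.nan, np.nan, False, "nonlinear",
                                   "fit diverged to non-positive D")
        return DiffusionResult(float(d_hat), float(np.sqrt(pcov[1, 1])),
                               float(i0), True, "nonlinear")
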