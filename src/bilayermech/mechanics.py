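"""Bilayer mechanics: surface tension, area per lipid, and the area
compressibility modulus K_A.

The workflow mirrors the tension-sweep protocol used for atomistic
bilayers: a membrane is simulated at several imposed surface tensions γ
(here −7, 0, 7 and 15 mN/m), the per-frame surface tension follows from
the pressure-tensor anisotropy,

    γ = Lz · (Pzz − (Pxx + Pyy)/2),

and K_A is the slope of γ against the fractional area strain
ε_A = (⟨A⟩ − ⟨A⟩₀)/⟨A⟩₀, with ⟨A⟩₀ the mean area per lipid at γ = 0.
Because bilayer areas are strongly autocorrelated in time, the standard
error of each ⟨A⟩ uses the statistical inefficiency g = 1 + 2τ estimated
from the integrated autocorrelation time τ.

The fit is exposed statsmodels-style: build an
:class:`AreaCompressibilityModel` from per-tension area series (or a
DataFrame), call :meth:`~AreaCompressibilityModel.fit`, and read the
estimates off the returned :class:`AreaCompressibilityResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.fft
import statsmodels.api as sm
from scipy import stats

from .frames import BoxedFrame

__all__ = [
    "surface_tension",
    "area_per_lipid",
    "autocorr_sem",
    "GammaAreaPoint",
    "GammaAreaSeries",
    "AreaCompressibilityModel",
    "AreaCompressibilityResults",
    "fit_area_compressibility",
    "percent_reduction",
]

#: bar·Å → mN/m  (1 bar = 1e5 Pa; 1 Å = 1e-10 m; 1e-5 N/m = 1e-2 mN/m)
BAR_ANGSTROM_TO_MN_PER_M = 0.01


def surface_tension(pressure, lz) -> np.ndarray | float:
    """Surface tension from the diagonal pressure tensor, in mN/m.

    Parameters
    ----------
    pressure : array_like (..., 3)
        (Pxx, Pyy, Pzz) in bar; vectorised over leading dimensions.
    lz : float or array_like
        Box height in Å.
    """
    p = np.asarray(pressure, dtype=float)
    lz = np.asarray(lz, dtype=float)
    if np.any(lz <= 0):
        raise ValueError("Lz must be positive")
    gamma = BAR_ANGSTROM_TO_MN_PER_M * lz * (p[..., 2] - 0.5 * (p[..., 0] + p[..., 1]))
    return float(gamma) if gamma.ndim == 0 else gamma


def area_per_lipid(frames: Sequence[BoxedFrame] | np.ndarray, lipids_per_leaflet: int) -> np.ndarray:
    """Per-frame lateral box area divided by the leaflet lipid count (Å²).

    ``frames`` may be a sequence of :class:`BoxedFrame` or an (n, 2)
    array of (Lx, Ly) pairs.
    """
    if lipids_per_leaflet <= 0:
        raise ValueError("lipids_per_leaflet must be positive")
    if len(frames) and isinstance(frames[0], BoxedFrame):
        areas = np.array([f.box[0] * f.box[1] for f in frames])
    else:
        arr = np.asarray(frames, dtype=float)
        areas = arr[:, 0] * arr[:, 1]
    return areas / lipids_per_leaflet


def autocorr_sem(series) -> tuple[float, float, float]:
    """Mean, autocorrelation-corrected SEM, and integrated τ of a series.

    The normalised autocovariance is summed from lag 1 until its first
    non-positive value (initial-positive-sequence truncation), giving the
    integrated autocorrelation time τ and statistical inefficiency
    g = 1 + 2τ; the SEM is ``sd · sqrt(g / N)``. A constant series returns
    (value, 0, 0).
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("autocorr_sem needs at least 10 samples")
    mu = float(x.mean())
    dx = x - mu
    c0 = float(dx @ dx) / n
    if c0 == 0.0 or not np.isfinite(c0):
        return mu, 0.0, 0.0
    m = scipy.fft.next_fast_len(2 * n)
    f = scipy.fft.rfft(dx, m)
    acov = scipy.fft.irfft(f * np.conj(f), m)[:n] / n
    c = acov / acov[0]
    nonpos = np.flatnonzero(c[1:] <= 0.0)
    stop = int(nonpos[0]) + 1 if nonpos.size else n
    tau = float(c[1:stop].sum())
    tau = max(tau, 0.0)
    g = 1.0 + 2.0 * tau
    sd = float(x.std(ddof=1))
    sem = sd * np.sqrt(g / n)
    return mu, float(sem), tau


def percent_reduction(value: float, reference: float) -> float:
    """Percentage by which ``value`` falls below ``reference``."""
    return 100.0 * (1.0 - value / reference)


@dataclass
class GammaAreaPoint:
    """Area-per-lipid statistics of one imposed-tension simulation."""

    gamma: float  # mN/m
    series: np.ndarray  # Å² per frame
    mean_apl: float  # Å²
    sem_apl: float  # Å²
    tau: float  # frames

    @classmethod
    def from_series(cls, gamma: float, series, discard_fraction: float = 0.0) -> "GammaAreaPoint":
        arr = np.asarray(series, dtype=float)
        if not 0.0 <= discard_fraction < 1.0:
            raise ValueError("discard_fraction must be in [0, 1)")
        arr = arr[int(round(discard_fraction * arr.size)):]
        if arr.size < 2:
            raise ValueError("area series needs at least 2 frames")
        mean, sem, tau = autocorr_sem(arr)
        return cls(gamma=float(gamma), series=arr, mean_apl=mean, sem_apl=sem, tau=tau)


@dataclass
class GammaAreaSeries:
    """Collection of per-tension area series feeding the K_A fit."""

    points: list[GammaAreaPoint]

    @classmethod
    def from_series(cls, series_by_gamma: Mapping[float, Iterable[float]],
                    discard_fraction: float = 0.0) -> "GammaAreaSeries":
        pts = [GammaAreaPoint.from_series(g, s, discard_fraction)
               for g, s in sorted(series_by_gamma.items())]
        return cls(points=pts)

    @property
    def gammas(self) -> np.ndarray:
        return np.array([p.gamma for p in self.points])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gamma": self.gammas,
                "mean_apl": [p.mean_apl for p in self.points],
                "sem_apl": [p.sem_apl for p in self.points],
                "tau": [p.tau for p in self.points],
                "n_frames": [p.series.size for p in self.points],
            }
        )


@dataclass
class AreaCompressibilityResults:
    """K_A fit results.

    ``K_A`` is the slope of the weighted regression of γ on area strain,
    in mN/m; ``K_A_se`` its standard error from the (unscaled) weighted
    covariance, treating the propagated strain SEMs as known; ``A0`` the
    reference area per lipid at γ = 0 in Å².
    """

    K_A: float
    K_A_se: float
    A0: float
    intercept: float
    intercept_se: float
    r_squared: float
    strain: np.ndarray
    strain_se: np.ndarray
    gammas: np.ndarray
    nobs: int
    method: str = "analytic"

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        """Normal-theory confidence interval for K_A."""
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        return self.K_A - z * self.K_A_se, self.K_A + z * self.K_A_se

    def to_dict(self) -> dict:
        return {
            "K_A_mN_per_m": self.K_A,
            "K_A_se_mN_per_m": self.K_A_se,
            "A0_A2": self.A0,
            "intercept_mN_per_m": self.intercept,
            "intercept_se_mN_per_m": self.intercept_se,
            "r_squared": self.r_squared,
            "n_points": self.nobs,
            "method": self.method,
        }

    def summary(self) -> str:
        lo, hi = self.conf_int()
        lines = [
            "Area compressibility fit (γ vs area strain)",
            "=" * 47,
            f"K_A            {self.K_A:12.3f} ± {self.K_A_se:.3f} mN/m",
            f"95% CI         [{lo:.3f}, {hi:.3f}] mN/m",
            f"A0 (γ=0)       {self.A0:12.3f} Å²",
            f"intercept      {self.intercept:12.4f} ± {self.intercept_se:.4f} mN/m",
            f"R²             {self.r_squared:12.4f}",
            f"points         {self.nobs:6d}   method: {self.method}",
            "-" * 47,
            f"{'γ (mN/m)':>10} {'strain':>12} {'strain se':>12}",
        ]
        for g, e, s in zip(self.gammas, self.strain, self.strain_se):
            lines.append(f"{g:>10.2f} {e:>12.3e} {s:>12.3e}")
        return "\n".join(lines)


class AreaCompressibilityModel:
    """Weighted linear model γ = K_A · ε_A + c for the tension sweep.

    γ is imposed exactly by the barostat, so the measurement error lives
    in the strain; the fit converts each strain SEM into an effective γ
    uncertainty via a preliminary slope and refines once (errors-in-x
    folded into y). Requires ≥ 3 distinct tensions including γ = 0,
    which anchors the reference area A0.
    """

    def __init__(self, series: GammaAreaSeries):
        gammas = series.gammas
        if len(np.unique(np.round(gammas, 9))) != len(gammas):
            raise ValueError("duplicate γ values; merge their series first")
        if len(gammas) < 3:
            raise ValueError("need at least 3 distinct surface tensions")
        if not np.any(np.isclose(gammas, 0.0, atol=1e-9)):
            raise ValueError("a γ = 0 point is required to define the reference area A0")
        self.series = series

    @classmethod
    def from_areas(cls, series_by_gamma: Mapping[float, Iterable[float]],
                   discard_fraction: float = 0.0) -> "AreaCompressibilityModel":
        return cls(GammaAreaSeries.from_series(series_by_gamma, discard_fraction))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, gamma_col: str = "gamma",
                       area_col: str = "area_per_lipid",
                       discard_fraction: float = 0.0) -> "AreaCompressibilityModel":
        """Build from long-format per-frame data (one row per frame)."""
        series = {float(g): sub[area_col].to_numpy() for g, sub in df.groupby(gamma_col)}
        return cls.from_areas(series, discard_fraction)

    def fit(self, method: str = "analytic", n_boot: int = 500, seed: int | None = None
            ) -> AreaCompressibilityResults:
        pts = self.series.points
        g = np.array([p.gamma for p in pts])
        m = np.array([p.mean_apl for p in pts])
        s = np.array([p.sem_apl for p in pts])
        i0 = int(np.flatnonzero(np.isclose(g, 0.0, atol=1e-9))[0])
        a0 = m[i0]
        eps = m / a0 - 1.0
        s_eps = s / a0

        slope, intercept, se, ise, r2 = self._wls(g, eps, s_eps)
        if method == "bootstrap":
            rng = np.random.default_rng(seed)
            reps = np.empty(n_boot)
            for b in range(n_boot):
                mb = rng.normal(m, s)
                a0b = mb[i0]
                epsb = mb / a0b - 1.0
                reps[b] = self._wls(g, epsb, s_eps)[0]
            se = float(reps.std(ddof=1))
        elif method != "analytic":
            raise ValueError(f"unknown method {method!r}")

        return AreaCompressibilityResults(
            K_A=slope, K_A_se=se, A0=float(a0), intercept=intercept, intercept_se=ise,
            r_squared=r2, strain=eps, strain_se=s_eps, gammas=g, nobs=len(g), method=method,
        )

    @staticmethod
    def _wls(g, eps, s_eps):
        X = sm.add_constant(eps)
        if np.allclose(s_eps, 0.0):
            res = sm.OLS(g, X).fit()
            cov = res.cov_params()
        else:
            slope = sm.OLS(g, X).fit().params[1]  # preliminary, for error conversion
            res = cov = None
            for _ in range(2):  # one refinement of the converted weights
                sig = np.abs(slope) * s_eps
                # a zero-SEM point would get infinite weight; floor it relative to the rest
                sig = np.maximum(sig, 1e-12 * sig.max()) if sig.max() > 0 else np.ones_like(sig)
                res = sm.WLS(g, X, weights=1.0 / sig**2).fit()
                slope = res.params[1]
            cov = res.cov_params(scale=1.0)  # absolute weights: no MSE rescaling
        cov = np.asarray(cov)
        return (float(res.params[1]), float(res.params[0]),
                float(np.sqrt(cov[1, 1])), float(np.sqrt(cov[0, 0])),
                float(res.rsquared))


def fit_area_compressibility(series: GammaAreaSeries, **fit_kwargs) -> AreaCompressibilityResults:
    """Convenience wrapper: fit K_A from a :class:`GammaAreaSeries`."""
    return AreaCompressibilityModel(series).fit(**fit_kwargs)
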