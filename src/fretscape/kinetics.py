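"""Auxiliary fits: disulfide-formation kinetics and equilibrium binding.

Disulfide crosslinking time courses follow a single-exponential approach
to a final extent; binding isotherms measured by fluorescence anisotropy
follow the Hill equation for a single site. Both are fit per replicate by
nonlinear least squares, with across-replicate means and SEMs reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = ["ExponentialKinetics", "ExpFitResult", "HillBinding",
           "HillFitResult", "fit_exponential", "fit_hill"]


def _exp_model(t, k, y0, yf):
    return yf - (yf - y0) * np.exp(-k * t)


def _hill_model(c, kd, n, a0, amax):
    cn = np.power(np.maximum(c, 0.0), n)
    return a0 + (amax - a0) * cn / (kd**n + cn)


@dataclass
class ExpFitResult:
    rate: float
    y0: float
    yf: float
    rate_sd: float
    y0_sd: float
    yf_sd: float
    replicate_rates: np.ndarray
    rate_sem: float
    yf_sem: float
    non_monotone_flag: bool = False

    def summary(self) -> str:
        return (f"single-exponential fit: k = {self.rate:.4g} +/- "
                f"{self.rate_sd:.2g} (SEM {self.rate_sem:.2g}), "
                f"y0 = {self.y0:.3f}, yf = {self.yf:.3f}"
                + ("  [non-monotone trend]" if self.non_monotone_flag else ""))


class ExponentialKinetics:
    """Single-exponential kinetics model y(t) = yf - (yf - y0) exp(-k t)."""

    def __init__(self, times, fractions, replicates=None):
        self.times = np.asarray(times, float)
        self.fractions = np.asarray(fractions, float)
        if self.times.size < 4:
            raise ValueError("need at least four time points")
        self.replicates = (np.zeros(self.times.size, dtype=int)
                           if replicates is None
                           else np.asarray(replicates, int))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame):
        rep = df["replicate"] if "replicate" in df else None
        return cls(df["time"], df["fraction"], rep)

    def _fit_one(self, t, y):
        k0 = 1.0 / max(t.mean(), 1e-9)
        p0 = [k0, float(y[np.argmin(t)]), float(y[np.argmax(t)])]
        popt, pcov = curve_fit(_exp_model, t, y, p0=p0,
                               bounds=([0, -0.5, -0.5], [np.inf, 1.5, 1.5]),
                               maxfev=5000)
        return popt, np.sqrt(np.diag(pcov))

    def fit(self) -> ExpFitResult:
        reps = np.unique(self.replicates)
        per_rep = []
        for r in reps:
            m = self.replicates == r
            per_rep.append(self._fit_one(self.times[m], self.fractions[m]))
        params = np.array([p for p, _ in per_rep])
        sds = np.array([s for _, s in per_rep])
        mean = params.mean(axis=0)
        sem = (params.std(axis=0, ddof=1) / np.sqrt(len(reps))
               if len(reps) > 1 else np.zeros(3))
        # monotone-trend check on the pooled data (flag only; fit is returned)
        order = np.argsort(self.times)
        yy = self.fractions[order]
        rising = mean[2] >= mean[1]
        diffs = np.diff(pd.Series(yy).rolling(3, min_periods=1).mean())
        frac_against = np.mean(diffs < 0 if rising else diffs > 0)
        return ExpFitResult(
            rate=float(mean[0]), y0=float(mean[1]), yf=float(mean[2]),
            rate_sd=float(sds[:, 0].mean()), y0_sd=float(sds[:, 1].mean()),
            yf_sd=float(sds[:, 2].mean()),
            replicate_rates=params[:, 0], rate_sem=float(sem[0]),
            yf_sem=float(sem[2]), non_monotone_flag=bool(frac_against > 0.45))


@dataclass
class HillFitResult:
    kd: float
    n_hill: float
    a0: float
    amax: float
    kd_ci: tuple
    n_ci: tuple
    saturating: bool
    kd_is_lower_bound: bool

    def normalized(self, concentrations) -> np.ndarray:
        """Isotherm normalized to the fitted saturation anisotropy."""
        return _hill_model(np.asarray(concentrations, float), self.kd,
                           self.n_hill, self.a0, self.amax) / self.amax

    def summary(self) -> str:
        kd_s = (f"> {self.kd:.3g} uM (lower bound; no saturation in range)"
                if self.kd_is_lower_bound else
                f"{self.kd:.3g} uM (95% CI {self.kd_ci[0]:.3g}"
                f"-{self.kd_ci[1]:.3g})")
        return (f"Hill fit: KD = {kd_s}, n = {self.n_hill:.2f}, "
                f"A0 = {self.a0:.4f}, Amax = {self.amax:.4f}")


class HillBinding:
    """Hill-equation binding model A(c) = A0 + (Amax-A0) c^n/(KD^n + c^n)."""

    def __init__(self, concentrations, anisotropies, replicates=None):
        self.conc = np.asarray(concentrations, float)
        self.aniso = np.asarray(anisotropies, float)
        if np.any(self.conc < 0):
            raise ValueError("concentrations must be nonnegative")
        pos = self.conc[self.conc > 0]
        if pos.size and pos.max() / pos.min() < 10:
            raise ValueError("concentrations must span at least one decade")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame):
        return cls(df["conc_uM"], df["anisotropy"],
                   df.get("replicate"))

    def fit(self, fix_n: Optional[float] = None) -> HillFitResult:
        c, a = self.conc, self.aniso
        a0_0, amax_0 = float(a[np.argmin(c)]), float(a[np.argmax(c)])
        kd0 = float(np.median(c[c > 0]))
        if fix_n is not None:
            def f(cc, kd, a0, amax):
                return _hill_model(cc, kd, fix_n, a0, amax)
            p0 = [kd0, a0_0, amax_0]
            bounds = ([1e-6, -1, -1], [1e6, 2, 2])
        else:
            f = _hill_model
            p0 = [kd0, 1.0, a0_0, amax_0]
            bounds = ([1e-6, 0.1, -1, -1], [1e6, 10, 2, 2])
        popt, pcov = curve_fit(f, c, a, p0=p0, bounds=bounds, maxfev=10000)
        sd = np.sqrt(np.diag(pcov))
        kd = float(popt[0])
        n = fix_n if fix_n is not None else float(popt[1])
        n_sd = 0.0 if fix_n is not None else float(sd[1])
        a0 = float(popt[-2])
        amax = float(popt[-1])
        saturating = kd < c.max()
        return HillFitResult(
            kd=kd, n_hill=n, a0=a0, amax=amax,
            kd_ci=(kd - 1.96 * sd[0], kd + 1.96 * sd[0]),
            n_ci=(n - 1.96 * n_sd, n + 1.96 * n_sd),
            saturating=saturating, kd_is_lower_bound=not saturating)


def fit_exponential(times, fractions, replicates=None) -> ExpFitResult:
    return ExponentialKinetics(times, fractions, replicates).fit()


def fit_hill(concentrations, anisotropies,
             fix_n: Optional[float] = None) -> HillFitResult:
    return HillBinding(concentrations, anisotropies).fit(fix_n=fix_n)
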