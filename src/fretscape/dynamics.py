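"""Exchange dynamics: photon distribution analysis and filtered FCS.

PDA fits windowed FRET-efficiency (proximity-ratio) histograms with
shot-noise-exact models: static limiting states produce binomial photon
splitting at fixed efficiency, while a dynamic component mixes the two
limiting efficiencies through the occupancy-time distribution of a
two-state telegraph switch within the window (sampled by seeded
Monte-Carlo).

Filtered FCS builds per-TCSPC-bin statistical filters from the limiting
states' decay patterns, computes species auto-/cross-correlation curves
with a multiple-tau estimator, and decomposes the relaxation into fixed
decades at 1e-5, 1e-4 and 1e-3 s whose amplitudes are ranked
major/middle/minor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize

from .core import PhotonStream, check_seed

__all__ = [
    "pda_histogram", "PdaHistogram", "PdaModel", "PdaResult",
    "telegraph_occupancy", "ffcs_filters", "ffcs_correlate",
    "CorrelationCurve", "FfcsModel", "FfcsResult", "RelaxationSpectrum",
]

RELAXATION_DECADES_S = (1e-5, 1e-4, 1e-3)


# ---------------------------------------------------------------------------
# PDA
# ---------------------------------------------------------------------------

@dataclass
class PdaHistogram:
    """Windowed proximity-ratio histogram with its photon-count marginal."""

    window_s: float
    edges: np.ndarray          # proximity-ratio bin edges
    counts: np.ndarray         # windows per bin
    photon_counts: np.ndarray  # total photons per window (marginal)
    proximity: np.ndarray      # per-window proximity ratio

    @property
    def n_windows(self):
        return self.proximity.size


def pda_histogram(stream: PhotonStream, window_ms: float = 2.0,
                  n_bins: int = 40, min_photons: int = 10,
                  bursts=None) -> PdaHistogram:
    """Cut donor-excitation photons into fixed time windows and histogram
    the per-window proximity ratio N_red / (N_red + N_green).

    With a burst table (from :func:`~fretscape.bursts.select_bursts`),
    windows are tiled within each burst instead of across the whole
    stream, so every window holds photons from a single molecule.
    """
    if window_ms <= 0:
        raise ValueError("window must be positive")
    w = window_ms * 1e-3
    dex = stream.donor_window
    t = stream.macro_times[dex]
    red = stream.is_red[dex]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    if t.size == 0:
        return PdaHistogram(w, edges, np.zeros(n_bins, int),
                            np.empty(0, int), np.empty(0))
    if bursts is None:
        idx = np.floor(t / w).astype(np.int64)
    else:
        idx = np.full(t.size, -1, dtype=np.int64)
        n_win = 0
        for _, b in bursts.iterrows():
            t0, t1 = b["t_start"], b["t_stop"]
            k = int((t1 - t0) / w)  # full windows inside the burst
            if k < 1:
                continue
            sel = (t >= t0) & (t < t0 + k * w)
            idx[sel] = n_win + np.floor((t[sel] - t0) / w).astype(np.int64)
            n_win += k
        t, red, idx = t[idx >= 0], red[idx >= 0], idx[idx >= 0]
        if t.size == 0:
            return PdaHistogram(w, edges, np.zeros(n_bins, int),
                                np.empty(0, int), np.empty(0))
    n_win = int(idx.max()) + 1
    n_tot = np.bincount(idx, minlength=n_win)
    n_red = np.bincount(idx, weights=red.astype(float), minlength=n_win)
    keep = n_tot >= max(min_photons, 1)
    prox = n_red[keep] / n_tot[keep]
    counts, _ = np.histogram(prox, bins=edges)
    return PdaHistogram(w, edges, counts, n_tot[keep].astype(int), prox)


def telegraph_occupancy(rng, k12: float, k21: float, window: float,
                        n_draws: int) -> np.ndarray:
    """Monte-Carlo fraction of the window spent in state 1 for a two-state
    telegraph process started from its stationary distribution."""
    if k12 <= 0 and k21 <= 0:
        s0 = (rng.random(n_draws) >= 0.5)
        return np.where(s0, 0.0, 1.0)
    p1 = k21 / (k12 + k21)
    state = (rng.random(n_draws) >= p1).astype(np.int8)  # 0 = state 1
    t_in_1 = np.zeros(n_draws)
    t_now = np.zeros(n_draws)
    active = np.ones(n_draws, dtype=bool)
    rates = np.array([k12, k21])
    while active.any():
        idx = np.flatnonzero(active)
        r = rates[state[idx]]
        dwell = rng.exponential(1.0, idx.size) / np.maximum(r, 1e-300)
        end = np.minimum(t_now[idx] + dwell, window)
        in1 = state[idx] == 0
        t_in_1[idx[in1]] += (end - t_now[idx])[in1]
        t_now[idx] = end
        state[idx] = 1 - state[idx]
        active[idx] = end < window
    return t_in_1 / window


class PdaModel:
    """Shot-noise-exact fit of proximity-ratio histograms.

    The model has two static limiting states at fixed efficiencies
    ``e_states`` plus one dynamic population exchanging between them; free
    parameters are the three fractions and the two exchange rates. Fitting
    multiple window sizes jointly makes the rates identifiable.
    """

    def __init__(self, histograms: Sequence[PdaHistogram],
                 e_states: Tuple[float, float],
                 n_draws: int = 100_000, seed: int = 0):
        hs = list(histograms)
        if not hs:
            raise ValueError("need at least one PDA histogram")
        self.histograms = hs
        self.e1, self.e2 = e_states
        self.n_draws = int(n_draws)
        self.seed = check_seed(seed)
        # exchange slower than the largest window is indistinguishable from
        # a static mixture; bound the rates away from that degeneracy
        wmax = max(h.window_s for h in hs)
        wmin = min(h.window_s for h in hs)
        self.log_rate_bounds = (np.log10(0.5 / wmax), np.log10(100.0 / wmin))

    def _model_hist(self, h: PdaHistogram, f_s1, f_s2, k12, k21, rng):
        """Monte-Carlo model probability per proximity-ratio bin, using the
        observed photon-count marginal (shot noise is binomial per window)."""
        n_mc = self.n_draws
        ns = rng.choice(h.photon_counts, size=n_mc)
        u = rng.random(n_mc)
        eff = np.empty(n_mc)
        s1 = u < f_s1
        s2 = (u >= f_s1) & (u < f_s1 + f_s2)
        dyn = ~(s1 | s2)
        eff[s1] = self.e1
        eff[s2] = self.e2
        nd = int(dyn.sum())
        if nd:
            occ = telegraph_occupancy(rng, k12, k21, h.window_s, nd)
            eff[dyn] = occ * self.e1 + (1.0 - occ) * self.e2
        red = rng.binomial(ns, np.clip(eff, 0.0, 1.0))
        prox = red / np.maximum(ns, 1)
        p, _ = np.histogram(prox, bins=h.edges)
        p = p.astype(float) + 0.5  # light regularization of empty bins
        return p / p.sum()

    def _objective(self, params):
        f1, f2, lk12, lk21 = params
        f1, f2 = np.clip(f1, 0, 1), np.clip(f2, 0, 1)
        if f1 + f2 > 1:
            return 1e6 * (f1 + f2)
        lo, hi = self.log_rate_bounds
        if not (lo <= lk12 <= hi and lo <= lk21 <= hi):
            return 1e6 * (1 + abs(lk12) + abs(lk21))
        rng = np.random.default_rng(self.seed)  # common random numbers
        dev = 0.0
        for h in self.histograms:
            p = self._model_hist(h, f1, f2, 10.0**lk12, 10.0**lk21, rng)
            obs = h.counts.astype(float)
            dev += -2.0 * np.sum(obs * np.log(np.maximum(p, 1e-300)))
        return dev

    def fit(self, x0: Optional[Sequence[float]] = None,
            de_iterations: int = 25,
            parsimony_margin: float = 10.0) -> "PdaResult":
        """Global fit by seeded differential evolution (the Monte-Carlo
        objective is deterministic per parameter set but rough, which
        stalls simplex methods) followed by a Nelder-Mead polish.

        A dynamic component that is very fast and strongly one-sided, or
        slower than every window, is indistinguishable from a static
        state; to resolve that ridge a static-only model is fit alongside
        and preferred unless the dynamic component lowers the deviance by
        more than ``parsimony_margin``.
        """
        from scipy.optimize import differential_evolution, minimize_scalar
        lo, hi = self.log_rate_bounds
        bounds = [(0.0, 1.0), (0.0, 1.0), (lo, hi), (lo, hi)]
        de = differential_evolution(
            self._objective, bounds, seed=self.seed, maxiter=de_iterations,
            popsize=8, tol=1e-4, polish=False, init="sobol",
            x0=np.asarray(x0, float) if x0 is not None else None)
        sol = minimize(self._objective, de.x, method="Nelder-Mead",
                       options={"xatol": 1e-3, "fatol": 0.05,
                                "maxfev": 200})
        if de.fun < sol.fun:
            sol = de
        mid = 0.5 * (lo + hi)
        static = minimize_scalar(
            lambda f1: self._objective([f1, 1.0 - f1, mid, mid]),
            bounds=(0.0, 1.0), method="bounded",
            options={"xatol": 1e-3})
        if static.fun - sol.fun < parsimony_margin:
            f1 = float(static.x)
            return PdaResult(model=self, fractions=(f1, 1.0 - f1, 0.0),
                             k12=np.nan, k21=np.nan,
                             deviance=float(static.fun), converged=True)
        f1, f2, lk12, lk21 = sol.x
        f1, f2 = float(np.clip(f1, 0, 1)), float(np.clip(f2, 0, 1))
        return PdaResult(model=self, fractions=(f1, f2, max(1 - f1 - f2, 0.0)),
                         k12=float(10.0**lk12), k21=float(10.0**lk21),
                         deviance=float(sol.fun), converged=bool(sol.success))


@dataclass
class PdaResult:
    """Fitted PDA model: (static1, static2, dynamic) fractions and rates."""

    model: PdaModel
    fractions: Tuple[float, float, float]
    k12: float
    k21: float
    deviance: float
    converged: bool

    @property
    def dynamic_fraction(self) -> float:
        return self.fractions[2]

    @property
    def relaxation_rate(self) -> float:
        return self.k12 + self.k21

    def summary(self) -> str:
        f = self.fractions
        return ("PDA fit\n"
                f"  static state 1 (E={self.model.e1:.2f}): {f[0]:.3f}\n"
                f"  static state 2 (E={self.model.e2:.2f}): {f[1]:.3f}\n"
                f"  dynamic fraction: {f[2]:.3f}\n"
                f"  k12 = {self.k12:.3g} /s, k21 = {self.k21:.3g} /s "
                f"(relaxation {1.0 / self.relaxation_rate:.3g} s)\n"
                f"  deviance = {self.deviance:.1f}  converged={self.converged}")


# ---------------------------------------------------------------------------
# Filtered FCS
# ---------------------------------------------------------------------------

def ffcs_filters(patterns: np.ndarray,
                 totals: Optional[np.ndarray] = None) -> np.ndarray:
    """Statistical unmixing filters from species decay patterns.

    ``patterns`` has one row per species (probability per TCSPC bin). The
    returned filter matrix F (same shape) satisfies the unbiasedness
    identity sum_j F[i, j] * patterns[k, j] = delta_ik, with minimal
    variance under Poisson weighting by the total counts per bin.
    """
    p = np.atleast_2d(np.asarray(patterns, float))
    if p.shape[0] < 2:
        raise ValueError("need at least two species patterns")
    p = p / p.sum(axis=1, keepdims=True)
    s = np.asarray(totals, float) if totals is not None else p.sum(axis=0)
    s = np.maximum(s, 1e-12)
    a = p / s  # P diag(1/s)
    m = a @ p.T
    if np.linalg.cond(m) > 1e10:
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = np.corrcoef(p)
        raise np.linalg.LinAlgError(
            "species patterns are degenerate (pattern correlation matrix:\n"
            f"{np.array2string(corr, precision=4)})")
    return np.linalg.solve(m, a)


@dataclass
class CorrelationCurve:
    """A species correlation curve on a log-spaced lag grid."""

    lags: np.ndarray   # s, positive increasing
    g: np.ndarray
    sd: np.ndarray
    kind: str          # "species-auto" | "species-cross"
    pair: Tuple[int, int] = (0, 0)

    def __post_init__(self):
        if np.any(np.diff(self.lags) <= 0) or self.lags[0] <= 0:
            raise ValueError("lag times must be positive and increasing")


def _multi_tau(w1: np.ndarray, w2: np.ndarray, bin_s: float,
               pts_per_level: int = 8, max_lag_s: float = 1e-2):
    """Multiple-tau correlation of two binned weight traces."""
    lags, g = [], []
    mean1, mean2 = w1.mean(), w2.mean()
    if mean1 <= 0 or mean2 <= 0:
        raise ValueError("filtered traces have nonpositive mean")
    a, b = w1.astype(np.float64), w2.astype(np.float64)
    level, dt = 0, bin_s
    lag_bins = range(1, 2 * pts_per_level)
    while dt * pts_per_level <= max_lag_s and a.size > 4 * pts_per_level:
        for k in (lag_bins if level == 0 else range(pts_per_level,
                                                    2 * pts_per_level)):
            lag = k * dt
            if lag > max_lag_s:
                break
            n = a.size - k
            g.append(np.dot(a[:n], b[k:]) / n / (mean1 * mean2))
            lags.append(lag)
        n2 = (a.size // 2) * 2
        a = a[:n2].reshape(-1, 2).mean(axis=1)
        b = b[:n2].reshape(-1, 2).mean(axis=1)
        dt *= 2
        level += 1
    return np.asarray(lags), np.asarray(g)


def ffcs_correlate(stream: PhotonStream, filters: np.ndarray,
                   micro_edges: np.ndarray, bin_s: float = 2e-6,
                   max_lag_s: float = 1e-2, n_blocks: int = 8
                   ) -> List[CorrelationCurve]:
    """Species auto- and cross-correlations of a filtered photon stream.

    Donor-excitation photons get per-species weights from their TCSPC bin
    (``micro_edges`` is the histogram grid the filters were built on); the
    weight traces are binned at ``bin_s`` and correlated with a
    multiple-tau estimator. Errors come from block subdivision of the
    trace. Returns [sACF_1, sACF_2, sCCF_12, sCCF_21].
    """
    dex = stream.donor_window & stream.is_green
    t = stream.macro_times[dex]
    if t.size == 0:
        raise ValueError("no donor-excitation photons to correlate")
    duration = stream.duration
    if duration < 10 * max_lag_s:
        raise ValueError("stream too short for the requested largest lag")
    mbin = np.clip(np.digitize(stream.micro_times[dex], micro_edges) - 1,
                   0, filters.shape[1] - 1)
    n_bins_t = int(np.ceil(duration / bin_s))
    idx = np.minimum((t / bin_s).astype(np.int64), n_bins_t - 1)
    traces = [np.bincount(idx, weights=filters[i][mbin],
                          minlength=n_bins_t).astype(np.float32)
              for i in range(filters.shape[0])]

    pairs = [((0, 0), "species-auto"), ((1, 1), "species-auto"),
             ((0, 1), "species-cross"), ((1, 0), "species-cross")]
    out = []
    block = n_bins_t // n_blocks
    for (i, j), kind in pairs:
        gs = []
        for b in range(n_blocks):
            sl = slice(b * block, (b + 1) * block)
            try:
                lags, g = _multi_tau(traces[i][sl], traces[j][sl], bin_s,
                                     max_lag_s=max_lag_s)
                gs.append(g)
            except ValueError:
                continue
        if not gs:
            raise ValueError("insufficient photons in all blocks")
        m = min(len(g) for g in gs)
        gm = np.vstack([g[:m] for g in gs])
        out.append(CorrelationCurve(
            lags[:m], gm.mean(axis=0),
            gm.std(axis=0) / np.sqrt(len(gs)), kind, (i, j)))
    return out


@dataclass
class RelaxationSpectrum:
    """Amplitudes at the three fixed relaxation decades, ranked."""

    times_s: Tuple[float, float, float]
    amplitudes: np.ndarray
    percentages: np.ndarray
    classification: Tuple[str, ...]
    flagged_static: bool = False

    def __post_init__(self):
        if not self.flagged_static and self.percentages.sum() > 0:
            assert np.isclose(self.percentages.sum(), 100.0)


def classify_amplitudes(amps: np.ndarray) -> Tuple[str, ...]:
    order = np.argsort(amps)[::-1]
    names = ["major", "middle", "minor"]
    out = [""] * len(amps)
    for rank, idx in enumerate(order):
        out[idx] = names[min(rank, 2)]
    return tuple(out)


class FfcsModel:
    """Global fit of species correlation curves.

    Model per curve:  G(tc) = 1 + (1/N_c) D(tc) [1 ± s_c sum_j A_j exp(-tc/tR_j)]
    with D(tc) = (1 + tc/t_diff)^-1, the sign + for species
    auto-correlations and − for cross-correlations, and tR_j fixed at
    three decades (1e-5, 1e-4, 1e-3 s). The relaxation *decomposition*
    A_j is shared across curves (the global information); each curve has
    a free particle number N_c and a free relaxation contrast s_c (fixed
    to 1 for the first curve), since auto- and cross-correlations see the
    same exchange process with different contrast.
    """

    def __init__(self, curves: Sequence[CorrelationCurve],
                 decades: Sequence[float] = RELAXATION_DECADES_S):
        cs = list(curves)
        if not cs:
            raise ValueError("need at least one correlation curve")
        grid = cs[0].lags
        for c in cs[1:]:
            if c.lags.size != grid.size or not np.allclose(c.lags, grid):
                raise ValueError("curves must share the lag grid")
        self.curves = cs
        self.decades = np.asarray(decades, float)

    def _predict(self, c, inv_n, t_diff, amps, scale):
        sign = 1.0 if c.kind == "species-auto" else -1.0
        d = 1.0 / (1.0 + c.lags / t_diff)
        relax = (amps[None, :] * np.exp(-c.lags[:, None] / self.decades[None, :])
                 ).sum(axis=1)
        return 1.0 + inv_n * d * (1.0 + sign * scale * relax)

    def fit(self) -> "FfcsResult":
        nc = len(self.curves)
        nd = self.decades.size

        def unpack(p):
            scales = np.concatenate([[1.0], p[nc + 1 + nd:]])
            return p[:nc], p[nc], p[nc + 1:nc + 1 + nd], scales

        def resid(p):
            inv_ns, t_diff, amps, scales = unpack(p)
            out = []
            for c, inv_n, s in zip(self.curves, inv_ns, scales):
                w = np.maximum(c.sd, np.nanmax(c.sd) * 1e-2 + 1e-12)
                out.append((c.g - self._predict(c, inv_n, t_diff, amps, s)) / w)
            return np.concatenate(out)

        g0 = max(np.mean([c.g[0] - 1.0 for c in self.curves]), 1e-3)
        p0 = np.concatenate([np.full(nc, g0), [1e-3], np.full(nd, 0.2),
                             np.ones(nc - 1)])
        lb = np.concatenate([np.full(nc, 1e-8), [1e-5], np.zeros(nd),
                             np.zeros(nc - 1)])
        ub = np.concatenate([np.full(nc, 1e4), [1.0], np.full(nd, 50.0),
                             np.full(nc - 1, 100.0)])
        sol = least_squares(resid, p0, bounds=(lb, ub), x_scale="jac",
                            max_nfev=2000)
        inv_ns, t_diff, amps, _ = unpack(sol.x)
        total = amps.sum()
        static = total < 1e-3
        pct = (amps / total * 100.0) if not static else np.zeros(nd)
        spectrum = RelaxationSpectrum(
            tuple(self.decades), amps, pct,
            classify_amplitudes(amps) if not static else ("undefined",) * nd,
            flagged_static=static)
        return FfcsResult(self, spectrum, inv_ns, float(t_diff),
                          float(np.sum(sol.fun**2)))


@dataclass
class FfcsResult:
    model: FfcsModel
    spectrum: RelaxationSpectrum
    inv_n: np.ndarray
    t_diff: float
    cost: float

    def summary(self) -> str:
        s = self.spectrum
        lines = ["filtered-FCS relaxation decomposition",
                 f"  diffusion time: {self.t_diff:.3g} s"]
        for t, a, p, c in zip(s.times_s, s.amplitudes, s.percentages,
                              s.classification):
            lines.append(f"  tR = {t:.0e} s: A = {a:.3f} ({p:.1f}%) [{c}]")
        if s.flagged_static:
            lines.append("  sample is static: no relaxation amplitude")
        return "\n".join(lines)
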