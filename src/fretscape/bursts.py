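"""Burst selection and multiparameter fluorescence detection (MFD) analysis.

Single-molecule transits are located as runs of short inter-photon times;
each burst gets an intensity-based FRET efficiency, a PIE stoichiometry
and a maximum-likelihood donor lifetime, which together populate the 2D
E vs. ⟨τ_DA⟩_f histogram. Static and dynamic FRET-lines give the expected
loci for frozen distance distributions and for two-state mixing; bursts
skewed right of the static line diagnose exchange. TIRF traces are handled
by per-molecule gamma normalization at the acceptor-bleach step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .core import PhotonStream
from .decay import DonorModel, fluorescence_weighted_lifetime

__all__ = [
    "select_bursts", "pie_filter", "burst_estimators",
    "FretLine", "static_fret_line", "dynamic_fret_line",
    "tirf_trace_analysis", "mfd_histogram",
]


def select_bursts(stream: PhotonStream, min_photons: int = 40,
                  sigma_factor: float = 1.0,
                  threshold_s: Optional[float] = None) -> pd.DataFrame:
    """All-photon burst search by inter-photon-time thresholding.

    Contiguous runs of photons whose inter-photon times fall below
    (mean - sigma_factor * SD) of the whole trace are kept when they hold
    at least ``min_photons``. For strongly bursty traces the literal
    mean-minus-SD rule can go nonpositive; pass ``threshold_s`` explicitly
    in that case (an error explains this).

    Returns a table with one row per burst: photon index range [start,
    stop), photon count, start/stop times and duration.
    """
    n = len(stream)
    if n < 2:
        return pd.DataFrame(columns=["start", "stop", "n_photons",
                                     "t_start", "t_stop", "duration"])
    dt = np.diff(stream.macro_times)
    if threshold_s is None:
        threshold_s = float(dt.mean() - sigma_factor * dt.std())
        if threshold_s <= 0:
            raise ValueError(
                "inter-photon-time threshold (mean - sigma*SD) is nonpositive "
                f"({threshold_s:.3e} s) for this trace; pass threshold_s "
                "explicitly for heavy-tailed gap distributions")
    below = dt <= threshold_s * (1 + 1e-9)  # tolerate float ties
    # photon i belongs to a burst run if it is joined to a neighbor by a
    # short gap; runs are maximal stretches of consecutive short gaps
    edges = np.flatnonzero(np.diff(np.concatenate([[0], below.view(np.int8), [0]])))
    rows = []
    for a, b in zip(edges[::2], edges[1::2]):
        start, stop = a, b + 1      # photons a .. b inclusive
        if stop - start >= min_photons:
            t0, t1 = stream.macro_times[start], stream.macro_times[stop - 1]
            rows.append((start, stop, stop - start, t0, t1, t1 - t0))
    return pd.DataFrame(rows, columns=["start", "stop", "n_photons",
                                       "t_start", "t_stop", "duration"])


def burst_estimators(stream: PhotonStream, bursts: pd.DataFrame,
                     donor: DonorModel,
                     alpha: float = 0.0, delta: float = 0.0,
                     gamma: float = 1.0,
                     tau_grid_ps: float = 1.0) -> pd.DataFrame:
    """Per-burst FRET efficiency, PIE stoichiometry and donor lifetime.

    E is corrected for spectral leakage (alpha), direct acceptor excitation
    (delta) and the detection factor gamma:

        F_A = N_R|D - alpha * N_G - delta * N_R|A
        E   = F_A / (F_A + gamma * N_G)

    The burst donor lifetime maximizes the likelihood of a single
    exponential (window-truncated) over the burst's green micro-times on a
    1 ps grid of tau in (0, 2 tau_D0]. Bursts with no donor photons get a
    NaN lifetime and are flagged.
    """
    if min(alpha, delta, gamma) < 0:
        raise ValueError("correction factors must be nonnegative")
    window = stream.pulse_period / 2.0
    dex = stream.donor_window
    green = stream.is_green
    red = stream.is_red
    # excitation-pulse position = mode of the green micro-time histogram
    gmt = stream.micro_times[green & dex]
    if gmt.size:
        hist, edges = np.histogram(gmt, bins=int(window / 0.05))
        t0 = float(edges[np.argmax(hist)])
    else:
        t0 = 2.0  # fallback offset

    tau_max = 2.0 * donor.tau_fluorescence
    grid = np.arange(tau_grid_ps * 1e-3, tau_max, tau_grid_ps * 1e-3)
    lognorm = np.log(grid * (1.0 - np.exp(-window / grid)))

    out = bursts.copy()
    cols = {k: np.zeros(len(bursts)) for k in
            ("n_green", "n_red_dex", "n_red_aex", "t_gg", "t_rr",
             "e_raw", "e_corrected", "s_pie", "tau_f")}
    flagged = np.zeros(len(bursts), dtype=bool)
    micro = stream.micro_times
    macro = stream.macro_times
    offset = t0  # shared across bursts; per-burst estimates are too noisy
    for i, (a, b) in enumerate(zip(bursts["start"], bursts["stop"])):
        sl = slice(int(a), int(b))
        g = green[sl] & dex[sl]
        r_dex = red[sl] & dex[sl]
        r_aex = red[sl] & ~dex[sl]
        ng, nrd, nra = int(g.sum()), int(r_dex.sum()), int(r_aex.sum())
        fa = nrd - alpha * ng - delta * nra
        fd = gamma * ng
        tot = fa + fd
        e_corr = fa / tot if tot > 0 else np.nan
        e_raw = nrd / (nrd + ng) if (nrd + ng) > 0 else np.nan
        s = (fd + fa) / (fd + fa + nra) if (fd + fa + nra) > 0 else np.nan
        tg = macro[sl][g | r_dex]
        tr = macro[sl][r_aex]
        t_gg = tg.max() - tg.min() if tg.size > 1 else 0.0
        t_rr = tr.max() - tr.min() if tr.size > 1 else 0.0
        if ng > 0:
            mt = np.clip(micro[sl][g] - offset, 0.0, window)
            s_sum = mt.sum()
            logl = -ng * lognorm - s_sum / grid
            tau = float(grid[np.argmax(logl)])
        else:
            tau, flagged[i] = np.nan, True
        for k, val in (("n_green", ng), ("n_red_dex", nrd), ("n_red_aex", nra),
                       ("t_gg", t_gg), ("t_rr", t_rr), ("e_raw", e_raw),
                       ("e_corrected", e_corr), ("s_pie", s), ("tau_f", tau)):
            cols[k][i] = val
    for k, v in cols.items():
        out[k] = v
    out["no_donor_flag"] = flagged
    return out


def pie_filter(bursts: pd.DataFrame, max_dt: float = 1e-3,
               s_low: float = 0.3, s_high: float = 0.7) -> pd.DataFrame:
    """Keep dual-labeled bursts: |T_GG - T_RR| < max_dt (s) and
    s_low < S_PIE < s_high."""
    if s_low >= s_high:
        raise ValueError("s_low must be below s_high")
    ok = (np.abs(bursts["t_gg"] - bursts["t_rr"]) < max_dt) \
        & (bursts["s_pie"] > s_low) & (bursts["s_pie"] < s_high)
    return bursts[ok.fillna(False)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# FRET-lines
# ---------------------------------------------------------------------------

@dataclass
class FretLine:
    """Sampled (⟨τ⟩_f, E) curve; kind 'static' or 'dynamic'."""

    tau_f: np.ndarray
    efficiency: np.ndarray
    kind: str
    parameters: dict = field(default_factory=dict)

    def interp(self, tau):
        order = np.argsort(self.tau_f)
        return np.interp(tau, self.tau_f[order], self.efficiency[order])


def static_fret_line(donor: DonorModel, sigma_link: float,
                     forster_radius: float, n_points: int = 300,
                     n_quad: int = 61) -> FretLine:
    """Static FRET-line: E vs fluorescence-weighted lifetime for frozen
    Gaussian distance distributions of width ``sigma_link``.

    Sweeps the mean distance; at each, E and ⟨τ⟩_f are averaged over the
    distance distribution and the donor lifetime components.
    """
    if sigma_link < 0:
        raise ValueError("sigma_link must be nonnegative")
    from .decay import _gauss_nodes
    r0 = forster_radius
    tref = donor.tau_fluorescence
    rbars = np.geomspace(0.3 * r0, 4.0 * r0, n_points)
    e_out = np.empty(n_points)
    tau_out = np.empty(n_points)
    for i, rbar in enumerate(rbars):
        r, w = _gauss_nodes(rbar, sigma_link, n_quad)
        r = np.clip(r, 1.0, None)
        e = 1.0 / (1.0 + (r / r0) ** 6)
        kt = (r0 / r) ** 6 / tref
        tau_mq = 1.0 / (1.0 / donor.lifetimes[:, None] + kt[None, :])
        wm = donor.amplitudes[:, None] * w[None, :]
        e_out[i] = np.sum(w * e)
        tau_out[i] = np.sum(wm * tau_mq**2) / np.sum(wm * tau_mq)
    return FretLine(tau_out, e_out, "static",
                    {"sigma_link": sigma_link, "R0": r0,
                     "tau_D0": donor.tau_fluorescence})


def dynamic_fret_line(tau1: float, tau2: float, tau_d0: float,
                      n_points: int = 200) -> FretLine:
    """Dynamic FRET-line between two limiting lifetimes:

        E(⟨τ⟩_f) = 1 - τ1 τ2 / (τ_D0 (τ1 + τ2 - ⟨τ⟩_f))

    sampled between the endpoints, which coincide with the limiting-state
    static points.
    """
    if not (0 < tau1 <= tau_d0 and 0 < tau2 <= tau_d0):
        raise ValueError("state lifetimes must lie in (0, tau_D0]")
    lo, hi = min(tau1, tau2), max(tau1, tau2)
    tau = np.linspace(lo, hi, n_points)
    e = 1.0 - tau1 * tau2 / (tau_d0 * (tau1 + tau2 - tau))
    return FretLine(tau, e, "dynamic",
                    {"tau1": tau1, "tau2": tau2, "tau_D0": tau_d0})


def dynamic_line_value(tau_f, tau1: float, tau2: float, tau_d0: float):
    lo, hi = min(tau1, tau2), max(tau1, tau2)
    tau_f = np.asarray(tau_f, float)
    if np.any(tau_f < lo - 1e-9) or np.any(tau_f > hi + 1e-9):
        raise ValueError("tau_f outside the two-state mixing range")
    return 1.0 - tau1 * tau2 / (tau_d0 * (tau1 + tau2 - tau_f))


def mfd_histogram(bursts: pd.DataFrame, tau_d0: float,
                  bins: int = 50):
    """2D burst histogram over E in [-0.1, 1.1], tau in [0, tau_D0+0.5]."""
    e = bursts["e_corrected"].to_numpy()
    t = bursts["tau_f"].to_numpy()
    ok = np.isfinite(e) & np.isfinite(t)
    h, xe, ye = np.histogram2d(t[ok], e[ok], bins=bins,
                               range=[[0.0, tau_d0 + 0.5], [-0.1, 1.1]])
    return h, xe, ye


# ---------------------------------------------------------------------------
# TIRF traces
# ---------------------------------------------------------------------------

def _detect_bleach_step(trace: np.ndarray, factor: float = 5.0) -> Optional[int]:
    """Largest single-frame drop exceeding ``factor`` x the pre-step SD."""
    if trace.size < 10:
        return None
    drops = -np.diff(trace)
    k = int(np.argmax(drops))
    if k < 5:
        return None
    pre_sd = trace[:k].std()
    if pre_sd == 0 or drops[k] > factor * pre_sd:
        return k + 1  # first post-bleach frame
    return None


def tirf_trace_analysis(traces, gamma_mode: str = "per-molecule",
                        global_gamma: float = 1.0) -> pd.DataFrame:
    """Per-molecule FRET from TIRF intensity traces.

    gamma is estimated from the acceptor photobleaching step as
    |dI_A| / |dI_D|; E_t = I_A / (I_A + gamma I_D) over the pre-bleach
    segment, together with the donor-acceptor Pearson correlation. When no
    bleach step is detected, falls back to ``global_gamma`` with a flag.
    """
    rows = []
    e_series = []
    for i, tr in enumerate(traces):
        ia, idn = np.asarray(tr.i_acceptor, float), np.asarray(tr.i_donor, float)
        step = _detect_bleach_step(ia)
        fallback = False
        if step is None:
            gamma, end = global_gamma, ia.size
            fallback = True
        else:
            d_a = ia[step] - ia[step - 1]
            d_d = idn[step] - idn[step - 1]
            gamma = abs(d_a) / abs(d_d) if d_d != 0 else global_gamma
            end = step
        if gamma_mode != "per-molecule":
            gamma = global_gamma
        seg_a, seg_d = ia[:end], idn[:end]
        e_t = seg_a / (seg_a + gamma * seg_d)
        if seg_a.size > 2 and seg_a.std() > 0 and seg_d.std() > 0:
            r = float(np.corrcoef(seg_d, seg_a)[0, 1])
        else:
            r = np.nan
        rows.append({"molecule": i, "gamma": gamma, "mean_e": float(e_t.mean()),
                     "pearson_r": r, "pre_bleach_frames": int(end),
                     "gamma_fallback": fallback})
        e_series.append(e_t)
    df = pd.DataFrame(rows)
    df.attrs["e_series"] = e_series
    return df
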