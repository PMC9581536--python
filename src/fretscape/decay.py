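"""Global analysis of FRET-sensitized donor fluorescence decays.

A network of labeling variants reports on one shared conformational
ensemble: the number of states and their occupancies are global fitting
parameters, while the mean inter-dye distance of each state is specific to
each variant. The decay model for a variant is

    F(t) = (1 - x_nf) * sum_s x_s * Int N(R; Rbar_s, sigma_s)
                 * sum_m a_m exp(-t * (1/tau_m + k_T(R))) dR
         + x_nf * sum_m a_m exp(-t / tau_m)

with the energy-transfer rate k_T(R) = (1/tau_ref) * (R0/R)^6 and tau_ref
the fluorescence-weighted average donor-only lifetime. The model is
convolved with the instrument response and scaled to the data.

The module also provides model-order selection over nested fits and the
FRET-network-robustness (FNR) subsampling analysis, which refits random
sub-networks to quantify how strongly each distance is constrained and
turns the spread into screening bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.optimize import least_squares
from scipy.signal import fftconvolve

from .core import DecayDataset, DistanceRestraint, check_seed

__all__ = [
    "DonorModel",
    "fit_donor_only",
    "fluorescence_weighted_lifetime",
    "model_decay",
    "GlobalDecayModel",
    "GlobalDecayResult",
    "select_model",
    "fnr_analysis",
    "fnr_bounds",
    "FnrResult",
]

_QUAD_POINTS = 121  # Gauss-Legendre nodes over Rbar +/- 4 sigma


@dataclass
class DonorModel:
    """Multi-exponential donor-only photophysics."""

    lifetimes: np.ndarray   # ns
    amplitudes: np.ndarray  # normalized species amplitudes
    background: float = 0.0
    chi2r: float = np.nan

    def __post_init__(self):
        self.lifetimes = np.asarray(self.lifetimes, dtype=float)
        amps = np.asarray(self.amplitudes, dtype=float)
        if np.any(self.lifetimes <= 0):
            raise ValueError("donor lifetimes must be positive")
        self.amplitudes = amps / amps.sum()

    @property
    def tau_fluorescence(self) -> float:
        """Fluorescence-weighted mean lifetime sum(a t^2)/sum(a t)."""
        return fluorescence_weighted_lifetime(self.lifetimes, self.amplitudes)

    @property
    def tau_species(self) -> float:
        return float(np.sum(self.amplitudes * self.lifetimes))


def fluorescence_weighted_lifetime(taus, amps) -> float:
    taus = np.asarray(taus, float)
    amps = np.asarray(amps, float)
    return float(np.sum(amps * taus**2) / np.sum(amps * taus))


def _convolve_irf(model: np.ndarray, irf: np.ndarray) -> np.ndarray:
    """Linear convolution with the (normalized) IRF, truncated to n bins."""
    irf = np.asarray(irf, float)
    total = irf.sum()
    if total <= 0:
        return model
    out = fftconvolve(model, irf / total)[: model.size]
    return np.clip(out, 0.0, None)


def _gauss_nodes(rbar: float, sigma: float, n: int = _QUAD_POINTS):
    """Distance quadrature nodes/weights for a Gaussian distance shell."""
    if sigma <= 0:
        return np.array([max(rbar, 1e-3)]), np.array([1.0])
    x, w = leggauss(n)
    lo = max(rbar - 4.0 * sigma, 1e-3)
    hi = rbar + 4.0 * sigma
    r = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
    pdf = np.exp(-0.5 * ((r - rbar) / sigma) ** 2)
    wts = w * pdf
    return r, wts / wts.sum()


def model_decay(
    time_ns: np.ndarray,
    irf_counts: np.ndarray,
    donor: DonorModel,
    distances: Sequence[float],
    state_fractions: Sequence[float],
    sigmas: Sequence[float],
    forster_radius: float,
    no_fret_fraction: float = 0.0,
    n_total: Optional[float] = None,
    background: float = 0.0,
    tau_ref: Optional[float] = None,
) -> np.ndarray:
    """Expected counts per TCSPC bin for a multi-state FRET mixture.

    Distances at or beyond ~10x R0 transfer essentially nothing and reduce
    to the donor-only shape. Returns the IRF-convolved model, scaled so the
    decay (excluding background) integrates to ``n_total`` when given.
    """
    t = np.asarray(time_ns, float)
    x = np.asarray(state_fractions, float)
    dist = np.asarray(distances, float)
    sig = np.broadcast_to(np.asarray(sigmas, float), x.shape)
    if np.any(dist <= 0):
        raise ValueError("state distances must be positive")
    tref = donor.tau_fluorescence if tau_ref is None else tau_ref

    decay = np.zeros_like(t)
    for xs, rbar, sg in zip(x, dist, sig):
        r, w = _gauss_nodes(rbar, sg)
        r = np.clip(r, 1e-3, None)
        kt = (forster_radius / r) ** 6 / tref              # (nq,)
        rates = 1.0 / donor.lifetimes[:, None] + kt[None, :]  # (m, nq)
        amp = donor.amplitudes[:, None] * w[None, :]
        decay += xs * np.einsum("mq,mqt->t", amp, np.exp(-rates[..., None] * t))
    decay *= 1.0 - no_fret_fraction
    decay += no_fret_fraction * (
        donor.amplitudes[:, None] * np.exp(-t[None, :] / donor.lifetimes[:, None])
    ).sum(axis=0)

    conv = _convolve_irf(decay, irf_counts)
    if n_total is not None and conv.sum() > 0:
        conv = conv * (n_total / conv.sum())
    return conv + background


def fit_donor_only(decay: DecayDataset, n_components: int = 2,
                   fit_background: bool = True) -> DonorModel:
    """Fit a multi-exponential, IRF-convolved model to a donor-only decay.

    Uses Poisson-weighted least squares; the reduced chi-square is computed
    over bins holding at least 5 counts.
    """
    counts = decay.donor_only_counts.astype(float)
    if counts.sum() < 100:
        raise ValueError("donor-only decay has too few counts to fit "
                         f"({int(counts.sum())}); need a populated histogram")
    t = decay.time_ns
    total = counts.sum()

    # crude mean lifetime for initialization (IRF-mean subtracted)
    irf_mean = np.average(t, weights=np.maximum(decay.irf_counts, 1e-12))
    tau0 = max(np.average(t, weights=counts) - irf_mean, 0.3)
    taus0 = tau0 * np.linspace(0.6, 1.4, n_components)
    amps0 = np.full(n_components, 1.0 / n_components)
    bg0 = max(counts[-max(3, len(t) // 50):].min(), 0.0) if fit_background else 0.0

    def unpack(p):
        taus = p[:n_components]
        amps = np.abs(p[n_components:2 * n_components])
        bg = p[-1] if fit_background else 0.0
        return taus, amps, bg

    def resid(p):
        taus, amps, bg = unpack(p)
        model = (amps[:, None] * np.exp(-t[None, :] / taus[:, None])).sum(axis=0)
        model = _convolve_irf(model, decay.irf_counts)
        s = model.sum()
        if s <= 0:
            return np.full_like(counts, 1e3)
        model = model * ((total - bg * len(t)) / s) + bg
        return (counts - model) / np.sqrt(np.maximum(counts, 1.0))

    p0 = np.concatenate([taus0, amps0, [bg0]]) if fit_background else \
        np.concatenate([taus0, amps0])
    lb = np.concatenate([np.full(n_components, 0.01),
                         np.zeros(n_components),
                         [0.0] if fit_background else []])
    ub = np.concatenate([np.full(n_components, 30.0),
                         np.full(n_components, 10.0),
                         [counts.max()] if fit_background else []])
    sol = least_squares(resid, p0, bounds=(lb, ub), x_scale="jac", max_nfev=2000)
    taus, amps, bg = unpack(sol.x)
    order = np.argsort(taus)[::-1]
    good = counts >= 5
    dof = max(good.sum() - len(sol.x), 1)
    chi2r = float(np.sum(sol.fun[good] ** 2) / dof)
    if not np.isfinite(chi2r) or amps.sum() <= 0:
        raise RuntimeError("donor-only fit failed to converge; "
                           f"status={sol.status}, params={sol.x}")
    if np.all(taus <= 0.05):
        raise RuntimeError(
            "donor-only fit is IRF-limited: every recovered lifetime sits at "
            f"the resolution floor (taus={np.round(taus, 4)} ns); the decay "
            "carries no resolvable fluorescence component")
    return DonorModel(taus[order], amps[order], background=float(bg), chi2r=chi2r)


# ---------------------------------------------------------------------------
# Global fit across the variant network
# ---------------------------------------------------------------------------

_SIGMA_BOUNDS = (1.0, 15.0)
_DIST_BOUNDS = (10.0, 200.0)


def _fractions_from_sticks(g: np.ndarray) -> np.ndarray:
    """Stick-breaking map from (0,1)^{n-1} to the simplex."""
    x = []
    rem = 1.0
    for gi in g:
        x.append(rem * gi)
        rem *= 1.0 - gi
    x.append(rem)
    return np.asarray(x)


def _sticks_from_fractions(x: np.ndarray) -> np.ndarray:
    g = []
    rem = 1.0
    for xi in x[:-1]:
        g.append(np.clip(xi / max(rem, 1e-12), 1e-6, 1 - 1e-6))
        rem -= xi
    return np.asarray(g)


class GlobalDecayModel:
    """Simultaneous fit of all variant decays with shared state occupancies.

    Parameters
    ----------
    decays : dict
        Mapping variant name -> :class:`DecayDataset`.
    donor : DonorModel or dict of DonorModel
        Donor-only photophysics (shared or per variant).
    n_states : int
        Number of FRET states (distance shells) in the model.
    forster_radius : float
    shared_no_fret : bool
        Fit one global no-FRET fraction instead of one per variant.
    """

    def __init__(self, decays: Dict[str, DecayDataset], donor,
                 n_states: int = 2, forster_radius: float = 52.0,
                 shared_no_fret: bool = False):
        if len(decays) < 1:
            raise ValueError("at least one decay dataset required")
        if n_states < 1:
            raise ValueError("n_states must be >= 1")
        self.decays = dict(decays)
        self.variants = list(decays)
        self.donor = donor
        self.n_states = n_states
        self.forster_radius = forster_radius
        self.shared_no_fret = shared_no_fret
        n_data = sum(d.n_bins for d in decays.values())
        if self._n_params() >= n_data:
            raise ValueError("model has more free parameters than data points")

    def donor_for(self, variant: str) -> DonorModel:
        return self.donor[variant] if isinstance(self.donor, dict) else self.donor

    # -- parameter vector layout: [sticks (n_states-1) | sigmas (n_states) |
    #    no-FRET (1 or n_var) | distances (n_var * n_states)] ---------------
    def _n_params(self) -> int:
        nv = len(self.variants)
        nf = 1 if self.shared_no_fret else nv
        return (self.n_states - 1) + self.n_states + nf + nv * self.n_states

    def _unpack(self, p):
        ns, nv = self.n_states, len(self.variants)
        i = ns - 1
        fracs = _fractions_from_sticks(p[:i]) if ns > 1 else np.array([1.0])
        sigmas = p[i:i + ns]
        i += ns
        nf = 1 if self.shared_no_fret else nv
        no_fret = p[i:i + nf]
        i += nf
        dists = p[i:].reshape(nv, ns)
        return fracs, sigmas, no_fret, dists

    def _pack(self, fracs, sigmas, no_fret, dists):
        parts = []
        if self.n_states > 1:
            parts.append(_sticks_from_fractions(np.asarray(fracs)))
        parts += [np.asarray(sigmas, float), np.atleast_1d(no_fret),
                  np.asarray(dists, float).ravel()]
        return np.concatenate(parts)

    def _bounds(self):
        ns, nv = self.n_states, len(self.variants)
        nf = 1 if self.shared_no_fret else nv
        lb = np.concatenate([np.full(ns - 1, 1e-4), np.full(ns, _SIGMA_BOUNDS[0]),
                             np.zeros(nf), np.full(nv * ns, _DIST_BOUNDS[0])])
        ub = np.concatenate([np.full(ns - 1, 1 - 1e-4), np.full(ns, _SIGMA_BOUNDS[1]),
                             np.full(nf, 0.5), np.full(nv * ns, _DIST_BOUNDS[1])])
        return lb, ub

    def _predict_variant(self, variant, fracs, sigmas, no_fret_v, dists_v):
        d = self.decays[variant]
        return model_decay(
            d.time_ns, d.irf_counts, self.donor_for(variant),
            dists_v, fracs, sigmas, self.forster_radius,
            no_fret_fraction=no_fret_v,
            n_total=d.counts.sum() - d.background_rate * d.n_bins,
            background=d.background_rate,
        )

    def _residuals(self, p):
        fracs, sigmas, no_fret, dists = self._unpack(p)
        out = []
        for i, v in enumerate(self.variants):
            nf = no_fret[0] if self.shared_no_fret else no_fret[i]
            model = self._predict_variant(v, fracs, sigmas, nf, dists[i])
            counts = self.decays[v].counts
            out.append((counts - model) / np.sqrt(np.maximum(counts, 1.0)))
        return np.concatenate(out)

    def _jac_sparsity(self):
        """Block structure of the Jacobian: each variant's residuals depend
        on the global parameters plus its own distances / no-FRET only."""
        from scipy.sparse import lil_matrix
        ns, nv = self.n_states, len(self.variants)
        n_rows = sum(self.decays[v].n_bins for v in self.variants)
        sp = lil_matrix((n_rows, self._n_params()), dtype=np.int8)
        n_global = (ns - 1) + ns
        nf = 1 if self.shared_no_fret else nv
        row = 0
        for i, v in enumerate(self.variants):
            nb = self.decays[v].n_bins
            sp[row:row + nb, :n_global] = 1
            sp[row:row + nb, n_global + (0 if self.shared_no_fret else i)] = 1
            c0 = n_global + nf + i * ns
            sp[row:row + nb, c0:c0 + ns] = 1
            row += nb
        return sp

    def _cost(self, p) -> float:
        r = self._residuals(p)
        return 0.5 * float(r @ r)

    def _refit_variant(self, p, vi, max_nfev=60):
        """Re-optimize one variant's distances (and its no-FRET fraction)
        with the global parameters held fixed."""
        fracs, sigmas, no_fret, dists = self._unpack(p)
        v = self.variants[vi]
        counts = self.decays[v].counts
        w = np.sqrt(np.maximum(counts, 1.0))
        per_var_nf = not self.shared_no_fret

        def resid(q):
            d = q[: self.n_states]
            nf = q[-1] if per_var_nf else no_fret[0]
            return (counts - self._predict_variant(v, fracs, sigmas, nf, d)) / w

        q0 = np.concatenate([dists[vi], [no_fret[vi]] if per_var_nf else []])
        lo = np.concatenate([np.full(self.n_states, _DIST_BOUNDS[0]),
                             [0.0] if per_var_nf else []])
        hi = np.concatenate([np.full(self.n_states, _DIST_BOUNDS[1]),
                             [0.5] if per_var_nf else []])
        sol = least_squares(resid, np.clip(q0, lo, hi), bounds=(lo, hi),
                            x_scale="jac", max_nfev=max_nfev)
        dists = dists.copy()
        dists[vi] = sol.x[: self.n_states]
        if per_var_nf:
            no_fret = no_fret.copy()
            no_fret[vi] = sol.x[-1]
        return self._pack(fracs, sigmas, no_fret, dists)

    def _refit_globals(self, p, max_nfev=80):
        """Re-optimize the shared parameters (fractions, widths, shared
        no-FRET) with all per-variant distances held fixed."""
        fracs, sigmas, no_fret, dists = self._unpack(p)
        ns = self.n_states
        n_shared = (ns - 1) + ns + (1 if self.shared_no_fret else 0)
        if n_shared == 0:
            return p

        def build(q):
            fr = _fractions_from_sticks(q[:ns - 1]) if ns > 1 else fracs
            sg = q[ns - 1:2 * ns - 1]
            nf = q[2 * ns - 1:] if self.shared_no_fret else no_fret
            return self._pack(fr, sg, nf, dists)

        def resid(q):
            return self._residuals(build(q))

        q0 = np.concatenate([
            _sticks_from_fractions(fracs) if ns > 1 else [],
            sigmas, no_fret if self.shared_no_fret else []])
        lo = np.concatenate([np.full(ns - 1, 1e-4),
                             np.full(ns, _SIGMA_BOUNDS[0]),
                             [0.0] if self.shared_no_fret else []])
        hi = np.concatenate([np.full(ns - 1, 1 - 1e-4),
                             np.full(ns, _SIGMA_BOUNDS[1]),
                             [0.5] if self.shared_no_fret else []])
        sol = least_squares(resid, np.clip(q0, lo, hi), bounds=(lo, hi),
                            x_scale="jac", max_nfev=max_nfev)
        return build(sol.x)

    def _coordinate_descent(self, p, n_cycles=2):
        """Alternate per-variant and global block refits: a cheap, robust
        descent toward the joint optimum before the full trust-region fit."""
        for _ in range(n_cycles):
            for vi in range(len(self.variants)):
                p = self._refit_variant(p, vi)
            p = self._refit_globals(p)
        return p

    def _swap_pass(self, p):
        """One pass of the discrete state-assignment refinement: for each
        variant, try exchanging its two state distances (locally
        re-optimized) and keep the assignment with the lower global cost."""
        best_cost = self._cost(p)
        improved = False
        for vi in range(len(self.variants)):
            fracs, sigmas, no_fret, dists = self._unpack(p)
            dists = dists.copy()
            dists[vi] = dists[vi][::-1]
            trial = self._refit_variant(
                self._pack(fracs, sigmas, no_fret, dists), vi)
            c = self._cost(trial)
            if c < best_cost - 1e-6:
                p, best_cost, improved = trial, c, True
        return p, improved

    def _initial_distance(self, variant: str) -> float:
        """Moment-based distance guess from the mean decay time."""
        d = self.decays[variant]
        donor = self.donor_for(variant)
        counts = np.maximum(d.counts - d.background_rate, 0.0)
        irf_mean = np.average(d.time_ns, weights=np.maximum(d.irf_counts, 1e-12))
        tau_obs = max(np.average(d.time_ns, weights=np.maximum(counts, 1e-12))
                      - irf_mean, 0.05)
        e = np.clip(1.0 - tau_obs / donor.tau_fluorescence, 0.02, 0.98)
        return float(self.forster_radius * (1.0 / e - 1.0) ** (1.0 / 6.0))

    def _per_variant_start(self):
        """Start from independent per-variant fits with free fractions and
        free per-state distribution widths.

        Each variant's decay pins down its (distance, width, weight)
        triplets almost independently; aligning the per-variant components
        by descending width (the states differ in basin fuzziness) gives a
        consistent state assignment, which is the hard discrete part of
        the global problem.
        """
        ns, nv = self.n_states, len(self.variants)
        per_frac, per_dist, per_sig, per_nf = [], [], [], []
        for v in self.variants:
            d = self.decays[v]
            counts = d.counts
            w = np.sqrt(np.maximum(counts, 1.0))
            donor = self.donor_for(v)
            base = self._initial_distance(v)

            def resid(q):
                fr = _fractions_from_sticks(q[:ns - 1]) if ns > 1 else [1.0]
                model = model_decay(
                    d.time_ns, d.irf_counts, donor, q[ns - 1:2 * ns - 1],
                    fr, q[2 * ns - 1:3 * ns - 1], self.forster_radius,
                    no_fret_fraction=q[-1],
                    n_total=counts.sum() - d.background_rate * d.n_bins,
                    background=d.background_rate)
                return (counts - model) / w

            offs = np.linspace(-7.0, 7.0, ns) if ns > 1 else np.array([0.0])
            lo = np.concatenate([np.full(ns - 1, 1e-4),
                                 np.full(ns, _DIST_BOUNDS[0]),
                                 np.full(ns, 2.0), [0.0]])
            hi = np.concatenate([np.full(ns - 1, 1 - 1e-4),
                                 np.full(ns, _DIST_BOUNDS[1]),
                                 np.full(ns, 12.0), [0.5]])
            sol = None
            for doff, s0 in ((offs, (8.0, 4.0)), (offs[::-1], (8.0, 4.0))):
                q0 = np.concatenate([np.full(ns - 1, 0.5),
                                     np.clip(base + doff, *_DIST_BOUNDS),
                                     np.resize(s0, ns), [0.05]])
                s = least_squares(resid, q0, bounds=(lo, hi), x_scale="jac",
                                  max_nfev=150)
                if sol is None or s.cost < sol.cost:
                    sol = s
            fr = _fractions_from_sticks(sol.x[:ns - 1]) if ns > 1 else np.ones(1)
            sig = sol.x[2 * ns - 1:3 * ns - 1]
            order = np.argsort(sig)[::-1]  # common order: broadest first
            per_frac.append(fr[order])
            per_dist.append(sol.x[ns - 1:2 * ns - 1][order])
            per_sig.append(sig[order])
            per_nf.append(sol.x[-1])
        fr0 = np.clip(np.mean(per_frac, axis=0), 1e-3, 1.0)
        sig0 = np.clip(np.median(per_sig, axis=0), *_SIGMA_BOUNDS)
        nf0 = (np.array([np.mean(per_nf)]) if self.shared_no_fret
               else np.asarray(per_nf))
        return self._pack(fr0 / fr0.sum(), sig0, nf0, np.asarray(per_dist))

    def _starts(self, n_restarts, seed, x0=None):
        rng = np.random.default_rng(seed)
        nv, ns = len(self.variants), self.n_states
        nf_len = 1 if self.shared_no_fret else nv
        starts = []
        if x0 is not None:
            starts.append(np.asarray(x0, float))
        pv = None
        try:
            pv = self._per_variant_start()
            starts.append(pv)
            if ns == 2:
                # same assignments but generic broad/narrow widths
                fr, _, nf, dd = self._unpack(pv)
                starts.append(self._pack(fr, np.array([9.0, 3.0]), nf, dd))
        except Exception:
            pass  # fall through to the moment-based start
        # moment-based start: mean-lifetime distances split per state
        base = np.array([self._initial_distance(v) for v in self.variants])
        offsets = np.linspace(-7.0, 7.0, ns) if ns > 1 else np.array([0.0])
        d0 = np.clip(base[:, None] + offsets[None, :], *_DIST_BOUNDS)
        starts.append(self._pack(np.full(ns, 1.0 / ns), np.full(ns, 6.0),
                                 np.full(nf_len, 0.05), d0))
        while len(starts) < n_restarts:
            # random perturbations of the best data-driven start
            ref = pv if pv is not None else starts[-1]
            fr, sg, nf, dd = self._unpack(ref)
            fr = np.clip(fr * rng.uniform(0.6, 1.4, ns), 1e-3, None)
            dd = np.clip(dd * rng.uniform(0.88, 1.12, size=dd.shape),
                         *_DIST_BOUNDS)
            sg = np.sort(rng.uniform(*_SIGMA_BOUNDS, ns))[::-1]
            starts.append(self._pack(fr / fr.sum(), sg,
                                     rng.uniform(0, 0.15, nf_len), dd))
        return starts[:n_restarts]

    def fit(self, n_restarts: int = 10, seed: int = 0, x0=None,
            max_nfev: int = 300, polish_swaps: bool = True
            ) -> "GlobalDecayResult":
        """Multi-start trust-region least squares; best run retained.

        Each restart runs a sparse-Jacobian trust-region fit; the best run
        is then refined by a discrete state-swap pass (two-state models
        only), which resolves the per-variant label-assignment degeneracy
        the continuous optimizer cannot cross. Ties are broken by the
        lowest summed chi-square, then states are relabeled in
        lexicographic distance order to fix global label switching.
        """
        seed = check_seed(seed)
        sparsity = self._jac_sparsity()
        best_x, best_cost = None, np.inf
        costs = []
        for idx, p0 in enumerate(self._starts(n_restarts, seed, x0=x0)):
            warm = x0 is not None and idx == 0
            if not warm:  # a supplied x0 is treated as a warm start
                p0 = self._coordinate_descent(p0)
                if self.n_states == 2:
                    p0, _ = self._swap_pass(p0)
            sol = least_squares(self._residuals, p0, bounds=self._bounds(),
                                x_scale="jac", max_nfev=max_nfev,
                                jac_sparsity=sparsity)
            costs.append(sol.cost)
            if sol.cost < best_cost - 1e-9:
                best_x, best_cost = sol.x, sol.cost
            # stop early once two restarts independently agree on the optimum
            if len(costs) >= 3 and sum(c < best_cost + 1.0 for c in costs) >= 2:
                break
        if polish_swaps and self.n_states == 2:
            # alternate discrete assignment swaps with global re-polish so
            # the shared fractions can follow each assignment change
            for _ in range(6):
                best_x, improved = self._swap_pass(best_x)
                if not improved:
                    break
                sol = least_squares(self._residuals, best_x,
                                    bounds=self._bounds(), x_scale="jac",
                                    max_nfev=60, jac_sparsity=sparsity)
                if sol.cost < self._cost(best_x):
                    best_x = sol.x
        best_cost = self._cost(best_x)
        fracs, sigmas, no_fret, dists = self._unpack(best_x)
        # canonical state order: lexicographic over the distance matrix
        order = np.lexsort(dists[::-1])
        fracs, sigmas, dists = fracs[order], np.asarray(sigmas)[order], dists[:, order]
        return GlobalDecayResult(self, fracs, sigmas, np.atleast_1d(no_fret),
                                 dists, float(best_cost))


@dataclass
class GlobalDecayResult:
    """Fitted state model: global occupancies plus per-variant distances."""

    model: GlobalDecayModel
    state_fractions: np.ndarray
    sigmas: np.ndarray
    no_fret: np.ndarray          # one entry, or one per variant
    distances: np.ndarray        # (n_variants, n_states) Å
    cost: float
    chi2r_: Optional[dict] = None

    @property
    def variants(self):
        return self.model.variants

    @property
    def n_states(self):
        return self.model.n_states

    def no_fret_for(self, variant: str) -> float:
        if self.no_fret.size == 1:
            return float(self.no_fret[0])
        return float(self.no_fret[self.variants.index(variant)])

    def predict(self, variant: str) -> np.ndarray:
        i = self.variants.index(variant)
        return self.model._predict_variant(
            variant, self.state_fractions, self.sigmas,
            self.no_fret_for(variant), self.distances[i])

    def chi2r(self) -> Dict[str, float]:
        """Poisson-weighted reduced chi-square per variant (bins with >= 5
        counts; per-variant share of the free parameters)."""
        if self.chi2r_ is None:
            per_var_params = self.model._n_params() / len(self.variants)
            out = {}
            for v in self.variants:
                counts = self.model.decays[v].counts
                m = self.predict(v)
                good = counts >= 5
                dof = max(int(good.sum() - per_var_params), 1)
                out[v] = float(np.sum((counts[good] - m[good]) ** 2
                                      / np.maximum(counts[good], 1.0)) / dof)
            self.chi2r_ = out
        return self.chi2r_

    @property
    def mean_chi2r(self) -> float:
        return float(np.mean(list(self.chi2r().values())))

    def distance_table(self):
        import pandas as pd
        return pd.DataFrame(self.distances, index=self.variants,
                            columns=[f"state_{s}" for s in range(self.n_states)])

    def summary(self) -> str:
        lines = [
            "Global decay fit",
            "=" * 50,
            f"variants: {len(self.variants)}   states: {self.n_states}",
            "state fractions: "
            + ", ".join(f"{x:.3f}" for x in self.state_fractions),
            "sigmas (A): " + ", ".join(f"{s:.2f}" for s in self.sigmas),
            f"mean chi2_r: {self.mean_chi2r:.3f}",
            "-" * 50,
            f"{'variant':>10} " + " ".join(f"{'R_'+str(s):>8}"
                                           for s in range(self.n_states))
            + f" {'x_noFRET':>9} {'chi2_r':>8}",
        ]
        c2 = self.chi2r()
        for i, v in enumerate(self.variants):
            lines.append(
                f"{v:>10} "
                + " ".join(f"{self.distances[i, s]:8.2f}"
                           for s in range(self.n_states))
                + f" {self.no_fret_for(v):9.3f} {c2[v]:8.3f}")
        return "\n".join(lines)


def select_model(fits: Dict[int, object], margin: float = 0.05,
                 min_improved: int = 3) -> dict:
    """Model-order selection over nested global fits.

    ``fits`` maps number of states -> either a :class:`GlobalDecayResult`
    or a per-variant chi2_r mapping/array. Starting from the smallest
    order, a larger model is adopted only if it lowers the average reduced
    chi-square by more than ``margin`` (fractionally) and individually
    improves at least ``min_improved`` variants by that margin.
    """
    orders = sorted(fits)
    if len(orders) < 2:
        raise ValueError("need nested fits at two or more model orders")

    def chi_vector(f):
        if hasattr(f, "chi2r"):
            return np.array(list(f.chi2r().values()))
        if isinstance(f, dict):
            return np.array(list(f.values()), float)
        return np.asarray(f, float)

    vecs = {n: chi_vector(fits[n]) for n in orders}
    sizes = {len(v) for v in vecs.values()}
    if len(sizes) != 1:
        raise ValueError("fits are not nested over the same variants")

    selected = orders[0]
    report = []
    for lo, hi in zip(orders[:-1], orders[1:]):
        avg_lo, avg_hi = vecs[lo].mean(), vecs[hi].mean()
        improved = int(np.sum(vecs[hi] < vecs[lo] * (1 - margin)))
        adopt = (avg_hi < avg_lo * (1 - margin)) and improved >= min_improved
        report.append({"from": lo, "to": hi, "avg_from": float(avg_lo),
                       "avg_to": float(avg_hi), "n_improved": improved,
                       "adopted": bool(adopt)})
        if adopt and selected == lo:
            selected = hi
        elif not adopt:
            break
    return {"selected": selected, "steps": report}


# ---------------------------------------------------------------------------
# FRET network robustness
# ---------------------------------------------------------------------------

@dataclass
class FnrResult:
    """Subsampled-refit deviations of the network distances."""

    subsets: List[tuple]
    refit_distances: List[np.ndarray]       # per subset, (len(subset), n_states)
    deviations_pct: Dict[tuple, list] = field(default_factory=dict)
    sd_pct: Dict[tuple, float] = field(default_factory=dict)

    def deviation_frame(self):
        import pandas as pd
        rows = [(v, s, d) for (v, s), devs in self.deviations_pct.items()
                for d in devs]
        return pd.DataFrame(rows, columns=["variant", "state", "deviation_pct"])


def draw_subsets(variants: Sequence[str], n_subsets: int, min_size: int,
                 min_membership: int, rng) -> List[tuple]:
    """Random variant subsets, each variant in >= min_membership of them."""
    nv = len(variants)
    if min_size > nv - 1:
        raise ValueError("min_size leaves no room for subsampling")
    if n_subsets * (nv - 1) < min_membership * nv:
        raise ValueError("membership constraint infeasible for this subset count")
    for _ in range(500):
        subsets = []
        for _ in range(n_subsets):
            size = int(rng.integers(min_size, nv))  # min_size .. nv-1
            subsets.append(tuple(sorted(rng.choice(nv, size=size, replace=False))))
        counts = np.bincount(np.concatenate([np.array(s) for s in subsets]),
                             minlength=nv)
        if counts.min() >= min_membership:
            return [tuple(variants[i] for i in s) for s in subsets]
    raise RuntimeError("could not satisfy the subset membership constraint")


def fnr_analysis(decays: Dict[str, DecayDataset], full_fit: GlobalDecayResult,
                 n_subsets: int = 50, min_size: int = 5,
                 min_membership: int = 3, seed: int = 0,
                 n_restarts: int = 1) -> FnrResult:
    """Refit random sub-networks and record the percent deviation of each
    refit distance from the full-network fit.

    Each subset keeps the model order of the full fit; refits start from
    the full-fit parameters (the deviations measure data support, not
    optimizer wandering).
    """
    if min_size < 5:
        raise ValueError("FNR subsets need at least five variants")
    rng = np.random.default_rng(check_seed(seed))
    variants = full_fit.variants
    subsets = draw_subsets(variants, n_subsets, min_size, min_membership, rng)

    result = FnrResult(subsets=subsets, refit_distances=[])
    dev_acc: Dict[tuple, list] = {}
    for subset in subsets:
        sub_decays = {v: decays[v] for v in subset}
        donor = full_fit.model.donor
        if isinstance(donor, dict):
            donor = {v: donor[v] for v in subset}
        m = GlobalDecayModel(sub_decays, donor, n_states=full_fit.n_states,
                             forster_radius=full_fit.model.forster_radius,
                             shared_no_fret=full_fit.model.shared_no_fret)
        idx = [variants.index(v) for v in subset]
        nf0 = (full_fit.no_fret if full_fit.no_fret.size == 1
               else full_fit.no_fret[idx])
        x0 = m._pack(full_fit.state_fractions, full_fit.sigmas, nf0,
                     full_fit.distances[idx])
        res = m.fit(n_restarts=n_restarts, seed=int(rng.integers(2**31)), x0=x0)
        result.refit_distances.append(res.distances)
        for j, v in enumerate(subset):
            i = variants.index(v)
            for s in range(full_fit.n_states):
                ref = full_fit.distances[i, s]
                dev = 100.0 * (res.distances[j, s] - ref) / ref
                dev_acc.setdefault((v, s), []).append(float(dev))
    result.deviations_pct = dev_acc
    result.sd_pct = {k: float(np.std(vv)) for k, vv in dev_acc.items()}
    return result


def fnr_bounds(fnr: FnrResult, full_fit: GlobalDecayResult,
               floor: float = 2.0, convention: str = "R_DA_E"
               ) -> List[DistanceRestraint]:
    """Distance restraints: full-fit mean +/- max(FNR SD in Å, floor)."""
    out = []
    for i, v in enumerate(full_fit.variants):
        for s in range(full_fit.n_states):
            mean = float(full_fit.distances[i, s])
            sd_pct = fnr.sd_pct.get((v, s), 0.0)
            bound = max(sd_pct / 100.0 * mean, floor)
            out.append(DistanceRestraint(
                variant=v, state=s, mean=mean, uncertainty=bound,
                lower=max(mean - bound, 1e-3), upper=mean + bound,
                convention=convention))
    return out
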