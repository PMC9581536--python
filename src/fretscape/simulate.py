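"""Synthetic-data generators for every stage of the pipeline.

The generators emulate the statistical structure the analysis assumes: a
FRET network of labeling variants reporting on a shared two-state (plus
no-FRET) conformational ensemble with slow telegraph exchange,
multi-exponential donor photophysics, Poisson shot noise, pulsed
interleaved excitation, Gaussian-profile confocal transits, TIRF-style
intensity traces with single-step photobleaching, and coarse bead-model
"proteins" for accessible-volume / docking / screening tests.

Everything is bit-reproducible per seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (DecayDataset, FretNetwork, FretVariant, GroundTruth,
                   PhotonStream, StructureModel, check_seed)
from .decay import DonorModel, model_decay

__all__ = [
    "gen_network", "simulate_decay", "simulate_photon_stream",
    "simulate_tirf_traces", "gen_toy_structures", "simulate_kinetics",
    "simulate_isotherm", "TirfTrace", "ToySnapshot", "telegraph_trajectory",
]

# the 12 variants measured on the PSG supramodule, grouped by domain pair
_VARIANT_TABLE = [
    ("P2-G6", "PDZ3-GuK", "P2", "G6"),
    ("P3-S2", "PDZ3-SH3", "P3", "S2"),
    ("S2-G6", "SH3-GuK", "S2", "G6"),
    ("P3-G4", "PDZ3-GuK", "P3", "G4"),
    ("P2-S2", "PDZ3-SH3", "P2", "S2"),
    ("S3-G1", "SH3-GuK", "S3", "G1"),
    ("P2-G1", "PDZ3-GuK", "P2", "G1"),
    ("S1-G1", "SH3-GuK", "S1", "G1"),
    ("P3-G5", "PDZ3-GuK", "P3", "G5"),
    ("P1-G3", "PDZ3-GuK", "P1", "G3"),
    ("P1-G4", "PDZ3-GuK", "P1", "G4"),
    ("P1-G2", "PDZ3-GuK", "P1", "G2"),
]

DEFAULT_FRACTIONS = (0.461, 0.539)   # state A / state B occupancies
DEFAULT_NO_FRET = 0.06
#: state A sits in the broad, fuzzy basin; state B in the discrete one
DEFAULT_HALFWIDTHS = (8.0, 4.0)      # Å
DEFAULT_RELAXATION_S = 1e-3          # slow basin exchange, 1/(k12+k21)
DEFAULT_DONOR_TAUS = (4.1, 1.8)      # ns, Alexa488-like bi-exponential
DEFAULT_DONOR_AMPS = (0.8, 0.2)
DEFAULT_R0 = 52.0                    # Å
IRF_FWHM_DEFAULT = 0.25              # ns
PULSE_PERIOD_NS = 32.0               # PIE period; donor window = first half


def gen_network(n_variants: int = 12, seed: int = 0,
                state_fractions: Sequence[float] = DEFAULT_FRACTIONS,
                no_fret_fraction: float = DEFAULT_NO_FRET,
                relaxation_time_s: float = DEFAULT_RELAXATION_S,
                distance_range: Tuple[float, float] = (35.0, 75.0),
                halfwidths: Sequence[float] = DEFAULT_HALFWIDTHS,
                forster_radius: float = DEFAULT_R0,
                ) -> Tuple[FretNetwork, GroundTruth]:
    """Generate a FRET network over a two-state conformational ensemble.

    Variant distances are spread over ``distance_range`` (default 35–75 Å,
    bracketing R0 so both limiting states are resolvable): each variant
    keeps one state distance in the FRET-sensitive range (below ~58 Å for
    the default R0) and the two state distances 8–17 Å apart, as for
    labeling sites pre-screened for usability. State A carries the broader
    distance halfwidth (fuzzy basin), state B the narrower one. The
    exchange rates are set so the stationary occupancy equals
    ``state_fractions`` with the requested relaxation time.
    """
    if n_variants < 2:
        raise ValueError("a FRET network needs at least two variants to be "
                         "identifiable in a global fit")
    rng = np.random.default_rng(check_seed(seed))
    rows = [_VARIANT_TABLE[i % len(_VARIANT_TABLE)] for i in range(n_variants)]
    names_seen, variants = set(), []
    for i, (name, pair, sa, sb) in enumerate(rows):
        if name in names_seen:
            name = f"{name}.{i // len(_VARIANT_TABLE)}"
        names_seen.add(name)
        variants.append(FretVariant(name, pair, sa, sb))

    x = np.asarray(state_fractions, float)
    ksum = 1.0 / relaxation_time_s if relaxation_time_s > 0 else 0.0
    rates = {(0, 1): x[1] * ksum, (1, 0): x[0] * ksum} if len(x) == 2 else {}

    lo, hi = distance_range
    # near-state distances spread over the FRET-sensitive range (E >~ 0.3)
    lows = np.linspace(lo + 1, lo + 23.0, n_variants)
    rng.shuffle(lows)
    distances = {}
    for v, low in zip(variants, lows):
        if len(x) == 1:
            distances[v.name] = np.array([low])
            continue
        gaps = rng.uniform(8.0, 17.0, size=len(x) - 1)
        d = np.minimum(low + np.concatenate([[0.0], np.cumsum(gaps)]), hi)
        rng.shuffle(d)  # which state is the near one varies per variant
        distances[v.name] = d

    network = FretNetwork(tuple(variants), forster_radius,
                          np.asarray(DEFAULT_DONOR_TAUS),
                          np.asarray(DEFAULT_DONOR_AMPS))
    truth = GroundTruth(
        state_fractions=x, no_fret_fraction=no_fret_fraction,
        exchange_rates=rates, distances=distances,
        distance_halfwidths=np.asarray(halfwidths, float)[: len(x)],
        donor_lifetimes=network.donor_lifetimes,
        donor_amplitudes=network.donor_amplitudes,
        forster_radius=forster_radius)
    return network, truth


def _donor_model(truth: GroundTruth) -> DonorModel:
    return DonorModel(truth.donor_lifetimes, truth.donor_amplitudes)


def make_irf(time_ns: np.ndarray, fwhm: float = IRF_FWHM_DEFAULT,
             center: float = 2.0, total: int = 100_000) -> np.ndarray:
    """Gaussian instrument response sampled on the TCSPC bin centers."""
    sigma = max(fwhm, 1e-3) / 2.3548
    pdf = np.exp(-0.5 * ((time_ns - center) / sigma) ** 2)
    return np.round(pdf / pdf.sum() * total).astype(np.int64)


def simulate_decay(truth: GroundTruth, variant: str, n_photons: int,
                   irf_width: float = IRF_FWHM_DEFAULT, seed: int = 0,
                   n_bins: int = 256, window_ns: float = PULSE_PERIOD_NS / 2,
                   background_rate: float = 0.05) -> DecayDataset:
    """Poisson-sampled seTCSPC decay for one variant of the network.

    Counts are drawn around the IRF-convolved multi-state model; the
    donor-only reference histogram is simulated alongside with the same
    photon budget. A state at (effectively) infinite distance contributes
    the donor-only shape.
    """
    if n_photons <= 0:
        raise ValueError("n_photons must be positive")
    rng = np.random.default_rng(check_seed(seed))
    dt = window_ns / n_bins
    t = (np.arange(n_bins) + 0.5) * dt
    irf = make_irf(t, fwhm=irf_width)
    donor = _donor_model(truth)

    expected = model_decay(
        t, irf, donor, truth.distances[variant], truth.state_fractions,
        truth.distance_halfwidths, truth.forster_radius,
        no_fret_fraction=truth.no_fret_fraction,
        n_total=n_photons, background=background_rate)
    counts = rng.poisson(expected)

    d0_expected = model_decay(t, irf, donor, [1e6], [1.0], [0.0],
                              truth.forster_radius, n_total=n_photons,
                              background=background_rate)
    donor_only = rng.poisson(d0_expected)
    return DecayDataset(t, counts, irf, donor_only,
                        background_rate=background_rate)


# ---------------------------------------------------------------------------
# Confocal photon streams
# ---------------------------------------------------------------------------

def telegraph_trajectory(rng, k12: float, k21: float, duration: float,
                         initial: Optional[int] = None):
    """Jump times and states of a two-state continuous-time Markov chain.

    Returns (times, states): piecewise-constant state starting at times[i].
    """
    if k12 == 0 and k21 == 0:
        s0 = initial if initial is not None else int(rng.integers(2))
        return np.array([0.0]), np.array([s0])
    p1 = k21 / (k12 + k21) if (k12 + k21) > 0 else 0.5
    s = initial if initial is not None else int(rng.random() >= p1)
    t, times, states = 0.0, [0.0], [s]
    rates = (k12, k21)
    while True:
        rate = rates[s]
        t += np.inf if rate == 0 else rng.exponential(1.0 / rate)
        if t >= duration:
            break
        s = 1 - s
        times.append(t)
        states.append(s)
    return np.asarray(times), np.asarray(states, dtype=np.int8)


def _state_at(times, states, query):
    idx = np.searchsorted(times, query, side="right") - 1
    return states[np.clip(idx, 0, len(states) - 1)]


def simulate_photon_stream(truth: GroundTruth, variant: str, duration: float,
                           brightness: float = 100.0, diffusion_time: float = 1.0,
                           seed: int = 0, transit_rate: float = 20.0,
                           background_rate: float = 200.0,
                           red_brightness_factor: float = 0.8,
                           acceptor_tau: float = 1.0,
                           pulse_period: float = PULSE_PERIOD_NS,
                           irf_width: float = IRF_FWHM_DEFAULT,
                           continuous: bool = False) -> PhotonStream:
    """Photon records from diffusing molecules under PIE excitation.

    Molecules transit the confocal volume as Poisson events (``transit_rate``
    per second) with a Gaussian intensity envelope whose width is drawn from
    an exponential of mean ``diffusion_time`` (ms). The conformational state
    follows the truth's telegraph exchange during each transit; donor-window
    photons split green/red according to the state's FRET efficiency and
    carry micro-times from the state's decay model. Direct acceptor
    excitation (second half of the PIE period) is simulated at a fixed
    brightness independent of state; a ``no_fret_fraction`` of transits are
    donor-only molecules lacking these photons.

    With ``continuous=True`` one molecule is held in the focus for the
    whole duration at constant brightness (no transits) — the clean
    telegraph world used to validate PDA and fFCS against the generator.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if brightness <= 0 or diffusion_time <= 0:
        raise ValueError("brightness and diffusion_time must be positive")
    rng = np.random.default_rng(check_seed(seed))
    donor = _donor_model(truth)
    r0 = truth.forster_radius
    dist = truth.distances[variant]
    sig = truth.distance_halfwidths
    k12 = truth.exchange_rates.get((0, 1), 0.0)
    k21 = truth.exchange_rates.get((1, 0), 0.0)
    window = pulse_period / 2.0
    irf_sigma = irf_width / 2.3548
    t0 = 2.0  # IRF centre within each excitation window, ns

    if continuous:
        transit_centers = np.array([duration / 2.0])
    else:
        n_transits = rng.poisson(transit_rate * duration)
        transit_centers = np.sort(rng.uniform(0, duration, n_transits))
    macro, micro, det, state_lbl = [], [], [], []

    def micro_green(n, tau_eff):
        m = t0 + rng.exponential(tau_eff, n) + rng.normal(0, irf_sigma, n)
        return np.mod(np.abs(m), window)

    def micro_red(n, offset=0.0):
        m = t0 + rng.exponential(acceptor_tau, n) + rng.normal(0, irf_sigma, n)
        return offset + np.mod(np.abs(m), window)

    for tc in transit_centers:
        if continuous:
            n_dex = rng.poisson(brightness * 1e3 * duration)
            times = np.sort(rng.uniform(0, duration, n_dex))
            sigma_t = duration
        else:
            sigma_t = rng.exponential(diffusion_time * 1e-3) / 2.0 + 1e-5
            n_dex = rng.poisson(brightness * 1e3 * sigma_t * np.sqrt(2 * np.pi))
            times = rng.normal(tc, sigma_t, n_dex)
            times = times[(times >= 0) & (times < duration)]
            n_dex = times.size
        is_no_fret = (not continuous) and rng.random() < truth.no_fret_fraction
        if is_no_fret or truth.n_states == 1:
            if is_no_fret:
                st = np.full(n_dex, -1, dtype=np.int8)
                rr = np.full(n_dex, 1e6)
            else:
                st = np.zeros(n_dex, dtype=np.int8)
                rr = rng.normal(dist[0], sig[0], n_dex)
        else:
            span = duration if continuous else 10 * sigma_t + 1e-9
            jt, js = telegraph_trajectory(rng, k12, k21, span)
            st = _state_at(jt + (times.min() if n_dex else 0.0), js, times
                           ).astype(np.int8)
            rr = rng.normal(dist[st], sig[st])
        rr = np.clip(rr, 5.0, None)
        eff = 1.0 / (1.0 + (rr / r0) ** 6)
        to_red = rng.random(n_dex) < eff
        # green (donor) photons: quenched exponential of a random component
        comp = rng.choice(len(donor.lifetimes), size=n_dex, p=donor.amplitudes)
        kt = (r0 / rr) ** 6 / donor.tau_fluorescence
        tau_eff = 1.0 / (1.0 / donor.lifetimes[comp] + kt)
        ng = int((~to_red).sum())
        macro.append(times[~to_red])
        micro.append(micro_green(ng, tau_eff[~to_red]))
        det.append(rng.integers(0, 2, ng).astype(np.int8))
        state_lbl.append(st[~to_red])
        nr = int(to_red.sum())
        macro.append(times[to_red])
        micro.append(micro_red(nr))
        det.append((2 + rng.integers(0, 2, nr)).astype(np.int8))
        state_lbl.append(st[to_red])
        if not is_no_fret:  # direct acceptor excitation checks the acceptor
            if continuous:
                n_aex = rng.poisson(red_brightness_factor * brightness * 1e3
                                    * duration)
                ta = rng.uniform(0, duration, n_aex)
            else:
                n_aex = rng.poisson(red_brightness_factor * brightness * 1e3
                                    * sigma_t * np.sqrt(2 * np.pi))
                ta = rng.normal(tc, sigma_t, n_aex)
                ta = ta[(ta >= 0) & (ta < duration)]
            macro.append(ta)
            micro.append(micro_red(ta.size, offset=window))
            det.append((2 + rng.integers(0, 2, ta.size)).astype(np.int8))
            state_lbl.append(np.full(ta.size, -1, dtype=np.int8))

    n_bg = rng.poisson(background_rate * duration)
    macro.append(rng.uniform(0, duration, n_bg))
    micro.append(rng.uniform(0, pulse_period, n_bg))
    det.append(rng.integers(0, 4, n_bg).astype(np.int8))
    state_lbl.append(np.full(n_bg, -1, dtype=np.int8))

    macro = np.concatenate(macro)
    order = np.argsort(macro, kind="stable")
    micro = np.clip(np.concatenate(micro)[order], 0, pulse_period * (1 - 1e-9))
    return PhotonStream(macro[order], micro,
                        np.concatenate(det)[order], pulse_period,
                        state=np.concatenate(state_lbl)[order])


# ---------------------------------------------------------------------------
# TIRF traces
# ---------------------------------------------------------------------------

@dataclass
class TirfTrace:
    """A per-molecule donor/acceptor intensity time trace (frames)."""

    i_donor: np.ndarray
    i_acceptor: np.ndarray
    frame_rate: float
    acceptor_bleach_frame: Optional[int] = None  # truth annotation
    donor_bleach_frame: Optional[int] = None
    states: Optional[np.ndarray] = None

    @property
    def n_frames(self):
        return self.i_donor.size

    @property
    def times(self):
        return np.arange(self.n_frames) / self.frame_rate


def simulate_tirf_traces(truth: GroundTruth, n_molecules: int = 50,
                         frame_rate: float = 10.0, bleach_rate: float = 0.05,
                         seed: int = 0, variant: Optional[str] = None,
                         n_frames: int = 400, total_intensity: float = 1000.0,
                         noise_sd: float = 30.0) -> List[TirfTrace]:
    """TIRF-style intensity traces: anti-correlated two-state switching,
    additive Gaussian noise, single-step acceptor then donor bleaching."""
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    rng = np.random.default_rng(check_seed(seed))
    variant = variant or next(iter(truth.distances))
    dist = truth.distances[variant]
    eff = 1.0 / (1.0 + (dist / truth.forster_radius) ** 6)
    k12 = truth.exchange_rates.get((0, 1), 0.0)
    k21 = truth.exchange_rates.get((1, 0), 0.0)
    t_frames = np.arange(n_frames) / frame_rate
    duration = n_frames / frame_rate
    traces = []
    for _ in range(n_molecules):
        if truth.n_states == 2:
            jt, js = telegraph_trajectory(rng, k12, k21, duration)
            st = _state_at(jt, js, t_frames)
        else:
            st = np.zeros(n_frames, dtype=int)
        e = eff[st]
        ia = total_intensity * e
        idn = total_intensity * (1.0 - e)
        ab = rng.exponential(1.0 / bleach_rate) if bleach_rate > 0 else np.inf
        db = ab + (rng.exponential(1.0 / bleach_rate) if bleach_rate > 0 else np.inf)
        ab_f = int(ab * frame_rate) if ab < duration else None
        db_f = int(db * frame_rate) if db < duration else None
        if ab_f is not None:
            ia[ab_f:] = 0.0
            idn[ab_f:] = total_intensity
        if db_f is not None:
            idn[db_f:] = 0.0
        traces.append(TirfTrace(
            i_donor=idn + rng.normal(0, noise_sd, n_frames),
            i_acceptor=ia + rng.normal(0, noise_sd, n_frames),
            frame_rate=frame_rate, acceptor_bleach_frame=ab_f,
            donor_bleach_frame=db_f, states=st.astype(np.int8)))
    return traces


# ---------------------------------------------------------------------------
# Toy bead structures for AV / docking / screening
# ---------------------------------------------------------------------------

@dataclass
class ToySnapshot:
    """One snapshot of the toy ensemble: a rigid placement of the mobile body."""

    rotation: np.ndarray     # (3, 3)
    translation: np.ndarray  # (3,) applied to the mobile body COM frame
    cluster: int             # planted cluster label

    def place(self, mobile: StructureModel) -> StructureModel:
        return mobile.transformed(self.rotation, self.translation)

    def assemble(self, fixed: StructureModel,
                 mobile: StructureModel) -> StructureModel:
        m = self.place(mobile)
        return StructureModel(
            name=f"snapshot_c{self.cluster}",
            coords=np.vstack([fixed.coords, m.coords]),
            radii=np.concatenate([fixed.radii, m.radii]),
            residue_ids=np.concatenate([fixed.residue_ids,
                                        m.residue_ids + 1000]),
            sites={**fixed.sites,
                   **{k: v + len(fixed) for k, v in m.sites.items()}})


def _blob(rng, center, radius, n_beads, bead_radius=3.0):
    pts = []
    while len(pts) < n_beads:
        p = rng.uniform(-radius, radius, 3)
        if np.linalg.norm(p) <= radius - bead_radius:
            pts.append(p + np.asarray(center, float))
    return np.asarray(pts)


def _surface_site(center, radius, direction):
    d = np.asarray(direction, float)
    return np.asarray(center, float) + d / np.linalg.norm(d) * (radius + 1.0)


def _small_rotation(rng, max_angle_deg=6.0):
    from scipy.spatial.transform import Rotation
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = np.deg2rad(rng.uniform(0, max_angle_deg))
    return Rotation.from_rotvec(axis * ang).as_matrix()


def gen_toy_structures(seed: int = 0, n_snapshots: int = 500,
                       occupancies: Sequence[float] = (0.46, 0.54)
                       ) -> Tuple[StructureModel, StructureModel, List[ToySnapshot]]:
    """Coarse bead 'proteins' plus a planted two-cluster snapshot ensemble.

    The fixed body holds two blobs (an SH3-like and a GuK-like domain) with
    labeled surface sites S1–S3 and G1–G6; the mobile body is a PDZ3-like
    blob with sites P1–P3. Snapshots place the mobile body in two spatial
    clusters with exact planted occupancies (round(occ * n) members each).
    """
    rng = np.random.default_rng(check_seed(seed))
    sh3_c, sh3_r = np.array([0.0, 0.0, 0.0]), 12.0
    guk_c, guk_r = np.array([30.0, 0.0, 0.0]), 14.0
    core = np.vstack([_blob(rng, sh3_c, sh3_r, 25), _blob(rng, guk_c, guk_r, 30)])
    site_dirs = {
        "S1": (sh3_c, sh3_r, [0, 1, 0]), "S2": (sh3_c, sh3_r, [0, -1, 0.3]),
        "S3": (sh3_c, sh3_r, [-1, 0, 0.5]),
        "G1": (guk_c, guk_r, [1, 0, 0]), "G2": (guk_c, guk_r, [0, 1, 0]),
        "G3": (guk_c, guk_r, [0, -1, 0]), "G4": (guk_c, guk_r, [0.5, 0, 1]),
        "G5": (guk_c, guk_r, [0.5, 0, -1]), "G6": (guk_c, guk_r, [1, 1, 0]),
    }
    site_coords = np.array([_surface_site(*v) for v in site_dirs.values()])
    coords = np.vstack([core, site_coords])
    fixed = StructureModel(
        name="SH3-GuK", coords=coords,
        radii=np.full(len(coords), 3.0),
        residue_ids=np.arange(len(coords)) + 1,
        sites={k: len(core) + i for i, k in enumerate(site_dirs)},
        linker_terminus=0)

    pdz_r = 10.0
    pcore = _blob(rng, [0, 0, 0], pdz_r, 18)
    pdirs = {"P1": [1, 0, 0], "P2": [0, 1, 0], "P3": [-0.5, -1, 0.5]}
    psites = np.array([_surface_site([0, 0, 0], pdz_r, d) for d in pdirs.values()])
    pcoords = np.vstack([pcore, psites])
    mobile = StructureModel(
        name="PDZ3", coords=pcoords - pcoords.mean(axis=0),
        radii=np.full(len(pcoords), 3.0),
        residue_ids=np.arange(len(pcoords)) + 1,
        sites={k: len(pcore) + i for i, k in enumerate(pdirs)},
        linker_terminus=0)

    from scipy.spatial.transform import Rotation
    centers = {0: np.array([-8.0, 28.0, 0.0]), 1: np.array([30.0, -26.0, 12.0])}
    base_rot = {0: Rotation.from_euler("xyz", [20, 40, 0], degrees=True).as_matrix(),
                1: Rotation.from_euler("xyz", [0, -30, 60], degrees=True).as_matrix()}
    n_a = int(round(occupancies[0] * n_snapshots))
    labels = np.array([0] * n_a + [1] * (n_snapshots - n_a))
    snapshots = []
    for lbl in labels:
        rot = _small_rotation(rng) @ base_rot[lbl]
        trans = centers[lbl] + rng.normal(0, 1.5, 3) - mobile.center_of_mass
        snapshots.append(ToySnapshot(rotation=rot, translation=trans,
                                     cluster=int(lbl)))
    return fixed, mobile, snapshots


# ---------------------------------------------------------------------------
# Kinetics and binding isotherms
# ---------------------------------------------------------------------------

def simulate_kinetics(k: float, y0: float, yf: float, times: Sequence[float],
                      noise_sd: float = 0.0, seed: int = 0,
                      n_replicates: int = 1) -> pd.DataFrame:
    """Single-exponential approach y(t) = yf - (yf - y0) exp(-k t) + noise."""
    if k < 0:
        raise ValueError("rate constant must be nonnegative")
    rng = np.random.default_rng(check_seed(seed))
    t = np.asarray(times, float)
    rows = []
    for rep in range(n_replicates):
        y = yf - (yf - y0) * np.exp(-k * t) + rng.normal(0, noise_sd, t.size)
        rows.append(pd.DataFrame({"time": t, "fraction": y, "replicate": rep}))
    return pd.concat(rows, ignore_index=True)


def simulate_isotherm(kd: float, n_hill: float, a0: float, amax: float,
                      concentrations: Sequence[float], noise_sd: float = 0.0,
                      seed: int = 0, n_replicates: int = 1) -> pd.DataFrame:
    """Hill binding isotherm A(c) = A0 + (Amax-A0) c^n / (KD^n + c^n)."""
    if kd <= 0:
        raise ValueError("KD must be positive")
    c = np.asarray(concentrations, float)
    if np.any(c < 0):
        raise ValueError("concentrations must be nonnegative")
    rng = np.random.default_rng(check_seed(seed))
    rows = []
    for rep in range(n_replicates):
        a = a0 + (amax - a0) * c**n_hill / (kd**n_hill + c**n_hill)
        a = a + rng.normal(0, noise_sd, c.size)
        rows.append(pd.DataFrame({"conc_uM": c, "anisotropy": a,
                                  "replicate": rep}))
    return pd.concat(rows, ignore_index=True)
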