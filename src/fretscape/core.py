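"""Core containers shared across the analysis stages.

The pipeline models a single-molecule FRET *network*: one protein measured
as many dye-labeling variants, each reporting a distance between two domains.
All stages (decay fitting, burst analysis, exchange dynamics, structural
modeling) consume or produce the containers defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "FretVariant",
    "FretNetwork",
    "GroundTruth",
    "PhotonStream",
    "DecayDataset",
    "StructureModel",
    "DistanceRestraint",
    "CHANNELS",
]

#: Detector channel codes: green/red x parallel/perpendicular polarization.
CHANNELS = {"G_par": 0, "G_perp": 1, "R_par": 2, "R_perp": 3}


@dataclass(frozen=True)
class FretVariant:
    """One dye-labeling variant: a pair of attachment sites on two domains."""

    name: str
    domain_pair: str  # e.g. "PDZ3-GuK", "PDZ3-SH3", "SH3-GuK"
    site_a: str       # attachment-site label on the first domain
    site_b: str       # attachment-site label on the second domain


@dataclass(frozen=True)
class FretNetwork:
    """A set of FRET variants with shared dye photophysics.

    Parameters
    ----------
    variants : tuple of FretVariant
    forster_radius : float
        Förster radius R0 of the dye pair in Å.
    donor_lifetimes : ndarray
        Donor-only fluorescence lifetime components, ns.
    donor_amplitudes : ndarray
        Species amplitudes of the donor lifetime components; normalized to 1.
    """

    variants: tuple
    forster_radius: float
    donor_lifetimes: np.ndarray
    donor_amplitudes: np.ndarray

    def __post_init__(self):
        taus = np.asarray(self.donor_lifetimes, dtype=float)
        amps = np.asarray(self.donor_amplitudes, dtype=float)
        if taus.size < 1:
            raise ValueError("at least one donor lifetime component required")
        if np.any(taus <= 0) or np.any(amps < 0):
            raise ValueError("donor lifetimes must be > 0 and amplitudes >= 0")
        object.__setattr__(self, "donor_lifetimes", taus)
        object.__setattr__(self, "donor_amplitudes", amps / amps.sum())

    @property
    def variant_names(self):
        return [v.name for v in self.variants]

    def domain_pair_classes(self):
        return sorted({v.domain_pair for v in self.variants})


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters of a two-basin conformational ensemble.

    ``state_fractions`` are occupancies among FRET-active molecules and sum
    to 1; ``no_fret_fraction`` is the separate fraction of molecules with an
    inactive acceptor, so the full species composition
    ``(x_s * (1 - x_nf), x_nf)`` sums to 1.
    """

    state_fractions: np.ndarray                 # per conformational state
    no_fret_fraction: float                     # donor-only species fraction
    exchange_rates: dict                        # {(i, j): rate s^-1}
    distances: dict                             # {variant name: ndarray per state, Å}
    distance_halfwidths: np.ndarray             # Gaussian half-width per state, Å
    donor_lifetimes: np.ndarray                 # ns
    donor_amplitudes: np.ndarray
    forster_radius: float                       # Å

    def __post_init__(self):
        x = np.asarray(self.state_fractions, dtype=float)
        if np.any(x < 0) or np.any(x > 1) or not np.isclose(x.sum(), 1.0):
            raise ValueError("state fractions must lie in [0,1] and sum to 1")
        if not 0 <= self.no_fret_fraction <= 1:
            raise ValueError("no-FRET fraction must lie in [0,1]")
        for v, d in self.distances.items():
            if np.any(np.asarray(d, dtype=float) <= 0):
                raise ValueError(f"distances for variant {v} must be > 0")
        for pair, k in self.exchange_rates.items():
            if k < 0:
                raise ValueError(f"exchange rate {pair} must be >= 0")
        taus = np.asarray(self.donor_lifetimes, dtype=float)
        if taus.size < 1 or np.any(taus <= 0):
            raise ValueError("at least one positive donor lifetime required")
        object.__setattr__(self, "state_fractions", x)
        object.__setattr__(self, "distances",
                           {k: np.asarray(v, float) for k, v in self.distances.items()})
        object.__setattr__(self, "distance_halfwidths",
                           np.asarray(self.distance_halfwidths, float))
        object.__setattr__(self, "donor_lifetimes", taus)
        a = np.asarray(self.donor_amplitudes, float)
        object.__setattr__(self, "donor_amplitudes", a / a.sum())

    @property
    def n_states(self) -> int:
        return len(self.state_fractions)

    def stationary_fractions(self) -> np.ndarray:
        """Stationary distribution of the two-state exchange Markov chain."""
        if self.n_states != 2:
            return self.state_fractions
        k12 = self.exchange_rates.get((0, 1), 0.0)
        k21 = self.exchange_rates.get((1, 0), 0.0)
        if k12 + k21 == 0:
            return self.state_fractions
        return np.array([k21, k12]) / (k12 + k21)


@dataclass
class PhotonStream:
    """Time-tagged photon records from a pulsed-interleaved-excitation setup.

    macro_times are absolute arrival times in seconds (nondecreasing);
    micro_times are TCSPC times within the pulse period in ns. The first half
    of the period is the donor-excitation window, the second half the direct
    acceptor-excitation window. ``detector`` holds the channel codes of
    :data:`CHANNELS`. ``state`` is an optional ground-truth annotation (the
    conformational state that emitted each photon) carried by the simulator.
    """

    macro_times: np.ndarray   # s
    micro_times: np.ndarray   # ns
    detector: np.ndarray      # int8 codes, see CHANNELS
    pulse_period: float       # ns
    state: Optional[np.ndarray] = None

    def __post_init__(self):
        self.macro_times = np.asarray(self.macro_times, dtype=np.float64)
        self.micro_times = np.asarray(self.micro_times, dtype=np.float64)
        self.detector = np.asarray(self.detector, dtype=np.int8)
        if np.any(np.diff(self.macro_times) < 0):
            raise ValueError("macro times must be nondecreasing")
        if self.micro_times.size and self.micro_times.max() >= self.pulse_period:
            raise ValueError("micro times must be below the pulse period")

    def __len__(self):
        return self.macro_times.size

    @property
    def donor_window(self) -> np.ndarray:
        """Boolean mask of photons detected after the donor pulse."""
        return self.micro_times < self.pulse_period / 2.0

    @property
    def is_green(self) -> np.ndarray:
        return self.detector <= 1

    @property
    def is_red(self) -> np.ndarray:
        return self.detector >= 2

    @property
    def duration(self) -> float:
        return float(self.macro_times[-1]) if len(self) else 0.0


@dataclass
class DecayDataset:
    """A TCSPC decay histogram plus its instrument response and donor-only
    reference, all on the same time axis (bin centers, ns)."""

    time_ns: np.ndarray
    counts: np.ndarray
    irf_counts: np.ndarray
    donor_only_counts: np.ndarray
    background_rate: float = 0.0  # expected background counts per bin

    def __post_init__(self):
        self.time_ns = np.asarray(self.time_ns, dtype=float)
        for name in ("counts", "irf_counts", "donor_only_counts"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != self.time_ns.shape:
                raise ValueError(f"{name} must match the time axis length")
            if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
                raise ValueError(f"{name} must be nonnegative integers")
            setattr(self, name, arr.astype(np.int64))

    @property
    def bin_width(self) -> float:
        return float(self.time_ns[1] - self.time_ns[0])

    @property
    def n_bins(self) -> int:
        return self.time_ns.size


@dataclass
class StructureModel:
    """A (coarse-grained) protein body: one bead per residue.

    ``sites`` maps labeling-site names to bead indices; ``linker_terminus``
    is the bead index where the interdomain linker attaches (used for the
    docking linker-feasibility constraint).
    """

    name: str
    coords: np.ndarray                 # (N, 3) Å
    radii: np.ndarray                  # (N,) effective vdW radii, Å
    residue_ids: np.ndarray            # (N,) int
    sites: dict = field(default_factory=dict)
    linker_terminus: Optional[int] = None

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.radii = np.asarray(self.radii, dtype=float)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        for nm, idx in self.sites.items():
            if not 0 <= idx < len(self.coords):
                raise ValueError(f"site {nm} points outside the structure")

    def __len__(self):
        return len(self.coords)

    @property
    def center_of_mass(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def site_coord(self, name: str) -> np.ndarray:
        return self.coords[self.sites[name]]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    about: Optional[np.ndarray] = None) -> "StructureModel":
        """Rigidly transform the body: rotate about ``about`` (default: its
        center of mass) then translate."""
        pivot = self.center_of_mass if about is None else np.asarray(about)
        new = (self.coords - pivot) @ np.asarray(rotation).T + pivot + translation
        return replace(self, coords=new)


@dataclass(frozen=True)
class DistanceRestraint:
    """A per-variant, per-state mean inter-dye distance with bounds."""

    variant: str
    state: int
    mean: float          # Å
    uncertainty: float   # Å (half-width of the bound)
    lower: float
    upper: float
    convention: str = "R_DA_E"  # one of R_mp | R_DA_mean | R_DA_E

    def __post_init__(self):
        if not (0 < self.lower <= self.mean <= self.upper):
            raise ValueError("restraint must satisfy 0 < lower <= mean <= upper")


def check_seed(seed) -> int:
    seed = int(seed)
    if seed < 0:
        raise ValueError("seed must be nonnegative")
    return seed
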