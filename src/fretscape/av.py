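"""Grid-based accessible-volume (AV) simulation of dye positions.

A dye on a flexible linker is modeled as a sphere (radius r) tethered to
an attachment atom by a linker of length L and width w. The accessible
volume is every grid point the dye center can reach: the geodesic path
from the attachment point must keep a clearance of w/2 from all obstacles
and stay within length L, and the dye center itself must clear every
heavy atom by (atom vdW radius + r). All points are weighted uniformly.

The AV pair of a donor and acceptor yields the three distance measures of
the FRET-positioning literature: the mean-position distance R_mp, the
mean inter-dye distance ⟨R_DA⟩, and the FRET-averaged apparent distance
R_DA,E = R0 (⟨E⟩^-1 - 1)^(1/6).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .core import StructureModel, check_seed

__all__ = ["AVCloud", "AVDistances", "compute_av", "av_distances",
           "convert_distance", "EmptyAVError", "DEFAULT_DYE"]

#: AV1-style single-radius dye defaults: linker length / width, dye radius (Å)
DEFAULT_DYE = {"linker_length": 21.0, "linker_width": 4.5, "dye_radius": 3.5}


class EmptyAVError(RuntimeError):
    pass


@dataclass
class AVCloud:
    """Dye accessible volume: allowed grid points with occupancy weights."""

    points: np.ndarray        # (M, 3) Å
    weights: np.ndarray       # sum to 1
    attachment_point: np.ndarray
    linker_length: float
    linker_width: float
    dye_radius: float
    grid_spacing: float

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, float))
        w = np.asarray(self.weights, float)
        self.weights = w / w.sum()

    @property
    def mean_position(self) -> np.ndarray:
        return self.weights @ self.points

    @property
    def volume(self) -> float:
        """Accessible volume in Å^3 (points x cell volume)."""
        return len(self.points) * self.grid_spacing**3

    def transformed(self, rotation, translation, about) -> "AVCloud":
        rot = np.asarray(rotation)
        pivot = np.asarray(about)
        pts = (self.points - pivot) @ rot.T + pivot + translation
        att = (self.attachment_point - pivot) @ rot.T + pivot + translation
        return AVCloud(pts, self.weights, att, self.linker_length,
                       self.linker_width, self.dye_radius, self.grid_spacing)


# all primitive offsets within Chebyshev radius 2: the richer neighborhood
# keeps the lattice geodesic within ~2% of the Euclidean distance
_NEIGHBORS = np.array([
    (i, j, k)
    for i in range(-2, 3) for j in range(-2, 3) for k in range(-2, 3)
    if (i, j, k) != (0, 0, 0)
    and np.gcd.reduce(np.abs(np.array([i, j, k]))) == 1
])


def compute_av(structure: StructureModel, site: str,
               linker_length: float = DEFAULT_DYE["linker_length"],
               linker_width: float = DEFAULT_DYE["linker_width"],
               dye_radius: float = DEFAULT_DYE["dye_radius"],
               grid_spacing: float = 0.8) -> AVCloud:
    """Accessible volume at a labeling site by geodesic grid search.

    The attachment atom itself is excluded from the obstacle list (the
    linker is bonded to it). Raises :class:`EmptyAVError` when the
    attachment point is fully buried.
    """
    if not 0.2 <= grid_spacing <= 2.0:
        raise ValueError("grid spacing must lie in [0.2, 2] Å")
    if site not in structure.sites:
        raise KeyError(f"site {site!r} not present on {structure.name}")
    att_idx = structure.sites[site]
    att = structure.coords[att_idx]
    mask = np.ones(len(structure), dtype=bool)
    mask[att_idx] = False
    obstacles = structure.coords[mask]
    radii = structure.radii[mask]

    n_half = int(np.ceil(linker_length / grid_spacing))
    axis = np.arange(-n_half, n_half + 1) * grid_spacing
    shape = (axis.size,) * 3
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3) + att

    clearance = np.full(pts.shape[0], np.inf)
    if len(obstacles):
        for c, r in zip(obstacles, radii):  # beads are few; loop is cheap
            d = np.linalg.norm(pts - c, axis=1) - r
            np.minimum(clearance, d, out=clearance)

    in_sphere = np.linalg.norm(pts - att, axis=1) <= linker_length
    path_ok = (clearance >= linker_width / 2.0) & in_sphere
    center_ok = (clearance >= dye_radius) & in_sphere
    path3d = path_ok.reshape(shape)
    src = np.ravel_multi_index((n_half, n_half, n_half), shape)
    if not path_ok[src]:
        # the attachment point sits at the body surface; allow the source
        path_ok[src] = True
        path3d = path_ok.reshape(shape)
    if path3d.sum() < 2:
        raise EmptyAVError(f"attachment site {site} is fully buried")

    # sparse geodesic graph over path-allowed cells (26-connectivity)
    node_id = -np.ones(pts.shape[0], dtype=np.int64)
    free = np.flatnonzero(path_ok)
    node_id[free] = np.arange(free.size)
    ijk = np.stack(np.unravel_index(free, shape), axis=1)
    rows, cols, vals = [], [], []
    n = axis.size
    for off in _NEIGHBORS:
        nb = ijk + off
        ok = np.all((nb >= 0) & (nb < n), axis=1)
        nb_flat = np.ravel_multi_index(nb[ok].T, shape)
        ok2 = node_id[nb_flat] >= 0
        rows.append(np.arange(free.size)[ok][ok2])
        cols.append(node_id[nb_flat[ok2]])
        vals.append(np.full(ok2.sum(), np.linalg.norm(off) * grid_spacing))
    graph = coo_matrix((np.concatenate(vals),
                        (np.concatenate(rows), np.concatenate(cols))),
                       shape=(free.size, free.size)).tocsr()
    dist = dijkstra(graph, directed=False, indices=node_id[src])

    reach = np.zeros(pts.shape[0], dtype=bool)
    reach[free] = dist <= linker_length
    allowed = reach & center_ok
    if not allowed.any():
        raise EmptyAVError(f"no accessible dye positions at site {site}")
    cloud_pts = pts[allowed]
    return AVCloud(cloud_pts, np.full(len(cloud_pts), 1.0 / len(cloud_pts)),
                   att.copy(), linker_length, linker_width, dye_radius,
                   grid_spacing)


@dataclass(frozen=True)
class AVDistances:
    r_mp: float
    r_da_mean: float
    r_da_e: float
    mean_efficiency: float

    def by_convention(self, convention: str) -> float:
        return {"R_mp": self.r_mp, "R_DA_mean": self.r_da_mean,
                "R_DA_E": self.r_da_e}[convention]


def av_distances(donor: AVCloud, acceptor: AVCloud, forster_radius: float,
                 n_samples: int = 100_000, seed: int = 0) -> AVDistances:
    """FRET distance measures from a donor/acceptor AV pair.

    ⟨R_DA⟩ and ⟨E⟩ come from weighted random pair sampling; coincident
    pairs (zero distance) are excluded with a warning.
    """
    if len(donor.points) == 0 or len(acceptor.points) == 0:
        raise ValueError("AV clouds must be nonempty")
    rng = np.random.default_rng(check_seed(seed))
    r_mp = float(np.linalg.norm(donor.mean_position - acceptor.mean_position))
    if len(donor.points) == 1 and len(acceptor.points) == 1:
        d = np.array([r_mp])
    else:
        di = rng.choice(len(donor.points), n_samples, p=donor.weights)
        ai = rng.choice(len(acceptor.points), n_samples, p=acceptor.weights)
        d = np.linalg.norm(donor.points[di] - acceptor.points[ai], axis=1)
    nz = d > 1e-9
    if not nz.all():
        import warnings
        warnings.warn(f"excluded {np.sum(~nz)} coincident dye-position pairs")
        d = d[nz]
    e = 1.0 / (1.0 + (d / forster_radius) ** 6)
    mean_e = float(e.mean())
    r_da_e = float(forster_radius * (1.0 / mean_e - 1.0) ** (1.0 / 6.0))
    return AVDistances(r_mp, float(d.mean()), r_da_e, mean_e)


def convert_distance(value: float, from_convention: str, to_convention: str,
                     donor: Optional[AVCloud] = None,
                     acceptor: Optional[AVCloud] = None,
                     forster_radius: float = 52.0, seed: int = 0) -> float:
    """Convert a distance between conventions using the AV pair distribution.

    The conversion is the additive offset between the two measures computed
    directly on the cloud pair (identity when the conventions coincide or
    the clouds are single points)."""
    if from_convention == to_convention:
        return float(value)
    if donor is None or acceptor is None:
        raise ValueError("cloud statistics required for distance conversion")
    stats = av_distances(donor, acceptor, forster_radius, seed=seed)
    return float(value + stats.by_convention(to_convention)
                 - stats.by_convention(from_convention))
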