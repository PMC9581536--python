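"""FRET-restrained structural modeling and the conformational landscape.

Rigid-body docking samples placements of a mobile domain against a fixed
body, scores each pose by the chi-square agreement between inter-AV dye
distances and the experimental FRET restraints, and reports an F-test
confidence ensemble. Snapshot ensembles (e.g. from an independent
simulation) are screened against per-state distance bounds. Contact-
probability maps, mean-linkage RMSD clustering, and a PCA-projected
potential of mean force (PMF = -kB T ln p) with basin rescaling complete
the landscape construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.ndimage import gaussian_filter
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist, squareform
from scipy.spatial.transform import Rotation

from .av import AVCloud, compute_av
from .core import DistanceRestraint, StructureModel, check_seed

__all__ = [
    "DockingResult", "rigid_dock", "dock_confidence", "screen_snapshots",
    "contact_map", "cluster_ensemble", "pmf_landscape", "PmfSurface",
    "KB_KCAL",
]

KB_KCAL = 1.987204e-3   # Boltzmann constant, kcal/mol/K (kB*300K = 0.5962)
CLASH_CUTOFF = 2.5      # Å, minimum allowed heavy-atom distance
LINKER_CONTOUR = 3.8    # Å per linker residue (contour-length bound)


def _site_av_means(structure: StructureModel, sites: Sequence[str],
                   av_params: Optional[dict] = None) -> Dict[str, np.ndarray]:
    """Mean dye position per site (AV computed once in the body frame)."""
    params = av_params or {}
    return {s: compute_av(structure, s, **params).mean_position for s in sites}


def restraint_sigma(r: DistanceRestraint, floor: float = 2.0) -> float:
    """Restraint weight: the bound converted to an SD (bound / 1.96),
    floored at ``floor`` Å."""
    return max(r.uncertainty / 1.96, floor)


@dataclass
class DockingResult:
    """Ranked rigid-body poses of the mobile body."""

    rotations: np.ndarray      # (n, 3, 3) applied about the mobile COM
    translations: np.ndarray   # (n, 3) new COM positions - old COM
    chi2: np.ndarray
    chi2r: np.ndarray
    com: np.ndarray            # (n, 3) mobile-body centers of mass
    n_restraints: int
    fixed: StructureModel
    mobile: StructureModel
    in_ci: Optional[np.ndarray] = None
    rejection_stats: dict = field(default_factory=dict)

    def __post_init__(self):
        order = np.argsort(self.chi2, kind="stable")
        for name in ("rotations", "translations", "chi2", "chi2r", "com"):
            setattr(self, name, getattr(self, name)[order])

    def __len__(self):
        return len(self.chi2)

    @property
    def rank(self):
        return np.arange(1, len(self) + 1)

    def pose_structure(self, i: int) -> StructureModel:
        return self.mobile.transformed(self.rotations[i], self.translations[i])


def rigid_dock(fixed: StructureModel, mobile: StructureModel,
               restraints: Sequence[DistanceRestraint],
               site_pairs: Dict[str, Tuple[str, str]],
               n_poses: int = 33_000,
               linker_max: Optional[float] = None,
               linker_residues: int = 15,
               seed: int = 0, state: Optional[int] = None,
               av_params: Optional[dict] = None,
               refine_top: int = 50, sigma_floor: float = 2.0
               ) -> DockingResult:
    """FRET-restrained rigid-body docking of ``mobile`` onto ``fixed``.

    ``site_pairs`` maps each restraint's variant name to its
    (fixed-site, mobile-site) labels. Poses are uniform random rotations
    plus translations in a bounding shell, rejected on steric clash
    (< 2.5 Å bead distance) or linker violation; each is scored

        chi2 = sum_k ((R_k^AV - R_k^restraint) / sigma_k)^2

    with AV mean positions computed once per body and transformed rigidly
    with the pose. The top-ranked sampled poses are then locally refined
    (least squares over the six transform parameters), which is what makes
    a planted noiseless pose exactly recoverable.
    """
    if n_poses < 1:
        raise ValueError("n_poses must be >= 1")
    rs = [r for r in restraints if state is None or r.state == state]
    if not rs:
        raise ValueError("no restraints for the requested state")
    for r in rs:
        if r.variant not in site_pairs:
            raise KeyError(f"no site pair for restraint variant {r.variant}")
    rng = np.random.default_rng(check_seed(seed))

    fixed_sites = sorted({site_pairs[r.variant][0] for r in rs})
    mobile_sites = sorted({site_pairs[r.variant][1] for r in rs})
    f_av = _site_av_means(fixed, fixed_sites, av_params)
    m_av = _site_av_means(mobile, mobile_sites, av_params)
    f_pts = np.array([f_av[site_pairs[r.variant][0]] for r in rs])
    m_pts = np.array([m_av[site_pairs[r.variant][1]] for r in rs])
    targets = np.array([r.mean for r in rs])
    sigmas = np.array([restraint_sigma(r, sigma_floor) for r in rs])

    com = mobile.center_of_mass
    m_local = m_pts - com                      # mobile site AVs in COM frame
    beads_local = mobile.coords - com
    if linker_max is None:
        linker_max = LINKER_CONTOUR * linker_residues
    f_term = (fixed.coords[fixed.linker_terminus]
              if fixed.linker_terminus is not None else fixed.center_of_mass)
    m_term_local = (beads_local[mobile.linker_terminus]
                    if mobile.linker_terminus is not None else np.zeros(3))
    center = fixed.center_of_mass
    shell = targets.max() + np.linalg.norm(beads_local, axis=1).max() + 10.0

    kept_R, kept_T = [], []
    stats = {"clash": 0, "linker": 0, "attempted": 0}
    batch = max(2 * n_poses, 1000)
    while len(kept_R) < n_poses and stats["attempted"] < 100 * n_poses + 1000:
        rot = Rotation.random(batch, random_state=rng).as_matrix()
        # uniform in the ball of radius `shell` around the fixed-body center
        u = rng.random(batch) ** (1.0 / 3.0)
        v = rng.normal(size=(batch, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pos = center + shell * u[:, None] * v
        stats["attempted"] += batch
        term = np.einsum("nij,j->ni", rot, m_term_local) + pos
        ok_link = np.linalg.norm(term - f_term, axis=1) <= linker_max
        stats["linker"] += int((~ok_link).sum())
        b = np.einsum("nij,kj->nki", rot[ok_link], beads_local) + \
            pos[ok_link][:, None, :]
        dmin = np.min(
            np.linalg.norm(b[:, :, None, :] - fixed.coords[None, None, :, :],
                           axis=-1), axis=(1, 2))
        ok_clash = dmin >= CLASH_CUTOFF
        stats["clash"] += int((~ok_clash).sum())
        kept_R.extend(rot[ok_link][ok_clash])
        kept_T.extend(pos[ok_link][ok_clash])
    if not kept_R:
        raise RuntimeError(f"no feasible docking poses; rejections: {stats}")
    R = np.asarray(kept_R[:n_poses])
    T = np.asarray(kept_T[:n_poses])

    def chi2_of(Rm, Tm):
        m = np.einsum("nij,kj->nki", Rm, m_local) + Tm[:, None, :]
        d = np.linalg.norm(m - f_pts[None, :, :], axis=-1)
        return np.sum(((d - targets[None, :]) / sigmas[None, :]) ** 2, axis=1)

    chi2 = chi2_of(R, T)

    # local refinement of the best sampled poses
    n_ref = min(refine_top, len(chi2))
    top = np.argsort(chi2)[:n_ref]

    def resid(p, rot0):
        rot = Rotation.from_rotvec(p[:3]).as_matrix() @ rot0
        m = m_local @ rot.T + p[3:6]
        d = np.linalg.norm(m - f_pts, axis=1)
        return (d - targets) / sigmas

    refine_method = "lm" if len(rs) >= 6 else "trf"
    for i in top:
        sol = least_squares(resid, np.concatenate([np.zeros(3), T[i]]),
                            args=(R[i],), method=refine_method, max_nfev=200)
        rot_new = Rotation.from_rotvec(sol.x[:3]).as_matrix() @ R[i]
        t_new = sol.x[3:6]
        # refined pose must stay feasible
        b = beads_local @ rot_new.T + t_new
        if cdist(b, fixed.coords).min() < CLASH_CUTOFF:
            continue
        if np.linalg.norm(rot_new @ m_term_local + t_new - f_term) > linker_max:
            continue
        c2 = float(np.sum(sol.fun**2))
        if c2 < chi2[i]:
            R[i], T[i], chi2[i] = rot_new, t_new, c2

    n_r = len(rs)
    return DockingResult(
        rotations=R, translations=T - com, chi2=chi2, chi2r=chi2 / n_r,
        com=T, n_restraints=n_r, fixed=fixed, mobile=mobile,
        rejection_stats=stats)


def dock_confidence(result: DockingResult, n_restraints: Optional[int] = None,
                    alpha: float = 0.05) -> Tuple[np.ndarray, np.ndarray]:
    """F-test confidence ensemble of docking poses.

    A pose is retained when chi2r / chi2r_best <= F_(1-alpha)(n, n) with n
    the number of restraints (free distances). Returns (in_ci mask, COM
    cloud of retained poses); the mask is also stored on the result.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    n = n_restraints if n_restraints is not None else result.n_restraints
    thresh = sps.f.ppf(1.0 - alpha, n, n)
    best = max(result.chi2r[0], 1e-12)
    in_ci = result.chi2r / best <= thresh
    in_ci[0] = True  # the best pose is always in its own CI
    result.in_ci = in_ci
    return in_ci, result.com[in_ci]


# ---------------------------------------------------------------------------
# Ensemble screening
# ---------------------------------------------------------------------------

def screen_snapshots(snapshots, fixed: StructureModel, mobile: StructureModel,
                     restraints: Sequence[DistanceRestraint],
                     site_pairs: Dict[str, Tuple[str, str]],
                     av_params: Optional[dict] = None) -> dict:
    """Accept snapshots whose AV distances satisfy every pair's bounds.

    ``snapshots`` are rigid placements of the mobile body (objects with
    ``rotation``/``translation`` attributes, e.g. the toy ensemble). A
    snapshot is accepted for state s iff, for every variant, the inter-AV
    distance lies within [lower, upper] of that state's restraint. Returns
    per-state index lists and mobile-COM clouds.
    """
    by_state: Dict[int, list] = {}
    for r in restraints:
        by_state.setdefault(r.state, []).append(r)
    variants = sorted({r.variant for r in restraints})
    for v in variants:
        if v not in site_pairs:
            raise KeyError(f"no site pair for variant {v}")
    fixed_sites = sorted({site_pairs[v][0] for v in variants})
    mobile_sites = sorted({site_pairs[v][1] for v in variants})
    f_av = _site_av_means(fixed, fixed_sites, av_params)
    m_av = _site_av_means(mobile, mobile_sites, av_params)
    com = mobile.center_of_mass
    m_local = {s: m_av[s] - com for s in mobile_sites}

    n = len(snapshots)
    dist = np.zeros((n, len(variants)))
    coms = np.zeros((n, 3))
    for i, snap in enumerate(snapshots):
        rot, tr = snap.rotation, snap.translation
        coms[i] = com + tr
        for j, v in enumerate(variants):
            fs, ms = site_pairs[v]
            m = rot @ m_local[ms] + com + tr
            dist[i, j] = np.linalg.norm(m - f_av[fs])

    out = {}
    for s, rl in sorted(by_state.items()):
        ok = np.ones(n, dtype=bool)
        for r in rl:
            j = variants.index(r.variant)
            ok &= (dist[:, j] >= r.lower) & (dist[:, j] <= r.upper)
        idx = np.flatnonzero(ok)
        out[s] = {"accepted": idx, "com_cloud": coms[idx],
                  "n_accepted": int(idx.size)}
    out["distances"] = pd.DataFrame(dist, columns=variants)
    return out


# ---------------------------------------------------------------------------
# Contact maps and clustering
# ---------------------------------------------------------------------------

def contact_map(structures: Sequence[StructureModel],
                group1: Sequence[int], group2: Sequence[int],
                cutoff: float = 5.5, normalize: bool = False) -> pd.DataFrame:
    """Pairwise residue contact probabilities across an ensemble.

    P(i, j) is the fraction of snapshots in which the minimum heavy-atom
    distance between residues i (group1) and j (group2) is below
    ``cutoff``. Residues are identified by ``residue_ids``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    structures = list(structures)
    if not structures:
        raise ValueError("empty ensemble")
    g1, g2 = list(group1), list(group2)
    counts = np.zeros((len(g1), len(g2)))
    for st in structures:
        id_to_idx: Dict[int, np.ndarray] = {}
        for rid in set(g1) | set(g2):
            id_to_idx[rid] = np.flatnonzero(st.residue_ids == rid)
        for a, r1 in enumerate(g1):
            i1 = id_to_idx[r1]
            if i1.size == 0:
                continue
            for b, r2 in enumerate(g2):
                i2 = id_to_idx[r2]
                if i2.size == 0:
                    continue
                if cdist(st.coords[i1], st.coords[i2]).min() < cutoff:
                    counts[a, b] += 1
    p = counts / len(structures)
    if normalize and p.max() > 0:
        p = p / p.max()
    return pd.DataFrame(p, index=g1, columns=g2)


def pairwise_rmsd(coords: np.ndarray) -> np.ndarray:
    """All-pairs RMSD of pre-aligned coordinate sets, shape (n, m, 3)."""
    n = coords.shape[0]
    flat = coords.reshape(n, -1)
    sq = cdist(flat, flat, "sqeuclidean") / coords.shape[1]
    return np.sqrt(np.maximum(sq, 0.0))


def cluster_ensemble(coords: np.ndarray, n_clusters: Optional[int] = None,
                     distance_threshold: Optional[float] = None) -> dict:
    """Agglomerative mean-linkage clustering on the pairwise-RMSD matrix.

    The cluster distance is the mean of all member-pair RMSDs; the
    centroid of each cluster is the member with the smallest average RMSD
    to the other members. Structures are assumed pre-aligned on the fixed
    body (no superposition is performed).
    """
    coords = np.asarray(coords, float)
    if coords.shape[0] < 2:
        return {"labels": np.zeros(coords.shape[0], dtype=int),
                "centroids": [0] if coords.shape[0] else [],
                "rmsd": np.zeros((coords.shape[0],) * 2)}
    rmsd = pairwise_rmsd(coords)
    z = linkage(squareform(rmsd, checks=False), method="average")
    if n_clusters is not None:
        labels = fcluster(z, t=n_clusters, criterion="maxclust")
    elif distance_threshold is not None:
        labels = fcluster(z, t=distance_threshold, criterion="distance")
    else:
        raise ValueError("give n_clusters or distance_threshold")
    labels = labels - 1
    centroids = []
    for c in range(labels.max() + 1):
        idx = np.flatnonzero(labels == c)
        sub = rmsd[np.ix_(idx, idx)]
        centroids.append(int(idx[np.argmin(sub.mean(axis=1))]))
    return {"labels": labels, "centroids": centroids, "rmsd": rmsd,
            "linkage": z}


# ---------------------------------------------------------------------------
# PMF landscape
# ---------------------------------------------------------------------------

@dataclass
class PmfSurface:
    """2D free-energy surface over the first two principal components."""

    pc1: np.ndarray            # grid centers
    pc2: np.ndarray
    density: np.ndarray        # (n1, n2), integrates to 1 over the grid
    pmf: np.ndarray            # kcal/mol, minimum 0
    basin_labels: np.ndarray   # int grid, 0 = unassigned
    basin_weights: Dict[int, float]
    temperature: float
    components: Optional[np.ndarray] = None
    explained_variance: Optional[np.ndarray] = None

    def basin_minimum(self, basin: int) -> float:
        return float(self.pmf[self.basin_labels == basin].min())

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        pm = np.where(np.isfinite(self.pmf), self.pmf, np.nan)
        im = ax.pcolormesh(self.pc1, self.pc2, pm.T, shading="auto", **kwargs)
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        plt.colorbar(im, ax=ax, label="PMF (kcal/mol)")
        return ax


def _merge_shallow_basins(pmf, labels, min_depth):
    """Merge watershed basins whose depth below the connecting saddle is
    less than ``min_depth`` (noise suppression at finite sampling)."""
    from scipy.ndimage import binary_dilation
    changed = True
    while changed:
        changed = False
        ids = [b for b in np.unique(labels) if b > 0]
        if len(ids) < 2:
            break
        minima = {b: pmf[labels == b].min() for b in ids}
        # boundary saddle between each adjacent pair
        best = None
        for b in ids:
            ring = binary_dilation(labels == b) & (labels != b) & (labels > 0)
            for o in np.unique(labels[ring]):
                saddle_mask = binary_dilation(labels == b) & (labels == o)
                saddle = pmf[saddle_mask].min()
                depth = saddle - max(minima[b], minima[o])
                if depth < min_depth and (best is None or depth < best[0]):
                    shallow = b if minima[b] > minima[o] else o
                    deep = o if shallow == b else b
                    best = (depth, shallow, deep)
        if best is not None:
            _, shallow, deep = best
            labels[labels == shallow] = deep
            changed = True
    return labels


def pmf_landscape(features: np.ndarray,
                  fractions: Optional[Sequence[float]] = None,
                  temperature: float = 300.0, grid_size: int = 120,
                  smooth_bins: float = 2.0, min_depth: float = 0.3,
                  min_basin_weight: float = 1e-3) -> PmfSurface:
    """PCA-projected potential of mean force with basin rescaling.

    Features (one vector per snapshot) are standardized and projected on
    their first two principal components; the sampled density on a 2D
    grid gives PMF = -kB T ln(p / p_max). Basins are segmented by
    watershed from the PMF minima (shallow basins pruned below
    ``min_depth`` kcal/mol, negligible ones below ``min_basin_weight``
    dropped) and, when ``fractions`` are given, the density is rescaled
    per basin so the integrated basin weights equal them, after which the
    PMF is recomputed.
    """
    x = np.asarray(features, float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need at least two features per snapshot")
    if fractions is not None:
        fractions = np.asarray(fractions, float)
        if fractions.sum() > 1 + 1e-9:
            raise ValueError("basin fractions must sum to at most 1")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"degenerate (constant) feature columns: {bad}")
    z = (x - x.mean(axis=0)) / sd
    cov = np.cov(z, rowvar=False)
    if np.linalg.matrix_rank(cov) < 2:
        raise ValueError("feature covariance is singular; remove collinear "
                         "features")
    from sklearn.decomposition import PCA
    pca = PCA(n_components=2)
    proj = pca.fit_transform(z)

    lo = proj.min(axis=0) - 0.05 * np.ptp(proj, axis=0)
    hi = proj.max(axis=0) + 0.05 * np.ptp(proj, axis=0)
    h, e1, e2 = np.histogram2d(proj[:, 0], proj[:, 1], bins=grid_size,
                               range=[[lo[0], hi[0]], [lo[1], hi[1]]])
    if smooth_bins > 0:
        h = gaussian_filter(h, smooth_bins)
    cell = (e1[1] - e1[0]) * (e2[1] - e2[0])
    density = h / (h.sum() * cell)
    kbt = KB_KCAL * temperature

    def to_pmf(dens):
        with np.errstate(divide="ignore"):
            pmf = -kbt * np.log(dens / dens.max())
        return pmf

    pmf = to_pmf(density)

    # watershed segmentation of the occupied region
    from skimage.segmentation import watershed
    from scipy.ndimage import minimum_filter
    occupied = density > density.max() * 1e-6
    finite = np.where(occupied, pmf, pmf[occupied].max() + 5.0)
    is_min = (minimum_filter(finite, size=5) == finite) & occupied
    markers = np.zeros_like(finite, dtype=int)
    for i, (a, b) in enumerate(zip(*np.nonzero(is_min)), start=1):
        markers[a, b] = i
    labels = watershed(finite, markers=markers, mask=occupied)
    labels = _merge_shallow_basins(finite, labels, min_depth)
    cell_weight = density * cell
    for b in np.unique(labels):
        if b > 0 and cell_weight[labels == b].sum() < min_basin_weight:
            labels[labels == b] = 0
    # relabel basins by ascending PMF minimum: basin 1 = deepest
    ids = sorted((b for b in np.unique(labels) if b > 0),
                 key=lambda b: finite[labels == b].min())
    relabeled = np.zeros_like(labels)
    for new, old in enumerate(ids, start=1):
        relabeled[labels == old] = new
    labels = relabeled

    # rescale basin densities to the supplied fractions
    dens = density.copy()
    if fractions is not None:
        n_basins = min(len(fractions), labels.max())
        for b in range(1, n_basins + 1):
            mask = labels == b
            w = dens[mask].sum() * cell
            if w > 0:
                dens[mask] *= fractions[b - 1] / w
    weights = {b: float(dens[labels == b].sum() * cell)
               for b in range(1, labels.max() + 1)}
    pmf = to_pmf(dens)
    pmf = pmf - np.nanmin(pmf[np.isfinite(pmf)])

    c1 = 0.5 * (e1[:-1] + e1[1:])
    c2 = 0.5 * (e2[:-1] + e2[1:])
    return PmfSurface(c1, c2, dens, pmf, labels, weights, temperature,
                      components=pca.components_,
                      explained_variance=pca.explained_variance_ratio_)
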