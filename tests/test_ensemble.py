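"""Docking, confidence ensembles, screening, contact maps, clustering and
the PMF landscape."""

import numpy as np
import pytest
from scipy import stats as sps
from scipy.spatial.transform import Rotation

import fretscape as fs
from fretscape.core import DistanceRestraint, StructureModel
from fretscape.ensemble import (KB_KCAL, _site_av_means, cluster_ensemble,
                                contact_map, dock_confidence, pmf_landscape,
                                rigid_dock, screen_snapshots)

AV_PARAMS = {"grid_spacing": 1.0}
PAIRS = [("S1", "P1"), ("S2", "P2"), ("S3", "P3"), ("G1", "P1"),
         ("G2", "P2"), ("G3", "P3"), ("G4", "P1"), ("G5", "P2"),
         ("G6", "P3")]


@pytest.fixture(scope="module")
def av_means(toy_bodies):
    fixed, mobile, _ = toy_bodies
    f_av = _site_av_means(fixed, sorted(fixed.sites), AV_PARAMS)
    m_av = _site_av_means(mobile, sorted(mobile.sites), AV_PARAMS)
    return f_av, m_av


def planted_restraints(toy_bodies, av_means, snap, sigma=2.0):
    fixed, mobile, _ = toy_bodies
    f_av, m_av = av_means
    com = mobile.center_of_mass
    site_pairs, restraints = {}, []
    for i, (fsite, msite) in enumerate(PAIRS):
        name = f"v{i}"
        site_pairs[name] = (fsite, msite)
        m = snap.rotation @ (m_av[msite] - com) + com + snap.translation
        d = float(np.linalg.norm(m - f_av[fsite]))
        restraints.append(DistanceRestraint(name, 0, d, sigma, d - sigma,
                                            d + sigma))
    return restraints, site_pairs


class TestRigidDock:
    @pytest.fixture(scope="class")
    def planted_dock(self, toy_bodies, av_means):
        fixed, mobile, snaps = toy_bodies
        restraints, site_pairs = planted_restraints(toy_bodies, av_means,
                                                    snaps[0])
        res = rigid_dock(fixed, mobile, restraints, site_pairs,
                         n_poses=4000, seed=5, av_params=AV_PARAMS,
                         linker_max=100.0)
        return res, snaps[0]

    def test_planted_pose_recovered(self, toy_bodies, planted_dock):
        """Noiseless restraints from a planted pose are satisfied to
        chi2 < 0.01 and the refined best pose matches the plant < 2 Å."""
        fixed, mobile, _ = toy_bodies
        res, snap = planted_dock
        assert res.chi2[0] < 0.01
        best = res.pose_structure(0)
        planted = snap.place(mobile)
        rmsd = np.sqrt(np.mean(np.sum((best.coords - planted.coords) ** 2,
                                      axis=1)))
        assert rmsd < 2.0

    def test_rank_ordering(self, planted_dock):
        res, _ = planted_dock
        assert np.all(np.diff(res.chi2) >= 0)
        assert res.rank[0] == 1

    def test_infeasible_restraints_scored_poorly(self, toy_bodies):
        fixed, mobile, _ = toy_bodies
        site_pairs = {f"v{i}": p for i, p in enumerate(PAIRS[:3])}
        zeroish = [DistanceRestraint(f"v{i}", 0, 1e-3, 2.0, 1e-4, 2e-3)
                   for i in range(3)]
        res = rigid_dock(fixed, mobile, zeroish, site_pairs, n_poses=200,
                         seed=1, av_params=AV_PARAMS, linker_max=100.0,
                         refine_top=5)
        assert res.chi2[0] > 10.0

    def test_score_invariant_under_global_transform(self, toy_bodies,
                                                    av_means):
        """A global rigid transform of the whole system (both bodies and
        the planted pose) leaves the attainable restraint score unchanged:
        the refined optimum is exact in both frames."""
        fixed, mobile, snaps = toy_bodies
        restraints, site_pairs = planted_restraints(toy_bodies, av_means,
                                                    snaps[0])
        rot = Rotation.from_euler("xyz", [11, -7, 23], degrees=True
                                  ).as_matrix()
        shift = np.array([5.0, -3.0, 8.0])
        fixed2 = fixed.transformed(rot, shift, about=np.zeros(3))
        mobile2 = mobile.transformed(rot, shift, about=np.zeros(3))
        for f, m in ((fixed, mobile), (fixed2, mobile2)):
            res = rigid_dock(f, m, restraints, site_pairs, n_poses=800,
                             seed=7, av_params=AV_PARAMS, linker_max=100.0,
                             refine_top=20)
            assert res.chi2[0] < 0.01

    def test_no_restraints(self, toy_bodies):
        fixed, mobile, _ = toy_bodies
        with pytest.raises(ValueError):
            rigid_dock(fixed, mobile, [], {}, n_poses=10)


class TestDockConfidence:
    def _result(self, chi2):
        n = len(chi2)
        from fretscape.ensemble import DockingResult
        return DockingResult(
            rotations=np.tile(np.eye(3), (n, 1, 1)),
            translations=np.zeros((n, 3)), chi2=np.asarray(chi2, float),
            chi2r=np.asarray(chi2, float) / 9.0, com=np.zeros((n, 3)),
            n_restraints=9, fixed=None, mobile=None)

    def test_threshold_is_f_quantile(self):
        """alpha = 0.05 with nine restraints thresholds at the 95th
        percentile of F(9, 9) ~ 3.18."""
        res = self._result([9.0, 20.0, 30.0, 200.0])
        in_ci, _ = dock_confidence(res, alpha=0.05)
        thr = sps.f.ppf(0.95, 9, 9)
        assert thr == pytest.approx(3.1789, abs=1e-3)
        expect = res.chi2r / res.chi2r[0] <= thr
        assert np.array_equal(in_ci, expect | (res.rank == 1))

    def test_best_pose_always_retained(self):
        res = self._result([5.0, 6.0])
        in_ci, cloud = dock_confidence(res, alpha=0.5)
        assert in_ci[0]
        assert cloud.shape[1] == 3

    def test_tight_alpha_shrinks_to_best(self):
        res = self._result([1.0, 1.5, 3.0, 10.0])
        in_ci, _ = dock_confidence(res, alpha=0.999)
        assert in_ci.sum() == 1

    def test_alpha_domain(self):
        res = self._result([1.0])
        with pytest.raises(ValueError):
            dock_confidence(res, alpha=1.5)


class TestScreenSnapshots:
    def test_open_bounds_accept_all(self, toy_bodies, av_means):
        fixed, mobile, snaps = toy_bodies
        restraints, site_pairs = planted_restraints(toy_bodies, av_means,
                                                    snaps[0], sigma=2.0)
        wide = [DistanceRestraint(r.variant, 0, r.mean, 1e6, 1e-3, 1e6)
                for r in restraints]
        out = screen_snapshots(snaps, fixed, mobile, wide, site_pairs,
                               av_params=AV_PARAMS)
        assert out[0]["n_accepted"] == len(snaps)

    def test_planted_cluster_recovered(self, toy_bodies, av_means):
        """Bounds spanning cluster A's own distance ranges accept exactly
        the cluster-A snapshots (planted-truth oracle)."""
        fixed, mobile, snaps = toy_bodies
        restraints, site_pairs = planted_restraints(toy_bodies, av_means,
                                                    snaps[0], sigma=8.0)
        open_bounds = [DistanceRestraint(r.variant, 0, r.mean, 1e6, 1e-3,
                                         1e6) for r in restraints]
        probe = screen_snapshots(snaps, fixed, mobile, open_bounds,
                                 site_pairs, av_params=AV_PARAMS)
        dist = probe["distances"]
        labels = np.array([s.cluster for s in snaps])
        bounds = []
        for v in dist.columns:
            in_a = dist[v][labels == 0]
            lo, hi = in_a.min() - 0.5, in_a.max() + 0.5
            mean = 0.5 * (lo + hi)
            bounds.append(DistanceRestraint(v, 0, mean, hi - mean, lo, hi))
        # the planted clusters must be separated on at least one pair
        sep = any(dist[v][labels == 1].min() > dist[v][labels == 0].max() + 1
                  or dist[v][labels == 1].max() < dist[v][labels == 0].min() - 1
                  for v in dist.columns)
        assert sep
        out = screen_snapshots(snaps, fixed, mobile, bounds, site_pairs,
                               av_params=AV_PARAMS)
        accepted = out[0]["accepted"]
        assert np.all(labels[accepted] == 0)
        assert len(accepted) == (labels == 0).sum()

    def test_monotone_widening(self, toy_bodies, av_means):
        """Widening any bound never removes an accepted snapshot."""
        fixed, mobile, snaps = toy_bodies
        restraints, site_pairs = planted_restraints(toy_bodies, av_means,
                                                    snaps[0], sigma=5.0)
        narrow = screen_snapshots(snaps, fixed, mobile, restraints,
                                  site_pairs, av_params=AV_PARAMS)
        wider = [DistanceRestraint(r.variant, 0, r.mean, r.uncertainty + 4,
                                   max(r.lower - 4, 1e-3), r.upper + 4)
                 for r in restraints]
        wide = screen_snapshots(snaps, fixed, mobile, wider, site_pairs,
                                av_params=AV_PARAMS)
        assert set(narrow[0]["accepted"]) <= set(wide[0]["accepted"])


class TestContactMap:
    def test_single_snapshot_example(self):
        st = StructureModel("s", np.array([[0.0, 0, 0], [4.0, 0, 0],
                                           [30.0, 0, 0]]),
                            np.full(3, 1.0), np.array([1, 2, 3]))
        p = contact_map([st], [1], [2, 3], cutoff=5.5)
        assert p.loc[1, 2] == 1.0 and p.loc[1, 3] == 0.0

    def test_matches_bruteforce_counting(self, toy_bodies):
        fixed, mobile, snaps = toy_bodies
        ensemble = [s.assemble(fixed, mobile) for s in snaps[:10]]
        g1 = list(range(1, 6))
        g2 = [1001, 1002, 1003]
        p = contact_map(ensemble, g1, g2, cutoff=8.0)
        # exhaustive reference
        ref = np.zeros((len(g1), len(g2)))
        for st in ensemble:
            for a, r1 in enumerate(g1):
                for b, r2 in enumerate(g2):
                    c1 = st.coords[st.residue_ids == r1]
                    c2 = st.coords[st.residue_ids == r2]
                    dmin = np.min(np.linalg.norm(
                        c1[:, None] - c2[None, :], axis=-1))
                    if dmin < 8.0:
                        ref[a, b] += 1
        assert np.allclose(p.to_numpy(), ref / len(ensemble))

    def test_empty_ensemble(self):
        with pytest.raises(ValueError):
            contact_map([], [1], [2], 5.0)


class TestClusterEnsemble:
    def test_identical_structures_one_cluster(self):
        c = np.random.default_rng(0).normal(size=(1, 10, 3))
        coords = np.repeat(c, 4, axis=0)
        out = cluster_ensemble(coords, distance_threshold=0.5)
        assert out["labels"].max() == 0

    def test_three_planted_conformers(self):
        """Three well-separated conformers plus jittered copies cluster
        into three groups whose centroids are the least-jittered members."""
        rng = np.random.default_rng(1)
        base = rng.normal(size=(3, 8, 3)) * 3
        centers = np.array([[0, 0, 0], [40, 0, 0], [0, 40, 0]])[:, None, :]
        coords, jitters = [], []
        for k in range(3):
            for j in range(5):
                amp = 0.1 + 0.4 * j
                coords.append(base[k] + centers[k]
                              + rng.normal(0, amp, (8, 3)))
                jitters.append(amp)
        coords = np.array(coords)
        out = cluster_ensemble(coords, n_clusters=3)
        assert out["labels"].max() == 2
        # centroid property: smallest average RMSD to cluster members
        rmsd = out["rmsd"]
        for c in range(3):
            idx = np.flatnonzero(out["labels"] == c)
            sub = rmsd[np.ix_(idx, idx)]
            cent = out["centroids"][c]
            pos = list(idx).index(cent)
            assert np.argmin(sub.mean(axis=1)) == pos

    def test_singular_input(self):
        out = cluster_ensemble(np.zeros((1, 5, 3)), n_clusters=2)
        assert out["labels"].tolist() == [0]


class TestPmfLandscape:
    def test_uniform_density_flat(self):
        from scipy.ndimage import binary_erosion
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, (60_000, 2))
        surf = pmf_landscape(x, smooth_bins=3.0)
        # flat within sampling noise over the interior of the support
        # (erosion clears the smoothing rolloff at the edge of the square)
        support = surf.density > 1e-3 * surf.density.max()
        interior = binary_erosion(support, iterations=20)
        assert interior.sum() > 100
        assert np.nanmax(surf.pmf[interior]) < 0.3
        assert np.nanstd(surf.pmf[interior]) < 0.1

    def test_two_gaussian_depth_difference(self):
        """A two-Gaussian mixture weighted exp(-dE/kBT) with dE = 2.0
        kcal/mol at 300 K recovers the inter-minimum PMF difference within
        0.1 kcal/mol at 1e5 samples."""
        rng = np.random.default_rng(4)
        kbt = KB_KCAL * 300
        w2 = 1.0 / (1.0 + np.exp(2.0 / kbt))
        n = 100_000
        n2 = int(round(w2 * n))
        x = np.vstack([rng.normal([-2.0, 0.0], 0.35, (n - n2, 2)),
                       rng.normal([2.0, 0.5], 0.35, (n2, 2))])
        feats = np.hstack([x, x @ np.array([[0.5], [1.0]])
                           + rng.normal(0, 0.1, (n, 1))])
        surf = pmf_landscape(feats)
        assert max(surf.basin_weights) == 2
        diff = surf.basin_minimum(2) - surf.basin_minimum(1)
        assert diff == pytest.approx(2.0, abs=0.1)

    def test_basin_rescaling_exact(self):
        rng = np.random.default_rng(5)
        n = 50_000
        x = np.vstack([rng.normal([-2.0, 0.0], 0.35, (n // 2, 2)),
                       rng.normal([2.0, 0.5], 0.35, (n - n // 2, 2))])
        surf = pmf_landscape(x, fractions=(0.461, 0.539))
        assert surf.basin_weights[1] == pytest.approx(0.461, abs=1e-6)
        assert surf.basin_weights[2] == pytest.approx(0.539, abs=1e-6)

    def test_pmf_differences_invariant_to_normalization(self):
        rng = np.random.default_rng(6)
        n = 40_000
        x = np.vstack([rng.normal([-2.0, 0.0], 0.35, (n // 2, 2)),
                       rng.normal([2.0, 0.5], 0.35, (n - n // 2, 2))])
        s1 = pmf_landscape(x)
        s2 = pmf_landscape(x, fractions=(0.25, 0.25))
        # rescaling changes depths but differences inside one basin do not
        m = s1.basin_labels == 1
        d1 = s1.pmf[m] - s1.basin_minimum(1)
        d2 = s2.pmf[m] - s2.basin_minimum(1)
        assert np.allclose(d1, d2, atol=1e-9)

    def test_degenerate_features_rejected(self):
        x = np.ones((100, 2))
        with pytest.raises(ValueError):
            pmf_landscape(x)

    def test_fraction_bound(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValueError):
            pmf_landscape(rng.normal(size=(500, 2)), fractions=(0.8, 0.8))


def test_planted_ensemble_basin_weights(toy_bodies):
    """Screening + landscape on the planted toy ensemble recover two
    basins with the planted occupancies (binomial error)."""
    fixed, mobile, snaps = toy_bodies
    coms = np.array([mobile.center_of_mass + s.translation for s in snaps])
    rng = np.random.default_rng(8)
    feats = np.hstack([coms, rng.normal(0, 0.5, (len(coms), 1))])
    surf = pmf_landscape(feats, smooth_bins=3.0)
    labels = np.array([s.cluster for s in snaps])
    p0 = (labels == 0).mean()
    weights = sorted(surf.basin_weights.values(), reverse=True)[:2]
    se = np.sqrt(p0 * (1 - p0) / len(snaps))
    assert abs(min(weights) - min(p0, 1 - p0)) < 3 * se + 0.02
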