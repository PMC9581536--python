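"""Burst search, MFD estimators, FRET-lines and TIRF trace analysis."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fretscape as fs
from fretscape.bursts import (burst_estimators, dynamic_fret_line,
                              dynamic_line_value, pie_filter, select_bursts,
                              static_fret_line, tirf_trace_analysis)
from fretscape.core import PhotonStream
from fretscape.decay import DonorModel


def _stream_from_times(times, micro=None, det=None, period=32.0):
    times = np.asarray(times, float)
    micro = np.full(times.size, 3.0) if micro is None else np.asarray(micro)
    det = np.zeros(times.size, np.int8) if det is None else np.asarray(det)
    return PhotonStream(times, micro, det, period)


def brute_force_bursts(times, threshold, min_photons):
    """Exhaustive reference segmentation: maximal runs of consecutive
    photons whose joining gaps are all <= threshold."""
    out = []
    start = 0
    for i in range(1, len(times)):
        if times[i] - times[i - 1] > threshold:
            if i - start >= min_photons:
                out.append((start, i))
            start = i
    if len(times) - start >= min_photons:
        out.append((start, len(times)))
    return out


class TestSelectBursts:
    def test_uniform_train_single_burst(self):
        s = _stream_from_times(np.arange(100) * 1e-4)
        bt = select_bursts(s, min_photons=40, sigma_factor=1.0)
        assert len(bt) == 1
        assert bt.n_photons.iloc[0] == 100

    def test_min_photons_boundary(self):
        """A 39-photon candidate is rejected at the 40-photon minimum."""
        gaps = np.concatenate([np.full(38, 1e-5), [1.0],
                               np.full(59, 1e-5)])
        times = np.concatenate([[0.0], np.cumsum(gaps)])
        bt = select_bursts(s := _stream_from_times(times), min_photons=40,
                           threshold_s=1e-4)
        assert len(bt) == 1  # only the 60-photon run survives
        assert bt.n_photons.iloc[0] == 60

    def test_empty_stream(self):
        s = _stream_from_times([])
        assert len(select_bursts(s, 40)) == 0

    def test_nonpositive_threshold_raises(self):
        # heavy-tailed gaps: SD exceeds the mean, the literal rule fails
        rng = np.random.default_rng(0)
        gaps = np.where(rng.random(500) < 0.02, 1.0, 1e-5)
        s = _stream_from_times(np.cumsum(gaps))
        with pytest.raises(ValueError, match="threshold"):
            select_bursts(s, 40)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force(self, seed):
        """Threshold segmentation reproduces the exhaustive scan on random
        1,000-photon toy streams."""
        rng = np.random.default_rng(seed)
        gaps = rng.exponential(1e-4, 999) + rng.choice(
            [0.0, 5e-3], size=999, p=[0.9, 0.1])
        times = np.concatenate([[0.0], np.cumsum(gaps)])
        s = _stream_from_times(times)
        dt = np.diff(times)
        thr = dt.mean() - dt.std()
        if thr <= 0:
            return
        bt = select_bursts(s, min_photons=10, sigma_factor=1.0)
        ref = brute_force_bursts(times, thr, 10)
        assert [(a, b) for a, b in zip(bt.start, bt.stop)] == ref


def _make_burst_stream(n_green, n_red_dex, n_red_aex, tau=2.5, seed=0,
                       period=32.0):
    rng = np.random.default_rng(seed)
    n = n_green + n_red_dex + n_red_aex
    times = np.sort(rng.uniform(0, 1e-3, n))
    det = np.array([0] * n_green + [2] * (n_red_dex + n_red_aex), np.int8)
    micro = np.concatenate([
        2.0 + rng.exponential(tau, n_green),
        2.0 + rng.exponential(1.0, n_red_dex),
        period / 2 + 2.0 + rng.exponential(1.0, n_red_aex)])
    micro = np.mod(micro, period)
    micro[:n_green + n_red_dex] = np.mod(micro[:n_green + n_red_dex],
                                         period / 2)
    micro[n_green + n_red_dex:] = period / 2 + np.mod(
        micro[n_green + n_red_dex:], period / 2)
    return PhotonStream(times, micro, det, period)


class TestBurstEstimators:
    donor = DonorModel([4.0], [1.0])

    def _table(self, stream):
        return pd.DataFrame({"start": [0], "stop": [len(stream)],
                             "n_photons": [len(stream)],
                             "t_start": [stream.macro_times[0]],
                             "t_stop": [stream.macro_times[-1]],
                             "duration": [stream.duration]})

    def test_e_half_with_gamma_one(self):
        s = _make_burst_stream(50, 50, 40, seed=1)
        out = burst_estimators(s, self._table(s), self.donor)
        assert out.e_corrected.iloc[0] == pytest.approx(0.5)
        # gamma = 1 estimator is exactly N_A / (N_A + N_D)
        assert out.e_corrected.iloc[0] == pytest.approx(
            out.n_red_dex.iloc[0]
            / (out.n_red_dex.iloc[0] + out.n_green.iloc[0]))

    def test_e_zero_without_acceptor_photons(self):
        s = _make_burst_stream(80, 0, 40, seed=2)
        out = burst_estimators(s, self._table(s), self.donor)
        assert out.e_corrected.iloc[0] == pytest.approx(0.0)

    def test_zero_donor_flagged(self):
        s = _make_burst_stream(0, 60, 40, seed=3)
        out = burst_estimators(s, self._table(s), self.donor)
        assert out.no_donor_flag.iloc[0]
        assert np.isnan(out.tau_f.iloc[0])

    def test_negative_correction_rejected(self):
        s = _make_burst_stream(10, 10, 10)
        with pytest.raises(ValueError):
            burst_estimators(s, self._table(s), self.donor, alpha=-0.1)

    def test_mle_lifetime_unbiased(self):
        """Grid MLE of a 2.5 ns exponential at 100 photons/burst is
        unbiased within twice the CRLB standard error of the mean."""
        tau, n_phot, n_bursts = 2.5, 100, 500
        rng = np.random.default_rng(4)
        rows, times, micro, det = [], [], [], []
        t_off = 0.0
        for b in range(n_bursts):
            tt = np.sort(rng.uniform(0, 1e-3, n_phot)) + t_off
            mm = 2.0 + rng.exponential(tau, n_phot)
            mm = np.mod(mm, 16.0)
            rows.append((len(times) and len(np.concatenate(times)) or 0,
                         0, 0, 0, 0, 0))
            times.append(tt)
            micro.append(mm)
            det.append(np.zeros(n_phot, np.int8))
            t_off = tt[-1] + 0.01
        times = np.concatenate(times)
        stream = PhotonStream(times, np.concatenate(micro),
                              np.concatenate(det), 32.0)
        starts = np.arange(n_bursts) * n_phot
        table = pd.DataFrame({
            "start": starts, "stop": starts + n_phot,
            "n_photons": n_phot,
            "t_start": times[starts], "t_stop": times[starts + n_phot - 1],
            "duration": 1e-3})
        out = burst_estimators(stream, table, self.donor)
        crlb_se = tau / np.sqrt(n_phot) / np.sqrt(n_bursts)
        assert abs(out.tau_f.mean() - tau) < 2 * crlb_se + 0.02


class TestPieFilter:
    table = pd.DataFrame({
        "t_gg": [1e-3, 1e-3, 5e-3, 1e-3],
        "t_rr": [1.2e-3, 1e-3, 1e-3, 1e-3],
        "s_pie": [0.5, 0.75, 0.5, 0.98],
    })

    def test_window(self):
        out = pie_filter(self.table, max_dt=1e-3, s_low=0.3, s_high=0.7)
        assert len(out) == 1 and out.s_pie.iloc[0] == 0.5

    def test_spie_boundary_removed(self):
        # S_PIE = 0.75 falls outside the (0.3, 0.7) selection window
        out = pie_filter(self.table.iloc[[1]], 1e-2, 0.3, 0.7)
        assert len(out) == 0

    def test_donor_only_removed(self):
        out = pie_filter(self.table.iloc[[3]], 1e-2, 0.3, 0.7)
        assert len(out) == 0

    def test_all_pass(self):
        out = pie_filter(self.table, max_dt=np.inf, s_low=0.0, s_high=1.0)
        assert len(out) == len(self.table)

    def test_bad_window(self):
        with pytest.raises(ValueError):
            pie_filter(self.table, 1e-3, 0.7, 0.3)


class TestFretLines:
    def test_ideal_static_line(self):
        """sigma = 0 with a mono-exponential donor collapses the static
        line onto E = 1 - tau / tau_D0."""
        donor = DonorModel([4.0], [1.0])
        line = static_fret_line(donor, 0.0, 52.0)
        assert np.allclose(line.efficiency,
                           1.0 - line.tau_f / 4.0, atol=1e-6)
        assert np.all(np.diff(line.efficiency[np.argsort(line.tau_f)]) <= 1e-9)

    def test_far_endpoint(self):
        donor = DonorModel([4.0], [1.0])
        line = static_fret_line(donor, 0.0, 52.0)
        i = np.argmax(line.tau_f)
        assert line.tau_f[i] == pytest.approx(4.0, abs=0.02)
        assert line.efficiency[i] == pytest.approx(0.0, abs=0.01)

    def test_linker_width_curves_above_ideal(self):
        """Averaging over a 6 Å distance distribution lifts the line above
        the ideal one at intermediate lifetimes (convexity)."""
        donor = DonorModel([4.0], [1.0])
        line = static_fret_line(donor, 6.0, 52.0)
        mid = (line.tau_f > 1.0) & (line.tau_f < 3.0)
        ideal = 1.0 - line.tau_f[mid] / 4.0
        assert np.all(line.efficiency[mid] > ideal)

    def test_dynamic_line_endpoints(self):
        line = dynamic_fret_line(1.0, 3.0, 4.0)
        assert line.efficiency[0] == pytest.approx(1 - 1.0 / 4.0)
        assert line.efficiency[-1] == pytest.approx(1 - 3.0 / 4.0)

    def test_dynamic_domain_error(self):
        with pytest.raises(ValueError):
            dynamic_line_value(3.5, 1.0, 3.0, 4.0)

    def test_lines_intersect_at_limiting_states(self):
        """Static and dynamic FRET-lines meet exactly at the two
        limiting-state points (mono-exponential donor, sigma = 0)."""
        donor = DonorModel([4.0], [1.0])
        static = static_fret_line(donor, 0.0, 52.0, n_points=2000)
        tau1, tau2 = 1.3, 2.9
        for tau in (tau1, tau2):
            e_dyn = dynamic_line_value(tau, tau1, tau2, 4.0)
            assert static.interp(tau) == pytest.approx(e_dyn, abs=1e-3)

    @pytest.mark.parametrize("x", [0.25, 0.5, 0.75])
    def test_dynamic_line_matches_photon_mixture(self, x):
        """Points on the dynamic line agree with a Monte-Carlo two-state
        photon mixture: photons are drawn from each state's exponential in
        proportion to its time fraction times its brightness (~ tau)."""
        rng = np.random.default_rng(5)
        tau1, tau2, tau_d0 = 1.2, 3.2, 4.0
        n = 500_000
        w1 = x * tau1 / (x * tau1 + (1 - x) * tau2)  # photon fraction
        from_1 = rng.random(n) < w1
        t = np.where(from_1, rng.exponential(tau1, n),
                     rng.exponential(tau2, n))
        # photons are already brightness-weighted, so the fluorescence-
        # weighted lifetime is the mean arrival time of the mixture
        tau_f_mc = t.mean()
        e_mc = 1.0 - (x * tau1 + (1 - x) * tau2) / tau_d0  # intensity E
        assert dynamic_line_value(tau_f_mc, tau1, tau2, tau_d0) == \
            pytest.approx(e_mc, abs=0.01)


class TestTirfAnalysis:
    def test_gamma_from_bleach_step(self):
        """|dI_A| / |dI_D| across a clean acceptor-bleach step gives
        gamma = 1 for symmetric intensity exchange."""
        ia = np.concatenate([np.full(100, 600.0), np.full(100, 100.0)])
        idn = np.concatenate([np.full(100, 400.0), np.full(100, 900.0)])
        rng = np.random.default_rng(0)
        tr = fs.simulate.TirfTrace(idn + rng.normal(0, 5, 200),
                                   ia + rng.normal(0, 5, 200), 10.0)
        out = tirf_trace_analysis([tr])
        assert out.gamma.iloc[0] == pytest.approx(1.0, abs=0.1)
        assert out.pre_bleach_frames.iloc[0] == 100

    def test_anticorrelated_trace_pearson(self):
        t = np.linspace(0, 10, 200)
        sq = (np.sin(2 * np.pi * t / 3) > 0).astype(float)
        ia = 200 + 400 * sq
        idn = 800 - 400 * sq
        tr = fs.simulate.TirfTrace(idn, ia, 10.0)
        out = tirf_trace_analysis([tr], gamma_mode="global")
        assert out.pearson_r.iloc[0] == pytest.approx(-1.0, abs=1e-9)

    def test_fallback_without_bleach(self):
        tr = fs.simulate.TirfTrace(np.full(50, 500.0), np.full(50, 500.0),
                                   10.0)
        out = tirf_trace_analysis([tr], global_gamma=1.0)
        assert out.gamma_fallback.iloc[0]

    def test_mean_e_matches_generator(self, network_truth):
        """Time-averaged per-molecule E from synthetic TIRF traces peaks at
        the generator's state efficiencies (within 0.03)."""
        _, truth = network_truth
        frozen = dataclasses.replace(
            truth, exchange_rates={(0, 1): 0.0, (1, 0): 0.0},
            no_fret_fraction=0.0)
        traces = fs.simulate.simulate_tirf_traces(
            frozen, n_molecules=60, bleach_rate=0.0, seed=12,
            noise_sd=10.0, n_frames=300)
        out = tirf_trace_analysis(traces, gamma_mode="global")
        d = frozen.distances[next(iter(frozen.distances))]
        e_states = 1.0 / (1.0 + (d / frozen.forster_radius) ** 6)
        for e in out.mean_e:
            assert min(abs(e - e_states[0]), abs(e - e_states[1])) < 0.03
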