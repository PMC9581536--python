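# fretscape

Single-molecule FRET network analysis for multidomain proteins: from
photon records to a conformational free-energy landscape.

Scaffold proteins such as the synaptic MAGuK PSD-95 carry a PDZ3–SH3–GuK
(PSG) supramodule whose domains exchange between discrete spatial
arrangements ("supertertiary" structure). A single FRET pair cannot
resolve such an ensemble; a *network* of dye-labeling variants measured
on the same protein can. `fretscape` implements the full analysis chain
for such networks, plus a synthetic-data module that generates every
input with the statistical structure the analysis assumes, so the whole
pipeline is testable without instrument data.

## What it does

- **Synthetic data** (`fretscape.simulate`): a 12-variant FRET network
  over a two-state (plus no-FRET) ensemble with slow telegraph exchange,
  Poisson TCSPC decays, pulsed-interleaved-excitation photon streams,
  TIRF traces with photobleaching, bead-model structures with a planted
  two-cluster snapshot ensemble, kinetics and binding tables.
- **Burst analysis** (`fretscape.bursts`): inter-photon-time burst
  search, PIE stoichiometry filtering, per-burst maximum-likelihood donor
  lifetimes, intensity FRET efficiencies, static and dynamic FRET-lines,
  TIRF trace analysis with per-molecule gamma from acceptor bleaching.
- **Global decay fitting** (`fretscape.decay`): a statsmodels-style
  `GlobalDecayModel` whose `fit()` returns a `GlobalDecayResult` with
  shared state occupancies x_s, per-state distance-distribution widths
  σ_s and per-variant distances R̄_{v,s}; each variant's decay is

      F(t) = (1−x_nf) Σ_s x_s ∫ N(R; R̄_s, σ_s) Σ_m a_m
                 e^{−t(1/τ_m + k_T(R))} dR + x_nf Σ_m a_m e^{−t/τ_m},
      k_T(R) = (1/τ_ref)(R0/R)^6,

  convolved with the IRF. Includes model-order selection and the
  FRET-network-robustness (FNR) subsampling analysis that turns
  refit-distance spread into screening bounds.
- **Exchange dynamics** (`fretscape.dynamics`): photon distribution
  analysis (shot-noise-exact windowed FRET histograms with a
  telegraph-sampled dynamic component) and filtered FCS (species
  auto-/cross-correlation with relaxation amplitudes at the fixed decades
  1e-5 / 1e-4 / 1e-3 s, ranked major/middle/minor).
- **Dye accessible volumes** (`fretscape.av`): grid/geodesic AV clouds,
  the distance measures R_mp, ⟨R_DA⟩, R_DA,E and conversions.
- **Structural ensembles** (`fretscape.ensemble`): FRET-restrained
  rigid-body docking with F-test confidence ensembles, screening of
  snapshot ensembles against per-state distance bounds, residue contact
  maps, mean-linkage RMSD clustering, and a PCA-projected potential of
  mean force E = −k_B T ln p with watershed basins rescaled to
  experimental occupancies.
- **Auxiliary fits** (`fretscape.kinetics`): single-exponential
  disulfide-formation kinetics and Hill binding isotherms.

## Worked example

```python
import fretscape as fs

net, truth = fs.simulate.gen_network(12, seed=1)
decays = {v: fs.simulate.simulate_decay(truth, v, 1_000_000, seed=100 + i)
          for i, v in enumerate(net.variant_names)}
donor = fs.fit_donor_only(next(iter(decays.values())), n_components=2)
model = fs.GlobalDecayModel(decays, donor, n_states=2,
                            forster_radius=truth.forster_radius,
                            shared_no_fret=True)
result = model.fit(n_restarts=6, seed=0)
print(result.summary())
```

prints (abridged):

```
Global decay fit
==================================================
variants: 12   states: 2
state fractions: 0.591, 0.409
sigmas (A): 4.13, 7.10
mean chi2_r: 0.953
--------------------------------------------------
   variant      R_0      R_1  x_noFRET   chi2_r
     P2-G6    52.29    64.65     0.060    0.957
     P3-S2    58.07    66.80     0.060    1.066
     S2-G6    44.40    60.26     0.060    0.802
     ...
```

State labels are canonical (lexicographic distance order); here the
second column is the broad-width state (σ = 7.1 Å), which is the fuzzy
basin. Against the generating truth (fractions 0.461/0.539, half-widths
8/4 Å) this realization recovers the 24 distances with an RMSE of 0.8 Å
— including which distance belongs to which state, an assignment pinned
by the globally shared state widths — and the fuzzy-state occupancy as
0.409 vs 0.461 (single-realization estimator noise; the bias across
seeds is below 0.03). A reduced chi-square near 1 says the two-state
model fully explains the photon noise.

Downstream, `fs.fnr_analysis` + `fs.fnr_bounds` convert that fit into
per-variant distance bounds, `fretscape.ensemble.rigid_dock` docks a
mobile domain against them, and `fretscape.ensemble.pmf_landscape`
projects a screened snapshot ensemble into a two-basin free-energy
surface whose basin weights are rescaled to the fitted occupancies.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the main computation from scratch: it generates the default
network, simulates one million photons per variant, performs the
two-state global fit, screens the planted toy ensemble and builds the
rescaled landscape, then writes the JSON report to `--out`.

## Command line

`fretscape simulate | fit-decays | fit-kinetics | fit-binding | av` — thin
wrappers over the library for the shell-facing stages; see `--help`.
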