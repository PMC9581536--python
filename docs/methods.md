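# Methods

`fretscape` implements a hybrid single-molecule-FRET / simulation analysis
for resolving the multi-state supertertiary ensemble of a multidomain
protein (the motivating system is the PDZ3–SH3–GuK supramodule of a
synaptic scaffold protein, probed by a 12-variant dye-labeling network).
This note records the models, the numerical choices, and what the
synthetic-data generators do and do not emulate.

## The global decay model

Each labeling variant reports one pair of inter-dye distances, one per
conformational state; the states themselves (number, occupancies x_s,
distance-distribution half-widths σ_s) are shared across the network. The
FRET-sensitized donor decay of a variant is

    F(t) = (1 − x_nf) Σ_s x_s ∫ N(R; R̄_{v,s}, σ_s) Σ_m a_m
               exp[−t (1/τ_m + k_T(R))] dR
         + x_nf Σ_m a_m exp(−t/τ_m),

with the transfer rate k_T(R) = (1/τ_ref)(R0/R)^6. The reference lifetime
τ_ref is the fluorescence-weighted average donor-only lifetime
Σ a τ² / Σ a τ, consistent with a Förster radius defined from the
aggregate donor quantum yield. The model is convolved with the measured
IRF and scaled to the histogram total; fits are Poisson-weighted least
squares, and reduced chi-squares use bins holding at least five counts.

Numerical choices:

- Distance quadrature: 121-point Gauss–Legendre over R̄ ± 4σ, weighted by
  the Gaussian density (verified against a 10^6-sample Monte-Carlo
  average to < 0.1%).
- σ_s is fit globally per state, bounded to [1, 15] Å, initialized at 6 Å.
- The no-FRET fraction is fit per variant by default, with a
  `shared_no_fret` option; the synthetic world has a single generating
  no-FRET fraction, so the recovery tests use the shared option.
- Optimizer: trust-region least squares with a sparse Jacobian structure
  (each variant's residuals touch only the global parameters and its own
  distances), multi-start (default 10 restarts, seeded; ties broken by
  total chi-square), preceded by a coordinate-descent warm-up that
  alternates per-variant and global block refits.

### State-assignment degeneracy

Assigning each variant's two distances to the two global states is a
discrete sub-problem. When both states share the same distance
half-width, a swapped assignment can reproduce a variant's decay exactly
(with slightly shifted distances), so the assignment carries no
likelihood information. The physical system breaks this symmetry: the
fuzzy basin (state A) has a broader distance distribution than the
discrete basin (state B). The generator therefore defaults to half-widths
of 8 Å (state A) and 4 Å (state B), and the fitter resolves assignments
by (i) aligning per-variant pre-fit components by width and (ii) a
discrete swap-refinement pass that exchanges one variant's assignment at
a time, locally re-optimizes, and keeps the lower global cost,
alternating with global re-polish. Fitted state labels are canonicalized
by lexicographic distance order; comparisons against generating truth
align states by the global permutation minimizing distance RMSE.

### Model selection and FRET-network robustness (FNR)

Model order is accepted only if adding a state improves the average
reduced chi-square by more than a margin (default 5%) and individually
improves at least a configurable number of variants (default 3).

FNR draws random sub-networks (size ≥ 5; every variant in ≥ 3 subsets),
refits each with the full model order starting from the full-network
optimum, and histograms the percent deviation of each refit distance.
The per-distance deviation SD, floored at 2 Å, becomes the screening
bound (and, divided by 1.96, the restraint SD used in docking).

## Burst analysis

Burst search thresholds inter-photon times at mean − k·SD of the whole
trace, implemented literally. On strongly bursty traces this threshold
can go nonpositive (the gap distribution is heavy-tailed); the function
then raises and asks for an explicit threshold, which the pipeline
supplies. Per-burst donor lifetimes maximize the window-truncated
single-exponential likelihood on a 1 ps grid over (0, 2τ_D0]; the
excitation-pulse offset is estimated as the mode of the pooled green
micro-time histogram. FRET efficiencies are corrected for leakage α,
direct excitation δ and detection factor γ (defaults 0, 0, 1 for the
synthetic world). Static FRET-lines average E and the fluorescence-
weighted lifetime over a Gaussian distance distribution; dynamic lines
use E(⟨τ⟩_f) = 1 − τ1τ2/(τ_D0(τ1 + τ2 − ⟨τ⟩_f)).

## Exchange dynamics

PDA cuts donor-excitation photons into fixed windows (optionally tiled
within bursts, which keeps each window single-molecule) and fits the
proximity-ratio histogram with two static states at fixed efficiencies
plus one dynamic component whose occupancy-time distribution is sampled
by a seeded telegraph Monte-Carlo (≥ 10^5 draws in production; tests use
3×10^4). The objective is a multinomial deviance with common random
numbers; it is optimized by seeded differential evolution with a simplex
polish, because the surface is deterministic but rough. Two degeneracies
are handled explicitly: exchange slower than the largest window is
indistinguishable from a static mixture (rates are bounded below at
0.5/window_max), and very fast, strongly one-sided exchange mimics a
static state at the averaged efficiency (a static-only nested fit is
preferred unless the dynamic component earns > 10 deviance units).

Filtered FCS builds minimum-variance unbiased unmixing filters from the
limiting-state decay patterns (Σ_j f_i(j) p_k(j) = δ_ik), correlates the
filtered photon weights with a multiple-tau estimator (base bin 2 µs,
block-wise error bars), and fits all four curves globally with

    G(t) = 1 + (1/N_c) D(t) [1 ± s_c Σ_j A_j exp(−t/t_Rj)],

D(t) = (1 + t/t_diff)^−1, relaxation times fixed at 1e−5, 1e−4 and
1e−3 s. The decomposition A_j is shared; each curve has a free particle
number and a free relaxation contrast s_c (auto- and cross-correlations
see the same exchange with different contrast; a single shared amplitude
cannot represent both). Percentages are normalized to 100 and ranked
major/middle/minor.

## Accessible volumes and structural modeling

The AV model is single-radius (AV1-style; defaults L = 21 Å, w = 4.5 Å,
r = 3.5 Å, grid 0.8 Å): Dijkstra geodesics over grid cells with path
clearance ≥ w/2, dye-center clearance ≥ atom radius + r, geodesic length
≤ L, uniform weights. The neighbor set includes all primitive offsets
within Chebyshev radius 2, keeping the lattice geodesic within ~2% of
the Euclidean distance. Distance measures R_mp, ⟨R_DA⟩ and
R_DA,E = R0(⟨E⟩^−1 − 1)^{1/6} come from seeded weighted pair sampling;
convention conversions are additive offsets computed from the same pair
distribution. Fitted FRET distances are interpreted as R_DA,E by default.

Rigid-body docking samples uniform rotations and shell translations,
rejects steric clashes (< 2.5 Å) and linker violations (contour bound
3.8 Å per linker residue), and scores χ² = Σ((R^AV − R^restraint)/σ)²
with AVs computed once per body and transformed rigidly per pose. The
top-ranked sampled poses are locally refined over the six transform
parameters — purely random sampling cannot hit χ² < 0.01 in a 6-D pose
space, and refinement is what docking tools do in practice. The
confidence ensemble keeps poses with χ²_r/χ²_r,best ≤ F_{1−α}(n, n).

The landscape builder standardizes the feature vectors, projects on the
first two principal components, estimates density by a smoothed 2-D
histogram, inverts to PMF = −k_B T ln(p/p_max) (k_B T = 0.5961 kcal/mol
at 300 K), segments basins by watershed with 0.3 kcal/mol minimum-depth
pruning (negligible basins below 0.1% weight dropped), and rescales the
density per basin so integrated basin weights match supplied occupancies.

## What the synthetic world does and does not emulate

The generators produce: a 12-variant network over two states plus a
no-FRET species (defaults: fractions 0.461/0.539, no-FRET 0.06, R0
52 Å, donor lifetimes 4.1/1.8 ns with amplitudes 0.8/0.2, distances
35–75 Å with every variant keeping one state in the FRET-sensitive
range, half-widths 8/4 Å, basin exchange relaxation 1 ms); Poisson
TCSPC histograms with a Gaussian IRF (0.25 ns FWHM); PIE photon streams
with Gaussian-envelope transits (exponential duration), telegraph state
switching, state-independent direct acceptor excitation and a
`continuous` single-molecule mode for PDA/fFCS validation; TIRF traces
with single-step acceptor-then-donor bleaching; bead-model bodies with a
planted two-cluster snapshot ensemble; and exponential/Hill tables.

Not emulated: acceptor dark states, triplet blinking, spectral crosstalk
beyond a single leakage fraction, anisotropy, detector afterpulsing, and
real dye-surface interactions. Overlapping transits occasionally merge
two molecules into one burst or window; the PDA oracle therefore uses
the continuous mode, and a green test establishes correctness of the
estimators under the stated model, not robustness to those artifacts.
Burst brightness and measurement durations are chosen for statistical
power, not fidelity to any instrument.

## Known limitations

- Per-variant state assignment remains data-degenerate if the true state
  half-widths are equal and occupancies near 0.5.
- PDA cannot distinguish exchange far outside the window range from
  static heterogeneity (bounded, flagged via the nested static fit).
- The fFCS diffusion term is the 2-D approximation; amplitudes at the
  fixed decades absorb mild mismatch of the true relaxation time.
- The deposited-data re-analysis paths require a local copy of the
  published dataset; they are exercised only when it is present.
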