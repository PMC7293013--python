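# Methods

`looprefine` integrates a simulated conformational ensemble of an RNA
hairpin with ensemble-averaged NMR observables, and then asks which
structural degrees of freedom — and which measurements — distinguish the
conformational states that the refined ensemble contains.  This note
documents the models, the numerical choices, and what the synthetic study
design does and does not show.

## Ensemble model and prior weights

An ensemble is a shared topology with `n` frames; every quantity the
package computes is an expectation over frames with a normalized weight
vector.  Plain MD gives the uniform prior `w0 = 1/n`.  For well-tempered
metadynamics trajectories the prior comes from the final bias potential,
`w0_j ∝ exp(+V_j / kB·T)` with `V_j` in kJ/mol; the weights are invariant
to constant shifts of the bias, and because deposited files sometimes store
`−V`, the sign is an explicit flag rather than a guess.  Coordinates are
stored in Å (nm-native formats converted on read); residues are indexed
1-based 5′→3′; frames 0-based.

## Forward models

* **NOE distances.** The effective distance of a proton pair is the
  r⁻⁶-weighted ensemble average, `r_eff = (Σ_j w_j r_j⁻⁶)^(−1/6)`, the
  standard isolated-spin-pair convention for NOE-derived distances.  It is
  bounded by the extreme frame distances and never exceeds the linear mean.
* **Scalar couplings.** Three-bond couplings follow Karplus relations
  `J(θ) = A·cos²(θ+φ) + B·cos(θ+φ) + C`.  Published parametrizations vary
  by author and coupling pathway, so coefficients are configuration (an
  editable TSV keyed by coupling type), with representative defaults for
  sugar H–C–C–H (9.67, −2.03, 0), backbone H–C–O–P (15.3, −6.1, 1.6) and
  C–C–O–P (6.9, −3.4, 0.7) Hz.
* **RDCs.** `D_i = D_max,i · ûᵀ S û` with a single global alignment
  (Saupe) tensor `S`, symmetric and traceless.  `S` is obtained by a
  five-parameter weighted linear least-squares fit to the measured RDCs
  over the weighted ensemble average of the bond-orientation products; a
  rank-deficient design (all bonds parallel) is reported as an
  unidentifiable tensor.  `D_max` values are configuration; the default is
  1 (reduced units).

## Bayesian/Maximum-Entropy reweighting

Refined weights minimize deviation from the experimental averages while
maximizing relative Shannon entropy against the prior.  The dual problem
minimizes, over one Lagrange multiplier per measurement,

    Γ(λ) = log Z(λ) + Σ_i λ_i F_i^exp + (θ/2) Σ_i λ_i² σ_i²,
    Z(λ) = Σ_j w0_j exp(−Σ_i λ_i F_i(x_j)),

giving `w*_j = w0_j exp(−Σ_i λ_i F_ij)/Z`.  θ ≥ 0 trades confidence in the
prior against the data; σ_i includes experimental and forward-model error.

Numerics: all observables enter in the space in which linear
weight-averaging is exact (r⁻⁶ for NOE, with σ propagated to first order
as `σ' = 6σr⁻⁷`; couplings and RDCs are already linear).  The solver works
in σ-scaled variables (each constraint measured in its own error bar) so
mixed units condition identically; L-BFGS with the analytic gradient
`∂Γ/∂λ_i = F_i^exp − ⟨F_i⟩_w(λ) + θλ_iσ_i²`, gradient tolerance 1e-8,
iteration cap 5000, 50 stored correction pairs, λ initialized at 0.  A
residual gradient below 1e-5 error bars is accepted when the line search
terminates abnormally; anything worse raises a convergence error with
diagnostics.  Z is always evaluated with log-sum-exp stabilization.

Because the RDC forward model is linearized around a fixed tensor, fitting
the tensor on the prior can bias the RDC rows once the refined weights
move far from the prior.  `reweight_with_tensor_refit` therefore iterates
fit-tensor → solve to self-consistency (tolerance 1e-6 on weights, at most
10 rounds) before θ is selected; each individual solve stays convex.

θ is chosen by 5-fold cross-validation: measurements are partitioned by a
seeded shuffle, the solver runs on the training folds, and χ² is evaluated
on the held-out fold; the default grid is logarithmic, 1e-2…1e4, 13
points.  Exact ties break towards the larger θ (less aggressive
reweighting).  Folds are not stratified by observable class.

Agreement statistics: reduced `χ² = (1/m) Σ (⟨F⟩_i − F_i^exp)²/σ_i²` and
per-measurement `|Z| = |⟨F⟩ − F_exp|/σ`; χ² is the mean squared Z-score.
χ² in the refinement report is given in linear (optimization) space per
dataset and, per measurement, in back-transformed physical units.  The
diagnostic `φ_eff = exp(−Σ w* ln(w*/w0))` is the effective fraction of
frames retained.  Upper/lower-bound restraints are parsed but treated as
equalities with their stated σ by default.

## Structural metrics and state assignment

* **eRMSD.** Base arrangements are compared with the nucleic-acid-specific
  eRMSD metric.  Each nucleobase carries a local frame: origin at the
  centroid of the six-membered ring, orientation from the C2/C4/C6
  triangle (x towards C2; the second in-plane atom is C4 for pyrimidines,
  C6 for purines, which keeps the positive z side on the same base face).
  The relative position of base j in the frame of base i is scaled
  anisotropically by (5, 5, 3) Å, mapped to the smooth 4-vector G with
  cutoff 2.4 and γ = π/2.4, and eRMSD = √(Σ_pairs |ΔG|²/N).  The constants
  are pinned module-level for reproducibility.
* **Torsions.** Backbone α…ζ from the standard quadruplets; χ is
  O4′–C1′–N9–C4 for purines and O4′–C1′–N1–C2 for pyrimidines; angles in
  (−180°, 180°], IUPAC sign; missing atoms yield NaN, never an error.
* **States.** A frame is state A when its eRMSD to the reference is
  strictly below the threshold (default 0.7), state B otherwise — the
  boundary value is B.  Populations are weight sums over labels.
* **Free-energy surfaces.** Weighted 2-D histograms mapped to −ln p in
  kB·T, anchored so the minimum over filled bins is zero (absolute free
  energies are undefined); empty bins are masked.
* **Block errors.** Frames are split into contiguous, time-ordered blocks
  (equal counts, remainder to the last block); the weighted statistic is
  recomputed per block with renormalized weights and the standard error is
  the across-block sample deviation over √n_blocks.  Contiguous blocks
  match trajectory-correlation logic; weight-stratified blocks were the
  alternative and are not used.

## Random-forest state discovery

50 000 bootstrap samples (configurable) are drawn with replacement with
probability equal to the refined weights; each sample is labeled by the
eRMSD threshold; features are torsions, ring-centre distances, or
per-sample back-calculated observables (NOE features are reported as
distances for interpretability; RDC features use the fixed prior-ensemble
tensor, since per-frame tensor fitting is ill-posed).  A 100-tree random
forest with maximum depth 2 is trained on 80% of the samples; held-out
accuracy is reported.  Circular torsions are encoded as (sin, cos) pairs
to avoid wrap-around artifacts in axis-aligned splits; a pair's importance
is summed under the torsion's name.

Feature importance is the total sample-weighted impurity decrease a
feature achieves across the whole forest, normalized once at the end.
This deliberately differs from the common per-tree-normalized mean, which
credits a tree's best *sampled* feature with full importance even when its
best split is barely informative — with feature subsampling that turns the
ranking into a selection lottery among weak features.  Summing raw
impurity decreases keeps weak and strong discriminators on one scale.
Because single-forest rankings still fluctuate with the bootstrap, the
pipeline driver aggregates importances over several seeded forests
(default 8) before reporting; measurements with aggregated importance
strictly above 0.2 are flagged as state-sensitive.

## Synthetic two-state study design

The generator builds a 14-residue pseudo-nucleotide hairpin (sequence
GGCACUUCGGUGCC: a 5-bp stem, loop residues 6–9).  Pseudo-nucleotides have
idealized hexagonal rings and a simplified backbone — every atom the
forward models, torsions and metrics need, but no chemical realism.  Two
templates define the states:

* **State A (ordered):** ring-centre contacts (6,8) and (6,9) closed
  (3.9–4.7 Å), the ζ torsion of residue 8 in the gauche+ well (+60°).
* **State B (disordered):** both contacts open (> 8.5 Å), ζ(8) in
  gauche− (−60°), loop bases orientationally tumbled (30–150°
  rotations).  Open-state loop positions roam a box around the hairpin;
  half of them (configurable) form transient nonspecific contacts along
  the chain, preferentially near sequence neighbours (tether-weighted),
  and either loop base can make the contact.  This gives every
  *non-planted* pair distance overlapping A/B distributions, as in a real
  disordered state, so that only the designated contacts separate the
  states cleanly.

Per-frame disorder: rigid translation wobble (stem 0.3 Å, residue 7
0.6 Å), base orientation noise (8°), an independent 120° wobble of each
backbone sub-body (the nucleobase arrangement carries the state; the
backbone is floppy in both states, so no linkage torsion secretly encodes
the state), and 0.08 Å atomic jitter.  The residue-9 backbone is rebuilt
in internal coordinates off residue 8 so that ζ(8) sits exactly in the
state's well while every other torsion along that chain is drawn from the
same distribution in both states.  Frames are rejected and resampled if
any two atoms come within 0.5 Å.

Frame counts per state follow `frame_fraction_a` (default 0.5, at least
one frame per state); the thermodynamic truth `population_a` is carried by
the true weights (state-A frames share it equally), so a uniform prior
genuinely differs from the truth.  Observables (30 NOE pairs, 10
couplings, 8 RDCs from a fixed generator tensor) are true-weight averages
plus independent Gaussian noise whose scale is also the reported σ.

**What this shows and what it does not.**  Passing the synthetic study
shows the machinery is correct: the solver finds the maximum-entropy
solution, populations are recovered when they are identifiable, the
forest recovers planted discriminators against realistic confounders.  It
does not validate forward-model parametrizations against real spectra,
NOE spin-diffusion effects, force-field accuracy, or alignment-tensor
prediction from molecular shape — none of which the generator emulates.

**Identifiability regime for population recovery.**  Recovering a state
population from ensemble-averaged data is well-posed only when the
within-state spread of each observable is small against the between-state
contrast; otherwise maximum-entropy refinement legitimately trades
population for within-state reweighting and shrinks towards the prior.
The feature-discovery default config deliberately has broad within-state
disorder (so that non-planted features overlap), which caps population
identifiability at roughly ±0.08.  The population-recovery experiment
therefore uses a documented low-disorder variant (`RECOVERY_CONFIG`:
tighter contact ranges, 4–5° torsion noise, 0.05 Å jitter), under which
recovered populations land within ±0.03 of truth at near-zero noise.
This mirrors the real situation: reported ensemble populations carry
uncertainties of ±5–16% for exactly this reason.

Problem sizes used throughout the tests and the acceptance script —
150–200 frames, 48 measurements, 2000–5000 bootstrap samples, forests of
100 trees — were chosen so the full study runs in minutes on one core
while every statistic remains comfortably clear of its acceptance bound.

## Known limitations

* Bound-sense NOE restraints are treated as equalities; the one-sided
  multiplier mode is not the default.
* The alignment tensor is global; ensembles with state-dependent alignment
  are outside the model.
* χ² for NOE data is reported in both r⁻⁶ (optimization) and distance
  space; the two orderings can differ for poorly fitting data.
* The generator's pseudo-nucleotides are geometric stand-ins; coupling
  values computed from them are internally consistent but not comparable
  to measured couplings of real RNA.
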