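# looprefine

Tools for integrating simulated conformational ensembles of RNA hairpin
loops with solution NMR data, and for discovering which structural degrees
of freedom separate the conformational states the refined ensemble
contains.

RNA tetraloops such as the hyper-stable UUCG loop exchange between a
well-defined folded conformation and lowly populated alternative loop
states.  An MD or enhanced-sampling ensemble proposes candidate
conformations with prior weights; NMR observables — exact-NOE distances,
three-bond scalar couplings, residual dipolar couplings — constrain their
populations.  `looprefine` is aimed at computational structural biologists
who have such an ensemble and such data and want to (i) refine the frame
weights against the measurements, (ii) quantify agreement, and (iii)
identify the torsions, base-base contacts and individual measurements that
report on minor states.

## What it computes

**Bayesian/Maximum-Entropy (BME) reweighting.**  Refined weights w*
minimize deviation from the experimental averages while maximizing
relative entropy to the prior w⁰.  The dual problem minimizes

    Γ(λ) = log Z(λ) + Σᵢ λᵢ Fᵢᵉˣᵖ + (θ/2) Σᵢ λᵢ² σᵢ²,
    Z(λ) = Σⱼ w⁰ⱼ exp(−Σᵢ λᵢ Fᵢ(xⱼ)),      w*ⱼ = w⁰ⱼ e^(−Σᵢ λᵢ Fᵢ(xⱼ)) / Z,

with one Lagrange multiplier per measurement and θ chosen by 5-fold
cross-validation.  Agreement is reported as reduced
χ² = (1/m) Σᵢ (⟨F⟩ᵢ − Fᵢᵉˣᵖ)²/σᵢ² and per-measurement Z-scores.

**Forward models.**  NOE effective distances as r⁻⁶ ensemble averages
(Σⱼ wⱼ rⱼ⁻⁶)^(−1/6); Karplus couplings J(θ) = A cos²θ + B cos θ + C with a
configurable coefficient table; RDCs Dᵢ = D_max û ᵀS û with a global
alignment tensor fit by linear least squares and refit to self-consistency
during reweighting.

**State assignment and discovery.**  Frames are assigned to the folded
state A when their eRMSD (a base-centric nucleic-acid dissimilarity built
from scaled base-base position/orientation vectors) to a reference
structure is below 0.7, else to state B.  A shallow random forest
(100 trees, depth 2) trained on weighted bootstrap samples ranks torsions,
ring-centre distances, or back-calculated measurements by how well they
discriminate the two states.

**Synthetic ground truth.**  A generator builds two-state pseudo-nucleotide
hairpin ensembles with known populations, a planted ζ-torsion switch and
two planted ring-ring contacts, plus noisy ensemble-averaged observables —
so the whole pipeline is testable end to end with no external data.

## Worked example

Generate a synthetic two-state bundle (true state-A population 0.8, frame
split 50/50, honest noise σ = 0.1), refine it, and classify:

```bash
looprefine simulate --seed 3 --outdir bundle --n-frames 60 --population-a 0.8

cat > refine.yaml <<EOF
ensemble: bundle/ensemble.pdb
measurements: bundle/measurements.tsv
reference: bundle/template_a.pdb
outdir: refined
seed: 5
EOF
looprefine refine --config refine.yaml
```

prints (abridged):

```json
{
  "chi2_train_before": 12.61,
  "chi2_train_after": 0.42,
  "theta": 31.62,
  "phi_eff": 0.78,
  "population_a_prior": 0.5,
  "population_a_refined": 0.716
}
```

The prior (uniform) ensemble disagrees with the data (χ² ≈ 12.6); after
reweighting at the cross-validated θ the agreement is within error
(χ² ≈ 0.4) while 78% of the effective frames are retained, and the
state-A population moves from the 50% frame split towards the generating
truth (0.72 vs 0.8 — residual shrinkage towards the prior is expected at
this noise level).  Running `classify` on the refined weights reports a
held-out accuracy of ~0.98 and ranks the planted discriminators first:
`zeta_8` among the torsions, and the `U6–C8` / `U6–G9` ring-centre
distances among the base-base contacts.

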