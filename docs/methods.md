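# Methods

## Problem and scope

The package implements three-state protein secondary-structure
prediction (H = helix, E = strand, C = coil, reduced from DSSP's
eight states by H,G,I→H; E,B→E; T,S,blank→C) with a fully
complex-valued relaxation network, together with the statistics used
to evaluate such predictors, a procedure for selecting a small
("compact") training set, and a distance-based hydrogen-bond analysis
of prediction outcomes.  The coarse-grained force-field pipeline that
produced the original 27-dimensional probability features (template
threading, contact maps, reference energies) is explicitly out of
scope; a synthetic generator stands in for it (below).

## Feature representation

Each residue `t` carries 27 raw values in [0, 1]: the probabilities of
positions `t−4 … t+4` adopting H, E and C, stored as three blocks of
nine (all P(H), then all P(E), then all P(C)).  Only residues with
four neighbours on both sides receive a vector, so a chain of length
L yields L − 8 vectors; chain termini are likewise dropped from model
development (`trim_termini`, default 4 per end), while blind-set
evaluation may keep them (`n_trim = 0`).

Normalization maps each value to [−1, 1] via `2(x − min)/(max − min)
− 1`.  Two modes exist because the original description is ambiguous
about the extrema's scope: **per-feature dataset-level extrema**
(default, reusable: held-out data is normalized with the development
set's recorded extrema and clipped to ±1, which preserves injectivity
of the circular map) and **per-vector extrema** (each 27-vector scaled
by its own min/max; stateless).  The circular transform
`z = exp(iαx)` then places values on the unit circle; `α` defaults to
π/2 and must stay below π so the map is injective on [−1, 1].  The
exact circular transformation of the original network is not published
in closed form; this definition preserves its stated properties (real
[−1, 1] → unit-modulus complex, injective) and is configurable.

## The classifier

Architecture: m = 27 complex inputs, K ≤ 100 hidden neurons with the
complex hyperbolic secant activation, n = 3 exponential output
neurons:

    h_k = sech(v_k · z + b_k),     ŷ_l = exp(Σ_k w_lk h_k).

Labels are coded as complex vectors: slot of the true class holds
`e^{iπ/4}`, all other slots `e^{i5π/4}` (antipodal unit-modulus codes
with well-defined logarithms).  Because the output layer is an
exponential, training reduces to a single linear problem: with
H the hidden-response matrix and `log y` the principal-branch
logarithm of the coded labels (whose real part carries label
magnitude and imaginary part label phase), the output weights solve

    min_W  Σ_t ‖W h^t − log y^t‖² + ridge‖W‖²

in closed form via the normal equations (ridge default 1e-8, for
conditioning).  Training is single-shot; identical data, parameters
and seed give bit-identical weights.  Prediction decodes each output
to the class whose code is nearest in the complex plane, ties broken
in the fixed order H, E, C.

**Hidden-parameter initialization.**  Projections `v_k` are complex
Gaussian with entry scale `projection_scale / √m`; biases `b_k` are
uniform on the unit circle.  The scale (default 0.2) matters: complex
`sech` has poles at `i·π(k + ½)`, and with unit-scale projections the
pre-activations of unit-modulus inputs land near those poles often
enough to give heavy-tailed hidden features and poor generalization of
the least-squares solve.  A scale well below π/2 keeps each neuron in
the smooth region around its bias point, while the unit-circle biases
spread neurons over the activation curve and supply feature
diversity.  Shrinking the biases as well collapses that diversity and
degrades accuracy, so only the projections are scaled.

**Numerical notes.**  `sech` is evaluated as `2e^{−su}/(1 + e^{−2su})`
with `s = sign(Re u)`, so no exponential can overflow; the measure-zero
poles are replaced by a large finite value (1e30) rather than inf, so
downstream linear algebra never sees non-finite entries.  Singular
normal equations at `ridge = 0` raise an error advising a positive
ridge.

## Synthetic feature generator

The generator emulates the statistical shape of probability-profile
features.  For each residue one triplet over (H, E, C) is drawn from
`Dirichlet(kappa · m + 1)` with mean direction `m = 0.95·e_true +
0.05/3` (a 5 % uniform smoothing of the true-state indicator), and
windows reuse neighbour triplets exactly as a sliding-window encoder
would, which induces the window-to-window correlation of real
profile features.  The `+1` baseline makes the two limits clean:
`kappa → 0` recovers the flat Dirichlet (mean (⅓, ⅓, ⅓), uninformative)
and `kappa → ∞` concentrates on `m` (center-position argmax equals the
true label essentially always).  A pure `kappa·m` concentration would
keep the mean fixed at `m` for all `kappa` and thus have no
uninformative limit, which is why the baseline is part of the design.
`kappa` is an artifact parameter — it tunes informativeness and is not
a quantity of the original feature pipeline.

Chains for synthetic studies come from `random_chain_set`: structure
strings are alternating state runs (state drawn from a composition
prior, default 35/23/42 H/E/C as in globular-protein benchmarks;
run length 1 + geometric with mean 5), sequences are uniform random
amino acids.  What the generator does **not** emulate: real features'
inter-class correlation structure, position-specific noise, sequence–
structure coupling, and long-range strand pairing.  Tests passing on
synthetic data therefore demonstrate correctness and recovery behaviour
of the machinery, not real-data accuracy; the published benchmark
figures are checked separately from the bundled tables.

## Evaluation statistics

Residue scores come from a 3×3 observed-vs-predicted confusion matrix:
Q3 = 100·trace/total; per-class Q_j = 100·diag_j/rowsum_j (reported as
absent, not zero, for an empty class); Q_HEerror = 100·(HE + EH)/total;
per-class MCC is one-vs-rest with the convention MCC = 0 when any
denominator factor vanishes.  SOV follows the 1999 revised definition:
for every overlapping same-state pair of observed segment s1 and
predicted segment s2, credit `len(s1)·(minov + δ)/maxov` with
`δ = min(maxov − minov, minov, ⌊len(s1)/2⌋, ⌊len(s2)/2⌋)`;
non-overlapping observed segments enter the normalizer only.  Multi-
chain scoring pools residues for the confusion-based scores and sums
per-chain SOV numerators and normalizers — segments never merge across
chain boundaries.  All percentages are kept at full precision and
rounded only for display, because the published tables themselves
round inconsistently in the last digit (e.g. a Q3 of 76.643 printed as
76.65, a Q_C of 42.857 printed as 42.8); bundled-fixture tests compare
at printed precision ±0.01 and assert the exact ratio where the print
is a truncation.

## Compact-model selection

Stage 1 estimates the number of training chains P: chains are shuffled
once (seeded) and added `step` at a time (default 5); at each size a
fresh network is trained (hidden width min(k_max, samples), k_max
default 100) and Q3 measured on all remaining chains; P is the size of
the curve maximum, first occurrence on ties.  One training per point
by default — the curve is treated as a single-run diagnostic.

Stage 2 builds candidate sets: `sampled` (P chains uniform without
replacement, optionally excluding the stage-1 chains), `balanced`
(equal residue counts per class, a residue-level set trained on
directly since the classifier consumes per-residue vectors), and
`spread` — a deterministic algorithmic proxy for picking chains
"spread over the composition space by eye": greedy farthest-point
sampling on (fH, fE, fC), starting from the chain nearest the dataset
centroid, each subsequent pick maximizing its minimum distance to the
chosen set, ties by dataset order.

Stage 3 trains one classifier per candidate and ranks candidates by
Q3 on a blind dataset that must be disjoint from every candidate; the
winner is the compact model.  Every stage is reproducible under fixed
seeds.

## Hydrogen-bond analysis

Contacts are polar-atom pairs (elements N or O, including water
oxygens) within a donor–acceptor distance cutoff, default 3.6 Å, with
donor/acceptor roles ignored.  Excluded: pairs within one residue and
the covalent backbone O(i)–N(i+1) peptide pair.  Atom roles: M =
backbone N/O/OXT of a standard residue, S = polar side-chain atom,
H = water oxygen (HOH/WAT/DOD); pair categories MM, MH, MS, SS, SH,
anything else "other".  Neighbour search uses a k-d tree and is
verified against the all-pairs scan.  The angular criteria of full
hydrogen-bond assignment programs are deliberately not implemented, so
absolute contact counts are not comparable with angular-filtered
tools; the outcome analysis (MM vs MH fractions per R_ij category)
is the supported quantity.  Tallies are per residue endpoint: a
contact between two scored residues contributes to both residues'
counts; a category's residue count includes residues with at least one
contact of any kind.  PDB files are read through gemmi; alternate
locations resolve to the highest-occupancy conformer (ties: first).

## Problem sizes used in tests

The shipped tests and the acceptance script run at desk scale chosen
to exercise every property with comfortable margins: recovery checks
use 200 training / 500 held-out residues (K = 30, kappa = 1e4);
training-curve checks use 60 chains of 56 residues over three seeds;
ranking checks use 10 + 10 development chains against an 8-chain blind
set over five seeds at kappa = 2 (a moderately informative regime
where training-set composition visibly matters); oracle-equivalence
checks use 1000 random chains of length ≤ 50 and 100-atom random
structures.

## Known limitations

* The original network's exact error functional, initialization and
  circular transform are not restated in public sources; the choices
  here are documented substitutes, not claims about that reference.
* The synthetic generator cannot certify real-data accuracy (above).
* SOV is implemented from the published 1999 definition rather than a
  specific historical scorer binary; multi-chain pooling treats chains
  independently.
* Contact detection is distance-only; no hydrogen placement, angular
  filtering or solvent-accessibility computation.
* Whether the published bond tallies counted endpoints or bonds is not
  stated; this implementation counts per residue endpoint.
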