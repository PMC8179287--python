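# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the limits of what the tests demonstrate.

## Problem setting

A reaction record consists of an atom-mapped reactant set, a list of
candidate outcomes — each a reacting heavy-atom pair (a, b) plus the
resulting product — and the index of the recorded major outcome.  The task
is to rank the candidates.  Because candidates of one reaction compete,
scores are normalised by a softmax *within* each record and the training
loss is the cross-entropy of that softmax against the major index; the
model therefore learns relative reactivity, not an absolute rate.

## Selectivity network

Atom features are discrete one-hots (element over C,O,N,P,S,F,Cl,Br,I,Si,B
plus an "other" bucket; degree 0–5; total valence 0–6; H count 0–4;
aromatic flag; formal charge), 32 slots in total.  Hydrogens are folded
into the H count; all graphs are heavy-atom graphs.

The WLN encoder runs L rounds of

    a⁽ˡ⁺¹⁾_v = relu(U₁ a⁽ˡ⁾_v + Σ_{u∈N(v)} relu(V [a⁽ˡ⁾_u ; f_uv])),

with a⁽⁰⁾_v = relu(W₀ x_v).  Bond features f_uv are the discrete
type/ring one-hots in graph-only mode, or the concatenated RBF expansions
of bond order and bond length in the fusion modes.  A single-head scaled
dot-product attention over all atoms of all reactant molecules produces a
context vector added residually to the local embedding; with zeroed logits
it degrades to mean pooling, which the tests exploit as a closed form.

Fusion concatenates, in fixed order (charge, electrophilic Fukui,
nucleophilic Fukui, NMR shielding), the RBF expansions of the four atomic
descriptors to the attended embedding.  The two reacting atoms'
representations are sum-pooled (order-invariant by construction) and scored
by an FFNN (hidden 64 → latent 32 → 1).  The latent layer is exposed as the
reaction's latent vector; distances between latents are plain Euclidean.

Baseline modes share the scoring head but change its input: graph-only
(embedding alone), descriptor-only (the pooled RBF blocks of the reacting
pair, no graph encoder at all), and a difference Morgan fingerprint
(product minus reactants, 2048 bits, radius 2).  Mode separation is strict
and is asserted by a poisoning test: corrupting the descriptor table can
change descriptor-mode predictions only.

Ties in the top-1 decision are broken toward the lowest candidate index
(NumPy argmax), and candidate lists are ordered by canonical product
SMILES, so predictions are deterministic.

## Descriptor predictor

The multitask model uses one D-MPNN encoder (hidden 64, depth 4) whose
directed-edge states are initialised from the source atom's features and
the bond's discrete features, updated with the standard
exclude-the-reverse-edge message sum, and aggregated into atom states.  Six
heads read out the channels; bond heads consume the sum of the two directed
edge states of a bond (a symmetric function, so bond outputs do not depend
on edge orientation) through a softplus, which keeps bond order and length
positive.

Conserved channels (charge → net formal charge; each Fukui index → 1) pass
through the attention constraint q_i^final = q_i + w_i (Q − Σ q_j) with
w = softmax(a·u) and a learnable query u per channel.  The constraint is
applied during training, not only at inference, so gradients flow through
the correction; dot-product similarity is the default with a cosine option.
Sums hold to ≤1e−6 (in practice ~1e−16) for trained and untrained weights
alike — this is an algebraic identity, not a learned property.

Per-channel squared-error losses are computed on post-constraint outputs
and standardised by the training-set standard deviation of each channel, so
ppm-scale shielding cannot drown the e-scale charges.  Training is Adam
(lr 5e−3) over minibatches of 32 molecules packed into one disjoint graph;
the best-on-validation parameter set is returned.  Net-charged molecules
are rejected at ingestion and prediction: Fukui indices of charged species
are outside this framework's domain.  Charges are predicted for heavy atoms
only, with hydrogen contributions folded into the heavy-atom values by the
oracle's design.

Both networks and their training loops run on a ~300-line reverse-mode
autodiff engine over NumPy arrays (`regioml.nn`) providing broadcasting
arithmetic, matmul, relu/softplus/softmax, row gather and segment
reductions; gradient correctness is checked against central finite
differences, and all randomness flows through seeded
`numpy.random.Generator` instances, so runs are bit-reproducible per seed.

## RBF expansion

A scalar x maps to exp(−γ(x−cₖ)²) on a fixed grid.  Grids (8 centers each,
γ chosen so neighbouring Gaussians cross at half height): charge −1…1 e,
Fukui channels 0…0.5 (indices of multi-atom molecules concentrate below
0.5 since each channel sums to 1), shielding 0…300 ppm, bond order 0.5…3,
bond length 0.9…2.4 Å.  Equal dimension per descriptor keeps the
concatenated QM block (32) the same width as the learned embedding (32), so
neither information source dominates the fused representation.

## Curation pipeline

Template extraction diffs the mapped reactant/product connectivity
(bond-order changes, H-count changes, formal-charge changes, atoms present
on one side only), grows the changed core by a configurable bond radius
over the reactant graphs, and renders each side as reaction SMARTS; the
reactant side carries explicit H counts so only sites with the right
hydrogen count match, while the product side leaves hydrogen counts to the
valence model.  The contract — reapplying a template to its own source
reactants regenerates the recorded product — is enforced at extraction
time.  Enumeration runs the template at every matching site and
deduplicates by canonical product SMILES, which collapses
symmetry-equivalent sites; a record is selective iff at least two distinct
candidates remain and the recorded product is one of them.

The yield filter keeps records with reported yield ≥ threshold (default
50%) and drops records with missing yield: without a yield one cannot be
confident the recorded product is the major one.  The scaffold split keys
each record by the generic Murcko framework (atoms and bonds made generic)
of its largest aromatic-ring-containing reactant, assigns scaffold groups
largest-first to the most-underfilled partition (greedy bin-packing, ties
by lexicographic key), and guarantees key-disjoint partitions; unreachable
ratios (one giant scaffold) are reported in the manifest rather than
raised.  Cross-validation draws disjoint fixed-size test folds from one
seeded permutation, and downsampling the training remainder never changes a
fold's test membership.

## Synthetic study conditions

The oracle maps topology to descriptors through documented coefficients:
charges from electronegativity differences across bonds plus folded
hydrogens, recentred exactly; Fukui site scores from a base value per atom
type plus directing effects of substituents (O/N/S donors strength 1,
halogens 0.4, alkyl 0.25; carbonyl/nitrile/CF₃ carbons and ring
heteroatoms as acceptors) with parity — odd topological distance is
ortho/para-like, even is weakly opposite — and a per-bond decay of 0.6, then
positive-clipped and normalised to sum to one; shielding from element
baselines shifted by neighbour electronegativity and aromaticity; bond
order from bond-type baselines with a small degree correction; bond length
from covalent-radius sums contracted by order.  Channel noise is Gaussian,
seeded per molecule from the canonical SMILES, and conserved channels are
renormalised after noise so constraints hold exactly.

The distance decay matters: with directing effects restricted to distances
1–3, topologically distinct sites frequently tie exactly, leaving the
argmax label undefined and unlearnable.  The decaying profile makes ties a
degenerate case, and the reaction generator additionally discards
substrates whose top-2 site scores are within 1e−6, since an exact tie
means the rule does not determine a major site.

Toy reactions are aromatic brominations/chlorinations over substrates from
a fragment grammar (12 aromatic cores, 25 substituents, 1–4 substitutions —
diverse enough that a graph-only model cannot memorise the rule from 200
examples, which is what makes the small-training-set contrast meaningful).
The major site is argmax of (nucleophilic Fukui − 0.005·steric), the steric
penalty counting heavy atoms within two bonds of the site; yields are
uniform on [50, 100]%, and optional label noise flips the major to a random
minor site with the stated probability.

What the fixtures do *not* emulate: real electronic structure (no claim of
matching any DFT distribution), stereochemistry, reagent-dependent
selectivity, multi-bond-change mechanisms, or the heterogeneity of patent
data.  Passing the recovery experiments shows the architecture can extract
descriptor-coded selectivity rules from data at these scales; it says
nothing quantitative about accuracy on experimental reaction corpora.

## Problem sizes and defaults

Defaults were chosen so every experiment runs on one CPU in seconds to a
few minutes with the NumPy engine: descriptor model hidden 64 / depth 4 /
60 epochs on corpora of 500–800 molecules; selectivity model H 32 / L 2 /
RBF dim 8 / 40 epochs on datasets of 120–700 reactions.  The
parameter-recovery experiment trains on 500 molecules with σ = 0.02 e
charge noise and reaches the σ√(2/π) noise-floor MAE; the selectivity
recovery experiment uses 700 reactions (560 train / 140 held out).

## Known limitations

* The descriptor oracle's Fukui normalisation couples all atoms of a
  molecule; a finite-depth message-passing model approximates but cannot
  represent it exactly, so descriptor MAEs plateau above zero even without
  noise.
* Bond-order/length heads recover their oracle rules less sharply than the
  atomic channels (the targets' variance is dominated by bond type, which
  the discrete features already encode).
* Template extraction handles single-product, fully mapped reactions with
  one newly formed bond between mapped atoms — the substitution setting —
  and is not a general reaction-template miner.
* The engine is CPU-only and unbatched across records at prediction time;
  it is sized for method study, not production screening throughput.
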