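# Methods

## Model

Labels live on a rooted tree: every dotted label ("1.6.5") names a leaf, and
every proper prefix ("1", "1.6") an internal node. For a tree with q leaves
and s non-root nodes, each leaf y carries a binary attribute vector
Λ(y) ∈ {0,1}^s indicating the nodes on its root path (the root itself is
excluded from numbering and from Λ; this is the convention under which a
3-leaf, 5-node two-family tree gives path({second leaf}) = {leaf, its
parent}). With the joint feature map Φ(x,y) = φ(x) ⊗ Λ(y), the discriminant
f(x) = argmax_y ⟨w, Φ(x,y)⟩ sums one weight-vector contribution per node on
y's path, and joint inner products factorize:

    ⟨Φ(x,y), Φ(x′,y′)⟩ = (Λ(y)·Λ(y′)) · k(x,x′),

where Λ(y)·Λ(y′) counts shared path nodes — equivalently, the depth of the
deepest common ancestor.

**Full model (oracle).** Minimize ½‖w‖² + CΣᵢξᵢ subject to
⟨w, Φ(xᵢ,yᵢ) − Φ(xᵢ,y)⟩ ≥ 1 − ξᵢ for every wrong leaf y ≠ yᵢ, ξᵢ ≥ 0 —
l·(q−1) constraints. There is no offset term. We solve this primal directly
(scipy `trust-constr` with a linear-constraint matrix in the explicit
(s × d) joint weight space; linear kernel only) rather than its dual, and
we report the objective at a *feasible* point: slacks are recomputed from
the returned w, so the reported value can only overestimate the true
optimum. The implementation caps instances at 2,000 constraints; it exists
as ground truth for the reduced model, not as a production trainer.

**Reduced model.** Each sample keeps a single margin constraint against one
competitor leaf ŷᵢ ≠ yᵢ. Substituting that constraint into the same
objective, the dual is

    max Σᵢαᵢ − ½ΣᵢΣⱼ αᵢαⱼ K̃ᵢⱼ,   0 ≤ αᵢ ≤ C,

with the modified kernel K̃ᵢⱼ = (Λ(yᵢ)−Λ(ŷᵢ))·(Λ(yⱼ)−Λ(ŷⱼ)) · k(xᵢ,xⱼ) — a
Schur product of two PSD Gram matrices, hence PSD. Only l dual variables
remain, and because the primal has no offset there is no equality
constraint coupling them. Scoring uses the kernel expansion
score(x,y) = Σᵢ αᵢ [Λ(yᵢ)·Λ(y) − Λ(ŷᵢ)·Λ(y)] k(xᵢ,x); prediction is the
argmax over leaves with ties broken toward the smallest leaf id (so an
untrained model predicts the first leaf, deterministically).

**Competitor rule.** ŷᵢ is the sibling leaf of yᵢ (same parent) with the
largest training count; a leaf with no sibling takes the largest class
overall. Siblings are the labels most easily confused, and margining against
the largest one counters the boundary bias that class imbalance induces.
Ties break toward the smallest node id. Competitors are recomputed from the
training split of whatever data the model is fit to.

## Solving the box QP

The dual is solved in two phases: an L-BFGS-B pass (scipy) over the box,
then cyclic coordinate ascent, where each update is the exact clipped
single-coordinate maximizer, with a projected-Newton refinement on the free
coordinate set (least-squares solve, backtracked into the box) — the
refinement matters when K̃ is near-singular, e.g. at vanishing RBF γ, where
plain coordinate ascent creeps. Convergence is certified by the duality
gap: the feasible primal reconstructed from α (½αᵀK̃α plus hinge slacks
from the margins K̃α) minus the dual value. Defaults: relative gap ≤ 1e-6;
oracle-grade comparisons in the tests use 1e-10..1e-12. Non-convergence
raises rather than returning silently. A Gram matrix whose minimum
eigenvalue falls below −1e-8 (scaled) also raises, since it indicates a
kernel bug rather than numerical noise.

Special cases with closed forms used as test anchors: a single training
sample has K̃₁₁ = ‖Λ(y)−Λ(ŷ)‖² (= 2 for siblings under an RBF kernel), so
α* = min(C, ½); a flat 2-leaf tree makes the reduced model *exactly* a
no-offset binary soft-margin SVM with penalty 2C (substitute β = 2α in the
dual), which the tests verify against an independent L-BFGS-B solve.

## Encoders

CTF: the 7-class partition {A,G,V}, {I,L,F,P}, {Y,M,T,S}, {H,N,Q,W}, {R,K},
{D,E}, {C}; a width-3 window slides with step 1; each window of three
classifiable residues increments its cell in the 343-vector (row-major over
the ordered class triple, fixed so feature tables are bit-stable); counts
are divided by the number of counted windows. Non-standard codes
(B, J, O, U, X, Z) are accepted in input but unclassifiable: windows
containing one are skipped and excluded from the denominator — a
deterministic rule that avoids inventing class memberships; sequences whose
every window is ambiguous are rejected by name. Lower-case input is
upper-cased. Frequencies sum to 1; an optional (f−min)/max rescaling — the
normalization of the original triad descriptor — is off by default. AAC is
the 20-vector of single-residue frequencies over standard residues only.

## Evaluation

Predictions are always leaves; evaluation at level k projects truth and
prediction to their k-digit prefix first, so a near-miss inside the right
subfamily is credited at the subfamily level. Per-class MCC is the
one-vs-rest binary Matthews coefficient; a zero factor in the denominator
yields 0 (logged). The headline multiclass figure is the macro average;
the generalized multi-category MCC (scikit-learn) is available behind
`multiclass_mcc=True`. Macro-F1 comes from scikit-learn. Cross-validation is
stratified on leaf labels (even when scoring at a shallower level), reduces
the fold count with a warning when the rarest class is smaller than the
fold count, and reports both pooled out-of-fold metrics and per-fold
mean ± SD (the SD is across folds, not across classes).

## Synthetic data

The sequence generator emulates the two properties the model exploits:
sibling classes share signal through their parent, and class sizes are
imbalanced. Each non-root node receives 2 private triad motifs (class
triples drawn without replacement across nodes, so signal is identifiable);
sequences are built from 3-residue blocks, each being a motif of a
uniformly chosen node on the leaf's root path with probability
`motif_rate`, otherwise uniform background, followed by per-residue
substitution noise. Defaults — length 120, motif_rate 0.3, noise_rate 0.05
— give a learnable but imperfect problem (leaf-level accuracy in the high
0.8s–0.9s for a calibrated model). The vector generator is the numeric
analogue: each node gets a random unit direction; a leaf's cluster center
sums `family_separation` (6.0) times its internal-node directions and
`sibling_separation` (1.5) times its leaf direction, with unit within-class
noise, so sibling clusters overlap more than cross-family ones.

What this does *not* emulate: homology structure and phylogenetic
correlation, length variation, realistic residue composition, shared motifs
*between* families, or label noise. Passing tests therefore demonstrate the
machinery is correct under the stated generative assumptions, not
performance on real enzyme data.

Train/test material is always one generated dataset split per leaf
(`split_by_leaf`, first-n per class): generating a second dataset from a
different seed would redraw the planted structure itself and the test set
would come from a different population. The classic toy shape is provided
as a preset: 175 points (29 / 70 / 76 over a two-family tree) split
146 / 29.

## The hierarchy-benefit benchmark

`hiersvm.benchmark` compares the reduced model with the flat one-vs-rest
baseline on sequences: two families × three sub-subfamilies, imbalanced
training counts 60/20/30/50/25/15, 15 held-out test sequences per leaf,
20 replicate seeds. Both methods are calibrated identically — (C, γ) by
stratified 3-fold CV on the training split over C ∈ {2⁻³…2⁷} and
γ ∈ γ_med·{2⁻⁴…2⁶}, where γ_med is the median heuristic (1/median pairwise
squared distance); CTF frequency vectors live at a much smaller scale than
O(1) features, which is why the γ grid is data-scaled. The reduced model in
particular needs a local kernel: with a broad nonnegative kernel, a leaf
that is nobody's competitor (the smallest sibling under each parent)
accumulates score unopposed, and the model degenerates. This locality
requirement is a genuine limitation of the single-constraint reduction, not
an implementation artifact, and under these conditions the flat baseline
remains slightly ahead on mean leaf-level macro-MCC (≈0.94 vs ≈0.89 in the
shipped configuration) — the speed of the reduction (l instead of l·(q−1)
variables) costs a few points of leaf-level quality on this kind of cleanly
identifiable synthetic data. `scripts/acceptance.py` recomputes both means
on every run rather than quoting them.

## Numerical and design choices

- Node ids are deterministic (leaves 1..q in lexicographic label order,
  then internal prefixes q+1..s), so serialized models and trees are
  reproducible byte-for-byte; single-child chains are kept as distinct
  nodes so EC prefixes map 1:1 to nodes.
- All tie-breaks (competitors, argmax prediction, grid search) go toward
  the smallest node id / smallest parameter value.
- Grid-search defaults C ∈ {2⁻⁵,2⁻³,…,2⁹}, γ ∈ {2⁻⁹,…,2³} suit O(1)-scale
  features; for CTF input use a data-scaled γ grid as in the benchmark.
- Model files are JSON with base64-encoded float64 arrays: text, and exact
  round trips.
- The class-size filter (`filter_min_class_size`) drops classes *strictly*
  below the threshold and errors if fewer than two classes survive.
- Oracle-vs-reduced comparisons use the linear kernel so the full model's
  weight vector is explicit; the relaxation ordering (reduced primal ≤ full
  optimum) is asserted with 1e-6 slack to absorb both solvers' tolerances.

## Known limitations

- The reduced model's competitor set is fixed before training; leaves never
  selected as competitors are constrained only indirectly (see above).
- The full-model oracle is dense and deliberately small-scale.
- One leaf per sample: no multi-label assignment, no DAG taxonomies.
- Sequence input supports the 20 standard residues plus the B/J/O/U/X/Z
  ambiguity codes; other characters are rejected at parse time.
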