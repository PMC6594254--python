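# Methods

This note documents the models and procedures implemented in `seqvis3d`,
the conventions the package fixes where the underlying method leaves a
choice open, and what the synthetic-data experiments do and do not show.

## From sequence to terrain

A nucleotide sequence over {A, C, G, T} (uracil is folded to thymine on
ingest, so RNA input is accepted) is turned into an integer terrain in
three steps.

**Frequency rank.** Let n_A, n_C, n_G, n_T be the base counts of the
sequence. The rank function f maps the most frequent base to 4 and the
least frequent to 1; with n_A > n_C > n_G > n_T this is f(A)=4, f(C)=3,
f(G)=2, f(T)=1. Ties are broken by a fixed base order (default A, C, G, T,
the earlier base taking the larger value); the order is configurable
because only the strict-inequality case is canonically defined. Applying f
position-wise yields the sequence's rank-digit encoding, e.g.
f(TGCCAATCGTTGT) = 1233441321121 under the canonical map. (A previously
printed rendering of this digit string, 1233441231121, transposes the
digits of positions 8 and 9 — bases C, G must encode as 3, 2; the digit
multiset is otherwise identical. The package treats that rendering as an
erratum and implements the substitution rule.)

**Spiral embedding.** Positions 1..L are laid out on a square grid of side
ceil(sqrt(L)) along a spiral curve, so consecutive positions always occupy
4-adjacent cells. The default spiral is Ulam-style: it starts at the
central cell and winds outward counterclockwise with a first step in +x.
Handedness, first step and a corner-inward alternative are configurable
(`SpiralConfig`), and the chosen convention is echoed into output
metadata, because no single convention is canonical and the triad spectrum
of the resulting graph depends on it. Non-square lengths leave the unused
cells simply absent — no padding elevation is invented, since padded cells
would inject fictitious visibility relations.

**Elevation.** Each occupied cell receives elevation z = f(base) in
{1..4}. The result is `Lattice3D`: an integer terrain whose heights encode
base-frequency structure and whose layout encodes sequence locality.

## The 3D visibility graph

Two terrain nodes are connected when they can "see" each other. The build
is a union of five steps with first-step-wins provenance (a pair is tagged
by the earliest step that produced it, and later steps never duplicate it):

- **Step 2 — adjacency.** Every node is joined to its existing
  4-neighbours; border nodes have degree 2–3, absent cells contribute
  nothing.
- **Step 3 — cell diagonals.** Every complete unit cell is split by one
  diagonal through its highest corner (ties broken by the lexicographically
  smallest (x, y) corner), joining it to the opposite corner. These
  diagonals also fix the triangulation used by step 5.
- **Step 4 — profile visibility.** Along every row (4x) and every column
  (4y), the 1D natural-visibility criterion is applied to the elevation
  profile: nodes i and k connect iff every intermediate node m of the same
  line satisfies z_m < z_k + (z_i − z_k)(x_k − x_m)/(x_k − x_i). The
  published form of the column-direction inequality repeats the
  row-direction left-hand symbol; the package uses the intermediate node's
  own elevation on the left, mirroring the row case, as the only reading
  consistent with the 1D criterion. Likewise, the per-line reading (rather
  than collapsing all rows onto a single projected profile) is used because
  a collapsed projection would superpose unrelated heights.
- **Step 5 — general line of sight.** Every remaining pair is connected
  iff the open 3D segment between the two nodes stays strictly above the
  terrain. The terrain here is the full wireframe-plus-surface: the nodes
  themselves, the unit edges between 4-adjacent nodes, and the two
  triangles of every complete cell (split by its step-3 diagonal). On a
  fully occupied lattice the nodes and edges lie inside the triangulated
  surface, so they add nothing there; they matter only for degenerate or
  partial lattices (e.g. a single-row terrain, which has no complete cells
  but whose raised middle node must still block the sightline between its
  neighbours). A literal alternative (`blocking="node"`) connects two
  nodes unless a third node's column reaches up to or above the sightline;
  equality is the "node exactly on the segment" case.

All comparisons are evaluated in exact rational arithmetic
(`fractions.Fraction` over integer coordinates); there are no
floating-point tolerances anywhere in the geometry. Strictness matters:
equal-height runs do not see through each other, and a segment lying *on*
the surface (as every long chord does on a flat terrain) is blocked, which
is why a flat 5×5 terrain yields exactly 40 adjacency + 16 diagonal = 56
dyads and steps 4–5 contribute nothing.

**Orientation.** The triad census is directed, but the construction alone
does not orient dyads. The default policy leaves step-2 adjacency dyads
mutual and directs step-3/4/5 dyads from the higher to the lower endpoint
(mutual on equal elevation). Alternatives — `all-mutual`, `z-descending`
(orient everything), `temporal` (direct from earlier to later sequence
position) — are selectable, and the choice is recorded in graph metadata,
because downstream censuses are only comparable under a fixed policy.

A 2D natural-visibility construction for ordinary series data
(`natural_visibility_2d`, the Lacasa-style criterion: two points connect
iff all intermediate points lie strictly below their chord) is included
both as a reference primitive and for the step-4 machinery.

## Triad statistics

The census counts the 16 directed three-node classes in the
Mutual-Asymmetric-Null labelling (003, 012, 102, 021D, 021U, 021C, 111D,
111U, 030T, 030C, 201, 120D, 120U, 120C, 210, 300); it always sums to
C(n, 3). The six columns reported for sequence networks are TP1 = 102,
TP2 = 003, TP3 = 012, TP4 = 021C, TP5 = 111D, TP6 = 111U. (TP1 has
occasionally been labelled "1-102"; in the standard 16-type order 102 is
type 3 — the package keys everything by the type label itself, so the
ordinal is irrelevant.)

The chi-square statistic is χ² = Σ_i (x_i − μ_i)² / σ_i², where x_i are
observed triad counts and μ_i, σ_i² their mean and variance under a null
model. The null is not canonically fixed by the statistic itself; the
package defaults to the classical dyad-census-conditional (U|MAN) null —
all digraphs with the observed numbers of mutual, asymmetric and null
dyads equally likely — which is the convention under which triad-count
z-scores are traditionally reported. Both moments are computed exactly:

- μ_i enumerates the 4³ = 64 dyad-slot states of one triple with
  multivariate-hypergeometric (falling-factorial) weights and a factor
  (1/2)^a for asymmetric-dyad orientations;
- E[x_i²] additionally enumerates ordered pairs of distinct triples
  sharing one dyad (4⁵ states; there are C(n,2)(n−2)(n−3) such pairs) and
  dyad-disjoint pairs (4⁶ states), giving σ_i² = E[x_i²] − μ_i².

Cells with σ_i² = 0 and x_i = μ_i are skipped (they carry no information);
σ_i² = 0 with x_i ≠ μ_i is an error rather than a silent infinity. A
Pearson-style variant (denominator μ_i, zero-mean cells skipped) and an
independence null (`null="uniform"`, dyad types i.i.d. with the observed
proportions) are available by flag. The exact moments are validated
against 10⁴ dyad-preserving Monte-Carlo shuffles in the test suite.

The per-sequence feature vector concatenates, in a documented, versioned
layout (`FEATURE_LAYOUT`, 13 entries): the six TP counts, the edge count
(unordered pairs; a mutual dyad counts once), the chi-square, the four
rank-digit counts, and the sequence length.

## Classification

The base learner is a four-layer feedforward network (input, hidden 8,
hidden 4, output 1; all sigmoid) trained by full-batch backpropagation
with momentum. Reference hyperparameters: learning rate 0.7, momentum 0.6,
learning-set tolerance 0.2, test-set tolerance 0.02. The tolerances are
interpreted as absolute output-error bands: training stops once every
training item's output is within 0.2 of its 0/1 target (or at
`max_epochs`, default 400); the 0.02 test tolerance is carried in the
configuration for reporting. Inputs are standardized on the training set
(the triad counts span orders of magnitude). Hidden widths (8, 4) are a
package default — no widths are canonically prescribed — and are
configurable. Everything is deterministic given the seed; single-class
training sets degrade to a constant predictor with a warning.

Three validation schemes: `split67_33` (67% learning / 33% test, test size
= round(0.33 n)), `split50_50`, and `loocv` (leave-one-out; every item is
predicted out-of-fold).

**Hybrids.** A hybrid wires k members so that each executed member's
per-item predictions are appended to the feature matrix seen by the next
member in the flow ("results transferred to input", i.e.
prediction-augmented stacking — the only reading under which members stay
independent yet connected; no weights are shared). Execution orders:
series 1→…→k; cyclic 1→…→k→1 (exactly one full cycle, member 1's second
pass emits the output — no other stopping rule is defined); cascade
1→…→k→…→1 (forward then backward, so a 3-member cascade executes
1,2,3,2,1). Re-executed members are fresh learners. The final execution in
the flow emits the output.

**n-hyper hybrids.** Level 0 is a hybrid of base learners; level L wires
three level-(L−1) systems under the same wiring, with the same
prediction-transfer rule between subsystems. A level-n series hybrid of
k-member hybrids therefore trains 3ⁿ·k leaf learners (the execution log
counts them). Per-execution seeds are drawn from one deterministic stream,
so a level-1 hybrid of single-member hybrids is bit-identical to a plain
3-member hybrid.

"Precision" of a method is its percent agreement (accuracy) with the
experimental label row: recomputing agreement between the packaged
prediction rows and the label row E reproduces the reported percentages
exactly for eight of the fifteen methods (NN1 30, NN2 60, 1-HH2 50,
2-HH1 30, 2-HH2 50, 10-HH1 50, 10-HH2 70, 10-HH3 90). The remaining seven
reported percentages (NN3, H1–H3, 1-HH1, 1-HH3, 2-HH3) do not match any
positional agreement computable from the printed rows (e.g. NN3 recomputes
to 80, not 70) and are treated as errata: the package asserts nothing
about them. The individual 0/1 prediction rows themselves are not
reproducible (they depend on unrecorded training randomness) and are
shipped only as a fixture; no attempt is made to retrain to bit-equality.

The label polarity in the packaged fixture follows the label table
(variant rows carry Y = 1); a contradictory prose statement of the
opposite polarity exists in the source material and is sidestepped by
always computing agreement positionally against row E.

## Synthetic data

`random_sequence` draws i.i.d. bases (default uniform); `random_lattice`
draws uniform elevations in {1..4} on a full grid — the elevation
distribution a rank-encoded sequence induces, without its spatial
correlations. `two_class_dataset` mirrors the real experimental design:
n_per_class random reference sequences (label 0), each paired with a
variant carrying one random single-base substitution (label 1), run
through the full pipeline; the positive class then receives a mean shift
of `effect` population standard deviations on one named feature (default
TP1, the mutual-dyad triad count, the feature reported to separate variant
networks). Defaults: n_per_class = 10 (the real design has 10 networks),
length = 99 nt (the precursor length of the first reference miRNA),
effect = 5 SD.

What this shows — and does not. The injected-shift construction makes the
class separation *known by construction*, so the recovery experiment
(LOOCV agreement ≥ 90% across seeds) validates the learner, the schemes
and the plumbing, not the biological claim that real variant networks are
separable: real SNP-induced feature differences are tiny (single-digit
changes in counts of order 10⁵) and carry no injected shift. Random
sequences also lack the compositional bias and secondary structure of real
precursor miRNAs. Exact reproduction of the real networks' census tables
is out of scope because it depends on the exact sequences and on spiral
conventions that are not recoverable.

## Numerical and degenerate-input choices

- Geometry is exact (integer/rational); ties are decided by stated rules
  (lexicographic corner tie-break; strict inequalities everywhere), so
  builds are bit-reproducible across platforms.
- Graphs with fewer than 3 nodes have an identically zero census and
  chi-square 0 in `summary_stats` (there are no triples); `triad_census`
  itself requires ≥ 3 nodes.
- An edit whose alternate base equals the reference is the identity on
  residues but is still recorded in provenance.
- Sequence positions are 1-based (edits quote "the 50th place");
  grid coordinates are 0-based.
- Split test sizes use round(); LOOCV needs n ≥ 2, splits n ≥ 3.

## Problem sizes used in validation

Oracle-equivalence runs use 200 random terrains of side ≤ 5 (full build
vs. definition-level brute force, including a ≥10³-point sampled
line-of-sight check made exact by also evaluating all piecewise-linear
breakpoints), 50 random 50-point series for 2D visibility, 20 random
12-node digraphs for the census, 10⁴ dyad-preserving shuffles for the
null model, and 10 seeds of the 10-pairs-per-class recovery experiment.
These sizes were chosen so the whole validation battery runs in minutes
on one core while leaving each check's power intact.
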