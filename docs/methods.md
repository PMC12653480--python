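# Methods

`orsite` prioritizes candidate functional residues of a membrane receptor —
typically an insect odorant receptor (OR) — by combining three orthogonal,
inexpensive signals: evolutionary conservation of alignment columns,
membrane topology, and a Cα-only solvent-exposure proxy. The terminal
product is a ranked shortlist of residues worth mutagenesis follow-up. This
note records the models, the defaults and why, and what the synthetic
generators do and do not emulate.

## Conservation

For each column *i* of a gapped multiple alignment, the conservation score
is the modal residue frequency

    C_i = max_r count(r ∈ col_i) / n_i ,

where `n_i` counts **valid** residues only: the gap character `-` and the
ambiguity codes `X`, `B`, `Z` are excluded from both numerator and
denominator. This makes the score a frequency over observed residues, so it
is invariant under duplicating members and under member order, and a column
is scored 1 exactly when all its valid residues agree. A column with no
valid residue is reported as `C_i = 0` with an explicit no-data flag so
threshold rules can never select it. Modal ties report the alphabetically
first residue for reproducible output.

Two thresholds serve two different purposes and are deliberately distinct
config keys: descriptive classification uses a strict inequality
(highly conserved means `C_i > t_high`, variable means `C_i ≤ t_var`;
defaults 0.9 and 0.7), while candidate selection uses the inclusive rule
`C_i ≥ candidate_threshold` (default 0.9).

Columns map to 1-based ungapped positions of a designated reference
sequence (the focal species), so results read as "Thr103"-style residue
coordinates. Columns where the reference is gapped carry no reference
position and cannot become candidates.

## Substitution model and distances

Pairwise distances are maximum-likelihood estimates under the JTT
(Jones–Taylor–Thornton) empirical amino-acid model. The packaged
exchangeabilities and frequencies (see `src/orsite/data/jtt.dat`, with
provenance in its header) are assembled into a reversible rate matrix

    Q_ij = s_ij π_j (i ≠ j),   Q_ii = −Σ_{j≠i} Q_ij ,

rescaled to unit expected rate at stationarity (−Σ π_i Q_ii = 1), so all
times and distances are in expected substitutions per site. Transition
matrices `P(t) = expm(Qt)` come from one eigendecomposition of the
π-symmetrized form — exact, cheap to evaluate for many `t`, and numerically
symmetric.

The distance between two aligned rows maximizes
`Σ log(π_a P_ab(t))` over their shared valid columns, by bounded scalar
maximization on `t ∈ [0, 10]` to an absolute tolerance of 1e-6. Identical
rows short-circuit to 0. An optimum at the cap (10 expected
substitutions/site) marks the pair *saturated*; saturated pairs are kept at
the cap and flagged rather than dropped, so the matrix stays complete. A
pair sharing no valid column has no defined distance; inside the matrix
builder such pairs are likewise capped and flagged.

## Neighbor-Joining and bootstrap support

Trees are built by the Saitou–Nei agglomeration on the Q-criterion, which
is exact on additive matrices. Two numerical policies make output
reproducible: among equal-criterion pairs the lexicographically smallest
label pair is merged (a merged cluster inherits its smallest leaf label),
and negative branch-length estimates are clamped to zero with a logged
warning. Two taxa give a single edge; three give the closed-form
three-point solution.

Bootstrap support resamples alignment columns with replacement to the
original length, recomputes distances and the NJ tree, and reports for each
internal bipartition of the **original** tree the percentage of replicate
trees containing it (default 100 replicates). Support is attached to the
original tree's edges, not to a consensus topology. Each replicate draws
from a random stream derived from the master seed and the replicate index,
so replicate *r* is reproducible in isolation. A replicate whose distances
are undefined is skipped and logged; if more than half are skipped the run
aborts. Newick output carries integer support as internal node labels, and
an optional display rooting on an outgroup edge leaves the unrooted
bipartition set untouched.

## Topology regions and the candidate mask

Topology is an input (ordered TM segment ranges plus the membrane side of
the N-terminus, as produced by an external predictor such as TOPCONS), not
something this package predicts. Sides alternate at every membrane
crossing; each inter-TM gap becomes an extracellular (EL) or intracellular
(IL) loop according to the side the preceding helix exits to, and the tails
take the flanking sides. All ranges are 1-based inclusive. Zero-length
loops or tails are representable and flagged rather than erroneous — a 7TM
receptor whose last helix ends at the final residue has an empty C-tail,
which is a real situation, not a malformed input.

The candidate-region mask has two modes because "the loops and the termini
of the TM helices" admits two readings:

* `loops_plus_full_tms` (default): all EL residues plus every residue of
  TM helices numbered ≥ `tm_min_index` (default 3). This is the
  figure-consistent reading for 7TM ORs, whose binding pocket is drawn from
  TM3–TM7 and the extracellular loops, and it contains the classic
  experimentally validated OR positions.
* `loops_plus_tm_termini`: all EL residues plus the `w` residues (default
  4) at the extracellular-facing end of every helix — the literal
  "junction residues only" reading.

Both are exposed; the discrepancy between the readings is documented here
rather than resolved, because it cannot be resolved from the regions'
definition alone.

## Cα exposure score

For residue *i* with Cα coordinates from a predicted structure, `N_i`
counts other Cα atoms within 8 Å (boundary inclusive — the radius is a
screening parameter, not a physical cutoff) and `D_i` is the distance to
the nearest other Cα regardless of radius (the formula needs `D_i` even
when `N_i = 0`). The raw score

    ASA_i = max(0, 20 − N_i) + 2 · D_i

rises for loosely packed residues and is linearly rescaled to [0, 100]
across the scored set. This is a screening proxy, **not** a probe-based
accessible surface area: it has no side chains, no probe sphere, and no
area units. It is monotone in the right directions and that is all the
ranking needs.

Two policies worth knowing: if every raw score is equal the rescale is
undefined and all normalized scores are set to 0 (never 100 — no residue
should be spuriously reported as "most exposed") with a loud warning; and
the normalization scope is configurable — over the selected candidates only
(default) or over all residues — because ranked shortlists read differently
under the two conventions. Rank order within the candidates is identical
either way.

Parsing keeps only `ATOM` records with atom name `CA` from the first model
of one chain; alternate locations resolve to the highest-occupancy
conformer; `HETATM` is ignored. At chain scale (hundreds of residues) the
all-pairs distance computation is exact and instantaneous, so no spatial
index is used.

## Selection and ranking

A candidate is a reference position with `C_i ≥ 0.9` that lies inside the
candidate mask — a pure set intersection, so raising the threshold or
shrinking the mask can only remove candidates. Candidates are ranked by
normalized exposure, descending, with deterministic tie-breaks: fewer
neighbors first, then larger nearest-neighbor distance, then smaller
position; the list is truncated to `top_k` (default 5, the size of a
typical mutagenesis panel). The alignment reference, the topology, and the
structure must agree on one 1-based coordinate system; an integer offset
maps PDB numbering when it differs, and any length mismatch is a hard
error naming all three lengths, never a silent drop.

The phylogeny stage contextualizes the family (how diverged, which
orthologs cluster) but does not gate selection, so it can be disabled for
speed.

All report floats are rounded to 4 decimals at serialization; internal
computation is full precision. A run manifest records config, seed, package
version, and SHA-256 checksums of the inputs; identical config and inputs
produce byte-identical reports.

## Synthetic generators

**Family simulator.** An ancestral sequence drawn from the JTT stationary
frequencies evolves down a random (or supplied) tree via `P(t)` sampling.
Columns belong to one of three rate classes — invariant (rate 0), moderate,
fast — mimicking the strongly bimodal conservation profile of OR ortholog
sets. Defaults: 11 taxa, 400 columns, class fractions 0.20/0.26/0.54,
rate multipliers (0, 1.0, 2.2), exponential branch lengths with mean 0.2.
The fractions mirror the highly-conserved/intermediate/variable column
shares reported for OR ortholog alignments; the rates and depth were then
chosen once so that the realized fraction of fully conserved columns stays
within the generator's own binomial tolerance of the invariant-class
fraction (moderate columns slow enough to sit above 0.7 conservation
become chance-invariant and would corrupt that ground truth). The
compromise: the realized mean conservation (~0.57) is lower than in the
real OR data (~0.67) whose class shares inspired the fractions. Length
variation among orthologs (315–415 aa in real sets) is emulated by
terminal deletions only, so internal columns stay aligned and the untrimmed
reference keeps `position == column`. Planted positions can be forced
invariant (or fast) to provide exact ground truth; because gaps are
excluded from `n_i`, terminal trimming never dilutes a planted column's
score.

**Bundle simulator.** Ideal α-helix geometry — 1.5 Å rise and 100° twist
per residue on a 2.3 Å helical radius (textbook values, a modeling choice,
not fitted) — with helix axes on a circle of radius 8.5 Å, alternating
up/down. The default layout (10-residue N-tail, seven 21-residue helices,
loops of 10/40/33/56/10/50, no C-tail) is the canonical 356-residue insect
OR chain, so the emitted topology matches the published helix ranges
exactly. Loops are guided random walks at fixed 3.8 Å Cα steps, biased
away from the membrane plane and radially outward, with candidate steps
deflected off already-placed atoms (clash distance 3.4 Å); this keeps loop
residues genuinely less packed than helix residues, which is the single
geometric fact the exposure score needs. Gaussian jitter (default
σ = 0.2 Å) roughens coordinates without changing the layout. Ground-truth
labels: helix residues beyond the axis circle by more than half the
helical radius are `exposed`, those inside by the same margin `buried`,
the band between `lateral`; loops and tails are `exposed`.

What the generators do **not** emulate: real indel placement (no internal
gaps), among-site rate correlation, rate variation within a class, actual
protein folding, side chains, or loop secondary structure. Passing tests
therefore demonstrate that the pipeline's logic and numerics are correct
and that the selection rule recovers planted signal under the stated
generative model — not that the score identifies binding residues in any
particular real receptor.

**Recovery fixtures.** The parameter-recovery check uses
`FixtureSpec(background="variable")`: every non-planted column evolves
fast on a deep tree (branch mean 0.35) with no terminal trimming, so
background conservation sits far below threshold, and key residues are
planted invariant at the extracellular-loop positions that are measurably
the most exposed in that very structure. This realizes the intended
contrast — conserved + surface-placed signal against variable background —
and all planted keys occupy the top of the final ranking across every
tested seed. The demo fixture (`background="calibrated"`, seed 42) instead
uses the realistic class mix and ragged ends, which deliberately produces
a broader candidate list.

## Problem sizes and tolerances

Tests run the exhaustive oracles at the scales where they are exact and
fast: conservation brute-force up to 15 × 400 columns; neighbor statistics
against the all-pairs oracle at 120–300 residues; NJ exactness on 108
random additive trees of 4–12 taxa; the ML-distance grid search at step
1e-4 over the full [0, 10] domain for a 200-column pair; bootstrap
determinism at 20–100 replicates; recovery over 20 generator seeds. The
ML optimizer tolerance is 1e-6 and is tested to 1e-3 against the grid;
Newick round-trips are checked to 1e-9; exposure invariance under random
rigid motions to 1e-8.

## Known limitations

* The exposure score saturates for `N_i ≥ 20` and has arbitrary units; it
  orders residues, nothing more.
* ML distances near saturation (≳ 3 substitutions/site) are noisy and get
  capped at 10; the cap is visible in the `saturated` flags, and summary
  statistics over matrices containing capped pairs inherit the cap.
* NJ is exact only on additive matrices; on noisy distances it is a
  heuristic, which is the standard trade-off for its speed.
* Conservation of columns with few valid residues (ragged alignment ends)
  is high-variance; the per-column `n_i` is exported precisely so users
  can filter on it.
* The candidate rule is a screen. It has no notion of ligand chemistry,
  and a residue can pass every filter while being structurally rather than
  functionally constrained.
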