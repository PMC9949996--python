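# Methods

## Model

`ovrfsim` simulates nucleotide substitutions as a continuous-time Markov
jump process over an entire genome, exactly (Gillespie), rather than
site-by-site. The per-event rate is HKY-like at the nucleotide level —
target-frequency π_j times transition bias κ times the site's mutation
category μ_i — multiplied by a selection factor ω that aggregates every
reading frame the site participates in. For each ORF membership the
affected codon is translated (standard nuclear code, reverse-complemented
for minus-strand ORFs) before and after the candidate change; an
amino-acid difference contributes the site's fixed dN/dS category for
that ORF to the corresponding entry of a six-entry frame vector
{−2, −1, −0, +0, +1, +2}, and ω is the product of the entries. A change
that is synonymous in every frame, or non-coding, has ω = 1 exactly.
Selective effects of overlapping frames are thus assumed multiplicative;
no epistasis or codon-frequency equilibrium (F3x4/F61) is modelled, and
there are no indels, recombination, or lineage-specific rate shifts.

Assumptions worth keeping in mind:

- Substitutions at different sites interact only through shared codons:
  a change at one position can flip the synonymy classification of its
  codon neighbours in every frame, which is why rates are re-derived for
  the full codon neighbourhood after each event.
- A substitution creating a premature internal stop codon is allowed and
  simply counts as non-synonymous in that frame; only each ORF's first
  and last codon are protected, meaning all six of those sites are
  excluded from the event pool entirely so reading frames can never be
  destroyed at their boundaries. ORFs are not required to literally start
  with ATG or end with a stop (a warning is logged when they do not).
- Per-site μ and ω category assignments are drawn once at initialization
  and stay fixed along the whole tree.

## Parameters

| parameter | meaning | default |
|---|---|---|
| κ | transition/transversion rate multiplier (dimensionless) | 0.3 |
| π | stationary target-nucleotide frequencies (A, C, G, T) | empirical frequencies of the root sequence |
| global_rate | expected substitutions per neutral site per unit branch length | 0.05 in the YAML config; always explicit in the library API |
| μ distribution | mutation-rate heterogeneity across sites (gamma/lognormal/constant, ncat equal-probability categories) | constant 1 |
| ω distribution per ORF | dN/dS heterogeneity across that ORF's sites | required per ORF |

Gamma distributions are parameterized by **shape α and scale β (mean
α·β)**. With shape 2, scale 0.5 and four categories the discretized rates
are 0.29327, 0.65501, 1.06999, 1.98172 (mean exactly 1). Discretization
uses equal-probability quantile bins represented by their **conditional
means**, computed in closed form (for the gamma via the identity
x·pdf_α(x) = αβ·pdf_{α+1}(x); for the lognormal via the shifted
normal-CDF identity). Median-of-bin representation is deliberately not
used: conditional means preserve the distribution mean exactly for every
family and category count. The lognormal takes `shape` as the σ of the
underlying normal and `scale` as the median e^μ; other location
conventions exist in the literature, and published category values
derived under an unstated convention may not be reproducible from these
definitions — the discretization here is validated against the gamma
closed form and an independent quadrature oracle instead.

Branch lengths are calibrated so that a neutral site accrues
`global_rate` substitutions per unit branch length on average: at
initialization all rates are scaled by global_rate · L / Λ_neutral, where
Λ_neutral is the root sequence's total event rate with ω ≡ 1 (all sites
counted, using the realized per-site μ values). This makes "0.01
substitutions per site along a branch of length 1 at global rate 0.01"
hold by construction in the neutral case; selection and composition
drift then modulate the realized rate as the model dictates.

## Event probability tree

Every candidate event (site, target nucleotide) at an unprotected site
is stored at exactly one tip of a five-level tree keyed by target
nucleotide → transition/transversion → μ signature → region →
ω-combination class. A *region* is a maximal set of sites sharing one
ORF-membership set; an ω-combination class is the sorted multiset of
(ORF, ω-category) pairs in which the event is non-synonymous, so the
region-level weight of a class is ω_k·N_k (class product times member
count), and the μ signature joins the global μ category with any
ORF-level μ-multiplier categories so that all members of a tip share one
rate — asserted at build time with a 1e−9 relative guard. Sampling walks
from the root choosing each child with probability proportional to its
cached subtree weight and picks a tip member uniformly, which is exactly
the flat λ_e/Λ distribution; that equivalence, not any particular
traversal convention, is the module's correctness contract and is
enforced by flat-enumeration oracle tests. After a substitution, events
are re-derived for the mutated site and every site sharing a codon with
it in any frame (≤ 1 + 2·(memberships) positions), and weight deltas are
propagated to the root; a property test asserts the incrementally
updated tree equals a fresh build event-by-event. The level order fixes
sampling efficiency only, not the distribution.

Numerical notes: cached weights are maintained by ±λ deltas and pruned
with their nodes when a tip empties, so float residue cannot accumulate
in dead branches; traversal skips non-positive weights and the weight
invariant (node weight = sum of children within 1e−9 relative) is
re-checkable at any time. Deep copies share the immutable annotation,
category assignments and parameters, and copy sequence, tips and
weights; a copy's sampling stream is identical to the original's under
the same RNG state.

## Simulation over the tree

The phylogeny must be rooted (a basal polytomy is rejected unless
explicitly allowed) with branch lengths on every edge. Nodes are visited
in level order; at each node the parent state — sequence plus event tree
— is deep-copied, evolved along the connecting branch by repeated
Exp(Λ) waiting times and λ/Λ event draws until the branch length is
exceeded, and the final waiting-time overshoot propagates the sequence
unchanged. Each branch consumes an independent RNG stream derived from
the master seed and the branch's level-order index, so enlarging the
tree does not perturb other lineages' draws; category assignment uses
stream index 0 before any branch is simulated. Identical inputs and seed
give bit-identical alignments. With deep copies at internal nodes the
output distribution is traversal-order invariant; level order is kept as
the canonical schedule.

## Entropy diagnostics

Alignment columns are summarized by Shannon entropy H = −Σ P_i log₂ P_i
in bits (0 = conserved, 2 = maximal for nucleotides), with 0·log 0 := 0
and gap/ambiguity characters excluded from the frequencies with a
warning. Sliding-window means default to width 20 nt, step 1; linear
alignments yield only full windows (L − width + 1), circular alignments
wrap and yield L windows, and window centers are recorded as
start + (width − 1)/2. Region summaries report mean and interquartile
range per region (midpoint-interpolation quartiles — the convention is
stated because others exist) plus a two-sided Wilcoxon rank-sum
comparison of overlapping (≥ 2 ORFs) versus single-ORF columns.

## Synthetic fixtures and what they do (not) show

All tests run on generated data. `make_genome` draws i.i.d. nucleotides
at a requested GC content; `make_overlap_layout` provides three
arrangements — `fig2` (one isolated ORF plus an overlapping pair,
partitioning a linear genome into five regions), `hbv-like` (four ORFs
on a circular genome, one wrapping the origin, with +1 and +0 overlaps,
mirroring the geometry of small DNA viruses), and `dense` (two
full-length ORFs on opposite strands) — and `make_tree` builds random
rooted binary ultrametric trees by successive pair merges. These
fixtures exercise every structural feature (strands, wraps, overlaps,
circularity) but are not real genomes: they lack codon-usage bias,
realistic base composition, functional ORFs (start/stop triplets occur
only by chance) and realistic tree shapes. Passing tests therefore
demonstrate the correctness of the simulator's distributions and
bookkeeping, not that any particular parameterization matches a real
virus.

Problem sizes used by the heavier checks, chosen to give the statistics
adequate power: neutral-rate calibration uses 20 replicates of a 100 kb
non-coding genome (branch length 1, global rate 0.01, agreement within
3 standard errors); stationary recovery evolves a 100 kb neutral
sequence to depth 20 at global rate 1 toward π = (0.1, 0.2, 0.3, 0.4)
(χ², α = 10⁻³; the slowest HKY relaxation mode decays ~e⁻²⁰ by that
depth); sampling-distribution equivalence uses exhaustive weight
comparison on randomized ≤ 60 nt genomes with up to three overlapping
ORFs plus a 10⁶-draw multinomial test; and the entropy-ordering check
runs 20 replicates of the hbv-like layout (1200 nt, 30 tips, depth 1.5,
global rate 0.1, ω ~ gamma(1.5, 0.2) in four categories — strongly
purifying, mean 0.3), requiring non-coding > single-ORF > overlap mean
entropy in at least 18 of 20. The ordering is a qualitative prediction;
its numeric values depend on the random tree and are not targets.

## Open design choices made here

- External coordinates (YAML, GenBank, logs) are 1-based inclusive;
  internal coordinates 0-based half-open, converted only in `io_formats`.
  Circular-origin wraps are always two segments meeting at the origin
  (GenBank `join` semantics); strand is an explicit field, never encoded
  by coordinate order.
- Ambiguous nucleotides in the root sequence are rejected, not
  randomized: every site must have well-defined rates.
- The six-entry frame vector anchors frame labels to the forward frame
  at genome position 0; when more than two ORFs overlap, pairwise
  frameshift labels are classified independently and two ORFs sharing a
  label multiply into the same slot (the product entering the rate is
  unchanged). Pairwise classification never relies on a global frame
  assignment.
- Config parsing is strict — unknown keys fail fast — with silent
  defaults only for the documented globals (linearity, κ = 0.3,
  empirical π, constant μ).
- ORF-level μ specifications are applied as per-site multipliers on the
  global μ category, keeping the global distribution the single source
  of genome-wide rate heterogeneity.

## Known limitations

- No indels, recombination, or time/lineage-varying rates.
- Spliced ORFs beyond a single circular-origin wrap (more than two
  segments) are not supported; ORF discovery is out of scope (only
  user-supplied or GenBank-annotated coordinates are used).
- The genetic code defaults to the standard nuclear table; alternative
  tables can be substituted but are untested.
- Amino-acid entropy (M = 20) works structurally but the diagnostics are
  exercised only for nucleotides.
- The event tree favors correctness and incremental-update transparency
  over asymptotically optimal sampling; alias-method style O(1) samplers
  are intentionally out of scope.
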