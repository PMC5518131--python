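# Methods

This note records the models and procedures tandemscope implements, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical and design choices made where the design
was genuinely open.

## Coordinate conventions

All intervals are 0-based half-open internally. The nucmer `show-coords`
tabular dialect (1-based inclusive, orientation encoded as start > end)
exists only at the parser boundary; reverse-strand records are normalized
to forward intervals with a strand flag so interval arithmetic never sees
descending coordinates. A consequence: a 1 bp alignment cannot carry
orientation in the coords dialect, so strand round-trips are guaranteed
only for intervals of length ≥ 2.

## Tandem repeat detection (alignment-to-self)

A tandem pair is an off-diagonal local self-alignment surviving four
filters, applied to a canonicalized record set (same-sequence records
only, earlier-starting interval first, mirrors and exact duplicates
removed, diagonal dropped):

| parameter | default | meaning |
|---|---|---|
| `min_identity_pct` | 95 | minimum alignment identity (≥) |
| `max_midpoint_sep` | 1,000,000 bp | maximum separation of unit midpoints |
| `long_unit_threshold` | 2,000 bp | long/short split on unit length |
| `include_reverse_strand` | true | keep inverted-orientation pairs |

Decisions taken where the procedure is underdetermined:

- **Long/short split uses the minimum of the two unit lengths** — a pair
  counts as gene-scale only if both units are. The threshold itself is
  inclusive (unit ≥ 2 kb is long).
- **Inverted (reverse-strand) self-alignments are retained by default**
  because the filter list does not exclude them; a flag drops them, since
  published pair counts may or may not have included inversions.
- **Midpoints are integer floors** ((start + end) // 2) for determinism.
- **Duplicate interval pairs keep the higher identity.** Overlapping
  alignments describing the same repeat at different extents are all kept;
  no merging is attempted.

Detection is idempotent, order-invariant, and mirror-invariant (checked by
property tests).

## Repeat-capture classification

Given pairs on a reference and assembly-to-reference alignments, a unit's
coverage is |union of target intervals ∩ unit| / |unit| per scaffold.
Categories, with "covered" meaning coverage **strictly greater than** the
0.5 threshold:

1. `one_scaffold` — some scaffold covers both units (checked first; this
   is the stronger claim, and it deliberately lets one collapsed assembly
   copy capture several reference repeats);
2. `two_scaffolds` — otherwise, some scaffold covers unit 1 and a
   different one covers unit 2 (the two candidate sets are necessarily
   disjoint once case 1 fails);
3. `underrepresented` — either unit uncovered.

`single_alignment` is set when one alignment record alone covers > 50% of
each unit — the same coverage rule applied to a single record, since
"captured within a single alignment" is otherwise unquantified. When
several scaffolds qualify for `one_scaffold`, the largest summed coverage
wins, ties by lexicographic id. Strand is ignored in coverage. The
reciprocal assessment flips every alignment record and reuses the same
classifier; categories then read one/two *chromosomes*.

## Tandem gene clusters

Zero E-values are replaced by the smallest non-zero E-value in the input
(undefined, hence an error, if all are zero); self-hits are dropped;
reciprocal hits merge keeping the lower E-value. Edge weight defaults to
−log10(E-value): the transform preserves hit ordering and keeps weights
finite after the zero repair; a raw 1/E mode exists. Markov clustering is
implemented in-package: column-stochastic matrix with self-loops at the
column maximum, expansion (matrix squaring) alternating with inflation
(entrywise power 2.0, then column renormalization), entries < 1e-9 pruned
each iteration, convergence when the largest entry change is < 1e-6
(default cap 100 iterations; non-convergence warns and interprets the
current matrix). Clusters are read from attractor rows; a node reachable
from two attractor systems joins the cluster containing the smallest id,
and the output is always a partition (singletons allowed). MCL can refine,
never merge, connected components.

Tandem pairs: two co-clustered genes on the same scaffold with at most
`max_intervening` (default 1) non-TE genes strictly between them in start
order. TE-flagged genes never join pairs and never count as intervening.
Gene order is start-coordinate order; duplicate start positions on a
scaffold are an error rather than a silent tie-break. Tandem clusters are
the connected components of the pair graph.

## Copy number

**Depth route.** RPM is defined as reads × 10⁶ / (library_size ×
region_length). The published tables do not pin this normalization down
exactly, but the estimator is the ratio gene RPM / mean(control RPMs), in
which any common constant cancels — the ratio-invariance property is
tested. Reads count toward a region when they overlap it by ≥ 1 bp
(half-open intervals: touching does not overlap). Estimates are reported
to one decimal, matching the precision of the published table they
reproduce (25.5 / 11.5 / 22.5 / 26.2).

**qPCR route.** The standard-curve slope is the signed OLS slope of CT on
log2(dilution) over the series (1, 2, 4, 8, 16, 32), replicates pooled.
Each CT is corrected *multiplicatively* by its primer's slope — the
literal published formula, implemented as stated even though
efficiency-based ΔΔCT corrections are more common; with a signed slope
near +1 the correction behaves as intended, and the consequence of the
sign convention is that inverted standard curves (negative slope) would
flip the correction rather than be rescaled. Copies per plant are
2^(mean corrected reference CT − mean corrected target CT); the genotype
estimate is the arithmetic mean over plants and primer combinations. The
published qPCR estimates themselves are not recomputable because the raw
CTs behind them are not available, so only the formula's identities
(2⁰ = 1, 2³ = 8, hand-checked slope cases) and slope recovery on simulated
curves are asserted.

## Synthetic-mate scaffolding

Sampling: per insert class (defaults 10/40/160 kb, spread 10% of the
insert, normal jitter) and guide scaffold, floor(coverage × L / (2 ×
read_len)) innie pairs of 2000 bp reads at uniform positions; pairs
overhanging the scaffold and reads > 50% N are skipped. Defaults match
the upstream pipeline's stated invocation (up to 200-fold per insert
class, interpreted per class); the fold coverage is the target before
end-effects.

Mapping is by unique full-length exact match: a read is anchored by its
leading 31-mer and verified by exact string extension in both
orientations; zero or multiple full-length occurrences leave it unmapped.
This stands in for a short-read mapper under the generator's
substitution-free reads and is checked against a brute-force substring
search.

Link bundling: a placed mate on strand + exits its contig through the R
end, on strand − through the L end; pairs are grouped by the (contig end,
contig end) they join, the gap estimate is the median of insert −
tail_a − tail_b over the group, and groups with support < 2 are dropped.

**The greedy end-occupancy layout is this package's own construction** —
the upstream pipeline delegates scaffolding to an assembler whose
algorithm is unpublished, so only its inputs (links) and outputs
(layouts) are modeled. Links are processed in decreasing support (ties
broken lexicographically); a link is accepted iff both facing ends are
free and no cycle results (union-find); accepted joins form simple paths.
Emitted gaps are floored at 20 bp so that contig extraction at the 20-N
rule exactly inverts scaffold rendering.

QC: scaffolds with fewer than 15 read placements are removed (boundary:
14 removed, 15 retained); in survivors every position with coverage below
2× is deleted and maximal kept runs ≥ 200 bp are emitted with source
offsets in their ids. Coverage is computed by difference-array
accumulation.

## Synthetic data and what passing tests show

Planted genomes are i.i.d. uniform backgrounds with arrays written over
them: each array is `copies` mutated instances of a master unit
(substitutions only, at the spec'd divergence) separated by fresh random
spacers. Substitution-only mutation keeps pairwise identity exactly
computable (Hamming), so expected tandem pairs — every copy pair passing
the detection thresholds — are known in closed form. Two independently
mutated copies agree per base with probability (1−d)² + d²/3 ≈ 98% at
d = 0.01, which the generator tests verify empirically.

Self-alignments are emitted analytically (diagonal, all copy-vs-copy
records, all mirrors: 1 + 2·C(k,2) records per k-copy array), keeping the
tests hermetic; no aligner runs. Consequently the suite demonstrates
correctness of the *filtering and classification logic*, not robustness
to aligner artifacts (split alignments, indel-shifted boundaries, repeat
families below 95% identity); real nucmer/minimap2 output will add those
complications. Indels, diploidy, and read error models are out of scope.

Corrupted assemblies pair each operator with the alignment-emission
policy under which its expected category is the ground truth. A collapsed
array emits alignments from the retained copy to *every* reference copy
(all-matches semantics — exactly why collapsed repeats land in
`one_scaffold`); fragmented and unit-deleted assemblies emit true-origin
alignments only (best-per-position filtered semantics, under which a
deleted unit is genuinely uncovered). No single policy realizes all three
categories at once — with all-matches alignments a surviving ≥ 95%
paralog would always re-cover a deleted unit — and real evaluations face
the same dichotomy between unfiltered and best-per-position alignment
sets.

Long-read simulation is uniform-start placement at a target fold
coverage; mean realized coverage is within 5% of target for coverage ≥ 10
on sequences ≥ 100 read lengths.

## Study sizes used by the test suite and acceptance script

Chosen as desk-scale renditions of the study conditions:

- capture drill: 51 randomized planted genomes (unit 0.5–3 kb, 2–5
  copies, divergence ≤ 0.02), one corruption operator each, 100% category
  agreement required;
- scaffolding drill: 20 linear genomes of 5–20 contigs; contig lengths
  6–10 kb and gaps 0.5–5 kb so that every junction is spannable by
  construction — an innie pair can bridge a junction iff
  2·read_len ≤ insert − gap ≤ len_a + len_b, which with 10 kb ± 1 kb
  inserts and 2 kb reads bounds gaps below ~6 kb and requires adjacent
  contigs jointly longer than insert − gap; 30-fold mate coverage (the
  200-fold library default is unnecessary at these sizes); strict
  recovery up to global reversal is required wherever all junctions
  received links, and split instances must still contain only correct
  contiguous sub-paths;
- contig-extraction reconstruction on 1,000 random scaffolds; N50/NG50
  brute-force agreement on all length multisets up to size 6 from 1–10;
  exhaustive gene-order permutation checks up to 7 genes.

## Known limitations

- The alignment-driven detector only sees what the aligner reports; it
  performs no sequence-based periodicity search.
- The MCL attractor interpretation resolves overlapping attractor systems
  lexicographically; graphs with near-symmetric weak bridges can be
  sensitive to the inflation parameter near 2.0.
- The exact mapper is intended for the generator's error-free reads;
  reads with even one substitution go unmapped by design.
- Reference-scale censuses (tens of thousands of pairs on a real genome
  self-alignment) run through the same code path but are validated here
  only at desk scale.
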