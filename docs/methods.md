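# Methods

## Model and procedure

### Repeat discovery

The repeat scan is defined as a genome self-vs-self local-alignment
search with two filters: aligned length ≥ `min_repeat_len` (default 50 bp)
and pairwise identity strictly above `min_repeat_identity` (default 85%).
blastn (word size 11, dust off) nominates candidate pairs; each candidate
is then *polished* so that the reported coordinates are a property of the
genome, not of engine internals:

1. terminal alignment columns are trimmed until both ends are exact
   matches, and any terminal exact run shorter than 8 columns is trimmed
   together with its adjoining mismatch/gap block (recursively) — repeat
   boundaries are therefore always anchored by ≥ 8 bp of exact match, and
   chance match tails beyond a true boundary are excluded;
2. both copies are extended outward while bases match exactly;
3. the polished copies are re-aligned globally (edlib) and the pair is
   kept only if it still passes both filters.

Same-orientation candidates on the same alignment diagonal (within 10 bp)
whose copies overlap are merged and re-polished, so fragmented hits of one
underlying repeat collapse to the maximal pair; distinct diagonals are
never merged, which preserves the separate pairwise listings of
overlapping tandem families. Pairs are canonicalized (copy 1 starts first),
deduplicated under copy reordering and strand flip, and self-identical
intervals — including perfect palindromes that map onto themselves — are
excluded. On genomes with exact duplications this procedure reproduces the
brute-force enumeration of maximal repeated substring pairs exactly (a
test and the acceptance script verify this on 20 seeded 5-kb genomes).

Identity is matches / alignment columns with gaps counted as columns and
`N` never counted as a match, reported to 2 decimals. Size classes:
small [50, 100) bp, medium [100, 1000] bp, large > 1000 bp; both boundary
values fall in the medium class. The census's gross repeat length is the
union of all copy intervals, counting multiply-covered positions once.

### Conformation references and screening

For a pair with copies R1, R2, flanks of `flank_len` (default 1000 bp) are
taken around each copy: A–R1–B and C–R2–D. For inverted pairs the copy-2
locus is viewed on the opposite strand (rc(D)–rc(R2)–rc(C)) so the two
repeat units are collinear; every reference is then a contiguous plausible
molecule. The reference set is the {A,C} × {R1,R2} × {B,D} cross product
restricted to valid junction combinations: the two masters, plus 2
recombinant products when the copies are identical (a single
distinguishable unit R) or all 6 shuffles when identity < 100%. Masters
are emitted as forward-strand genome substrings. On circular genomes
flanks wrap around the origin; on linear genomes they truncate with a
warning, and building fails if a truncated flank drops below the required
read flank coverage.

Screening removes an alternative whose full sequence (recombinant
junction included) aligns to the genome on either strand at
`screen_identity` (default 95%) — this eliminates the A–R2–B style
shuffles of high-identity pairs, which differ from the genome only by the
repeat-internal variants, and any product already present in the
assembly. The threshold is a package decision exposed in the
configuration; the screening contract is simply "located in the genome".
Masters are never removed.

### Read support

A read supports a reference when the window [repeat start − 200 bp,
repeat end + 200 bp] of the reference aligns as one alignment inside the
read (either strand) at identity > `read_support_identity` (default 95%).
The single-alignment rule is deliberate: disjoint partial hits are never
chained, which is the stricter reading of "coverage in both flanking
regions". Alignment is edlib infix mode with a distance bound just above
the identity threshold's implied maximum, so non-qualifying references
fail fast. Each read is counted at most once per repeat pair: it is
assigned to the reference with the smallest alignment distance among
qualifying hits, ties breaking toward master and then lowest reference
index, which makes the active flag conservative. Percentages are rounded
half-up to 2 decimals. A repeat is recombinationally active when ≥ 1 read
supports an alternative; a read may count for several distinct repeat
pairs, which are analysed independently.

Best-reference assignment matters: for a large identical-copy repeat, an
error-free master read also exceeds 95% identity against the alternative
window (the repeat unit dominates the window), but its master alignment is
strictly better, so the tally is still correct.

### Gene orders

The dialect: `>`-prefixed organism lines; one chromosome per line of
whitespace-separated signed gene tokens (`-` prefix = minus strand); a
trailing `)` (standalone or suffixed to the last token) marks a circular
chromosome. The writer emits a standalone `)`, and parse→write→parse is
the identity on normalized input. Trans-spliced gene fragments that appear
as separate tokens are distinct ordered markers and are never merged.

DCJ distance follows the standard adjacency-graph construction: gene
extremities (tail/head), adjacencies between consecutive signed genes
(wrapping on circular chromosomes, telomeres on linear ones), and
d = N − (C + I/2) with C the cycles and I the odd paths (components with
an odd number of extremities). The model is fixed to unrestricted DCJ.
Because compared mitogenomes differ in gene content, both orders are
first restricted to genes present exactly once in each; dropped genes are
logged so the reduction is auditable. The test-side oracle is a
breadth-first search over all perfect matchings of gene extremities
(circular genome states); the formula is checked against it on *every*
state for n ≤ 6 (10,395 matchings).

Conserved clusters are maximal runs of ≥ 2 genes occurring contiguously,
with consistent relative orientation, in every organism; a run and its
signed reversal are one cluster, and a full circular chromosome is
canonicalized over rotations.

### Homology segments and matrix statistics

Homology hits (blastn, e-value ≤ `homology_evalue`, default 1e-6) that
overlap by ≥ 1 bp on the query are merged into maximal disjoint segments;
a merged segment reports its best constituent hit's identity and e-value.
Carried subject genes are annotated "(partial)" whenever the hit coverage
does not span the gene's full length. Spacer sharing is the length of the
intersection of segment query intervals with the spacer set. Whether a
published insertion count refers to raw or merged hits is not decidable
from the table layout alone; merging was chosen because the published
insertions are listed disjointly, so segment counts are an approximate
comparison surface.

A column is parsimony-informative iff ≥ 2 distinct unambiguous nucleotide
states each occur in ≥ 2 rows; gaps and IUPAC ambiguity codes (and any
non-ACGT character) are missing data, never states — the conventional
definition. Concatenation fills taxa absent from a gene with the missing
symbol and records 1-based column ranges per gene.

## Synthetic data: what it emulates, and what it does not

`generate_genome` plants repeat pairs into an i.i.d. background (uniform
by default; GC content configurable, e.g. 0.466 to mimic a magnoliid
mitogenome). Copy 2 is degraded to the target identity by substitutions
at distinct interior positions — interior, so the planted coordinates
remain the maximal extent of the repeat — and reverse-complemented for
inverted pairs. A 1200-bp margin keeps planted copies and their
conformation flanks from colliding; infeasible packings raise an error
naming the offending spec.

`recombination_products` applies one crossover at the copy boundaries:
inverted pair → one molecule with the intervening segment inverted
(length-preserving, involutory); direct pair on a circle → two
sub-circles whose lengths sum to the parent; direct pair on a linear
molecule → excised circle plus deletion remainder. Nested or overlapping
copies are rejected as ill-defined.

`simulate_reads` draws each read's source conformation from the mixture
weights, start uniform (wrapping on circles), strand uniform, length
lognormal (default mean 15,000 bp, sigma 0.5 — surveys of this kind
report only mean read lengths, of order 10–25 kb), and applies i.i.d.
errors split substitution:insertion:deletion = 2:1:1. Every read's
provenance is recorded in a truth sidecar, and identical seeds give
byte-identical outputs.

Uniform read starts on a ~100-kb genome rarely span a multi-kilobase
repeat plus flanks, so recovery experiments use `simulate_pair_reads`,
which constrains starts so every read covers one repeat copy (master
reads) or one recombinant junction (alternative reads) plus the required
flank coverage — the reads a support counter can actually use, analogous
to conditioning on the informative subset of a real read database.

Limitations of the generator: the error model is i.i.d., not a
nanopore-specific homopolymer model (sufficient to exercise the 95%
identity threshold; the surveys it mimics used error-corrected reads);
no chimeric reads, no coverage bias, constant base quality; backgrounds
are unstructured, so passing tests demonstrate correctness of the
detection arithmetic, not robustness to genome-wide repeat families or
context-dependent error.

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| `min_repeat_len` | 50 bp | smallest repeat unit reported |
| `min_repeat_identity` | 85% | strict lower bound on pair identity |
| `flank_len` | 1000 bp | context on each side of a repeat copy in references |
| `read_support_identity` | 95% | strict lower bound for a qualifying read alignment |
| `read_support_flank_cov` | 200 bp | required read coverage of each flank |
| `screen_identity` | 95% | alternative-vs-genome identity that triggers removal |
| `homology_evalue` | 1e-6 | blastn cutoff for homology annotation / mt-read extraction |
| `size_class_small_max` / `medium_max` | 100 / 1000 bp | size-class boundaries (both assigned to medium) |
| `scan_word_size` / `scan_evalue` | 11 / 1e-3 | blastn settings for the self-scan |

All are overridable via `PipelineConfig`, a `key = value` config file, or
CLI flags.

## Numerical conventions and degenerate inputs

Coordinates are 1-based inclusive at every interface. Sequence case is
normalized to uppercase on load; IUPAC ambiguity codes pass through but
never count as matches or as alignment-column states. Percentages round
half-up to 2 decimals; identity to 2 decimals. A genome shorter than two
minimum-length repeat copies yields an empty scan with a warning rather
than an error; an empty read database yields 0/0 counts with percentages
reported as NA; an empty feature list makes the whole genome one spacer.
Support-assignment ties go to master, then to the lowest reference index.

## Problem sizes used in tests and the acceptance script

Recovery experiments use 100-kb genomes with three planted repeats
(5 kb direct 100%, 2 kb inverted 99.5%, 300 bp direct 100%) and 400
spanning error-free reads per repeat per condition, across five seeds in
the test suite (two in the acceptance script); at n = 400 the 3-standard-
error band around a planted fraction of 0.5 is ±0.075. Scanner/oracle
equivalence uses twenty 5-kb genomes, small enough for the quadratic
enumeration oracle. DCJ is verified against BFS on the complete 6-gene
circular state space. These sizes were chosen so each check is decisive
at desk scale; genome-scale inputs (a ~1-Mb mitogenome with a multi-
gigabase read set) run through the same code paths via the CLI.

## Known limitations

- The repeat census depends on engine-level settings (word size, merge
  tolerance); counts on real genomes are approximate comparison surfaces,
  unlike the per-pair re-verification, which is engine-independent.
- Screening uses full-length infix alignment of the alternative against
  the genome; a local match covering only the junction but much less than
  the full reference would not trigger removal.
- Read support evaluates one alignment per read/reference; structural
  chimeras or reads spanning two recombination events are out of scope.
- DCJ is unrestricted; restricted models (e.g. inversion-only) can give
  larger distances on the same orders and are not implemented.
- Circular genomes are scanned for repeats in linearized form; a repeat
  copy spanning the origin would be missed by the scanner (conformation
  building and read simulation do handle the wrap).
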