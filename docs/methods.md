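# Methods

This note records the models implemented by `coregscan`, the defaults that
matter, the numerical choices, and what the synthetic fixtures do and do not
establish.

## Coordinates and promoter convention

All internal coordinates are 0-based half-open on the forward chromosome
strand.  GFF3 (1-based inclusive) and BED (0-based half-open) are converted
on read; a gene's TSS is the 5' end of its interval (`start` on +, `end − 1`
on −).  Transcript-isoform TSS selection is out of scope; the gene record's
5' end stands in for it.

A promoter region spans `upstream_len` (default 1500 nt) before the TSS and
`downstream_len` (default 500 nt) from the TSS into the gene, reported 5'→3'
on the coding strand.  Windows clipped by a chromosome edge are truncated and
flagged rather than rejected, since partial promoters are still scannable.

Sequence QC discards gapped sequences and sequences whose fraction of `N`
strictly exceeds `max_unknown_frac` (default 0.10) — "more than 10%" is read
literally, so a sequence at exactly the threshold is kept.  The fraction can
be assessed over the whole sequence or restricted to a sub-region (the
promoter part), since both usages occur in practice; the `region` parameter
exposes both readings.

## Distance phylogenies

Ortholog promoter sets are vetted with distance trees, not likelihood
methods: the purpose is annotation checking (does the set cluster the way
mammalian phylogeny says it should?), for which p-distance, JC69 and K2P
under complete deletion suffice.  Complete deletion removes every alignment
column containing `-` or `N` in any sequence before any distance is
computed.  JC69 is undefined at p ≥ 0.75 and K2P at its corresponding
saturation points; both raise errors naming the offending pair rather than
returning infinities.

Neighbor joining follows Saitou–Nei with the standard Q criterion; UPGMA uses
arithmetic-mean cluster distances.  Two choices make runs reproducible:

- all tie-breaks select the lowest-index pair (strictly-better comparisons
  with a 1e-12 guard), so equidistant inputs yield one deterministic
  topology;
- negative NJ branch lengths are clamped to zero with a warning, the common
  convention, so branch-length invariants stay testable.

Bootstrap resamples alignment columns with replacement per replicate
(default 100 replicates, the standard setting for this kind of vetting) and
attaches to each internal edge of the point-estimate tree the percentage of
replicates containing the same bipartition (clade, for rooted UPGMA trees).
No consensus tree is built; supports annotate the point estimate.  A
replicate whose columns all die under complete deletion is redrawn, with 100
retries before error.  An optional divergence filter drops taxa whose
distance to a named reference exceeds a threshold before the analysis; it is
off by default because no principled universal cutoff exists.

## PWM scoring

A PWM carries per-position base frequencies `f(i, b)` and a conservation
vector `Ci = (100/ln 4)(Σ_b f ln f + ln 4)` in [0, 100] (0 for a uniform
position, 100 for a single-base position), with `0·ln 0 ≡ 0`.  Matrix files
may also state `Ci` explicitly, in which case the stated vector is used.  The
*core* is the run of `core_length` (default 4) consecutive positions
maximizing total conservation, leftmost on ties.

A window scores `Σᵢ Ci·f(i,bᵢ) / Σᵢ Ci·max_b f(i,b)` over all positions
(matrix similarity) or core positions only (core similarity); the consensus
scores exactly 1 and zero-information positions cannot penalize.  An `N` in
the window contributes zero frequency.  A scan emits a hit wherever core
similarity ≥ `core_threshold` (default 0.75) **and** matrix similarity ≥
`matrix_threshold` (default 0.80); minus-strand windows are scored on the
reverse complement and reported in forward coordinates.  The defaults are
mid-stringency and deliberately global: per-matrix optimized thresholds
require a calibrated matrix library, which this package does not ship.
Mismatch allowances apply to IUPAC strings only; PWMs are controlled by the
two thresholds.

IUPAC matching uses the standard 15-letter code; `N` in a *sequence*
satisfies only the pattern symbol `N`, never a constrained class, so unknown
bases cannot fake a match.

## Framework discovery

Frameworks are mined Apriori-style from per-sequence hit lists: every
ordered motif pair co-occurring (downstream, non-overlapping, same strand by
default) in at least `quorum` sequences seeds a 2-element framework, and
seeds are extended rightward one element at a time up to `max_elements`
(default 6).  Support is anti-monotone under extension, so the search is
complete at the given quorum.

Gap consistency (gap = 3' end of one element to 5' start of the next; gap
length rather than start-to-start distance, because it is invariant to
element widths and makes the doubled-distance rule below well defined) is a
window rule: the observed gaps of the new adjacency must admit a window of
width ≤ 2·`gap_tolerance` (default 10 nt) covering instances from ≥ quorum
sequences.  The recorded `[dmin, dmax]` is the observed min/max inside the
best window, ranked by supporting sequences, then by observed instances
covered, then by smaller `dmin`.  The instance-count tie-break matters in
practice: stray background co-occurrences can otherwise anchor the window
away from the genuine, densely populated gap cluster.  When all observed
gaps fit one window, the rule reduces to plain observed min/max.

Only maximal frameworks are reported: a framework is dropped when its
element chain is a subsequence of another reported framework with equal
support.  Output order (element count descending, then element names) is
deterministic.

Converting a framework to a screenable model sets each allowed gap range to
`[0, distance_factor × g_ref]` with `distance_factor` = 2.0 by default,
where `g_ref` is the gap observed in the reference-sequence instance — twice
the reference promoter's spacing, the pipeline's default screening slack.

## Model screening

A model is an ordered chain of PWM/IUPAC elements with inclusive per-gap
ranges.  Scanning chains element hits left to right per orientation; the
minus orientation scans the reverse complement and reports forward
coordinates.  All maximal non-identical chains are reported without greedy
suppression, so downstream consumers see exact positions and can deduplicate
by span.  By default every element must match (`quorum_k = |elements|`); a
relaxed `quorum_k` allows skipped elements, in which case the gap across a
skipped element is unconstrained — the chain is only required to respect the
ranges between consecutively matched adjacent elements.  Mixed-strand
elements within one model are unsupported: models read 5'→3' on one strand.

Conservation across species is a per-species boolean (any promoter of the
species' ortholog set contains ≥ 1 model hit) with an overall pass at
`min_species`; empty species sets count as absent with a warning.

## Gene assignment

Model hits are found in clones (contigs) placed on a chromosome at
`[x, y)` with an orientation.  Four cases, keyed by the (model-in-clone,
clone-on-chromosome) signs, lift a hit at clone offset `a` to its
chromosomal anchor `a'` and TSS-search far bound `z` (window `W` = 2000 nt):

| case | model | clone | chromosomal strand | `a'`    | `z`      |
|------|-------|-------|--------------------|---------|----------|
| A    | +     | +     | +                  | `x + a` | `a' + W` |
| B    | −     | +     | −                  | `x + a` | `a' − W` |
| C    | −     | −     | +                  | `y − a` | `a' + W` |
| D    | +     | −     | −                  | `y − a` | `a' − W` |

The chromosomal strand is the product of the model and clone signs; the
mapping is an involution (offset `a` is recoverable exactly), which the test
suite checks over randomized placements.

Candidate genes are sought inside `[a', z]` only, which itself enforces
"directly downstream": a TSS behind the model's anchor is never evaluated.
Within the window three named filters decide retention:

- **orientation** — gene strand equals the hit's chromosomal strand;
- **tss_distance** — distance from the model's 3' end to the TSS, measured
  in the reading direction, at most `max_tss_distance` (default 500 nt,
  inclusive: the parameter defines the boundary);
- **overlap** — when the TSS falls inside the model span (negative
  distance), the overlap may be at most `max_overlap` (default 200 nt).

Every evaluated gene is returned with its filter booleans; hits in clones
with no genes nearby simply yield an empty candidate list rather than being
dropped, so "no gene found" is a visible outcome.  The 2000 nt window and
the 500 nt filter coexist deliberately: the window is the search region, the
filter the retention rule applied within it.

## Expression validation

Quantile normalization replaces each sample's rank-r value with the
across-sample mean of the r-th order statistics; ties receive the mean of
their ranks' reference values (implemented as linear interpolation on the
reference vector at average ranks).  The transform is idempotent and
preserves the grand mean; afterwards every sample shares one empirical
distribution.

The two-tissue comparison reports, per probe: tissue means, fold change
(target/reference; undefined-with-flag when the reference mean is zero),
log2 ratio, a two-sided Wilcoxon rank-sum p-value, and an over-expression
flag that is **inclusive** at `fold_threshold` (default 1.5 — "at least"
1.5-fold).  The flag follows fold change alone; p-values and
Benjamini–Hochberg FDR are reported alongside but do not gate the flag, so
statistical and magnitude criteria stay separable.  The Wilcoxon
implementation enumerates the exact null over rank assignments (midranks for
ties) when the pooled size is ≤ 12 and tie-free, else uses the tie-corrected
normal approximation with continuity correction; an all-tied comparison
returns p = 1.  Two-sided was chosen because over- and under-expression are
both of interest at this stage; the flag already encodes direction.

When a probe→gene map is supplied, the gene-level fold change is the average
of probe-level ratios, and the gene-level p-value comes from Wilcoxon on
per-sample means across the gene's probes.

## Synthetic fixtures

The generators produce the study conditions used throughout the tests:

- **Promoter sets**: i.i.d. background at a stated GC (default 0.5),
  2000 nt (the 1500+500 promoter convention), with model element sites (PWM
  consensus; degenerate IUPAC symbols sampled) inserted in order, gaps drawn
  uniformly within ± `gap_jitter` of the model's reference gaps, in a
  `plant_fraction` subset.  An order-0 background was chosen deliberately:
  the properties under test (recovery, negative controls) concern chain
  geometry, not compositional realism.
- **Toy genomes**: one chromosome per clone-orientation case, a clone at
  known `(x, y, strand)`, a planted model instance at a known clone offset,
  a target gene 300 nt downstream (inside the 500 nt default) and decoys
  violating exactly one filter each — wrong strand, TSS past 500 nt, overlap
  past 200 nt.  Overlap decoys require a model span above ~220 nt so only
  the overlap filter trips; the generator enforces this.
- **Expression matrices**: per-probe log-normal baselines rounded to a
  dyadic grid (so exact planted ratios such as the 1.5 boundary survive
  floating point in the noiseless limit), planted probes multiplied by their
  fold in the target tissue, log-scale Gaussian noise (default sd 0.1),
  10 samples per tissue by default.

Every generator is driven by one integer seed and is byte-reproducible; the
returned truth object fully determines the expected output of the stage
under test.  What passing these tests does *not* show: robustness to indels
and motif turnover in real promoter evolution, to correlated (array-batch)
noise in real expression data, or to compositional biases (CpG islands,
repeats) in real genomic background — the fixtures do not model those.

## Problem sizes

Test and demonstration runs use desk-scale inputs chosen to exercise every
code path: 6–10 promoters of 0.5–2 kb, 4–7 taxa with 200-column alignments
and 100 bootstrap replicates, 100-case scanner randomizations on ≤ 500 nt
sequences, four-chromosome toy genomes of 20 kb, and 200-probe × 20-sample
expression matrices.  All algorithms are polynomial in these quantities;
genome-scale screening is linear in sequence length per model element.

## Known limitations

- No p-value calibration of PWM similarity scores and no dinucleotide
  background model; thresholds are operational, not statistical.
- Framework discovery works on hit coordinates only; it does not use a
  multiple alignment to anchor positions, so columns of conserved elements
  must be rediscovered through gap consistency.
- The relaxed-quorum gap rule (unconstrained gaps across skipped elements)
  is one of several defensible readings of partial-match screening.
- Distance phylogenies only; no ML/Bayesian inference, no rate
  heterogeneity.
- Probe-set summarization, array preprocessing (CEL files) and probe
  annotation are out of scope; the expression stage starts from a
  probes × samples intensity table.
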