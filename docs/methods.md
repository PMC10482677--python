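# Methods

## The screen model

`trapscreen` analyses phenotype-sorted haploid gene-trap screens.  The
statistical object is, for every gene, the 2×2 table of unique *disruptive*
insertion counts in the two sorted tails:

|            | gene X | all other genes |
|------------|--------|-----------------|
| high tail  | a      | H − a           |
| low tail   | b      | L − b           |

A *disruptive* insertion is a unique site (deduplicated by chromosome,
position and cassette orientation) that lies inside a gene body **and** is
in the sense orientation (cassette strand = gene strand) **and** falls in
the 5′ UTR, an exon or an intron.  3′-UTR hits are annotated but never
disruptive; antisense and intergenic insertions are carried through all
files for diagnostics but enter neither the per-gene counts nor the totals
H and L.  When gene bodies overlap, one site may be disruptive for several
genes: it contributes to each gene's `a`/`b`, but only once to H/L so the
normalizer is not inflated; on disjoint models Σ a = H exactly, which the
tests assert.

The mutational index is the leave-one-out odds ratio
MI = (a/(H−a)) / (b/(L−b)).  Edge policy: a = 0 → MI = 0; b = 0 (or a = H)
with a > 0 → MI = +∞; a = b = 0 → undefined (NaN, excluded from plots).
Enrichment is tested with a two-sided Fisher's exact test on the same
table, using the minimum-likelihood definition (sum of hypergeometric
probabilities of all same-margin tables no more probable than the observed
one).  Terms are accumulated in log space (`hypergeom.logpmf` +
`logsumexp`), and the inclusion comparison carries a 1e−7 relative slack so
exact ties are never dropped by floating-point jitter.  The unit tests and
the acceptance script verify the implementation against full-support
enumeration in exact rational arithmetic (`math.comb` + `Fraction`), with
worst-case disagreement ≲1e−13 over thousands of random tables, and against
`scipy.stats.fisher_exact` as a second, independent cross-check.

Calls are strict: significant ⇔ P < α (a gene whose P equals α exactly is
not called).  Direction follows MI: significant with MI > 1 means
disruptions accumulate in the high tail, i.e. the gene normally *suppresses*
the phenotype ("negative regulator"); MI < 1 marks a positive regulator.
No multiple-testing correction is applied by default, matching the raw
P < 0.05 convention of single-pass sorted screens; Benjamini–Hochberg is
available behind `fdr=True`.

### log₂ MI and pseudocounts

The exact MI is kept 0/∞ at zero counts.  Only for log-scale displays
(fishtail plots) and screen comparisons is an optional Haldane-style
pseudocount offered: MI_h = ((a+0.5)/(H−a)) / ((b+0.5)/(L−b)), applied to
every gene when enabled and stamped into the output's metadata.  Fishtail
tables default to the Haldane policy (so every plotted gene is finite);
screen comparisons default to the exact policy (so clean ratios stay
exact).  log₂ MI is computed from integer cross-products
(a·(L−b))/((H−a)·b), which keeps power-of-two fixtures bit-exact.

### Comparing two screens

`compare_screens` joins two result tables on gene id and reports
Δlog₂ MI = log₂ MI₁ − log₂ MI₂ for every gene with at least
`min_insertions` (default 30) disruptive insertions (a+b) in *both*
screens; genes failing the filter are retained with `passes_filter = False`
and no delta.  The insertion filter counts disruptive insertions — the same
quantity the statistics use — which is this package's explicit reading of
"insertions per screen".

## Read mapping

Junction reads are placed by exact matching tolerating at most one
substitution (Hamming distance; no indels — gene-trap junction reads are
short and already LTR-trimmed, and the published practice is
mismatch-tolerant exact alignment).  The search uses the pigeonhole
principle: any placement with ≤1 mismatch matches one half of the read
exactly, so candidates come from exact substring search of both halves on
both strands and are verified by full Hamming distance; reads shorter than
8 bases fall back to a full scan.  The unique minimal-distance placement is
reported; ties at the minimum are discarded as ambiguous (conservative and
deterministic), and `N` never matches anything.  The reported position is
the 0-based coordinate of the *leftmost* base of the matched window on the
forward strand for both orientations, which makes the strand-mirroring
property exact: flipping the reference maps a hit at p to n − p − L with
the opposite orientation.  The contract — unique best placement within one
mismatch — is what the tests pin down (exhaustive agreement with a naive
all-positions scan on 100 kb genomes); an index-based matcher could replace
the search strategy without changing any test.

## The synthetic generator

The generator emulates the statistical structure of a genome-wide sorted
screen at desk scale.  Model and defaults:

- **Genome**: one chromosome, 400 kb of uniform random A/C/G/T; 100
  disjoint genes of 1.5–3 kb packed with random intergenic gaps.  Every
  gene has an explicit 5′ UTR (~10% of its length), 1–3 exons with
  intervening introns, and a 3′ UTR, so the disruptive-region rule is
  always exercised on both strands.
- **Mutagenesis**: one insertion per cell (true haploid gene-trap biology;
  multi-insertion cells are not modelled, keeping truth assignment
  unambiguous), uniform position, cassette orientation sense with
  probability 0.5.  `intergenic_fraction` optionally stratifies positions
  between genic and intergenic space; by default it is `None` and the
  intergenic fraction simply follows the genome layout, consistent with
  uniform integration.
- **Phenotype**: baseline 0, Gaussian noise SD 1 (arbitrary fluorescence
  units), plus the configured per-gene additive shift iff the cell's
  insertion is disruptive for that gene.  A Gaussian-additive model is the
  simplest one that produces tail enrichment proportional to effect size;
  real fluorescence distributions are heavier-tailed and the simulator
  makes no attempt to match instrument-specific gating.
- **Sorting**: cells ranked by phenotype; the top and bottom `tail_fraction`
  (default 5%) form the pools, from which `cells_sorted_per_tail` cells are
  drawn without replacement and collapsed to unique sites (presence/absence,
  not read-depth weighted — mirroring unique-mutation counting).
- **Scale**: defaults of 1.5 M cells and 70 k sorted per 5% tail yield
  ≈190 disruptive insertions per gene per population — the same per-gene
  order of magnitude as a real screen that recovers millions of unique
  sense insertions over ~20,000 genes, scaled down to a 100-gene genome so
  a full simulation runs in about a second.  The real recovery efficiency
  from sorted cells to unique mapped insertions is not asserted; it is a
  free parameter (`cells_sorted_per_tail`).
- **Reads**: one read per site, `read_length` 40, taken from the forward
  strand window starting at the site position (reverse-complemented for
  reverse-orientation sites, so mapping recovers site coordinates exactly);
  0/1/2 substitutions injected with configurable probabilities at distinct
  positions.  Read names encode the true site for round-trip oracles.  No
  PCR/duplication, indel or quality model is included.

Every stochastic operation takes an explicit seed, and a fixed seed gives
byte-identical FASTA/FASTQ/BED/TSV outputs.

What passing the simulation-based tests shows — and does not show: the
pipeline's bookkeeping, statistics and calibration are correct under the
generator's assumptions (independent single insertions, additive Gaussian
phenotype, unbiased recovery).  Real screens add insertion hotspots,
growth-rate selection, sorting impurity and sequencing artefacts that the
generator deliberately omits; results on real data inherit none of the
calibration guarantees demonstrated here.

## Calibration and power checks

With all gene effects zero, the per-gene Fisher call at α = 0.05 over
20 simulated screens × 100 genes (2,000 gene-replicates) must land inside
the 95% binomial band around 0.05 — at the default per-gene counts the
discrete test is close to its nominal level.  With planted ±8-SD effects,
the affected genes must be recovered (significant, correct direction,
≥30 insertions) in ≥90% of 100 seeded replicates; a positive-shift gene — a
suppressor whose mutants brighten the stain — must always be called
`enriched_high` / "negative regulator", fixing the direction convention.

## Calorimetry

RER = VCO₂/VO₂; glucose oxidation ((4.585·VCO₂) − (3.226·VO₂))·4; fat
oxidation ((1.695·VO₂) − (1.701·VCO₂))·9; all values divided by each
animal's lean mass.  The coefficients are applied exactly as printed on the
numeric columns; units ride along from input metadata as opaque labels.
Negative oxidation rates (possible at RER outside [0.707, 1.0]) are
reported and flagged, never clipped, so phase means stay unbiased.  At
RER = 1 the fat term is −0.054·V — a small negative residual of the
coefficient pair, asserted as a sanity property.  Fed/fasted/refed phases
come from an explicit schedule (half-open time windows), never inferred
from food-intake traces.

## Lipidomics postprocessing

Starting from an identified, internal-standard-scaled table, a species is
retained iff S/N > 5 **and** amount > 5 × matched blank, both strictly
("greater than" taken literally; a species at exactly the boundary is
rejected).  Blank matching is by an explicit pre-joined column, keeping the
rule testable.  mol% is computed over the species that survive filtering
(the denominator is the post-filter per-sample total, configurable), and
per-sample totals must return 100 within 1e−9.  Condition contrasts average
mol% per species within condition, outer-join the vocabularies, mark
species absent from one side, and report Δmol% and log₂ ratios; the ratio
pseudocount policy is shared with the screen statistics and stamped in the
output.

## Numerical and degenerate-input policy

- Fisher P for degenerate margins (H = 0, L = 0, or a+b ∈ {0, H+L}) is 1.
- `mutational_index` validates 0 ≤ a ≤ H, 0 ≤ b ≤ L and raises otherwise.
- Empty sorted tails, unsortable configurations and gene sets that cannot
  fit the genome raise configuration/simulation errors rather than
  degrading silently; the CLI maps configuration, input and stage errors to
  exit codes 2/3/4.
- Site deduplication keys are (chromosome, position, orientation) within a
  population; collapse is idempotent and order-independent.
- The pipeline writes a JSON manifest (config, seeds, SHA-256 digests,
  timings, policy stamps); `resume=True` skips stages whose outputs match
  their recorded digests.

## Known limitations

- Hamming-only mapping (no indels), single-end, no quality awareness.
- The simulator's phenotype model is Gaussian-additive with one insertion
  per cell; epistasis, hotspots and growth selection are out of scope.
- Calorimetry coefficients are used as printed without unit conversion.
- Raw MS identification (spectra interpretation, isotope correction,
  internal-standard quantification) is upstream of the lipidomics module.
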