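# Methods

## Distance model

Pairwise distances are computed from the transition proportion *P* and
transversion proportion *Q* of each sequence pair, tallied with
**pairwise deletion**: a site enters the comparison only when both
sequences carry a plain A, C, G or T. Gaps, `N` and IUPAC ambiguity
codes are treated as missing at that site — no fractional matching of
ambiguity codes is attempted, which is the simplest defensible rule and
mirrors how barcode portals treat such sites. The Kimura 2-parameter
distance is

d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q),

assuming equal base frequencies and one shared transition rate against
one shared transversion rate. When a log argument is non-positive the
pair is *saturated*: the estimate is reported as a flagged undefined
value, never as NaN or zero, so saturated pairs can never inflate an
apparent barcode gap. A pair with zero compared sites is a distinct
error condition (no data, rather than too much divergence); at the
matrix level both situations are recorded as undefined entries with a
warning. The uncorrected p-distance `(ts + tv)/n` is available as an
alternative model; K2P ≥ p-distance wherever both are defined, with
equality exactly at zero.

Distances are proportions internally; reports multiply by 100 and round
to two decimals (percent), retaining full precision in the distance
matrix file (six decimals of percent).

## Species summaries

* **Intraspecific summary** — mean and maximum over all within-species
  pairs. A species sampled once reports both as not available (`N/A`),
  not as zero: a singleton carries no information about intraspecific
  variation.
* **Nearest neighbour (NN)** — for each species, the minimum distance
  from any of its members to any member of another species, and that
  species' name. Ties are broken lexicographically by species name and
  logged; real datasets essentially never tie.
* **Overall NN summary** — min, arithmetic mean, max and SE over the
  per-species NN distances, with SE defined as the sample standard
  deviation (ddof = 1) divided by √k over the k species. How published
  NN tables compute their SE is generally unstated; this definition is
  fixed and documented here. For k = 1 the SE is reported as 0.
* **Threshold clustering** — single-linkage connected components over
  the graph linking pairs strictly below the threshold, labelled by the
  lexicographically smallest member id. The default threshold of 2% is
  the conventional barcode screening value and is always overridable.
  This is a transparent proxy for BIN-style OTU assignment, not a
  re-implementation of the proprietary RESL algorithm. Undefined
  distances make clustering ill-posed, so they raise unless the caller
  opts in to treating them as above-threshold.

## SNP filters and diagnostics

The diagnostic pipeline applies, in order: (1) keep tags genotyped in
every sample at every site (0% missing data); (2) keep tags with
exactly one variable site whose observed alleles number exactly two.
"Bi-allelic" is judged on the genotypes of the analysed samples, not on
declared-but-unobserved VCF ALT alleles (which are ignored and logged),
since the filter's purpose concerns the sample set at hand. Both
filters are idempotent and sample-order invariant.

A **fixed difference** is a site at which the union of alleles observed
in group 1 is disjoint from that of group 2, every sample genotyped. A
heterozygote carrying the other group's allele disqualifies the site —
the strictest reading of "fixed". Sites, not tags, are the unit of
diagnosis; after the single-SNP filter each retained tag contributes at
most one candidate. `find_fixed_differences` enforces that its input
passed both filters and raises otherwise, so skipping the prefilter is
an explicit, visible act.

A site is **parsimony-informative** when at least two distinct alleles
are each carried by at least two samples, where a sample carries every
allele present in its genotype. A private homozygote therefore does
*not* make its allele informative, even though it contributes two
copies; counting per copy instead would change the tally only for
alleles confined to a single sample, and the per-sample reading is the
one consistent with the classical haploid definition applied to
carriers. SNP density is SNPs per tag over the tags present in the
analysed matrix. **Observed heterozygosity** is, per sample,
heterozygous calls over called sites across all sites of all tags in
the matrix (invariant sites included when present). It is not the
model-based heterozygosity parameter that assembly pipelines such as
ipyrad estimate from read data, and the two are not directly
comparable; a sample with zero called sites is flagged unavailable
rather than reported as 0.

Genotype coordinates are 0-based half-open internally; VCF input/output
and all reports are 1-based. Missing genotypes are `./.` (VCF) or `NN`
(TSV dialect); any other malformed genotype cell is a parse error, not
missing data.

## Synthetic data

The barcode simulator evolves sequences under the exact K2P
continuous-time process: with transition/transversion rate ratio κ and
rates scaled so the branch length *d* is the expected number of
substitutions per site (α = κ/(κ+2), β = 1/(κ+2)), a site changes by a
transition with probability ¼ + ¼e^(−4βd) − ½e^(−2(α+β)d) and to each
transversion partner with probability ¼ − ¼e^(−4βd). Plugging the
resulting expected P and Q back into the estimator returns exactly *d*,
which is what the parameter-recovery tests exploit. The genealogy is a
**star tree**: one uniform-composition ancestor, species ancestors at
`d_inter/2`, specimens at `d_intra` from their ancestor, hence expected
divergences of `2·d_intra` within and `d_inter + 2·d_intra` between
species. Defaults (658 bp, `d_intra = 0.002`, `d_inter = 0.04`,
κ = 2) emulate a typical mitochondrial COI barcode study of closely
related congeners: intraspecific variation of a few tenths of a
percent, interspecific divergence of a few percent, and a moderate
mitochondrial transition bias. Barcode sequences are haploid — no
heterozygous base calls are ever generated.

The genotype simulator defaults to 13 samples in groups of 8 + 5 over
66 tags with 30 planted fixed differences, the scale of a small ddRAD
diagnosis. Planted tags carry a single fully genotyped bi-allelic site
with disjoint group alleles and are never given missing calls, so the
planted signal is invariant to the completeness filter. Background tags
carry 1–4 sites that may be invariant (20%), heterozygous
(`het_rate`, default 0.1 per call pattern), tri-allelic
(`triallelic_rate`, default 0.05) or missing (`missing_rate`, default
0); every background variable site has one allele anchored in both
groups so it can never masquerade as a fixed difference. A truth record
lists the planted coordinates, per-site provenance, the tags free of
injected missing calls, the single-bi-allelic tag set and per-sample
heterozygous-call counts, which is what the planted-recovery and
bookkeeping tests compare against.

All generators draw from a single seeded `numpy` generator per dataset
and iterate sites left to right, so outputs are byte-reproducible from
the seed across platforms.

### What the simulator does not model

No coalescent within species (every specimen is an independent draw
from its species ancestor), no recombination, indels, rate variation
across sites, base-composition bias, sequencing error or read-level
artefacts, and no linkage between tags. Passing tests on synthetic data
therefore demonstrate the *computations* are correct, not that real
data satisfy the model: real barcode data have genealogical structure
within species and alignment gaps, and real ddRAD matrices have
allele-dropout patterns correlated with depth. The pipelines make no
assumption that inputs came from the simulator.

## Numerical and design choices

* Undefined distances propagate as flags; every operation states
  whether it skips them (summaries, with a warning), raises
  (clustering, by default), or records them (matrix construction).
* Filters never reorder sites; all outputs are deterministic functions
  of their inputs, so re-running a pipeline reproduces files
  byte-for-byte.
* Report rounding: two decimals for percent distances, six for
  heterozygosity, two for read counts in millions; computations always
  use full precision and round only at the formatting boundary.
* Problem sizes used by the test suite and the acceptance script
  (658-site sequences, 200 simulation replicates per divergence, 100
  brute-force instances of ≤ 10 sequences, 50 planted-matrix seeds)
  are chosen to make Monte-Carlo errors small relative to the effects
  being checked while keeping a full run in the order of seconds.

## Known limitations

* The single-linkage threshold proxy can chain clusters through
  intermediate specimens in ways BIN assignment would not; it is a
  screening tool, not a replacement for the original algorithm.
* Only two-group diagnosis is supported; multi-group diagnosability
  and population-genetic statistics beyond observed heterozygosity are
  out of scope.
* Inputs must be pre-aligned (barcodes) and pre-assembled (genotypes);
  the package performs no alignment, read processing or tree inference.
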