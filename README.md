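# taxgap

Molecular species-delimitation computations for two-marker studies of
cryptic sister species: **DNA barcode-gap analysis** on aligned COI
barcodes and **diagnostic-SNP discovery** on ddRAD-style genotype
matrices, plus a synthetic-data generator that gives every statistic a
planted ground truth. It is aimed at taxonomists who want the distance
and SNP summaries behind a species split to be reproducible, scriptable
and testable rather than produced inside a web portal or a one-off
notebook.

## What it computes

**Barcode side.** For each pair of aligned sequences the transition
proportion *P* and transversion proportion *Q* are tallied over the
sites where both sequences carry a plain A/C/G/T (pairwise deletion of
gaps, N and IUPAC ambiguities). The Kimura 2-parameter distance is

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

with the uncorrected p-distance `(ts + tv)/n` available as an
alternative. Saturated pairs (non-positive log argument) are flagged
*undefined*, never silently zeroed. From the distance matrix the
package derives per-species mean and maximum intraspecific distance,
each species' nearest-neighbour (NN) species and NN distance (the
minimum interspecific distance to any other species), an overall NN
summary (min / mean / max / SE), and single-linkage clusters below a
distance threshold (default 2%) as a transparent stand-in for
BIN/OTU assignment. A barcode gap is present when every NN distance
exceeds every maximum intraspecific distance.

**Genotype side.** A samples × sites genotype matrix (unordered allele
pairs, sites grouped into ddRAD tags) is filtered to loci genotyped in
*every* sample (0% missing data) and then to tags carrying exactly one
bi-allelic SNP. The package counts SNPs and parsimony-informative sites
(PIS: at least two alleles each carried by at least two samples),
reports SNP density per locus, computes per-sample observed
heterozygosity, and returns the **fixed allelic differences**: sites
whose allele sets in the two species groups are disjoint, heterozygotes
counting both alleles. Those sites are the candidate species-diagnostic
SNPs.

**Simulator.** Barcode alignments are evolved under the exact K2P
substitution process on a star genealogy (one ancestor, species
ancestors at `d_inter/2`, specimens at `d_intra`), so the estimator can
be validated against the generative truth. Genotype matrices are built
with a controlled number of planted fixed differences alongside
non-diagnostic variable sites, heterozygous and tri-allelic calls,
invariant sites and missing data, with all planted coordinates recorded
in a truth file.

## Worked example

Simulate a two-species barcode dataset (10 + 10 specimens, 658 bp,
within-species branch length 0.002, between-ancestor divergence 0.04)
and run the barcode-gap pipeline:

```sh
taxgap simulate barcodes --out-prefix sim --seed 7
taxgap barcode-gap --fasta sim.fasta --species sim.species.tsv --out-prefix gap
```

which prints

```
species  n mean_intra max_intra nn_species nn_distance
   sp01 10       0.34      0.76       sp02        2.63
   sp02 10       0.46      0.92       sp01        2.63
NN distances (%): min 2.63 mean 2.63 max 2.63 SE 0.00
clusters: 2
```

Distances are percent K2P. Each species' maximum intraspecific distance
(0.76%, 0.92%) sits well below the NN distance (2.63%) — a clear
barcode gap — and single-linkage clustering at the default 2% threshold
recovers exactly one cluster per species. The expected values follow
from branch-length additivity on the star tree: ~0.4% within species
(2 × 0.002) and ~4.4% between (0.04 + 2 × 0.002); the NN *minimum* over
190 interspecific pairs naturally sits below that mean.

The genotype pipeline on a simulated 13-sample matrix (groups of 8 and
5, 66 tags, 30 planted fixed differences):

```sh
taxgap simulate genotypes --out-prefix sim --seed 7
taxgap snp-diag --vcf sim.vcf --groups sim.groups.tsv --out-prefix snp
```

prints

```
loci retained: 40  SNPs: 40  PIS: 40  SNP/locus: 1.00
fixed differences: 30
```

All 30 planted diagnostic sites are recovered, and no background site
leaks in. (With this seed, 40 of the 66 tags survive the
one-bi-allelic-SNP filter; each retained tag carries exactly one SNP by
construction of the filter, hence the density of 1.00.) Full outputs —
diagnostics TSV, counts JSON, per-sample heterozygosity, run report —
are written under the `--out-prefix`.

Published summary columns can be re-aggregated with
`taxgap summarize table.tsv --column heterozygosity` or
`taxgap.summarize_numeric_column` from Python.

## Layout

The implementation is one sectioned module, `src/taxgap/core.py`,
ordered the way the method runs (simulation → barcode metrics →
SNP diagnostics → file formats → pipelines), re-exported from
`taxgap`; the CLI in `taxgap/__main__.py` is a thin wrapper. The model
choices and their limitations are documented in `docs/methods.md`.
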