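# Methods

This note documents the models, parameter choices and numerical decisions
behind `meromix`, and what the synthetic tests do and do not demonstrate
about real data.

## Contig taxonomy voting

A contig's taxonomy is voted from its genes' reference lineages. The rules,
in order:

1. *Assignment gate.* The fraction of genes carrying any lineage must be at
   least 30% of **all** predicted genes on the contig (the unannotated ones
   count in the denominator). The threshold is inclusive (≥ 30%). Contigs
   with no genes, or failing the gate, are unassigned.
2. *Deepest-majority vote.* Candidate taxa are full lineage prefixes.
   Scanning from species toward domain, the first rank at which a unique
   taxon is carried by ≥ 2 genes and strictly more genes than any rival
   wins; the contig is assigned that prefix at that rank.
3. *Tie escalation.* A tie at a rank (two taxa with the same maximal count)
   re-votes one rank higher; a tie at domain leaves the contig unassigned.
   This is the conservative reading of "lowest rank available": a contig
   split between two congeneric genera is still confidently their shared
   family.
4. *Unopposed singleton.* A single assigned gene on a qualifying contig
   wins at its own lowest rank — "most of its genes" degenerates to 1-of-1.

`vote_fraction` is the winner's share of the contig's *assigned* genes.
The voter is a total function and is verified exhaustively against an
independent brute-force implementation on all gene multisets of size ≤ 6
over a three-lineage alphabet (210 cases).

OTU bins are keyed by (winning lineage, rank); bins at different ranks of
the same path are distinct OTUs. Alphanumeric placeholder labels (e.g.
`SW10`) get their parent rank's label prepended for readability. Contigs
with ≤ 2 genes stay in their bin for abundance but are excluded from the
per-bin functional subset.

## Abundance accounting

Coverage (length × read depth) is the weight throughout. The relative
abundance denominator is computed per metagenome over **all** contigs —
abundant OTUs, non-abundant OTUs folded into domain-level "Other" columns,
and the unassigned pool — which makes rows close to exactly 100 and values
comparable across metagenomes. Filter fractions are separate metagenomes
and never merged. The abundant-OTU rule is RA ≥ 1% (inclusive) in ≥ 1
metagenome, ordered by descending total abundance (summed coverage over all
samples). Peak relative abundance is a maximum over an explicit sample
scope (all samples, a season, a depth, a fraction); an empty scope is an
error rather than a silent NaN.

## KEGG profiling

KO abundance is contig-based: a contig's read depth counts once per KO it
carries, regardless of gene multiplicity (the annotation phrase "read depth
of contigs corresponding to predicted genes" is contig-level). Pathway
aggregation defaults to `sum`, with `mean` available per pathway definition
for panels better summarized by their average step. Normalization
multiplies each sample's rate (pathway abundance / summed depth of
KO-bearing contigs) by the dataset mean of those summed depths; with one
sample the factors cancel, and globally rescaling all read depths by *c*
rescales every normalized value by *c* (both tested).

Role disambiguation scores a query protein against labelled references with
local alignment: match +2, mismatch −1, gap open −0.5 (charged on the first
gapped position), gap extend −0.1, score only — fractional scores are kept
as-is. The scoring is delegated to `Bio.Align.PairwiseAligner` and verified
against a hand-written Gotoh dynamic program (which allows an insertion to
follow a deletion, each opening its own gap) exhaustively on short pairs.
Ties between roles resolve to the lexicographically first and are flagged.

## Viral linkage

Cluster abundance per time period (calendar month + year, e.g. "Dec. 2006")
sums member-contig read depths over **all** metagenomes of the period —
every depth and filter fraction pooled; whether to pool was left open by
the upstream protocol, and pooling is the simplest consistent choice. The
abundance flag requires total depth strictly above the threshold (default
4000) in at least one period. The threshold is a configuration value: it is
data-dependent in origin (a fraction of the dominant phototroph's maximum
read depth), so at other sequencing scales users should set it accordingly.

Spacer matching replaces e-value gates (database-size dependent, not
reproducible at desk scale) with two explicit thresholds that dominate for
20–60 bp queries: identity ≥ 97% (matches / aligned length) and alignment
fraction ≥ 0.97 (aligned length / spacer length). Candidate placements are
anchored by exact 12-mer seeds on both strands and extended ungapped; a
spacer shorter than the seed is an error. With ≤ 1 mismatch in a 32-mer a
12-mer seed always exists, so the seeded scan equals the exhaustive
all-offsets Hamming scan in the regime the thresholds admit (tested against
that oracle). Coordinates are 0-based half-open on the target's forward
strand.

Cluster expansion uses gapped local alignment (match 2 / mismatch −1 /
gap −1.5 per position), identity over aligned columns and alignment
fraction relative to the candidate; it is idempotent on a fixed candidate
set. Host assignment is deliberately unranked: every taxon whose spacers
hit a member is a candidate host.

## Community statistics

All resemblance work uses square-root-transformed percent abundances and
Bray-Curtis similarity on a 0–100 scale; dissimilarity is 100 − similarity.
SIMPER decomposes each pair's similarity (2·min terms) and dissimilarity
(|difference| terms) per taxon; the per-taxon terms sum exactly to the
pair's Bray-Curtis values (conservation identity, tested to 1e-9), and
contributions are averaged over within-group and between-group pairs
respectively. Groups with fewer than two samples are skipped with a
warning.

Simpson's index of diversity is 1 − Σp², computed by default over **all**
columns of a row including "Other" groups and the unassigned pool (whether
to restrict to abundant OTUs is exposed simply by slicing the row first).
A row not closing to 100 is an error.

The distance-based linear model embeds the dissimilarity matrix by
principal coordinates with additive (Lingoes) correction when negative
eigenvalues appear — Bray-Curtis is not generally Euclidean-embeddable and
the correction keeps the variance decomposition non-negative; the
correction is applied only when the smallest eigenvalue is materially
negative. The Gower-centered matrix *G* is projected through the hat matrix
of the (column-centered, z-scored) predictors; eigen-decomposition of
*HGH* yields the constrained axes, with per-axis percent of fitted
variation (eigenvalue / Σ eigenvalues) and of total variation
(eigenvalue / trace *G*). Variable selection is forward-only on adjusted
R², ties broken by column order; collinear predictors are rejected by
condition number (default 1e8) with the offending columns named. Samples
missing environmental values are dropped with a reported count.

## Synthetic lake generator

The generator emulates the statistical structure of a meromictic-lake
sampling campaign at the annotation level (no reads, no assembly):

* **Design** — 7 depth codes (U1–U3 oxic, I interface, L1–L3 anoxic) ×
  filter fractions (3.0, 0.8, 0.1 µm) × 8 mid-month dates covering summer,
  winter and spring; the lower zone is not sampled in winter (as in real
  campaigns, for safety reasons), giving 150 metagenomes.
* **Community** — ~20 cellular OTUs with depth niches and per-season target
  abundances: a dominant interface green sulfur bacterium whose targets are
  80% (summer) / 6% (winter) / 1% (spring); a photic-zone cyanobacterium
  with a spring bloom; a summer-only picoeukaryote; winter-responsive
  polysaccharide degraders; and lower-zone anaerobes (sulfate reducers,
  fermenters, a methanogen). Season responses are free scenario parameters,
  not inference targets.
* **Emission** — contig counts per OTU are uniform in a configured range,
  lengths log-normal (default µ = 8 log-bp ≈ 3 kb, σ = 0.6); read depths
  are scaled so each OTU's coverage share equals its target, then perturbed
  by multiplicative log-normal noise on depth only (default σ = 0.1) —
  lengths stay noiseless so composition targets are preserved in
  expectation. Genes are placed at 1 per kbp and carry the OTU lineage with
  probability `taxon_assignment_rate` (default 0.8, leaving a realistic
  annotation shortfall). The residual target share is emitted as an
  unassigned background whose genes carry no lineage (but may carry
  housekeeping KO terms, so every metagenome has KO-bearing contigs and the
  KEGG normalization is defined). Total coverage is 10⁶ per metagenome.
* **Viruses** — each virus has one genome (random sequence, 15–30 kb), is
  virion-partitioned (contigs only in the 0.1 µm fraction while hosts
  appear only in 0.8/3.0 µm), and a target Pearson coupling to its host:
  its share series is `coupling × standardized-host-share + independent
  noise`, mapped affinely around its mean share and clipped to a bounded
  band. Spacer-donor viruses contribute CRISPR spacers: uniform substrings
  of the genome (default 32 bp) mutated by independent per-base
  substitution; at rate 0.05 the mean identity is the binomial expectation
  95%, straddling the 97% matching gate.
* **Ground truth** — the truth table records *realized* (post-noise)
  coverage shares, so a noise-free run must be recovered exactly and any
  run can be checked against its own truth.
* **Environment** — daylength is a polar photoperiod sinusoid clipped to
  [0, 24] h; sunlight hours discount daylength by a seasonally varying
  cloudiness factor (correlated with daylength but not collinear); air
  temperature is a smooth seasonal sinusoid; salinity is a
  halocline-shaped sigmoid of depth (brackish mixolimnion, ~4.2% at the
  bottom) — deliberately nonlinear in depth so depth and salinity are
  jointly usable in the ordination.

Everything is driven by one `numpy` `SeedSequence`; identical scenario +
seed reproduce byte-identical outputs (tested through the CLI with sha256
manifests). Dedicated scenarios exist for specific analyses: a noise-free,
fully annotated variant (exact recovery), a 40-date interface series for
host–virus correlation estimation (coupling 0.9, noise σ = 0.05), and a
single-gradient Gaussian-niche community for ordination recovery.

**What the generator does not emulate:** read-level error, assembly
chimerism and fragmentation, strain-level lineage mixtures on one contig,
horizontally transferred genes with foreign lineages, uneven genome sizes
within an OTU, compositional coupling between fractions, and e-value
behaviour of real database searches. Passing tests therefore demonstrate
the correctness of the accounting, voting, matching and statistical
machinery on data with the assumed structure — not robustness to
annotation artefacts of real pipelines.

## Problem sizes

Default analyses run on the 150-metagenome scenario (~6,700 contigs,
~20,000 genes), the exhaustive voter oracle on 210 gene multisets, the
alignment oracle on all ≤ 4-mer pairs over a 3-letter alphabet plus seeded
random pairs up to length 10, spacer Monte-Carlo on 20 replicates × 40
spacers, and the ordination on 25–60 sample communities. These sizes were
chosen so the full suite and the acceptance script each complete in about a
minute while keeping Monte-Carlo standard errors well inside the asserted
tolerances.

## Known limitations

* The hierarchical tie-break (escalate one rank) and the per-rank prefix
  vote are one consistent interpretation of the voting rules; per-gene
  full-lineage voting would differ on contigs mixing assignment depths.
* OTU merging/splitting against curated genome bins (a manual step in real
  analyses) is out of scope; bins are exactly the voted (taxon, rank) keys.
* The dbRDA axes match the usual distLM conventions up to axis sign and
  the handling of negative eigenvalues; comparisons against other software
  should use the variance fractions, not raw scores.
* Cluster expansion computes full pairwise alignments and is intended for
  desk-scale contig sets, not millions of sequences.
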