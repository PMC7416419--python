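# meromix

Metagenome time-series analysis for permanently stratified (meromictic)
lakes: contig-level taxonomy by gene-lineage voting, coverage-weighted OTU
abundance accounting, KEGG functional profiling with cross-sample
normalization, viral-cluster abundance with CRISPR-spacer host linkage, and
the seasonal/depth community statistics (Bray-Curtis, SIMPER, Simpson
diversity, distLM/dbRDA).

It is aimed at microbial ecologists working with assembled, annotated
shotgun metagenomes sampled across depths, size-fractionation filters
(20–3, 3–0.8, 0.8–0.1 µm) and seasons — the kind of design used for polar
lake time series, where a dense layer of green sulfur bacteria at the
oxic/anoxic interface collapses and rebounds with the polar light cycle.
Because such datasets are large and access-controlled, the package ships a
first-class synthetic generator that emits the same annotation tables with
known ground truth, so every stage is testable end to end.

## The model

**Contig taxonomy.** Each contig inherits a taxonomy from its genes'
reference lineages: (a) at least 30% of the contig's genes must carry any
assignment, else the contig is *unassigned*; (b) the winner is the taxon
held by the most genes, voted at the deepest rank where ≥ 2 assigned genes
agree, with ties escalating one rank up (species → … → domain); (c) with no
unique winner at any rank the contig is unassigned. Contigs sharing a
winning taxon are binned as OTUs at that lowest available rank.

**Abundance.** The relative abundance of OTU *O* in metagenome *m* is

```
RA(O, m) = Σ_{i∈O} (L_i · d_i) / Σ_{j∈m} (L_j · d_j) × 100
```

where `L_i` is contig length and `d_i` its mean read depth; the denominator
spans **all** contigs of the metagenome (abundant OTUs, the low-abundance
remainder grouped as *Other Bacteria/Archaea/Eukarya/Viruses*, and the
unassigned pool), so rows close to 100% and values are comparable across
metagenomes. OTUs reaching ≥ 1% in at least one metagenome are *abundant*.

**Functional potential.** The abundance of a KO term is the summed read
depth of the contigs carrying it (once per contig); pathway abundances are
normalized as

```
[Σ_{KO∈pathway} abundance_KO / ReadDepth_cont(m)] × [Σ_m ReadDepth_cont(m) / N]
```

with `ReadDepth_cont` the per-metagenome summed depth of KO-bearing contigs
and `N` the number of metagenomes. Functionally ambiguous enzyme families
(redox partners, homologs) are disambiguated by local protein alignment
(match +2, mismatch −1, gap open −0.5, gap extend −0.1, score only).

**Viruses.** Pre-clustered viral contigs are summed per time period
(e.g. "Dec. 2006"); a cluster with total read depth strictly above 4000 in
some period is *abundant*. CRISPR spacers are matched to contigs by exact
12-mer seeding plus ungapped extension on both strands, gated at ≥ 97%
identity and ≥ 0.97 alignment fraction; spacer origins give each cluster
its candidate hosts, and host–virus coupling is measured by Pearson
correlation of marker read-depth series.

**Community statistics.** Relative abundances are square-root transformed;
Bray-Curtis similarity (0–100) drives SIMPER decomposition (within-season
similarity, between-season dissimilarity, per-taxon contributions) and a
distance-based linear model: principal coordinates of the dissimilarity
matrix (Lingoes-corrected) are regressed on z-scored environmental
variables (depth, salinity, daylength, sunlight hours, air temperature)
with forward selection on adjusted R², reporting per-axis percent of fitted
and total variation.

## Worked example

```python
from meromix.synthetic_lake import default_scenario, simulate
from meromix.contig_taxonomy import assign_contig_taxonomy, bin_otus
from meromix.abundance import abundance_table, peak_relative_abundance

scenario = default_scenario(seed=1)           # 7 depths x 3 fractions x 8 dates
result = simulate(scenario)
assignments = [assign_contig_taxonomy(c)
               for s in result.samples for c in s.contigs]
bins, unassigned = bin_otus(assignments)
table = abundance_table(result.samples, bins)
print(f"{len(result.samples)} metagenomes, {len(bins)} OTU bins")
season = {s.sample_id: s.meta.season for s in result.samples}
for name in ("summer", "winter", "spring"):
    scope = [sid for sid in table.index if season[sid] == name]
    peak = peak_relative_abundance(table, scope)["Chlorobium"]
    print(f"Chlorobium peak relative abundance, {name}: {peak:.1f}%")
```

prints

```
150 metagenomes, 24 OTU bins
Chlorobium peak relative abundance, summer: 80.3%
Chlorobium peak relative abundance, winter: 6.4%
Chlorobium peak relative abundance, spring: 1.1%
```

The interface phototroph's planted seasonal collapse (dominant in summer, a
few percent in winter, ~1% in spring) is recovered through the full
taxonomy-vote → OTU-bin → coverage-accounting chain, within sampling noise.

The same flow is available from the shell:

```
meromix run-all --seed 1 --out results/
```

which chains simulate → classify-contigs → abundance → kegg-profile →
viral → ecology and writes `manifest.json` with per-stage row counts and a
sha256 checksum of every output (reruns with the same seed are
byte-identical).

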