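# wetviro

Quantifying soil virus dynamics after wet-up (the first rewetting of
seasonally dry soil) from tabular read-mapping evidence. The package
implements the full analysis chain downstream of assembly and mapping:

- **catalog** — vOTU set construction: multi-tool consensus viral
  prediction filter (≥2 predictors, circular or ≥10 kb), single-linkage
  dereplication over a precomputed ANI/breadth pair table (95% ANI, 85%
  breadth, longest member as representative), and the integrase ×
  circularity partition.
- **abundance** — relative abundance (mapped / total sample reads),
  breadth-based presence calls (80% per virome sample; 50% in all three
  replicate tubes for SIP fractions), richness and viral-biomass
  trajectories with OLS trends, Bray-Curtis dissimilarity + PCoA, and
  flag-based abundance aggregation.
- **response** — classification of persistent vOTUs (≥3 time points in a
  plot) into five temporal response categories (early / late /
  ubiquitous / zero_and_168 / other) plus per-category host composition.
- **hosts** — CRISPR spacer-hit filtering (≤1 mismatch, no gaps, full
  spacer length) and consensus host taxonomy via deepest-common-rank
  resolution of multi-source predictions.
- **qsip** — quantitative stable isotope probing: DNA-weighted mean
  buoyant density per genome and tube, the GC → molar-mass → atom
  fraction excess (APE) chain, percentile bootstrap over replicate tubes
  with the negative-CI exclusion rule, and lineage-level activity
  summaries.
- **mortality** — virion counts from viral DNA mass and mean genome
  length, 16S-loss → cells-died conversion, percent viral contribution
  to microbial mortality across a burst-size grid (per-time and
  cumulative), and the genome-length sensitivity analysis (exact 1/N →
  log-log slope −1).
- **lysogeny** — cross-mapping candidate detection, alignment-based
  lysogen candidacy (identity > 90%, e-value ≤ 1e-100, ≥10 kb aligned,
  >10 kb flanking), prophage activity by differential coverage, and the
  integrase-enrichment chi-square test.
- **synth** — a seeded synthetic-scenario generator emitting every input
  table with a truth ledger (planted response categories, host links,
  APE values, lysogens), used throughout the test suite.

Note on the mortality model: cells lysed are computed as virions
*divided by* burst size — each lysis event releases `burst_size`
virions, so a fixed virion pool implies fewer lysed cells at larger
burst sizes, and the contribution is largest at burst size 1.

## Command-line usage

```sh
# generate a synthetic scenario as a directory of TSVs
wetviro simulate --seed 5 --n-votus 200 --n-mags 30 --out scenario/

# richness from virome mapping records
wetviro abundance --mapping scenario/virome_mapping.tsv --assay virome --out richness.tsv

# response-category classification
wetviro classify --mapping scenario/virome_mapping.tsv --drop-frac 0.1 --out categories.tsv

# bootstrap APE estimates from density-fraction tables
wetviro qsip --fractions scenario/fraction_records.tsv \
             --abundance scenario/fraction_abundance.tsv \
             --n-boot 1000 --ci 0.90 --seed 7 --out ape.tsv

# mortality model across burst sizes
wetviro mortality --inputs mortality_inputs.tsv --bursts 1,10,25,50,100,200 --out contrib.tsv
```

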