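# sibmap

Linkage mapping and genome characterization for full-sib outcross (F1)
populations, with a truth-annotated meiosis simulator so the whole chain is
testable without external data.

The pipeline covers:

- **synthdata** — population simulator: Poisson chiasma meioses with a 2-of-4
  chromatid rule (no chromatid interference), optional pericentromeric
  crossover suppression, sex-specific crossover rate scales, finite paternal
  tetrad pools (pollen shed as intact tetrads), viability-selection loci, and
  missing/error noise applied only to observed tables. Ground truth (maps,
  phased gametes, crossover positions, centromeres, tetrad ids) is recorded.
- **pipeline_io** — CP genotype TSV (codes `lm×ll`, `nn×np`, `hk×hk`, `ef×eg`,
  `ab×cd`, missing `--`), map TSV (`lg/marker/cm/bin`), phased-matrix TSV,
  pedigree CSV, read-only VCF/HapMap-like convenience, and a minimal VCF
  export. Writers are byte-exact inverses of readers on their own output.
- **markerprep** — segregation-type classification from parental genotypes and
  the pre-mapping filters: missing fraction > 20%, MAF < 10% (progeny allele
  counts), extreme segregation distortion (χ² P < 1e-5).
- **linkmap** — pseudo-testcross two-point r̂/LOD (phase resolved per pair),
  LOD > 5 grouping, SARF marker ordering (MST seriation + 2-opt + tie polish),
  Kosambi distances by windowed weighted regression, and iterative
  nearest-neighbor cleaning (fit > 2 cM, stress > 0.035, stress-cM > 3.5).
- **phaseimpute** — global phase assignment along the map, linkage-informed
  imputation from flanking markers (posterior ≥ 0.95), `hk×hk` parental-origin
  resolution, and splitting of biparental markers into uniparental `_m`/`_p`
  markers.
- **binmap** — singleton/error detection on phased data, cosegregation bins
  (missing entries wildcard-match), per-progeny recombination-event counts,
  and `correct_table` to feed an error-corrected table into a second mapping
  round.
- **mergemap** — composite map by linear programming on marker intervals
  (L1 objective, order constraints, minimum-weight cycle resolution), with the
  maximum interval size k swept 1..10 and chosen by per-component RMSE.
- **genomechar** — χ² (1 df, allele-level 1:1) distortion scan and SDR calling,
  bidirectional RF_M profiles and centromere spans (curve intersection out to
  the first markers with RF_M ≥ 0.45), Spearman map collinearity, paired
  maternal-vs-paternal recombination comparison, and recursive pedigree
  kinship.

## CLI

```sh
sibmap simulate --seed 1 --config cfg.yaml --out-prefix out/sim
sibmap filter out/sim.genotypes.tsv --max-missing 0.2 --min-maf 0.1 \
    --sd-alpha 1e-5 --out out/filtered.tsv
sibmap map out/filtered.tsv --parent maternal --lod-threshold 5 --out out/mat.map.tsv
sibmap phase out/filtered.tsv out/mat.map.tsv --parent maternal --out-prefix out/mat
sibmap bin out/mat.LG*.phases.tsv --out out/bins.tsv --counts-out out/counts.tsv
sibmap merge map1.tsv map2.tsv ... --k-max 10 --out out/composite.tsv
sibmap characterize out/filtered.tsv out/mat.map.tsv --parent maternal \
    --sd-alpha 0.1 --rf-threshold 0.45 --out out/char.json
sibmap report out/composite.tsv --characterize-json out/char.json --out out/report.json
```

Each subcommand accepts `--help`; `simulate` reads simulator settings from a
YAML file mirroring `synthdata.SimConfig`.

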