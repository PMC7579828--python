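# File formats

All files are plain text. Internal genomic coordinates are 1-based,
closed; BED input is converted on ingest.

## Pedigree CSV
Columns `animal,sire,dam` (+ optional metadata such as `sex`,
`generation`, `birth_year`). Missing parent: empty, `0`, `NA` or `.`.
Readers topologically sort and reject duplicates and cycles.

## Phenotype CSV
One hair shedding score per row: `animal_id, score` (1–5, fractional
allowed after same-day averaging), `date, year, farm_id, calving_season`
(spring/fall/empty), `fescue_status` (yes/no/empty), `sex, birth_date,
age_days`. After preparation a `cg_id` column holds the six-part
contemporary-group key `farm/year/season/status/agegroup/scoregroup`.

## Genotypes
* **PLINK `.raw`** — header `FID IID PAT MAT SEX PHENOTYPE` then one
  `<snp>_<allele>` column per marker with allele counts 0/1/2 or `NA`.
  Chromosome/position come from the sidecar `snp_map.tsv`
  (`snp, chrom, pos, a1, a2`).
* **VCF** — plain-text VCF with GT; `0/1`, `1/0` and `0|1` all count 1,
  `./.` is missing.

## Annotations
BED (0-based half-open, ≥4 columns) or GFF3 (`gene` features only;
`ID=` attribute names the gene). Unified to
`gene_id, chrom, start, end, strand`.

## Outputs
* `ebv.tsv` — `animal, ebv, se, pev, reliability`.
* `variance_components.tsv` — `component, estimate, se`.
* `lr_iterations.tsv` / `lr_summary.tsv` — per-iteration `d/b/rho` for
  validation and reference sets, and their mean/min/max.
* `gwas.tsv` — `snp, chrom, pos, beta, se, p, q`; `gene_hits.tsv` —
  `snp, gene_id, distance`.
* `removal_log.tsv` — every dropped record with one `reason` code.
* Relationship matrices persist as indexed upper-triangle TSV
  (`row, col, value`) via `write_matrix_tsv`, or as a sparse `.npz`
  cache in pipeline runs.
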