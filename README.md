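# hyperlpa

Tools for studying familial hyperlipoprotein(a)emia — pedigrees in which a
single over-expressing *LPA* allele drives extreme plasma Lp(a) and, through
it, a large share of the inherited coronary artery disease (CAD) risk.

Lp(a) concentration is controlled almost entirely by the *LPA* locus on
chromosome 6q26-27: the kringle-IV type 2 (KIV-2) copy-number repeat sets
apo(a) isoform size (shorter isoforms → higher Lp(a)), and rare SNP
haplotypes (rs3798220, rs186696265, rs140570886, the KIV-2 splice variant
4925G>A) shift expression beyond what isoform size predicts. The package
implements, as a tested and reusable pipeline, the analyses such a family
study needs:

* **`hyperlpa.sim`** — a synthetic-data generator: Mendelian gene dropping of
  *LPA* haplotypes through a packaged 22-member, three-generation pedigree in
  which a 21-KIV allele carrying the three rare Lp(a)-raising SNPs segregates
  with Lp(a) > 150 nmol/L; phenotype simulation (size-dependent Lp(a),
  oxidized phospholipids per particle, LDL-C, liability-threshold CAD); and a
  Hardy–Weinberg reference cohort. Emits VCF / PED / BED / TSV fixtures.
* **`hyperlpa.scoring`** — a polygenic score engine: S = Σᵢ wᵢ·dᵢ over
  effect-allele dosages, with allele re-orientation, missing-data policies and
  *locus ablation* (excluding every weight row in a genomic interval, e.g.
  the broader *LPA* region chr6:159,991,850–161,753,083, so that
  S_full = S_ablated + S_interval exactly).
* **`hyperlpa.percentiles`** — empirical mid-rank percentile placement of
  scores against a reference cohort, with 95th/97.5th-percentile flags and
  paired full-vs-ablated reports (the ablated reference is recomputed under
  the same exclusion).
* **`hyperlpa.segregation`** — family-based exome variant prioritization:
  depth filter (default ≥ 4×), exon-proximity filter (±50 bp), and a
  dominant-model segregation test with configurable phenocopy and
  homozygous-carrier tolerances.
* **`hyperlpa.phenomodels`** — Lp(a) threshold classification (> 125 nmol/L
  clinical; > 150 / ≤ 90 nmol/L family phenotypes), LDL-C corrected for
  Lp(a)-cholesterol (30% of Lp(a) mass), rank-based inverse-normal transform
  (Blom offsets), nested variance-explained OLS models, and Welch's t test.
* **`hyperlpa.io` / `hyperlpa.pipeline` / `hyperlpa.cli`** — VCF/PED/BED/GFF3
  readers and writers, a validated YAML run configuration, and the `hyperlpa`
  command line (`simulate`, `score`, `percentile`, `segregate`, `models`,
  `compare`, `run`).

## Worked example

Generate the synthetic study, score the family against the reference cohort
and place each member in the reference distribution:

```python
from hyperlpa import io, percentiles, scoring, sim

sim.write_fixtures("demo", seed=1)
family, fam_ids = io.read_vcf("demo/family.vcf")
reference, ref_ids = io.read_vcf("demo/reference.vcf")
weights = scoring.read_score_file("demo/lpa_weights.tsv")   # 48-SNP Lp(a) score

fam = scoring.compute_grs(family, weights, samples=fam_ids)
ref = scoring.compute_grs(reference, weights, samples=ref_ids)
print(percentiles.reports_table(
    percentiles.build_reports(fam, [r.score for r in ref])).round(1))
```

```
           score  percentile  flag_95  flag_975
sample_id
II-A2      397.9       100.0     True      True
II-C1       93.7        93.4    False     False
III-B3      32.0        55.5    False     False
III-C3      54.1        78.0    False     False
III-C4     437.6       100.0     True      True
...
```

Every carrier of the 21-KIV allele sits above the 97.5th percentile of the
reference; III-C3 — high Lp(a) through the 15-KIV allele inherited from the
spouse II-C1, not the 21-KIV allele — stays low; II-C1 himself is close to
but below the 95th band. The dominant-model exome scan on the 13-member
sequenced subset recovers the planted causal variant uniquely:

```sh
$ hyperlpa segregate --vcf demo/family.vcf --ped demo/family.ped \
      --exons demo/exons.bed \
      --samples II-A2,II-B1,II-C2,II-D1,II-E2,III-A3,III-B1,III-C1,III-C4,II-A1,II-B2,II-D2,III-B3 \
      --out candidates.tsv
stage=depth in=117 out=114 dropped=3
stage=exon_proximity in=114 out=20 dropped=94
stage=segregation in=20 out=1 dropped=19
wrote candidates.tsv (1 candidates)
```

The single survivor is the exonic rs3798220 carried on the 21-KIV
haplotype. The full pipeline (`hyperlpa run --config cfg.yaml`) additionally
writes CAD scores with and without the *LPA* interval — the family's
97.5th-percentile CAD flags clear once the locus is ablated — plus the
variance-explained models and the oxPL/Lp(a) group comparison.

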