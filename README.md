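# sexsignal

Detection of genetic sex-determination systems — male heterogamety
(XX/XY), female heterogamety (ZZ/ZW), or no detectable genetic signal —
from population genomic data, for researchers studying sex-chromosome
evolution in non-model organisms (fishes in particular, where sex
chromosomes are often young and barely differentiated).

The package combines four lines of evidence, each usable on its own:

1. **Carrier association** (`sexassoc`): given per-individual
   presence/absence of a candidate master sex-determining sequence
   (e.g. a male-limited *amh* duplicate), test sex linkage with the
   Yates-corrected chi-square on the 2×2 table

   χ² = n·(max(|ad−bc| − n/2, 0))² / ((a+b)(c+d)(a+c)(b+d)),  df = 1.

2. **RAD presence/absence markers** (`radmarkers`): exact-sequence
   marker depth table, marker-by-sex tile distribution with
   Bonferroni-corrected per-tile chi-square tests (presence = depth ≥ 10),
   and a sex-locus size yardstick n_markers / (2 × cut-sites-per-Mb).

3. **Pooled sequencing** (`poolsig`): per-site classification of
   male-/female-specific SNPs (heterozygous-like at 0.5 ± 0.15 in one
   pool, fixed at ≥ 0.95 in the other), Nei FST between pools, 50 kb
   window scans, and detection of hemizygous Y/W-specific regions as
   1 kb windows with <3 female reads/kb and male relative depth in
   [0.4, 0.6].

4. **Sex-biased k-mers** (`kmersex`): canonical 31-mer counts per sex
   pool; k-mers >25× in one sex and <5× in the other are sex-specific,
   and a strong excess on one side calls the heterogametic sex.

`sdcall` integrates evidence into one report (any unopposed significant
directed line → call; conflicts → UNDETERMINED, never auto-resolved),
and `simpop` simulates XY/ZW/no-GSD populations — reference, planted
sex locus (hemizygous insertion or X/Y SNP divergence), RAD reads,
pooled pileups, k-mer tables, configurable sex-reversal rate — so the
whole pipeline is testable against planted truth without external data.
See `docs/methods.md` for models, conventions and limitations.

## Worked example

Association between male phenotype and marker presence, from the 2×2
counts (21 of 23 males carriers, 0 of 22 females):

```
$ sexsignal assoc --counts 21,2,0,22
a       b       c       d       chi2    p       degenerate
21      2       0       22      34.08   5.28e-09        0
```

The marker is sex linked (p ≈ 5.3×10⁻⁹): strong evidence for an XX/XY
system with the candidate on the Y. Heterogamety from sex-specific
k-mer counts (23,816 male-specific vs 1,081,792 female-specific):

```
$ sexsignal kmer call --n-male 23816 --n-female 1081792
ZW      ratio=45.4
```

A 45-fold female excess means females carry sequence males lack — a
ZZ/ZW system. Full pipeline on a simulated XY population (300 kb
genome, 30 kb Y-specific insertion, 12 males + 12 females, 30× depth):

```yaml
# scenario.yaml
seed: 5
simulate:
  system: XY_INSERTION
  chrom_length: 300000
  locus: {chrom: chr1, start: 150000, length: 30000}
  n_males: 12
  n_females: 12
  rad_depth: 30
  pool_depth: 30
analyses: [rad, pool, kmer]
```

```
$ sexsignal run scenario.yaml --outdir out
```

The JSON report calls `XY` with a locus-size estimate of 0.15 Mb
("small") from these evidence lines:

```
rad_markers    n_significant_male_markers    5    M  significant
rad_markers    n_significant_female_markers  0    F  -
pool_coverage  y_specific_windows            30   M  significant
pool_coverage  w_specific_windows            0    F  -
kmers          sex_specific_kmer_ratio       >10  M  significant
```

Five RAD markers are male-limited, thirty 1 kb windows show the
half-coverage male / zero-coverage female signature of a hemizygous Y
region, and all sex-specific k-mers are male-specific — three unopposed
male-directed lines, hence XX/XY. `out/` also contains the marker
table, tile distribution, window scan TSVs and the Y-specific BED.

The same machinery is exposed as library functions
(`sexsignal.sexassoc.yates_chi2`, `sexsignal.poolsig.window_scan`, …)
and as per-stage subcommands (`sexsignal markers process|distrib|signif`,
`sexsignal pool scan|hemizygous`, `sexsignal kmer count|filter|call`,
`sexsignal simulate`).

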