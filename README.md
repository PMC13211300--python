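# fixmark

Mining and validation of **fixed species-diagnostic SNP/InDel markers** for
distinguishing a target species from its relatives inside a natural hybrid
swarm — the situation faced in conservation genetics of the endangered
orchid *Calanthe aristulifera*, which hybridizes freely with sympatric
congeners (*C. sieboldii*, *C. × kibanakirishima*) so that floral morphology
alone misidentifies cryptic hybrids.

The package is aimed at conservation geneticists and molecular-breeding
practitioners who have genome-wide genotypes (e.g. from GBS) for a mixed
panel of purebreds, relatives and hybrids, and who need a small set of
cheap, auditable PCR assays (KASP and SCAR) that separate purebred target
individuals from everything else.

## What it computes

* **QC cascade** — per-genotype depth masking (depth ≥ 3), site mapping
  quality (MAPQ ≥ 20), per-locus missingness (< 30%), panel-wide minor
  allele frequency (MAF > 5%), and an exact conditional Hardy–Weinberg test
  within the target population (exclude p < 0.001).
* **Fixed-allele mining** — a locus is diagnostic when every reference
  (purebred) individual is homozygous for one allele and that allele is
  entirely absent (frequency 0) from the non-target contrast set; mining
  runs in two stages, first with all morphologically target-labelled
  individuals (n = 36), then after removing a reclassified cryptic hybrid
  and the atypical variants (n = 32).
* **Assay design** — allele-specific KASP primers terminating on the
  discriminating base (Tm 58–62 °C, GC 40–60%, 20–30 nt, nearest-neighbor
  thermodynamics) and SCAR primer pairs around large InDels (codominant
  when the amplicon sizes differ by ≥ 20 bp, dominant when one allele's
  primer site is deleted and yields no band).
* **Calling** — a deterministic allele-ratio caller for two-channel
  (FAM/HEX) endpoint fluorescence; band-size matching for SCAR gels; a
  merged two-locus SCAR decision table whose off-table patterns are
  `ambiguous`, never `target`.
* **Diagnostics** — concordance, sensitivity and specificity with Wilson
  score intervals,

  `CI = (p̂ + z²/2n ± z√(p̂(1−p̂)/n + z²/4n²)) / (1 + z²/n)`,

  under an explicitly named scoring convention (morphological
  pre-classification or molecular ground truth), and the hybrid index
  `h = (# target alleles)/(2 × # diagnostic loci)` (1 for purebreds, 0.5
  for an F1, 0.75 expected for a BC1 toward the target).
* **Panel simulator** — a first-class generative model of the 64-accession
  hybrid-swarm study design (32 purebreds, one cryptic F1 labelled as
  typical, 3 atypical variants, 16 non-target accessions, 12 F1 hybrids)
  with locus-structured GBS dropout, read-depth and mapping-quality
  contamination, class-conditional fluorescence and allele-dependent gel
  bands, so the whole pipeline is testable without any external data.

## Worked example

Simulate the KASP validation scenario (S1) and run the full pipeline —
filter → two-stage mining → calling → scoring:

```sh
fixmark full --scenario S1 --seed 1 --outdir out/
```

prints, among the four reports:

```
== KASP, morphological convention ==

convention: morphological
concordance: 98.4% (63/64; 95% CI 91.7-99.7%)
sensitivity: 100.0% (32/32)
specificity: 96.9% (31/32)
discordant: S36
```

Reading: of 64 accessions, 63 KASP species calls agree with the
morphological pre-classification. The single discordant sample (S36) is the
cryptic F1 — morphologically a perfect target purebred, but heterozygous
(dual FAM+HEX signal) at every diagnostic locus. Under the genetic
convention the same call set is 100% concordant: the assay is right and the
morphology is wrong, which is exactly the marker set's purpose. All 32
genetically purebred individuals are recovered (sensitivity 100%);
specificity against morphology is 31/32 = 96.9% because the cryptic hybrid
is counted against the morphological label it contradicts.

`out/` also receives the simulated panel VCF and sample sheet, the
per-stage filter report (e.g. 2000 loci in, ~1960 after MAPQ, ~1300 after
missingness/MAF/HWE), the stage-2 candidate TSV (~120–140 fixed loci, of
which the planted 200 diagnostic loci are the only true positives), raw
fluorescence and band tables, per-sample calls, and a provenance JSON.
Every stage is also available as its own subcommand (`simulate`, `filter`,
`mine`, `design`, `call`, `score`) and as plain library functions
(`fixmark.run_scenario`, `fixmark.mine_fixed_alleles`, ...).

## Layout

```
src/fixmark/
  variant_io.py        genotype-matrix data model, VCF/TSV IO
  variant_filters.py   QC cascade incl. exact HWE test
  fixed_allele_miner.py  fixed-allele definition, two-stage mining
  assay_designer.py    KASP/SCAR primer screening (nearest-neighbor Tm)
  assay_caller.py      fluorescence/band calling, merged two-locus table
  diagnostics.py       scoring conventions, Wilson intervals, hybrid index
  panel_simulator.py   synthetic hybrid-swarm panels and assay observations
  pipeline.py          scenario orchestration
  cli.py               click CLI (`fixmark`)
docs/methods.md        model and design notes
```
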