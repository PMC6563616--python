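# tdgtool

Analysis toolkit for two experimental readouts used when probing thymine
DNA glycosylase (TDG) as a cancer target:

1. **DREAM methylome quantification** — Digital Restriction Enzyme
   Analysis of Methylation. Genomic DNA is digested sequentially with
   SmaI (methylation-sensitive, blunt CCC^GGG) and XmaI
   (methylation-insensitive, C^CCGGG + fill-in), so sequenced fragment
   ends start with 5′-GGG at unmethylated CCCGGG sites and 5′-CCGGG at
   methylated ones. The pipeline enumerates recognition sites in a
   reference genome, classifies aligned reads by these digestion
   signatures, computes per-site methylation levels
   (m = n_meth/(n_meth+n_unmeth)), tests sites between conditions with
   exact Fisher tests under Benjamini–Hochberg FDR control, summarises
   genome-wide hyper-/hypomethylation percentages, and maps differential
   sites to adjacent genes with background-corrected hypergeometric
   gene-set enrichment. Spike-in standards of known methylation provide
   calibration QC.
2. **Molecular-beacon screening analysis** — a fluorescence assay in
   which TDG excises a mismatched base and APE1 incision releases a
   quenched fluorophore. The package models the two-step kinetics
   (closed form for S → AP → fluorophore conversion), computes activity
   metrics from well time-courses, Z′-factor plate QC
   (Z′ = 1 − 3(σ₊+σ₋)/|μ₊−μ₋|), percent inhibition against uninhibited
   and no-enzyme controls, threshold hit calling, and four-parameter
   logistic IC50 fits.

Both tracks ship seeded synthetic-data generators with ground truth
(genomes with planted CCCGGG sites, beta-distributed methylomes with a
knockdown-like hypermethylation effect, digestion-anchored SAM reads,
kinetics-driven screening plates with planted inhibitors), so every stage
can be validated end-to-end without access to the original sequencing or
screening data. It is aimed at epigenomics analysts working with
restriction-signature methylation data and at screening groups analysing
coupled-enzyme fluorescence assays.

## Worked example

Simulate a small two-condition experiment, count signatures, and call
differential methylation:

```bash
tdgtool sim-dream --seed 4 --out sim/
tdgtool index-sites --genome sim/genome.fa --out sites.bed
tdgtool count-signatures --bam sim/A_rep1.sam --genome sim/genome.fa --out A.tsv
tdgtool count-signatures --bam sim/B_rep1.sam --genome sim/genome.fa --out B.tsv
tdgtool diff-meth --a A.tsv --b B.tsv --out volcano.tsv
```

Output:

```
146 sites, 584 anchors (genome 191b0dc2543776bb)
examined=14416 classified=14366 unassigned=50 lowmapq=0
{
  "n_tested": 146,
  "pct_hyper": 3.4246575342465753,
  "pct_hypo": 0.0,
  "pct_unchanged": 96.57534246575342
}
```

Reading this: the simulated genome contains 146 CCCGGG sites (each with 4
signature anchors); of 14,416 reads in replicate A, 14,366 carried an
exact digestion signature at an anchor (50 were lost to the simulated
0.1% sequencing error corrupting the GGG/CCGGG prefix). Of the 146 sites
tested between control (A) and knockdown-like (B) conditions, 3.4% were
called hypermethylated and none hypomethylated — the generator plants a
+0.3 methylation gain in 5% of sites, and single-replicate depth recovers
most of them. `volcano.tsv` holds the per-site deltas, −log10 p and q
values behind the summary.

The screening track is analogous:

```bash
tdgtool sim-screen --seed 5 --out plate.tsv
tdgtool screen-hits --plate plate.tsv --out hits.tsv
# -> Z'=0.748; 3 hits / 300 compounds
```

Both tracks can also run end-to-end from one YAML via `tdgtool run
--config run.yaml`, which writes a checksummed manifest per track. The
same functionality is available as a library (`tdgtool.site_index`,
`signature_count`, `meth_call`, `diff_meth`, `gene_map_enrich`,
`dream_sim`, `beacon_screen`, `workflow`).

## Documentation

`docs/methods.md` describes the models, the digestion geometry, the
statistical choices and their tunable parameters, what the simulators do
and do not emulate, and known limitations.
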