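# Methods

## The DREAM methylome track

### Model

DREAM (Digital Restriction Enzyme Analysis of Methylation) quantifies CpG
methylation at CCCGGG sites by sequential digestion with two isoschizomers.
SmaI cuts blunt, CCC^GGG, but only when the internal CpG is unmethylated;
XmaI cuts C^CCGGG regardless of methylation, leaving a 4-nt 5′ overhang
(CCGG) that is filled in before adapter ligation. Sequenced fragment ends
therefore carry a methylation signature: 5′-GGG if the site was cut by SmaI
(unmethylated), 5′-CCGGG if only XmaI cut it (methylated).

Working the cut geometry through for a site whose first C sits at 0-based
position *p*, each site has exactly four read anchors — the only
(strand, 5′-coordinate) pairs at which a read can report the site's state:

| strand | 5′ position | prefix | state |
|---|---|---|---|
| + | p+3 | GGG   | unmethylated |
| − | p+2 | GGG   | unmethylated |
| + | p+1 | CCGGG | methylated |
| − | p+4 | CCGGG | methylated |

A read is counted iff its mapped 5′-most base lands exactly on an anchor,
it has zero 5′ clipping, and its first bases in read orientation equal the
expected prefix **exactly**. No mismatch allowance is given: a single
substitution can flip the GGG/CCGGG identity, so tolerance would trade a
small sensitivity gain for classification errors. Reads failing any
condition are tallied as unassigned with a reason code, and the counter
maintains the reconciliation invariant
`classified + unassigned + lowmapq = examined`.

The per-site methylation level is the exact fraction
`n_meth / (n_meth + n_unmeth)` at sites with classified coverage of at
least `min_coverage` (default 20; under-covered sites are absent from the
output, never reported as zero). "Uniquely mapped" is operationalised as
MAPQ ≥ 20 (configurable); secondary, supplementary and duplicate-flagged
alignments are never examined.

### Differential testing

Each site covered in both conditions is tested with a two-sided Fisher
exact test on the 2×2 table of pooled replicate counts. The test is
implemented with exact integer hypergeometric weights (`math.comb`): the
two-sided p-value sums every table at the observed margins whose
probability does not exceed the observed table's, with ties decided by
exact integer comparison rather than floating-point tolerance. Fisher on
pooled counts is a deliberate, substitutable choice: it is the natural
exact test on signature counts at duplicate-level replication, but it
ignores biological between-replicate dispersion, so with many replicates a
beta-binomial model would be preferable (not implemented).

P-values are adjusted by Benjamini–Hochberg (via
`statsmodels.stats.multitest`). A site is called hypermethylated when
`delta = level_B − level_A ≥ min_delta` (default 0.10 absolute) and
`q ≤ alpha` (default 0.05); hypomethylated symmetrically. The genome-wide
summary reports class percentages over tested sites — both thresholds and
the denominator are explicit parameters because different choices move the
headline percentage. The volcano export caps −log10 p at 320 purely for
presentation; a capped row is flagged.

### Gene mapping and enrichment

"Adjacent gene" is TSS proximity: distance 0 if the site lies inside a
gene span, otherwise |site − TSS|, capped at `max_dist` (default 10 kb),
ties broken to the lexicographically smallest gene id for determinism.
Enrichment is a one-sided hypergeometric upper tail per user-supplied GMT
set, with the universe restricted to the background (genes with at least
one covered site) and each set intersected with that universe first —
this is what "background-corrected" means here. No pathway database is
bundled; term-level results are a function of the GMT the user provides.

### Spike-in calibration

Spike-in standards (contigs of known methylation, defaults 0/25/50/75/100%)
are scanned and counted like biological contigs. The calibration report is
a coverage-weighted least-squares line of observed on known level with a
weighted R². It is reported by default and applied (inverting the line,
optionally clipping to [0,1]) only on request, because spiking standards
in does not by itself imply the study's calls were transformed.

## The synthetic DREAM generator

The generator emulates exactly the features the pipeline consumes:

* **Genome** — uniform-random contigs with CCCGGG hexamers planted at
  jittered regular spacing at least 2 read-lengths apart; incidental motif
  occurrences are kept (truth is keyed to the scanned index, so a site is
  a site regardless of provenance). Spike-in contigs (3 kb, 6 planted
  sites each) are appended, one per standard level.
* **Methylome** — baseline levels Beta(2, 2) per site (a broad unimodal
  methylome; the acceptance simulations use the same shape), condition B
  adds +0.3 to an exact 5% subset, clipped to [0, 1]. These defaults model
  a knockdown that shifts a small fraction of the genome toward
  hypermethylation; with the default alpha/min-delta rule and ~100×
  coverage they yield a reported hypermethylated percentage of roughly
  4–5%, i.e. the same order as the mid-single-digit gains such
  perturbations produce on real methylomes.
* **Reads** — per site and replicate, a Poisson(coverage_mean = 100)
  number of classifiable reads, each methylated with probability equal to
  the true level, placed at a methylated or unmethylated anchor with a
  fair strand coin, sequence copied from the reference (so it carries the
  correct signature) with i.i.d. substitutions at `error_rate`
  (default 0.001), emitted as coordinate-sorted SAM with MAPQ 60.

What it does **not** model: real fragment pairing (each digestion event
yields two ends; anchors here are sampled independently), PCR duplicates,
GC bias, size selection, mapping ambiguity, or beta-binomial overdispersion
across replicates. Coverage is Poisson, not negative-binomial. Passing
tests therefore demonstrate correctness of the counting/testing machinery
and calibrated statistical behaviour under the stated sampling model — not
robustness to every artifact of a real library.

All randomness flows from one seed through spawned child generators
(genome, methylome, one per condition×replicate), so identical configs
give byte-identical bundles.

## The beacon screening track

### Kinetic model

The molecular-beacon assay couples two enzymes: the glycosylase excises
the mismatched base (rate `kg`, proportional to TDG activity), APE1
incises the resulting abasic site (rate `kap`), and incision releases the
fluorophore from the quencher. Treating both steps as first order gives
sequential conversion S → AP → F with closed form

    F(t) = F_bg + drift·t + F_scale·S0·[1 − (kap·e^(−kg·t) − kg·e^(−kap·t))/(kap − kg)]

implemented in an `expm1`-stable form that is exact in the kg → kap limit.
Defaults: S0 = 280 nM substrate, kg = 2×10⁻⁴/s, kap = 10⁻³/s,
F_scale = 1 RFU/nM, F_bg = 50 RFU, drift = 10⁻³ RFU/s, noise 5 RFU — i.e.
~70% substrate conversion over the 2-h read and a Z′ around 0.75–0.8 for
control plates, comfortably inside the usable-assay regime (Z′ ≥ 0.5).
Inhibitors scale `kg` by 1/(1 + conc/Ki); this is activity scaling, not a
mechanistic binding model, and is adequate for generating plates with
known answers. Simulated plates sample every 60 s; the analysis
interpolates, so it is agnostic to sampling rate.

### Analysis

* **Activity** — endpoint ΔRFU between two interpolated times (default
  0 → 2 h; the miniaturised assay's 0-and-3-h readout maps directly onto
  this metric) or the least-squares slope over an early window for kinetic
  mode. Both are provided because either readout is defensible.
* **QC** — Z′ = 1 − 3(sd₊ + sd₋)/|mean₊ − mean₋| with sample standard
  deviations; equal control means are an error (undefined separation).
  The workflow gates hit calling at Z′ ≥ 0.5 by default.
* **Inhibition** — 100 × (1 − (a − mean₋)/(mean₊ − mean₋)), reported raw
  (values outside [0, 100] are informative).
* **Hits** — median inhibition per compound across replicate wells,
  thresholded at 50% by default. The threshold is a declared parameter;
  the screening literature uses anything from 3·SD of inactives upward.
* **IC50** — 4PL fit `R(c) = bottom + (top − bottom)/(1 + (c/IC50)^h)` by
  least squares in log-concentration with multi-start initials from the
  span quartiles, bottom/top free (robust to control drift). The fit is
  canonicalised to top ≥ bottom; a non-positive Hill slope (response
  rising with dose in an inhibition fit), a flat response below the noise
  floor, or an IC50 outside 100× the tested span report
  `converged = False` with a reason rather than a number to be trusted.

## Numerical and design notes

* Coordinates are 0-based half-open throughout; BED/GFF conversions happen
  at the parsers.
* N bases never match the recognition motif (ambiguity cannot confirm a
  site). Anchor-key collisions are geometrically impossible for this motif
  (sites cannot be < 6 bp apart) but are guarded: colliding anchors are
  excluded from counting and recorded.
* Sites closer than `min_fragment` (default 40 bp) to a neighbour are
  flagged in QC but counted; real libraries may deplete such short
  fragments, and the handling of sites closer than a read length is
  genuinely underdetermined — flagged, not resolved.
* Problem sizes in the test-suite and acceptance runs (2,000-site
  methylomes at ~100×, 1,000-site null panels × 50 runs, 300-compound
  plates, 50-seed fit-recovery studies) were chosen as the smallest sizes
  at which the checked statistical bands are comfortably stable across
  seeds.
* Levels are stored as fractions everywhere; percentages appear only in
  summaries.
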