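# Methods

## Scope and model

`polybs` re-implements, as a tested library, a candidate m⁵C calling and
polysome-fraction analysis pipeline for bisulfite-converted RNA-seq
(bsRNA-seq). Bisulfite treatment deaminates unmethylated cytosine to
uracil (sequenced as T) while 5-methylcytosine resists conversion, so the
per-position non-conversion level C/(C+T) at a reference cytosine
estimates methylation stoichiometry. The pipeline consumes bisulfite-aware
alignments in which each retained read carries its original unconverted
bases, and proceeds through a fixed filter cascade:

1. **read filter** — reads retaining more than 3 cytosines are removed;
   clustered non-conversion is the signature of structure-driven
   conversion failure, not methylation;
2. **pileup** — quality-aware counting at transcript-strand cytosines
   with a minimum base quality of Q30 and a 6-nt end mask (a read-end
   cytosine bias of uncertain origin motivates the mask);
3. **signal-to-noise** — positions where fewer than 90% of covering reads
   survive the read filter are flagged and suppressed (boundary strict;
   configurable);
4. **per-replicate thresholds** — read coverage ≥ 30, retained-C depth
   ≥ 5, C+T purity ≥ 80%;
5. **replicate merging** — a candidate must pass in all three biological
   replicates with a mean non-conversion of at least 10%.

Two deliberate interpretations, both config-exposed:

* **End-mask semantics.** Masked positions contribute to coverage but
  neither C nor T evidence. Masking only retained Cs (and keeping the
  converted Ts) would deflate the non-conversion estimate by roughly the
  fraction of covering reads that carry the site within 6 nt of an end
  (~12% at 101-nt reads), destroying the estimator's calibration at
  genuine sites. `mask_as_converted=True` restores the count-as-converted
  alternative.
* **Purity denominator.** The 80% C+T rule is applied over scored base
  calls (C+T+other). Mask- and quality-dropped calls carry no base
  identity; counting them against purity would spuriously reject sites
  that sit near transcript ends, where a large share of covering reads
  have the site inside the end mask.

tRNA-like genes are called from "processed" reads only — reads wholly
contained in the annotated mature region, which is flanked by 100 nt of
precursor sequence in the reference. Genes carrying four clustered
high-stoichiometry sites are a known false-negative mode: reads
co-retaining all sites fail the read filter, so recovery degrades there
by design (the tests assert the recovered set is a strict subset of the
planted truth).

## Synthetic data

`simdata` generates the study conditions every downstream stage is tested
against: a toy reference (mRNA genes with 5′UTR/CDS/3′UTR structure on
either strand, tRNA genes with flanked mature regions, rRNA-like genes,
spike-ins), a planted truth table, and aligned reads for a 4-fraction ×
3-replicate polysome design. Key defaults, with rationale:

| parameter | default | rationale |
|---|---|---|
| conversion failure | 0.002 per unmethylated C | the >99.8% spike-in conversion regime of efficient bisulfite protocols |
| planted stoichiometry | uniform 0.2–0.6 | the mid-range where most transcriptome-wide candidates sit |
| trend mix (neg/neu/pos) | 0.6 / 0.2 / 0.2 | the observed dominance of negative methylation-vs-translation trends |
| trend step | 0.05–0.09 per fraction | total swings of 15–27 points, matching profiled single-site examples |
| replicate jitter | Beta, concentration 200 | mild between-replicate wobble reproducing high replicate concordance |
| read length / quality | 101 nt; Q37 with 2% Q20 | typical paired-end short-read data; the low tail exercises the Q30 filter |
| end bias | 0.01 within 6 nt of ends | magnitude unknown in the field; a guess, config-exposed |
| structure clusters | 2 windows, ≥5 co-retained Cs, P=0.35 per read | reproduces rRNA-like clustered non-conversion that must trip both filters |
| coverage | 50 reads/position per fraction library | enough for the ≥30 coverage rule after compositing |

Sites are capped at three per mRNA gene so that genuine methylation alone
cannot trip the more-than-three-retained-C read filter; adjacent multi-site
methylation is characteristic of tRNA, not mRNA, and is planted on the
tRNA-like genes instead. The generator logs, per site and sample, the
realised (jittered) methylation probability and the exact
retained/converted read tallies; tests reconcile these logs against
brute-force recounts of the emitted reads.

What the generator does not emulate: indels and soft-clipping, PCR
duplicates, sequence-composition bias, expression-level variation between
genes, partial rRNA depletion, and multi-mapping ambiguity. Passing tests
therefore demonstrate the correctness and statistical behaviour of the
cascade under its own model assumptions, not robustness to every artefact
of real libraries.

## Statistics

* **Differential methylation** between adjacent fractions uses a binomial
  logistic-regression likelihood-ratio test on replicate-averaged
  methylated/unmethylated counts (rounded to integers, as the test needs
  counts; the rounding rule is config-independent and documented here).
  The intercept-only GLM's residual deviance *is* the LRT statistic
  because the saturated two-group model fits the two observations
  exactly; tests verify agreement with a closed-form oracle to 1e-6.
  Multiplicity is handled with Benjamini–Hochberg; a site is called
  differentially methylated at q < 0.05 with an absolute difference of at
  least 10 percentage points (a `relative` mode divides by the first
  fraction's level instead).
* **Fuzzy c-means** (fuzzifier m = 2, c = 9 clusters) runs on per-site
  standardised profiles with k-means++ seeding, 10 restarts, best
  objective kept, fully seed-determined. Memberships follow the standard
  inverse-distance update; the objective is non-increasing under the
  update rule (property-tested).
* **Trend labels.** Per-site standardisation is scale-free: a flat
  profile becomes unit-norm noise whose direction is isotropic, so no
  threshold on the *standardised* centroid slope can separate neutral
  from trending clusters. Clusters are therefore labelled by the
  least-squares slope of their hard-member mean **raw** non-conversion
  profile (ε = 0.02 per fraction step, between the cluster-mean noise
  floor ≈0.007 and the planted steps 0.05–0.09). Sites inherit their
  argmax-cluster label, refined by per-site evidence: a trend-labelled
  site whose own slope z-score (binomial SEs) is below 1.5 is demoted to
  neutral, and a neutral-labelled site with z ≥ 2.5 is promoted. The
  residual error is dominated by realisations whose jittered profiles
  genuinely contradict their generating label.
* **Enrichment** anchors sites in spliced-transcript coordinates and
  compares binned counts against a null of matched-size uniform draws
  from unmodified cytosines of the same transcripts (100 resamples
  aggregated by default). Each bin gets a Fisher exact p, a Woolf log-OR
  95% CI (Haldane–Anscombe corrected and flagged when a cell is zero),
  and BH q-values across bins; raw p-values are retained since it is not
  standard in this analysis style to adjust across bins.
* **Secondary structure** uses a maximum base-pairing dynamic program
  (AU/GC/GU pairs, minimum hairpin loop 3, non-crossing) as a stand-in
  for thermodynamic folding. It shares the qualitative contract the
  pairing meta-profile needs — structured versus unstructured flanks —
  and is oracle-tested against exhaustive enumeration up to length 12.
  The profile functions accept any callable with the same
  sequence-in/indicator-out signature, so a thermodynamic folder can be
  substituted for publication-grade figures.
* **Bulk comparisons** are unpaired two-tailed t-tests (Student by
  default, Welch optional) on per-site non-conversion between adjacent
  fractions; trend-category composition is tested per region with exact
  binomial tests against the all-sites proportions; translation-efficiency
  and half-life associations use ECDFs and two-sample KS tests, with the
  more-than-60-reads inclusion rule applied when raw counts are supplied.

## Numerical and degenerate-input choices

Internal coordinates are 0-based half-open; site tables emit both a BED
interval and a 1-based `coord1` column. Longest-transcript ties break
lexicographically by transcript id. Constant clustering profiles (zero
SD) are dropped with a log message. Fisher tables with a zero cell use
the Haldane–Anscombe correction and are flagged. Zero-information LRT
tables (no methylated or no unmethylated observations overall) return
deviance 0, p = 1. Empty amplicon coverage yields missing grid cells;
single-replicate amplicon designs produce grids without tests.

## Validation experiments and their sizes

`scripts/acceptance.py` re-runs the full validation suite: a 50-read
exact recount of the filter cascade; specificity on >10⁵ unmethylated
cytosine observations; recovery and exact-binomial calibration on 2 × 200
planted sites (calibration is assessed against the realised per-replicate
methylation probabilities, coverage-weighted, aggregated across the two
experiments); artefact suppression with the filters toggled; spike-in
conversion on ~7 × 10⁴ observations; differential-methylation type-I
error (2000 null sites), power (300 sites at 40 points) and oracle
agreement; trend recovery over three full 4 × 3 experiments (~290 sites);
the folding oracle on ~1700 sequences; and enrichment CI coverage over
200 Monte-Carlo placements. These sizes keep the whole run around five
minutes on one CPU while holding the Monte-Carlo error of each reported
rate near or below one percentage point.

## Known limitations

The package does not align reads, call indels, or distinguish m⁵C from
hm⁵C (bisulfite chemistry cannot). TMM normalisation of expression tables
is out of scope: normalised inputs are accepted as-is. GO enrichment and
comparisons against external site catalogues are not implemented. The
folding stand-in maximises pair count, not free energy, and should not be
used for quantitative structure prediction.
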