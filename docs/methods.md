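# Methods

## The comparative E/EQ design

The workflow locates protease cleavage sites by comparing two otherwise
identical digests: substrate incubated with the active enzyme (E) and with
a catalytically dead active-site point mutant (EQ, Glu→Gln). Both samples
are then digested with a *working* protease (trypsin or GluC) and
quantified label-free by LC-MS/MS at the peptide level. Cleavage by the
enzyme under study leaves two complementary signatures:

* **Semi-specific peptides.** A peptide with exactly one terminus
  conforming to the working protease's rule carries a foreign terminus at
  its other end. When such a peptide is strongly enriched in the E digest,
  that terminus marks a candidate scissile bond: for a ragged N-terminus
  the bond P1–P1′ is `(start−1, start)`, for a ragged C-terminus
  `(end, end+1)` (Schechter–Berger numbering, 1-based inclusive residue
  coordinates throughout).
* **Spanning peptides.** A fully specific peptide whose interval contains
  a candidate bond is destroyed by cleavage, so enrichment in the EQ
  control corroborates a site strictly inside it.

### z-scores

For every peptide quantified in both groups the log2 ratio
`r = log2(E) − log2(EQ)` is computed, and `z = (r − mean)/sd` over all
co-quantified peptides of the same experiment (one working protease = one
experiment; trypsin and GluC digests are scored separately and merged at
the site level afterwards). The standard deviation is the sample (n−1)
form. Peptides quantified in only one group carry no ratio: they are
excluded from the population and reported in a side channel
(`exclusive_group`), because a one-group intensity is censored rather than
infinite. The population therefore satisfies mean(z)=0, sd(z)=1 to
numerical precision, which the tests assert at 1e-9.

A semi-specific, positionally internal peptide with `z ≥ z_threshold`
(default 2.0) nominates its site; calls at the same (protein, P1) merge
with pooled evidence. A cut at the very first peptide bond (P1 = residue 1)
is treated as ragged, not positionally internal. Fully specific peptides
with `z ≤ −z_threshold` attach to calls whose bond they contain; those
covering no call are reported as orphan signals (cleavage whose products
escaped detection).

### Abundance stratification

Evidence is stratified — never filtered — by abundance using Tukey fences
on the log2 abundances of the whole co-quantified population: quartiles by
linear interpolation of order statistics, fences at `Q1 − k·IQR` and
`Q3 + k·IQR` with k = 1.5. A call whose best semi peptide falls below the
lower fence is retained with tier `outlier_low`; the reference intensity of
a peptide is the enriched group's intensity by default (config:
`mean_of_both`). Low-abundance significant peptides are real evidence in
this assay (some printed table rows sit far below the bulk), hence
stratification instead of exclusion.

### Working-protease rules

Trypsin cleaves after K/R and is blocked by proline in P1′ by default;
GluC (bicarbonate conditions) cleaves after E and D with no blocking.
Both blocked sets are configurable, because upstream search engines differ
on the proline rule and the evidence tables contain no discriminating case.
Protein termini count as specific for classification; a configurable
mature-protein start (post signal peptide) may optionally also count as
specific (default off). Modifications never change specificity class — an
acetylated ragged N-terminus is evidence like any other.

## Site catalogues

Site identity across enzymes is the P1 position on the same protein
isoform. Cross-isoform identity (versican V1 vs V2 numbering) requires an
explicit block-wise position map, shipped as an editable fixture; it is
never inferred by alignment, since silent renumbering between isoforms is
the main error mode of cleavage-site catalogues. Domain labels come from
interval tables; lookups take the first containing interval in file order,
and positions outside all intervals are labelled `interdomain`. The
packaged domain tables reproduce the printed domain column of the evidence
tables; the boundaries themselves are reverse-engineered fixture data (the
tables print labels, not coordinates) and are editable without touching
code. The biglycan table contains one boundary-straddling label
("LRR2/LRR3"), represented as a single-position interval listed first.

## Subsite specificity (logo) scoring

Windows P5…P1′…P5′ are extracted around each site, padding positions that
fall outside the protein. Per position, residue percentages are computed
over the non-padded observations (padding is excluded from the
denominator rather than counted as a 21st symbol, keeping percentages
comparable to the reference set) and compared with a reference proteome
composition by simple difference, so per-position differences sum to zero.
Significance per cell is a two-sided normal test of the observed proportion
against the reference proportion p0 with standard error
`sqrt(p0(1−p0)/n)` at level 0.05 — the percentage-scoring convention of
iceLogo-style tools. The packaged reference is a human Swiss-Prot-style
composition (renormalised to exactly 100%); it is fixture data and can be
replaced by any other background.

## Enzyme kinetics

* **Calibration.** Fluorescence rates convert to product formation rates
  by dividing by the RFU yielded per molar product, derived from complete
  digestion of a known substrate amount; inner-filter corrections enter as
  per-well multiplicative factors supplied by the user (default 1), since
  the correction protocol is instrument-specific.
* **Michaelis–Menten.** `v0 = Vmax·S/(Km+S)` by unweighted nonlinear least
  squares (scipy `curve_fit`), initialised at `Vmax ≈ max v0`,
  `Km ≈ median S`; `kcat = Vmax/[E]active` and `kcat/Km` follow as exact
  identities, never a re-fit. Fits are exact to machine precision on
  noiseless generative data, which the tests assert for several parameter
  decades.
* **Active-site titration.** Residual activity against a 1:1 tight-binding
  inhibitor is fit by least squares over the initial linear portion —
  by default all points with residual activity ≥ 20%, an overridable
  convention since the linear region is otherwise operator-defined — and
  the active concentration is the x-intercept. A non-negative slope is an
  error (no titration endpoint).
* **Progress curves.** Product formation at sub-saturating substrate
  (S0 ≪ Km) follows `P(t) = S0(1 − exp(−(kcat/Km)·E·t))`; the single
  fitted constant is the specificity constant. The single-exponential
  model is a documented assumption: with 50 nM substrate against a
  micromolar-range Km the reaction is first order in substrate, and the
  model's initial slope `(kcat/Km)·E·S0` is verified against a finite
  difference in the tests.
* **Fold comparison.** Ratios against a reference enzyme, reported as
  "n-fold higher/lower" with folds always ≥ 1.

## The synthetic E/EQ generator

`simulate_experiment` builds a full peptide table with known ground truth:

* substrate: supplied or drawn from the packaged proteome composition
  (default length 300);
* planted sites: default 10 bonds at cleavage fraction 0.8, placed away
  from termini and working-protease sites (a planted bond coinciding with
  a working-protease site is warned about — its semi evidence would be
  indistinguishable from the digest background);
* base intensities log-normal (log2 mean 18, sd 2), per-group
  multiplicative noise with CV 0.1 (log2-domain Gaussian, matching the
  log2 LFQ intensity scale);
* fully specific peptides: in-silico digest with ≤2 missed cleavages,
  length 6–75 (the standard search settings), detected with probability
  0.9; E-side intensity reduced by `(1−fraction)` per planted bond inside
  the peptide (independent cleavage per site);
* planted semi peptides: re-digestion of the two cleavage products,
  keeping peptides abutting the planted bond; E intensity
  `fraction × base`, EQ at a 1% trace. The trace sits at the detection
  limit and is quantified only with probability 0.6 — the standard
  intensity-dependent missingness of label-free data. An undetected trace
  leaves an E-only exclusive that the caller sidelines, mirroring the rule
  that one-group peptides are never auto-called;
* background semi peptides: ragged truncations of detected fully
  peptides, symmetric between groups, Poisson-distributed with mean 3 per
  fully peptide — the semi:fully ratio seen in real digest searches. Their
  cut points avoid working-protease sites (which would remain fully
  specific) and planted bonds (which would fabricate evidence).

Everything is deterministic given the seed. What the generator does *not*
emulate: spectra and identification error, retention-time effects,
modification-state inflation, shared/razor peptides, and correlated
(batch) intensity structure. Passing recovery tests therefore show that
the statistical machinery behaves as designed under its own model, not
that real searches achieve these error rates.

Under the default conditions the pipeline attains recall ≥ 0.9 with
precision 1.0 at z ≥ 2, and with nothing planted and no background it
calls nothing at any seed. The background z distribution under the null is
standard normal by construction; the benchmark script measures
P(|z| ≥ 2) against 2·Φ(−2) on a 2000-residue null substrate.

## Problem sizes

The test suite and analysis scripts run on the packaged evidence tables
(tens of rows), synthetic substrates of 300–2000 residues, 100-replicate
fit-recovery studies, and a 3×3 power grid — sizes chosen so the entire
analysis reruns from scratch in well under a minute on one CPU.

## Known limitations

* The evidence tables ship without the full-length protein sequences they
  are numbered against (UniProt sequences are not redistributed), so
  peptide-vs-sequence validation and full P5–P5′ window extraction on the
  published substrates require the user to supply the FASTA files; the
  flank residues printed with each peptide still give exact P1/P1′
  identities.
* No multiple-testing correction is applied across peptides, matching the
  workflow being reproduced; z-thresholding at 2.0 is a per-peptide rule.
* Replicate structure (multiple injections per group) is not modelled;
  the schema carries one abundance per group.
* Domain boundaries and the V1/V2 position map are fixture
  reconstructions, exact only where the printed site/domain assignments
  constrain them.
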