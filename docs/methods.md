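# Methods

This note records the models, defaults, and numerical choices behind
`probescout`, and what the synthetic-data tests do and do not demonstrate.

## Mass arithmetic

All masses are monoisotopic. Peptide neutral mass is the sum of residue
(dehydrated) masses plus one water (18.010565 Da); m/z uses the proton mass
1.007276 Da. Residue and elemental masses come from `pyteomics.mass`.
Average-mass chemistry is deliberately unsupported, and non-canonical residue
codes (B, J, O, U, X, Z) are rejected rather than skipped, because a silently
dropped residue corrupts every downstream fragment mass.

The modification registry (`data/modifications.tsv`) carries the probe
remnants (VS +192.0569, VME +172.0848, PA +112.0637, VPS with DADPS linker
+387.1940, VPS with DDE linker +344.1631, hydrolyzed VPE +158.0691 Da) and
the standard search modifications. Entries whose elemental composition is
public (oxidation = O, carbamidomethyl = C2H3NO, Gly-Gly = C4H6N2O2) are
revalidated from atomic masses in the tests; the probe remnants whose
post-cleavage composition is not published are stored as constants and
cannot be independently recomputed — a known limitation.

## Digestion model

Proteases are C-terminal-side rules: trypsin cleaves after K/R but not before
P (the common search-engine convention), Lys-C after K unconditionally,
chymotrypsin after F/W/Y/L not before P, Glu-C after E only — matching
digestion in ammonium bicarbonate buffer; cleavage after D is available as
the `gluC_DE` enzyme for users whose buffer promotes it. `digest` returns all
peptides spanning at most `max_missed` internal cut sites (default 2,
matching the search setting used for this kind of data).

The sequential on-bead workflow is modeled deterministically: the
fully-cleaved (zero-missed) tiling of the protein decides which fraction each
residue lands in, so the on-bead, washed, and cleaved fractions exactly
partition the protein — the property the tests verify. Missed-cleavage
variants matter for the search space, not for fraction membership; this keeps
the fraction model a partition rather than an ensemble of partial digests.
Protein N-terminal Met is not clipped; sequences are used as given.
Internally all coordinates are 0-based half-open; every user-facing table is
1-based, following the convention in which the UCHL1 active site is "C90".

Site detectability uses a window of 6–40 residues and 600–6000 Da neutral
mass, typical practice for LC-MS/MS peptide observability; the synthetic
spectrum generator emits peptides of length 6–45 for the same reason.

## Identification and localization

Spectra are scored by a transparent matched-fragment-ion count: the maximum
one-to-one assignment of theoretical singly-charged b/y ions to observed
peaks within the fragment tolerance (default 0.8 Da; precursor tolerance 50
ppm). This deliberately replaces opaque search-engine scoring with something
auditable; the cost is that the score is not calibrated across peptide
lengths, which the FDR machinery absorbs. Candidate peptides are enumerated
from a joint digest with all scheme enzymes, with every placement of 1–3
probe remnants on the peptide's Cys residues (bead-released peptides carry at
least one label but can carry several). Ties break toward fewer
modifications, then lexicographic sequence. One spectrum yields at most one
PSM; chimeric spectra are out of scope.

Localization is the binomial Ascore: at peak depth d = 10 per 100 m/z
(p = 0.1), each placement's site-determining ions (those not shared by every
placement) are counted and scored as −10·log10 P(X ≥ k; n, p); the Ascore is
the gap between the best and runner-up placements, with a sentinel of 1000
when the peptide has a single Cys. For multi-remnant placements each site is
scored conservatively as the smallest gap against any placement that moves
that one remnant to an unmodified Cys. Localization depends only on peak
positions after depth filtering, so it is invariant to uniform intensity
scaling.

Confidence filtering is target–decoy with whole-protein sequence reversal.
Target and decoy candidates compete per spectrum (the spectrum keeps its
single best PSM, ties to the target), the modern competition form of the
method; with a 0.8 Da tolerance the reversed copy of the true peptide is
nearly isobaric with correlated fragments, and separate target/decoy searches
would overestimate the decoy tail badly. q-values are
#decoys ≥ s / #targets ≥ s, monotonized, applied at 5% on the peptide tier;
protein scores are each protein's best retained peptide score, filtered the
same way at 2%. An empty decoy set yields zero q-values with an explicit
"uncalibrated" warning rather than an error.

## Aggregation rules

One record per (protein, 1-based site). High confidence requires observation
in ≥ 2 distinct biological replicates; digestion conditions within one
replicate deliberately do not count (configurable). PSMs with Ascore < 13
(roughly a p-gap of 0.05) support protein-level evidence but not site
records. Sites on annotated proteins are catalytic iff they equal an
annotated catalytic Cys; protein identification uses ≥ 3 unique peptide
forms per sample.

The packaged `data/table1_sites.tsv` is a curated transcription of the
published labeling-site summary for HEK 293T lysate (one row per protein ×
site with the high-confidence and non-catalytic flags); per-protein
annotations (class, catalytic Cys) are derived from it. The headline counts
recomputed from it — 43 DUB-class proteins with high-confidence sites, 11
with high-confidence non-catalytic sites, 27 USP-class proteins, 4 UCHL1
sites — are the desk-scale reference values.

## Enrichment model

`FeatureEnrichment` fits the voom chain on a proteins × samples feature-count
matrix with an intercept + condition design (no batch terms; the comparison
is a single probe-vs-control contrast). Features are unique
(sequence, modification set, charge) triples per protein per sample; rows
with fewer than 3 total features are discarded before fitting. log2-CPM uses
the +0.5 / +1 offsets; the mean–variance trend is a lowess (span 0.5, 3
robustifying iterations — the reference defaults) of √(residual sd) against
average log2 count, and weights are the predicted √sd at the fitted
log-count, raised to the −4th power. Residual sd is floored at 1e-8 before
trend fitting and such rows are flagged `zero_residual` in the output.

Prior df d₀ and prior variance s₀² come from closed-form moment matching of
log s² (solving trigamma(d₀/2) = var − trigamma(d/2) by Newton iteration);
when the observed spread of variances is no larger than expected under a
single common variance the fit falls back to d₀ = ∞ (common-variance limit)
with a warning — with 3 vs 3 NB samples of similar abundance this is the
usual outcome and matches what the reference implementation does. The
implementation agrees with Bioconductor limma-voom to ~1e-3 on coefficients
and t statistics in both the finite and infinite-d₀ regimes (cross-checked
in the test suite by calling `Rscript`).

Library-size normalization is total count per sample, no TMM — deliberate,
because probe and control libraries differ by construction. Consequence:
when a sizeable fraction of total signal is truly enriched, background
proteins shift to slightly negative log2FC and can reach significance in the
depletion direction; enrichment calls should be read from the positive side
of the volcano (q threshold plus positive log2FC), which in the simulations
recovers the planted targets with high precision.

## Synthetic data: what it emulates, what it does not

The generator emulates the study design: a probe condition against a
negative-control probe, three biological replicates per condition,
negative-binomial feature counts (mean 50, dispersion 0.2 — overdispersion
consistent with count data that voom is designed for), a log2 enrichment
effect of 3 on true targets, and 10% of proteins as DUB-like true targets
(the same enriched fraction used in the calibration conditions). DUB-like
proteins embed their catalytic Cys in a 45-residue K/R-free window with Glu
every ~8 residues, reproducing the long-tryptic-peptide problem of USP
active sites: the tryptic active-site peptide exceeds the 40-residue window
while the Glu-C sub-peptide falls inside it. The probe labels catalytic
sites with probability 0.9 per replicate; every Cys in both conditions picks
up background labeling at rate 0.05, modeling electrophile promiscuity that
the control shares. Spectra keep each theoretical b/y ion with probability
0.7, add 5 uniform noise peaks, and jitter the precursor within ±3 ppm.

Not emulated: intensity structure beyond presence/absence, retention time,
co-isolation/chimeric spectra, isotope errors, and real proteome sequence
composition (sequences are i.i.d. draws from average amino-acid
frequencies, Cys ≈ 1.4%). Passing tests therefore demonstrate correctness
of the algorithms under the assumed noise model, not performance on real
instrument data.

All randomness flows through one `numpy` Generator seeded from the config;
identical configs reproduce byte-identical outputs.

## Problem sizes used in validation

The validation scripts use desk-scale sizes chosen to give stable Monte
Carlo estimates: 1000 random sequences for the digestion oracle and the
partition check; 200 simulated 500-protein null matrices for type-I error
(accepted band 0.03–0.07 at α = 0.05) and 50 for power (≥ 90% of planted
targets at q < 0.05); 20 simulated 40-protein experiments (~600 planted
peptide-yielding sites) for end-to-end recovery (≥ 95%); and 200 simulated
searches for the realized false-discovery proportion at the 5% peptide
threshold (≤ 0.10).

## Known limitations

- The matched-ion-count score ignores intensity and length calibration;
  modern rescoring would improve sensitivity but is out of scope.
- The DADPS/DDE remnant masses are constants taken on faith; their
  elemental compositions after cleavage are not public.
- Whether high-confidence status should also count distinct probe types is
  untested; replicate-only is assumed.
- Enrichment supports exactly one contrast; multi-contrast designs, batch
  effects, and intensity-based (LFQ) quantification are non-goals.
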