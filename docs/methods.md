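# Methods

## The scoring framework

`arvcurate` implements the semiquantitative evidence framework used by gene
curation expert panels to grade gene–disease validity, instantiated for
arrhythmogenic right ventricular cardiomyopathy (ARVC). Evidence for a
gene–disease pair is scored on an 18-point scale split into a genetic
subtotal (cap 12) and an experimental subtotal (cap 6):

* **Case-level variant evidence.** Each proband observation resolves to a
  category from (inheritance, variant class, de novo status, phase):
  predicted/proven null variants (default 1.5, range 0–3, category cap 10),
  other variants with evidence of gene impact (0.1, 0–1.5, cap 7), de novo
  non-null variants (0.5), and the biallelic in-trans (2) and phase-unknown
  (1) categories for recessive disease. Adjudicated awards recorded in a
  curation file take precedence over defaults; an award outside its
  category range is an error, never silently clamped — these files record
  panel decisions, and silent modification would hide data errors.
* **Segregation.** Family LOD scores are either published values (passed
  through) or estimated from counted informative meioses as n·log₁₀2 — the
  likelihood-ratio contribution of n phenotype-concordant genotyped
  transmissions (proband excluded) under full penetrance with no
  phenocopies. LODs are summed per sequencing approach and binned:
  candidate-gene LOD 2–3 → 1 point, 3–5 → 2, ≥5 → 3; exome/genome studies
  earn half, reflecting the weaker prior of a genome-wide search.
  Segregation caps at 3 points. No likelihood-based pedigree computation is
  attempted; only counting or pass-through.
* **Case-control.** Adjudicated per-study points in [0, 6], summed, cap 12.
* **Experimental evidence** in three capped groups: protein function
  (biochemical function / interaction / expression, cap 2), functional
  alteration in patient or non-patient cells (cap 2), and model systems
  plus rescue (cap 4). The ARVC panel rule layered on top: a model-system
  or rescue item whose phenotype the panel judged *not* consistent with
  ARVC contributes zero points regardless of its award. We apply the gate
  to the whole models+rescue group, including cell-culture models, since
  all are "model systems" under the panel's phenotype rule; the consistency
  boolean is curator input, never inferred.

All constants live in `data/score_matrix.yaml` (user-overridable; every
pipeline run logs its SHA-256). Points are exact decimals on a 0.05 grid —
never binary floats — so half-point totals such as 9.5 survive arithmetic
and caps exactly.

### Classification bands

Total 0 → No Known Relationship; (0, 7) → Limited; [7, 12) → Moderate;
[12, 18] → Strong, upgraded to Definitive when the association has been
replicated over time across independent cohorts. Published band wordings
("1–6", "12–18") leave (6, 7) unstated; we assign it to Limited so every
representable total classifies, and conservatively so — 6.5 points does not
reach Moderate. Disputed and Refuted are expert-panel overrides that
dominate any total. Replication is a stored panel judgment; an advisory
helper (≥2 independent publications spanning ≥3 years) is provided but
never applied automatically, because the operational threshold used by
panels is not standardized.

### Dual curation and consensus

Two teams assemble records independently; each is scored and classified
with overrides and the replication upgrade suppressed (both are panel-level
decisions). Concordance is defined on these preliminary *bands*, not raw
points — point differences are reported but do not affect the match flag.
Consensus applies the panel flags only to a concordant pair; a discordant
pair surfaces as `needs_panel_review`, never auto-resolved.

## Allele-frequency admissibility

A candidate variant in a dominant disease of prevalence P cannot credibly
exceed

    AF_max = P × max_allelic_contribution × (1 / penetrance) × inheritance_factor

Shipped ARVC defaults: prevalence 1/1000, max allelic contribution 0.1,
penetrance 0.5, inheritance factor 0.5 (alleles per affected genotype for
monoallelic disease), giving AF_max = 1×10⁻⁴. These are configuration, not
ground truth — panels publish the existence of a cutoff more often than its
parameters — and every run logs the values used.

Observed counts are compared through the filtering allele frequency: the
one-sided lower confidence bound (default 95%) on the true frequency given
ac alleles among an, obtained by inverting the Poisson tail
P(X ≥ ac | λ) = 1 − confidence; the inversion is exact via
λ = χ²(1−confidence, 2·ac)/2. The bound is 0 with no observations, so a
variant absent from reference populations always passes. The worst
(highest) bound across populations with adequate depth (allele number
≥ 2000 by default) decides pass/fail and is named in the assessment;
when no population is adequately sampled the verdict is explicitly
undetermined rather than a silent pass. Founder variants can be exempted
per variant with a logged justification, since a bona fide founder allele
legitimately exceeds generic cutoffs in its founder region. The assessment
is informational on the evidence record: whether an inadmissible variant is
excluded from scoring remains a curator decision.

## Synthetic data and the packaged fixture

Every generator records ground truth at construction time via an
independent tally — plain running sums with caps applied once at the end,
re-derived inside the synthetic module, which imports no scoring module (a
test audits this). Curation generators draw evidence counts and awards
uniformly within matrix ranges, then add or remove items until the tally
lands in the requested band; segregation simulation emits families with a
known informative-meiosis count (optionally thinned by a noise fraction
marking meioses uninformative); variant-table generation emits exactly the
requested per-gene significance-class counts in seeded shuffled order.

The packaged 26-gene ARVC fixture encodes the published panel outcome: six
definitive genes (PKP2, DSP, DSG2, DSC2, JUP, TMEM43; all replicated), two
moderate (DES 9.5 points, PLN 11), ten limited (SCN5A at 6 the highest),
LDB3 disputed, RYR2 refuted, and six sarcomeric genes with no evidence.
Totals for DES, PLN and SCN5A are pinned to the published values; the
genetic-vs-experimental split of every gene is a synthetic placeholder
constrained to the published band and marked provisional, since gene-level
subscores were published only in supplementary material. Team-B records are
the same evidence shifted by half a point within the band, modelling
concordant-but-not-identical independent curation. The bundled
variant-class table transcribes the published aggregate distribution of
ARVC-associated ClinVar assertions — 450 of 462 P/LP variants (97.4%) in
the five desmosomal genes, 5 (1.1%) in limited-evidence genes (1 CTNNA3,
3 LMNA, 1 TGFB3), the remaining 7 on the PLN/TMEM43 side — with synthetic
VUS/benign filler rows for realism; it is a transcription, not a ClinVar
re-download.

What passing tests on this fixture do **not** show: the fixture encodes the
published judgments, so reproducing its category counts validates the
scoring arithmetic, caps, band edges and pipeline plumbing — not the
literature appraisal that produced those judgments, which is out of scope.

## Numerical choices

* Decimal points (0.05 granularity) throughout scoring; LODs are floats
  (log-scale, no exactness requirement) converted to Decimal only at bin
  lookup.
* Segregation bins take the highest threshold met; bin edges are inclusive
  at their lower bound.
* Confirmed and assumed de novo occurrence score identically in the shipped
  matrix; a panel that down-weights assumed de novo can edit the config.
* Deterministic everything: record serialization is canonical (sorted keys,
  schema version tag), report files are byte-identical across reruns, and
  all generators are seeded `random.Random` instances.

## Problem sizes

The property suites run 1,000 random ≤6-item evidence sets against a flat
brute-force summation and 200 generated curations across all bands against
their construction-time tallies; both complete in seconds and the whole
suite in well under a minute.

## Known limitations

* The shipped frequency-cutoff parameters and the de novo handling are
  defensible defaults, not reconstructions of any specific panel's
  unpublished settings.
* Case-control points are accepted as adjudicated values; no statistical
  scoring of allele counts is performed.
* The fixture's per-gene evidence items are placeholders: correct in band
  and total, fictional in composition.
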