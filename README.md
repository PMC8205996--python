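# arvcurate

Semiquantitative gene–disease clinical-validity curation for
arrhythmogenic right ventricular cardiomyopathy (ARVC).

Diagnostic sequencing panels for ARVC list anywhere from 11 to 46 genes,
yet for many of them the published evidence is thin, dated, or belongs to a
different disease altogether. Because a pathogenic variant in an
"ARVC gene" is itself a major diagnostic criterion, an inflated gene list
directly causes overdiagnosis and misdirected cascade testing. This package
implements, as a tested library plus CLI, the evidence-point machinery an
expert panel uses to grade each gene–disease claim — for curators,
clinical-genetics panels and methodologists who want the arithmetic of such
a reappraisal reproducible and auditable.

## The framework

Evidence for a gene–disease pair scores on an 18-point scale:

* **Genetic evidence (cap 12):** case-level variant points (null variants
  default 1.5, range 0–3, category cap 10; other variants 0.1, 0–1.5, cap
  7; de novo and biallelic categories), segregation points from family LOD
  scores (LOD ≈ n·log₁₀2 for n informative meioses; binned 2→1, 3→2, 5→3
  points, cap 3), and case-control points (0–6 per study, cap 12).
* **Experimental evidence (cap 6):** function (cap 2), functional
  alteration (cap 2), model systems and rescue (cap 4) — with the
  ARVC-specific rule that a model whose phenotype is not convincingly ARVC
  contributes zero points.
* **Classification:** total 0 → No Known Relationship; (0,7) → Limited;
  [7,12) → Moderate; [12,18] → Strong, upgraded to Definitive with
  replication across cohorts. Disputed/Refuted are expert overrides that
  beat any point total.

Candidate variants are screened by allele frequency: a variant passes when
its filtering allele frequency (95% lower Poisson bound on the observed
population frequency) does not exceed the maximum credible frequency
`prevalence × max_allelic_contribution / penetrance × inheritance_factor`.

All constants ship in an editable YAML matrix; runs log its checksum.

## Worked example

```python
from decimal import Decimal
import arvcurate as av

matrix = av.default_matrix()
record = av.GeneDiseaseRecord(
    gene_symbol="DES",
    proband_evidence=[
        av.ProbandVariantEvidence(
            proband_id="fam1-III:2",
            variant_class="predicted_or_proven_null",
            awarded_points=Decimal("3"),
        ),
        av.ProbandVariantEvidence(
            proband_id="fam2-II:1",
            variant_class="other_with_gene_impact",
            awarded_points=Decimal("1.5"),
        ),
    ],
    segregation_evidence=[
        av.SegregationEvidence(family_id="fam1", informative_meioses=11)
    ],
    experimental_evidence=[
        av.ExperimentalEvidenceItem(category="expression",
                                    awarded_points=Decimal("2")),
    ],
)
bd = av.score_record(record, matrix)
print(bd.genetic_subtotal, bd.experimental_subtotal, bd.total,
      bd.classification.value)
```

prints

```
6.5 2 8.5 moderate
```

— 4.5 variant points plus 2 segregation points (11 meioses give LOD 3.31,
the 3–5 bin) make the genetic subtotal 6.5; with 2 experimental points the
total of 8.5 lands in the Moderate band [7, 12).

The packaged 26-gene fixture reproduces the panel outcome end to end:

```
$ arvcurate simulate --out /tmp/fixture
$ arvcurate run-all /tmp/fixture --out /tmp/reports
{"final_classes": {"definitive": 6, "disputed": 1, "limited": 10,
  "moderate": 2, "no_known_relationship": 6, "refuted": 1}, "n_genes": 26}
```

Six genes (PKP2, DSP, DSG2, DSC2, JUP, TMEM43) are definitive, DES and PLN
moderate, ten limited, RYR2 refuted, LDB3 disputed — 18 of 26 published
"ARVC genes" without convincing evidence. `/tmp/reports` holds per-gene
score breakdowns, the dual-curation concordance table (fully concordant)
and the final classification TSV.

Other subcommands: `score`, `classify`, `freq-filter`, `concordance`,
`clinvar-summary`, `simulate --target <band>`.

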