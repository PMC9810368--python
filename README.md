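# morphosca

Structural covariance analysis (SCA) of regional brain morphometry, built
around a three-group clinical design: healthy controls (HC), essential-tremor
patients before stereotactic thalamotomy (ET_pre), and the same patients one
year after (ET_post).

SCA asks how a morphometric measure — cortical thickness (CT, mm), surface
area (SA, mm²) or mean curvature (MC, 1/mm) — co-varies *across subjects*
between pairs of brain regions. Because one covariance value exists per group
(not per subject), group comparison and clinical linkage need dedicated
machinery, which this package implements:

- **Edge-wise SCA** — for P = 87 regions (68 Desikan-Killiany cortical parcels
  plus 19 noncortical volumes) and each group, the Pearson correlation R over
  subjects for every region pair ("edge"), after regressing age, gender and
  total gray matter volume out of each regional measure within group.
  Edges whose coefficient of determination stays below R² < 0.2
  (|R| < √0.2 ≈ 0.4472) in *every* group are excluded as noise.
- **Permutation group contrasts** — the per-edge difference ΔSC (HC − ET_pre,
  or ET_post − ET_pre) is compared with a null built by reshuffling subjects
  across groups (default 300,000 realizations), with the add-one estimator
  p = (1 + #{|Δ_null| ≥ |Δ_obs|}) / (1 + n_perm) and Benjamini–Hochberg FDR
  correction per (measure, contrast) family. A Wilcoxon rank-sum z compares
  the groups' whole SC distributions.
- **Leave-out clinical link** — each significant edge's group difference is
  recomputed after excluding the r = 1..10 patients at either end of a
  clinical score (baseline tremor score TSTH, or its percent improvement),
  giving curves SC₁(r) (low-score end excluded) and SC₂(r) (high-score end).
  With y(r) = |SC₂(r)| − |SC₁(r)|, the summary metrics are μ_SC = mean(y) and
  β_SC = the OLS slope of y on r; an edge is clinically associated iff both
  are strictly positive.
- **Cross-measure covariance** — per cortical region, the across-subject
  correlation C between two measures (CT/SA, CT/MC, SA/MC), contrasted
  between groups with the same permutation + FDR machinery over the 68
  regional tests (no noise thresholding).
- **Synthetic studies** — a generator that emulates the full design
  (29/34/34 subjects, paired pre/post draws, confound effects, clinical
  scores matching the reported cohort marginals, planted covariance
  differences and severity-dependent links), so every stage is testable
  with known ground truth and no data download.

## Worked example

`examples/03_clinical_link.py` plants a severity link — patient-group edge
coupling ρᵢ = 0.1 + 0.6·(standardized TSTH), against a strong 0.8 coupling in
controls — and runs the leave-out procedure:

```
SC1(r) (excluding least impaired): 0.744 0.744 0.744 0.744 0.741 ...
SC2(r) (excluding most impaired):  0.745 0.747 0.747 0.747 0.747 ...

mu_SC = 0.0057, beta_SC = 0.00102 -> associated: True
without a planted link: mu_SC = -0.0009, beta_SC = -0.00007 -> associated: False
```

Excluding the most impaired patients lowers the patients' edge correlation
(they carried the strongest coupling), which widens the HC-vs-patient
difference: SC₂ sits above SC₁ and grows with r, so μ_SC > 0 and β_SC > 0
and the edge is classified as tracking severity. Without the planted link
both metrics hover at zero and the edge is not flagged.

`examples/02_edgewise_contrast.py` shows the edge-wise stage on a synthetic
study (noise mask retains 322 of 3,741 edges; the planted SA differences are
recovered among the FDR-significant set), and `examples/05_full_pipeline.py`
runs everything end to end, writing result CSVs and a reproducibility
manifest.

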