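# immunomethyl

Methylation-derived immune-cell profiling for matched case–control blood
studies.

A shift in the composition of circulating leukocytes — more neutrophils,
fewer NK cells and other lymphocytes — accompanies many cancers, including
triple-negative breast cancer. Because DNA methylation is cell-type specific
and chemically stable, the composition of archival blood DNA can be read off
its methylation profile without intact cells. This package implements that
immunomethylomic workflow end to end:

- **Marker selection** (`marker_panel`): from a reference methylome of sorted
  leukocyte subtypes (NK, CD4+ T, CD8+ T, Treg, monocytes, neutrophils,
  B cells), select *immune cell-specific unmethylated sites* (ISUS) — CpGs
  with beta ≤ `low_thr` in one subtype and ≥ `high_thr` in all others — plus
  opposing neutrophil-methylated and pan-lymphocyte-methylated sets, ranked
  by the specificity margin (gap between the two groups' betas). A curated
  published panel (21 ISUS + 3 + 3 mdNLR sites, GRCh37) ships with the
  package.
- **Proxy scoring** (`proxy_scores`): per sample, `unmeth = 1 − β` at an ISUS
  proxies the target subtype's ratio; the methylation-derived
  neutrophil-to-lymphocyte ratio is
  `mdNLR = β(neutrophil CpG) / β(pan-lymphocyte CpG)` for each of the 3 × 3
  marker pairs (nine scores); NK-to-neutrophil ratios are ratios of
  unmethylation proxies.
- **Reference-based deconvolution** (`deconvolution`): per-sample proportions
  of six cell types by constrained projection,
  `ŵ = argmin ‖y − Xw‖² s.t. w ≥ 0, Σw = 1`, and
  `mdNLR_ref = w_Neu / (w_NK + w_TCD4 + w_TCD8 + w_B)`.
- **Matched inference** (`matched_stats`): 1:1 conditional logistic
  regression via the within-pair-difference likelihood
  `ℓ(β) = Σᵢ log σ(dᵢᵀβ)` (Newton, separation detection), odds ratios per
  0.1 methylation increment with Wald CIs, Mann–Whitney AUC with DeLong CIs,
  Holm step-down adjustment, backward selection (stay at p ≤ 0.20), Harrell
  optimism-bootstrap AUC validation, and Wilcoxon / Mann–Whitney /
  Jonckheere–Terpstra / Spearman tests.
- **Synthetic cohorts** (`synthetic_cohort`): matched case–control cohorts as
  noisy convex mixtures of reference profiles with Dirichlet-distributed
  proportions, calibrated to published group shifts (neutrophils 49% vs 45%,
  pan-lymphocytes 36% vs 40.3%, NK cells the largest relative drop), plus a
  prospective-arm single-locus ddPCR-style NK readout.

## Worked example

```python
from immunomethyl import synthetic_cohort as sc, proxy_scores as ps, \
    matched_stats as ms, deconvolution as dc
from immunomethyl.marker_panel import build_panel

ref = sc.simulate_reference(n_probes=300, markers_per_type=8, seed=12)
panel = build_panel(ref, k_per_type=8)
betas, sheet, truth = sc.simulate_cohort(ref, sc.CohortConfig(n_pairs=231, seed=0))

cohort = ms.MatchedCohort(sheet, age_tolerance=1.0)
mdnlr = ps.compute_mdnlr(betas, panel.neu_probes[:3], panel.panlym_probes[:3])
assoc = ms.univariable_associations(cohort, mdnlr.reindex(sheet.index))
print(assoc[["OR", "CI_low", "CI_high", "p_adj", "AUC"]].round(3).head(3))

X = dc.signature_from_panel(ref, panel, max_probes=50)
props = dc.deconvolve(betas, X).proportions
print(dc.mdnlr_ref(props).groupby(sheet.is_case).mean().round(2).to_dict())
```

prints

```text
                          OR  CI_low  CI_high  p_adj    AUC
exposure
cg00000057.cg00000059  1.231   1.149    1.319    0.0  0.683
cg00000057.cg00000060  1.228   1.144    1.318    0.0  0.672
cg00000057.cg00000061  1.239   1.150    1.335    0.0  0.675
{False: 1.17, True: 1.43}
```

Each row is one mdNLR score (neutrophil probe . lymphocyte probe): the odds
ratio of being a case per 0.1 increase in the score, its 95% Wald CI, the
Holm-adjusted p-value over the nine-score family, and the score's AUC for
discriminating cases from controls. The final line shows the
deconvolution-based mdNLR_ref averaged within controls (1.17) and cases
(1.43): the case excess in the neutrophil-to-lymphocyte balance is recovered
by both routes.

The same pipeline is scriptable from the shell:

```sh
immunomethyl simulate --seed 3 --n-pairs 100 --out run/
immunomethyl select-markers --reference run/reference.tsv --out run/panel
immunomethyl quantify --panel run/panel.yaml --betas run/betas.tsv --out run/scores.tsv
immunomethyl associate --cohort run/samples.csv --scores run/scores.tsv \
    --block mdnlr --out run/assoc.tsv
immunomethyl report --associations run/assoc.tsv
```

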