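# Curated blood leukocyte marker panel (Illumina 450K probe ids, GRCh37).
# 21 ISUS (three per subtype) plus the opposing neutrophil-/pan-lymphocyte-
# methylated mdNLR sites, as published from sorted-leukocyte methylomes and a
# TNBC case-control blood methylation study. Margins are not published (NaN).
isus:
  B:
  - {probe_id: cg07721872, target: B, orientation: target-unmethylated, margin: .nan}
  - {probe_id: cg04838847, target: B, orientation: target-unmethylated, margin: .nan}
  - {probe_id: cg27565966, target: B, orientation: target-unmethylated, margin: .nan}
  Mono:
  - {probe_id: cg23244761, target: Mono, orientation: target-unmethylated, margin: .nan}
  - {probe_id: cg05923857, target: Mono, orientation: target-unmethylated, margin: .nan}
  - {probe_id: cg24788483, target: Mono, orientation: target-unmethylated, margin: .nan}
  TCD4:
  - {probe_id: cg05617307, target: TCD4, orientation: target-unmethylated, margin: .nan}
  - {probe_id: cg14477767, target: TCD4, orientation: target-unmethylated, margin: .nan}
  - {probe_id: cg20737812, target: TCD4, orientation: target-unmethylated, margin: .nan}
  TCD8:
  - {probe_id: cg18857618, target: TCD8, orientation: target-unmethylated, margin: .nan}
  - {probe_id: cg00219921, target: TCD8, orientation: target-unmethylated, margin: .nan}
  - {probe_id: cg06419846, target: TCD8, orientation: target-unmethylated, margin: .nan}
  Neu:
  - {probe_id: cg25006077, target: Neu, orientation: target-unmethylated, margin: .nan}
  - {probe_id: cg25739938, target: Neu, orientation: target-unmethylated, margin: .nan}
  - {probe_id: cg05398700, target: Neu, orientation: target-unmethylated, margin: .nan}
  NK:
  - {probe_id: cg08326410, target: NK, orientation: target-unmethylated, margin: .nan}
  - {probe_id: cg23855986, target: NK, orientation: target-unmethylated, margin: .nan}
  - {probe_id: cg23060465, target: NK, orientation: target-unmethylated, margin: .nan}
  Treg:
  - {probe_id: cg04920616, target: Treg, orientation: target-unmethylated, margin: .nan}
  - {probe_id: cg02033323, target: Treg, orientation: target-unmethylated, margin: .nan}
  - {probe_id: cg07499259, target: Treg, orientation: target-unmethylated, margin: .nan}
neu_methylated:
- {probe_id: cg09993145, target: neutrophil, orientation: target-methylated, margin: .nan}
- {probe_id: cg10825315, target: neutrophil, orientation: target-methylated, margin: .nan}
- {probe_id: cg23954655, target: neutrophil, orientation: target-methylated, margin: .nan}
panlym_methylated:
- {probe_id: cg04552418, target: pan-lymphocyte, orientation: target-methylated, margin: .nan}
- {probe_id: cg13580758, target: pan-lymphocyte, orientation: target-methylated, margin: .nan}
- {probe_id: cg26942829, target: pan-lymphocyte, orientation: target-methylated, margin: .nan}
provenance:
  source: published sorted-leukocyte methylome panel (450K, GRCh37)
  coordinates:
    cg09993145: {chrom: '1', pos: 25291905, gene: RUNX3}
    cg10825315: {chrom: '14', pos: 81425912, gene: TSHR}
    cg23954655: {chrom: '13', pos: 99223562, gene: STK24}
    cg04552418: {chrom: '1', pos: 31956405, gene: null}
    cg13580758: {chrom: '4', pos: 57824450, gene: REST}
    cg26942829: {chrom: '6', pos: 13408158, gene: GFOD1}
    cg07721872: {chrom: '16', pos: 87735256, gene: LOC100129637}
    cg04838847: {chrom: '8', pos: 110587155, gene: GOLSYN}
    cg27565966: {chrom: '16', pos: 28943198, gene: CD19}
    cg23244761: {chrom: '6', pos: 161796850, gene: PARK2}
    cg05923857: {chrom: '10', pos: 114911615, gene: TCF7L2}
    cg24788483: {chrom: '10', pos: 114911652, gene: TCF7L2}
    cg05617307: {chrom: '10', pos: 121413182, gene: BAG3}
    cg14477767: {chrom: '4', pos: 170195438, gene: null}
    cg20737812: {chrom: '15', pos: 86336631, gene: KLHL25}
    cg18857618: {chrom: '2', pos: 87048489, gene: CD8B}
    cg00219921: {chrom: '2', pos: 87012810, gene: CD8A}
    cg06419846: {chrom: '11', pos: 66083697, gene: CD248}
    cg25006077: {chrom: '3', pos: 152176018, gene: MBNL1}
    cg25739938: {chrom: '2', pos: 9528072, gene: CPSF3}
    cg05398700: {chrom: '14', pos: 102677141, gene: WDR20}
    cg08326410: {chrom: '19', pos: 55314884, gene: KIR2DL4}
    cg23855986: {chrom: '11', pos: 129980502, gene: APLP2}
    cg23060465: {chrom: '8', pos: 141625545, gene: EIF2C2}
    cg04920616: {chrom: 'X', pos: 49121288, gene: FOXP3}
    cg02033323: {chrom: 'X', pos: 49005257, gene: FOXP3}
    cg07499259: {chrom: '1', pos: 12188502, gene: TNFRSF8}
  group_mean_beta:
    # published case / control mean betas at the mdNLR sites
    cg09993145: {case: 0.56, control: 0.51}
    cg10825315: {case: 0.43, control: 0.40}
    cg23954655: {case: 0.48, control: 0.44}
    cg04552418: {case: 0.36, control: 0.41}
    cg13580758: {case: 0.36, control: 0.40}
    cg26942829: {case: 0.36, control: 0.40}
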