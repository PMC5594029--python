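# pulmolip

Analysis toolkit for lung-tissue shotgun lipidomics: identification and
quantification filters, mol% normalization, discriminative lipid panels
with a signed-sum score and ROC evaluation, unsupervised exploration
(complete-linkage clustering, PCA), and PLS2 (NIPALS) regression linking
lipid profiles to clinical covariates and histology scores with
patient-grouped Q² cross-validation. A synthetic-cohort generator
reproduces the statistical structure the analysis assumes, so the whole
pipeline is testable without external data.

## Package layout

| module | contents |
| --- | --- |
| `pulmolip.nomenclature` | lipid name parsing/formatting (`PC [32:0]`, `Cer [42:1;0]`, `PE-O [36:4]`, sn-resolved names collapsed to sum composition) |
| `pulmolip.matrix` | `LipidomeMatrix`: samples × lipids grid with explicit missingness and mol% closure checks |
| `pulmolip.ingest` | mass-accuracy / blank-ratio identification filters, internal-standard quantification, mol% normalization, presence filters |
| `pulmolip.panel` | panel selection (Welch t-test + log2 fold-change gates), the signed-sum discrimination score, ROC/AUC, Mann-Whitney U |
| `pulmolip.explore` | complete-linkage hierarchical clustering (Newick export), PCA, clade correlation summaries |
| `pulmolip.pls` | min–max scaling, NIPALS PLS2, patient-grouped segment cross-validation with the Q² ≥ 0.0975 significance rule, correlation circles, categorical response evaluation |
| `pulmolip.simulate` | configurable synthetic cohorts with planted effects and ground truth; `paper_like_cohort` preset (26 patients / 43 samples / 311 lipids) |

## CLI

```bash
pulmolip simulate --seed 0 --out cohort/
pulmolip quantify --intensities F.csv --standards IS.csv --blanks B.csv \
    --max-ppm 2.5 --blank-ratio 10 --out molpct.csv
pulmolip panel --matrix molpct.csv --labels labels.csv \
    --group1 tumour --group2 alveolar --p 0.01 --log2fc 1 --out panel.csv
pulmolip score --matrix molpct.csv --panel panel.csv --labels labels.csv \
    --out scores.csv --roc-out roc.csv
pulmolip explore --matrix molpct.csv --what cluster --out tree
pulmolip pls --matrix molpct.csv --meta metadata.csv --config pls.yaml --out out/
```

All file formats are plain CSV (wide lipid tables use empty cells for
missing values); trees are written as Newick; the PLS config is YAML with
keys `responses`, `n_components`, `n_segments`, `seed`.

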