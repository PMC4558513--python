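# mlpa-ddr

Computational pipeline for an ATM-p53 functional assay in chronic
lymphocytic leukemia (CLL) based on reverse-transcriptase multiplex
ligation-dependent probe amplification (RT-MLPA). CLL cells are assayed
with and without DNA damage (5 Gy irradiation); the transcriptional
response of a 10-gene panel distinguishes tumors that are
**ATM/p53-functional**, **p53-dysfunctional** or **ATM-dysfunctional** —
a functional read-out that complements FISH and sequencing of *TP53* and
*ATM*, and can flag DNA-damage-response defects that have no detectable
mutation.

The package is aimed at assay developers and computational biologists who
need the full analysis stack: signal normalization, fold-induction
quantification, discriminative probe selection, the nested two-stage SVM
classifier, evaluation against genotype labels, and a synthetic-cohort
simulator (including clone-dilution limit-of-detection scans) so that
every stage is testable without patient material.

## Method

For each sample and condition, probe signals are normalized within-sample
to the geometric mean of four irradiation-independent housekeeping genes
(*Diablo*, *Aif*, *Gusb*, *Parn*):

```
norm(probe) = signal(probe) / geomean(housekeeping signals)
```

The **fold induction** (FI) per probe is the ratio of normalized
expression in the irradiated aliquot over the paired non-irradiated one.
The classification panel holds ten genes in four response clusters:

| cluster | genes | behaviour |
|---|---|---|
| I | FAS, Bax, BBC3, CDKN1A, PCNA, FDXR | induced by irradiation when ATM-p53 signalling is intact; blunted in TP53- or ATM-defective cells |
| II | NME1 | up in TP53-defective vs ATM-defective |
| III | MYC, PYCR1 | up in TP53-defective vs ATM-defective |
| IV | ACSM3 | down in TP53-defective vs ATM-defective |

Each gene is measured by several candidate probes; per gene, the probe
with the smallest Mann-Whitney p-value in the relevant genotype contrast
is kept (cluster I: WT vs biallelic-defective; clusters II–IV:
TP53-defective vs ATM-defective), with exact-p ties broken by the larger
difference of group geometric-mean FIs.

Classification is a nested two-stage linear SVM on log2(FI), standardized
per feature: stage 1 calls functional vs dysfunctional from the six
cluster-I genes; only dysfunctional samples reach stage 2, which calls
p53- vs ATM-dysfunctional from all ten genes and is trained exclusively
on biallelic TP53-/ATM-defective samples. Evaluation reports
genotype-by-call confusion counts plus sensitivity (any dysfunction,
TP53-specific, ATM-specific) and specificity.

## Worked example

```python
from mlpa_ddr import (
    GeneratorConfig, simulate_cohort, compute_fi_table, select_probes,
    resolve_profile, fit, cross_validate, default_panel,
)

panel = default_panel()
measurements, metadata = simulate_cohort(GeneratorConfig(n_per_group=30, seed=1))
fi = compute_fi_table(measurements, panel)            # probe x sample FI table
selection = select_probes(fi, metadata, panel)        # one probe per gene
profiles, _ = resolve_profile(fi, selection)          # gene-keyed feature vectors
model = fit(profiles, metadata, panel)                # nested two-stage SVM
report = cross_validate(profiles, metadata, panel)    # leave-one-out

print(selection.probe_for("MYC"), f"p={selection.selection['MYC'].p_value:.3g}")
for name in ("sensitivity_tp53", "sensitivity_atm", "specificity"):
    print(name, f"{report.percent(name)}%")
```

prints

```
MYC_p1 p=8.89e-10
sensitivity_tp53 90%
sensitivity_atm 93%
specificity 100%
```

i.e. on this synthetic cohort the most discriminative MYC probe separates
TP53- from ATM-defective samples at p ≈ 9e-10, and held-out (leave-one-out)
classification recovers 27/30 TP53-defective, 28/30 ATM-defective and all
30 wild-type samples. The same stages are available as a shell pipeline:

```bash
mlpa-ddr simulate --n-per-group 30 --seed 1 --out-signals signals.tsv --out-meta meta.tsv
mlpa-ddr normalize --signals signals.tsv --out fi.tsv
mlpa-ddr select-probes --fi fi.tsv --meta meta.tsv --out selection.json
mlpa-ddr fit --fi fi.tsv --meta meta.tsv --selection selection.json --out model.json
mlpa-ddr predict --model model.json --selection selection.json --fi fi.tsv --out calls.tsv
mlpa-ddr evaluate --calls calls.tsv --meta meta.tsv --out report.json
```

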