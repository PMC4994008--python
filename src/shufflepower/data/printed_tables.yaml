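# Transcribed published group summary statistics (mean +/- SEM) used by the
# standard comparison report.  Units: body weight in grams, leptin in ng/ml,
# LH:T dimensionless.
comparisons:
  - kind: percent_difference
    source: "F1 male terminal body weight, maternal HFD vs control"
    control: {label: "F1 male CD", mean: 434, sem: 4, n: 13}
    treated: {label: "F1 male maternal HFD", mean: 478, sem: 10, n: 13}
  - kind: percent_difference
    source: "F1 female terminal body weight, maternal HFD vs control"
    control: {label: "F1 female CD", mean: 260, sem: 5, n: 10}
    treated: {label: "F1 female maternal HFD", mean: 278, sem: 4, n: 10}
  - kind: fold_ratio
    source: "F2 male LH:testosterone ratio, maternal-grandfather HFD vs control"
    control: {label: "F2 male control", mean: 0.07, sem: 0.01, n: 5}
    treated: {label: "F2 male MGF-HFD", mean: 0.21, sem: 0.04, n: 5}
  - kind: fold_ratio
    source: "F2 male plasma leptin, maternal-grandfather HFD vs control"
    control: {label: "F2 male control", mean: 2.5, sem: 0.3, n: 8}
    treated: {label: "F2 male MGF-HFD", mean: 5.0, sem: 0.8, n: 8}
  - kind: de_proportion
    source: "miRNA differential expression proportion (observed analysis)"
    n_significant: 1
    n_tested: 285
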