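# Demo pipeline: small simulated dataset, all stages enabled.
seed = 42
n_footprints = 20000

[simulate]
n_genes = 120
target_fraction = 0.3
multi_site_fraction = 0.2
lib_size_mean = 300000.0
n_replicates = 4
dispersion = 0.1

[simulate.effect_model]
stability = -1.0
te = 0.0

[panel_truth]
"miR-96" = 2.78
"miR-183" = 0.3
"let-7b" = 0.0

[thresholds]
fdr = 0.05
lfc = 0.5
context = -0.2

[steps]
simulate = true
scan = true
qc = true
de = true
stratify = true
panel = true
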