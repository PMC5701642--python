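"""Miniature replay of the model-simplification experiment.

Eight quasi-tangential sources, high sensor noise, and scanning leadfields
perturbed by 0 / 10 / 20 % relative Frobenius error emulate a cascade of
simplified forward models diverging from the reference.  The printed table
gives the median localization error per mismatch level for the array-gain
beamformer: the matched model stays at the ~0.55 mm grid floor and errors
grow (into the multi-millimeter range and beyond) with mismatch.
"""
import pandas as pd

from beamcascade import (ExperimentConfig, render_summary, run_experiment,
                         summarize_experiment)

cfg = ExperimentConfig(modality="eeg", n_reference_sources=8, n_source_nodes=800,
                       perturbation_levels=(0.0, 0.1, 0.2), noise_levels=("high",),
                       constraints=("unit_array_gain",),
                       orientation_classes=("quasi_tangential",),
                       duration_s=4.0, spike_onsets_s=(1.0, 2.6),
                       seed=21, replicates=2)
table = run_experiment(cfg)
print(f"{len(table)} result rows "
      "(sources x models x criteria x replicates)")

pd.set_option("display.width", 160)
print("\nmedian error (mm) by mismatch level:")
print(table.pivot_table(index="criterion", columns="model", values="error_mm",
                        aggfunc="median").round(2))

summary, _ = summarize_experiment(table)
print("\nrounded Tukey summaries (median-anchored whiskers, 40 mm display cap):")
print(render_summary(summary)[["model", "criterion", "n", "median_mm", "q1_mm",
                               "q3_mm", "n_outliers"]].to_string(index=False))
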