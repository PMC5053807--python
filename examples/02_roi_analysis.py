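"""ROI pattern-similarity change analysis on a simulated cohort.

Simulates a small cohort whose post-learning patterns carry an implanted
similarity change tracking each subject's remembered distances (Spearman
-0.6 in the effect region), then runs the full first- and second-level
ROI pipeline: cross-correlation with block exclusion, PS', Spearman model
fits, shuffle-null z, sign-flip group test, FDR over the ROI x model
family.
"""

from eventmap import roi_pipeline, simulate_cohort

route, subjects, rois = simulate_cohort(
    n_subjects=8, seed=5, effect_size=-0.6, noise_sd=0.3, grid_shape=(8, 8, 8)
)
table = roi_pipeline(subjects, rois, n_shuffles=2000, n_flips=2000, seed=9)
print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print()
print(
    "mean_z: average first-level shuffle-null z across subjects (negative =\n"
    "similarity increases for pairs remembered as close); p: one-tailed\n"
    "sign-flip p; p_fdr: corrected over all", len(table), "ROI x model tests.\n"
    "The implanted effect makes every model significant in the 'effect' region\n"
    "while the 'control' region stays at chance."
)
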