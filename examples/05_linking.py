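"""Stocking-Lord linking of a new calibration onto a reference metric.

Generates two populations — one answering anchor items on the reference
metric, one on a new metric offset by known constants (A=1.2, B=0.5) —
calibrates each from its own data, and recovers the constants by matching
anchor test characteristic curves.
"""

from probank import (CalibrationConfig, fit_grm, make_bank,
                     make_linking_design, stocking_lord, transform_bank)

anchors = make_bank(n_items=20, seed=17)
ref_data, new_data, truth = make_linking_design(
    anchors, unique_items=[], A=1.2, B=0.5, n_per_group=2000, seed=23)

cfg = CalibrationConfig(compute_se=False)
ref_bank = fit_grm(ref_data, cfg, metric_name="reference").bank
new_bank = fit_grm(new_data, cfg, metric_name="new").bank

constants = stocking_lord(new_bank, ref_bank)
print(f"true      A={truth['A']:.3f}  B={truth['B']:.3f}")
print(f"recovered A={constants.A:.3f}  B={constants.B:.3f} "
      f"({len(constants.anchor_ids)} anchors)")

linked = transform_bank(new_bank, constants, metric_name="reference")
print("linked bank metric:", linked.metric_name)
# After transformation, scores from the new instrument are directly
# comparable with reference-metric scores (theta -> A*theta + B).
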