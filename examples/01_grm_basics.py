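"""GRM building blocks: category probabilities, information, EAP scores.

Builds a tiny five-item bank by hand, scores one response pattern, and
reports the trait estimate on the theta and T metrics.
"""

import numpy as np

from probank import (ItemBank, ItemParameters, category_probabilities,
                     eap_score, item_information, to_t_metric)

bank = ItemBank((
    ItemParameters("mood1", 1.8, (-2.0, -1.0, 0.0, 1.0)),
    ItemParameters("mood2", 1.2, (-1.5, -0.5, 0.5, 1.5)),
    ItemParameters("mood3", 2.4, (-1.0, 0.0, 1.0, 2.0)),
    ItemParameters("mood4", 0.9, (-0.5, 0.3, 1.1, 1.9)),
    ItemParameters("mood5", 1.5, (-2.2, -1.2, 0.2, 1.2)),
), metric_name="reference")

item = bank.item("mood3")
print("P(category | theta=0) for mood3:",
      np.round(category_probabilities(0.0, item), 3))
print("Fisher information of mood3 at theta = -1, 0, +1:",
      np.round(item_information(np.array([-1.0, 0.0, 1.0]), item), 3))

# a respondent endorsing mostly high categories
pattern = {"mood1": 5, "mood2": 4, "mood3": 4, "mood4": 5, "mood5": 4}
est = eap_score(pattern, bank)
print(f"EAP theta = {est.theta:.3f} (SE {est.se:.3f}) "
      f"-> T score {to_t_metric(est.theta):.1f}")
# Theta is in reference-population SD units (mean 0); the T metric rescales
# it to mean 50 / SD 10, so this respondent is about 1 SD above the mean.
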