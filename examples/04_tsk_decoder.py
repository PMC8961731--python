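"""The TSK fuzzy decoder up close: rules, memberships, predictions.

Fits a five-rule Takagi-Sugeno-Kang fuzzy system on labelled 2-D latent
factors and prints its learned IF-THEN rules in linguistic form, the way
fuzzy systems are usually presented.
"""

import numpy as np

from eegmanifold.decoders import (
    firing_strengths,
    tsk_fit,
    tsk_predict,
)
from eegmanifold.decoders.tsk import export_rules
from eegmanifold.synthetic import generate_feature_table

X, y = generate_feature_table(400, separation=6.0, seed=3)
model = tsk_fit(X, y, K=5, seed=0)

_, _, pred = tsk_predict(model, X)
print(f"training accuracy on 5 separable clusters: {np.mean(pred == y):.3f}\n")

print("learned fuzzy rules (antecedent linguistic labels by center rank):")
for rule in export_rules(model):
    c = ", ".join(f"{v:.2f}" for v in rule["center"])
    print(f"  Rule {rule['rule']}: IF {rule['if']}  (center [{c}])")
    intercepts = [f"{row[0]:+.3f}" for row in rule["consequents"]]
    print(f"           THEN per-class affine consequents, intercepts "
          f"[{', '.join(intercepts)}]")

u = X[0]
strengths = firing_strengths(model, u[None, :])[0]
scores, decision, label = tsk_predict(model, u)
print(f"\nexample input {np.round(u, 2)} (true class {y[0]}):")
print(f"  normalized firing strengths {np.round(strengths, 3)} (sum=1)")
print(f"  class scores {np.round(scores, 3)}")
print(f"  one-hot decision {decision.astype(int)} -> predicted class {label}")
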