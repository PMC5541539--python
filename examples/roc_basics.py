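"""ROC curves and the pairwise meaning of AUC.

The positive class is outcome 0 (death in hospital).  The area under the
ROC curve equals the probability that a randomly chosen death receives a
higher predicted death probability than a randomly chosen survivor, ties
counted half — demonstrated here against an explicit pair count.
"""

import itertools

import numpy as np

from mlscape import auc, mann_whitney_auc, roc_curve

p0 = np.array([0.9, 0.4, 0.6, 0.1])  # predicted death probabilities
labels = np.array([0, 0, 1, 1])  # first two patients died

curve = roc_curve(p0, labels)
print("threshold  F_pr   T_pr")
for t, (f, tp) in zip(curve.thresholds, curve.points):
    print(f"  {t:6.2f}  {f:5.2f}  {tp:5.2f}")
print(f"trapezoidal AUC: {auc(curve):.4f}")

pairs = list(itertools.product([0.9, 0.4], [0.6, 0.1]))
wins = sum(1.0 if d > s else 0.5 if d == s else 0.0 for d, s in pairs)
print(f"pairwise count: {wins:.0f} of {len(pairs)} (death, survivor) pairs "
      f"correctly ordered -> {wins / len(pairs):.4f}")
print(f"rank-based statistic: {mann_whitney_auc(p0, labels):.4f}")
print("All three numbers agree: the ROC integral IS the pairwise statistic.")
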