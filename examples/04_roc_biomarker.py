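"""ROC evaluation of a spatial metric as a response predictor.

Seven responders and four non-responders whose nearest-neighbor distances
order with exactly three discordant pairs: AUC = 25/28 ≈ 0.893, and the
Youden-optimal cutoff classifies 6 of 7 responders correctly with no
false positives (sensitivity 0.857, specificity 1.000). The asymptotic
Mann-Whitney p on the same ordering is 0.038.
"""

from spatialtme import mann_whitney, roc_curve

nnd_responders = [2.5, 6, 7, 8, 9, 10, 11]    # larger CAF-TAEC distances
nnd_nonresponders = [2, 3, 4, 5]

roc = roc_curve(nnd_responders + nnd_nonresponders, [1] * 7 + [0] * 4)
mw = mann_whitney(nnd_responders, nnd_nonresponders, mode="asymptotic")

print(f"AUC = {roc.auc:.3f}")
print(f"Youden-optimal cutoff: {roc.youden_threshold:g} um")
print(f"sensitivity = {roc.sensitivity:.3f}, "
      f"specificity = {roc.specificity:.3f}")
print(f"Mann-Whitney (asymptotic) p = {mw.p:.3f}")
# A distance cutoff separating the groups this cleanly means the spatial
# decoupling of fibroblasts from vessels predicts pathological response.
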