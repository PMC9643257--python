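"""Diagnostic metric table from raw confusion counts.

Feeds a 62-swallow test outcome (53 true normals all correct, 9 true
aspirating of which 8 caught) into the metrics module and prints the
per-class PPV/NPV/specificity/sensitivity/F1 table with total accuracy.
"""

from sscswallow import ConfusionMatrix, evaluation_report

cm = ConfusionMatrix(tn=53, fp=0, fn=1, tp=8)
print(evaluation_report(cm, decimals=2))
# NPV 0.98 for the aspirating class: a "normal" call is wrong only
# 1 time in 54. Sensitivity 0.89: one aspirating swallow in nine missed.
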