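"""Evaluate a behavior classifier against human annotation.

Builds an annotated ("true") lunge bout table and a noisy predicted table
(misses one bout, adds two spurious ones), then reports recall and the
FP-augmented precision alongside the conventional precision.
"""

from flydyad import Bout, BoutTable
from flydyad.classifier_eval import evaluation_report

true = BoutTable([Bout("lunge", "tester", s, s + 8) for s in (100, 300, 500, 700, 900)])
pred = BoutTable(
    [Bout("lunge", "tester", s + 2, s + 10) for s in (100, 300, 500, 700)]  # 4 hits
    + [Bout("lunge", "tester", 2000, 2010), Bout("lunge", "tester", 3000, 3006)]  # 2 FPs
)

report = evaluation_report(true, pred)
print(report.to_string(index=False))
# recall = detected true bouts / all true bouts (4/5).
# precision = detected true bouts / (all detections + false positives)
# (4/8): the FP-augmented denominator penalizes false positives twice, so it
# is never above precision_conventional = 4/6.
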