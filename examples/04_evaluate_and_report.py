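"""Score a detector against ground truth and render the QC report.

A deliberately degraded detector (jittered corners, spurious low-confidence
boxes) is compared with the oracle's boxes via the confusion matrix and the
trapezoid area under the precision-recall curve; assembly statistics feed
the four-section JSON + HTML report.
"""

import numpy as np

import hic_curator as hc
from hic_curator.evaluation import pr_curve

rng = np.random.default_rng(6)
truths, preds = [], []
for i in range(12):
    x = 10.0 + 50.0 * i
    cat = "translocation" if i % 2 else "inversion"
    truths.append(hc.Box(cat, x, x, x + 20, x + 20, 1.0))
    jitter = rng.uniform(-2, 2, 4)
    preds.append(hc.Box(cat, x + jitter[0], x + jitter[1],
                        x + 20 + jitter[2], x + 20 + jitter[3],
                        float(rng.uniform(0.6, 1.0))))
for _ in range(3):  # spurious low-confidence boxes
    x = float(rng.uniform(700, 900))
    preds.append(hc.Box("translocation", x, x, x + 15, x + 15, float(rng.uniform(0.0, 0.3))))

cm = hc.confusion_matrix(preds, truths, iou_min=0.5)
print("confusion matrix (rows = truth, columns = prediction):")
print(cm)
for cat in ("translocation", "inversion"):
    a = hc.auprc(pr_curve(preds, truths, cat, iou_min=0.5))
    print(f"AUPRC[{cat}] at IOU 0.5 = {a:.3f}")

lengths = [480_000, 430_000, 310_000]
stats = hc.contiguity_stats(lengths)
q = hc.quality_ratios(3, 3, [12_000], [8_000], sum(lengths), sum(lengths))
print(f"N50 = {stats['N50']:,} (L50 = {stats['L50']}), CC ratio = {q.cc_ratio:.2f}, "
      f"R_error = {q.r_error:.6f} = {q.r_translocation:.6f} + {q.r_inversion:.6f}")

data = hc.build_report_data(
    {"total_length": sum(lengths), "N50": stats["N50"], "cc_ratio": q.cc_ratio,
     "r_error": q.r_error},
    [],
    iteration_counts=[{"iteration": 1, "translocation": 1, "inversion": 1, "debris": 0}],
    chromosome_proportions={f"chr_{i+1}": l / sum(lengths) for i, l in enumerate(lengths)},
)
json_path, html_path = hc.render_report(data, "example_report")
print(f"wrote {json_path} and {html_path}")
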