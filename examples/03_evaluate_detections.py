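"""Evaluate detection quality: precision/recall and AP at IoU 0.3 and 0.5.

Detections are matched to ground truth greedily in score order at a
fixed IoU threshold; AP is the exact area under the monotone precision
envelope of the all-point PR sweep.  The looser IoU 0.3 matching is the
more relevant figure for counting, where presence matters more than
pixel-perfect localization.
"""

from trapcount import (
    BlobDetector,
    SceneConfig,
    average_precision,
    count_trap,
    generate_scene,
    match,
    precision_recall,
)

config = SceneConfig(n_insects=300, seed=3).scaled(0.25)
image, truth = generate_scene(config)
result = count_trap(image, BlobDetector(), window_size=125, overlap=25, score_threshold=0.0)
dets = result.all_detections

m = match(dets, truth, iou_threshold=0.5)
p, r = precision_recall(m)
print(f"matching at IoU 0.5: TP {m.TP}, FP {m.FP}, FN {m.FN}")
print(f"precision {p:.2f}%, recall {r:.2f}%")
for thr in (0.3, 0.5):
    ap = average_precision(dets, truth, thr)
    print(f"AP at IoU {thr}: {100 * ap:.2f}%")

# AP at 0.3 is never below AP at 0.5: relaxing the localization
# requirement can only promote detections from FP to TP.
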