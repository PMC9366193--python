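"""Compare bisector key points with uniform-random contour sampling.

Writes a small phantom dataset, then scores both point-selection methods
by the IOU between their 16-point polygon and the ground-truth mask —
the comparison that motivates near-equidistant key points.
"""

import tempfile
from pathlib import Path

import boundaryseg as bs
from boundaryseg.harness import run_compare_sampling

with tempfile.TemporaryDirectory() as tmp:
    data_dir = Path(tmp) / "phantoms"
    bs.make_dataset(20, bs.PhantomSpec(seed=42), data_dir)
    result = run_compare_sampling(data_dir, n_points=16, seed=42,
                                  out_csv=data_dir / "comparison.csv")

agg = result["aggregate"]
print("method              mean IOU   std")
print(f"bisector keypoints  {agg['keypoint_iou']['mean']:.4f}   "
      f"{agg['keypoint_iou']['std']:.4f}")
print(f"random sampling     {agg['random_iou']['mean']:.4f}   "
      f"{agg['random_iou']['std']:.4f}")
# Near-equidistant key points cover the contour evenly, so their polygon is
# both more accurate (higher mean) and more stable (lower spread) than the
# same number of randomly sampled contour points.
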