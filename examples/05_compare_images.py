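"""Colorized fuzzy-ratio comparison of two chromatograms.

Compares a sample against a copy with one extra peak: the signed field is
positive (rendered green) where the analyzed image has more signal and
negative (red) where the reference dominates; a 1-pixel fuzzy radius absorbs
residual misalignment.
"""

from pathlib import Path

import numpy as np

import volatilofp as v
from volatilofp.synthetic_data import render_peak

rng = np.random.default_rng(0)
reference = v.ChromatogramGrid(8 + rng.normal(0, 1, (120, 400)), 4.0, 100.0, sample_id="T0")
for k in range(5):
    render_peak(reference, 60.0 + 70 * k, 0.8 + 0.5 * k, 400.0, None, 4.0, 0.06)

analyzed = v.ChromatogramGrid(reference.intensities.copy(), 4.0, 100.0, sample_id="T1")
render_peak(analyzed, 250.0, 3.2, 600.0, None, 4.0, 0.06)  # new VOC at T1

cmp_ = v.fuzzy_ratio(analyzed, reference, radius=1)
Path("scratch").mkdir(exist_ok=True)
v.render_rgb(cmp_, "scratch/comparison.png")

pos = (cmp_.signed > 0.2).sum()
neg = (cmp_.signed < -0.2).sum()
print(f"signed field range: [{cmp_.signed.min():.2f}, {cmp_.signed.max():.2f}]")
print(f"pixels with analyzed >> reference: {pos}; reference >> analyzed: {neg}")
print("wrote scratch/comparison.png (green blob = the peak added at T1)")
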