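"""Extract the background-normalized intensity trace and annotate the protocol.

The readout is the whole-frame mean divided by the mean of a background ROI
free of islet signal; the ratio cancels per-frame illumination and gain
drift exactly.  Phases of the standard stimulation protocol (low glucose,
high glucose, low glucose, KCl) are attached by time.
"""

import numpy as np

from isletscope import (
    RegionMask,
    annotate_protocol,
    normalized_intensity_trace,
    stabilize_stack,
)
from isletscope.benchmark import gsis_benchmark

stack, manifest, protocol = gsis_benchmark(seed=1)
stabilized, shifts, window = stabilize_stack(stack)
mask = RegionMask(manifest.background_mask).crop(*window.slices())

trace = normalized_intensity_trace(stabilized, mask)
trace = annotate_protocol(trace, protocol, stabilized.frame_interval_min)

print(f"background ROI: {mask.n_pixels} px")
for label, lo, hi in trace.annotations:
    seg = trace.values[lo:hi]
    print(f"  {label:<22s} frames [{lo:2d}, {hi:2d})  mean ratio {seg.mean():.4f}")
drop1 = trace.values[:15].mean() - trace.values[16:44].mean()
print(f"high-glucose onset lowers the ratio by ~{drop1:.4f} "
      "(granule-patch backscatter lost to secretion)")
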