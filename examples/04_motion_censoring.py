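"""Framewise displacement, DVARS and the three-stage censoring rule.

Builds a motion trace with injected spikes, computes FD and DVARS, and
applies the outlier-frame rule (threshold, pad one frame before / two
after, then censor surviving segments shorter than five frames).
"""

import numpy as np

from diurnalfmri import (CohortSpec, EffectParams, compute_dvars, compute_fd,
                         outlier_frames, session_exclusion, simulate_bold,
                         simulate_cohort, simulate_motion)

spec = CohortSpec(n_families=1, family_size_weights=(1.0,), n_frames=120,
                  n_regions=20, n_cortical=18, seed=3)
effects = EffectParams(seed=3, motion_spike_rate=4.0)
ctx = next(simulate_cohort(spec, effects).contexts())

motion = simulate_motion(ctx, effects)
bold, noise = simulate_bold(ctx, effects, return_noise=True)
fd = compute_fd(motion)
dvars = compute_dvars(bold)

mask = outlier_frames(fd, dvars, fd_thresh=0.2, dvars_thresh=75.0)
hit_frames = np.flatnonzero(np.isin(mask.provenance, ["fd", "dvars", "fd+dvars"]))
print(f"FD exceeds 0.2 mm at {int((fd > 0.2).sum())} frames; "
      f"DVARS exceeds 75 at {int((dvars > 75).sum())} frames")
print(f"rule hits at frames {hit_frames.tolist()}")
print(f"after padding and short-segment censoring: "
      f"{int(mask.outlier.sum())}/{fd.size} frames flagged "
      f"({mask.outlier_pct:.1f}%)")
print(f"session kept? {not session_exclusion([mask.outlier_pct, 0.0])}")
print("\nThe padded mask is what feeds the outlier-% summary metric; a")
print("session is dropped when either of its runs exceeds 50% outliers.")
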