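"""Edgewise connectivity effects and the network-based statistic.

Plants a time-of-day decline in one network's internal coupling, builds
per-participant RSFC matrices, correlates every edge with scan hour, and
lets NBS find the affected subnetwork against a family-respecting
permutation null.
"""

import numpy as np

from diurnalfmri import (CohortSpec, EffectParams, median_abs_z,
                         edgewise_covariate_corr, network_average,
                         network_based_statistic, rsfc_matrix, simulate_bold,
                         simulate_cohort)

spec = CohortSpec(n_families=60, sessions=1, runs_per_session=1, n_frames=200,
                  n_regions=180, n_cortical=170, seed=21)
effects = EffectParams(seed=21, gs_base_amp=0.0, beta_run_gs=0.0,
                       gamma_rv_gs=0.0, family_re_sd=0.0, subject_amp_sd=0.0,
                       session_amp_sd=0.0, amp_run_sd=0.0,
                       network_block_corr=0.3, noise_sd=10.0,
                       network_tod_slopes={"VisCent": -0.02})
cohort = simulate_cohort(spec, effects)

mats, hours, fams = [], [], []
for ctx in cohort.contexts():
    mats.append(rsfc_matrix(simulate_bold(ctx, effects)))
    hours.append(ctx.scan_hour)
    fams.append(ctx.family_id)
stack, hours = np.stack(mats), np.asarray(hours)

edge_r = edgewise_covariate_corr(stack, hours)
labels = simulate_bold(next(cohort.contexts()), effects).network_labels
blocks = network_average(edge_r, labels)
print(f"median |z| of edge-hour correlations: {median_abs_z(edge_r):.3f}")
print(f"network-block average for VisCent-VisCent: "
      f"{blocks.loc['VisCent', 'VisCent']:+.3f} "
      f"(planted decline); for ContA-ContA: "
      f"{blocks.loc['ContA', 'ContA']:+.3f} (no effect)")

res = network_based_statistic(stack, hours, families=fams, n_perm=499, seed=0)
top = int(np.argmax(res.sizes))
print(f"NBS: {len(res.components)} suprathreshold component(s); top component "
      f"has {int(res.sizes[top])} edges, p = {res.p_values[top]:.4f}")
print(f"top-component regions: {sorted(set(np.unique(res.components[top])))[:12]}")
print("\nRegions 0-9 are the planted VisCent block: the component-level")
print("permutation test recovers exactly the subnetwork whose coupling was")
print("made to decline with scan hour.")
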