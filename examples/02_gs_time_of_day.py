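"""Global-signal fluctuation vs time of day with family-aware inference.

Simulates a mid-size cohort with the default injected decline, computes
per-run GS fluctuation, averages it within sessions, and tests the
between-participant correlation with scan hour using permutations that
respect family structure.
"""

import pandas as pd

from diurnalfmri import (CohortSpec, EffectParams, between_participant_corr,
                         compute_gs, gs_fluctuation, simulate_bold,
                         simulate_cohort, to_percent_signal_change)

spec = CohortSpec(n_families=120, sessions=1, n_frames=300, n_regions=30,
                  n_cortical=28, seed=7)
effects = EffectParams(seed=7)
cohort = simulate_cohort(spec, effects)

rows = []
for ctx in cohort.contexts():
    fluct = gs_fluctuation(compute_gs(simulate_bold(ctx, effects)))
    rows.append((ctx.participant_id, ctx.family_id, ctx.scan_hour, fluct))
df = (pd.DataFrame(rows, columns=["pid", "fam", "hour", "gs"])
      .groupby(["pid", "fam"], as_index=False).mean())

res = between_participant_corr(df["gs"].to_numpy(), df["hour"].to_numpy(),
                               df["fam"].to_numpy(), n_perm=999, seed=0)
early = df[df["hour"] < 12]["gs"].mean()
late = df[df["hour"] > 16]["gs"].mean()
print(f"N = {res.n} participants (session averages)")
print(f"between-participant r(GS fluctuation, scan hour) = {res.r:+.3f}, "
      f"permutation p = {res.p:.4f}")
print(f"mean GS fluctuation before noon: {to_percent_signal_change(early):.3f}% "
      f"of mean signal; after 4 PM: {to_percent_signal_change(late):.3f}%")
print("\nA negative r with small p means participants scanned later in the")
print("day show systematically lower global-signal fluctuation, as planted")
print("by the generator's time-of-day slope.")
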