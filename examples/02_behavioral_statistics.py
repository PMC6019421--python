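"""Accuracy, signal-detection and subgroup statistics for a simulated study.

Reproduces the behavioral analysis chain: per-condition accuracies with
group confidence intervals, d' and criterion per participant, the quintile
split by mask accuracy, and the 2 x 2 mixed ANOVA contrasting the extreme
subgroups on mask vs face accuracy.
"""

import numpy as np

import maskcue as mc
from maskcue import behavior as bh

stimuli = mc.make_stimulus_set("exp2", rng_seed=7)
panel = mc.default_panel(30, rng_seed=7)
trials = mc.simulate_trials(stimuli, panel, rng_seed=7)

acc, stats = bh.condition_accuracy(trials)
for cond, s in stats.items():
    print(f"{cond}: M = {100 * s.mean:.1f}%, SE = {100 * s.se:.1f}, "
          f"CI = {100 * s.ci_low:.1f}-{100 * s.ci_high:.1f}")

sdt = bh.sdt_by_participant(trials)
dprimes = [s.dprime for s in sdt.values()]
print(f"d' mean {np.mean(dprimes):.2f} (range {min(dprimes):.2f}-{max(dprimes):.2f}); "
      f"p(correct) mean {np.mean([s.pcorrect for s in sdt.values()]):.3f}")
# d' > 0 throughout: every simulated observer separates the classes at least
# weakly; the wide range is the individual-differences signal.

pivot = acc.pivot(index="participant_id", columns="condition", values="accuracy")
split = bh.quintile_split(pivot["high_realism_mask"].to_dict())
high = split.loc[split.subgroup == "high", "participant_id"].tolist()
low = split.loc[split.subgroup == "low", "participant_id"].tolist()
members = high + low
res = bh.mixed_anova_2x2(
    {p: pivot["high_realism_mask"][p] for p in members},
    {p: pivot["real_face"][p] for p in members},
    {p: ("high" if p in high else "low") for p in members})
r = res["subgroup"]
print(f"subgroup main effect: F({r.df[0]},{r.df[1]}) = {r.value:.2f}, "
      f"p = {r.p:.2g}, partial eta^2 = {r.effect_size:.2f}")
# A large F confirms the quintile split separates genuinely different
# ability levels rather than sampling noise.
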