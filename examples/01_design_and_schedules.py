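"""Build a pseudorandomized block schedule and inspect its design guarantees.

Every 36-trial set cues each of the four targets exactly 9 times and rewards
them exactly 9/6/3/0 times for probabilities 1, 2/3, 1/3 and 0 — so realized
reward frequency matches the nominal probability exactly, the achievable
reward prediction errors form five symmetric levels, and RPE sums to zero
over any complete set.
"""

from fractions import Fraction

from reachvigor import design

probs = {1: 1, 2: Fraction(2, 3), 3: Fraction(1, 3), 4: 0}
sched = design.build_block_schedule(probs, mode="learned", seed=0)

singles = sched.trials[sched.trials.trial_type == "single"]
print(f"single trials: {sched.n_single}, choice trials: {sched.n_choice}")
for k in range(4):
    chunk = singles.iloc[k * 36:(k + 1) * 36]
    rewards = chunk.groupby("target").reward.sum().to_dict()
    print(f"  set {k + 1}: rewards per target {rewards}, "
          f"sum RPE = {(chunk.reward - chunk.e_r).sum():+.1f}")

rpes = sorted(design.enumerate_design_rpes())
print("achievable RPE levels:", [f"{float(r):+.3f}" for r in rpes])
print(f"bonus denominator: {float(design.max_expected_chosen_reward()):.4f} "
      f"(printed form {design.max_expected_chosen_reward_printed()})")
# A participant who always picks the better option of every pair earns the
# full $5 bonus; the denominator is what makes that normalization exact.
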