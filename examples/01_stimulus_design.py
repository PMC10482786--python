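"""Enumerate the two stimulus sets and build balanced sessions.

The numerical comparison task uses all 56 unequal (global, local) digit pairs
in 2..9; the gamble task uses all 64 (gain, loss) pairs crossed with two
framing conditions (which hierarchical level carries the gain).
"""

from collections import Counter

from glocal import build_session, enumerate_lotteries, enumerate_numeric_stimuli

stims = enumerate_numeric_stimuli()
print(f"{len(stims)} comparison stimuli; "
      f"{sum(s.congruent for s in stims)} congruent (global digit larger)")
print("stimuli per numerical distance:",
      dict(sorted(Counter(s.distance for s in stims).items())))

lotteries = enumerate_lotteries()
print(f"\n{len(lotteries)} lotteries; "
      f"{sum(1 for l in lotteries if l.ev == 0)} with expected value 0 "
      "(the EV=0 diagonal used by loss-aversion method 1)")

numeric = build_session("numeric", seed=1)
pref = build_session("preference", seed=1, condition_order="GLLG_first")
print(f"\nnumeric session: {len(numeric.trials)} trials in {numeric.n_blocks} blocks "
      "(each stimulus 8x)")
print(f"preference session: {len(pref.trials)} trials, per condition:",
      pref.trials["condition"].value_counts().to_dict())
print("first block condition (GLLG_first counterbalancing):",
      pref.trials.loc[pref.trials.block == 0, "condition"].iloc[0])
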