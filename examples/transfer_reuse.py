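"""Q-value reuse: warming up a tagger on a related task.

Trains a source tagger, then learns a related target task (half the marker
words renamed) twice — from scratch and with the frozen source table behind
an inter-task mapping — and compares the learning curves.
"""

from bioqner.experiments import summarize_transfer, transfer_comparison

results = transfer_comparison([0], max_episodes=1000, eval_every=100)
r = results[0]
print("episode  cold-F  warm-F")
for c, w in zip(r.cold, r.warm):
    print(f"{c.episode:7d}  {c.f:.3f}   {w.f:.3f}")
# Cold starts from lexicon votes alone; warm starts from the source policy
# read through the identity state mapping, so its curve begins far higher.

print(f"episodes to reach span F 0.8: cold {r.cold_episodes_to_target}, "
      f"warm {r.warm_episodes_to_target}")
s = summarize_transfer(results)
print(f"area under the curve: cold {s['mean_cold_aulc']:.3f}, "
      f"warm {s['mean_warm_aulc']:.3f}")
# A value of 2 * max_episodes means the run never reached the target F.
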