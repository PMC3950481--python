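"""The three-recogniser comparison on a small synthetic panel.

Compares the lexicon+rules baseline, the Q-learning recogniser, and
Q-learning with transfer on a reduced panel (two task pairs, one training
repetition) of the rich-source / data-poor-target setting.  The full panel
used for reported results is experiments.benchmark's default (five tasks,
two repetitions).
"""

from bioqner.experiments import benchmark

res = benchmark(0, n_tasks=2, reps=1, target_episodes=1000)
print(f"panel: {res['n_tasks']} task pairs, {res['reps']} repetition(s)")
for mode, f in res["mean_f"].items():
    print(f"  {mode:16s} mean entity-level F = {f:.3f}")
# Expected ordering: qlearn_transfer >= qlearn >= baseline.  The baseline
# tags each token independently from the lexicons; Q-learning adds sequence
# context through its state; transfer additionally reuses the action-value
# table of a richly annotated related source task.
for mode, fs in res["per_task_f"].items():
    print(f"  {mode:16s} per-task F = {[round(f, 3) for f in fs]}")
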