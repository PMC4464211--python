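"""Race two reactions for a shared reactant and record the trajectory.

A -> B draws its waiting time from the single-molecule MM density (with
the live amount of A as substrate); A -> C is exponential with live rate
10*[A].  Each step samples one tau per fireable reaction and fires the
smaller; the race runs until A is exhausted.
"""

import numpy as np

from taurace import StopCriterion, example5_system, simulate

system, init = example5_system()
rng = np.random.default_rng(7)
traj = simulate(system, init, StopCriterion(max_iterations=10**6), rng)

df = traj.to_dataframe()
print(df.head(6).to_string(index=False))
print("...")
final = traj.final_counts()
print(f"{traj.iterations} firings, final time {traj.records[-1].time:.4f}")
print(f"final counts: A={final['A']}, B={final['B']}, C={final['C']} "
      f"(A+B+C = {final['A'] + final['B'] + final['C']})")
# total copy number is conserved at every step; with these parameters the
# exponential channel (rate 10*[A]) wins essentially every race.
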