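"""Individual mutator trajectories versus the ensemble average.

Single realizations show an apparent frequency threshold -- replicates started
rare almost always end in loss, replicates started common in fixation. The
ensemble mean shows no threshold: after a transient dip (the mutator's
deleterious load) it rises above x0 at every starting frequency and converges
to Pfix(x0).
"""

from mutsim import (DfeSpec, OutcomeStatus, SimParams, average_trajectories,
                    run_replicates)

dfe = DfeSpec(mode="constant")
for x0 in (1e-3, 0.01, 0.3):
    params = SimParams(N=10_000, U_ben=1e-6, U_del=1e-4, s_ben=0.1, s_del=-0.1,
                       m_fold=100, x0=x0, base_seed=7)
    trajs = run_replicates(params, dfe, n_reps=400, record=True)
    horizon = max(t.outcome.generations_elapsed for t in trajs)
    avg = average_trajectories(trajs, horizon=horizon)
    n_fixed = sum(t.outcome.status is OutcomeStatus.FIXED for t in trajs)
    first = trajs[0].outcome.status.value
    print(f"x0 = {x0:<6g} first replicate: {first:<5}  "
          f"fixed {n_fixed}/400  ensemble mean -> {avg.mean_freq[-1]:.4f} "
          f"(min of mean {avg.mean_freq.min():.4f})")

print()
print("Per-replicate outcomes flip from mostly-LOST to mostly-FIXED with x0,")
print("but every ensemble mean ends above its x0: the 'threshold' is a")
print("sampling artifact, not frequency-dependent selection.")
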