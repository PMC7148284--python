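"""Fit the hierarchical drift-diffusion model to a small synthetic cohort.

Generates 4 participants x 240 trials/session from the group defaults, runs
the adaptive Metropolis-within-Gibbs sampler (shortened chains for a quick
demonstration), and prints the posterior mean +/- SD of the group-level
parameters next to their generating values, plus Geweke convergence scores.

Runtime: roughly two minutes on one CPU.
"""

import numpy as np

from joyddm import GroupParameters, build_model, geweke_diagnostic, sample_posterior, synth_cohort

group = GroupParameters()
design, trials, _ = synth_cohort(n_participants=4, seed=1, n_blocks=2, reps_per_cell=15)
model = build_model(trials)
chains = sample_posterior(model, n_total=1500, n_burn=500, seed=2)

print(f"{'parameter':28s} {'generating':>10s} {'posterior':>18s} {'geweke z':>9s}")
for m in ("joystick", "keyboard"):
    ref = group.means[m]
    for k in ("a", "ter", "sv", "st"):
        s = chains.get(f"{k}({m})")
        z = geweke_diagnostic(s)
        print(f"{k}({m}):{'':12s} {ref[k]:10.3f} {s.mean():9.3f} +/- {s.std():.3f} {z:9.2f}")
for d in ("up", "right"):
    for diff in ("easy", "difficult"):
        tv = group.means["joystick"]["v"][(diff, d)]
        s = chains.get(f"v(joystick,{diff},{d})")
        print(f"v(joystick,{diff},{d}):{'':2s} {tv:10.3f} {s.mean():9.3f} +/- {s.std():.3f} "
              f"{geweke_diagnostic(s):9.2f}")

print("\nEasy drift rates sit well above difficult ones and the posterior "
      "means are within a few posterior SDs of the generating values.  "
      "|Geweke z| >= 1.96 flags chains that have not converged at this "
      "deliberately short demonstration length — the boundary separation "
      "and the across-trial variabilities mix slowest.  Production fits use "
      "longer chains (3,000+ samples) and more participants, as in "
      "scripts/acceptance.py.")
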