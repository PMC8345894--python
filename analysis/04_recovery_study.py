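#!/usr/bin/env python
"""Parameter-recovery study: can the pipeline recover a known 15% annual
amplitude from a biased, noisy panel?

Three replicates of the reduced-scale experiment (8 soft strata x 200
weeks x ~5,000 enrollees each): reports the posterior-mean peak relative
fluctuation, the pooled first-harmonic amplitude with its 95% HPD interval
and whether the interval covers the generative truth.
"""

import json
import sys
from pathlib import Path

import numpy as np

from cyclemetry.experiments import run_recovery

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1, n_replicates: int = 3) -> None:
    rows = []
    for k in range(n_replicates):
        r = run_recovery(seed + k)
        rows.append({k2: r[k2] for k2 in
                     ("max_s_pct", "A1_mean", "A1_hpd", "A1_true",
                      "A1_covered", "dr_avg")})
        print(f"replicate {k}: peak |s| = {r['max_s_pct']:.2f}% "
              f"(truth 15%), A1 = {r['A1_mean']:.5f} "
              f"HPD [{r['A1_hpd'][0]:.5f}, {r['A1_hpd'][1]:.5f}] "
              f"covers truth: {r['A1_covered']}")
    OUT.mkdir(exist_ok=True)
    with open(OUT / "recovery_study.json", "w") as fh:
        json.dump(rows, fh, indent=2, default=float)
    print(f"mean peak |s| = "
          f"{np.mean([r['max_s_pct'] for r in rows]):.2f}% over "
          f"{n_replicates} replicates")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
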