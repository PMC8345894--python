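#!/usr/bin/env python
"""Generate the desk-scale synthetic claims panel used by the analyses.

Emulates a commercial-claims structure: 8 employer-like enrollment groups
over ~4 years, one seasonal condition (15% relative annual amplitude,
New-Year shifts) plus an all-visit pseudo-condition, 50% holiday dips and
binomial count noise.  Writes members/claims CSVs and the ground truth.
"""

import sys
from pathlib import Path

from cyclemetry.config import GeneratorConfig, default_conditions
from cyclemetry.simulate import simulate_panel, write_panel

OUT = Path(__file__).resolve().parent.parent / "results" / "panel"


def main(seed: int = 1) -> None:
    cfg = GeneratorConfig(n_members=20_000, n_weeks=208, n_groups=8,
                          conditions=default_conditions(), holiday_dip=0.5,
                          boundary_jitter=1, seed=seed)
    members, claims, truth = simulate_panel(cfg)
    write_panel(OUT, members, claims, truth)
    print(f"panel: {len(members)} members, {len(claims)} claims, "
          f"{cfg.n_weeks} weeks -> {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
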