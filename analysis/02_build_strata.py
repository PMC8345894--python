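#!/usr/bin/env python
"""Build population strata from the simulated panel and summarize them.

Hard strata share an exact (sex, age group, enrollment window); soft
strata merge nearby windows by weighted K-means per age-sex cell.
"""

import sys
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from cyclemetry.io import read_panel
from cyclemetry.strata import build_hard_strata, merge_strata_kmeans

ROOT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1, k_per_age_group: int = 2) -> None:
    members, claims, report = read_panel(ROOT / "panel" / "members.csv",
                                         ROOT / "panel" / "claims.csv")
    print(f"panel validated: {report.n_members} members, "
          f"{report.n_claims} claims, {report.n_over_age_excluded} over-65")
    hard = build_hard_strata(members)
    soft = merge_strata_kmeans(hard, k_per_age_group, seed=seed)
    hard.to_csv(ROOT / "hard_strata.csv", index=False)
    pd.DataFrame([asdict(s) for s in soft]).drop(columns="hard_keys").to_csv(
        ROOT / "soft_strata.csv", index=False)
    conserved = sum(s.total_members for s in soft) == hard["member_count"].sum()
    print(f"{len(hard)} hard strata merged into {len(soft)} soft strata "
          f"(member counts conserved: {conserved})")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
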