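"""Panel I/O and schema validation."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .simulate import CLAIM_COLUMNS, MEMBER_COLUMNS
from .strata import MAX_AGE


@dataclass
class PanelValidation:
    """Validation report of a members/claims panel."""

    n_members: int = 0
    n_claims: int = 0
    n_over_age_excluded: int = 0
    n_orphan_claims: int = 0
    week_range: tuple[int, int] = (0, 0)
    errors: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def read_panel(members_path, claims_path):
    """Read and validate a members/claims panel.

    Returns ``(members, claims, report)``.  Members over age 65 are
    retained but counted; claims referencing unknown members are dropped
    and itemized in the report.
    """
    report = PanelValidation()
    members = pd.read_csv(members_path)
    claims = pd.read_csv(claims_path)
    for col in MEMBER_COLUMNS:
        if col not in members.columns:
            report.errors.append(f"members: missing column {col!r}")
    for col in CLAIM_COLUMNS:
        if col not in claims.columns:
            report.errors.append(f"claims: missing column {col!r}")
    if report.errors:
        return members, claims, report

    if (members["enroll_start_week"] > members["enroll_end_week"]).any():
        report.errors.append("members: enroll_start_week > enroll_end_week")
    if (members["age_mid"] < 0).any():
        report.errors.append("members: negative age_mid")
    report.n_over_age_excluded = int((members["age_mid"] > MAX_AGE).sum())

    known = set(members["member_id"])
    orphan = ~claims["member_id"].isin(known)
    if orphan.any():
        report.n_orphan_claims = int(orphan.sum())
        report.errors.append(
            f"claims: {report.n_orphan_claims} rows reference unknown members "
            f"(dropped)")
        claims = claims[~orphan].reset_index(drop=True)

    report.n_members = len(members)
    report.n_claims = len(claims)
    if len(claims):
        report.week_range = (int(claims["week"].min()), int(claims["week"].max()))
    return members, claims, report


def write_curves(curves, path) -> None:
    """Write seasonality curves as tidy CSV."""
    frames = [c.to_frame() for c in curves]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_posterior(draws, outdir) -> None:
    """Serialize posterior draws as a long CSV plus a JSON diagnostics sidecar."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    names = {"alpha": draws.alpha, "beta": draws.beta, "sigma_y": draws.sigma_y,
             "nu": draws.nu}
    for name, arr in names.items():
        for i in range(arr.shape[1]):
            sid = draws.strata_meta[i]["stratum_id"]
            rows.append(pd.DataFrame({
                "draw": range(arr.shape[0]),
                "parameter": f"{name}[{sid}]",
                "value": arr[:, i]}))
    for name, arr in (("gamma", draws.gamma), ("p", draws.p), ("q", draws.q)):
        for i in range(arr.shape[1]):
            sid = draws.strata_meta[i]["stratum_id"]
            for k in range(arr.shape[2]):
                rows.append(pd.DataFrame({
                    "draw": range(arr.shape[0]),
                    "parameter": f"{name}[{sid},{k}]",
                    "value": arr[:, i, k]}))
    pd.concat(rows, ignore_index=True).to_csv(outdir / "posterior.csv", index=False)
    with open(outdir / "diagnostics.json", "w") as fh:
        json.dump(draws.diagnostics, fh, indent=2)
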