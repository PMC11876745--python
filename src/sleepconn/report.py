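"""Study-level bookkeeping report.

Recomputes every percentage from counts at call time (nothing cached):
runs coded, state counts and their chi-square test, motion exclusions,
minutes per state, minutes of analysed data per infant, and — for
synthetic studies — the coder-vs-ground-truth epoch concordance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import sleepcode

__all__ = ["study_report", "report_from_manifest"]


def study_report(summary: sleepcode.CodingSummary,
                 concordances: list[float] | None = None) -> dict:
    out = summary.to_dict()
    if summary.n_as + summary.n_qs > 0:
        chi2, p = sleepcode.state_count_test(summary.n_as, summary.n_qs)
        out["state_count_chi2"] = chi2
        out["state_count_p"] = p
    conc = [c for c in (concordances or []) if np.isfinite(c)]
    if conc:
        out["mean_concordance"] = float(np.mean(conc))
    return out


def report_from_manifest(out_dir: str | Path) -> dict:
    """Report for a completed pipeline directory."""
    manifest = json.loads((Path(out_dir) / "manifest.json").read_text())
    fields = ("run_id", "label", "mean_fd", "included", "exclusion_reason")
    assignments = [
        sleepcode.RunStateAssignment(**{k: a[k] for k in fields})
        for infant in manifest["infants"] for a in infant.get("assignments", [])
    ]
    summary = sleepcode.coding_summary(assignments, len(manifest["infants"]))
    concs = [infant.get("concordance") for infant in manifest["infants"]
             if infant.get("concordance") is not None]
    rep = study_report(summary, concs)
    if "stats" in manifest:
        rep["stats"] = manifest["stats"]
    return rep
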