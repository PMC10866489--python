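"""Run manifests and panel summaries from deposited per-species scores.

``panel_from_scores`` recomputes the figure-panel statistics (group medians,
counts, pairwise test batteries) directly from a table of per-species CCM2
scores with grouping labels — the shape in which completeness studies
deposit their data.  This is the path by which published panels are
reproduced when a study's deposited workbook is available locally.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from ccmkit.comparisons import (
    ComparisonFamily,
    DistributionSummary,
    run_family,
    summarize_distribution,
)


def load_deposited_scores(
    path: str | Path, sheet: str | int | None = None
) -> pd.DataFrame:
    """Load a deposited per-species score table (CSV or Excel workbook).

    Required columns: ``species`` and ``ccm2``; any further columns are
    grouping labels (landmass, formation, taxon_group, ...).
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        df = pd.read_excel(path, sheet_name=sheet if sheet is not None else 0)
    else:
        df = pd.read_csv(path)
    missing = {"species", "ccm2"} - set(df.columns)
    if missing:
        raise ValueError(f"deposited score table missing columns {sorted(missing)}")
    return df


@dataclass
class PanelResult:
    """One figure panel: per-group summaries + the Bonferroni test family."""

    group_col: str
    summaries: list[DistributionSummary]
    family: ComparisonFamily | None

    def medians(self) -> dict[str, float]:
        return {s.label: s.median for s in self.summaries}

    def counts(self) -> dict[str, int]:
        return {s.label: s.n for s in self.summaries}


def panel_from_scores(
    df: pd.DataFrame,
    group_col: str,
    min_n: int = 1,
    run_tests: bool = True,
) -> PanelResult:
    """Group a score table and recompute a panel's medians, counts, tests."""
    if group_col not in df.columns:
        raise ValueError(f"no column {group_col!r} in score table")
    groups = [
        (str(label), grp["ccm2"].to_numpy())
        for label, grp in df.groupby(group_col, sort=True)
        if len(grp) >= min_n
    ]
    summaries = [summarize_distribution(s, lab) for lab, s in groups]
    family = run_family(groups) if run_tests and len(groups) >= 2 else None
    return PanelResult(group_col=group_col, summaries=summaries, family=family)


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    command: str,
    inputs: Sequence[str | Path],
    config: Mapping,
) -> Path:
    """Write a machine-readable record sufficient to reproduce a run."""
    import ccmkit

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "version": ccmkit.__version__,
        "python": platform.python_version(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "inputs": {
            str(p): _sha256(Path(p)) for p in inputs if Path(p).is_file()
        },
        "config": dict(config),
    }
    path = out / f"manifest_{command}.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
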