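"""Report tables: standardized parameters, BMDD summaries, OLS morphometry.

The report layer does no analysis of its own beyond rounding and the
cortical-vs-trabecular percent differences; every number traces to an
upstream result object. Flagged entries (|z| above the configured
threshold, default 2 SD) are marked in bold in the Markdown rendering,
mirroring how clinical tables highlight abnormal values.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from . import __version__
from ._rounding import round_half_away
from .bmdd import (
    CA_HIGH_CUT,
    CA_LOW_CUT,
    DEFAULT_BIN_WIDTH,
    BMDDResult,
    compare_compartments,
)
from .calibration import BONE_GL_THRESHOLD, DEFAULT_ANCHORS
from .histomorphometry import DEFAULT_LABEL_INTERVAL
from .ols import MAX_LACUNA_AREA, OLSummary
from .zscore import FLAG_THRESHOLD, ZScoreSet


@dataclass
class RunConfig:
    """Analysis configuration embedded in every output for provenance."""

    calibration_anchors: tuple = DEFAULT_ANCHORS
    bone_gl_threshold: int = BONE_GL_THRESHOLD
    max_lacuna_area_um2: float = MAX_LACUNA_AREA
    ca_low_cut: float = CA_LOW_CUT
    ca_high_cut: float = CA_HIGH_CUT
    bin_width: float = DEFAULT_BIN_WIDTH
    smooth_window: int = 3
    label_interval_days: float = DEFAULT_LABEL_INTERVAL
    flag_threshold: float = FLAG_THRESHOLD
    seed: Optional[int] = None
    ascii_minus: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        d["version"] = __version__
        return d


def _fmt(x: float, nd: int = 2) -> str:
    return f"{round_half_away(x, nd):g}"


def zset_frame(zset: ZScoreSet) -> pd.DataFrame:
    return zset.to_frame()


def _zset_markdown(zset: ZScoreSet, title: str) -> list[str]:
    lines = [f"### {title}", "", "| Parameter | Value | Reference (mean ± SD) | Difference (SD) |",
             "|---|---|---|---|"]
    for row in zset:
        diff = f"{row.z2:+.2f}"
        if row.flagged:
            diff = f"**{diff}**"
        lines.append(
            f"| {row.parameter} | {_fmt(row.value, 4)} | "
            f"{row.ref_mean:g} ± {row.ref_sd:g} | {diff} |"
        )
    lines.append("")
    return lines


def render_report(
    zsets: Optional[list[ZScoreSet]] = None,
    bmdd_results: Optional[Mapping[str, BMDDResult]] = None,
    ols: Optional[OLSummary] = None,
    config: Optional[RunConfig] = None,
    out_dir=None,
    title: str = "Bone tissue analysis report",
) -> dict:
    """Assemble CSV tables and a Markdown report; optionally write them.

    Returns ``{"markdown": str, "tables": {name: DataFrame}, "config": dict}``.
    Missing sections are omitted with a notice rather than raising.
    """
    config = config or RunConfig()
    tables: dict[str, pd.DataFrame] = {}
    lines: list[str] = [f"# {title}", ""]

    any_section = False
    for zset in zsets or []:
        any_section = True
        name = zset.label or f"zscores_{len(tables)}"
        tables[name] = zset_frame(zset)
        lines += _zset_markdown(zset, name.replace("_", " "))

    if bmdd_results:
        any_section = True
        df = pd.DataFrame(
            {comp: res.as_dict() for comp, res in bmdd_results.items()}
        )
        tables["bmdd_parameters"] = df
        lines += ["### BMDD parameters", "", df.round(2).to_markdown(), ""]
        if {"cortical", "trabecular"} <= set(bmdd_results):
            diffs = compare_compartments(
                bmdd_results["cortical"], bmdd_results["trabecular"]
            )
            tables["bmdd_compartment_diff_pct"] = pd.DataFrame(
                {"percent_difference": diffs}
            )
            lines += ["### Cortical vs trabecular (% difference)", ""]
            lines += [f"- {k}: {v:+.1f}%" for k, v in diffs.items()]
            lines.append("")

    if ols is not None:
        any_section = True
        df = pd.DataFrame({"value": ols.as_dict()})
        tables["ols_summary"] = df
        lines += ["### Osteocyte lacunae sections", "", df.round(3).to_markdown(), ""]

    if not any_section:
        lines += ["_No analysis results supplied._", ""]

    lines += ["---", "", "Configuration:", "", "```json",
              json.dumps(config.to_dict(), indent=2, default=list), "```", ""]
    markdown = "\n".join(lines)
    if not config.ascii_minus:
        # typographic minus in front of numbers only; machine CSVs stay ASCII
        import re

        markdown = re.sub(r"-(?=\d)", "−", markdown)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.md").write_text(markdown)
        for name, df in tables.items():
            df.to_csv(out_dir / f"{name}.csv")
        (out_dir / "config.json").write_text(
            json.dumps(config.to_dict(), indent=2, default=list)
        )
    return {"markdown": markdown, "tables": tables, "config": config.to_dict()}
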