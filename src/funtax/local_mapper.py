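"""Single-pathway drill-down: enzyme-level profiles, per-taxon contributor
tables in lineage context, and KEGG Mapper "Search&Color" export files."""

from __future__ import annotations

import difflib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .function_db import FunctionDB, PathwayDefinition
from .inference import ContributionTensor, UnitProfile

logger = logging.getLogger(__name__)

#: 5-bin diverging palette over log2 class ratio clipped to +/-2
#: (class_b-enriched blue ... neutral ... class_a-enriched red).
DEFAULT_PALETTE: tuple[str, ...] = (
    "#2166ac", "#92c5de", "#f7f7f7", "#f4a582", "#b2182b",
)
NEUTRAL_GRAY = "#bdbdbd"
FOREGROUND = "#000000"
LOG_RATIO_CLIP = 2.0
KEGG_NAMESPACES = ("EC", "KO")


class LocalMapperError(ValueError):
    pass


@dataclass
class PathwayReport:
    pathway_id: str
    enzyme_profile: pd.DataFrame         # member units x samples, columns sum to 1
    coverage: pd.Series                  # per-sample detected-unit fraction
    contributors: pd.DataFrame           # taxon, lineage, one mean column per group
    namespace: str
    groups: dict[str, list[str]] = field(default_factory=dict)


def _resolve_pathway(db: FunctionDB, pathway_id: str) -> PathwayDefinition:
    try:
        return db.pathway(pathway_id)
    except KeyError:
        ids = [p.pathway_id for p in db.pathways]
        near = difflib.get_close_matches(pathway_id, ids, n=3)
        raise LocalMapperError(
            f"unknown pathway {pathway_id!r}; close matches: {near or ids[:3]}"
        ) from None


def _group_map(samples: list[str], groups: pd.Series | None) -> dict[str, list[str]]:
    if groups is None:
        return {"all": list(samples)}
    out: dict[str, list[str]] = {}
    for s in samples:
        out.setdefault(str(groups.get(s, "NA")), []).append(s)
    return out


def pathway_enzyme_profile(
    up: UnitProfile, db: FunctionDB, pathway_id: str,
    groups: pd.Series | None = None,
) -> PathwayReport:
    """Member-unit abundances renormalized within the pathway, plus the
    per-sample functional coverage (detected-unit fraction)."""
    pw = _resolve_pathway(db, pathway_id)
    members = list(pw.member_units)
    sub = up.abundance.reindex(members).fillna(0.0)
    coverage = (sub > 0).sum(axis=0) / len(members)
    totals = sub.sum(axis=0)
    if (totals == 0).any():
        logger.warning(
            "pathway %s undetected in samples %s",
            pathway_id, list(totals.index[totals == 0]),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        profile = sub.div(totals.where(totals > 0), axis=1).fillna(0.0)
    return PathwayReport(
        pathway_id=pathway_id,
        enzyme_profile=profile,
        coverage=coverage,
        contributors=pd.DataFrame(),
        namespace=up.namespace,
        groups=_group_map(list(up.abundance.columns), groups),
    )


def pathway_contributors(
    ct: ContributionTensor, db: FunctionDB, pathway_id: str,
    groups: pd.Series | None = None,
    lineages: dict[str, dict[str, str]] | None = None,
) -> pd.DataFrame:
    """Per-group mean taxon contributions to one pathway ("dendrobar" table).

    Each row carries the taxon's full lineage path so a lineage tree with
    leaf bars can be rendered; taxa contributing nothing in any group are
    omitted.
    """
    _resolve_pathway(db, pathway_id)
    if pathway_id not in ct.functions:
        raise LocalMapperError(f"pathway {pathway_id!r} not in contribution tensor")
    by_label = _group_map(ct.samples, groups)
    rows = []
    for taxon in ct.taxa:
        series = ct.taxon_series(taxon, pathway_id)
        means = {label: float(series[s].mean()) for label, s in sorted(by_label.items())}
        if not any(v > 0 for v in means.values()):
            continue
        lineage = (lineages or {}).get(taxon, {})
        rows.append(
            {
                "taxon": taxon,
                "lineage": "; ".join(f"{r}:{n}" for r, n in lineage.items()) or taxon,
                **{f"mean_{label}": v for label, v in means.items()},
            }
        )
    cols = ["taxon", "lineage"] + [f"mean_{label}" for label in sorted(by_label)]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# KEGG Mapper export


def _bin_color(log_ratio: float, palette: tuple[str, ...]) -> str:
    clipped = float(np.clip(log_ratio, -LOG_RATIO_CLIP, LOG_RATIO_CLIP))
    edges = np.linspace(-LOG_RATIO_CLIP, LOG_RATIO_CLIP, len(palette) + 1)
    idx = int(np.searchsorted(edges[1:-1], clipped, side="right"))
    return palette[idx]


def export_kegg_colormap(
    pr: PathwayReport,
    class_a: str,
    class_b: str,
    path: str | Path,
    palette: tuple[str, ...] = DEFAULT_PALETTE,
    pseudocount: float = 1e-9,
) -> Path:
    """Write a KEGG Mapper Search&Color file for a two-class comparison.

    One line per member unit, ``<id>\\t<bgcolor>,<fgcolor>``; the background
    encodes the 5-bin diverging log2 ratio of class means (positive toward
    `class_a`); units undetected in both classes get neutral gray.  ASCII,
    LF line endings.
    """
    if pr.namespace not in KEGG_NAMESPACES:
        raise LocalMapperError(
            f"namespace {pr.namespace!r} is not KEGG-mappable (need one of {KEGG_NAMESPACES})"
        )
    for cls in (class_a, class_b):
        if cls not in pr.groups:
            raise LocalMapperError(f"class {cls!r} not in grouping {sorted(pr.groups)}")
    mean_a = pr.enzyme_profile[pr.groups[class_a]].mean(axis=1)
    mean_b = pr.enzyme_profile[pr.groups[class_b]].mean(axis=1)

    lines = []
    for unit in pr.enzyme_profile.index:
        a, b = float(mean_a[unit]), float(mean_b[unit])
        if a == 0 and b == 0:
            bg = NEUTRAL_GRAY
        else:
            bg = _bin_color(np.log2((a + pseudocount) / (b + pseudocount)), palette)
        lines.append(f"{unit}\t{bg},{FOREGROUND}")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n", encoding="ascii", newline="\n")
    return path


def export_kegg_heightmap(pr: PathwayReport, path: str | Path) -> Path:
    """Companion numeric file for KEGG 3D maps: unit, mean abundance height."""
    heights = pr.enzyme_profile.mean(axis=1)
    lines = [f"{unit}\t{heights[unit]:.10g}" for unit in pr.enzyme_profile.index]
    path = Path(path)
    path.write_text("\n".join(lines) + "\n", encoding="ascii", newline="\n")
    return path


def parse_kegg_colormap(path: str | Path) -> pd.DataFrame:
    """Strict parser of the emitted Search&Color dialect (round-trip check)."""
    rows = []
    for i, line in enumerate(Path(path).read_text(encoding="ascii").splitlines(), start=1):
        parts = line.split("\t")
        if len(parts) != 2:
            raise LocalMapperError(f"line {i}: expected one tab, got {line!r}")
        unit, colors = parts
        bg, _, fg = colors.partition(",")
        for c in (bg, fg):
            if not (len(c) == 7 and c[0] == "#" and all(ch in "0123456789abcdefABCDEF" for ch in c[1:])):
                raise LocalMapperError(f"line {i}: bad color {c!r}")
        rows.append({"unit": unit, "bgcolor": bg, "fgcolor": fg})
    return pd.DataFrame(rows)
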