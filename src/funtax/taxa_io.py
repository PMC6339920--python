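"""Parsing of taxonomic abundance tables (Greengenes / SILVA / RDP lineage
dialects) and multi-column sample metadata.

Abundance input may be counts or proportions; every sample column is
renormalized to sum 1, since the inference math is scale-free per sample.
Duplicate lineages are merged by summation (standard OTU-table collapse).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .function_db import RANKS, normalize_name

logger = logging.getLogger(__name__)

DIALECTS = ("greengenes", "silva", "rdp")

_GG_PREFIX_RE = re.compile(r"[kdpcofgs]__")
_GG_RANK = {
    "k": "domain", "d": "domain", "p": "phylum", "c": "class",
    "o": "order", "f": "family", "g": "genus", "s": "species",
}
#: tokens that terminate a lineage (prevent spurious genome matches)
_STOP_TOKENS = {"unclassified", "uncultured", "unknown", "other", ""}

_RDP_RANK_TOKENS = {
    "rootrank", "domain", "kingdom", "phylum", "class", "subclass",
    "order", "suborder", "family", "genus", "species",
}


class ParseError(ValueError):
    """Raised on malformed taxa or metadata tables."""


@dataclass
class TaxaProfile:
    """Taxa x samples relative-abundance matrix with parsed lineages."""

    lineages: list[dict[str, str]]          # rank -> name, canonical order
    deepest_ranks: list[str]
    samples: list[str]
    abundance: pd.DataFrame                 # index: lineage keys, cols: samples
    dialect: str
    unassigned_mass: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def __post_init__(self) -> None:
        if self.abundance.lt(0).any().any():
            raise ParseError("negative abundance entries")
        sums = self.abundance.sum(axis=0)
        bad = sums[(sums > 0) & (~np.isclose(sums, 1.0, atol=1e-9))]
        if len(bad):
            raise ParseError(f"columns not normalized: {list(bad.index)}")
        if len(set(self.samples)) != len(self.samples):
            raise ParseError("duplicate sample ids")


@dataclass
class SampleMetadata:
    samples: list[str]
    categories: dict[str, dict[str, str]]   # category -> sample -> label

    def labels(self, category: str) -> pd.Series:
        if category not in self.categories:
            raise ParseError(
                f"unknown metadata category {category!r}; have {sorted(self.categories)}"
            )
        return pd.Series(self.categories[category])


# ---------------------------------------------------------------------------
# dialect detection


def detect_dialect(first_column_values: list[str]) -> str:
    """Auto-detect the lineage dialect of a taxa table's first column.

    Greengenes when at least half the strings carry ``x__`` rank prefixes;
    SILVA when semicolon-delimited prefix-free strings start from a known
    domain token with >= 5 fields; RDP otherwise.
    """
    values = [v for v in first_column_values if v and v.strip()]
    if not values:
        raise ParseError("no lineage strings to detect dialect from")

    n = len(values)
    n_prefixed = sum(1 for v in values if _GG_PREFIX_RE.search(v))
    if n_prefixed / n >= 0.5:
        logger.info("dialect=greengenes (%d/%d strings carry rank prefixes)", n_prefixed, n)
        return "greengenes"

    def is_silva(v: str) -> bool:
        fields = [f.strip() for f in v.split(";")]
        return (
            len(fields) >= 5
            and not _GG_PREFIX_RE.search(v)
            and normalize_name(fields[0]) in ("bacteria", "archaea")
        )

    n_silva = sum(1 for v in values if is_silva(v))
    if n_silva / n >= 0.5:
        logger.info("dialect=silva (%d/%d domain-rooted prefix-free strings)", n_silva, n)
        return "silva"
    logger.info("dialect=rdp (fallback; %d strings)", n)
    return "rdp"


# ---------------------------------------------------------------------------
# lineage parsing


def _truncate_at_stop(names: list[tuple[str, str]]) -> list[tuple[str, str]]:
    out = []
    for rank, name in names:
        if normalize_name(name) in _STOP_TOKENS:
            break
        out.append((rank, name))
    return out


def parse_lineage(value: str, dialect: str) -> dict[str, str]:
    """Parse one lineage string into an ordered rank -> name map."""
    tokens = [t.strip() for t in value.split(";")]
    pairs: list[tuple[str, str]] = []
    if dialect == "greengenes":
        for t in tokens:
            m = re.match(r"^([a-zA-Z])__(.*)$", t)
            if m and m.group(1).lower() in _GG_RANK:
                pairs.append((_GG_RANK[m.group(1).lower()], m.group(2)))
    elif dialect == "silva":
        for rank, t in zip(RANKS, tokens):
            pairs.append((rank, t))
    elif dialect == "rdp":
        tokens = [t for t in tokens if normalize_name(t) != "root"]
        # name;rank alternation if every second token is a rank word
        if len(tokens) >= 2 and all(
            normalize_name(t) in _RDP_RANK_TOKENS for t in tokens[1::2]
        ):
            for name, rank in zip(tokens[0::2], tokens[1::2]):
                r = normalize_name(rank)
                r = {"kingdom": "domain", "rootrank": "domain"}.get(r, r)
                if r in RANKS:
                    pairs.append((r, name))
        else:
            for rank, t in zip(RANKS, tokens):
                pairs.append((rank, t))
    else:
        raise ParseError(f"unknown dialect {dialect!r}")

    pairs = _truncate_at_stop(pairs)
    lineage: dict[str, str] = {}
    for rank in RANKS:                      # canonical order, no repeats
        for r, name in pairs:
            if r == rank and rank not in lineage:
                lineage[rank] = name.strip()
    return lineage


def lineage_key(lineage: dict[str, str]) -> str:
    """Canonical Greengenes-style string form of a parsed lineage."""
    return "; ".join(
        f"{rank[0] if rank != 'domain' else 'k'}__{lineage[rank]}"
        for rank in RANKS
        if rank in lineage
    )


# ---------------------------------------------------------------------------
# table parsing


def parse_taxa_table(path: str | Path, dialect: str | None = None) -> TaxaProfile:
    """Parse a TSV taxa table (lineages in column 1, samples thereafter)."""
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if raw.shape[1] < 2:
        raise ParseError(f"{path}: need a lineage column plus >= 1 sample column")
    lineage_col = raw.columns[0]
    samples = [str(c) for c in raw.columns[1:]]
    if raw[lineage_col].isna().any() or raw.iloc[:, 1:].isna().any().any():
        raise ParseError(f"{path}: ragged or empty cells")

    try:
        values = raw.iloc[:, 1:].astype(float)
    except ValueError:
        for i, row in raw.iloc[:, 1:].iterrows():
            for col, cell in row.items():
                try:
                    float(cell)
                except ValueError:
                    raise ParseError(
                        f"{path}: non-numeric abundance {cell!r} at row {i + 2}, column {col!r}"
                    ) from None
        raise
    if (values < 0).any().any():
        raise ParseError(f"{path}: negative abundances")

    if dialect is None:
        dialect = detect_dialect(list(raw[lineage_col]))
    elif dialect not in DIALECTS:
        raise ParseError(f"unknown dialect {dialect!r}")

    col_totals = values.sum(axis=0)
    merged: dict[str, np.ndarray] = {}
    lineage_by_key: dict[str, dict[str, str]] = {}
    unassigned = np.zeros(len(samples))
    dropped_rows = 0
    for i in range(len(raw)):
        lineage = parse_lineage(str(raw.iloc[i, 0]), dialect)
        row = values.iloc[i].to_numpy()
        if not lineage:
            unassigned += row
            dropped_rows += 1
            continue
        if not row.any():
            dropped_rows += 1
            logger.info("dropping all-zero row %r", raw.iloc[i, 0])
            continue
        key = lineage_key(lineage)
        if key in merged:
            merged[key] = merged[key] + row
        else:
            merged[key] = row
            lineage_by_key[key] = lineage
    if not merged:
        raise ParseError(f"{path}: no parseable, nonzero taxa rows")
    if dropped_rows:
        logger.info("dropped %d unparseable/all-zero rows", dropped_rows)

    abundance = pd.DataFrame(merged, index=samples).T
    totals = abundance.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        abundance = abundance.div(totals.where(totals > 0), axis=1).fillna(0.0)
    zero_cols = totals[totals == 0]
    if len(zero_cols):
        logger.warning("all-zero sample columns: %s", list(zero_cols.index))

    safe_tot = col_totals.replace(0, np.nan)
    unassigned_mass = pd.Series(unassigned, index=samples) / safe_tot.to_numpy()
    unassigned_mass = unassigned_mass.fillna(0.0)

    lineages = [lineage_by_key[k] for k in abundance.index]
    deepest = [[r for r in RANKS if r in lg][-1] for lg in lineages]
    return TaxaProfile(lineages, deepest, samples, abundance, dialect, unassigned_mass)


def write_taxa_table(profile: TaxaProfile, path: str | Path) -> None:
    """Write a profile back to TSV (canonical Greengenes lineage strings)."""
    out = profile.abundance.copy()
    out.index.name = "lineage"
    out.to_csv(path, sep="\t", float_format="%.12g")


def parse_metadata(path: str | Path, profile: TaxaProfile) -> SampleMetadata:
    """Parse a metadata TSV (sample id column 1, one category per column)."""
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if raw.shape[1] < 2:
        raise ParseError(f"{path}: need a sample column plus >= 1 category column")
    sample_col = raw.columns[0]
    ids = [str(s) for s in raw[sample_col]]
    dupes = {s for s in ids if ids.count(s) > 1}
    if dupes:
        raise ParseError(f"{path}: duplicate sample rows {sorted(dupes)}")
    unknown = [s for s in ids if s not in profile.samples]
    if unknown:
        raise ParseError(f"{path}: sample ids absent from profile: {unknown}")

    categories: dict[str, dict[str, str]] = {}
    for cat in raw.columns[1:]:
        mapping = dict(zip(ids, raw[cat].fillna("NA").astype(str)))
        for s in profile.samples:
            if s not in mapping:
                logger.info("sample %s missing from metadata; labeled NA in %r", s, cat)
                mapping[s] = "NA"
        categories[str(cat)] = mapping
    return SampleMetadata(list(profile.samples), categories)
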