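"""Genome-function database: data model, serialization, lookup, synthetic generation.

The back-end map pairs every reference genome with its 16S rRNA gene copy
number and its per-functional-unit copy counts (EC / KO / COG / Pfam /
TIGRfam), plus pathway definitions arranged in a three-level functional
hierarchy and cross-maps between unit namespaces.  Downstream inference only
ever touches this map through :func:`taxon_lookup`, which aggregates genome
records matching a query lineage.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical taxonomic ranks, shallowest to deepest.
RANKS: tuple[str, ...] = (
    "domain", "phylum", "class", "order", "family", "genus", "species",
)

#: Supported functional-unit namespaces.
NAMESPACES: tuple[str, ...] = ("EC", "KO", "COG", "Pfam", "TIGRfam")

_RANK_PREFIX_RE = re.compile(r"^[a-zA-Z]__")
_BRACKET_RE = re.compile(r"\[[^\]]*\]")


class DatabaseError(ValueError):
    """Raised on structural or referential-integrity violations."""


def normalize_name(name: str) -> str:
    """Normalize a taxon name for matching.

    Lower-cases, strips Greengenes-style rank prefixes (``g__``), bracketed
    qualifiers (``[Clostridium]``) and surrounding whitespace.
    """
    name = _RANK_PREFIX_RE.sub("", name.strip())
    name = _BRACKET_RE.sub("", name)
    return re.sub(r"\s+", " ", name).strip().lower()


def _validate_lineage(lineage: dict[str, str]) -> None:
    ranks = list(lineage)
    if len(set(ranks)) != len(ranks):
        raise DatabaseError(f"repeated rank in lineage: {ranks}")
    order = [r for r in RANKS if r in lineage]
    if ranks != order:
        raise DatabaseError(f"lineage ranks out of canonical order: {ranks}")
    unknown = set(ranks) - set(RANKS)
    if unknown:
        raise DatabaseError(f"unknown ranks in lineage: {sorted(unknown)}")


@dataclass
class GenomeRecord:
    """One reference genome: lineage, 16S copies, functional-unit copy counts."""

    genome_id: str
    lineage: dict[str, str]
    ssu_copies: int
    unit_copies: dict[str, int]

    def __post_init__(self) -> None:
        if self.ssu_copies < 1:
            raise DatabaseError(
                f"genome {self.genome_id}: ssu_copies must be >= 1, got {self.ssu_copies}"
            )
        bad = {u: c for u, c in self.unit_copies.items() if c < 0}
        if bad:
            raise DatabaseError(f"genome {self.genome_id}: negative copy counts {bad}")
        _validate_lineage(self.lineage)


@dataclass(frozen=True)
class FunctionalUnit:
    unit_id: str
    namespace: str
    description: str = ""

    def __post_init__(self) -> None:
        if self.namespace not in NAMESPACES:
            raise DatabaseError(
                f"unit {self.unit_id}: namespace {self.namespace!r} not in {NAMESPACES}"
            )


@dataclass
class PathwayDefinition:
    """A pathway: a named set of functional units under a 3-level hierarchy."""

    pathway_id: str
    name: str
    level1: str
    level2: str
    level3: str
    member_units: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.member_units:
            raise DatabaseError(f"pathway {self.pathway_id}: empty member_units")
        self.member_units = tuple(sorted(set(self.member_units)))


@dataclass
class CrossMap:
    """Many-to-many mapping between two unit namespaces."""

    source_namespace: str
    target_namespace: str
    pairs: frozenset[tuple[str, str]]

    def outdegree(self, source_id: str) -> int:
        return sum(1 for s, _ in self.pairs if s == source_id)


@dataclass
class FunctionDB:
    genomes: list[GenomeRecord]
    units: dict[str, FunctionalUnit]
    pathways: list[PathwayDefinition]
    crossmaps: list[CrossMap] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- integrity ---------------------------------------------------------
    def validate(self) -> None:
        if not self.genomes:
            raise DatabaseError("database holds no genomes")
        if not self.pathways:
            raise DatabaseError("database holds no pathways")
        dangling: set[str] = set()
        for g in self.genomes:
            dangling.update(u for u in g.unit_copies if u not in self.units)
        for p in self.pathways:
            dangling.update(u for u in p.member_units if u not in self.units)
        for cm in self.crossmaps:
            dangling.update(s for s, _ in cm.pairs if s not in self.units)
            dangling.update(t for _, t in cm.pairs if t not in self.units)
        if dangling:
            raise DatabaseError(
                f"dangling unit references: {sorted(dangling)}"
            )
        seen_pw = set()
        for p in self.pathways:
            if p.pathway_id in seen_pw:
                raise DatabaseError(f"duplicate pathway_id {p.pathway_id}")
            seen_pw.add(p.pathway_id)

    # -- convenience views -------------------------------------------------
    def units_in_namespace(self, namespace: str) -> list[str]:
        return sorted(u for u, rec in self.units.items() if rec.namespace == namespace)

    def pathways_in_namespace(self, namespace: str) -> list[PathwayDefinition]:
        ns_units = {u for u, rec in self.units.items() if rec.namespace == namespace}
        return [p for p in self.pathways if set(p.member_units) <= ns_units]

    def pathway(self, pathway_id: str) -> PathwayDefinition:
        for p in self.pathways:
            if p.pathway_id == pathway_id:
                return p
        raise KeyError(pathway_id)

    def unit_multiplicity(self, namespace: str) -> dict[str, int]:
        """Number of pathways (in `namespace`) containing each unit."""
        mult: dict[str, int] = {}
        for p in self.pathways_in_namespace(namespace):
            for u in p.member_units:
                mult[u] = mult.get(u, 0) + 1
        return mult

    def crossmap(self, source_namespace: str, target_namespace: str) -> CrossMap:
        for cm in self.crossmaps:
            if (cm.source_namespace, cm.target_namespace) == (source_namespace, target_namespace):
                return cm
        raise DatabaseError(
            f"no crossmap from {source_namespace} to {target_namespace}"
        )

    def copy_matrix(self, namespace: str) -> pd.DataFrame:
        """Dense genome x unit copy-count matrix for one namespace (zeros filled)."""
        cols = self.units_in_namespace(namespace)
        data = np.zeros((len(self.genomes), len(cols)))
        idx = {u: j for j, u in enumerate(cols)}
        for i, g in enumerate(self.genomes):
            for u, c in g.unit_copies.items():
                j = idx.get(u)
                if j is not None:
                    data[i, j] = c
        return pd.DataFrame(data, index=[g.genome_id for g in self.genomes], columns=cols)


# ---------------------------------------------------------------------------
# lookup


def taxon_lookup(
    db: FunctionDB, lineage: dict[str, str], rank: str
) -> tuple[pd.Series, float, int]:
    """Aggregate genome records matching `lineage` at `rank`.

    A genome matches when its (normalized) name equals the query's at `rank`
    and at every shallower rank the query provides.  Returns the arithmetic
    mean unit-copy vector over matched genomes (indexed by every unit id in
    the database, zeros filled), the mean 16S copy number, and the number of
    genomes matched.  No match yields an empty vector, NaN and 0, and the
    miss is logged.
    """
    if rank not in RANKS:
        raise DatabaseError(f"unknown rank {rank!r}; expected one of {RANKS}")
    depth = RANKS.index(rank)
    query = {
        r: normalize_name(lineage[r])
        for r in RANKS[: depth + 1]
        if r in lineage and lineage[r]
    }
    if rank not in query:
        raise DatabaseError(f"query lineage lacks a name at rank {rank!r}")

    matched = [
        g
        for g in db.genomes
        if all(normalize_name(g.lineage.get(r, "")) == name for r, name in query.items())
    ]
    if not matched:
        logger.warning("taxon_lookup miss: %s at rank %s", query, rank)
        return pd.Series(dtype=float), float("nan"), 0

    all_units = sorted(db.units)
    vec = pd.Series(0.0, index=all_units)
    for g in matched:
        for u, c in g.unit_copies.items():
            vec[u] += c
    vec /= len(matched)
    ssu = float(np.mean([g.ssu_copies for g in matched]))
    return vec, ssu, len(matched)


# ---------------------------------------------------------------------------
# serialization (four flat TSVs: inspectable, diffable fixtures)


def save_db(db: FunctionDB, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    all_units = sorted(db.units)
    rows = []
    for g in db.genomes:
        row: dict[str, object] = {"genome_id": g.genome_id}
        for r in RANKS:
            row[r] = g.lineage.get(r, "")
        row["ssu_copies"] = g.ssu_copies
        for u in all_units:
            row[u] = g.unit_copies.get(u, 0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path / "genomes.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {"unit_id": u.unit_id, "namespace": u.namespace, "description": u.description}
            for u in sorted(db.units.values(), key=lambda u: u.unit_id)
        ]
    ).to_csv(path / "units.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "pathway_id": p.pathway_id,
                "name": p.name,
                "level1": p.level1,
                "level2": p.level2,
                "level3": p.level3,
                "member_units": ";".join(p.member_units),
            }
            for p in db.pathways
        ]
    ).to_csv(path / "pathways.tsv", sep="\t", index=False)

    cm_rows = [
        {
            "source_ns": cm.source_namespace,
            "target_ns": cm.target_namespace,
            "source_id": s,
            "target_id": t,
        }
        for cm in db.crossmaps
        for s, t in sorted(cm.pairs)
    ]
    pd.DataFrame(cm_rows, columns=["source_ns", "target_ns", "source_id", "target_id"]).to_csv(
        path / "crossmaps.tsv", sep="\t", index=False
    )


def load_db(path: str | Path) -> FunctionDB:
    path = Path(path)
    for table in ("genomes", "units", "pathways", "crossmaps"):
        if not (path / f"{table}.tsv").exists():
            raise DatabaseError(f"missing table {table}.tsv in {path}")

    units_df = pd.read_csv(path / "units.tsv", sep="\t", dtype=str).fillna("")
    units = {
        r.unit_id: FunctionalUnit(r.unit_id, r.namespace, r.description)
        for r in units_df.itertuples()
    }

    gdf = pd.read_csv(path / "genomes.tsv", sep="\t", dtype={"genome_id": str})
    unit_cols = [c for c in gdf.columns if c not in ("genome_id", "ssu_copies", *RANKS)]
    genomes = []
    for rec in gdf.to_dict("records"):
        lineage = {
            rank: str(rec[rank]) for rank in RANKS if rank in rec and str(rec[rank]) not in ("", "nan")
        }
        copies = {u: int(rec[u]) for u in unit_cols if int(rec[u]) > 0}
        genomes.append(
            GenomeRecord(str(rec["genome_id"]), lineage, int(rec["ssu_copies"]), copies)
        )

    pdf = pd.read_csv(path / "pathways.tsv", sep="\t", dtype=str)
    pathways = [
        PathwayDefinition(
            r.pathway_id, r.name, r.level1, r.level2, r.level3,
            tuple(r.member_units.split(";")),
        )
        for r in pdf.itertuples()
    ]

    cdf = pd.read_csv(path / "crossmaps.tsv", sep="\t", dtype=str)
    crossmaps = []
    if len(cdf):
        for (src, tgt), grp in cdf.groupby(["source_ns", "target_ns"], sort=True):
            crossmaps.append(
                CrossMap(src, tgt, frozenset(zip(grp["source_id"], grp["target_id"])))
            )
    return FunctionDB(genomes, units, pathways, crossmaps)


# ---------------------------------------------------------------------------
# synthetic database generation

_LEVEL1 = ("Metabolism", "Cellular Processes")
_LEVEL2 = {
    "Metabolism": ("Amino Acid Metabolism", "Carbohydrate Metabolism", "Energy Metabolism"),
    "Cellular Processes": ("Cell Motility", "Transport and Catabolism"),
}


def generate_synthetic_db(
    n_genomes: int = 20,
    n_units: int = 40,
    n_pathways: int = 6,
    max_copies: int = 6,
    seed: int = 0,
) -> FunctionDB:
    """Generate a structurally realistic random genome-function database.

    Lineages are drawn from a small generated taxonomy; 16S copy numbers are
    uniform on [1, 15] (the biological span of known genomes); unit copy
    counts uniform on [0, max_copies]; each pathway holds 3-12 EC members
    under a full 3-level hierarchy path.  A KO namespace of equal size and an
    EC->KO crossmap (1-2 targets per EC) are included so cross-mapping is
    exercised.  The same seed always yields an identical database.
    """
    if n_units < 3:
        raise DatabaseError("n_units must be >= 3 (pathways need >= 3 candidate members)")
    if min(n_genomes, n_pathways, max_copies) < 1:
        raise DatabaseError("all counts must be >= 1")
    rng = np.random.default_rng(seed)

    ec_ids = [f"E{i:04d}" for i in range(n_units)]
    ko_ids = [f"K{i:05d}" for i in range(n_units)]
    units = {u: FunctionalUnit(u, "EC", f"enzyme {u}") for u in ec_ids}
    units.update({u: FunctionalUnit(u, "KO", f"ortholog {u}") for u in ko_ids})

    # small random taxonomy: genera hang off a pool of higher clades
    n_genera = max(2, n_genomes // 2)
    phyla = [f"Phylum{i:02d}" for i in range(max(2, n_genera // 3))]
    genera = []
    for i in range(n_genera):
        ph = phyla[int(rng.integers(len(phyla)))]
        genera.append(
            {
                "domain": "Bacteria",
                "phylum": ph,
                "class": f"{ph}Class",
                "order": f"{ph}Order",
                "family": f"{ph}Family{int(rng.integers(2))}",
                "genus": f"Genus{i:03d}",
            }
        )

    genomes = []
    for i in range(n_genomes):
        base = genera[int(rng.integers(n_genera))]
        lineage = dict(base)
        lineage["species"] = f"{base['genus'].lower()} sp{i:03d}"
        copies_vec = rng.integers(0, max_copies + 1, size=n_units)
        unit_copies = {ec_ids[j]: int(c) for j, c in enumerate(copies_vec) if c > 0}
        genomes.append(
            GenomeRecord(
                genome_id=f"G{i:04d}",
                lineage=lineage,
                ssu_copies=int(rng.integers(1, 16)),
                unit_copies=unit_copies,
            )
        )

    pathways = []
    for i in range(n_pathways):
        size = int(rng.integers(3, min(12, n_units) + 1))
        members = rng.choice(n_units, size=size, replace=False)
        l1 = _LEVEL1[int(rng.integers(len(_LEVEL1)))]
        l2 = _LEVEL2[l1][int(rng.integers(len(_LEVEL2[l1])))]
        l3 = f"Pathway {i:02d}"
        pathways.append(
            PathwayDefinition(
                pathway_id=f"P{i:03d}",
                name=l3,
                level1=l1,
                level2=l2,
                level3=l3,
                member_units=tuple(ec_ids[j] for j in members),
            )
        )

    pairs = set()
    for j, ec in enumerate(ec_ids):
        n_targets = int(rng.integers(1, 3))
        targets = rng.choice(n_units, size=n_targets, replace=False)
        for t in targets:
            pairs.add((ec, ko_ids[t]))
    crossmaps = [CrossMap("EC", "KO", frozenset(pairs))]

    return FunctionDB(genomes, units, pathways, crossmaps)
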