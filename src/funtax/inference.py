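"""Community function inference from taxonomic profiles.

The pipeline: (1) divide each taxon's relative abundance by its mean 16S
gene copy number (amplicon counts over-represent multi-copy organisms),
(2) expand the corrected community through per-taxon functional-unit copy
numbers into a unit abundance profile, (3) optionally cross-map units to
other namespaces, and (4) estimate pathway abundances under one of two
assumptions:

* **CoM** (co-metabolism) — community members pool the units they encode;
  pathway presence and abundance are evaluated on the pooled profile.
* **ICo** (independent contributions) — each taxon is an independent
  functional entity; pathway abundance is computed per taxon and summed,
  yielding a taxon x pathway x sample contribution tensor.

A pathway is reported present in a sample only when the detected fraction of
its member units reaches the pathway exclusion cut-off (PEC) quorum, swept
over 50-90% in 10-point steps.  A unit shared by several pathways has its
abundance split equally among them ("multiplicity split") so pathway totals
conserve unit mass; ``split=False`` disables this.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .function_db import FunctionDB, PathwayDefinition, taxon_lookup
from .taxa_io import TaxaProfile, lineage_key

logger = logging.getLogger(__name__)

#: PEC quorum grid (percent).
PEC_GRID: tuple[int, ...] = (50, 60, 70, 80, 90)
PEC_ALLOWED: tuple[int, ...] = (0, *PEC_GRID)


class InferenceError(ValueError):
    pass


@dataclass
class CoverageReport:
    """Per-sample accounting of input mass that could not be inferred."""

    dropped_mass: pd.Series              # fraction of mass on unmatched taxa
    uninferable_samples: list[str]
    unmatched_taxa: list[str]


@dataclass
class CorrectedProfile:
    """16S-copy-corrected taxa x samples matrix plus lineage context."""

    abundance: pd.DataFrame              # taxa keys x samples, columns sum to 1
    lineages: dict[str, dict[str, str]]  # taxon key -> lineage
    deepest_ranks: dict[str, str]
    coverage: CoverageReport

    @property
    def samples(self) -> list[str]:
        return list(self.abundance.columns)


@dataclass
class UnitProfile:
    """Functional-unit x sample abundance matrix (one namespace)."""

    abundance: pd.DataFrame
    namespace: str
    provenance: str = "CoM"


@dataclass
class FunctionProfile:
    """Pathway (or hierarchy-level) x sample abundances.

    ``abundance`` is column-normalized over surviving functions; ``raw``
    keeps the pre-normalization values so contribution conservation can be
    checked exactly.
    """

    abundance: pd.DataFrame
    raw: pd.DataFrame
    level: str
    algorithm: str
    pec: int

    def __post_init__(self) -> None:
        if self.pec not in PEC_ALLOWED:
            raise InferenceError(f"pec {self.pec} not in {PEC_ALLOWED}")


@dataclass
class ContributionTensor:
    """Taxon x function x sample ICo contributions (pre-normalization)."""

    values: pd.DataFrame                 # MultiIndex (taxon, function) x samples
    taxa: list[str]
    functions: list[str]
    samples: list[str]
    normalizer: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def taxon_series(self, taxon: str, function: str) -> pd.Series:
        return self.values.loc[(taxon, function)]

    def summed(self) -> pd.DataFrame:
        """Sum over taxa: reproduces the un-normalized ICo profile."""
        out = self.values.groupby(level=1, sort=False).sum()
        return out.reindex(self.functions)


# ---------------------------------------------------------------------------
# step 2: 16S copy-number correction


def correct_abundance(
    profile: TaxaProfile, db: FunctionDB
) -> tuple[CorrectedProfile, CoverageReport]:
    """Divide taxon abundances by mean 16S copies and renormalize columns."""
    keys = [lineage_key(lg) for lg in profile.lineages]
    ssu = {}
    unmatched = []
    for key, lg, rank in zip(keys, profile.lineages, profile.deepest_ranks):
        _, mean_ssu, n = taxon_lookup(db, lg, rank)
        if n == 0:
            unmatched.append(key)
        else:
            ssu[key] = mean_ssu

    ab = profile.abundance
    dropped = ab.loc[[k for k in keys if k in set(unmatched)]].sum(axis=0)
    kept = ab.loc[[k for k in keys if k in ssu]]
    corrected = kept.div(pd.Series(ssu).reindex(kept.index), axis=0)
    totals = corrected.sum(axis=0)
    uninferable = [s for s in ab.columns if totals[s] == 0]
    if uninferable:
        logger.warning("samples with no matched taxa (uninferable): %s", uninferable)
    with np.errstate(invalid="ignore", divide="ignore"):
        corrected = corrected.div(totals.where(totals > 0), axis=1).fillna(0.0)

    report = CoverageReport(dropped, uninferable, unmatched)
    cp = CorrectedProfile(
        corrected,
        {k: lg for k, lg in zip(keys, profile.lineages) if k in ssu},
        {k: r for k, r in zip(keys, profile.deepest_ranks) if k in ssu},
        report,
    )
    return cp, report


def _taxon_copy_table(corrected: CorrectedProfile, db: FunctionDB, namespace: str) -> pd.DataFrame:
    """Taxa x unit mean-copy matrix for the corrected profile's taxa."""
    units = db.units_in_namespace(namespace)
    if not units:
        raise InferenceError(f"no units in namespace {namespace!r}")
    rows = {}
    for key in corrected.abundance.index:
        vec, _, n = taxon_lookup(db, corrected.lineages[key], corrected.deepest_ranks[key])
        assert n > 0  # unmatched taxa were dropped by correct_abundance
        rows[key] = vec.reindex(units).fillna(0.0)
    return pd.DataFrame(rows).T.reindex(corrected.abundance.index)


# ---------------------------------------------------------------------------
# step 3: unit profiles and cross-mapping


def community_unit_profile(
    corrected: CorrectedProfile, db: FunctionDB, namespace: str = "EC"
) -> UnitProfile:
    """Pooled (CoM) unit profile: abundance-weighted sum of taxon copy vectors."""
    copies = _taxon_copy_table(corrected, db, namespace)
    data = copies.T @ corrected.abundance
    return UnitProfile(data, namespace, provenance="CoM")


def crossmap_profile(up: UnitProfile, db: FunctionDB, target_namespace: str) -> UnitProfile:
    """Map a unit profile to another namespace, splitting each source unit's
    abundance equally across its mapping targets; unmapped mass is logged."""
    cm = db.crossmap(up.namespace, target_namespace)
    targets = db.units_in_namespace(target_namespace)
    out = pd.DataFrame(0.0, index=targets, columns=up.abundance.columns)
    outdeg: dict[str, int] = {}
    for s, _ in cm.pairs:
        outdeg[s] = outdeg.get(s, 0) + 1
    for s, t in sorted(cm.pairs):
        if s in up.abundance.index:
            out.loc[t] += up.abundance.loc[s] / outdeg[s]
    unmapped = up.abundance.loc[[u for u in up.abundance.index if u not in outdeg]].sum()
    if (unmapped > 0).any():
        logger.info(
            "unmapped source mass per sample (%s->%s): %s",
            up.namespace, target_namespace, unmapped.to_dict(),
        )
    return UnitProfile(out, target_namespace, provenance=f"crossmap:{up.provenance}")


# ---------------------------------------------------------------------------
# step 4: pathway estimation


def pathway_presence(up: UnitProfile, pw: PathwayDefinition, pec: int) -> pd.Series:
    """Quorum rule: present iff detected member fraction >= pec/100."""
    members = [u for u in pw.member_units]
    missing = [u for u in members if u not in up.abundance.index]
    detected = (up.abundance.reindex(members).fillna(0.0) > 0).sum(axis=0)
    frac = detected / len(members)
    if missing:
        logger.debug("pathway %s: units %s absent from profile", pw.pathway_id, missing)
    return frac >= pec / 100.0


def _raw_pathway_matrix(
    unit_ab: pd.DataFrame,
    pathways: list[PathwayDefinition],
    mult: dict[str, int],
    pec: int,
    split: bool,
) -> pd.DataFrame:
    """Un-normalized pathway x sample matrix with quorum filtering applied."""
    raw = {}
    for pw in pathways:
        members = list(pw.member_units)
        sub = unit_ab.reindex(members).fillna(0.0)
        present = (sub > 0).sum(axis=0) / len(members) >= pec / 100.0
        if split:
            weights = np.array([1.0 / mult.get(u, 1) for u in members])
        else:
            weights = np.ones(len(members))
        vals = weights @ sub.to_numpy()
        raw[pw.pathway_id] = np.where(present.to_numpy(), vals, 0.0)
    return pd.DataFrame(raw, index=unit_ab.columns).T


def _normalize_columns(raw: pd.DataFrame) -> pd.DataFrame:
    totals = raw.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return raw.div(totals.where(totals > 0), axis=1).fillna(0.0)


def pathway_abundance_com(
    up: UnitProfile, db: FunctionDB, pec: int = 50, split: bool = True
) -> FunctionProfile:
    """Pathway abundances under the co-metabolism assumption."""
    pathways = db.pathways_in_namespace(up.namespace)
    if not pathways:
        raise InferenceError(f"no pathways defined in namespace {up.namespace!r}")
    mult = db.unit_multiplicity(up.namespace)
    raw = _raw_pathway_matrix(up.abundance, pathways, mult, pec, split)
    if not (raw.sum(axis=0) > 0).any():
        logger.warning("no pathway survives PEC %d in any sample", pec)
    return FunctionProfile(_normalize_columns(raw), raw, "level3", "CoM", pec)


def pathway_abundance_ico(
    corrected: CorrectedProfile, db: FunctionDB, pec: int = 50,
    namespace: str = "EC", split: bool = True,
) -> tuple[FunctionProfile, ContributionTensor]:
    """Pathway abundances under independent contributions.

    Each taxon's private unit vector is quorum-filtered and scored on its
    own; the community profile is the sum over taxa.  The tensor keeps the
    pre-normalization values and the per-sample normalizer, so summing the
    tensor over taxa reproduces the un-normalized profile exactly.
    """
    pathways = db.pathways_in_namespace(namespace)
    if not pathways:
        raise InferenceError(f"no pathways defined in namespace {namespace!r}")
    mult = db.unit_multiplicity(namespace)
    copies = _taxon_copy_table(corrected, db, namespace)

    taxa = list(corrected.abundance.index)
    samples = corrected.samples
    pw_ids = [p.pathway_id for p in pathways]
    blocks = []
    for t in taxa:
        private = np.outer(copies.loc[t].to_numpy(), corrected.abundance.loc[t].to_numpy())
        unit_ab = pd.DataFrame(private, index=copies.columns, columns=samples)
        blocks.append(_raw_pathway_matrix(unit_ab, pathways, mult, pec, split))
    values = pd.concat(blocks, keys=taxa, names=["taxon", "function"])

    raw = values.groupby(level="function", sort=False).sum().reindex(pw_ids)
    raw.index.name = None
    normalizer = raw.sum(axis=0)
    profile = FunctionProfile(_normalize_columns(raw), raw, "level3", "ICo", pec)
    tensor = ContributionTensor(values, taxa, pw_ids, list(samples), normalizer)
    return profile, tensor


def rollup_hierarchy(fp: FunctionProfile, db: FunctionDB, level: str) -> FunctionProfile:
    """Sum a level3 profile up the functional hierarchy (column sums preserved)."""
    if level not in ("level1", "level2"):
        raise InferenceError(f"level must be level1 or level2, got {level!r}")
    if fp.level != "level3":
        raise InferenceError(f"can only roll up a level3 profile, got {fp.level}")
    keymap = {}
    for p in db.pathways:
        keymap[p.pathway_id] = p.level1 if level == "level1" else f"{p.level1}|{p.level2}"
    labels = [keymap.get(f, f) for f in fp.abundance.index]
    ab = fp.abundance.groupby(labels, sort=True).sum()
    raw = fp.raw.groupby(labels, sort=True).sum()
    return FunctionProfile(ab, raw, level, fp.algorithm, fp.pec)


def pec_sweep(
    corrected: CorrectedProfile, db: FunctionDB, algorithm: str = "com",
    namespace: str = "EC", split: bool = True,
) -> dict[int, FunctionProfile]:
    """One FunctionProfile per PEC grid level; presence sets are nested."""
    algorithm = algorithm.lower()
    out: dict[int, FunctionProfile] = {}
    if algorithm == "com":
        up = community_unit_profile(corrected, db, namespace)
        for pec in PEC_GRID:
            out[pec] = pathway_abundance_com(up, db, pec, split)
    elif algorithm == "ico":
        for pec in PEC_GRID:
            out[pec], _ = pathway_abundance_ico(corrected, db, pec, namespace, split)
    else:
        raise InferenceError(f"algorithm must be 'com' or 'ico', got {algorithm!r}")
    return out
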