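"""Synthetic study generator: seeded taxa tables and metadata matching a
synthetic genome-function database.

Emulates a two-factor 16S study (treatment status x timepoint, the classic
treated/control longitudinal design): genus-level lognormal community
profiles with per-sample noise, and a planted multiplicative treatment
effect on a subset of genera so differential tests have signal.  What it
does not emulate: sequencing error, compositional zero-inflation, or real
phylogenetic correlation between genomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .function_db import FunctionDB, RANKS, generate_synthetic_db, save_db

#: defaults for the synthetic study design
N_SAMPLES = 12            # 2 x 2 balanced design, 3 samples per cell
EFFECT_SIZE = 3.0         # fold-change planted on affected genera in Treated
NOISE_SIGMA = 0.5         # per-sample lognormal noise
AFFECTED_FRACTION = 0.3   # fraction of genera carrying the treatment effect


@dataclass
class SyntheticStudy:
    taxa_table: pd.DataFrame      # lineage strings x samples (raw counts)
    metadata: pd.DataFrame        # samples x {Status, Timepoint}


def _genus_lineage_string(lineage: dict[str, str]) -> str:
    prefix = {r: (r[0] if r != "domain" else "k") for r in RANKS}
    return "; ".join(
        f"{prefix[r]}__{lineage[r]}" for r in RANKS[:-1] if r in lineage
    )


def generate_synthetic_study(
    db: FunctionDB,
    n_samples: int = N_SAMPLES,
    seed: int = 0,
    effect_size: float = EFFECT_SIZE,
    noise_sigma: float = NOISE_SIGMA,
    affected_fraction: float = AFFECTED_FRACTION,
) -> SyntheticStudy:
    """Draw a seeded genus-level community table over the database's taxa."""
    rng = np.random.default_rng(seed)
    genera: dict[str, dict[str, str]] = {}
    for g in db.genomes:
        key = _genus_lineage_string(g.lineage)
        genera.setdefault(key, {r: g.lineage[r] for r in RANKS[:-1] if r in g.lineage})
    lineage_strings = sorted(genera)
    n_taxa = len(lineage_strings)

    samples = [f"S{i + 1:02d}" for i in range(n_samples)]
    half = n_samples // 2
    status = ["Control"] * half + ["Treated"] * (n_samples - half)
    timepoint = [("Day2" if i % 2 == 0 else "Day42") for i in range(n_samples)]
    metadata = pd.DataFrame({"Status": status, "Timepoint": timepoint}, index=samples)
    metadata.index.name = "sample"

    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_taxa)
    n_affected = max(1, int(round(affected_fraction * n_taxa)))
    affected = rng.choice(n_taxa, size=n_affected, replace=False)

    table = np.empty((n_taxa, n_samples))
    for j, s in enumerate(samples):
        profile = base * rng.lognormal(mean=0.0, sigma=noise_sigma, size=n_taxa)
        if status[j] == "Treated":
            profile[affected] *= effect_size
        table[:, j] = np.round(profile / profile.sum() * 1e5, 3)
    taxa_table = pd.DataFrame(table, index=lineage_strings, columns=samples)
    taxa_table.index.name = "lineage"
    return SyntheticStudy(taxa_table, metadata)


def write_bundle(
    out_dir: str | Path,
    seed: int = 0,
    n_genomes: int = 20,
    n_units: int = 40,
    n_pathways: int = 6,
    max_copies: int = 6,
    n_samples: int = N_SAMPLES,
    effect_size: float = EFFECT_SIZE,
) -> Path:
    """Write a complete fixture bundle: db/ tables, taxa.tsv, metadata.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    db = generate_synthetic_db(n_genomes, n_units, n_pathways, max_copies, seed)
    save_db(db, out_dir / "db")
    study = generate_synthetic_study(db, n_samples, seed + 1, effect_size)
    study.taxa_table.to_csv(out_dir / "taxa.tsv", sep="\t", float_format="%.10g")
    study.metadata.to_csv(out_dir / "metadata.tsv", sep="\t")
    return out_dir
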