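"""Straight-line brute-force recomputation of the inference pipeline.

Deliberately shares no code with the package: plain dicts and loops only.
Communities are species-level (one taxon row per distinct genome lineage),
so matching is exact lineage equality.
"""


def brute_force(genomes, pathways, abundance, pec, split=True):
    """Recompute everything with plain loops.

    genomes: list of (lineage_tuple, ssu, {unit: copies})
    pathways: dict pathway_id -> list of units
    abundance: dict taxon_lineage_tuple -> {sample: value}
    Returns dict with corrected, units, com_raw, com_rel, ico_raw, tensor.
    """
    samples = sorted({s for v in abundance.values() for s in v})
    taxa = sorted(abundance)

    # mean ssu / copies over genomes whose lineage equals the taxon's
    mean_ssu, mean_copies = {}, {}
    for t in taxa:
        matched = [(ssu, cp) for lg, ssu, cp in genomes if lg == t]
        assert matched, f"oracle community references unknown lineage {t}"
        mean_ssu[t] = sum(m[0] for m in matched) / len(matched)
        units_here = set()
        for _, cp in matched:
            units_here |= set(cp)
        mean_copies[t] = {
            u: sum(cp.get(u, 0) for _, cp in matched) / len(matched) for u in units_here
        }

    corrected = {}
    for s in samples:
        col = {t: abundance[t].get(s, 0.0) / mean_ssu[t] for t in taxa}
        total = sum(col.values())
        corrected[s] = {t: (v / total if total > 0 else 0.0) for t, v in col.items()}

    all_units = sorted({u for _, _, cp in genomes for u in cp})
    units = {
        s: {
            u: sum(corrected[s][t] * mean_copies[t].get(u, 0.0) for t in taxa)
            for u in all_units
        }
        for s in samples
    }

    mult = {}
    for members in pathways.values():
        for u in members:
            mult[u] = mult.get(u, 0) + 1

    def raw_pathways(unit_vec_by_sample):
        out = {}
        for p, members in pathways.items():
            out[p] = {}
            for s in samples:
                detected = sum(1 for u in members if unit_vec_by_sample[s].get(u, 0.0) > 0)
                if detected / len(members) >= pec / 100.0:
                    out[p][s] = sum(
                        unit_vec_by_sample[s].get(u, 0.0) / (mult[u] if split else 1)
                        for u in members
                    )
                else:
                    out[p][s] = 0.0
        return out

    com_raw = raw_pathways(units)
    com_rel = {}
    for s in samples:
        total = sum(com_raw[p][s] for p in pathways)
        com_rel[s] = {
            p: (com_raw[p][s] / total if total > 0 else 0.0) for p in pathways
        }

    tensor = {}
    for t in taxa:
        private = {
            s: {u: corrected[s][t] * mean_copies[t].get(u, 0.0) for u in all_units}
            for s in samples
        }
        tensor[t] = raw_pathways(private)
    ico_raw = {
        p: {s: sum(tensor[t][p][s] for t in taxa) for s in samples} for p in pathways
    }
    return {
        "corrected": corrected,
        "units": units,
        "com_raw": com_raw,
        "com_rel": com_rel,
        "ico_raw": ico_raw,
        "tensor": tensor,
    }


def bh_stepup(p_values):
    """Closed-form Benjamini-Hochberg step-up adjusted p values."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    prev = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        value = min(prev, p_values[i] * m / rank)
        adjusted[i] = value
        prev = value
    return adjusted


RANK_PREFIX = {
    "domain": "k", "phylum": "p", "class": "c", "order": "o",
    "family": "f", "genus": "g", "species": "s",
}
RANK_ORDER = ("domain", "phylum", "class", "order", "family", "genus", "species")


def make_inputs(db, n_samples, rng):
    """Build a species-level community over a FunctionDB's genomes.

    Returns (taxa_tsv_text, genomes, pathways, abundance) where the last
    three are the plain-dict inputs brute_force() expects.  Only data fields
    are read from the db; no package logic is reused.
    """
    genomes = [
        (tuple(g.lineage.get(r, "") for r in RANK_ORDER), g.ssu_copies, dict(g.unit_copies))
        for g in db.genomes
    ]
    pathways = {p.pathway_id: list(p.member_units) for p in db.pathways}

    samples = [f"S{j + 1}" for j in range(n_samples)]
    seen = set()
    rows = []
    abundance = {}
    for g in db.genomes:
        key = tuple(g.lineage.get(r, "") for r in RANK_ORDER)
        if key in seen:
            continue  # duplicate lineages would merge on parse; keep 1:1
        seen.add(key)
        values = [float(x) for x in rng.integers(0, 100, size=n_samples)]
        if not any(values):
            values[0] = 1.0
        lineage_str = "; ".join(
            f"{RANK_PREFIX[r]}__{g.lineage[r]}" for r in RANK_ORDER if r in g.lineage
        )
        rows.append(lineage_str + "\t" + "\t".join(f"{v:.10g}" for v in values))
        abundance[key] = dict(zip(samples, values))

    header = "lineage\t" + "\t".join(samples)
    return header + "\n" + "\n".join(rows) + "\n", genomes, pathways, abundance
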