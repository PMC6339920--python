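"""Analytics over inferred function profiles.

Covers ranked top functions, core-function detection (abundance floor plus
prevalence floor), nonparametric differential testing (Wilcoxon rank-sum for
two classes, Kruskal-Wallis for more, Benjamini-Hochberg correction),
PEC-consensus significance scoring, Jensen-Shannon-divergence PCoA
ordination, and function-driven taxa co-contribution networks.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon
from scipy.stats import kruskal, mannwhitneyu, spearmanr
from statsmodels.stats.multitest import multipletests

from .inference import PEC_GRID, ContributionTensor, FunctionProfile

logger = logging.getLogger(__name__)


class AnalysisError(ValueError):
    pass


# ---------------------------------------------------------------------------
# top / core functions


def _groups_or_all(samples: list[str], groups: pd.Series | None) -> dict[str, list[str]]:
    if groups is None:
        return {"all": list(samples)}
    out: dict[str, list[str]] = {}
    for s in samples:
        out.setdefault(str(groups.get(s, "NA")), []).append(s)
    return out


def top_functions(
    fp: FunctionProfile, n: int, groups: pd.Series | None = None
) -> dict[str, pd.DataFrame]:
    """Rank functions by mean relative abundance per group (descending).

    Ties break lexicographically by function id.  The returned frame keeps
    the per-sample values alongside the group mean (box-plot ready).
    """
    if n < 1:
        raise AnalysisError("n must be >= 1")
    result = {}
    for label, samp in _groups_or_all(list(fp.abundance.columns), groups).items():
        sub = fp.abundance[samp]
        means = sub.mean(axis=1)
        order = means.to_frame("mean_abundance")
        order["_id"] = order.index
        order = order.sort_values(["mean_abundance", "_id"], ascending=[False, True])
        if n > len(order):
            logger.warning("requested top %d of only %d functions", n, len(order))
        ranked = order.head(n).drop(columns="_id")
        result[label] = ranked.join(sub)
    return result


def core_functions(
    fp: FunctionProfile,
    abundance_floor: float,
    prevalence_floor: float,
    groups: pd.Series | None = None,
) -> dict[str, pd.DataFrame]:
    """Functions meeting `abundance_floor` in >= `prevalence_floor` of a
    group's samples ("high as well as consistently abundant")."""
    for floor in (abundance_floor, prevalence_floor):
        if not 0 < floor <= 1:
            raise AnalysisError(f"floors must lie in (0, 1], got {floor}")
    result = {}
    for label, samp in _groups_or_all(list(fp.abundance.columns), groups).items():
        if not samp:
            raise AnalysisError(f"group {label!r} has no samples")
        sub = fp.abundance[samp]
        prevalence = (sub >= abundance_floor).sum(axis=1) / len(samp)
        core = prevalence[prevalence >= prevalence_floor]
        result[label] = pd.DataFrame(
            {"prevalence": core, "mean_abundance": sub.loc[core.index].mean(axis=1)}
        ).sort_values("mean_abundance", ascending=False)
    return result


# ---------------------------------------------------------------------------
# differential testing


@dataclass
class DifferentialTable:
    """Per-function nonparametric test results with BH correction."""

    table: pd.DataFrame       # function, medians, test, statistic, p_raw, p_bh, direction
    test: str
    skipped: list[str] = field(default_factory=list)


def _wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and tie_free) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def differentiating_functions(
    fp: FunctionProfile, groups: pd.Series
) -> DifferentialTable:
    """Wilcoxon rank-sum (2 classes) or Kruskal-Wallis (>2) per function.

    Functions constant across all samples are skipped and listed; both raw
    and BH-corrected p values are reported.
    """
    by_label = _groups_or_all(list(fp.abundance.columns), groups)
    labels = sorted(by_label)
    if len(labels) < 2:
        raise AnalysisError("need >= 2 classes for differential testing")
    small = [l for l in labels if len(by_label[l]) < 2]
    if small:
        raise AnalysisError(f"classes with < 2 samples: {small}")
    test = "wilcoxon" if len(labels) == 2 else "kruskal-wallis"

    rows = []
    skipped = []
    for f in fp.abundance.index:
        series = fp.abundance.loc[f]
        if series.nunique() <= 1:
            skipped.append(f)
            continue
        parts = [series[by_label[l]].to_numpy(dtype=float) for l in labels]
        if test == "wilcoxon":
            stat, p = _wilcoxon_rank_sum(parts[0], parts[1])
        else:
            stat, p = kruskal(*parts)
        medians = {f"median_{l}": float(np.median(v)) for l, v in zip(labels, parts)}
        direction = max(labels, key=lambda l: (medians[f"median_{l}"], l))
        rows.append(
            {"function": f, **medians, "test": test, "statistic": float(stat),
             "p_raw": float(p), "direction": direction}
        )
    if skipped:
        logger.info("skipped %d constant functions: %s", len(skipped), skipped)
    if rows:
        table = pd.DataFrame(rows).set_index("function")
        table["p_bh"] = multipletests(table["p_raw"], method="fdr_bh")[1]
    else:
        table = pd.DataFrame(
            columns=["test", "statistic", "p_raw", "p_bh", "direction"]
        )
    return DifferentialTable(table, test, skipped)


# ---------------------------------------------------------------------------
# PEC consensus


@dataclass
class PECConsensus:
    matrix: pd.DataFrame      # functions x pec levels, entries {0, 1}
    score: pd.Series          # fraction of levels at which significant


def pec_consensus(
    tables: dict[int, DifferentialTable], alpha: float = 0.05
) -> PECConsensus:
    """Binary significance matrix across the PEC grid plus a consensus score.

    A function scores at a level only if it both survived that PEC filter
    (appears in the table, i.e. was non-constant and tested) and has
    BH-corrected p below alpha there.
    """
    if not 0 < alpha < 1:
        raise AnalysisError(f"alpha must lie in (0, 1), got {alpha}")
    levels = sorted(tables)
    functions = sorted({f for t in tables.values() for f in t.table.index})
    mat = pd.DataFrame(0, index=functions, columns=levels, dtype=int)
    for pec, dt in tables.items():
        sig = dt.table.index[dt.table["p_bh"] < alpha]
        mat.loc[sig, pec] = 1
    return PECConsensus(mat, mat.mean(axis=1))


# ---------------------------------------------------------------------------
# JSD ordination


def jsd(p: np.ndarray, q: np.ndarray, pseudocount: float = 1e-9) -> float:
    """Jensen-Shannon divergence, base-2 logs, after pseudocount renormalization."""
    p = np.asarray(p, dtype=float) + pseudocount
    q = np.asarray(q, dtype=float) + pseudocount
    return float(jensenshannon(p / p.sum(), q / q.sum(), base=2) ** 2)


def jsd_distance_matrix(fp: FunctionProfile, pseudocount: float = 1e-9) -> pd.DataFrame:
    """Pairwise sqrt(JSD) distances between samples (a metric, used for PCoA)."""
    cols = fp.abundance.columns
    X = fp.abundance.to_numpy(dtype=float) + pseudocount
    X = X / X.sum(axis=0)
    n = X.shape[1]
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        D[i, j] = D[j, i] = jensenshannon(X[:, i], X[:, j], base=2)
    return pd.DataFrame(D, index=cols, columns=cols)


@dataclass
class Ordination:
    coordinates: pd.DataFrame    # samples x axes
    eigenvalues: np.ndarray      # all eigenvalues, descending (negatives kept)
    variance_explained: np.ndarray


def jsd_pcoa(fp: FunctionProfile, k: int = 2) -> Ordination:
    """Classical (metric) PCoA on sqrt(JSD) sample distances.

    Double-centers -d^2/2 and eigendecomposes; axes are ordered by
    eigenvalue, negative eigenvalues are reported rather than dropped, and
    each axis is sign-fixed so its first nonzero loading is positive.
    """
    samples = list(fp.abundance.columns)
    n = len(samples)
    if n < 3:
        raise AnalysisError(f"ordination needs >= 3 samples, got {n}")
    if not 1 <= k <= n - 1:
        raise AnalysisError(f"k must lie in [1, {n - 1}], got {k}")
    D = jsd_distance_matrix(fp).to_numpy()
    if not (D > 0).any():
        raise AnalysisError("all samples identical: every pairwise distance is 0")

    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    coords = np.zeros((n, k))
    for a in range(k):
        if eigval[a] > 1e-12:
            axis = eigvec[:, a] * np.sqrt(eigval[a])
            nz = np.flatnonzero(np.abs(axis) > 1e-12)
            if nz.size and axis[nz[0]] < 0:
                axis = -axis
            coords[:, a] = axis
    pos_total = eigval[eigval > 0].sum()
    var = np.where(eigval[:k] > 0, eigval[:k] / pos_total, 0.0)
    frame = pd.DataFrame(coords, index=samples, columns=[f"PCo{a + 1}" for a in range(k)])
    return Ordination(frame, eigval, var)


# ---------------------------------------------------------------------------
# co-contribution networks


@dataclass
class CoContributionNetwork:
    graph: nx.Graph
    edges: pd.DataFrame          # taxon_i, taxon_j, rho, p_bh, supporting_functions
    node_metrics: pd.DataFrame   # degree, betweenness, clustering


def contribution_network(
    ct: ContributionTensor,
    rho_min: float = 0.6,
    alpha: float = 0.05,
    min_samples: int = 4,
) -> CoContributionNetwork:
    """Link taxa whose contribution series to a shared function are
    positively rank-correlated (Spearman), BH-corrected across all candidate
    (pair, function) tests.

    An edge survives when at least one shared function passes alpha; its
    supporting-function list names the survivors.  Metrics (degree,
    normalized betweenness, local clustering coefficient) are computed on the
    final simple graph.
    """
    if len(ct.samples) < min_samples:
        raise AnalysisError(
            f"need >= {min_samples} samples for correlation, got {len(ct.samples)}"
        )
    candidates = []
    for ti, tj in itertools.combinations(ct.taxa, 2):
        for f in ct.functions:
            a = ct.taxon_series(ti, f).to_numpy(dtype=float)
            b = ct.taxon_series(tj, f).to_numpy(dtype=float)
            if not a.any() or not b.any():
                continue    # function not contributed by both
            if len(np.unique(a)) == 1 or len(np.unique(b)) == 1:
                continue    # constant series: correlation undefined
            rho, p = spearmanr(a, b)
            if np.isnan(rho) or rho < rho_min:
                continue
            candidates.append((ti, tj, f, float(rho), float(p)))

    G = nx.Graph()
    G.add_nodes_from(ct.taxa)
    edge_rows = []
    if candidates:
        p_bh = multipletests([c[4] for c in candidates], method="fdr_bh")[1]
        surviving: dict[tuple[str, str], list[tuple[str, float, float]]] = {}
        for (ti, tj, f, rho, _), q in zip(candidates, p_bh):
            if q < alpha:
                surviving.setdefault((ti, tj), []).append((f, rho, float(q)))
        for (ti, tj), hits in surviving.items():
            best = min(hits, key=lambda h: h[2])
            G.add_edge(ti, tj)
            edge_rows.append(
                {
                    "taxon_i": ti,
                    "taxon_j": tj,
                    "rho": best[1],
                    "p_bh": best[2],
                    "supporting_functions": ";".join(sorted(h[0] for h in hits)),
                }
            )
    edges = pd.DataFrame(
        edge_rows, columns=["taxon_i", "taxon_j", "rho", "p_bh", "supporting_functions"]
    )
    metrics = pd.DataFrame(
        {
            "degree": pd.Series(dict(G.degree())),
            "betweenness": pd.Series(nx.betweenness_centrality(G, normalized=True)),
            "clustering": pd.Series(nx.clustering(G)),
        }
    ).reindex(ct.taxa)
    return CoContributionNetwork(G, edges, metrics)


def contribution_table(
    ct: ContributionTensor, groups: pd.Series | None = None
) -> pd.DataFrame:
    """Queryable long table: per (function, taxon), mean contribution per class."""
    by_label = _groups_or_all(ct.samples, groups)
    rows = []
    for (taxon, function), series in ct.values.iterrows():
        if not series.to_numpy().any():
            continue
        row = {"function": function, "taxon": taxon}
        for label, samp in sorted(by_label.items()):
            row[f"mean_{label}"] = float(series[samp].mean())
        rows.append(row)
    return pd.DataFrame(rows)
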