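"""Co-occurrence networks of endophyte ASVs.

Edges are positive, significant Spearman correlations between taxa computed
on TMM-normalised CPM profiles: the meta network uses r > 0.6 and p < 0.001
over within-kingdom pairs; per-health-group networks use r > 0.8 (bacteria)
or r > 0.7 (fungi) with p < 0.01 after a prevalence prefilter.  Modules come
from greedy modularity maximisation (Clauset-Newman-Moore); complexity is
summarised by node/edge counts, mean normalised betweenness centrality, and
degree assortativity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .sensitive import HsASVReport, NormalizedTable
from .tables import SampleMetadata, TaxonomyTable

__all__ = [
    "CoNetwork",
    "spearman_matrix",
    "build_network",
    "greedy_modules",
    "topology_metrics",
    "module_summary",
    "write_graphml",
]


@dataclass
class CoNetwork:
    """Thresholded correlation graph with optional module partition."""

    graph: nx.Graph
    r_min: float
    p_max: float
    modularity: float | None = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def modules(self) -> dict[str, int]:
        return nx.get_node_attributes(self.graph, "module")

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "r": d["r"], "p": d["p"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "r", "p"])


def spearman_matrix(
    norm: NormalizedTable | pd.DataFrame,
    kingdoms: dict[str, str] | None = None,
    within_kingdom: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman correlations between taxa over samples.

    Returns ``(r, p)`` DataFrames indexed by taxon.  Correlations use
    mid-rank Pearson-on-ranks with the t-approximation for p-values.
    Pairs crossing kingdoms are masked to NaN when ``within_kingdom`` and a
    kingdom tag mapping is given; constant taxa yield NaN (never an edge).
    """
    df = norm.to_dataframe() if isinstance(norm, NormalizedTable) else norm
    x = df.to_numpy(dtype=float)
    n_taxa, n_samples = x.shape
    if n_samples < 5:
        raise ValueError("need >= 5 samples for correlation networks")
    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    sd = ranks.std(axis=1)
    constant = sd == 0
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.outer(sd, sd) * n_samples
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (centered @ centered.T) / denom
    r = np.clip(r, -1.0, 1.0)
    r[constant, :] = np.nan
    r[:, constant] = np.nan
    np.fill_diagonal(r, 1.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = r * np.sqrt((n_samples - 2) / np.maximum(1 - r**2, 1e-300))
    p = 2 * stats.t.sf(np.abs(tstat), df=n_samples - 2)
    np.fill_diagonal(p, 0.0)
    p[np.isnan(r)] = np.nan

    if within_kingdom and kingdoms:
        tags = np.array([kingdoms.get(t, "unspecified") for t in df.index])
        cross = tags[:, None] != tags[None, :]
        r[cross] = np.nan
        p[cross] = np.nan

    idx = list(df.index)
    return pd.DataFrame(r, index=idx, columns=idx), pd.DataFrame(p, index=idx, columns=idx)


def build_network(
    r: pd.DataFrame,
    p: pd.DataFrame,
    r_min: float,
    p_max: float,
    positive_only: bool = True,
    kingdoms: dict[str, str] | None = None,
    adjust: bool = False,
) -> CoNetwork:
    """Threshold correlation matrices into a graph.

    An edge is kept iff ``r > r_min`` and ``p < p_max`` (and r > 0 when
    ``positive_only``); isolated nodes are dropped.  ``adjust=True`` applies
    BH correction to the off-diagonal p-values before thresholding (off by
    default: the raw-p convention of the underlying workflow is kept).
    """
    if not (0 <= p_max <= 1):
        raise ValueError("p_max must be in [0, 1]")
    rm = r.to_numpy(dtype=float)
    pm = p.to_numpy(dtype=float).copy()
    taxa = list(r.index)
    iu = np.triu_indices(len(taxa), k=1)
    if adjust:
        from statsmodels.stats.multitest import multipletests

        vals = pm[iu]
        ok = ~np.isnan(vals)
        adj = np.full_like(vals, np.nan)
        if ok.any():
            adj[ok] = multipletests(vals[ok], method="fdr_bh")[1]
        pm[iu] = adj
        pm[(iu[1], iu[0])] = adj

    g = nx.Graph()
    keep = (
        ~np.isnan(rm[iu])
        & ~np.isnan(pm[iu])
        & (rm[iu] > r_min)
        & (pm[iu] < p_max)
    )
    if positive_only:
        keep &= rm[iu] > 0
    for i, j in zip(iu[0][keep], iu[1][keep]):
        g.add_edge(taxa[i], taxa[j], r=float(rm[i, j]), p=float(pm[i, j]))
    if kingdoms:
        nx.set_node_attributes(
            g, {n: kingdoms.get(n, "unspecified") for n in g.nodes}, "kingdom"
        )
    return CoNetwork(graph=g, r_min=r_min, p_max=p_max)


def greedy_modules(net: CoNetwork) -> CoNetwork:
    """Assign modules by greedy (CNM) modularity maximisation.

    Node order is sorted before agglomeration so the result is deterministic.
    An edgeless network gets one singleton module per node and Q = 0.
    """
    g = nx.Graph()
    g.add_nodes_from(sorted(net.graph.nodes(data=True)))
    g.add_edges_from(sorted(net.graph.edges(data=True)))
    if g.number_of_edges() == 0:
        for i, n in enumerate(sorted(g.nodes)):
            net.graph.nodes[n]["module"] = i
        net.modularity = 0.0
        return net
    communities = nx.algorithms.community.greedy_modularity_communities(g, weight=None)
    communities = sorted((sorted(c) for c in communities), key=lambda c: (-len(c), c))
    for mid, members in enumerate(communities):
        for n in members:
            net.graph.nodes[n]["module"] = mid
    net.modularity = float(
        nx.algorithms.community.modularity(
            g, [set(c) for c in communities], weight=None
        )
    )
    return net


def topology_metrics(net: CoNetwork) -> dict[str, float | int | None]:
    """Node/edge counts, mean normalised betweenness, degree assortativity.

    Betweenness is Brandes' shortest-path centrality on the unweighted
    graph, normalised by (n-1)(n-2)/2, averaged over nodes.  Assortativity
    is the Pearson correlation of end-point degrees over edges; it is
    reported as None when undefined (degree-regular graphs or no edges).
    """
    g = net.graph
    out: dict[str, float | int | None] = {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
    }
    if g.number_of_nodes() == 0:
        out["mean_betweenness"] = None
        out["degree_assortativity"] = None
        out["modularity"] = net.modularity
        return out
    bc = nx.betweenness_centrality(g, normalized=True)
    out["mean_betweenness"] = float(np.mean(list(bc.values())))
    if g.number_of_edges() == 0:
        out["degree_assortativity"] = None
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            assort = nx.degree_assortativity_coefficient(g)
        out["degree_assortativity"] = None if math.isnan(assort) else float(assort)
    out["modularity"] = net.modularity
    return out


def write_graphml(net: CoNetwork, path) -> None:
    """Write the network as GraphML with module and kingdom node attributes.

    Optional layout coordinates (Fruchterman-Reingold) can be attached by
    callers as ``x``/``y`` node attributes before writing; they are
    presentation-only and never affect metrics.
    """
    g = net.graph.copy()
    for _, data in g.nodes(data=True):
        data.setdefault("kingdom", "unspecified")
        if "module" in data:
            data["module"] = int(data["module"])
    nx.write_graphml(g, path)


def module_summary(
    net: CoNetwork,
    norm: NormalizedTable,
    hs: HsASVReport | None = None,
    tax: TaxonomyTable | None = None,
    groups: SampleMetadata | None = None,
    sensitive_quantile: float = 0.75,
) -> pd.DataFrame:
    """Per-module membership, hsASV content, cumulative CPM, composition.

    A module is flagged *sensitive* when its hsASV fraction strictly exceeds
    the ``sensitive_quantile`` quantile of module hsASV fractions (and is
    nonzero).  Cumulative CPM is the per-sample sum of member CPMs,
    summarised as mean +- SD per group.
    """
    modules = net.modules
    if not modules:
        raise ValueError("run greedy_modules before module_summary")
    cpm = norm.to_dataframe()
    hs_set = set(hs.hsasvs) if hs is not None else set()
    hs_groups = (
        hs.table.loc[hs.table["hs_flag"], "assigned_group"] if hs is not None else None
    )

    rows = []
    fractions = {}
    by_module: dict[int, list[str]] = {}
    for node, mid in modules.items():
        by_module.setdefault(mid, []).append(node)
    for mid, members in sorted(by_module.items()):
        fractions[mid] = len([m for m in members if m in hs_set]) / len(members)
    cutoff = float(np.quantile(list(fractions.values()), sensitive_quantile))

    for mid, members in sorted(by_module.items()):
        members_in = [m for m in members if m in cpm.index]
        row: dict[str, object] = {
            "module": mid,
            "n_members": len(members),
            "hs_fraction": fractions[mid],
            "sensitive": fractions[mid] > max(cutoff, 0.0)
            if any(f > 0 for f in fractions.values())
            else False,
        }
        if hs_groups is not None:
            for g in ("HL", "NL"):
                row[f"n_hs_{g}"] = int(
                    sum(
                        1
                        for m in members
                        if m in hs_set and hs_groups.get(m, "") == g
                    )
                )
        if groups is not None and members_in:
            cum = cpm.loc[members_in].sum(axis=0)
            for g, samples in groups.split(list(cpm.columns)).items():
                row[f"cum_cpm_mean_{g}"] = float(cum[samples].mean())
                row[f"cum_cpm_sd_{g}"] = float(cum[samples].std(ddof=1))
        if tax is not None:
            classes = pd.Series(
                [tax.rank_of(m, "class") for m in members]
            ).value_counts(normalize=True)
            row["class_composition"] = dict(classes)
        rows.append(row)
    return pd.DataFrame(rows).set_index("module")
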