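"""Mutual-information networks within a module and key-driver ranking.

Within a co-expression module, every gene pair's mutual information (MI)
is estimated by a plug-in estimator on equal-frequency bins; pairs whose
MI clears a permutation-derived significance threshold form an
undirected network, which is then pruned by ARACNE's data processing
inequality (DPI): in every triangle, the weakest edge is removed when
its MI falls below ``(1 - tolerance)`` times the smaller of the other
two.  Hubs are the genes in the top fraction of network degree;
aged-specific hubs are hubs of the aged network absent from the young
hubs; key regulators are ranked by the number of N-hop neighborhood
nodes (NHNN) — distinct nodes reachable within N edges.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "MINetwork",
    "KeyDriverReport",
    "estimate_mi",
    "mi_threshold",
    "build_mi_network",
    "dpi_prune",
    "identify_hubs",
    "aged_specific_hubs",
    "nhnn_rank",
    "key_driver_report",
]


@dataclass
class MINetwork:
    """Undirected MI network over a module's genes.

    ``graph`` has an ``mi`` attribute on every edge; ``nodes`` always
    includes isolated genes so degree-0 members stay in the universe.
    """

    graph: nx.Graph
    group: str = ""
    threshold: float = float("nan")
    dpi_tolerance: float | None = None

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def degree(self) -> pd.Series:
        return pd.Series(dict(self.graph.degree()), name="degree").sort_index()

    def edges(self) -> pd.DataFrame:
        rows = [
            {"gene_a": a, "gene_b": b, "mi": d["mi"]} for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "mi"])


def _auto_bins(n: int) -> int:
    return max(2, int(np.floor(np.sqrt(n) / 2.0)))


def _discretize(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency bin labels; rank-based, ties broken by position."""
    order = np.argsort(x, kind="mergesort")
    labels = np.empty(len(x), dtype=np.int64)
    labels[order] = np.arange(len(x)) * bins // len(x)
    return labels


def estimate_mi(
    x: np.ndarray, y: np.ndarray, bins: int | str = "auto", miller_madow: bool = True
) -> float:
    """Mutual information (nats) on equal-frequency bins.

    With ``bins="auto"`` the number of bins is
    ``max(2, floor(sqrt(n) / 2))``.  By default the plug-in estimate is
    debiased with the Miller-Madow correction (the raw plug-in MI of
    independent vectors is positive by roughly ``(B-1)^2 / 2n``); pass
    ``miller_madow=False`` for the pure plug-in value.  The estimate is
    non-negative and exactly symmetric in its arguments.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 8:
        raise ValueError("need at least 8 samples to estimate MI")
    b = _auto_bins(n) if bins == "auto" else int(bins)
    lx = _discretize(x, b)
    ly = _discretize(y, b)
    joint = np.zeros((b, b))
    np.add.at(joint, (lx, ly), 1.0)
    joint /= n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    terms = joint[nz] * np.log(joint[nz] / np.outer(px, py)[nz])
    # canonical summation order makes the value exactly argument-symmetric
    mi = float(np.sort(terms).sum())
    if miller_madow:
        m_x = int((px > 0).sum())
        m_y = int((py > 0).sum())
        m_xy = int(nz.sum())
        mi += ((m_x - 1) + (m_y - 1) - (m_xy - 1)) / (2.0 * n)
    return max(mi, 0.0)


def mi_threshold(
    values: pd.DataFrame,
    n_perm: int = 1000,
    alpha: float = 0.05,
    bins: int | str = "auto",
    seed: int = 0,
) -> float:
    """Significance threshold for MI from a permutation null.

    Draws ``n_perm`` null MI values between independently shuffled
    expression vectors of randomly chosen gene pairs and returns the
    ``1 - alpha/n_pairs`` quantile (Bonferroni scaling over the number of
    testable pairs, clamped to the largest attainable quantile).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    x = values.to_numpy(float)
    n_genes, n = x.shape
    n_pairs = n_genes * (n_genes - 1) // 2
    null = np.empty(n_perm)
    for i in range(n_perm):
        a, bb = rng.choice(n_genes, size=2, replace=False)
        null[i] = estimate_mi(rng.permutation(x[a]), rng.permutation(x[bb]), bins=bins)
    level = min(1.0 - alpha / max(n_pairs, 1), n_perm / (n_perm + 1.0))
    return float(np.quantile(null, level))


def build_mi_network(
    values: pd.DataFrame,
    group: str = "",
    threshold: float | None = None,
    tolerance: float | None = 0.15,
    bins: int | str = "auto",
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> MINetwork:
    """All-pairs MI network over the genes (rows) of ``values``.

    When ``threshold`` is None it is derived by :func:`mi_threshold`;
    edges at or below the threshold are dropped; DPI pruning runs unless
    ``tolerance`` is None.
    """
    if threshold is None:
        threshold = mi_threshold(values, n_perm=n_perm, alpha=alpha, bins=bins, seed=seed)
    genes = list(values.index)
    x = values.to_numpy(float)
    g = nx.Graph()
    g.add_nodes_from(genes)
    for i, j in itertools.combinations(range(len(genes)), 2):
        mi = estimate_mi(x[i], x[j], bins=bins)
        if mi > threshold:
            g.add_edge(genes[i], genes[j], mi=mi)
    net = MINetwork(graph=g, group=group, threshold=float(threshold))
    if tolerance is not None:
        net = dpi_prune(net, tolerance=tolerance)
    return net


def dpi_prune(network: MINetwork, tolerance: float = 0.15) -> MINetwork:
    """Remove indirect edges by the data processing inequality.

    Edges are processed in ascending MI order; an edge (i, j) is removed
    when some common neighbor k in the current graph satisfies
    ``mi(i,j) < (1 - tolerance) * min(mi(i,k), mi(j,k))``.  Afterwards no
    remaining triangle violates the rule.  Never adds edges; independent
    of the input edge ordering.
    """
    if not 0.0 <= tolerance < 1.0:
        raise ValueError("tolerance must lie in [0, 1)")
    g = network.graph.copy()
    edges = sorted(g.edges(data="mi"), key=lambda e: (e[2], e[0], e[1]))
    for a, b, mi in edges:
        if not g.has_edge(a, b):
            continue
        for k in set(g.neighbors(a)) & set(g.neighbors(b)):
            other = min(g[a][k]["mi"], g[b][k]["mi"])
            if mi < (1.0 - tolerance) * other:
                g.remove_edge(a, b)
                break
    return MINetwork(
        graph=g, group=network.group, threshold=network.threshold, dpi_tolerance=tolerance
    )


def identify_hubs(network: MINetwork, top_fraction: float = 0.05) -> set[str]:
    """Genes in the top ``top_fraction`` of degree, ties included.

    The degree cutoff is the ``ceil(top_fraction * n)``-th largest
    degree; every gene at or above it is a hub (so exact ties at the
    cutoff all enter).  Degree-0 genes are never hubs.
    """
    deg = network.degree()
    if len(deg) == 0:
        raise ValueError("empty network")
    k = max(1, int(np.ceil(top_fraction * len(deg))))
    cutoff = deg.sort_values(ascending=False).iloc[k - 1]
    if cutoff <= 0:
        return set()
    return set(deg.index[deg >= cutoff])


def aged_specific_hubs(
    young: MINetwork, aged: MINetwork, top_fraction: float = 0.05
) -> set[str]:
    """Hubs of the aged network that are not hubs of the young network."""
    if set(young.graph.nodes) != set(aged.graph.nodes):
        raise ValueError("young and aged networks must share their node universe")
    return identify_hubs(aged, top_fraction) - identify_hubs(young, top_fraction)


def nhnn_rank(network: MINetwork, n_hops: int = 2) -> pd.Series:
    """Number of N-hop neighborhood nodes per gene, ranked descending.

    ``NHNN(g)`` counts distinct nodes reachable from ``g`` within
    ``n_hops`` edges, excluding ``g`` itself.  Ties are ordered by gene
    label for determinism.
    """
    if n_hops < 1:
        raise ValueError("n_hops must be >= 1")
    scores = {}
    for node in network.graph.nodes:
        reach = nx.single_source_shortest_path_length(network.graph, node, cutoff=n_hops)
        scores[node] = len(reach) - 1
    s = pd.Series(scores, name="nhnn")
    return s.sort_index().sort_values(ascending=False, kind="mergesort")


@dataclass
class KeyDriverReport:
    """Per-gene degrees, NHNN and hub flags for one module's networks."""

    table: pd.DataFrame
    module: str = ""
    top_fraction: float = 0.05
    n_hops: int = 2
    hubs_young: set[str] = field(default_factory=set)
    hubs_aged: set[str] = field(default_factory=set)
    aged_specific: set[str] = field(default_factory=set)


def key_driver_report(
    young: MINetwork,
    aged: MINetwork,
    module: str = "",
    top_fraction: float = 0.05,
    n_hops: int = 2,
) -> KeyDriverReport:
    """Assemble hub sets and NHNN ranking for a young/aged network pair."""
    hy = identify_hubs(young, top_fraction)
    ha = identify_hubs(aged, top_fraction)
    aspec = aged_specific_hubs(young, aged, top_fraction)
    nhnn = nhnn_rank(aged, n_hops=n_hops)
    table = pd.DataFrame(
        {
            "degree_young": young.degree(),
            "degree_aged": aged.degree(),
            "nhnn_aged": nhnn,
        }
    ).fillna(0)
    table["hub_young"] = table.index.isin(sorted(hy))
    table["hub_aged"] = table.index.isin(sorted(ha))
    table["aged_specific_hub"] = table.index.isin(sorted(aspec))
    table = table.loc[nhnn.index]
    return KeyDriverReport(
        table=table,
        module=module,
        top_fraction=top_fraction,
        n_hops=n_hops,
        hubs_young=hy,
        hubs_aged=ha,
        aged_specific=aspec,
    )
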