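"""Co-occurrence networks: construction, topology, robustness, node roles.

Edges are Spearman correlations between taxa that pass a prevalence and
mean-relative-abundance filter; only strong (|rho| > 0.7) and FDR-significant
(Benjamini-Hochberg q < 0.05) correlations are kept.  Topology is compared
with same-size Erdos-Renyi G(n, m) ensembles; robustness is natural
connectivity under betweenness-ordered node removal; node roles follow the
within-module degree z-score (Zi) and participation coefficient (Pi), with
module hubs at Zi > 2.5 and Pi <= 0.62.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .containers import CommunityMatrix
from .errors import (
    EmptyNetworkError,
    ImpossibleGraphError,
    InvalidArgumentError,
)


# ---------------------------------------------------------------------------
# filtering and construction
# ---------------------------------------------------------------------------

def filter_taxa(
    matrix: CommunityMatrix,
    prevalence_min: float = 0.75,
    rel_abund_min: float = 0.0001,
) -> CommunityMatrix:
    """Keep taxa detected in at least ``prevalence_min`` of samples (inclusive)
    AND with mean relative abundance strictly above ``rel_abund_min``."""
    if matrix.n_samples < 4:
        raise InvalidArgumentError("need at least 4 samples to filter for a network")
    rel = matrix.relative_abundance()
    prevalence = (matrix.counts > 0).mean(axis=0)
    mean_rel = rel.mean(axis=0)
    keep = matrix.counts.columns[(prevalence >= prevalence_min) & (mean_rel > rel_abund_min)]
    if len(keep) == 0:
        raise EmptyNetworkError("no taxa survive the prevalence/abundance filter")
    return matrix.subset_taxa(list(keep))


def spearman_all_pairs(rel: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """All-pairs Spearman rho and two-sided P (t approximation, midrank ties).

    Constant taxa are excluded with a warning (rho undefined)."""
    const = rel.columns[rel.nunique(axis=0) <= 1]
    if len(const) > 0:
        warnings.warn(f"excluding constant taxa from correlation: {list(const)}")
        rel = rel.drop(columns=list(const))
    taxa = list(rel.columns)
    rho, p = stats.spearmanr(rel.to_numpy(), axis=0)
    rho = np.atleast_2d(rho)
    p = np.atleast_2d(p)
    return rho, p, taxa


@dataclass
class CorrelationNetwork:
    graph: nx.Graph
    edges: pd.DataFrame  # taxon_a, taxon_b, rho, p, q, sign
    taxa: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(
    matrix: CommunityMatrix,
    rho_min: float = 0.7,
    alpha: float = 0.05,
    taxonomy: dict[str, str] | None = None,
) -> CorrelationNetwork:
    """Filtered Spearman co-occurrence graph.

    BH adjustment is applied across all tested pairs; an edge is kept iff
    |rho| > rho_min and q < alpha.  Nodes carry mean relative abundance and,
    when provided, a taxonomy label.
    """
    if matrix.n_samples < 5:
        raise InvalidArgumentError("need at least 5 samples to estimate correlations")
    rel = matrix.relative_abundance()
    rho, p, taxa = spearman_all_pairs(rel)
    iu = np.triu_indices(len(taxa), 1)
    pvals = p[iu]
    qvals = multipletests(pvals, method="fdr_bh")[1] if pvals.size else np.array([])

    mean_rel = rel[taxa].mean(axis=0)
    g = nx.Graph()
    for t in taxa:
        g.add_node(t, mean_relative_abundance=float(mean_rel[t]))
        if taxonomy and t in taxonomy:
            g.nodes[t]["taxonomy"] = taxonomy[t]

    rows = []
    for (i, j), q in zip(zip(*iu), qvals):
        r = rho[i, j]
        if abs(r) > rho_min and q < alpha:
            a, b = taxa[i], taxa[j]
            sign = "positive" if r > 0 else "negative"
            g.add_edge(a, b, rho=float(r), q=float(q), sign=sign)
            rows.append((a, b, float(r), float(p[i, j]), float(q), sign))
    edges = pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "rho", "p", "q", "sign"])
    return CorrelationNetwork(graph=g, edges=edges, taxa=taxa)


def split_by_group(
    matrix: CommunityMatrix, metadata: pd.DataFrame, group_cols=("cultivar", "niche")
) -> dict[str, CommunityMatrix]:
    """Per cultivar x niche sub-tables (one network per subset)."""
    meta = metadata.set_index("sample_id")
    out = {}
    for gkey, sub in meta.groupby(list(group_cols), sort=True):
        name = gkey if isinstance(gkey, str) else "_".join(map(str, gkey))
        ids = [s for s in matrix.sample_ids if s in set(sub.index)]
        if ids:
            out[name] = matrix.subset_samples(ids).drop_empty_taxa()
    return out


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

def detect_modules(graph: nx.Graph) -> dict[str, int]:
    """Greedy modularity-maximization partition (deterministic)."""
    if graph.number_of_edges() == 0:
        return {n: i for i, n in enumerate(sorted(graph.nodes))}
    comms = nx.community.greedy_modularity_communities(graph)
    return {n: i for i, c in enumerate(comms) for n in c}


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    average_degree: float
    average_clustering: float
    modularity: float
    n_modules: int
    density: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def topology(network: CorrelationNetwork | nx.Graph, modules: dict[str, int] | None = None) -> TopologySummary:
    g = network.graph if isinstance(network, CorrelationNetwork) else network
    if g.number_of_nodes() == 0:
        raise InvalidArgumentError("empty network")
    n, m = g.number_of_nodes(), g.number_of_edges()
    if modules is None:
        modules = detect_modules(g)
    groups: dict[int, set] = {}
    for node, mod in modules.items():
        groups.setdefault(mod, set()).add(node)
    mod_q = nx.community.modularity(g, list(groups.values())) if m > 0 else 0.0
    return TopologySummary(
        n_nodes=n,
        n_edges=m,
        average_degree=2.0 * m / n,
        average_clustering=float(nx.average_clustering(g)),
        modularity=float(mod_q),
        n_modules=len(groups),
        density=float(nx.density(g)),
    )


def random_reference(
    network: CorrelationNetwork | nx.Graph, n_random: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Erdos-Renyi G(n, m) ensemble: mean, sd and z-score per topology metric."""
    if n_random < 10:
        raise InvalidArgumentError("n_random must be >= 10")
    g = network.graph if isinstance(network, CorrelationNetwork) else network
    n, m = g.number_of_nodes(), g.number_of_edges()
    if m > n * (n - 1) // 2:
        raise ImpossibleGraphError(f"{m} edges impossible on {n} nodes")
    emp = topology(g).as_dict()
    records = []
    for i in range(n_random):
        rg = nx.gnm_random_graph(n, m, seed=seed + i)
        records.append(topology(rg).as_dict())
    ens = pd.DataFrame(records)
    out = pd.DataFrame(
        {
            "empirical": pd.Series(emp),
            "random_mean": ens.mean(),
            "random_sd": ens.std(ddof=1),
        }
    )
    sd = out["random_sd"].replace(0.0, np.nan)
    out["z"] = (out["empirical"] - out["random_mean"]) / sd
    return out


# ---------------------------------------------------------------------------
# robustness
# ---------------------------------------------------------------------------

def natural_connectivity(network: CorrelationNetwork | nx.Graph) -> float:
    """ln of the average of e^lambda_i over adjacency eigenvalues.

    Uses the unweighted, unsigned adjacency; the empty graph (all eigenvalues
    zero) gives ln(1) = 0.
    """
    g = network.graph if isinstance(network, CorrelationNetwork) else network
    n = g.number_of_nodes()
    if n == 0:
        raise InvalidArgumentError("graph has no nodes")
    a = nx.to_numpy_array(g, weight=None)
    lam = np.linalg.eigvalsh(a)
    return float(logsumexp(lam) - np.log(n))


@dataclass
class RobustnessCurve:
    removal_fraction: np.ndarray
    natural_connectivity: np.ndarray
    removed_nodes: list

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "removal_fraction": self.removal_fraction,
                "natural_connectivity": self.natural_connectivity,
            }
        )


def robustness_curve(
    network: CorrelationNetwork | nx.Graph,
    removal_max: float = 0.8,
    recompute_betweenness: bool = False,
    normalize_by_n: bool = False,
) -> RobustnessCurve:
    """Natural connectivity while removing nodes in descending betweenness.

    The ranking is computed once on the intact network by default (static
    ordering); ties break by node id.  The curve has floor(removal_max * N)
    removals plus the intact-network point.
    """
    g = (network.graph if isinstance(network, CorrelationNetwork) else network).copy()
    n0 = g.number_of_nodes()
    if n0 < 5:
        raise InvalidArgumentError("need at least 5 nodes for a removal curve")
    n_remove = int(np.floor(removal_max * n0))

    def ordering(h: nx.Graph) -> list:
        bc = nx.betweenness_centrality(h)
        return sorted(bc, key=lambda v: (-bc[v], str(v)))

    static_order = ordering(g)
    fracs = [0.0]
    ncs = [natural_connectivity(g) - (np.log(n0) if normalize_by_n else 0.0)]
    removed = []
    for i in range(n_remove):
        victim = ordering(g)[0] if recompute_betweenness else static_order[i]
        g.remove_node(victim)
        removed.append(victim)
        fracs.append((i + 1) / n0)
        val = natural_connectivity(g) if g.number_of_nodes() else 0.0
        if normalize_by_n and g.number_of_nodes():
            val -= np.log(g.number_of_nodes())
        ncs.append(val)
    return RobustnessCurve(
        removal_fraction=np.asarray(fracs),
        natural_connectivity=np.asarray(ncs),
        removed_nodes=removed,
    )


# ---------------------------------------------------------------------------
# Zi-Pi node roles
# ---------------------------------------------------------------------------

def zi_pi(
    network: CorrelationNetwork | nx.Graph, modules: dict[str, int] | None = None
) -> pd.DataFrame:
    """Within-module degree z-score (Zi) and participation coefficient (Pi).

    Zi standardizes a node's within-module degree against its module's
    distribution; Pi = 1 - sum_t (k_it / k_i)^2 over modules t.  Roles:
    module_hub (Zi > 2.5, Pi <= 0.62), network_hub (Zi > 2.5, Pi > 0.62),
    connector (Zi <= 2.5, Pi > 0.62), else non_hub.  Modules whose
    within-module degrees have zero spread get Zi = 0 with a warning.
    """
    g = network.graph if isinstance(network, CorrelationNetwork) else network
    if modules is None:
        modules = detect_modules(g)
    nodes = sorted(g.nodes, key=str)
    mod_members: dict[int, list] = {}
    for v in nodes:
        mod_members.setdefault(modules[v], []).append(v)

    within_k = {
        v: sum(1 for u in g.neighbors(v) if modules[u] == modules[v]) for v in nodes
    }
    mod_stats = {}
    for mod, members in mod_members.items():
        ks = np.array([within_k[v] for v in members], dtype=float)
        mu, sd = ks.mean(), ks.std(ddof=0)
        if sd == 0:
            warnings.warn(f"module {mod} has uniform within-module degree; Zi set to 0")
        mod_stats[mod] = (mu, sd)

    rows = []
    for v in nodes:
        k = g.degree(v)
        mu, sd = mod_stats[modules[v]]
        zi = 0.0 if sd == 0 else (within_k[v] - mu) / sd
        if k == 0:
            pi = 0.0
        else:
            counts: dict[int, int] = {}
            for u in g.neighbors(v):
                counts[modules[u]] = counts.get(modules[u], 0) + 1
            pi = 1.0 - sum((c / k) ** 2 for c in counts.values())
        if zi > 2.5 and pi <= 0.62:
            role = "module_hub"
        elif zi > 2.5:
            role = "network_hub"
        elif pi > 0.62:
            role = "connector"
        else:
            role = "non_hub"
        rows.append((v, modules[v], k, within_k[v], zi, pi, role))
    return pd.DataFrame(
        rows, columns=["taxon", "module", "degree", "within_module_degree", "zi", "pi", "role"]
    )


def write_graphml(network: CorrelationNetwork, path) -> None:
    nx.write_graphml(network.graph, path)
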