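"""Co-occurrence network construction, topology profiling and core-taxon calls.

One network per treatment (the study design's six watering stages), built
from genus-level relative abundances in three steps:

1. prevalence filter — keep genera detected in strictly more than a
   fraction (default 0.8) of the in-scope samples;
2. pairwise Spearman correlation with average ranks for ties; p-values
   from the t-distribution approximation by default, with a vectorized
   exact-permutation option for small sample counts;
3. edge rule — keep pairs with |rho| strictly above 0.6 and p strictly
   below 0.05; isolated genera are dropped from the node set (the edge-list
   convention of network-visualization tools), so node counts vary per
   treatment.

Topology reports the seven standard parameters (node and edge counts,
average degree 2E/N, Louvain modularity at resolution 1, mean local
clustering with zeros for degree<2 nodes, average shortest-path length
over connected ordered pairs, diameter).  Core taxa are nodes jointly in
the upper quantile of both degree and closeness centrality; classic
per-component, Wasserman-Faust component-size-scaled, and harmonic
closeness are all reported, with the Wasserman-Faust variant driving the
core rule on disconnected graphs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .tables_io import CountTable, StudyDesign, ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EdgeRule:
    """Thresholds defining a co-occurrence edge."""

    method: str = "spearman"
    min_abs_r: float = 0.6       # strict: |rho| must exceed this
    max_p: float = 0.05          # strict: p must be below this
    prevalence: float = 0.8      # strict: detected in > this fraction of samples
    scope: str = "per-treatment"  # or "global"
    adjust_p: bool = False       # optional BH over edge p-values (off: raw rule)

    def __post_init__(self) -> None:
        if not 0 < self.min_abs_r < 1:
            raise ValidationError("min_abs_r must be in (0,1)")
        if not 0 < self.max_p <= 1:
            raise ValidationError("max_p must be in (0,1]")
        if not 0 < self.prevalence <= 1:
            raise ValidationError("prevalence must be in (0,1]")
        if self.scope not in ("per-treatment", "global"):
            raise ValidationError("scope must be 'per-treatment' or 'global'")


def prevalence_filter(table: CountTable, design: StudyDesign,
                      rule: EdgeRule) -> dict[str, list[str]]:
    """Genera detected in strictly more than ``prevalence`` of scope samples.

    Returns a mapping scope label -> retained genus ids.  Scope is each
    treatment separately (default) or all samples pooled ("global").
    An empty retained set is allowed (warning; downstream yields an empty
    network).
    """
    scopes: dict[str, list[str]]
    if rule.scope == "global":
        scopes = {"global": list(design.samples)}
    else:
        scopes = {t: design.samples_for(t) for t in design.treatments}
    out: dict[str, list[str]] = {}
    for label, samples in scopes.items():
        if len(samples) < 2:
            raise ValidationError(f"scope {label!r} has fewer than 2 samples")
        sub = table.counts[samples]
        present = (sub > 0).sum(axis=1)
        retained = sub.index[present > rule.prevalence * len(samples)].tolist()
        if not retained:
            log.warning("prevalence filter retained no genera in scope %r", label)
        out[label] = retained
    return out


# ---------------------------------------------------------------------------
# Spearman correlation matrix
# ---------------------------------------------------------------------------

def spearman_matrix(abundances: pd.DataFrame, method: str = "t",
                    exact_max_n: int = 9
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho and p over the rows of `abundances`.

    Rows are genera, columns are the in-scope samples.  Ties get average
    ranks.  ``method='t'`` uses the t-distribution approximation;
    ``method='exact'`` (n <= `exact_max_n`) enumerates all n! sample
    permutations for a two-sided permutation p; ``method='auto'`` picks
    exact when feasible.  Constant rows have undefined correlation and are
    reported as NaN (never coerced to 0) with a logged warning.
    """
    x = abundances.to_numpy(dtype=float)
    genera = list(abundances.index)
    n = x.shape[1]
    if n < 3:
        raise ValidationError("need at least 3 samples for Spearman correlation")
    const = np.ptp(x, axis=1) == 0
    if const.any():
        log.warning("constant-abundance genera excluded from correlation: %s",
                    [g for g, c in zip(genera, const) if c])
    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    safe = norms.copy()
    safe[safe == 0] = 1.0
    rho = (centered @ centered.T) / np.outer(safe, safe)
    np.clip(rho, -1.0, 1.0, out=rho)
    np.fill_diagonal(rho, 1.0)
    rho[const, :] = np.nan
    rho[:, const] = np.nan

    use_exact = method == "exact" or (method == "auto" and n <= exact_max_n)
    if use_exact:
        if n > exact_max_n:
            raise ValidationError(
                f"exact permutation p requested for n={n} > {exact_max_n}")
        p = _exact_p_matrix(ranks, rho, const)
    else:
        p = _t_approx_p(rho, n)
    np.fill_diagonal(p, np.nan)
    idx = pd.Index(genera)
    return (pd.DataFrame(rho, index=idx, columns=idx),
            pd.DataFrame(p, index=idx, columns=idx))


def _t_approx_p(rho: np.ndarray, n: int) -> np.ndarray:
    r = np.clip(rho, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt((n - 2) / (1 - r ** 2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rho) >= 1 - 1e-12] = 0.0
    p[np.isnan(rho)] = np.nan
    return p


def _exact_p_matrix(ranks: np.ndarray, rho: np.ndarray,
                    const: np.ndarray) -> np.ndarray:
    """Two-sided exact permutation p for every pair, with a cache.

    The null distribution of rho under permutation depends only on the two
    rank multisets, so untied pairs (both rank vectors a permutation of
    1..n) share a single precomputed null; tied patterns are cached by
    their sorted rank tuples.
    """
    m, n = ranks.shape
    perms = np.array(list(permutations(range(n))), dtype=np.intp)
    cache: dict[tuple, np.ndarray] = {}

    def null_abs_rho(rx: np.ndarray, ry: np.ndarray) -> np.ndarray:
        key = (tuple(np.sort(rx)), tuple(np.sort(ry)))
        key = min(key, key[::-1])
        if key not in cache:
            cx = rx - rx.mean()
            cy = ry - ry.mean()
            denom = math.sqrt((cx ** 2).sum() * (cy ** 2).sum())
            vals = (cx[perms] @ cy) / denom
            cache[key] = np.abs(vals)
        return cache[key]

    p = np.full((m, m), np.nan)
    for i in range(m):
        if const[i]:
            continue
        for j in range(i + 1, m):
            if const[j]:
                continue
            nulls = null_abs_rho(ranks[i], ranks[j])
            obs = abs(rho[i, j])
            p[i, j] = p[j, i] = (nulls >= obs - 1e-12).mean()
    return p


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def build_network(rho: pd.DataFrame, p: pd.DataFrame, rule: EdgeRule,
                  treatment: str | None = None,
                  genus_names: pd.Series | None = None,
                  drop_isolated: bool = True) -> nx.Graph:
    """Undirected signed network from the edge rule (strict inequalities).

    Edge iff |rho| > `min_abs_r` AND p < `max_p`; undefined (NaN)
    correlations never form edges.  Isolated genera are excluded from the
    node set by default.
    """
    if rho.shape != p.shape or not rho.index.equals(p.index):
        raise ValidationError("rho and p matrices are not conformable")
    g = nx.Graph(treatment=treatment or "", min_abs_r=rule.min_abs_r,
                 max_p=rule.max_p, prevalence=rule.prevalence)
    genera = list(rho.index)
    r = rho.to_numpy()
    pv = p.to_numpy().copy()
    iu = np.triu_indices(len(genera), k=1)
    if rule.adjust_p:
        from statsmodels.stats.multitest import multipletests
        raw = pv[iu]
        ok = ~np.isnan(raw)
        adj = raw.copy()
        if ok.any():
            adj[ok] = multipletests(raw[ok], method="fdr_bh")[1]
        pv[iu] = adj
        pv[(iu[1], iu[0])] = adj
    if not drop_isolated:
        g.add_nodes_from(genera)
    for a, b in zip(*iu):
        rv, pval = r[a, b], pv[a, b]
        if np.isnan(rv) or np.isnan(pval):
            continue
        if abs(rv) > rule.min_abs_r and pval < rule.max_p:
            g.add_edge(genera[a], genera[b], rho=float(rv),
                       sign="+" if rv > 0 else "-", p=float(pval))
    if genus_names is not None:
        for node in g.nodes:
            g.nodes[node]["genus"] = str(genus_names.get(node, node))
    return g


def networks_per_scope(table: CountTable, design: StudyDesign, rule: EdgeRule,
                       method: str = "t",
                       genus_names: pd.Series | None = None
                       ) -> dict[str, nx.Graph]:
    """Prevalence filter -> proportions -> Spearman -> edge rule, per scope."""
    from .community import relative_abundance
    props = relative_abundance(table)
    retained = prevalence_filter(table, design, rule)
    scopes = ({"global": list(design.samples)} if rule.scope == "global"
              else {t: design.samples_for(t) for t in design.treatments})
    nets = {}
    for label, samples in scopes.items():
        genera = retained[label]
        if len(genera) < 2:
            nets[label] = nx.Graph(treatment=label)
            continue
        sub = props.loc[genera, samples]
        rho, p = spearman_matrix(sub, method=method)
        nets[label] = build_network(rho, p, rule, treatment=label,
                                    genus_names=genus_names)
    return nets


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

@dataclass
class TopologyReport:
    """The seven standard co-occurrence network parameters."""

    nodes: int
    edges: int
    average_degree: float
    modularity: float
    average_clustering: float
    average_path_length: float
    diameter: float
    treatment: str = ""

    COLUMNS = ("Node", "Edge", "Average degree", "Modularity",
               "Average clustering coefficient", "Average path length",
               "Network diameter")

    def to_row(self) -> list:
        return [self.nodes, self.edges, self.average_degree, self.modularity,
                self.average_clustering, self.average_path_length,
                self.diameter]


def topology(g: nx.Graph, seed: int = 0, resolution: float = 1.0,
             weighted: bool = False, n_restarts: int = 8) -> TopologyReport:
    """Topology profile of one network.

    Average degree is 2E/N.  Modularity is that of the best partition over
    `n_restarts` seeded Louvain runs at the given resolution (unweighted by
    default) — Louvain is a stochastic heuristic, and keeping the best of a
    few deterministic restarts is the usual way to stabilize it.  Path
    length and diameter are over connected ordered pairs only; undefined
    quantities (empty or edgeless graphs) are NaN.
    """
    n, e = g.number_of_nodes(), g.number_of_edges()
    avg_deg = (2.0 * e / n) if n > 0 else float("nan")
    weight = "weight" if weighted else None
    if e > 0:
        mod = -np.inf
        for r in range(max(1, n_restarts)):
            parts = nx.community.louvain_communities(
                g, weight=weight, seed=seed + r, resolution=resolution)
            q = nx.community.modularity(g, parts, weight=weight,
                                        resolution=resolution)
            mod = max(mod, q)
    else:
        mod = float("nan")
    clust = nx.average_clustering(g) if n > 0 else float("nan")
    total, count, diam = 0.0, 0, 0
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            for target, d in dists.items():
                if d > 0:
                    total += d
                    count += 1
                    diam = max(diam, d)
    apl = total / count if count else float("nan")
    diameter = float(diam) if count else float("nan")
    return TopologyReport(n, e, avg_deg, float(mod), float(clust),
                          apl, diameter, treatment=str(g.graph.get("treatment", "")))


def topology_table(nets: dict[str, nx.Graph], seed: int = 0) -> pd.DataFrame:
    rows = {}
    for label, g in nets.items():
        rep = topology(g, seed=seed)
        rows[label] = rep.to_row()
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(TopologyReport.COLUMNS))


# ---------------------------------------------------------------------------
# core taxa
# ---------------------------------------------------------------------------

@dataclass
class CoreTaxaResult:
    table: pd.DataFrame      # per node: degree, closeness, harmonic, core flag
    quantile: float
    degree_cutoff: float
    closeness_cutoff: float

    @property
    def core(self) -> list[str]:
        return self.table.index[self.table["core"]].tolist()


def core_taxa(g: nx.Graph, q: float = 0.9,
              closeness_kind: str = "wf") -> CoreTaxaResult:
    """Joint degree/closeness core call.

    Core = nodes whose degree and closeness are both at or above the
    q-quantile of their distributions over all nodes (ties at the boundary
    included).  Three closeness variants are reported: classic
    per-component closeness, the Wasserman-Faust component-size-scaled
    closeness, and harmonic closeness.  The core rule uses the
    Wasserman-Faust variant by default (`closeness_kind` in
    {"wf", "classic", "harmonic"}): on the disconnected graphs these
    networks typically are, classic closeness assigns 1.0 to every member
    of an isolated dyad, which would let trivial satellite components
    outrank the genuinely central taxa of the main component.
    """
    if g.number_of_nodes() == 0:
        empty = pd.DataFrame(columns=["degree", "closeness", "wf_closeness",
                                      "harmonic", "core"])
        return CoreTaxaResult(empty, q, float("nan"), float("nan"))
    if not 0 <= q <= 1:
        raise ValidationError("quantile must be in [0,1]")
    nodes = list(g.nodes)
    degree = np.array([g.degree(v) for v in nodes], dtype=float)
    classic_map = nx.closeness_centrality(g, wf_improved=False)
    wf_map = nx.closeness_centrality(g, wf_improved=True)
    harmonic_map = nx.harmonic_centrality(g)
    classic = np.array([classic_map[v] for v in nodes])
    wf = np.array([wf_map[v] for v in nodes])
    denom = max(len(nodes) - 1, 1)
    harmonic = np.array([harmonic_map[v] / denom for v in nodes])
    chosen = {"wf": wf, "classic": classic, "harmonic": harmonic}
    if closeness_kind not in chosen:
        raise ValidationError(f"unknown closeness_kind {closeness_kind!r}")
    closeness = chosen[closeness_kind]
    dq = float(np.quantile(degree, q))
    cq = float(np.quantile(closeness, q))
    core = (degree >= dq) & (closeness >= cq)
    df = pd.DataFrame({"degree": degree.astype(int), "closeness": classic,
                       "wf_closeness": wf, "harmonic": harmonic,
                       "core": core}, index=nodes)
    return CoreTaxaResult(df, q, dq, cq)
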