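"""Structural and functional enrichment of trend clusters.

Two complementary analyses per feature cluster:

* **Structural over-representation** — for every chemical-taxonomy term, a
  one-sided Fisher's exact test on the 2x2 table {in cluster vs not} x
  {annotated with term vs not}, with Benjamini-Hochberg adjustment across
  the terms tested within a cluster (switchable to Bonferroni).  The
  background set is the set of classified explanatory features.

* **Functional (pathway) diffusion** — compounds matched to the cluster's
  features seed a personalized PageRank over a compound-reaction-pathway
  knowledge graph (restart mass uniform on the seeds, damping 0.85).  A
  pathway's significance is an empirical *p-score*: the add-one tail
  probability that an equally sized random compound seed set gives the
  pathway an equal or higher stationary score.  Smaller p-scores mean the
  pathway is better connected to the observed compounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("leafprint")

DEFAULT_DAMPING = 0.85
DEFAULT_N_NULL = 1000

NODE_TYPES = ("compound", "reaction", "pathway")


# ---------------------------------------------------------------------------
# structural over-representation (Fisher)
# ---------------------------------------------------------------------------

def fisher_ora(cluster: list[str], background: list[str],
               annotations: dict[str, set[str] | list[str]],
               adjust: str = "bh") -> pd.DataFrame:
    """One-sided Fisher over-representation per annotation term.

    ``annotations`` maps feature id -> taxonomy terms.  Terms never seen in
    the background are skipped (logged).  Returns one row per term with the
    2x2 counts, raw p and adjusted p, sorted by raw p.
    """
    bg = list(dict.fromkeys(background))
    cl = list(dict.fromkeys(cluster))
    stray = set(cl) - set(bg)
    if stray:
        raise ValueError(f"cluster features missing from background: {sorted(stray)[:5]}")
    if not cl:
        logger.warning("fisher_ora: empty cluster, no tests performed")
        return pd.DataFrame(columns=["term", "in_cluster", "cluster_size",
                                     "in_background", "background_size",
                                     "p_value", "adjusted_p"])
    terms = sorted({t for f in bg for t in annotations.get(f, ())})
    N, n = len(bg), len(cl)
    rows = []
    for term in terms:
        has = {f for f in bg if term in annotations.get(f, ())}
        K = len(has)
        k = len(has.intersection(cl))
        # one-sided enrichment p: hypergeometric upper tail P(X >= k),
        # identical to Fisher's exact test with alternative="greater"
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "in_cluster": k, "cluster_size": n,
                     "in_background": K, "background_size": N,
                     "p_value": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if out.empty:
        return out.reindex(columns=["term", "in_cluster", "cluster_size",
                                    "in_background", "background_size",
                                    "p_value", "adjusted_p"])
    method = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[adjust]
    out["adjusted_p"] = multipletests(out["p_value"], method=method)[1]
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)


def cluster_structural_enrichment(clusters: pd.Series,
                                  annotations: dict[str, set[str] | list[str]],
                                  adjust: str = "bh") -> pd.DataFrame:
    """Fisher ORA of every cluster against the all-classified background."""
    background = [f for f in clusters.index if annotations.get(f)]
    frames = []
    for cid in sorted(clusters.unique()):
        members = [f for f in clusters.index[clusters == cid] if f in background]
        tab = fisher_ora(members, background, annotations, adjust)
        if tab.empty:
            continue
        tab.insert(0, "cluster", cid)
        frames.append(tab)
    cols = ["cluster", "term", "in_cluster", "cluster_size", "in_background",
            "background_size", "p_value", "adjusted_p"]
    return pd.concat(frames, ignore_index=True) if frames else \
        pd.DataFrame(columns=cols)


# ---------------------------------------------------------------------------
# knowledge graph
# ---------------------------------------------------------------------------

def _node_type(node: str) -> str:
    if node.startswith("cpd"):
        return "compound"
    if node.startswith("rxn"):
        return "reaction"
    if node.startswith("path"):
        return "pathway"
    raise ValueError(f"cannot infer node type of {node!r}")


def build_knowledge_graph(edges: pd.DataFrame,
                          compounds: list[str] | None = None) -> nx.Graph:
    """Undirected compound-reaction-pathway graph from an edge list.

    Node types are inferred from id prefixes (cpd/rxn/path).  When a
    compound list is given, edges referring to unknown compounds are an
    error (dangling references).
    """
    if not {"source", "target"}.issubset(edges.columns):
        raise ValueError("edge list needs 'source' and 'target' columns")
    G = nx.Graph()
    dangling = []
    known = set(compounds) if compounds is not None else None
    for _, row in edges.iterrows():
        for node in (row["source"], row["target"]):
            t = _node_type(str(node))
            if t == "compound" and known is not None and node not in known:
                dangling.append(node)
            G.add_node(str(node), type=t)
        G.add_edge(str(row["source"]), str(row["target"]))
    if dangling:
        raise ValueError(f"dangling compound ids in edge list: {sorted(set(dangling))}")
    n_comp = sum(1 for _, d in G.nodes(data=True) if d["type"] == "compound")
    comps = list(nx.connected_components(G))
    logger.info("knowledge graph: %d nodes (%d compounds), %d edges, "
                "%d connected components", G.number_of_nodes(), n_comp,
                G.number_of_edges(), len(comps))
    return G


def graph_nodes(G: nx.Graph, node_type: str) -> list[str]:
    return sorted(n for n, d in G.nodes(data=True) if d.get("type") == node_type)


# ---------------------------------------------------------------------------
# personalized-PageRank diffusion enrichment
# ---------------------------------------------------------------------------

def personalized_pagerank(G: nx.Graph, seeds: list[str],
                          damping: float = DEFAULT_DAMPING,
                          tol: float = 1e-12) -> dict[str, float]:
    """Stationary scores of a random walk with restart on ``seeds``."""
    if not (0 < damping < 1):
        raise ValueError("damping must be in (0, 1)")
    missing = [s for s in seeds if s not in G]
    if missing or not seeds:
        raise ValueError(f"seed compounds not in graph: {missing or 'empty seed set'}")
    personal = {s: 1.0 / len(seeds) for s in seeds}
    return nx.pagerank(G, alpha=damping, personalization=personal, tol=tol,
                       max_iter=1000)


@dataclass
class PagerankEnrichment:
    scores: pd.Series                # observed stationary score per node
    p_scores: pd.Series              # empirical p per non-seed node
    seeds: list[str]
    n_null: int


def pagerank_enrichment(G: nx.Graph, seeds: list[str],
                        damping: float = DEFAULT_DAMPING,
                        n_null: int = DEFAULT_N_NULL,
                        seed: int = 0) -> PagerankEnrichment:
    """Empirical diffusion enrichment against random same-size seed sets.

    p-score(v) = (1 + #{null runs with score(v) >= observed}) / (1 + n_null),
    computed for every non-seed node; pathway rows are what Table-style
    reports consume.
    """
    seeds = list(dict.fromkeys(seeds))
    observed = personalized_pagerank(G, seeds, damping)
    compounds = graph_nodes(G, "compound")
    if len(compounds) < len(seeds):
        raise ValueError("fewer compounds in graph than seeds")
    rng = np.random.default_rng(seed)
    nodes = sorted(G.nodes)
    obs = pd.Series({n: observed.get(n, 0.0) for n in nodes})
    exceed = pd.Series(0, index=nodes, dtype=int)
    for _ in range(n_null):
        draw = list(rng.choice(compounds, size=len(seeds), replace=False))
        null_scores = personalized_pagerank(G, draw, damping)
        null = pd.Series({n: null_scores.get(n, 0.0) for n in nodes})
        exceed += (null >= obs).astype(int)
    p = (1 + exceed) / (1 + n_null)
    non_seed = [n for n in nodes if n not in set(seeds)]
    return PagerankEnrichment(scores=obs, p_scores=p.loc[non_seed],
                              seeds=seeds, n_null=n_null)


def pathway_table(result: PagerankEnrichment, G: nx.Graph,
                  cluster_id=None) -> pd.DataFrame:
    """Pathway rows of a diffusion-enrichment run, sorted by p-score."""
    rows = []
    for pw in graph_nodes(G, "pathway"):
        if pw in result.p_scores.index:
            rows.append({"cluster": cluster_id, "pathway_id": pw,
                         "score": float(result.scores[pw]),
                         "p_score": float(result.p_scores[pw])})
    return (pd.DataFrame(rows, columns=["cluster", "pathway_id", "score", "p_score"])
            .sort_values(["p_score", "pathway_id"], kind="stable")
            .reset_index(drop=True))


def cluster_functional_enrichment(clusters: pd.Series,
                                  feature_compounds: dict[str, list[str]],
                                  G: nx.Graph,
                                  damping: float = DEFAULT_DAMPING,
                                  n_null: int = DEFAULT_N_NULL,
                                  seed: int = 0) -> pd.DataFrame:
    """Diffusion enrichment of every cluster's matched compounds."""
    frames = []
    for cid in sorted(clusters.unique()):
        members = clusters.index[clusters == cid]
        seeds = sorted({c for f in members
                        for c in feature_compounds.get(f, []) if c in G})
        if not seeds:
            logger.warning("cluster %s: no seed compounds in graph, skipped", cid)
            continue
        res = pagerank_enrichment(G, seeds, damping, n_null,
                                  seed=int(np.random.SeedSequence([seed, hash(str(cid)) % (2**31)])
                                           .generate_state(1)[0] % (2**31)))
        frames.append(pathway_table(res, G, cluster_id=cid))
    return pd.concat(frames, ignore_index=True) if frames else \
        pd.DataFrame(columns=["cluster", "pathway_id", "score", "p_score"])
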