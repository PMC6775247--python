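"""Similarity graphs, random-walk communities, and the majority-voting consensus.

Each time step of the experiment becomes a node.  Within one segment, a
node is connected to its k most similar steps (by the Markov likelihood
similarity index) that also exceed a threshold S, keeping only the highly
significant relations; the directed selections are symmetrized for
clustering.  Communities of the resulting graph — found with the WalkTrap
random-walk method of Pons and Latapy — are read as functional-connectivity
states of that segment.

To describe the whole lumbar ensemble, every segment votes: each step's
list of most-similar steps (at most k entries, each above a threshold mst)
counts as votes, votes are pooled over segments, and a consensus graph
joins each step to its k2 most-voted partners.  WalkTrap communities of
the consensus graph are the global functional states; the step-ordered
sequence of community memberships is the state-transition narrative.

Default parameters: k = 3, S = 0.9 for per-segment graphs and k = 4,
mst = 0.9, k2 = 3 for the consensus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd

logger = logging.getLogger("cdpstates")

#: Per-segment neighborhood-graph defaults.
DEFAULT_K = 3
DEFAULT_S = 0.9

#: Consensus defaults.
DEFAULT_CONSENSUS_K = 4
DEFAULT_MST = 0.9
DEFAULT_K2 = 3

#: WalkTrap random-walk length.
WALKTRAP_STEPS = 4


@dataclass
class StepGraph:
    """Undirected weighted graph over time steps with a community partition.

    ``step_keys`` maps node position to the original (1-based) step index;
    ``conditions`` optionally tags each node; ``communities`` is a 0-based
    community id per node.
    """

    graph: ig.Graph
    step_keys: list[int]
    conditions: list[str] = field(default_factory=list)
    communities: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.vcount()

    def membership_table(self) -> pd.DataFrame:
        """Ordered (step, condition, community) table — the transition narrative."""
        if self.communities is None:
            raise ValueError("communities not computed")
        df = pd.DataFrame({
            "step": self.step_keys,
            "condition": self.conditions if self.conditions else [""] * self.n_nodes,
            "community": self.communities.astype(int),
        })
        return df.sort_values("step", kind="stable").reset_index(drop=True)


def _validate_similarity(sim: np.ndarray) -> np.ndarray:
    S = np.asarray(sim, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("similarity matrix must be square")
    if np.any(S < -1e-12) or np.any(S > 1 + 1e-12):
        raise ValueError("similarity entries must lie in [0, 1]")
    return np.clip(S, 0.0, 1.0)


def _topk_selections(scores: np.ndarray, k: int, threshold: float) -> list[list[int]]:
    """Per row: up to k columns with score >= threshold, best first.

    Ties break toward the smaller column index (determinism).  The diagonal
    never qualifies.
    """
    n = scores.shape[0]
    out: list[list[int]] = []
    for i in range(n):
        cand = [j for j in range(n) if j != i and scores[i, j] >= threshold]
        cand.sort(key=lambda j: (-scores[i, j], j))
        out.append(cand[:k])
    return out


def build_similarity_graph(sim: np.ndarray, k: int = DEFAULT_K,
                           S: float = DEFAULT_S,
                           step_keys: list[int] | None = None,
                           conditions: list[str] | None = None) -> StepGraph:
    """Per-segment neighborhood graph from a similarity matrix.

    Each node selects its k most similar other nodes whose index reaches
    the threshold S (fewer when fewer qualify); the union of the directed
    selections gives the undirected edge set, each edge weighted by the
    larger of the two directed similarities.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0.0 <= S <= 1.0:
        raise ValueError("threshold S must lie in [0, 1]")
    M = _validate_similarity(sim)
    n = M.shape[0]
    sel = _topk_selections(M, k, S)
    edges = sorted({(min(i, j), max(i, j)) for i, js in enumerate(sel) for j in js})
    weights = [float(max(M[i, j], M[j, i])) for i, j in edges]
    g = ig.Graph(n=n, edges=edges, directed=False)
    g.es["weight"] = weights
    return StepGraph(graph=g,
                     step_keys=list(step_keys) if step_keys is not None else list(range(1, n + 1)),
                     conditions=list(conditions) if conditions is not None else [],
                     params={"k": k, "S": S})


def community_clusters(step_graph: StepGraph) -> np.ndarray:
    """WalkTrap communities of a step graph (best-modularity cut).

    Random-walk agglomerative community detection (walk length 4) on the
    non-isolated part of the graph; isolated nodes become singleton
    communities.  Deterministic for a fixed graph.  The assignment is also
    stored on the input graph.
    """
    g = step_graph.graph
    n = g.vcount()
    membership = np.full(n, -1, dtype=int)
    degrees = np.asarray(g.degree())
    active = np.flatnonzero(degrees > 0)
    if active.size:
        sub = g.induced_subgraph(active.tolist())
        weights = sub.es["weight"] if "weight" in sub.es.attributes() else None
        dendro = sub.community_walktrap(weights=weights, steps=WALKTRAP_STEPS)
        clustering = dendro.as_clustering()
        for pos, node in enumerate(active):
            membership[node] = clustering.membership[pos]
    next_id = membership.max() + 1 if active.size else 0
    for node in np.flatnonzero(degrees == 0):
        membership[node] = next_id
        next_id += 1
    step_graph.communities = membership
    return membership


@dataclass(frozen=True)
class VoteTable:
    """Pooled cross-segment votes.

    ``votes[i, j]`` counts the segments in which step i listed step j among
    its most-similar steps (directed).  ``n_segments`` and the per-segment
    parameters are kept for provenance.
    """

    votes: np.ndarray
    n_segments: int
    mst: float
    k: int

    def pair_votes(self) -> np.ndarray:
        """Total votes on each unordered pair: votes[i, j] + votes[j, i]."""
        return self.votes + self.votes.T


def collect_votes(sims: list[np.ndarray], mst: float = DEFAULT_MST,
                  k: int = DEFAULT_CONSENSUS_K) -> VoteTable:
    """Pool each segment's most-similar-step lists into a vote table.

    Per segment, every step votes for its up-to-k most similar steps with
    index >= mst; votes are summed over segments.
    """
    if not sims:
        raise ValueError("need at least one segment similarity matrix")
    mats = [_validate_similarity(s) for s in sims]
    n = mats[0].shape[0]
    if any(m.shape != (n, n) for m in mats):
        raise ValueError("all segments must share the step axis")
    votes = np.zeros((n, n), dtype=np.int64)
    for M in mats:
        for i, js in enumerate(_topk_selections(M, k, mst)):
            votes[i, js] += 1
    return VoteTable(votes=votes, n_segments=len(mats), mst=mst, k=k)


def build_consensus_graph(votes: VoteTable, k2: int = DEFAULT_K2,
                          step_keys: list[int] | None = None,
                          conditions: list[str] | None = None) -> StepGraph:
    """Consensus graph joining each step to its k2 most-voted partners.

    A step's candidates are the steps it voted for in at least one segment,
    ranked by the total votes on the pair (both directions); ties break
    toward the smaller step index.  The union of selections is the edge
    set, weighted by pair votes; communities come from WalkTrap as for the
    per-segment graphs.  All-zero votes give an edgeless graph (all
    singleton communities).
    """
    if k2 < 1:
        raise ValueError("k2 must be >= 1")
    V = votes.votes
    n = V.shape[0]
    pair = votes.pair_votes()
    edges_set: set[tuple[int, int]] = set()
    for i in range(n):
        cand = np.flatnonzero(V[i] > 0)
        ranked = sorted(cand.tolist(), key=lambda j: (-int(pair[i, j]), j))
        for j in ranked[:k2]:
            edges_set.add((min(i, j), max(i, j)))
    edges = sorted(edges_set)
    g = ig.Graph(n=n, edges=edges, directed=False)
    g.es["weight"] = [float(pair[i, j]) for i, j in edges]
    sg = StepGraph(graph=g,
                   step_keys=list(step_keys) if step_keys is not None else list(range(1, n + 1)),
                   conditions=list(conditions) if conditions is not None else [],
                   params={"k": votes.k, "mst": votes.mst, "k2": k2})
    community_clusters(sg)
    return sg


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def write_graphml(path, step_graph: StepGraph) -> None:
    """Export a step graph as GraphML with step/condition/community attributes."""
    g = step_graph.graph.copy()
    g.vs["step"] = [int(s) for s in step_graph.step_keys]
    g.vs["condition"] = (step_graph.conditions if step_graph.conditions
                         else [""] * step_graph.n_nodes)
    comm = (step_graph.communities if step_graph.communities is not None
            else np.full(step_graph.n_nodes, -1))
    g.vs["community"] = [int(c) for c in comm]
    g.write_graphml(str(path))


def write_votes_csv(path, votes: VoteTable, step_keys: list[int] | None = None) -> None:
    keys = step_keys if step_keys is not None else list(range(1, votes.votes.shape[0] + 1))
    pd.DataFrame(votes.votes, index=keys, columns=keys).to_csv(path)
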