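"""Median-joining haplotype networks (Bandelt, Forster & Roehl 1999).

The network starts from the minimum-spanning network (MSN: the union of
all minimum spanning trees, with an optional tolerance epsilon on the
component-merge level). Median (quasi-Steiner) vectors are added for
triplets of mutually linked nodes whenever the star through the median is
strictly shorter than connecting the triplet along its two cheapest edges;
the procedure iterates to closure and then prunes inferred vectors whose
removal does not increase the length of a minimum spanning tree over the
remaining nodes. All candidate orderings are broken lexicographically so
the result is independent of input order.

Edge weights count mutational steps (pairwise differences under the
package's masking rule: sites ambiguous in either sequence are skipped).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .seqio import Alignment, HaplotypeTable, pairwise_differences


@dataclass
class HaploNetwork:
    """Observed haplotypes plus inferred medians, with mutational-step edges."""

    graph: nx.Graph  # node attrs: sequence, inferred, counts (dict) or None

    @property
    def observed(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if not d["inferred"]]

    @property
    def medians(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["inferred"]]

    def total_length(self) -> float:
        return sum(w for _, _, w in self.graph.edges(data="weight"))

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {"node_a": a, "node_b": b, "steps": int(w)}
            for a, b, w in sorted(self.graph.edges(data="weight"))
        ]
        return pd.DataFrame(rows, columns=["node_a", "node_b", "steps"])

    def node_table(self) -> pd.DataFrame:
        rows = []
        for n, d in sorted(self.graph.nodes(data=True)):
            row = {
                "node": n,
                "inferred": d["inferred"],
                "sequence": d["sequence"],
                "total": 0 if d["inferred"] else sum(d["counts"].values()),
            }
            if not d["inferred"]:
                row.update(d["counts"])
            rows.append(row)
        return pd.DataFrame(rows).fillna(0)


def _distances(seqs: list[str]) -> np.ndarray:
    aln = Alignment([f"s{i}" for i in range(len(seqs))], list(seqs))
    return pairwise_differences(aln).values


def _msn_edges(seqs: list[str], eps: float = 0.0):
    """Minimum-spanning-network edges over a node set.

    Kruskal by distance level: all edges of a length level that join two
    components distinct at the start of the level enter the network (the
    union of every minimum spanning tree); a positive ``eps`` widens each
    level to admit slightly longer alternatives.
    """
    n = len(seqs)
    if n <= 1:
        return []
    d = _distances(seqs)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    edges = []
    remaining = sorted(
        ((d[i, j], i, j) for i, j in combinations(range(n), 2)),
        key=lambda t: (t[0], seqs[t[1]], seqs[t[2]]),
    )
    while remaining and len({find(i) for i in range(n)}) > 1:
        level = remaining[0][0]
        batch = [e for e in remaining if e[0] <= level + eps]
        remaining = [e for e in remaining if e[0] > level + eps]
        # all batch edges joining two (pre-batch) distinct components enter
        comp_before = [find(i) for i in range(n)]
        for w, i, j in batch:
            if comp_before[i] != comp_before[j]:
                edges.append((i, j, int(w)))
        for _, i, j in batch:
            parent[find(i)] = find(j)
    return edges


def _mst_length(seqs: list[str]) -> float:
    d = _distances(seqs)
    g = nx.Graph()
    g.add_nodes_from(range(len(seqs)))
    for i, j in combinations(range(len(seqs)), 2):
        g.add_edge(i, j, weight=d[i, j])
    t = nx.minimum_spanning_tree(g)
    return sum(w for _, _, w in t.edges(data="weight"))



def _median(a: str, b: str, c: str) -> str:
    """Site-wise majority consensus; three-way ties take the base of the
    lexicographically smallest parent."""
    first = min(a, b, c)
    out = []
    for x, y, z, f in zip(a, b, c, first):
        if x == y or x == z:
            out.append(x)
        elif y == z:
            out.append(y)
        else:
            out.append(f)
    return "".join(out)


def median_joining_network(
    ht: HaplotypeTable, epsilon: float = 0.0, max_iter: int = 50
) -> HaploNetwork:
    """Construct the median-joining network of a haplotype table."""
    if ht.Nh == 0:
        raise ValueError("empty haplotype table")
    observed = list(ht.hap_seqs)
    obs_ids = dict(zip(observed, ht.hap_ids))
    nodes = sorted(set(observed))
    for _ in range(max_iter):
        edges = _msn_edges(nodes, epsilon)
        adj = {i: set() for i in range(len(nodes))}
        for i, j, _ in edges:
            adj[i].add(j)
            adj[j].add(i)
        d = _distances(nodes)
        new = set()
        for i, j, k in combinations(range(len(nodes)), 3):
            if j in adj[i] and k in adj[i] and k in adj[j]:
                m = _median(nodes[i], nodes[j], nodes[k])
                if m in nodes or m in new:
                    continue
                dm = _distances([m, nodes[i], nodes[j], nodes[k]])[0, 1:]
                star = dm.sum()
                tri = sorted([d[i, j], d[i, k], d[j, k]])
                if star < tri[0] + tri[1]:
                    new.add(m)
        if not new:
            break
        nodes = sorted(set(nodes) | new)

    # prune inferred vectors that do not shorten the minimum spanning tree
    changed = True
    while changed:
        changed = False
        base = _mst_length(nodes)
        for m in sorted(n for n in nodes if n not in obs_ids):
            reduced = [n for n in nodes if n != m]
            if _mst_length(reduced) <= base:
                nodes = reduced
                changed = True
                break

    g = nx.Graph()
    med_counter = 0
    name_of = {}
    for seq in nodes:
        if seq in obs_ids:
            name = obs_ids[seq]
            counts = ht.counts.loc[name].to_dict()
            g.add_node(name, sequence=seq, inferred=False, counts=counts)
        else:
            med_counter += 1
            name = f"mv{med_counter}"
            g.add_node(name, sequence=seq, inferred=True, counts=None)
        name_of[seq] = name
    for i, j, w in _msn_edges(nodes, epsilon):
        g.add_edge(name_of[nodes[i]], name_of[nodes[j]], weight=int(w))
    if len(nodes) == 1:
        pass  # single-node network
    return HaploNetwork(g)


def subnetwork_separation(
    net: HaploNetwork, partition: dict[str, str]
) -> pd.DataFrame:
    """Minimum mutational steps separating each pair of haplotype groups.

    ``partition`` maps every observed node id to a group label. Steps
    internal to either group cost nothing; edges through median vectors or
    between groups count their full weight.
    """
    groups = sorted(set(partition.values()))
    obs = set(net.observed)
    missing = [n for n in partition if n not in obs]
    if missing:
        raise ValueError(f"partition refers to unknown nodes: {missing[:5]}")
    for n in obs:
        if n not in partition:
            raise ValueError(f"observed node {n!r} missing from partition")
    rows = []
    for ga, gb in combinations(groups, 2):
        g = net.graph.copy()
        for u, v, data in g.edges(data=True):
            pu, pv = partition.get(u), partition.get(v)
            if pu is not None and pu == pv:
                data["cost"] = 0.0
            else:
                data["cost"] = float(data["weight"])
        sources = [n for n in obs if partition[n] == ga]
        targets = {n for n in obs if partition[n] == gb}
        if not sources or not targets:
            raise ValueError(f"group absent from network: {ga!r} or {gb!r}")
        best = np.inf
        lengths = nx.multi_source_dijkstra_path_length(g, sources, weight="cost")
        for t in targets:
            if t in lengths:
                best = min(best, lengths[t])
        rows.append({"group_a": ga, "group_b": gb, "steps": best})
    return pd.DataFrame(rows)
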