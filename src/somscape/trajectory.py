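"""Principal-tree trajectory over samples in metagene space.

Samples are reduced by principal components, tree nodes are placed by
k-means, the tree is the minimum spanning tree over node centroids, and
each sample projects to its nearest node. Segments are maximal
branch-free node paths (split at nodes of degree >= 3), labeled Seg1,
Seg2, ... by descending sample count; pseudotime is the geodesic
distance from a root node along the tree. This is a deliberately simple,
fully specified principal tree, not a port of any single-cell trajectory
package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from somscape.som_portrayal import SOMResults


class PrincipalTree:
    """Principal-tree model over a samples x features matrix.

    Parameters
    ----------
    data : pandas.DataFrame or SOMResults
        Samples x features coordinates. A fitted SOM may be passed
        directly; its transposed prototype matrix (samples x metagenes)
        is used.
    n_components : int
        Principal components kept before node placement.
    n_nodes : int
        Number of tree nodes (k-means centroids).
    seed : int
        Seed for k-means; the fit is deterministic under a fixed seed.
    """

    def __init__(
        self,
        data,
        n_components: int = 10,
        n_nodes: int = 20,
        seed: int = 0,
        prune_min_frac: float = 0.08,
    ):
        from somscape.som_portrayal import SOMResults

        if isinstance(data, SOMResults):
            data = data.prototypes.T
        self.data = pd.DataFrame(data)
        n_samples = len(self.data)
        if n_nodes < 2:
            raise ValueError("need at least 2 tree nodes")
        if n_nodes > n_samples:
            raise ValueError(f"n_nodes={n_nodes} exceeds n_samples={n_samples}")
        if n_components >= n_samples:
            raise ValueError(f"n_components={n_components} must be < n_samples={n_samples}")
        self.n_components = n_components
        self.n_nodes = n_nodes
        self.seed = seed
        self.prune_min_frac = prune_min_frac

    @staticmethod
    def _mst(centroids: np.ndarray) -> nx.Graph:
        d = np.sqrt(((centroids[:, None, :] - centroids[None, :, :]) ** 2).sum(-1))
        full = nx.Graph()
        n = len(centroids)
        full.add_nodes_from(range(n))
        for i in range(n):
            for j in range(i + 1, n):
                full.add_edge(i, j, weight=float(d[i, j]))
        return nx.minimum_spanning_tree(full)

    def _prune_twigs(self, tree: nx.Graph, nos: pd.Series, coords: np.ndarray, reduced):
        """Remove leaf chains carrying fewer than prune_min_frac of the samples.

        Noise in the reduced space grows spurious side twigs on the spanning
        tree; a genuine branch carries a substantial share of the cohort.
        Samples of pruned nodes re-project to the nearest surviving node.
        Deterministic: twigs are inspected in node order, one per pass.
        """
        n = len(nos)
        min_samples = max(2, self.prune_min_frac * n)
        changed = True
        while changed and tree.number_of_nodes() > 2:
            changed = False
            counts = nos.value_counts()
            for leaf in sorted(v for v in tree.nodes if tree.degree[v] == 1):
                chain = [leaf]
                while True:
                    nxts = [u for u in tree.neighbors(chain[-1]) if u not in chain]
                    if not nxts or tree.degree[nxts[0]] > 2:
                        break
                    chain.append(nxts[0])
                attach = [u for u in tree.neighbors(chain[-1]) if u not in chain]
                chain_samples = sum(int(counts.get(v, 0)) for v in chain)
                if attach and tree.degree[attach[0]] >= 3 and chain_samples < min_samples:
                    tree.remove_nodes_from(chain)
                    survivors = sorted(tree.nodes)
                    for s in nos.index[nos.isin(chain)]:
                        x = reduced.loc[s].to_numpy()
                        d = ((coords[survivors] - x) ** 2).sum(axis=1)
                        nos[s] = survivors[int(np.argmin(d))]
                    changed = True
                    break
        return tree, nos

    def fit(self) -> "TrajectoryResults":
        X = self.data.to_numpy(dtype=float)
        k = min(self.n_components, min(X.shape) - 1)
        reduced_arr = PCA(n_components=k, random_state=self.seed).fit_transform(X)
        reduced = pd.DataFrame(reduced_arr, index=self.data.index)
        km = KMeans(n_clusters=self.n_nodes, random_state=self.seed, n_init=10)
        nos = pd.Series(km.fit_predict(reduced_arr), index=self.data.index, name="node")
        centroids = km.cluster_centers_

        tree = self._mst(centroids)
        if self.prune_min_frac > 0:
            tree, nos = self._prune_twigs(tree, nos, centroids, reduced)

        # relabel surviving nodes 0..m-1 for a compact coordinate array
        survivors = sorted(tree.nodes)
        relabel = {old: new for new, old in enumerate(survivors)}
        tree = nx.relabel_nodes(tree, relabel)
        centroids = centroids[survivors]
        nos = nos.map(relabel)

        return TrajectoryResults(
            model=self,
            node_coords=centroids,
            graph=tree,
            sample_coords=reduced,
            node_of_sample=nos,
        )


@dataclass
class TrajectoryResults:
    """A fitted principal tree, before or after segment/pseudotime labeling."""

    model: PrincipalTree
    node_coords: np.ndarray
    graph: nx.Graph
    sample_coords: pd.DataFrame
    node_of_sample: pd.Series
    root: int | None = None
    pseudotime: pd.Series | None = None
    segment_of_sample: pd.Series | None = None
    segment_table: pd.DataFrame | None = None
    _node_segment: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.node_coords)
        if self.graph.number_of_nodes() != n or self.graph.number_of_edges() != n - 1:
            raise ValueError("principal graph must be a spanning tree (|E| = |V| - 1)")
        if not nx.is_connected(self.graph):
            raise ValueError("principal graph must be connected")

    # ------------------------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.node_of_sample.index)

    def leaves(self) -> list[int]:
        return [v for v in self.graph.nodes if self.graph.degree[v] == 1]

    def _segments(self) -> list[list[int]]:
        """Maximal branch-free node paths, split at nodes of degree >= 3."""
        g = self.graph
        if g.number_of_nodes() == 1:
            return [[next(iter(g.nodes))]]
        breaks = {v for v in g.nodes if g.degree[v] != 2}
        if not breaks:  # cycle impossible in a tree; path of all-degree-2 can't exist
            breaks = {min(g.nodes)}
        segments = []
        seen_edges = set()
        for b in sorted(breaks):
            for nb in sorted(g.neighbors(b)):
                if (b, nb) in seen_edges or (nb, b) in seen_edges:
                    continue
                path = [b, nb]
                while path[-1] not in breaks:
                    nxt = [v for v in g.neighbors(path[-1]) if v != path[-2]]
                    path.append(nxt[0])
                for u, v in zip(path, path[1:]):
                    seen_edges.add((u, v))
                    seen_edges.add((v, u))
                segments.append(path)
        return segments

    def assign_segments_pseudotime(
        self,
        root_node: int | None = None,
        root_spot: str | None = None,
        spot_profiles: pd.DataFrame | None = None,
    ) -> "TrajectoryResults":
        """Label segments and compute pseudotime from a root.

        The root is an explicit node ID, or the leaf whose samples maximize
        the mean expression of ``root_spot`` in ``spot_profiles``; with
        neither given, the lowest-numbered leaf is used.
        """
        if root_node is not None:
            if root_node not in self.graph:
                raise ValueError(f"unknown root node {root_node}")
            root = int(root_node)
        elif root_spot is not None:
            if spot_profiles is None or root_spot not in spot_profiles.index:
                raise KeyError(f"unknown spot {root_spot!r} for root selection")
            prof = spot_profiles.loc[root_spot]
            best, best_val = None, -np.inf
            for leaf in sorted(self.leaves()):
                members = self.node_of_sample.index[self.node_of_sample == leaf]
                if len(members) == 0:
                    continue
                val = prof.reindex(members).mean()
                if val > best_val:
                    best, best_val = leaf, val
            root = best if best is not None else sorted(self.leaves())[0]
        else:
            root = sorted(self.leaves())[0]
        self.root = root

        # geodesic distance from root along the tree
        dist = nx.single_source_dijkstra_path_length(self.graph, root, weight="weight")
        node_pt = np.array([dist[v] for v in range(len(self.node_coords))])
        self.pseudotime = pd.Series(
            node_pt[self.node_of_sample.to_numpy()], index=self.node_of_sample.index,
            name="pseudotime",
        )

        # order segments by descending tentative sample count, then node path
        node_counts = self.node_of_sample.value_counts()
        paths = self._segments()
        tentative = [int(node_counts.reindex(p).fillna(0).sum()) for p in paths]
        order = sorted(range(len(paths)), key=lambda i: (-tentative[i], paths[i]))
        labeled = [(f"Seg{rank + 1}", paths[i]) for rank, i in enumerate(order)]

        # each node belongs to exactly one segment: interior nodes are unique,
        # break nodes go to their lowest-ranked incident segment
        node_segment: dict[int, str] = {}
        for lab, path in labeled:
            for v in path:
                node_segment.setdefault(v, lab)
        self._node_segment = node_segment
        self.segment_of_sample = self.node_of_sample.map(node_segment).rename("segment")

        rows = []
        for lab, path in labeled:
            members = self.segment_of_sample.index[self.segment_of_sample == lab]
            rows.append({"segment": lab, "nodes": path, "n_samples": len(members)})
        self.segment_table = pd.DataFrame(rows).set_index("segment")
        return self

    # ------------------------------------------------------------------
    def sample_table(self) -> pd.DataFrame:
        """Per-sample table: node, segment, pseudotime."""
        if self.pseudotime is None:
            raise ValueError("call assign_segments_pseudotime first")
        return pd.DataFrame(
            {
                "node": self.node_of_sample,
                "segment": self.segment_of_sample,
                "pseudotime": self.pseudotime,
            }
        )

    def to_newick(self) -> str:
        """Newick string of the node tree rooted at the pseudotime root."""
        root = self.root if self.root is not None else sorted(self.leaves())[0]

        def recurse(v, parent):
            children = [u for u in sorted(self.graph.neighbors(v)) if u != parent]
            w = self.graph[parent][v]["weight"] if parent is not None else 0.0
            if not children:
                return f"N{v}:{w:.6g}"
            inner = ",".join(recurse(u, v) for u in children)
            return f"({inner})N{v}:{w:.6g}"

        return recurse(root, None) + ";"

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"node_a": u, "node_b": v, "length": self.graph[u][v]["weight"]}
                for u, v in sorted(self.graph.edges)
            ]
        )

    def summary(self) -> str:
        lines = [
            "Principal-tree trajectory",
            "=========================",
            f"nodes:    {self.graph.number_of_nodes()}",
            f"edges:    {self.graph.number_of_edges()}",
            f"leaves:   {len(self.leaves())}",
            f"samples:  {len(self.samples)}",
        ]
        if self.segment_table is not None:
            lines.append(f"root:     node {self.root}")
            lines.append(f"segments: {len(self.segment_table)}")
            for lab, row in self.segment_table.iterrows():
                lines.append(f"  {lab}: {row['n_samples']} samples, {len(row['nodes'])} nodes")
        return "\n".join(lines)


def overlap_coefficient(set_a, set_b) -> float:
    """OC = |A intersect B| / min(|A|, |B|); both sets must be nonempty."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise ValueError("overlap coefficient undefined for empty sets")
    return len(a & b) / min(len(a), len(b))


def segment_overlap_table(
    segments: pd.Series, subtypes: pd.Series
) -> pd.DataFrame:
    """Overlap coefficients between every subtype and every segment."""
    segments = pd.Series(segments)
    subtypes = pd.Series(subtypes).reindex(segments.index)
    out = {}
    for seg in sorted(segments.unique()):
        seg_set = set(segments.index[segments == seg])
        out[seg] = {
            sub: overlap_coefficient(set(subtypes.index[subtypes == sub]), seg_set)
            for sub in sorted(subtypes.unique(), key=str)
        }
    return pd.DataFrame(out)


def segment_spot_profiles(
    tree: TrajectoryResults,
    spot_profiles: pd.DataFrame,
    hr_scores: pd.Series | None = None,
    model: "SOMResults | None" = None,
    subtypes: pd.Series | None = None,
) -> dict:
    """Per-segment tables ordered by pseudotime, plus mean portraits and flows.

    Returns a dict with keys ``tables`` (segment -> DataFrame of spot
    expression, pseudotime, optional ΔHR score, ordered by pseudotime with
    sample-ID tie-break), ``portraits`` (segment -> mean portrait, if a
    fitted SOM is given), and ``flows`` (subtype x segment contingency
    table for river-flow rendering, if subtypes are given).
    """
    if tree.segment_of_sample is None:
        raise ValueError("assign segments and pseudotime before profiling")
    missing = [s for s in tree.samples if s not in spot_profiles.columns]
    if missing:
        raise ValueError(f"spot profiles missing samples: {missing[:5]}")
    if hr_scores is not None:
        missing = [s for s in tree.samples if s not in hr_scores.index]
        if missing:
            raise ValueError(f"HR scores missing samples: {missing[:5]}")

    tables = {}
    portraits = {}
    for seg in tree.segment_table.index:
        members = tree.segment_of_sample.index[tree.segment_of_sample == seg]
        order = sorted(members, key=lambda s: (tree.pseudotime[s], s))
        tab = spot_profiles[order].T
        tab.insert(0, "pseudotime", tree.pseudotime.reindex(order))
        if hr_scores is not None:
            tab["delta_hr"] = hr_scores.reindex(order)
        tables[seg] = tab
        if model is not None and len(order):
            portraits[seg] = model.group_mean_portrait(order)

    out = {"tables": tables, "portraits": portraits}
    if subtypes is not None:
        subtypes = pd.Series(subtypes).reindex(tree.samples)
        out["flows"] = pd.crosstab(subtypes, tree.segment_of_sample)
    return out
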