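"""Peptide-protein bipartite graph, protein clusters, and cluster filters.

Peptides shared between proteins connect those proteins into connected
components of the bipartite membership graph; each component ("protein
cluster") is the joint summarization unit. This module builds the graph from
a feature table, extracts clusters, merges indistinguishable proteins
(identical peptide evidence), and removes subset proteins (those identified
by shared peptides only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

_P = "protein"
_F = "feature"


def membership_from_table(features: pd.DataFrame, protein_delimiter: str = ";") -> dict[str, frozenset[str]]:
    """Per-feature protein membership V(f), unioned over table rows."""
    members: dict[str, set[str]] = {}
    for fid, prot in zip(features["feature_id"], features["protein"]):
        labels = {p for p in str(prot).split(protein_delimiter) if p}
        members.setdefault(fid, set()).update(labels)
    return {fid: frozenset(s) for fid, s in members.items()}


@dataclass
class ProteinCluster:
    """A connected component of the peptide-protein bipartite graph.

    ``membership`` maps each feature id to its protein set within the
    cluster; a feature is *unique* iff that set has exactly one element.
    """

    proteins: list[str]
    features: list[str]
    membership: dict[str, frozenset[str]] = field(repr=False)

    def __post_init__(self) -> None:
        self.proteins = sorted(self.proteins)
        self.features = sorted(self.features)

    def is_unique(self, feature_id: str) -> bool:
        return len(self.membership[feature_id]) == 1

    @property
    def unique_features(self) -> list[str]:
        return [f for f in self.features if self.is_unique(f)]

    @property
    def shared_features(self) -> list[str]:
        return [f for f in self.features if not self.is_unique(f)]

    def features_of(self, protein: str) -> frozenset[str]:
        return frozenset(f for f in self.features if protein in self.membership[f])

    def unique_features_of(self, protein: str) -> frozenset[str]:
        return frozenset(
            f for f in self.features if self.membership[f] == frozenset({protein})
        )

    @property
    def is_empty(self) -> bool:
        return not self.proteins

    @property
    def is_trivial(self) -> bool:
        """Single-protein clusters bypass the weighted model."""
        return len(self.proteins) == 1


def build_graph(features: pd.DataFrame, protein_delimiter: str = ";") -> nx.Graph:
    """Build the bipartite graph: one node per protein accession and per
    distinct feature id, with an edge for every membership in V(f)."""
    if features.empty:
        raise ValueError("cannot build a graph from an empty feature table")
    g = nx.Graph()
    for fid, labels in membership_from_table(features, protein_delimiter).items():
        g.add_node((_F, fid), kind=_F)
        for acc in labels:
            g.add_node((_P, acc), kind=_P)
            g.add_edge((_F, fid), (_P, acc))
    return g


def protein_nodes(graph: nx.Graph) -> list[str]:
    return sorted(n[1] for n, d in graph.nodes(data=True) if d["kind"] == _P)


def feature_nodes(graph: nx.Graph) -> list[str]:
    return sorted(n[1] for n, d in graph.nodes(data=True) if d["kind"] == _F)


def find_clusters(graph: nx.Graph) -> list[ProteinCluster]:
    """Protein clusters = connected components of the bipartite graph.

    Clusters are returned sorted by their (lexicographically first) protein
    accession so output order is independent of input row order.
    """
    clusters = []
    for comp in nx.connected_components(graph):
        proteins = sorted(n[1] for n in comp if n[0] == _P)
        feats = sorted(n[1] for n in comp if n[0] == _F)
        membership = {
            fid: frozenset(n[1] for n in graph.neighbors((_F, fid))) for fid in feats
        }
        clusters.append(ProteinCluster(proteins, feats, membership))
    return sorted(clusters, key=lambda c: c.proteins)


def merge_indistinguishable(
    cluster: ProteinCluster, protein_delimiter: str = ";"
) -> ProteinCluster:
    """Merge proteins identified by exactly the same set of features.

    Merged proteins get the delimiter-joined, sorted accession label; the
    feature-to-cluster assignment is unchanged.
    """
    by_featset: dict[frozenset[str], list[str]] = {}
    for p in cluster.proteins:
        by_featset.setdefault(cluster.features_of(p), []).append(p)
    relabel: dict[str, str] = {}
    for accs in by_featset.values():
        label = protein_delimiter.join(sorted(accs))
        for acc in accs:
            relabel[acc] = label
        if len(accs) > 1:
            logger.info("merged indistinguishable proteins %s", label)
    membership = {
        fid: frozenset(relabel[p] for p in mem)
        for fid, mem in cluster.membership.items()
    }
    return ProteinCluster(sorted(set(relabel.values())), list(cluster.features), membership)


def filter_shared_only(cluster: ProteinCluster, keep_subset: bool = False) -> ProteinCluster:
    """Remove subset proteins (no unique feature), iterating to a fixed point.

    Removing a protein can promote a formerly shared feature to unique for a
    remaining protein, which in turn can rescue that protein; membership is
    therefore recomputed and the removal rule re-applied until stable.
    Features left with no protein are dropped. A cluster whose proteins are
    all removed is returned empty (``is_empty``) and should be excluded from
    fitting.
    """
    if keep_subset:
        return cluster
    proteins = list(cluster.proteins)
    membership = dict(cluster.membership)
    while True:
        subset = [p for p in proteins if not any(membership[f] == frozenset({p}) for f in membership)]
        if not subset:
            break
        logger.info("removed subset proteins (shared peptides only): %s", sorted(subset))
        proteins = [p for p in proteins if p not in subset]
        membership = {
            fid: frozenset(mem - set(subset))
            for fid, mem in membership.items()
            if mem - set(subset)
        }
    return ProteinCluster(proteins, sorted(membership), membership)


def filter_single_shared_peptide(cluster: ProteinCluster) -> ProteinCluster:
    """Remove proteins whose entire evidence is a single shared peptide.

    A stricter variant of subset-protein removal (count threshold of one);
    provided as a separate filter, applied once, then membership cleaned up.
    """
    drop = {
        p
        for p in cluster.proteins
        if len(cluster.features_of(p)) == 1
        and not cluster.unique_features_of(p)
    }
    if not drop:
        return cluster
    logger.info("removed single-shared-peptide proteins: %s", sorted(drop))
    membership = {
        fid: frozenset(mem - drop)
        for fid, mem in cluster.membership.items()
        if mem - drop
    }
    return ProteinCluster(
        [p for p in cluster.proteins if p not in drop], sorted(membership), membership
    )


def prepare_clusters(
    features: pd.DataFrame,
    keep_subset: bool = False,
    merge: bool = True,
    protein_delimiter: str = ";",
) -> list[ProteinCluster]:
    """Full cluster preparation: graph, components, merge, subset filtering.

    Empty clusters (all proteins removed) are excluded. Filtering can split a
    cluster into disconnected parts; components are recomputed afterwards.
    """
    clusters = find_clusters(build_graph(features, protein_delimiter))
    out: list[ProteinCluster] = []
    for cl in clusters:
        if merge:
            cl = merge_indistinguishable(cl, protein_delimiter)
        cl = filter_shared_only(cl, keep_subset=keep_subset)
        if cl.is_empty:
            continue
        out.extend(_split_components(cl))
    return sorted(out, key=lambda c: c.proteins)


def _split_components(cluster: ProteinCluster) -> list[ProteinCluster]:
    g = nx.Graph()
    for fid, mem in cluster.membership.items():
        for p in mem:
            g.add_edge((_F, fid), (_P, p))
    return find_clusters(g)


def apply_cluster_membership(
    features: pd.DataFrame,
    clusters: Iterable[ProteinCluster],
    protein_delimiter: str = ";",
) -> pd.DataFrame:
    """Rewrite the feature table's protein column from cluster membership
    (post merge/filter); features absent from every cluster are dropped."""
    labels: dict[str, str] = {}
    for cl in clusters:
        for fid, mem in cl.membership.items():
            labels[fid] = protein_delimiter.join(sorted(mem))
    out = features[features["feature_id"].isin(labels)].copy()
    out["protein"] = out["feature_id"].map(labels)
    return out.reset_index(drop=True)


def export_edge_list(graph: nx.Graph, path: str | Path) -> None:
    # normalise edge orientation (networkx edge order is arbitrary)
    rows = []
    for a, b in graph.edges():
        f, p = (a, b) if a[0] == _F else (b, a)
        rows.append({"feature_id": f[1], "protein": p[1]})
    pd.DataFrame(rows).sort_values(["protein", "feature_id"]).to_csv(path, sep="\t", index=False)


def cluster_report(clusters: Iterable[ProteinCluster]) -> pd.DataFrame:
    """Per-cluster size report: protein count, feature count, shared count."""
    rows = []
    for i, cl in enumerate(clusters):
        rows.append(
            {
                "cluster": i,
                "proteins": len(cl.proteins),
                "features": len(cl.features),
                "shared_features": len(cl.shared_features),
            }
        )
    return pd.DataFrame(rows, columns=["cluster", "proteins", "features", "shared_features"])
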