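"""Spearman co-expression networks over differentially expressed probe sets.

Nodes are probe sets (annotated with genotype of origin, direction of
regulation under stress, a functional role category and a transcription-
factor flag); an edge joins two sets whose Spearman rank correlation across
a genotype's samples reaches the threshold (default 0.9, on |rho| so that
anti-correlated induced/repressed pairs connect; a positive-only mode is
available).  Per-genotype networks can be merged with provenance kept on
nodes and edges, and transcription factors are ranked by vertex degree in
the whole network and in a dehydration-specific subnetwork.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats

from .chipmodel import ExpressionMatrix, ValidationError

NODE_ATTRS = ("genotype_origin", "direction", "role_category", "is_tf", "name")


def spearman_matrix(expr: ExpressionMatrix, samples=None) -> pd.DataFrame:
    """Pairwise Spearman rho (average ranks) between probe sets.

    Computed across the given samples (>= 3 required).  Probe sets that are
    constant across the samples have undefined correlations; their entries
    are NaN and never become edges.
    """
    cols = list(expr.sample_ids) if samples is None else list(samples)
    if len(cols) < 3:
        raise ValidationError("need >= 3 samples for rank correlation")
    x = expr.values[cols].to_numpy(dtype=float)
    ranks = stats.rankdata(x, axis=1)  # average ranks for ties
    constant = x.std(axis=1) == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(ranks)
    r = np.clip(r, -1.0, 1.0)
    r[constant, :] = np.nan
    r[:, constant] = np.nan
    np.fill_diagonal(r, 1.0)
    r[constant, constant] = np.nan
    ids = expr.probe_set_ids
    return pd.DataFrame(r, index=ids, columns=ids)


def build_network(
    corr: pd.DataFrame,
    threshold: float = 0.9,
    mode: str = "absolute",
    annotations: pd.DataFrame | None = None,
    genotype_origin: str | None = None,
) -> nx.Graph:
    """Threshold a correlation matrix into an undirected co-expression graph.

    ``mode='absolute'`` links pairs with |rho| >= threshold; ``'positive'``
    requires rho >= threshold.  Every probe set in ``corr`` becomes a node.
    ``annotations`` (indexed or keyed by probe_set_id, with any of
    ``name, is_tf, role_category, direction``) and ``genotype_origin`` are
    attached as node attributes; edges carry ``rho`` and ``sign``.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValidationError("threshold must be in (0, 1]")
    if mode not in ("absolute", "positive"):
        raise ValidationError(f"unknown mode {mode!r}")
    r = corr.to_numpy(dtype=float)
    ids = list(corr.index)
    g = nx.Graph()
    g.add_nodes_from(ids)
    with np.errstate(invalid="ignore"):
        strong = np.abs(r) >= threshold if mode == "absolute" else r >= threshold
    strong &= ~np.isnan(r)
    iu, ju = np.triu_indices(len(ids), k=1)
    hit = strong[iu, ju]
    for i, j in zip(iu[hit], ju[hit]):
        rho = float(r[i, j])
        g.add_edge(ids[i], ids[j], rho=rho, sign=1 if rho >= 0 else -1)
    if genotype_origin is not None:
        nx.set_node_attributes(g, genotype_origin, "genotype_origin")
    if annotations is not None:
        ann = annotations
        if "probe_set_id" in ann.columns:
            ann = ann.set_index("probe_set_id")
        for node in g.nodes:
            if node in ann.index:
                for key in ann.columns:
                    g.nodes[node][key] = ann.at[node, key]
    return g


def merge_networks(net_a: nx.Graph, net_b: nx.Graph) -> nx.Graph:
    """Union of two genotype networks with provenance annotations.

    Shared nodes get ``genotype_origin='both'``; a shared node whose
    ``direction`` annotations disagree keeps both with
    ``direction='conflict'`` (recorded, not dropped).  Edges keep the set of
    genotypes that contributed them in ``origins``.
    """
    merged = nx.Graph()
    for net in (net_a, net_b):
        for node, attrs in net.nodes(data=True):
            if node not in merged:
                merged.add_node(node, **attrs)
            else:
                existing = merged.nodes[node]
                for key, val in attrs.items():
                    if key == "genotype_origin":
                        continue
                    if key == "direction" and existing.get(key, val) != val:
                        existing[key] = "conflict"
                    else:
                        existing.setdefault(key, val)
                a = net_a.nodes[node].get("genotype_origin")
                b = net_b.nodes[node].get("genotype_origin")
                existing["genotype_origin"] = (
                    "both" if a != b or a is None else a
                )
        for u, v, attrs in net.edges(data=True):
            origin = net.nodes[u].get("genotype_origin", "?")
            if merged.has_edge(u, v):
                prev = merged.edges[u, v].get("origins", "")
                parts = set(prev.split(",")) - {""}
                parts.add(str(origin))
                merged.edges[u, v]["origins"] = ",".join(sorted(parts))
            else:
                merged.add_edge(u, v, **attrs, origins=str(origin))
    return merged


def degree_table(
    network: nx.Graph,
    drought_subnetwork_nodes=None,
    tf_only: bool = True,
) -> pd.DataFrame:
    """Vertex-degree ranking: whole-network vs dehydration-subnetwork degree.

    ``degree_whole`` counts all incident edges; ``degree_drought`` counts
    edges within the subgraph induced by ``drought_subnetwork_nodes``.
    Rows are sorted by descending whole-network degree (then id), restricted
    to transcription-factor nodes when ``tf_only`` and ``is_tf`` annotations
    exist.
    """
    if drought_subnetwork_nodes is None:
        drought_subnetwork_nodes = set(network.nodes)
    drought_subnetwork_nodes = set(drought_subnetwork_nodes)
    extra = drought_subnetwork_nodes - set(network.nodes)
    if extra:
        raise ValidationError(
            f"subnetwork nodes {sorted(extra)[:3]} absent from the network"
        )
    sub = network.subgraph(drought_subnetwork_nodes)
    rows = []
    for node in network.nodes:
        attrs = network.nodes[node]
        if tf_only and not _as_bool(attrs.get("is_tf", False)):
            continue
        rows.append(
            {
                "probe_set_id": node,
                "name": attrs.get("name", node),
                "degree_whole": network.degree(node),
                "degree_drought": sub.degree(node) if node in sub else 0,
            }
        )
    out = pd.DataFrame(
        rows, columns=["probe_set_id", "name", "degree_whole", "degree_drought"]
    )
    return out.sort_values(
        ["degree_whole", "probe_set_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def export_network(network: nx.Graph, fmt: str, path) -> None:
    """Write the network as SIF (``source co target``) or GraphML."""
    if fmt.lower() == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            written = set()
            for u, v in sorted(map(lambda e: tuple(sorted(e)), network.edges())):
                if (u, v) not in written:
                    fh.write(f"{u}\tco\t{v}\n")
                    written.add((u, v))
            for node in sorted(network.nodes):
                if network.degree(node) == 0:
                    fh.write(f"{node}\n")
    elif fmt.lower() == "graphml":
        nx.write_graphml(_stringify_nones(network), path)
    else:
        raise ValidationError(f"unknown export format {fmt!r}")


def import_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


def _stringify_nones(g: nx.Graph) -> nx.Graph:
    """GraphML cannot carry None attribute values; drop them on a copy."""
    out = g.copy()
    for _, attrs in out.nodes(data=True):
        for key in [k for k, v in attrs.items() if v is None]:
            del attrs[key]
    for _, _, attrs in out.edges(data=True):
        for key in [k for k, v in attrs.items() if v is None]:
            del attrs[key]
    return out


def _as_bool(x) -> bool:
    if isinstance(x, str):
        return x.strip().lower() in ("true", "1", "yes")
    return bool(x)
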