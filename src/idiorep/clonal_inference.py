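"""Clonal grouping by junction relatedness, connectivity graphs, and top-clone tables.

Clones (clonal lineages) are inferred the standard way for bulk BCR data:
records are first partitioned by V gene, J gene and junction length, then
within each partition sequences whose normalized junction Hamming distance is
at or below a threshold are linked — single linkage takes connected components
of the threshold graph, complete linkage cuts a hierarchical clustering.  The
resulting groups drive connectivity-network exports, reproducible subsampling
of clonal groups, and enumeration of the most expanded heavy chains.
"""

from __future__ import annotations

import hashlib
import random
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .airr_io import RearrangementSet, gene_from_call, translate_nt
from .errors import ValidationError


@dataclass
class CloneGroup:
    """One inferred clonal lineage: members share V, J and junction length."""

    clone_id: str
    v_gene: str
    j_gene: str
    junction_length: int
    member_ids: list[str]
    dominant_category: str | None = None

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class TopCloneTable:
    """Ranked table of heavy-chain V-region aa sequences by unique-CDR3 support."""

    df: pd.DataFrame = field(default_factory=pd.DataFrame)


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _clone_id(member_ids: list[str]) -> str:
    digest = hashlib.sha1("|".join(sorted(member_ids)).encode()).hexdigest()
    return f"cl-{digest[:12]}"


def _partition_distances(junctions: list[str]) -> np.ndarray:
    """All-pairs Hamming distance matrix for equal-length junctions."""
    arr = np.frombuffer("".join(junctions).encode(), dtype=np.uint8).reshape(
        len(junctions), -1
    )
    return (arr[:, None, :] != arr[None, :, :]).sum(axis=2)


def group_clones(
    rset: RearrangementSet,
    distance_threshold: float = 0.15,
    linkage: str = "single",
) -> list[CloneGroup]:
    """Partition records into clones by junction relatedness.

    Records sharing V gene, J gene and junction length are clustered on
    normalized junction Hamming distance (<= ``distance_threshold``).  Single
    linkage takes connected components of the threshold graph; complete
    linkage cuts an agglomerative tree at the threshold.  Records with a
    missing junction are excluded (and counted in the set's provenance).
    Clone ids are content-addressed (hash of sorted member ids), so identical
    inputs give identical ids; groups are returned sorted by clone_id.
    """
    if not 0 <= distance_threshold <= 1:
        raise ValidationError("distance_threshold must be in [0, 1]")
    if linkage not in ("single", "complete"):
        raise ValidationError(f"unknown linkage: {linkage}")
    df = rset.df
    has_junction = df["junction"].astype(str).str.len() > 0
    excluded = int((~has_junction).sum())
    if excluded:
        rset.provenance.append(f"group_clones: {excluded} records without junction excluded")
    df = df[has_junction]

    groups: list[CloneGroup] = []
    parts = df.groupby(
        [
            df["v_call"].map(gene_from_call),
            df["j_call"].map(gene_from_call),
            df["junction"].str.len(),
        ],
        sort=True,
    )
    for (v_gene, j_gene, jlen), part in parts:
        ids = part["sequence_id"].astype(str).tolist()
        junctions = part["junction"].astype(str).tolist()
        if len(ids) == 1:
            members = [ids]
        else:
            dist = _partition_distances(junctions) / jlen
            if linkage == "single":
                g = nx.Graph()
                g.add_nodes_from(range(len(ids)))
                ii, jj = np.nonzero(dist <= distance_threshold)
                g.add_edges_from((int(i), int(j)) for i, j in zip(ii, jj) if i < j)
                components = nx.connected_components(g)
                members = [[ids[i] for i in sorted(comp)] for comp in components]
            else:
                condensed = squareform(dist, checks=False)
                labels = fcluster(
                    scipy_linkage(condensed, method="complete"),
                    t=distance_threshold,
                    criterion="distance",
                )
                by_label: dict[int, list[str]] = {}
                for idx, lab in enumerate(labels):
                    by_label.setdefault(int(lab), []).append(ids[idx])
                members = list(by_label.values())
        for member_ids in members:
            member_ids = sorted(member_ids)
            groups.append(
                CloneGroup(
                    clone_id=_clone_id(member_ids),
                    v_gene=str(v_gene),
                    j_gene=str(j_gene),
                    junction_length=int(jlen),
                    member_ids=member_ids,
                )
            )
    groups.sort(key=lambda g: g.clone_id)
    if "idiotope_category" in rset.df.columns:
        cat_by_id = dict(
            zip(rset.df["sequence_id"].astype(str), rset.df["idiotope_category"])
        )
        for group in groups:
            counts = Counter(cat_by_id.get(m, "") for m in group.member_ids)
            # plurality with deterministic (lexicographic) tie-break
            best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
            group.dominant_category = best
    return groups


def assign_clones(rset: RearrangementSet, groups: list[CloneGroup]) -> pd.DataFrame:
    """Return the set's DataFrame with a ``clone_id`` extension column."""
    mapping = {m: g.clone_id for g in groups for m in g.member_ids}
    out = rset.df.copy()
    out["clone_id"] = out["sequence_id"].astype(str).map(mapping)
    return out


def build_connectivity_graph(
    groups: list[CloneGroup],
    rset: RearrangementSet,
    edge_rule: int = 1,
) -> nx.Graph:
    """Build the clonal connectivity network (one node per member sequence).

    Nodes carry clone_id, category, isotype and size (duplicate_count)
    attributes; undirected edges connect members of the same clone whose
    junctions differ by at most ``edge_rule`` nucleotides, with the distance
    stored on the edge.  Singleton clones appear as isolated nodes and edges
    never cross clones.
    """
    df = rset.df.set_index(rset.df["sequence_id"].astype(str))
    g = nx.Graph()
    for group in groups:
        for sid in group.member_ids:
            rec = df.loc[sid]
            g.add_node(
                sid,
                clone_id=group.clone_id,
                category=str(rec.get("idiotope_category", "")),
                isotype=gene_from_call(str(rec.get("c_call", ""))),
                size=int(rec.get("duplicate_count", 1)),
            )
        junctions = {sid: str(df.loc[sid, "junction"]) for sid in group.member_ids}
        members = sorted(group.member_ids)
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                d = _hamming(junctions[a], junctions[b])
                if d <= edge_rule:
                    g.add_edge(a, b, junction_distance=d)
    return g


def sample_groups(groups: list[CloneGroup], n: int, seed: int) -> list[CloneGroup]:
    """Uniform sample of min(n, len(groups)) clone groups without replacement.

    Sampling is over groups (not sequences) and uses Python's integer-based
    Mersenne Twister on the clone_id-sorted list, so a fixed seed gives a
    bit-identical sample on every platform.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    ordered = sorted(groups, key=lambda g: g.clone_id)
    if n >= len(ordered):
        return ordered
    rng = random.Random(seed)
    sampled = rng.sample(ordered, n)
    return sorted(sampled, key=lambda g: g.clone_id)


def _v_region_aa(sequence: str, junction: str) -> str:
    """Heavy-chain V-region aa: translate the part of the read before the junction."""
    sequence = str(sequence)
    junction = str(junction)
    idx = sequence.find(junction) if junction else -1
    if idx <= 0:
        return translate_nt(sequence)
    return translate_nt(sequence[: idx - idx % 3])


def enumerate_top_clones(rset: RearrangementSet, n: int = 10) -> TopCloneTable:
    """Rank heavy-chain V-region aa sequences by the number of unique CDR3s.

    Mirrors a top-expanded-receptor table: each row is one heavy-chain aa
    sequence, ``n_unique_cdr3`` counts the distinct junction_aa values carried
    by it, and per-isotype columns count records by constant-region call.
    Ties are broken lexicographically by the aa sequence.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    df = rset.df
    if df.empty:
        return TopCloneTable(pd.DataFrame())
    keys = [
        _v_region_aa(seq, junc)
        for seq, junc in zip(df["sequence"].astype(str), df["junction"].astype(str))
    ]
    work = pd.DataFrame(
        {
            "heavy_chain_aa": keys,
            "junction_aa": df["junction_aa"].astype(str).to_numpy(),
            "isotype": df["c_call"].map(gene_from_call).to_numpy(),
        }
    )
    rows = []
    for aa, sub in work.groupby("heavy_chain_aa", sort=False):
        row = {
            "heavy_chain_aa": aa,
            "n_unique_cdr3": int(sub["junction_aa"].nunique()),
        }
        for isotype, count in sub["isotype"].value_counts().items():
            if isotype:
                row[f"n_{isotype}"] = int(count)
        rows.append(row)
    table = pd.DataFrame(rows).fillna(0)
    iso_cols = sorted(c for c in table.columns if c.startswith("n_IGH"))
    table[iso_cols] = table[iso_cols].astype(int)
    table = table.sort_values(
        ["n_unique_cdr3", "heavy_chain_aa"], ascending=[False, True]
    ).head(n)
    table.insert(0, "rank", range(1, len(table) + 1))
    return TopCloneTable(table.reset_index(drop=True))


def export_graph(graph: nx.Graph, out_dir: str | Path, stem: str = "connectivity") -> list[Path]:
    """Write the network as GraphML plus a node/edge TSV pair (data-only export)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    graphml = out_dir / f"{stem}.graphml"
    nx.write_graphml(graph, graphml)
    paths.append(graphml)
    nodes = pd.DataFrame(
        [{"sequence_id": n, **attrs} for n, attrs in sorted(graph.nodes(data=True))]
    )
    edges = pd.DataFrame(
        [
            {"source": a, "target": b, **attrs}
            for a, b, attrs in sorted(graph.edges(data=True))
        ],
        columns=["source", "target", "junction_distance"],
    )
    node_path = out_dir / f"{stem}_nodes.tsv"
    edge_path = out_dir / f"{stem}_edges.tsv"
    nodes.to_csv(node_path, sep="\t", index=False)
    edges.to_csv(edge_path, sep="\t", index=False)
    paths += [node_path, edge_path]
    return paths
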