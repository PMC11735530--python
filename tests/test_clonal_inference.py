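"""Clonal grouping, connectivity graphs, subsampling and top-clone tables."""

import random

import numpy as np
import pytest
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from idiorep.airr_io import translate_nt
from idiorep.clonal_inference import (
    build_connectivity_graph,
    enumerate_top_clones,
    group_clones,
    sample_groups,
)
from idiorep.errors import ValidationError

from conftest import make_set


def brute_force_clones(records, threshold):
    """Independent oracle: flat all-pairs distance matrix + sparse connected
    components (scipy csgraph), no partition pre-grouping."""
    n = len(records)
    edges_i, edges_j = [], []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = records[i], records[j]
            if (a["v"], a["j"], len(a["junction"])) != (b["v"], b["j"], len(b["junction"])):
                continue
            d = sum(x != y for x, y in zip(a["junction"], b["junction"])) / len(a["junction"])
            if d <= threshold:
                edges_i.append(i)
                edges_j.append(j)
    graph = coo_matrix(
        (np.ones(len(edges_i)), (edges_i, edges_j)), shape=(n, n)
    )
    _, labels = connected_components(graph, directed=False)
    partition = {}
    for idx, label in enumerate(labels):
        partition.setdefault(label, set()).add(records[idx]["id"])
    return {frozenset(m) for m in partition.values()}


def random_instance(rng, n):
    """Clustered junctions: perturbed copies of a few ancestors."""
    ancestors = [
        "".join(rng.choice("ACGT") for _ in range(rng.choice([9, 12, 15])))
        for _ in range(max(2, n // 8))
    ]
    records = []
    for i in range(n):
        junction = list(rng.choice(ancestors))
        for _ in range(rng.randint(0, 2)):
            pos = rng.randrange(len(junction))
            junction[pos] = rng.choice("ACGT")
        records.append(
            {
                "id": f"seq{i + 1:03d}",
                "v": rng.choice(["IGHV4-34", "IGHV3-23"]),
                "j": rng.choice(["IGHJ4", "IGHJ6"]),
                "junction": "".join(junction),
            }
        )
    return records


def as_set(records):
    return make_set(
        [
            {"v_call": r["v"] + "*01", "j_call": r["j"] + "*01", "junction": r["junction"]}
            for r in records
        ]
    )


class TestGroupClones:
    def test_identical_junctions_one_clone(self):
        rset = make_set([{"junction": "TGTGCTAGATGG"}] * 2)
        groups = group_clones(rset)
        assert len(groups) == 1
        assert groups[0].size == 2

    def test_single_linkage_chains(self):
        # pairwise distance 1/12 <= 0.15 between neighbours chains all three
        rset = make_set(
            [
                {"junction": "TGTGCTAGATGG"},
                {"junction": "TGTGCTAAATGG"},
                {"junction": "TGTGCTACATGG"},
            ]
        )
        groups = group_clones(rset, distance_threshold=0.15, linkage="single")
        assert len(groups) == 1

    def test_different_j_gene_splits(self):
        rset = make_set(
            [
                {"junction": "TGTGCTAGATGG", "j_call": "IGHJ4*01"},
                {"junction": "TGTGCTAGATGG", "j_call": "IGHJ6*01"},
            ]
        )
        assert len(group_clones(rset)) == 2

    def test_missing_junction_excluded_and_tallied(self):
        rset = make_set([{"junction": "TGTGCTAGATGG"}, {"junction": ""}])
        groups = group_clones(rset)
        assert sum(g.size for g in groups) == 1
        assert any("excluded" in note for note in rset.provenance)

    def test_partition_property(self):
        rng = random.Random(5)
        records = random_instance(rng, 60)
        groups = group_clones(as_set(records))
        all_members = [m for g in groups for m in g.member_ids]
        assert sorted(all_members) == sorted(r["id"] for r in records)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = random.Random(seed)
        records = random_instance(rng, 60)
        groups = group_clones(as_set(records), distance_threshold=0.15, linkage="single")
        ours = {frozenset(g.member_ids) for g in groups}
        assert ours == brute_force_clones(records, 0.15)

    def test_threshold_monotonicity(self):
        rng = random.Random(11)
        records = random_instance(rng, 80)
        rset = as_set(records)
        counts = [
            len(group_clones(rset, distance_threshold=t))
            for t in (0.0, 0.1, 0.2, 0.4, 1.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_complete_linkage_is_no_coarser_than_single(self):
        rng = random.Random(3)
        records = random_instance(rng, 60)
        rset = as_set(records)
        single = group_clones(rset, 0.2, "single")
        complete = group_clones(rset, 0.2, "complete")
        assert len(complete) >= len(single)

    def test_deterministic_clone_ids(self):
        rset = make_set([{"junction": "TGTGCTAGATGG"}] * 3)
        ids1 = [g.clone_id for g in group_clones(rset)]
        ids2 = [g.clone_id for g in group_clones(rset)]
        assert ids1 == ids2

    def test_invalid_parameters(self):
        rset = make_set([{}])
        with pytest.raises(ValidationError):
            group_clones(rset, distance_threshold=1.5)
        with pytest.raises(ValidationError):
            group_clones(rset, linkage="ward")


class TestConnectivityGraph:
    def test_singleton_clone_isolated_node(self):
        rset = make_set([{"junction": "TGTGCTAGATGG"}])
        graph = build_connectivity_graph(group_clones(rset), rset)
        assert graph.number_of_nodes() == 1
        assert graph.number_of_edges() == 0

    def test_identical_triplet_forms_triangle(self):
        rset = make_set([{"junction": "TGTGCTAGATGG"}] * 3)
        graph = build_connectivity_graph(group_clones(rset), rset)
        assert graph.number_of_edges() == 3

    def test_no_inter_clone_edges(self):
        rng = random.Random(2)
        records = random_instance(rng, 50)
        rset = as_set(records)
        groups = group_clones(rset)
        clone_of = {m: g.clone_id for g in groups for m in g.member_ids}
        graph = build_connectivity_graph(groups, rset, edge_rule=3)
        assert all(clone_of[a] == clone_of[b] for a, b in graph.edges)

    def test_node_attributes_present(self):
        rset = make_set([{"junction": "TGTGCTAGATGG", "c_call": "IGHG1"}])
        graph = build_connectivity_graph(group_clones(rset), rset)
        attrs = graph.nodes["seq001"]
        assert attrs["isotype"] == "IGHG1"
        assert attrs["size"] == 1


class TestSampleGroups:
    def _groups(self, n):
        # length-distinct junctions: every record is its own clone group
        rows = [{"junction": "TGT" + "A" * (i + 1) + "TGG"} for i in range(n)]
        return group_clones(make_set(rows))

    def test_fixed_seed_reproducible_and_exact_size(self):
        groups = self._groups(500)
        a = sample_groups(groups, 200, seed=7)
        b = sample_groups(groups, 200, seed=7)
        assert len(a) == 200
        assert [g.clone_id for g in a] == [g.clone_id for g in b]

    def test_n_larger_than_available_returns_all(self):
        groups = self._groups(20)
        assert len(sample_groups(groups, 200, seed=1)) == 20

    def test_different_seeds_differ(self):
        groups = self._groups(500)
        a = sample_groups(groups, 200, seed=1)
        b = sample_groups(groups, 200, seed=2)
        assert [g.clone_id for g in a] != [g.clone_id for g in b]

    def test_n_below_one_rejected(self):
        with pytest.raises(ValidationError):
            sample_groups([], 0, seed=1)


class TestTopClones:
    def test_ranked_by_unique_cdr3_support(self, v434):
        rows = []
        # heavy chain A carries 5 aa-distinct CDR3s, heavy chain B carries 2
        for codon in ("GCT", "TGC", "GAT", "GAA", "TTT"):  # A C D E F
            junction = "TGT" + codon + "AGATGG"
            rows.append({"sequence": v434.sequence_nt + junction + "ACT",
                         "junction": junction})
        other = v434.sequence_nt[:-3] + ("AAA" if v434.sequence_nt[-3:] != "AAA" else "CCC")
        for junction in ("TGTAAATGG", "TGTCCCTGG"):  # CKW, CPW
            rows.append({"sequence": other + junction + "ACT", "junction": junction})
        table = enumerate_top_clones(make_set(rows), n=10).df
        assert list(table["n_unique_cdr3"]) == [5, 2]
        assert list(table["rank"]) == [1, 2]

    def test_all_identical_records_single_row(self, v434):
        junction = "TGTGCTAGATGG"
        rows = [{"sequence": v434.sequence_nt + junction + "ACT", "junction": junction}] * 3
        table = enumerate_top_clones(make_set(rows), n=10).df
        assert len(table) == 1
        assert table["n_unique_cdr3"].iloc[0] == 1

    def test_isotype_totals_match_record_counts(self, v434):
        junction = "TGTGCTAGATGG"
        seq = v434.sequence_nt + junction + "ACT"
        rows = [
            {"sequence": seq, "junction": junction, "c_call": c}
            for c in ["IGHM"] * 3 + ["IGHD"] * 2 + ["IGHA"]
        ]
        table = enumerate_top_clones(make_set(rows), n=10).df
        assert table["n_IGHM"].iloc[0] == 3
        assert table["n_IGHD"].iloc[0] == 2
        assert table["n_IGHA"].iloc[0] == 1

    def test_counts_sum_to_unique_pairs(self, v434):
        rng = random.Random(9)
        rows = []
        for _ in range(40):
            junction = "TGT" + "".join(rng.choice("ACGT") for _ in range(6)) + "TGG"
            stem = v434.sequence_nt[:-3] + rng.choice(["AAA", "CCC", "GGG"])
            rows.append({"sequence": stem + junction + "ACT", "junction": junction})
        rset = make_set(rows)
        table = enumerate_top_clones(rset, n=1000).df
        # oracle at the aa level: unique (heavy-chain aa, CDR3 aa) pairs
        unique_pairs = len(
            {
                (translate_nt(r["sequence"][: -len("ACT") - 12]), translate_nt(r["junction"]))
                for r in rows
            }
        )
        assert int(table["n_unique_cdr3"].sum()) == unique_pairs

    def test_invalid_n_rejected(self):
        with pytest.raises(ValidationError):
            enumerate_top_clones(make_set([{}]), n=0)
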