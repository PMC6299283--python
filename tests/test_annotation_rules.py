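import networkx as nx
import numpy as np
import pandas as pd
import pytest

from phyloprof.annotation_rules import (
    NO_HIT,
    HitRecord,
    TaxonAssignment,
    assign_taxon_bestsum,
    build_presence_matrix,
    decide_kegg_transfer,
    dedup_identical,
    filter_clusters_by_organisms,
    hits_from_frame,
    mcl_cluster,
    run_decontamination,
    screen_cellular_origin,
    screen_host_first_hit,
    screen_host_identity,
    transfer_kegg_ids,
)


def hit(query="q1", rank=1, bitscore=100.0, species="SpX", superkingdom="Eukaryota",
        evalue=1e-30, flags=(), pident=50.0):
    return HitRecord(
        query=query,
        subject=f"{species}|p{rank}",
        rank=rank,
        bitscore=bitscore,
        evalue=evalue,
        percent_identity=pident,
        superkingdom=superkingdom,
        lineage_flags=frozenset(flags),
        species=species,
    )


class TestBestsum:
    def test_single_hit(self):
        a = assign_taxon_bestsum([hit(species="SpX")])
        assert a.species == "SpX"
        assert a.superkingdom == "Eukaryota"

    def test_summed_scores_beat_single_best(self):
        hits = [
            hit(rank=1, bitscore=100.0, species="B"),
            hit(rank=2, bitscore=60.0, species="A"),
            hit(rank=3, bitscore=50.0, species="A"),
        ]
        a = assign_taxon_bestsum(hits)
        assert a.species == "A"
        assert a.score == pytest.approx(110.0)

    def test_top_n_enforced(self):
        hits = [hit(rank=r, bitscore=100.0 - r, species="A") for r in range(1, 11)]
        hits.append(hit(rank=11, bitscore=89.0, species="C"))
        a = assign_taxon_bestsum(hits)
        assert a.species == "A"
        # rank 11, regardless of score, is ignored
        hits[-1] = hit(rank=11, bitscore=89.0, species="C")
        assert assign_taxon_bestsum(hits).species == "A"

    def test_no_hits(self):
        assert assign_taxon_bestsum([]).species == NO_HIT

    def test_tie_broken_by_best_single_hit(self):
        hits = [
            hit(rank=1, bitscore=100.0, species="B"),
            hit(rank=2, bitscore=60.0, species="A"),
            hit(rank=3, bitscore=40.0, species="A"),
        ]
        # sums equal (100 vs 100): B owns the single best hit
        assert assign_taxon_bestsum(hits).species == "B"

    def test_order_independence(self):
        hits = [
            hit(rank=1, bitscore=90.0, species="B"),
            hit(rank=2, bitscore=50.0, species="A"),
            hit(rank=3, bitscore=45.0, species="A"),
        ]
        assert (
            assign_taxon_bestsum(hits).species
            == assign_taxon_bestsum(list(reversed(hits))).species
        )


class TestScreens:
    def test_cellular_origin(self):
        assignments = [
            TaxonAssignment("q1", NO_HIT, None, 0.0),
            TaxonAssignment("q2", "Ecoli", "Bacteria", 10.0),
            TaxonAssignment("q3", "Yeast", "Eukaryota", 10.0),
            TaxonAssignment("q4", "Halo", "Archaea", 10.0),
            TaxonAssignment("q5", "Phage", "Viruses", 10.0),
        ]
        keep = screen_cellular_origin(assignments)
        assert keep == {"q1": False, "q2": False, "q3": True, "q4": False, "q5": False}

    def test_cellular_unknown_kingdom(self):
        with pytest.raises(ValueError, match="unknown superkingdom"):
            screen_cellular_origin([TaxonAssignment("q", "X", "Plantae", 1.0)])

    def test_host_first_hit_discard(self):
        hits = [hit(rank=1, flags=("stramenopile",), evalue=1e-20)]
        assert screen_host_first_hit(hits) is False

    def test_host_second_hit_kept(self):
        hits = [
            hit(rank=1, species="Fungus", evalue=1e-20),
            hit(rank=2, flags=("stramenopile",), evalue=1e-30, bitscore=90.0),
        ]
        assert screen_host_first_hit(hits) is True

    def test_cutoff_semantics(self):
        hits = [hit(rank=1, flags=("stramenopile",), evalue=1e-5)]
        assert screen_host_first_hit(hits) is True  # fails the 1e-10 cutoff

    @pytest.mark.parametrize(
        "identity,keep",
        [(100.0, False), (96.2, False), (95.0, True), (None, True), (95.0001, False)],
    )
    def test_host_identity(self, identity, keep):
        assert screen_host_identity(identity) is keep

    def test_host_identity_out_of_range(self):
        with pytest.raises(ValueError):
            screen_host_identity(101.0)


class TestDedup:
    def test_exact_duplicates(self):
        retained, cmap = dedup_identical({"a": "MKV", "b": "MKV"})
        assert retained == {"a": "MKV"}
        assert cmap == {"b": "a"}

    def test_substring_collapsed(self):
        retained, cmap = dedup_identical({"short": "MKV", "long": "MKVLL"})
        assert retained == {"long": "MKVLL"}
        assert cmap == {"short": "long"}

    def test_distinct_kept(self):
        retained, cmap = dedup_identical({"a": "MKV", "b": "QQL", "c": "AAA"})
        assert len(retained) == 3 and cmap == {}

    def test_exact_only_mode(self):
        retained, cmap = dedup_identical({"short": "MKV", "long": "MKVLL"}, exact_only=True)
        assert set(retained) == {"short", "long"}

    def test_tie_smallest_id(self):
        retained, _ = dedup_identical({"zeta": "MKV", "alpha": "MKV"})
        assert set(retained) == {"alpha"}

    def test_empty_error(self):
        with pytest.raises(ValueError):
            dedup_identical({})


class TestMCL:
    def _clique(self, g, names, w=1.0):
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                g.add_edge(a, b, weight=w)

    def test_disjoint_triangles(self):
        g = nx.Graph()
        self._clique(g, ["a1", "a2", "a3"])
        self._clique(g, ["b1", "b2", "b3"])
        clusters = mcl_cluster(g)
        assert sorted(sorted(c) for c in clusters) == [
            ["a1", "a2", "a3"],
            ["b1", "b2", "b3"],
        ]

    def test_single_edge(self):
        g = nx.Graph()
        g.add_edge("x", "y", weight=2.0)
        assert mcl_cluster(g) == [frozenset({"x", "y"})]

    def test_weak_bridge_barbell(self):
        g = nx.Graph()
        self._clique(g, [f"a{i}" for i in range(4)])
        self._clique(g, [f"b{i}" for i in range(4)])
        g.add_edge("a0", "b0", weight=0.05)
        clusters = mcl_cluster(g)
        assert sorted(sorted(c) for c in clusters) == [
            [f"a{i}" for i in range(4)],
            [f"b{i}" for i in range(4)],
        ]

    def test_partition_property_random_graphs(self):
        rng = np.random.default_rng(13)
        for trial in range(20):
            g = nx.gnp_random_graph(10, 0.3, seed=int(rng.integers(1e6)))
            for u, v in g.edges:
                g[u][v]["weight"] = float(rng.uniform(0.1, 2.0))
            if g.number_of_nodes() == 0:
                continue
            clusters = mcl_cluster(g)
            nodes = [n for c in clusters for n in c]
            assert sorted(nodes) == sorted(g.nodes)  # exact partition
            # clusters never span disconnected components
            comp_of = {}
            for ci, comp in enumerate(nx.connected_components(g)):
                for n in comp:
                    comp_of[n] = ci
            for c in clusters:
                assert len({comp_of[n] for n in c}) == 1

    def test_relabeling_invariance(self):
        g = nx.Graph()
        self._clique(g, ["a", "b", "c"])
        self._clique(g, ["d", "e", "f"])
        g.add_edge("c", "d", weight=0.01)
        mapping = {"a": "z9", "b": "z8", "c": "z7", "d": "z6", "e": "z5", "f": "z4"}
        h = nx.relabel_nodes(g, mapping)
        c1 = {frozenset(mapping[n] for n in c) for c in mcl_cluster(g)}
        c2 = set(mcl_cluster(h))
        assert c1 == c2

    def test_non_positive_weight_error(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.0)
        with pytest.raises(ValueError, match="non-positive"):
            mcl_cluster(g)


class TestClusterFilter:
    def test_three_organisms_retained(self):
        clusters = [frozenset({"p1", "p2", "p3"})]
        orgs = {"p1": "a", "p2": "b", "p3": "c"}
        assert filter_clusters_by_organisms(clusters, orgs) == clusters

    def test_two_organisms_dropped(self):
        clusters = [frozenset({"p1", "p2", "p3", "p4", "p5"})]
        orgs = {f"p{i}": ("a" if i < 4 else "b") for i in range(1, 6)}
        assert filter_clusters_by_organisms(clusters, orgs) == []

    def test_min_one_retains_all(self):
        clusters = [frozenset({"p1"}), frozenset({"p2"})]
        orgs = {"p1": "a", "p2": "a"}
        assert filter_clusters_by_organisms(clusters, orgs, min_organisms=1) == clusters

    def test_unmapped_node_error(self):
        with pytest.raises(ValueError, match="organism"):
            filter_clusters_by_organisms([frozenset({"p1"})], {})

    def test_monotone_in_min_organisms(self):
        rng = np.random.default_rng(3)
        clusters = [
            frozenset(f"p{i}_{j}" for j in range(rng.integers(1, 8))) for i in range(10)
        ]
        orgs = {n: f"org{rng.integers(4)}" for c in clusters for n in c}
        counts = [
            len(filter_clusters_by_organisms(clusters, orgs, min_organisms=k))
            for k in range(1, 6)
        ]
        assert counts == sorted(counts, reverse=True)


class TestKeggTransfer:
    def test_boundary_inclusive(self):
        assert decide_kegg_transfer(100.0, 80.0).transfer is True

    def test_below_threshold(self):
        assert decide_kegg_transfer(100.0, 79.9).transfer is False

    def test_existing_id_precedence(self):
        assert decide_kegg_transfer(100.0, 200.0, existing_kegg_id="K00001").transfer is False

    def test_missing_uniprot_error(self):
        with pytest.raises(ValueError, match="UniProt"):
            decide_kegg_transfer(None, 50.0)

    def test_table_form(self):
        table = pd.DataFrame(
            {
                "family": ["f1", "f2", "f3"],
                "uniprot_best_bit": [100.0, 100.0, 100.0],
                "kegg_best_bit": [80.0, 79.0, np.nan],
                "existing_kegg_id": [None, None, None],
            }
        )
        out = transfer_kegg_ids(table)
        assert out["transfer"].tolist() == [True, False, False]


class TestPresenceMatrix:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["genome", "protein", "hmm", "full_evalue", "domain_evalue"]
        )

    def test_both_thresholds_pass(self):
        t = self._table([("g1", "p1", "h1", 1e-6, 1e-5)])
        m = build_presence_matrix(t, {"h1": "K1"})
        assert m.at["g1", "K1"] == 1

    def test_full_evalue_fails(self):
        t = self._table([("g1", "p1", "h1", 1e-4, 1e-9)])
        m = build_presence_matrix(t, {"h1": "K1"})
        assert m.at["g1", "K1"] == 0

    def test_idempotent_presence(self):
        t = self._table(
            [("g1", "p1", "h1", 1e-9, 1e-9), ("g1", "p2", "h2", 1e-9, 1e-9)]
        )
        m = build_presence_matrix(t, {"h1": "K1", "h2": "K1"})
        assert m.at["g1", "K1"] == 1

    def test_negative_evalue_error(self):
        t = self._table([("g1", "p1", "h1", -1e-9, 1e-9)])
        with pytest.raises(ValueError):
            build_presence_matrix(t, {"h1": "K1"})

    def test_tightening_thresholds_monotone(self):
        rng = np.random.default_rng(8)
        rows = [
            (
                f"g{rng.integers(3)}",
                f"p{i}",
                f"h{rng.integers(5)}",
                10.0 ** -rng.uniform(2, 9),
                10.0 ** -rng.uniform(2, 9),
            )
            for i in range(60)
        ]
        t = self._table(rows)
        kegg = {f"h{i}": f"K{i}" for i in range(5)}
        loose = build_presence_matrix(t, kegg, 1e-3, 1e-3)
        tight = build_presence_matrix(t, kegg, 1e-6, 1e-6)
        assert ((tight <= loose).all()).all()


class TestRowOrderInvariance:
    def test_pipeline_determinism(self):
        from phyloprof.synthetic_data import HitComposition, simulate_hit_table

        hits, truth = simulate_hit_table(HitComposition(4, 3, 3, 2, 2), 21)
        shuffled = hits.sample(frac=1.0, random_state=0)
        hid = {
            r.query: r.host_identity
            for r in truth.itertuples(index=False)
            if pd.notna(r.host_identity)
        }
        queries = truth["query"].tolist()
        rep1 = run_decontamination(hits_from_frame(hits), queries, hid)
        rep2 = run_decontamination(hits_from_frame(shuffled), queries, hid)
        assert rep1.kept == rep2.kept
        assert rep1.removed_cellular == rep2.removed_cellular
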