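"""Edge screening, prediction filtering, and connectivity summaries."""

import numpy as np
import pandas as pd
import pytest

from emphymir.network import (
    build_network,
    collapse_duplicate_genes,
    connectivity,
    edge_screen,
    edge_screen_all,
    summarize_edges,
    to_graphml,
    to_sif,
)


@pytest.fixture(scope="module")
def planted(metadata64):
    """One miRNA, genes coupled as coherent / incoherent / independent."""
    rng = np.random.default_rng(8)
    meta = metadata64
    codes = pd.factorize(meta["patient_id"])[0]
    n = len(meta)
    mirna = pd.Series(rng.normal(7, 0.6, n), index=meta.index, name="miR-A")
    mc = mirna - mirna.mean()
    driver = rng.normal(0, 0.5, n)
    genes = {}
    genes["coherent"] = 8 - 0.8 * mc + rng.normal(0, 0.3, n)
    genes["incoherent"] = 8 + 3.0 * driver + rng.normal(0, 0.3, n)
    genes["independent"] = 8 + rng.normal(0, 0.3, n)
    gene = pd.DataFrame(genes).T
    gene.columns = meta.index
    mirna_drv = mirna + driver
    mirna_drv.name = "miR-A"
    return meta, mirna_drv, gene


class TestEdgeScreen:
    def test_coherent_gene_negative(self, planted):
        meta, mirna, gene = planted
        res = edge_screen(gene, mirna, meta).set_index("gene_id")
        assert res.loc["coherent", "beta"] < 0
        assert res.loc["coherent", "p"] < 1e-4

    def test_incoherent_gene_positive(self, planted):
        meta, mirna, gene = planted
        res = edge_screen(gene, mirna, meta).set_index("gene_id")
        assert res.loc["incoherent", "beta"] > 0
        assert res.loc["incoherent", "p"] < 1e-4

    def test_independent_gene_null(self, metadata64):
        # p approximately uniform over repeated independent simulations
        rng = np.random.default_rng(9)
        meta = metadata64
        n = len(meta)
        gene = pd.DataFrame(rng.normal(8, 0.4, size=(300, n)), columns=meta.index)
        mirna = pd.Series(rng.normal(7, 0.6, n), index=meta.index, name="m")
        res = edge_screen(gene, mirna, meta)
        assert 0.02 <= (res["p"] < 0.05).mean() <= 0.09
        assert abs(res["p"].mean() - 0.5) < 0.06


class TestBuildNetwork:
    stats = pd.DataFrame(
        {
            "mirna_id": ["m1", "m1", "m2"],
            "gene_id": ["g1", "g2", "g1"],
            "beta": [0.5, -0.5, 1.0],
            "t": [2.0, -2.0, 3.0],
            "p": [0.01, 0.01, 0.001],
            "q": [0.2, 0.2, 0.3],
        }
    )
    pred = pd.DataFrame(
        {"mirna_id": ["m1", "m2"], "gene_id": ["g1", "g1"], "n_sources": [1, 5]}
    )

    def test_q_and_prediction_both_required(self):
        edges = build_network(self.stats, self.pred)
        pairs = set(zip(edges["mirna_id"], edges["gene_id"]))
        assert ("m1", "g1") in pairs      # q=0.2, predicted
        assert ("m1", "g2") not in pairs  # q=0.2, unpredicted
        assert ("m2", "g1") not in pairs  # q=0.3 above cutoff
        assert edges.set_index("gene_id").loc["g1", "sign"] == "+"

    def test_empty_predictions_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            edges = build_network(self.stats, pd.DataFrame())
        assert edges.empty

    def test_matches_brute_force_intersection(self, small_cohort):
        from emphymir.synthetic import generate_prediction_table

        rng = np.random.default_rng(1)
        pred = generate_prediction_table(
            small_cohort.truth, list(small_cohort.mirna.index),
            list(small_cohort.gene.index), source_fpr=0.005, rng=rng,
        )
        rng2 = np.random.default_rng(2)
        stats = pd.DataFrame(
            {
                "mirna_id": rng2.choice(small_cohort.mirna.index, 500),
                "gene_id": rng2.choice(small_cohort.gene.index, 500),
                "beta": rng2.normal(size=500),
                "t": rng2.normal(size=500),
                "p": rng2.uniform(size=500),
                "q": rng2.uniform(size=500),
            }
        ).drop_duplicates(["mirna_id", "gene_id"])
        edges = build_network(stats, pred)
        predicted = set(zip(pred["mirna_id"], pred["gene_id"]))
        expected = {
            (m, g)
            for m, g, q in zip(stats["mirna_id"], stats["gene_id"], stats["q"])
            if q < 0.25 and (m, g) in predicted
        }
        assert set(zip(edges["mirna_id"], edges["gene_id"])) == expected

    def test_removing_a_source_never_adds_edges(self):
        pred_less = self.pred.copy()
        pred_less["n_sources"] -= 1
        pred_less = pred_less[pred_less["n_sources"] >= 1]
        full = build_network(self.stats, self.pred)
        less = build_network(self.stats, pred_less)
        assert set(zip(less["mirna_id"], less["gene_id"])) <= set(
            zip(full["mirna_id"], full["gene_id"])
        )


class TestConnectivity:
    def make_edges(self, n_pos, n_neg, mirna="m1"):
        rows = [
            {"mirna_id": mirna, "gene_id": f"g{i}", "sign": "+" if i < n_pos else "-",
             "q": 0.1, "n_sources": 2, "beta": 1.0, "t": 1.0, "p": 0.01}
            for i in range(n_pos + n_neg)
        ]
        return pd.DataFrame(rows)

    def test_counts_partition(self):
        conn = connectivity(self.make_edges(30, 25))
        row = conn.loc["m1"]
        assert row["n_targets"] == 55 == row["n_pos"] + row["n_neg"]
        assert bool(row["hub"]) is True

    def test_zero_target_mirna_absent(self):
        conn = connectivity(self.make_edges(3, 2))
        assert "m2" not in conn.index
        assert bool(conn.loc["m1", "hub"]) is False

    def test_positive_fraction_report(self):
        edges = self.make_edges(708, 371)
        summary = summarize_edges(edges)
        assert summary["n_edges"] == 1079
        assert summary["pct_positive"] == 66


@pytest.fixture(scope="module")
def screened(small_cohort):
    truth = set(small_cohort.truth.lm_mirnas)
    mirnas = small_cohort.mirna.loc[small_cohort.mirna.index.isin(truth)]
    return edge_screen_all(small_cohort.gene, mirnas, small_cohort.metadata)


class TestRecoveryAndFdr:

    def test_false_edge_fraction_controlled(self, small_cohort, screened):
        from emphymir.synthetic import generate_prediction_table

        pred = generate_prediction_table(
            small_cohort.truth, list(small_cohort.mirna.index),
            list(small_cohort.gene.index), source_fpr=0.02,
            rng=np.random.default_rng(5),
        )
        edges = build_network(screened, pred)
        true_pairs = {(m, g) for m, g, _ in small_cohort.truth.circuits}
        false_frac = np.mean([
            (m, g) not in true_pairs
            for m, g in zip(edges["mirna_id"], edges["gene_id"])
        ])
        assert len(edges) > 20
        assert false_frac <= 0.30

    def test_hub_recovered_with_most_targets(self, small_cohort, screened):
        from emphymir.synthetic import generate_prediction_table

        pred = generate_prediction_table(
            small_cohort.truth, list(small_cohort.mirna.index),
            list(small_cohort.gene.index), rng=np.random.default_rng(6),
        )
        edges = build_network(screened, pred)
        conn = connectivity(edges, hub_threshold=20)
        hub = small_cohort.truth.hub_mirna
        assert conn.index[0] == hub
        assert conn.loc[hub, "n_targets"] >= 0.8 * 30

    def test_fdr_families_partition_correctly(self, small_cohort, screened):
        from emphymir.lmm import bh_fdr

        per = edge_screen_all(
            small_cohort.gene,
            small_cohort.mirna.loc[screened["mirna_id"].unique()],
            small_cohort.metadata,
            fdr_family="per_mirna",
        )
        # joint q = BH over all pairs at once; per-miRNA q = BH within
        # each miRNA's gene family
        np.testing.assert_allclose(
            screened["q"], bh_fdr(screened["p"].to_numpy()), atol=1e-12
        )
        for _, sub in per.groupby("mirna_id"):
            np.testing.assert_allclose(
                sub["q"], bh_fdr(sub["p"].to_numpy()), atol=1e-12
            )


class TestHelpers:
    def test_duplicate_genes_collapsed_by_variance(self):
        m = pd.DataFrame(
            [[1.0, 2.0, 3.0], [0.0, 10.0, 20.0], [5.0, 5.0, 5.0]],
            index=["gA", "gA", "gB"],
        )
        out = collapse_duplicate_genes(m)
        assert list(out.index) == ["gA", "gB"]
        np.testing.assert_allclose(out.loc["gA"], [0.0, 10.0, 20.0])

    def test_exports_roundtrip(self, tmp_path):
        import networkx as nx

        edges = pd.DataFrame(
            {"mirna_id": ["m1"], "gene_id": ["g1"], "sign": ["-"],
             "n_sources": [3], "q": [0.1], "beta": [-1.0], "t": [-2.0],
             "p": [0.01]}
        )
        to_graphml(edges, tmp_path / "net.graphml")
        g = nx.read_graphml(tmp_path / "net.graphml")
        assert g.edges[("m1", "g1")]["sign"] == "-"
        assert g.edges[("m1", "g1")]["n_sources"] == 3
        to_sif(edges, tmp_path / "net.sif")
        assert (tmp_path / "net.sif").read_text() == "m1\tneg\tg1\n"
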