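import io

import numpy as np
import pandas as pd
import pytest

from axonmod import (
    cluster_semsim,
    filter_evidence,
    gene_sim_bma,
    generate_annotations,
    generate_toy_ontology,
    read_gaf,
    semsim_matrix,
    svalues,
    term_sim_wang,
)
from axonmod.semsim import AnnotationSet, GODag

NS = "biological_process"


class TestSvalues:
    def test_root_term_alone(self, chain_dag):
        s = svalues("R", chain_dag)
        assert s == {"R": 1.0}

    def test_chain_propagation(self, chain_dag):
        s = svalues("G", chain_dag)
        assert s == pytest.approx({"G": 1.0, "C": 0.8, "R": 0.64})
        assert sum(s.values()) == pytest.approx(2.44)

    def test_diamond_join_uses_max_not_sum(self):
        # two paths to the root: is_a(0.8)*part_of(0.6) vs part_of(0.6)*is_a(0.8)
        dag = GODag(
            {t: NS for t in "TABR"},
            [
                ("T", "A", "is_a"),
                ("T", "B", "part_of"),
                ("A", "R", "part_of"),
                ("B", "R", "is_a"),
            ],
        )
        s = svalues("T", dag)
        assert s["R"] == pytest.approx(0.48)  # max of the two path products

    def test_missing_term_errors(self, chain_dag):
        with pytest.raises(KeyError):
            svalues("NOPE", chain_dag)

    def test_cyclic_ontology_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            GODag(
                {"A": NS, "B": NS},
                [("A", "B", "is_a"), ("B", "A", "is_a")],
            )


class TestTermSim:
    def test_self_similarity_is_one(self, chain_dag):
        assert term_sim_wang("G", "G", chain_dag) == 1.0

    def test_chain_worked_example(self, chain_dag):
        expected = (0.8 + 1 + 0.64 + 0.8) / (2.44 + 1.8)
        assert term_sim_wang("G", "C", chain_dag) == pytest.approx(expected)
        assert expected == pytest.approx(0.764, abs=5e-4)

    def test_symmetry(self, chain_dag):
        assert term_sim_wang("G", "C", chain_dag) == term_sim_wang(
            "C", "G", chain_dag
        )

    def test_sharing_only_the_root_stays_positive(self):
        dag = generate_toy_ontology(depth=3, branching=2)
        left, right = "GO:7000007", "GO:7000014"  # deepest leaves, far apart
        sim = term_sim_wang(left, right, dag)
        assert 0 < sim < 0.5

    def test_monotone_specificity_down_a_chain(self, chain_dag):
        assert term_sim_wang("G", "C", chain_dag) > term_sim_wang(
            "G", "R", chain_dag
        )

    def test_namespace_mismatch_errors(self):
        dag = GODag(
            {"a": "biological_process", "b": "molecular_function"}, []
        )
        with pytest.raises(ValueError, match="namespace"):
            term_sim_wang("a", "b", dag)

    @pytest.mark.parametrize("seed", range(5))
    def test_fuzz_similarities_within_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        dag = generate_toy_ontology(
            depth=int(rng.integers(2, 5)),
            branching=int(rng.integers(2, 4)),
            part_of_every=3,
        )
        terms = sorted(dag.namespace)
        for _ in range(25):
            a, b = (terms[i] for i in rng.integers(0, len(terms), 2))
            sim = term_sim_wang(a, b, dag)
            assert 0 <= sim <= 1


class TestGeneSim:
    def _annots(self, mapping):
        return AnnotationSet(
            {g: {(t, "EXP") for t in ts} for g, ts in mapping.items()}
        )

    def test_identical_term_sets_give_one(self, chain_dag):
        ann = self._annots({"g1": {"G", "C"}, "g2": {"G", "C"}})
        assert gene_sim_bma("g1", "g2", ann, chain_dag) == pytest.approx(1.0)

    def test_single_pair_matrix_is_that_similarity(self, chain_dag):
        ann = self._annots({"g1": {"G"}, "g2": {"C"}})
        assert gene_sim_bma("g1", "g2", ann, chain_dag) == pytest.approx(
            term_sim_wang("G", "C", chain_dag)
        )

    def test_bma_two_by_one_formula(self, chain_dag, monkeypatch):
        # force a 2x1 similarity matrix with values 0.8 and 0.4
        import axonmod.semsim as ss

        ann = self._annots({"g1": {"G", "C"}, "g2": {"R"}})
        fake = {("G", "R"): 0.8, ("C", "R"): 0.4}

        def fake_sim(a, b, dag, weights=None):
            return fake[(a, b)]

        monkeypatch.setattr(ss, "term_sim_wang", fake_sim)
        got = ss.gene_sim_bma("g1", "g2", ann, chain_dag)
        assert got == pytest.approx((0.8 + 0.4 + 0.8) / 3)

    def test_unannotated_gene_named_in_error(self, chain_dag):
        ann = self._annots({"g1": {"G"}, "g2": set()})
        with pytest.raises(ValueError, match="g2"):
            gene_sim_bma("g1", "g2", ann, chain_dag)


class TestEvidenceFilter:
    def test_all_electronic_gene_is_flagged(self):
        ann = AnnotationSet({"g1": {("G", "IEA")}, "g2": {("G", "EXP")}})
        out = filter_evidence(ann)
        assert "g1" not in out.annotations
        assert out.flagged_genes == ("g1",)

    def test_mixed_codes_keep_experimental(self):
        ann = AnnotationSet({"g": {("G", "EXP"), ("C", "IEA"), ("R", "IPI")}})
        out = filter_evidence(ann)
        assert out.annotations["g"] == {("G", "EXP")}

    def test_empty_exclusion_is_identity(self):
        ann = AnnotationSet({"g": {("G", "IEA")}})
        out = filter_evidence(ann, excluded=set())
        assert out.annotations == ann.annotations


class TestClustering:
    def _block_matrix(self):
        genes = ["a1", "a2", "a3", "b1", "b2", "b3"]
        m = np.full((6, 6), 0.1)
        m[:3, :3] = 0.9
        m[3:, 3:] = 0.9
        np.fill_diagonal(m, 1.0)
        return pd.DataFrame(m, index=genes, columns=genes)

    def test_two_planted_blocks_recovered(self):
        z, labels = cluster_semsim(self._block_matrix(), height=0.5)
        assert labels.nunique() == 2
        assert labels["a1"] == labels["a2"] == labels["a3"]
        assert labels["b1"] == labels["b2"] == labels["b3"]

    def test_perfect_similarity_single_cluster(self):
        m = pd.DataFrame(np.ones((4, 4)), index=list("wxyz"), columns=list("wxyz"))
        _, labels = cluster_semsim(m, height=0.01)
        assert labels.nunique() == 1

    def test_zero_offdiagonal_keeps_genes_apart(self):
        m = pd.DataFrame(np.eye(4), index=list("wxyz"), columns=list("wxyz"))
        _, labels = cluster_semsim(m, height=0.5)
        assert labels.nunique() == 4

    def test_requested_cluster_count(self):
        _, labels = cluster_semsim(self._block_matrix(), n_clusters=2)
        assert labels.nunique() == 2

    def test_non_square_rejected(self):
        m = pd.DataFrame(np.ones((2, 3)))
        with pytest.raises(ValueError):
            cluster_semsim(m)


class TestFileFormats:
    def test_obo_round_trip_preserves_svalues(self, tmp_path):
        from axonmod.cli import _write_obo

        dag = generate_toy_ontology(depth=3, branching=2, part_of_every=4)
        path = tmp_path / "toy.obo"
        _write_obo(dag, path)
        loaded = GODag.from_obo(str(path))
        assert set(loaded.namespace) == set(dag.namespace)
        leaf = sorted(dag.namespace)[-1]
        assert svalues(leaf, loaded) == pytest.approx(svalues(leaf, dag))

    def test_gaf_reader_extracts_expected_columns(self):
        gaf = io.StringIO(
            "!gaf-version: 2.1\n"
            "SYN\tMFN2\tMFN2\t\tGO:0000001\tSYN:1\tEXP\t\tP\t\t\tprotein\t"
            "taxon:9606\t20190101\tSYN\t\t\n"
            "SYN\tMFN2\tMFN2\t\tGO:0000002\tSYN:1\tIEA\t\tP\t\t\tprotein\t"
            "taxon:9606\t20190101\tSYN\t\t\n"
        )
        ann = read_gaf(gaf)
        assert ann.annotations["MFN2"] == {
            ("GO:0000001", "EXP"),
            ("GO:0000002", "IEA"),
        }

    def test_matrix_drops_unannotated_genes_with_warning(self, chain_dag):
        ann = AnnotationSet({"g1": {("G", "EXP")}, "g2": {("C", "EXP")}})
        with pytest.warns(UserWarning, match="g3"):
            m = semsim_matrix(["g1", "g3"], ["g2"], ann, chain_dag)
        assert m.shape == (1, 1)

    def test_generated_annotations_feed_bma(self):
        dag = generate_toy_ontology(depth=3, branching=2)
        ann = filter_evidence(
            generate_annotations([f"g{i}" for i in range(10)], dag, rng_seed=3)
        )
        genes = ann.genes()[:4]
        m = semsim_matrix(genes, genes, ann, dag)
        assert ((m.values >= 0) & (m.values <= 1)).all()
        assert np.allclose(np.diag(m.values), 1.0)
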