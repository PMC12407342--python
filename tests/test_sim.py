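import numpy as np
import pandas as pd
import pytest

from conftest import small_sim_config
from kranz.sim import (
    ConfigError,
    DEEffectSpec,
    FamilySpec,
    PlantedMotif,
    SimConfig,
    simulate_all,
    simulate_expression,
    simulate_ortholog_scores,
    simulate_peak_links,
    simulate_promoters,
)


def _tiny_config(**overrides):
    defaults = dict(
        n_genes=50, cell_types=["IMC", "KC"], conditions=["terrestrial"],
        cells_per_group=40,
        family_specs=[FamilySpec("fam", 10, "IMC", 0.7)],
        de_effects=[], n_promoters=5, promoter_length=300,
        n_species2_genes=15, n_true_orthologs=10,
        n_elements_per_group=100,
        motif_rate_vectors={"C4": {"IMC": {"terrestrial": {"NAC": 0.6, "bZIP": 0.3, "MYB": 0.1}}}},
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


class TestValidation:
    def test_invalid_fields_named(self):
        with pytest.raises(ConfigError, match="true_weight_B_AB"):
            _tiny_config(family_specs=[FamilySpec("f", 5, "IMC", 1.2)]).validate()
        with pytest.raises(ConfigError, match="nb_dispersion"):
            _tiny_config(nb_dispersion=-1).validate()
        with pytest.raises(ConfigError, match="motif_rate_vectors"):
            _tiny_config(motif_rate_vectors={
                "C4": {"IMC": {"terrestrial": {"NAC": 0.6, "bZIP": 0.6}}}}).validate()
        with pytest.raises(ConfigError, match="IUPAC"):
            _tiny_config(planted_motifs=[PlantedMotif("f", "AXT", 1)]).validate()
        with pytest.raises(ConfigError, match="promoter_length"):
            _tiny_config(planted_motifs=[PlantedMotif("f", "A" * 400, 1)]).validate()

    def test_default_config_valid(self):
        SimConfig().validate()

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        cfg = _tiny_config()
        path = tmp_path / "sim.yaml"
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        back = SimConfig.from_yaml(path)
        assert back.to_dict() == cfg.to_dict()


class TestDeterminism:
    def test_expression_bit_identical(self):
        cfg = _tiny_config()
        a = simulate_expression(cfg, 11)
        b = simulate_expression(cfg, 11)
        assert (a[0].matrix != b[0].matrix).nnz == 0
        pd.testing.assert_frame_equal(a[1], b[1])
        c = simulate_expression(cfg, 12)
        assert (a[0].matrix != c[0].matrix).nnz > 0

    def test_links_promoters_orthologs_identical(self):
        cfg = _tiny_config()
        pd.testing.assert_frame_equal(simulate_peak_links(cfg, 3)[0],
                                      simulate_peak_links(cfg, 3)[0])
        assert simulate_promoters(cfg, 3)[0] == simulate_promoters(cfg, 3)[0]
        pd.testing.assert_frame_equal(simulate_ortholog_scores(cfg, 3)[0],
                                      simulate_ortholog_scores(cfg, 3)[0])


class TestExpression:
    def test_counts_nonnegative_integers_and_library_size(self):
        cfg = small_sim_config(family_specs=[FamilySpec("fam", 50, "IMC", 0.5)],
                               cells_per_group=600)
        cm, cells, genes, hom, truth = simulate_expression(cfg, 0)
        data = cm.matrix.data
        assert np.all(data >= 0) and np.all(data == np.floor(data))
        totals = cm.cell_totals()
        assert totals.size >= 1000
        assert abs(totals.mean() - cfg.mean_library_size) / cfg.mean_library_size < 0.05

    def test_truth_ids_exist_in_outputs(self):
        cfg = _tiny_config(de_effects=[DEEffectSpec("eff", 10, "terrestrial", 2.0)])
        cm, cells, genes, hom, truth = simulate_expression(cfg, 5)
        gene_set = set(cm.gene_ids)
        for fam, pairs in truth.homeolog_pairs.items():
            for ga, gb in pairs:
                assert ga in gene_set and gb in gene_set
        for spec in truth.de_genes.values():
            assert set(spec["genes"]) <= gene_set
        ann = genes.set_index("gene_id")
        assert (ann.loc[[p[0] for p in truth.homeolog_pairs["fam"]], "subgenome"] == "A").all()
        assert (ann.loc[[p[1] for p in truth.homeolog_pairs["fam"]], "subgenome"] == "B").all()

    def test_symmetric_weight_recovered_when_flat(self):
        from kranz.dominance import family_weights
        from kranz.expression import celltype_means, normalize_cp10k

        cfg = small_sim_config(
            family_specs=[FamilySpec("fam", 200, "IMC", 0.5, enrichment_fold=3.0)])
        cm, cells, genes, hom, truth = simulate_expression(cfg, 1)
        prof = celltype_means(normalize_cp10k(cm), cells)
        w = family_weights(prof, hom, "IMC", "KC", "terrestrial")[0]
        assert abs(w.weight_B_AB - 0.5) < 0.06


class TestPeakLinks:
    def test_degenerate_rate_vector(self):
        cfg = _tiny_config(motif_rate_vectors={
            "C4": {"IMC": {"terrestrial": {"NAC": 1.0}}}})
        links, truth = simulate_peak_links(cfg, 0)
        assert (links["motif_family"] == "NAC").all()

    def test_planted_rates_recovered(self):
        cfg = _tiny_config(n_elements_per_group=1000)
        links, truth = simulate_peak_links(cfg, 2)
        freq = links["motif_family"].value_counts(normalize=True)
        for fam, rate in truth.motif_rates["C4|IMC|terrestrial"].items():
            assert abs(freq.get(fam, 0.0) - rate) < 0.03

    def test_coordinates_half_open(self):
        links, _ = simulate_peak_links(_tiny_config(), 0)
        assert (links["end"] > links["start"]).all()


class TestPromoters:
    def test_planted_occurrences_recorded_and_findable(self):
        from kranz.motifs import count_matches

        cfg = _tiny_config(planted_motifs=[PlantedMotif("bZIP", "TGACGTCA", 3)])
        seqs, truth = simulate_promoters(cfg, 4)
        for gene, seq in seqs.items():
            rec = truth.promoter_occurrences[gene]["bZIP"]
            assert rec["count"] == 3
            assert len(rec["positions"]) == 3
            for pos in rec["positions"]:
                assert seq[pos:pos + 8] == "TGACGTCA"
            assert count_matches(seq, "TGACGTCA") >= 3

    def test_sequence_alphabet_and_length(self):
        seqs, _ = simulate_promoters(_tiny_config(), 0)
        for seq in seqs.values():
            assert len(seq) == 300
            assert set(seq) <= set("ACGT")


class TestOrthologScores:
    def test_true_pairs_recovered_by_rbh(self):
        from kranz.comparative import reciprocal_best_hits

        cfg = _tiny_config()
        scores, truth = simulate_ortholog_scores(cfg, 6)
        rbh = reciprocal_best_hits(scores)
        got = set(zip(rbh["gene_sp1"], rbh["gene_sp2"]))
        assert got == set(truth.ortholog_pairs)

    def test_evalues_monotone_in_score(self):
        scores, _ = simulate_ortholog_scores(_tiny_config(), 7)
        s = scores.sort_values("score")
        assert (np.diff(s["evalue"].to_numpy()) <= 1e-30).all()


def test_simulate_all_links_reference_homeolog_genes():
    cfg = _tiny_config()
    bundle = simulate_all(cfg, 8)
    c4 = set(bundle.homeologs["gene_A"]) | set(bundle.homeologs["gene_B"])
    assert set(bundle.links["gene_id"]) <= c4
    assert set(bundle.truth.link_gene_sets["C4"]) == c4
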