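import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comorbnet.data_model import GeneDiseaseMap, GeneSetCollection, InteractionNetwork
from comorbnet.gene_maps import (
    Crosswalk,
    aggregate_genes_to_dg,
    bh_adjust,
    build_geneset_feature_map,
    filter_sets,
    fisher_enrichment,
    gene_feature_map,
    integrate_sources,
    ppi_extend,
    read_crosswalk,
    write_crosswalk,
)
from comorbnet.grouping import DiseaseGroupMap


def hypergeom_tail_oracle(k, n_universe, n_set, n_draw):
    """Brute-force P(X >= k) by direct enumeration of the pmf."""
    total = math.comb(n_universe, n_draw)
    return sum(
        math.comb(n_set, x) * math.comb(n_universe - n_set, n_draw - x)
        for x in range(k, min(n_set, n_draw) + 1)
    ) / total


XW = Crosswalk(entries={("termX", "MESH", "496"), ("termY", "MESH", "491"),
                        ("termY", "MESH", "492")})


def raw(rows):
    return pd.DataFrame(rows, columns=["gene", "term", "vocabulary", "source"])


class TestIntegrateSources:
    def test_crosswalk_expansion(self):
        m = integrate_sources([raw([("7124", "termX", "MESH", "ctd")])], XW)
        assert m.associations == {("7124", "496")}

    def test_provenance_union_across_sources(self):
        m = integrate_sources(
            [raw([("7124", "termX", "MESH", "ctd")]),
             raw([("7124", "termX", "MESH", "omim")])], XW,
        )
        assert m.associations == {("7124", "496")}
        assert m.provenance[("7124", "496")] == {"ctd", "omim"}

    def test_fan_out_term(self):
        m = integrate_sources([raw([("348", "termY", "MESH", "ctd")])], XW)
        assert m.associations == {("348", "491"), ("348", "492")}

    def test_native_icd9_and_unmapped_skipped(self):
        m = integrate_sources(
            [raw([("1", "8", "ICD9", "ctd"), ("2", "unknown", "MESH", "ctd")])], XW
        )
        assert m.associations == {("1", "008")}

    def test_crosswalk_round_trip(self, tmp_path):
        write_crosswalk(XW, tmp_path / "xw.tsv")
        assert read_crosswalk(tmp_path / "xw.tsv").entries == XW.entries


class TestAggregateToDG:
    DGM = DiseaseGroupMap(groups={"DG1": ("resp", {"491", "492"})})

    def test_member_code_association(self):
        m1 = GeneDiseaseMap(associations={("g1", "491")})
        m = aggregate_genes_to_dg(m1, self.DGM)
        assert m.associations == {("g1", "DG1")}
        assert m.level == "DG"

    def test_nonmember_code_dropped(self):
        m1 = GeneDiseaseMap(associations={("g1", "493")})
        assert aggregate_genes_to_dg(m1, self.DGM).associations == set()

    def test_two_member_codes_single_association(self):
        m1 = GeneDiseaseMap(associations={("g1", "491"), ("g1", "492")})
        assert aggregate_genes_to_dg(m1, self.DGM).associations == {("g1", "DG1")}

    def test_passthrough_keeps_index_code(self):
        m1 = GeneDiseaseMap(associations={("g1", "496")})
        m = aggregate_genes_to_dg(m1, self.DGM, passthrough=("496",))
        assert m.associations == {("g1", "496")}


class TestPpiExtend:
    def test_one_hop_only(self):
        m = GeneDiseaseMap(associations={("g1", "496")})
        net = InteractionNetwork(edges={frozenset(("g1", "g2")), frozenset(("g2", "g3"))})
        m2 = ppi_extend(m, net)
        assert m2.genes_for("496") == {"g1", "g2"}
        assert m2.provenance[("g2", "496")] == {"ppi-extension"}

    def test_empty_network_unchanged(self):
        m = GeneDiseaseMap(associations={("g1", "496")})
        assert ppi_extend(m, InteractionNetwork(edges=set())).associations == m.associations

    def test_superset_and_monotone(self):
        m = GeneDiseaseMap(associations={("g1", "496"), ("g4", "491")})
        small = InteractionNetwork(edges={frozenset(("g1", "g2"))})
        big = InteractionNetwork(edges=small.edges | {frozenset(("g4", "g5"))})
        small_ext = ppi_extend(m, small).associations
        big_ext = ppi_extend(m, big).associations
        assert m.associations <= small_ext <= big_ext

    def test_idempotent_without_new_neighbors(self):
        m = GeneDiseaseMap(associations={("g1", "496"), ("g2", "496")})
        net = InteractionNetwork(edges={frozenset(("g1", "g2"))})
        once = ppi_extend(m, net)
        twice = ppi_extend(once, net)
        assert once.associations == twice.associations

    def test_mapping2_row_sums_dominate(self, study):
        fm1 = gene_feature_map(study.gene_map)
        m2 = ppi_extend(study.gene_map, study.network)
        for d in study.gene_map.diseases():
            assert len(m2.genes_for(d)) >= len(study.gene_map.genes_for(d))


class TestFisher:
    def test_complete_overlap_example(self):
        universe = {f"g{i}" for i in range(20)}
        s = {f"g{i}" for i in range(5)}
        p = fisher_enrichment(s, s, universe)
        assert p == pytest.approx(1 / math.comb(20, 5))  # 1/15504

    def test_zero_overlap_is_certain(self):
        universe = {f"g{i}" for i in range(10)}
        p = fisher_enrichment({"g0"}, {"g9"}, universe)
        assert p == pytest.approx(1.0)

    def test_disease_equals_universe(self):
        universe = {f"g{i}" for i in range(10)}
        assert fisher_enrichment(universe, {"g0", "g1"}, universe) == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment({"g"}, {"g"}, set())

    @settings(derandomize=True, max_examples=60)
    @given(st.data())
    def test_matches_enumeration_oracle(self, data):
        n_u = data.draw(st.integers(5, 30))
        universe = {f"g{i}" for i in range(n_u)}
        n_set = data.draw(st.integers(1, n_u))
        n_draw = data.draw(st.integers(1, n_u))
        gene_set = {f"g{i}" for i in range(n_set)}
        # draw from the back so overlap varies
        disease = {f"g{n_u - 1 - i}" for i in range(n_draw)}
        k = len(gene_set & disease)
        expect = hypergeom_tail_oracle(k, n_u, n_set, n_draw)
        assert fisher_enrichment(disease, gene_set, universe) == pytest.approx(expect)


class TestBH:
    def test_hand_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_all_equal_unchanged(self):
        assert bh_adjust([0.5, 0.5, 0.5]) == pytest.approx([0.5, 0.5, 0.5])

    def test_order_preserved_and_adjusted_geq_raw(self):
        ps = [0.04, 0.001, 0.9, 0.2]
        adj = bh_adjust(ps)
        assert np.all(adj >= np.asarray(ps))
        assert np.all(adj <= 1.0)
        # adjusted values are a monotone transform of the raw order
        assert np.all(np.argsort(np.argsort(ps)) >= np.argsort(np.argsort(ps)) * 0)
        assert np.all(np.diff(adj[np.argsort(ps)]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestGenesetFeatureMap:
    def make_collection(self):
        sets = {
            "TOO_SMALL": {f"g{i}" for i in range(19)},
            "AT_MIN": {f"g{i}" for i in range(20)},
            "AT_MAX": {f"g{i}" for i in range(200)},
            "OK": {f"g{i}" for i in range(30)},
        }
        return GeneSetCollection(sets=sets, source_label="KEGG")

    def test_size_filter_bounds(self):
        retained = filter_sets(self.make_collection())
        assert set(retained) == {"AT_MIN", "OK"}

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            filter_sets(self.make_collection(), 200, 20)

    def test_planted_enriched_set_enters_map(self, study):
        from comorbnet.gene_maps import ALPHA_MAP
        fm, res = build_geneset_feature_map(
            study.gene_map, study.collections, alpha=ALPHA_MAP
        )
        disease, set_name = study.truth.enriched_sets[0]
        col = f"{study.collections[0].source_label}:{set_name}"
        frame = fm.to_frame()
        assert frame.loc[disease, col] == 1

    def test_zero_gene_disease_all_zero_row(self):
        m = GeneDiseaseMap(associations={("g0", "496")}, level="DG")
        m.associations.add(("g0", "496"))
        coll = GeneSetCollection(
            sets={"S": {f"g{i}" for i in range(25)}}, source_label="KEGG"
        )
        m2 = GeneDiseaseMap(associations={("g0", "496"), ("zz", "491")}, level="DG")
        fm, _ = build_geneset_feature_map(m2, [coll], min_size=20, max_size=200, alpha=0.5)
        # disease 491 maps only to gene zz, outside every set
        assert fm.to_frame().loc["491"].sum() == 0

    def test_padj_at_least_p(self, study):
        _, res = build_geneset_feature_map(study.gene_map, study.collections)
        assert (res.rows["p_adj"] >= res.rows["p"] - 1e-12).all()


def test_gene_feature_map_matches_associations():
    m = GeneDiseaseMap(associations={("g1", "DG1"), ("g2", "DG1"), ("g1", "DG2")},
                       level="DG")
    fm = gene_feature_map(m)
    frame = fm.to_frame()
    assert frame.loc["DG1", "g1"] == 1 and frame.loc["DG1", "g2"] == 1
    assert frame.loc["DG2", "g2"] == 0
    assert fm.features_of("DG2") == {"g1"}
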