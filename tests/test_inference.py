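import numpy as np
import pandas as pd
import pytest

import funtax as ft
from funtax.function_db import FunctionDB, FunctionalUnit, GenomeRecord, PathwayDefinition
from funtax.inference import (
    InferenceError,
    UnitProfile,
    community_unit_profile,
    correct_abundance,
    crossmap_profile,
    pathway_abundance_com,
    pathway_abundance_ico,
    pathway_presence,
    pec_sweep,
    rollup_hierarchy,
)
from funtax.taxa_io import parse_taxa_table

from _oracle import brute_force, make_inputs
from conftest import TAXON_A, TAXON_B


class TestCorrectAbundance:
    def test_fixture_correction(self, fixture_corrected):
        col = fixture_corrected.abundance["S1"]
        assert col[TAXON_A] == pytest.approx(2 / 3, abs=1e-12)
        assert col[TAXON_B] == pytest.approx(1 / 3, abs=1e-12)

    def test_identity_when_all_single_copy(self, tmp_path):
        units = {"e1": FunctionalUnit("e1", "EC")}
        genomes = [
            GenomeRecord("G1", {"domain": "Bacteria", "genus": "A"}, 1, {"e1": 1}),
            GenomeRecord("G2", {"domain": "Bacteria", "genus": "B"}, 1, {"e1": 2}),
        ]
        db = FunctionDB(genomes, units, [PathwayDefinition("P", "p", "a", "b", "c", ("e1",))])
        p = tmp_path / "t.tsv"
        p.write_text("lineage\tS1\nk__Bacteria; g__A\t30\nk__Bacteria; g__B\t70\n")
        prof = parse_taxa_table(p)
        corrected, _ = correct_abundance(prof, db)
        pd.testing.assert_frame_equal(corrected.abundance, prof.abundance)

    def test_unmatched_taxon_mass_reported(self, tmp_path, fixture_db):
        p = tmp_path / "t.tsv"
        p.write_text(
            "lineage\tS1\nk__Bacteria; g__Taxona\t40\nk__Bacteria; g__Taxonb\t40\n"
            "k__Bacteria; g__Ghost\t20\n"
        )
        prof = parse_taxa_table(p)
        corrected, report = correct_abundance(prof, fixture_db)
        assert report.dropped_mass["S1"] == pytest.approx(0.2)
        assert report.unmatched_taxa == ["k__Bacteria; g__Ghost"]
        assert corrected.abundance["S1"].sum() == pytest.approx(1.0)

    def test_all_unmatched_sample_flagged_uninferable(self, tmp_path, fixture_db):
        p = tmp_path / "t.tsv"
        p.write_text("lineage\tS1\nk__Bacteria; g__Ghost\t10\n")
        prof = parse_taxa_table(p)
        corrected, report = correct_abundance(prof, fixture_db)
        assert report.uninferable_samples == ["S1"]


class TestUnitProfiles:
    def test_fixture_community_pool(self, fixture_corrected, fixture_db):
        up = community_unit_profile(fixture_corrected, fixture_db, "EC")
        expect = {"e1": 4 / 3, "e2": 4 / 3, "e3": 2 / 3, "e4": 0.0}
        for u, v in expect.items():
            assert up.abundance.loc[u, "S1"] == pytest.approx(v, abs=1e-12)

    def test_single_taxon_equals_copy_vector(self, tmp_path, fixture_db):
        p = tmp_path / "t.tsv"
        p.write_text("lineage\tS1\nk__Bacteria; g__Taxona\t100\n")
        corrected, _ = correct_abundance(parse_taxa_table(p), fixture_db)
        up = community_unit_profile(corrected, fixture_db, "EC")
        assert up.abundance.loc["e1", "S1"] == pytest.approx(2.0)
        assert up.abundance.loc["e2", "S1"] == pytest.approx(1.0)

    def test_row_permutation_invariance(self, tmp_path, fixture_db):
        a = tmp_path / "a.tsv"
        a.write_text("lineage\tS1\nk__Bacteria; g__Taxona\t50\nk__Bacteria; g__Taxonb\t50\n")
        b = tmp_path / "b.tsv"
        b.write_text("lineage\tS1\nk__Bacteria; g__Taxonb\t50\nk__Bacteria; g__Taxona\t50\n")
        up_a = community_unit_profile(correct_abundance(parse_taxa_table(a), fixture_db)[0],
                                      fixture_db, "EC")
        up_b = community_unit_profile(correct_abundance(parse_taxa_table(b), fixture_db)[0],
                                      fixture_db, "EC")
        pd.testing.assert_frame_equal(up_a.abundance, up_b.abundance)

    def test_unknown_namespace_fatal(self, fixture_corrected, fixture_db):
        with pytest.raises(InferenceError):
            community_unit_profile(fixture_corrected, fixture_db, "KO")


class TestCrossmap:
    def _db_with_crossmap(self, pairs):
        units = {u: FunctionalUnit(u, "EC") for u in ("u1", "u2")}
        units.update({v: FunctionalUnit(v, "KO") for v in ("v1", "v2")})
        genomes = [GenomeRecord("G", {"domain": "Bacteria", "genus": "A"}, 1, {"u1": 1})]
        pw = [PathwayDefinition("P", "p", "a", "b", "c", ("u1",))]
        return FunctionDB(genomes, units, pw, [ft.CrossMap("EC", "KO", frozenset(pairs))])

    def test_one_to_one(self):
        db = self._db_with_crossmap({("u1", "v1")})
        up = UnitProfile(pd.DataFrame({"S1": [3.0, 0.0]}, index=["u1", "u2"]), "EC")
        out = crossmap_profile(up, db, "KO")
        assert out.abundance.loc["v1", "S1"] == pytest.approx(3.0)

    def test_equal_split_over_targets(self):
        db = self._db_with_crossmap({("u1", "v1"), ("u1", "v2")})
        up = UnitProfile(pd.DataFrame({"S1": [4.0, 0.0]}, index=["u1", "u2"]), "EC")
        out = crossmap_profile(up, db, "KO")
        assert out.abundance.loc["v1", "S1"] == pytest.approx(2.0)
        assert out.abundance.loc["v2", "S1"] == pytest.approx(2.0)

    def test_missing_crossmap_fatal(self):
        db = self._db_with_crossmap({("u1", "v1")})
        up = UnitProfile(pd.DataFrame({"S1": [1.0]}, index=["u1"]), "EC")
        with pytest.raises(ft.function_db.DatabaseError):
            crossmap_profile(up, db, "Pfam")

    @pytest.mark.parametrize("seed", range(5))
    def test_mass_conservation_over_random_crossmaps(self, seed):
        db = ft.generate_synthetic_db(6, 10, 3, 4, seed=seed)
        rng = np.random.default_rng(seed)
        up = UnitProfile(
            pd.DataFrame(rng.random((10, 3)), index=db.units_in_namespace("EC"),
                         columns=["S1", "S2", "S3"]),
            "EC",
        )
        out = crossmap_profile(up, db, "KO")
        # every EC maps to >= 1 KO in the synthetic crossmap: mass is conserved
        assert np.allclose(out.abundance.sum(axis=0), up.abundance.sum(axis=0), atol=1e-9)


class TestPathwayEstimation:
    def test_presence_quorum_grid(self, fixture_corrected, fixture_db):
        up = community_unit_profile(fixture_corrected, fixture_db, "EC")
        p2 = fixture_db.pathway("P2")
        for pec, expect in [(0, True), (50, True), (60, True), (70, False),
                            (80, False), (90, False)]:
            assert bool(pathway_presence(up, p2, pec)["S1"]) is expect

    def test_presence_below_half(self):
        units = {f"e{i}": FunctionalUnit(f"e{i}", "EC") for i in range(10)}
        genomes = [GenomeRecord("G", {"domain": "B", "genus": "A"}, 1,
                                {f"e{i}": 1 for i in range(4)})]
        pw = PathwayDefinition("P", "p", "a", "b", "c", tuple(f"e{i}" for i in range(10)))
        db = FunctionDB(genomes, units, [pw])
        up = UnitProfile(
            pd.DataFrame({"S1": [1.0] * 4 + [0.0] * 6}, index=[f"e{i}" for i in range(10)]),
            "EC",
        )
        assert not pathway_presence(up, pw, 50)["S1"]  # 40% < 50%

    def test_com_fixture_values(self, fixture_corrected, fixture_db):
        up = community_unit_profile(fixture_corrected, fixture_db, "EC")
        fp = pathway_abundance_com(up, fixture_db, pec=50)
        assert fp.raw.loc["P1", "S1"] == pytest.approx(2.0, abs=1e-12)
        assert fp.raw.loc["P2", "S1"] == pytest.approx(4 / 3, abs=1e-12)
        assert fp.abundance.loc["P1", "S1"] == pytest.approx(0.6, abs=1e-12)
        assert fp.abundance.loc["P2", "S1"] == pytest.approx(0.4, abs=1e-12)

    def test_com_pec70_drops_p2(self, fixture_corrected, fixture_db):
        up = community_unit_profile(fixture_corrected, fixture_db, "EC")
        fp = pathway_abundance_com(up, fixture_db, pec=70)
        assert fp.abundance.loc["P1", "S1"] == pytest.approx(1.0)
        assert fp.abundance.loc["P2", "S1"] == 0.0

    def test_unshared_pathway_is_plain_sum(self):
        units = {u: FunctionalUnit(u, "EC") for u in ("a1", "a2")}
        genomes = [GenomeRecord("G", {"domain": "B", "genus": "A"}, 1, {"a1": 2, "a2": 3})]
        pw = PathwayDefinition("P", "p", "x", "y", "z", ("a1", "a2"))
        db = FunctionDB(genomes, units, [pw])
        up = UnitProfile(pd.DataFrame({"S1": [2.0, 3.0]}, index=["a1", "a2"]), "EC")
        fp = pathway_abundance_com(up, db, pec=50)
        assert fp.raw.loc["P", "S1"] == pytest.approx(5.0)

    def test_ico_fixture_contributions(self, fixture_corrected, fixture_db):
        fp, ct = pathway_abundance_ico(fixture_corrected, fixture_db, pec=50)
        assert ct.values.loc[(TAXON_A, "P1"), "S1"] == pytest.approx(5 / 3, abs=1e-12)
        assert ct.values.loc[(TAXON_A, "P2"), "S1"] == 0.0
        assert ct.values.loc[(TAXON_B, "P1"), "S1"] == pytest.approx(1 / 3, abs=1e-12)
        assert ct.values.loc[(TAXON_B, "P2"), "S1"] == pytest.approx(1.0, abs=1e-12)
        assert fp.raw.loc["P1", "S1"] == pytest.approx(2.0, abs=1e-12)
        assert fp.raw.loc["P2", "S1"] == pytest.approx(1.0, abs=1e-12)

    def test_single_taxon_com_equals_ico(self, tmp_path, fixture_db):
        p = tmp_path / "t.tsv"
        p.write_text("lineage\tS1\tS2\nk__Bacteria; g__Taxona\t60\t40\n")
        corrected, _ = correct_abundance(parse_taxa_table(p), fixture_db)
        up = community_unit_profile(corrected, fixture_db, "EC")
        com = pathway_abundance_com(up, fixture_db, pec=50)
        ico, _ = pathway_abundance_ico(corrected, fixture_db, pec=50)
        pd.testing.assert_frame_equal(com.raw, ico.raw, atol=1e-12, rtol=0)

    @pytest.mark.parametrize("seed", range(5))
    def test_tensor_sums_to_unnormalized_profile(self, seed, tmp_path):
        db = ft.generate_synthetic_db(8, 12, 4, 4, seed=seed)
        text, *_ = make_inputs(db, 3, np.random.default_rng(seed))
        p = tmp_path / "t.tsv"
        p.write_text(text)
        corrected, _ = correct_abundance(parse_taxa_table(p), db)
        fp, ct = pathway_abundance_ico(corrected, db, pec=50)
        summed = ct.summed()
        assert np.allclose(summed.to_numpy(), fp.raw.to_numpy(), atol=1e-9)


class TestHierarchyAndSweep:
    def test_rollup_sums_and_preserves_column_totals(self, fixture_corrected, fixture_db):
        up = community_unit_profile(fixture_corrected, fixture_db, "EC")
        fp = pathway_abundance_com(up, fixture_db, pec=50)
        l1 = rollup_hierarchy(fp, fixture_db, "level1")
        assert l1.abundance.loc["Metabolism", "S1"] == pytest.approx(1.0)
        l2 = rollup_hierarchy(fp, fixture_db, "level2")
        assert len(l2.abundance) == 2
        assert abs(l2.abundance["S1"].sum() - fp.abundance["S1"].sum()) < 1e-12

    def test_rollup_rejects_bad_level(self, fixture_corrected, fixture_db):
        up = community_unit_profile(fixture_corrected, fixture_db, "EC")
        fp = pathway_abundance_com(up, fixture_db, pec=50)
        with pytest.raises(InferenceError):
            rollup_hierarchy(fp, fixture_db, "level3")

    def test_fixture_sweep_p2_membership(self, fixture_corrected, fixture_db):
        sweep = pec_sweep(fixture_corrected, fixture_db, "com")
        present_at = [pec for pec, fp in sweep.items() if fp.raw.loc["P2", "S1"] > 0]
        assert present_at == [50, 60]
        # P1 is fully detected: present at every level
        assert all(fp.raw.loc["P1", "S1"] > 0 for fp in sweep.values())

    @pytest.mark.parametrize("algorithm", ["com", "ico"])
    def test_presence_nesting_on_random_communities(self, algorithm, tmp_path):
        for seed in range(5):
            db = ft.generate_synthetic_db(8, 12, 4, 4, seed=seed)
            text, *_ = make_inputs(db, 4, np.random.default_rng(seed))
            p = tmp_path / f"t{algorithm}{seed}.tsv"
            p.write_text(text)
            corrected, _ = correct_abundance(parse_taxa_table(p), db)
            sweep = pec_sweep(corrected, db, algorithm)
            for lo, hi in zip((50, 60, 70, 80), (60, 70, 80, 90)):
                present_hi = sweep[hi].raw > 0
                present_lo = sweep[lo].raw > 0
                assert (present_lo | ~present_hi).all().all()

    def test_scale_invariance_of_relative_outputs(self, tmp_path, fixture_db):
        a = tmp_path / "a.tsv"
        a.write_text("lineage\tS1\tS2\nk__Bacteria; g__Taxona\t50\t10\nk__Bacteria; g__Taxonb\t50\t10\n")
        b = tmp_path / "b.tsv"
        b.write_text("lineage\tS1\tS2\nk__Bacteria; g__Taxona\t50\t1000\nk__Bacteria; g__Taxonb\t50\t1000\n")
        fa = pec_sweep(correct_abundance(parse_taxa_table(a), fixture_db)[0], fixture_db, "com")
        fb = pec_sweep(correct_abundance(parse_taxa_table(b), fixture_db)[0], fixture_db, "com")
        for pec in fa:
            pd.testing.assert_frame_equal(fa[pec].abundance, fb[pec].abundance,
                                          atol=1e-12, rtol=0)


class TestBruteForceOracle:
    @pytest.mark.parametrize("seed", range(5))
    def test_small_db_matrices_match_oracle(self, seed, tmp_path):
        rng = np.random.default_rng(seed)
        db = ft.generate_synthetic_db(
            n_genomes=int(rng.integers(2, 6)), n_units=8,
            n_pathways=int(rng.integers(1, 4)), max_copies=4, seed=seed,
        )
        text, genomes, pathways, abundance = make_inputs(db, 3, rng)
        p = tmp_path / "t.tsv"
        p.write_text(text)
        profile = parse_taxa_table(p)
        corrected, _ = correct_abundance(profile, db)
        expected = brute_force(genomes, pathways, abundance, pec=50)

        key_of = {
            k: tuple(lg.get(r, "") for r in
                     ("domain", "phylum", "class", "order", "family", "genus", "species"))
            for k, lg in corrected.lineages.items()
        }
        for k in corrected.abundance.index:
            for s in corrected.abundance.columns:
                assert corrected.abundance.loc[k, s] == pytest.approx(
                    expected["corrected"][s][key_of[k]], abs=1e-9)

        up = community_unit_profile(corrected, db, "EC")
        for u in up.abundance.index:
            for s in up.abundance.columns:
                assert up.abundance.loc[u, s] == pytest.approx(
                    expected["units"][s].get(u, 0.0), abs=1e-9)

        com = pathway_abundance_com(up, db, pec=50)
        ico, ct = pathway_abundance_ico(corrected, db, pec=50)
        for pw in com.raw.index:
            for s in com.raw.columns:
                assert com.raw.loc[pw, s] == pytest.approx(
                    expected["com_raw"][pw][s], abs=1e-9)
                assert com.abundance.loc[pw, s] == pytest.approx(
                    expected["com_rel"][s][pw], abs=1e-9)
                assert ico.raw.loc[pw, s] == pytest.approx(
                    expected["ico_raw"][pw][s], abs=1e-9)
        for (t, pw) in ct.values.index:
            for s in ct.samples:
                assert ct.values.loc[(t, pw), s] == pytest.approx(
                    expected["tensor"][key_of[t]][pw][s], abs=1e-9)
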