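"""Cross-mapping, cultured fractions, copy correction, culturability, summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from isoamp.cluster import greedy_cluster
from isoamp.crossmap import (
    composition_summary,
    copy_number_correct,
    correct_matrix,
    cultured_read_fraction,
    culturability_ratio,
    match_ziotus_to_asvs,
    media_overlap,
    overall_cultured_fraction,
    rank_abundance_overlay,
)
from isoamp.io import (
    AmpliconTable,
    CopyNumberTable,
    FormatError,
    IsolateRecord,
    PlateCountTable,
    reverse_complement,
)

from conftest import mutate, random_seq


def _amplicon(counts, seqs, meta_rows):
    counts = pd.DataFrame(
        counts["data"],
        index=pd.Index(counts["samples"], name="sample_id"),
        columns=counts["asvs"],
    )
    meta = pd.DataFrame(meta_rows, index=counts.index)
    return AmpliconTable(counts=counts, asv_sequences=seqs, sample_meta=meta)


@pytest.fixture()
def gene_and_asvs():
    rng = np.random.default_rng(8)
    gene = random_seq(rng, 1400)
    window = gene[515:888]
    other = random_seq(rng, 373)
    table = _amplicon(
        {
            "data": [[60, 40]],
            "samples": ["s1"],
            "asvs": ["A", "B"],
        },
        {"A": window, "B": other},
        [{"season": "summer", "treatment": "VL", "time": "tf", "replicate": "1"}],
    )
    ziotus = greedy_cluster({"z1": gene}, 1.0)
    return gene, window, other, table, ziotus


class TestMatching:
    def test_exact_slice_matches(self, gene_and_asvs):
        gene, window, other, table, ziotus = gene_and_asvs
        res = match_ziotus_to_asvs(ziotus, {"z1": gene}, table)
        assert res.matches["A"] == ["z1"]
        assert res.matches["B"] == []
        assert res.cultured_flag == {"A": True, "B": False}
        assert res.n_ziotus_matched == 1

    def test_reverse_complement_slice_matches(self, gene_and_asvs):
        gene, window, other, table, ziotus = gene_and_asvs
        table.asv_sequences["A"] = reverse_complement(window)
        res = match_ziotus_to_asvs(ziotus, {"z1": gene}, table)
        assert res.cultured_flag["A"] is True

    def test_single_substitution_breaks_match(self, gene_and_asvs):
        gene, window, other, table, ziotus = gene_and_asvs
        table.asv_sequences["A"] = mutate(window, 1, np.random.default_rng(0))
        res = match_ziotus_to_asvs(ziotus, {"z1": gene}, table)
        assert res.cultured_flag["A"] is False

    def test_ambiguity_codes_never_match(self, gene_and_asvs):
        gene, window, other, table, ziotus = gene_and_asvs
        table.asv_sequences["A"] = "N" + window[1:]
        res = match_ziotus_to_asvs(ziotus, {"z1": gene}, table)
        assert res.cultured_flag["A"] is False


class TestCulturedFraction:
    def test_sixty_forty_split(self, gene_and_asvs):
        gene, *_, table, ziotus = gene_and_asvs
        res = match_ziotus_to_asvs(ziotus, {"z1": gene}, table)
        res = cultured_read_fraction(res, table)
        frac = res.per_group_fraction_raw
        assert frac["cultured_pct_mean"].tolist() == [60.0]

    def test_boundaries_zero_and_hundred(self, gene_and_asvs):
        gene, window, other, table, ziotus = gene_and_asvs
        # no cultured ASV
        table.asv_sequences["A"] = other
        res = cultured_read_fraction(
            match_ziotus_to_asvs(ziotus, {"z1": gene}, table), table
        )
        assert res.per_group_fraction_raw["cultured_pct_mean"].tolist() == [0.0]
        # all cultured
        table.asv_sequences["A"] = gene[515:888]
        table.asv_sequences["B"] = gene[100:300]
        res = cultured_read_fraction(
            match_ziotus_to_asvs(ziotus, {"z1": gene}, table), table
        )
        assert res.per_group_fraction_raw["cultured_pct_mean"].tolist() == [100.0]

    def test_invariant_to_uniform_read_rescaling(self, gene_and_asvs):
        gene, *_, table, ziotus = gene_and_asvs
        res = match_ziotus_to_asvs(ziotus, {"z1": gene}, table)
        res = cultured_read_fraction(res, table)
        scaled = AmpliconTable(
            counts=table.counts * 10,
            asv_sequences=table.asv_sequences,
            sample_meta=table.sample_meta,
        )
        res2 = cultured_read_fraction(
            match_ziotus_to_asvs(ziotus, {"z1": gene}, scaled), scaled
        )
        pd.testing.assert_frame_equal(
            res.per_group_fraction_raw, res2.per_group_fraction_raw
        )


class TestCopyCorrection:
    def test_forced_arithmetic_example(self, gene_and_asvs):
        # reads {A: 60 (4 copies), B: 40 (1 copy)}, A cultured
        # corrected cultured fraction = 100 * 15 / 55 = 27.27%
        gene, *_, table, ziotus = gene_and_asvs
        table.asv_class = {"A": "Gammaproteobacteria", "B": "SAR11"}
        copies = CopyNumberTable(
            copies={"Gammaproteobacteria": 4.0, "SAR11": 1.0}
        )
        res = match_ziotus_to_asvs(ziotus, {"z1": gene}, table)
        res = cultured_read_fraction(res, table, copies)
        corrected = res.per_group_fraction_corrected["cultured_pct_mean"].iloc[0]
        assert corrected == pytest.approx(100 * 15 / 55)
        assert res.per_group_fraction_raw["cultured_pct_mean"].iloc[0] == 60.0

    def test_equal_copies_leave_fractions_unchanged(self, gene_and_asvs):
        gene, *_, table, ziotus = gene_and_asvs
        table.asv_class = {"A": "X", "B": "Y"}
        copies = CopyNumberTable(copies={"X": 3.0, "Y": 3.0, "SAR11": 3.0})
        res = match_ziotus_to_asvs(ziotus, {"z1": gene}, table)
        res = cultured_read_fraction(res, table, copies)
        assert res.per_group_fraction_corrected["cultured_pct_mean"].iloc[0] == (
            pytest.approx(res.per_group_fraction_raw["cultured_pct_mean"].iloc[0])
        )

    def test_sar11_uses_its_own_entry_and_renormalization(self):
        counts = pd.DataFrame(
            [[8, 4]],
            index=pd.Index(["s"], name="sample_id"),
            columns=["a", "b"],
        )
        classes = {"a": "Alphaproteobacteria", "b": "SAR11"}
        copies = CopyNumberTable(copies={"Alphaproteobacteria": 2.0, "SAR11": 1.0})
        corrected = correct_matrix(counts, classes, copies)
        assert corrected.loc["s"].tolist() == [4.0, 4.0]
        meta = pd.DataFrame(
            {"season": ["winter"], "treatment": ["t0"], "time": ["t0"], "replicate": ["1"]},
            index=counts.index,
        )
        table = AmpliconTable(
            counts=counts,
            asv_sequences={"a": "ACGT", "b": "TTTT"},
            sample_meta=meta,
            asv_class=classes,
        )
        norm = copy_number_correct(table, copies)
        assert norm.loc["s"].tolist() == [0.5, 0.5]

    def test_missing_class_falls_back_to_default(self, caplog):
        counts = pd.DataFrame(
            [[6, 6]], index=pd.Index(["s"], name="sample_id"), columns=["a", "b"]
        )
        copies = CopyNumberTable(copies={"SAR11": 1.0}, default_copies=3.0)
        with caplog.at_level("WARNING"):
            corrected = correct_matrix(counts, {}, copies)
        assert "default" in caplog.text
        assert corrected.loc["s"].tolist() == [2.0, 2.0]


class TestCulturability:
    def test_forced_arithmetic(self):
        plates = PlateCountTable(
            rows=pd.DataFrame(
                [
                    {
                        "sample_group": "g",
                        "medium": "MA",
                        "replicate": "1",
                        "colonies": 100,
                        "dilution_factor": 10,
                        "plated_volume_mL": 0.1,
                    }
                ]
            ),
            dapi={"g": 1e7},
        )
        (rec,) = culturability_ratio(plates)
        assert rec.cfu_per_mL == pytest.approx(1e4)
        assert rec.culturability_pct == pytest.approx(0.1)

    def test_zero_colonies_zero_culturability(self):
        plates = PlateCountTable(
            rows=pd.DataFrame(
                [
                    {
                        "sample_group": "g",
                        "medium": "MA",
                        "replicate": "1",
                        "colonies": 0,
                        "dilution_factor": 1,
                        "plated_volume_mL": 0.1,
                    }
                ]
            ),
            dapi={"g": 1e6},
        )
        (rec,) = culturability_ratio(plates)
        assert rec.culturability_pct == 0.0

    def test_missing_dapi_rejected(self):
        plates = PlateCountTable(
            rows=pd.DataFrame(
                [
                    {
                        "sample_group": "g",
                        "medium": "MA",
                        "replicate": "1",
                        "colonies": 5,
                        "dilution_factor": 1,
                        "plated_volume_mL": 0.1,
                    }
                ]
            ),
            dapi={"other": 1e6},
        )
        with pytest.raises(FormatError, match="DAPI"):
            culturability_ratio(plates)

    def test_replicates_averaged(self):
        rows = [
            {
                "sample_group": "g",
                "medium": "MA",
                "replicate": str(r),
                "colonies": c,
                "dilution_factor": 1,
                "plated_volume_mL": 0.1,
            }
            for r, c in ((1, 90), (2, 110))
        ]
        plates = PlateCountTable(rows=pd.DataFrame(rows), dapi={"g": 1e6})
        (rec,) = culturability_ratio(plates)
        assert rec.cfu_per_mL == pytest.approx(1000.0)


class TestRankAbundance:
    def _table(self, reads):
        return _amplicon(
            {"data": [reads], "samples": ["s1"], "asvs": ["A", "B", "C"]},
            {"A": "ACGT", "B": "CCCC", "C": "GGGG"},
            [{"season": "summer", "treatment": "DL", "time": "tf", "replicate": "1"}],
        )

    def _fake_result(self, table, cultured):
        from isoamp.crossmap import CrossmapResult

        return CrossmapResult(
            matches={a: (["z"] if a in cultured else []) for a in table.asv_ids},
            cultured_flag={a: a in cultured for a in table.asv_ids},
            n_asvs_cultured=len(cultured),
            n_ziotus_matched=1,
            n_ziotus_total=1,
        )

    def test_ranks_by_descending_abundance(self):
        table = self._table([50, 30, 20])
        res = self._fake_result(table, {"A"})
        ra = rank_abundance_overlay(table, res, ("summer", "DL", "tf"))
        assert ra["asv_id"].tolist() == ["A", "B", "C"]
        assert ra["rank"].tolist() == [1, 2, 3]
        assert ra["cultured"].tolist() == [True, False, False]

    def test_ties_broken_by_ascending_id(self):
        table = self._table([40, 40, 20])
        res = self._fake_result(table, set())
        ra = rank_abundance_overlay(table, res, ("summer", "DL", "tf"))
        assert ra["asv_id"].tolist() == ["A", "B", "C"]

    def test_unknown_group_rejected(self):
        table = self._table([1, 1, 1])
        res = self._fake_result(table, set())
        with pytest.raises(ValueError):
            rank_abundance_overlay(table, res, ("winter", "t0", "t0"))


class TestComposition:
    def _isolates(self):
        recs = []
        k = 0
        for cls, season, treat, time, medium, n in [
            ("Gammaproteobacteria", "fall", "t0", "t0", "MA", 3),
            ("Alphaproteobacteria", "fall", "VL", "tf", "MA", 1),
            ("Gammaproteobacteria", "summer", "DL", "tf", "mR2A", 2),
        ]:
            for _ in range(n):
                k += 1
                recs.append(
                    IsolateRecord(
                        f"i{k}", "ACGTACGT", season, treat, time, medium,
                        genus=f"G_{cls[:4]}", class_label=cls,
                    )
                )
        return recs

    def test_single_class_is_hundred_percent(self):
        recs = [
            IsolateRecord("i1", "ACGT", "fall", "t0", "t0", "MA",
                          class_label="Bacilli")
        ]
        out = composition_summary(recs, "class_x_season")
        assert out["pct:fall"].tolist() == [100.0]

    def test_columns_sum_to_hundred(self):
        out = composition_summary(self._isolates(), "class_x_season")
        for col in [c for c in out.columns if c.startswith("pct:")]:
            assert out[col].sum() == pytest.approx(100.0)
        out = composition_summary(self._isolates(), "class_x_treatment")
        for col in [c for c in out.columns if c.startswith("pct:")]:
            assert out[col].sum() == pytest.approx(100.0)

    def test_t0_pools_all_initial_time(self):
        out = composition_summary(self._isolates(), "class_x_treatment")
        assert "pct:t0" in out.columns
        assert out["count:t0"].sum() == 3  # the three initial-time isolates

    def test_fall_column_fraction(self):
        out = composition_summary(self._isolates(), "class_x_season").set_index(
            "class_label"
        )
        # 3 of 4 fall isolates are Gammaproteobacteria
        assert out.loc["Gammaproteobacteria", "pct:fall"] == pytest.approx(75.0)

    def test_unknown_facet_rejected(self):
        with pytest.raises(ValueError):
            composition_summary(self._isolates(), "phylum_x_moon")


class TestMediaOverlap:
    def _cluster_set(self, seqs):
        return greedy_cluster(seqs, 1.0)

    def test_three_cluster_toy(self):
        # 1 MA-only, 1 mR2A-only, 1 mixed -> shared 33.3%
        rng = np.random.default_rng(9)
        s1, s2, s3 = (random_seq(rng, 120) for _ in range(3))
        seqs = {"a1": s1, "a2": s1, "b1": s2, "c1": s3, "c2": s3}
        media = {"a1": "MA", "a2": "MA", "b1": "mR2A", "c1": "MA", "c2": "mR2A"}
        recs = [
            IsolateRecord(i, seqs[i], "fall", "t0", "t0", media[i]) for i in seqs
        ]
        out = media_overlap(self._cluster_set(seqs), recs)
        assert (out["only_MA"], out["only_mR2A"], out["shared"]) == (1, 1, 1)
        assert out["shared_pct"] == pytest.approx(100 / 3)

    def test_single_medium_no_sharing(self):
        rng = np.random.default_rng(10)
        seqs = {f"i{k}": random_seq(rng, 120) for k in range(4)}
        recs = [IsolateRecord(i, seqs[i], "fall", "t0", "t0", "MA") for i in seqs]
        out = media_overlap(self._cluster_set(seqs), recs)
        assert out["shared"] == 0
        assert out["only_MA"] == out["total_iotus"]


class TestOverallFraction:
    def test_overall_weighted_by_reads(self, gene_and_asvs):
        gene, *_, table, ziotus = gene_and_asvs
        res = match_ziotus_to_asvs(ziotus, {"z1": gene}, table)
        assert overall_cultured_fraction(res, table) == pytest.approx(60.0)
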