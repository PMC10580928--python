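"""Generator contracts: determinism, planted effects, truth bookkeeping."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from isoamp.cluster import pairwise_identity
from isoamp.crossmap import correct_matrix, culturability_ratio
from isoamp.simulate import (
    SimParams,
    mutate_to_identity,
    simulate_all,
    simulate_amplicon_reads,
    simulate_community,
    simulate_isolation,
)


def _tiny_params(**kw):
    defaults = dict(
        seed=3,
        n_taxa=12,
        seasons=("summer",),
        isolate_effort=8,
        reads_per_sample=3000,
        novelty_plan=((0.96, 0.96, 1), (0.93, 0.92, 1)),
        n_decoy_taxa=1,
    )
    defaults.update(kw)
    return SimParams(**defaults)


class TestMutateToIdentity:
    def test_target_one_returns_input(self):
        assert mutate_to_identity("ACGT" * 100, 1.0, 0) == "ACGT" * 100

    def test_forced_substitution_count_and_identity(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 1000))
        out = mutate_to_identity(seq, 0.95, 2)
        diffs = sum(a != b for a, b in zip(seq, out))
        assert diffs == 50
        assert pairwise_identity(seq, out) == pytest.approx(0.95)

    def test_infeasible_target_rejected(self):
        with pytest.raises(ValueError):
            mutate_to_identity("ACGT", -0.5, 0)


class TestDeterminism:
    def test_same_seed_identical_truth_and_outputs(self):
        p = _tiny_params()
        t1, a1, i1, pl1 = simulate_all(p)
        t2, a2, i2, pl2 = simulate_all(p)
        assert t1.genes == t2.genes
        pd.testing.assert_frame_equal(t1.cell_fractions, t2.cell_fractions)
        pd.testing.assert_frame_equal(a1.counts, a2.counts)
        assert [r.isolate_id for r in i1] == [r.isolate_id for r in i2]
        assert [r.sequence for r in i1] == [r.sequence for r in i2]
        pd.testing.assert_frame_equal(pl1.rows, pl2.rows)

    def test_different_seed_different_reads(self):
        a1 = simulate_amplicon_reads(simulate_community(_tiny_params(seed=3)))
        a2 = simulate_amplicon_reads(simulate_community(_tiny_params(seed=4)))
        assert not a1.counts.equals(a2.counts)


class TestCommunityModel:
    def test_no_treatment_effect_means_identical_distributions(self):
        p = _tiny_params(
            treatment_effects={k: 1.0 for k in ("t0", "CL", "CD", "PL", "PD", "DL", "VL")},
            replicate_sigma=0.0,
        )
        truth = simulate_community(p)
        groups = truth.group_samples()
        t0 = truth.cell_fractions.loc[groups[("summer", "t0", "t0")][0]]
        for (season, treat, time), samples in groups.items():
            row = truth.cell_fractions.loc[samples[0]]
            assert np.allclose(row.to_numpy(), t0.to_numpy())

    def test_copiotroph_boost_shifts_tf_fractions(self):
        boost = 10.0
        p = _tiny_params(
            seed=6,
            n_taxa=40,
            copiotroph_fraction=0.4,
            replicate_sigma=0.0,
            treatment_effects={"t0": 1.0, "CL": 1.0, "CD": 1.0, "PL": 1.0,
                               "PD": 1.0, "DL": boost, "VL": boost},
            novelty_plan=(),
            n_decoy_taxa=0,
        )
        truth = simulate_community(p)
        cop = truth.taxa["copiotroph"].to_numpy()
        groups = truth.group_samples()
        f_t0 = truth.cell_fractions.loc[groups[("summer", "t0", "t0")]].mean()
        f_dl = truth.cell_fractions.loc[groups[("summer", "DL", "tf")]].mean()
        share_t0 = f_t0[cop].sum()
        share_dl = f_dl[cop].sum()
        # odds-ratio of the copiotroph share equals the planted boost exactly
        # in the noise-free limit
        odds = (share_dl / (1 - share_dl)) / (share_t0 / (1 - share_t0))
        assert odds == pytest.approx(boost, rel=1e-9)

    def test_amplicon_window_must_fit_gene(self):
        with pytest.raises(ValueError):
            SimParams(gene_length=500, amplicon_window=(400, 900))


class TestReadModel:
    def test_expected_read_ratio_follows_copy_number(self):
        # two taxa, equal cells, copies 4 vs 1 -> expected read ratio 4:1
        p = _tiny_params(
            seed=8,
            n_taxa=2,
            abundance_sigma=0.0,
            replicate_sigma=0.0,
            reads_per_sample=100_000,
            novelty_plan=(),
            n_decoy_taxa=0,
            class_profile={"Gammaproteobacteria": (0.5, 4.0), "SAR11": (0.5, 1.0)},
        )
        truth = simulate_community(p)
        # force the two classes regardless of the random class draw
        truth.taxa["class"] = ["Gammaproteobacteria", "SAR11"]
        truth.taxa["copies"] = [4.0, 1.0]
        table = simulate_amplicon_reads(truth)
        s = table.counts.iloc[0]
        ratio = s.iloc[0] / s.iloc[1]
        # multinomial noise at n=1e5: 3 sigma of the 0.8 share is ~0.4%
        assert ratio == pytest.approx(4.0, rel=0.05)

    def test_copy_correction_recovers_cell_fractions_noise_free(self):
        p = _tiny_params(seed=9, n_taxa=6, novelty_plan=(), n_decoy_taxa=0)
        truth = simulate_community(p)
        # expected (noise-free) read shares: cells x copies, renormalised
        copies = truth.taxa["copies"].to_numpy()
        w = truth.cell_fractions.to_numpy() * copies
        expected_reads = pd.DataFrame(
            w / w.sum(axis=1, keepdims=True),
            index=truth.cell_fractions.index,
            columns=truth.cell_fractions.columns,
        )
        classes = truth.taxa["class"].to_dict()
        corrected = correct_matrix(expected_reads, classes, truth.copy_table)
        corrected = corrected.div(corrected.sum(axis=1), axis=0)
        assert np.allclose(
            corrected.to_numpy(), truth.cell_fractions.to_numpy(), atol=1e-12
        )

    def test_identical_slices_collapse_to_one_asv(self):
        p = _tiny_params(seed=10, novelty_plan=(), n_decoy_taxa=0)
        truth = simulate_community(p)
        # force two taxa to share the amplicon slice
        t0, t1 = truth.cell_fractions.columns[:2]
        start, end = p.amplicon_window
        truth.asv_sequence_of_taxon[t1] = truth.asv_sequence_of_taxon[t0]
        table = simulate_amplicon_reads(truth)
        shared_asv = truth.asv_of_taxon[t0]
        assert truth.asv_of_taxon[t1] == shared_asv
        assert sorted(truth.asv_taxa[shared_asv]) == sorted([t0, t1])
        assert len(table.asv_ids) == p.n_taxa - 1


class TestIsolation:
    def test_single_culturable_taxon_dominates(self):
        p = _tiny_params(seed=11, novelty_plan=(), n_decoy_taxa=0)
        truth = simulate_community(p)
        coeff = np.zeros(p.n_taxa)
        coeff[4] = 1.0
        truth.taxa["culturability_coefficient"] = coeff
        isolates, _ = simulate_isolation(truth)
        only = truth.cell_fractions.columns[4]
        assert truth.isolated_taxa == [only]
        gene = truth.genes[only]
        start, end = p.amplicon_window
        for r in isolates:
            assert gene[start:end] in r.sequence

    def test_planted_culturability_recovered_exactly(self):
        p = _tiny_params(seed=12)
        truth = simulate_community(p)
        _, plates = simulate_isolation(truth)
        recs = culturability_ratio(plates)
        by_group = {(r.sample_group, r.medium): r.culturability_pct for r in recs}
        for (group, _), pct in by_group.items():
            treatment = group.split("_")[1]
            planted = p.culturability_targets[treatment]
            assert pct == pytest.approx(100 * planted, abs=1e-9)

    def test_strain_variants_stay_outside_amplicon_window(self, small_sim):
        params, truth, _, isolates, _ = small_sim
        start, end = params.amplicon_window
        for r in isolates:
            if r.isolate_id.startswith("ISO") and len(r.sequence) == params.gene_length:
                # every emitted isolate still contains its taxon's exact slice
                slices = set(truth.asv_sequence_of_taxon.values()) | {
                    g[start:end] for g in truth.decoy_genes.values()
                }
                assert any(s in r.sequence for s in slices)
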