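"""Instrument selection: threshold and concordance filters, greedy LD
clumping, region exclusion, and the colocalisation-based pleiotropy filter."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cismr.instruments import (
    select_cis, select_genomewide, clump, filter_pleiotropy, attach_outcome,
    with_biomarker_exposure,
)
from cismr.simulate import LdPanel, make_ld_panel, make_study
from cismr.sumstats import Region
from cismr.coloc import ColocResult
from conftest import make_sumstats


def ld_panel_from_r2(ids, r2_pairs, pos=None):
    """Build a small panel with given pairwise r^2 (positive r)."""
    k = len(ids)
    R = np.eye(k)
    index = {v: i for i, v in enumerate(ids)}
    for (a, b), r2 in r2_pairs.items():
        r = np.sqrt(r2)
        R[index[a], index[b]] = R[index[b], index[a]] = r
    return LdPanel(np.array(ids, object), np.array(["1"] * k, object),
                   np.array(pos if pos is not None else range(100, 100 + 10 * k, 10)),
                   np.array(["A"] * k, object), np.array(["G"] * k, object),
                   np.array([0.3] * k), R)


def candidates(ids, pvalues, pos=None):
    return pd.DataFrame({
        "variant_id": ids, "pvalue": pvalues,
        "pos": pos if pos is not None else range(100, 100 + 10 * len(ids), 10),
    })


class TestClump:
    def test_unlinked_all_retained(self):
        panel = ld_panel_from_r2(["a", "b", "c"], {})
        out = clump(candidates(["a", "b", "c"], [1e-8, 1e-7, 1e-6]), panel, 0.1)
        assert list(out["variant_id"]) == ["a", "b", "c"]

    def test_greedy_keeps_smallest_p(self):
        panel = ld_panel_from_r2(["a", "b"], {("a", "b"): 0.5})
        out = clump(candidates(["a", "b"], [1e-8, 1e-6]), panel, 0.1)
        assert list(out["variant_id"]) == ["a"]

    def test_chain_hand_trace(self):
        # a-b r2=0.3, b-c r2=0.3, a-c r2=0: greedy retains {a, c}
        panel = ld_panel_from_r2(["a", "b", "c"],
                                 {("a", "b"): 0.3, ("b", "c"): 0.3})
        out = clump(candidates(["a", "b", "c"], [1e-9, 1e-7, 1e-5]), panel, 0.1)
        assert list(out["variant_id"]) == ["a", "c"]

    def test_r2_boundary_strict(self):
        # r2 exactly at the threshold is retained ("r2 > 0.1" rule)
        panel = ld_panel_from_r2(["a", "b"], {("a", "b"): 0.1})
        out = clump(candidates(["a", "b"], [1e-8, 1e-6]), panel, 0.1)
        assert list(out["variant_id"]) == ["a", "b"]

    def test_missing_candidate_is_hard_error(self):
        panel = ld_panel_from_r2(["a"], {})
        with pytest.raises(KeyError, match="ghost"):
            clump(candidates(["a", "ghost"], [1e-8, 1e-6]), panel, 0.1)

    def test_p_tie_broken_by_position(self):
        panel = ld_panel_from_r2(["a", "b"], {("a", "b"): 0.5})
        out = clump(candidates(["a", "b"], [1e-8, 1e-8]), panel, 0.1)
        assert list(out["variant_id"]) == ["a"]  # equal p: smaller position leads

    @given(st.integers(0, 2**31 - 1))
    def test_no_retained_pair_violates_threshold(self, seed):
        rng = np.random.default_rng(seed)
        panel = make_ld_panel(20, 0.9, seed=seed % 1000)
        cand = candidates(list(panel.variant_ids), rng.uniform(1e-10, 1e-5, 20),
                          pos=list(panel.positions))
        out = clump(cand, panel, 0.1)
        R = panel.submatrix(out["variant_id"].tolist())
        off = R[~np.eye(len(out), dtype=bool)]
        assert np.all(off**2 <= 0.1 + 1e-12)


@pytest.fixture
def cis_setup():
    """Disease + biomarker over a 4-variant unlinked region."""
    ids = ["rs1", "rs2", "rs3", "rs4"]
    panel = ld_panel_from_r2(ids, {})
    disease = make_sumstats(ids, [0.2, 0.2, 0.2, 0.2], [0.02, 0.02, 0.02, 0.02],
                            trait="t2d", trait_type="binary")
    region = Region("GENE", "1", 100, 130)
    return ids, panel, disease, region


class TestSelectCis:
    def test_concordant_significant_variant_retained(self, cis_setup):
        ids, panel, disease, region = cis_setup
        bio = make_sumstats(ids, [0.05, 0.05, 0.05, 0.05], [0.02] * 4, trait="hba1c")
        inst = select_cis(disease, bio, region, panel=panel)
        assert set(inst.table["variant_id"]) == set(ids)
        assert inst.exposure_scale == "per-1-unit-higher-log-odds"

    def test_discordant_direction_removed(self, cis_setup):
        ids, panel, disease, region = cis_setup
        bio = make_sumstats(ids, [0.05, -0.05, 0.05, 0.05], [0.02] * 4, trait="hba1c")
        inst = select_cis(disease, bio, region, panel=panel)
        assert "rs2" not in set(inst.table["variant_id"])
        assert dict(inst.provenance)["concordant_direction"] == 1

    def test_exposure_p_boundary_strict(self, cis_setup):
        # p exactly 5e-6 fails the strict "<" rule
        ids, panel, _, region = cis_setup
        disease = make_sumstats(ids, [0.2] * 4, [0.02] * 4, trait="t2d",
                                trait_type="binary")
        disease.table.loc[1, "pvalue"] = 5e-6  # rs2 sits exactly at the threshold
        bio = make_sumstats(ids, [0.05] * 4, [0.02] * 4, trait="hba1c")
        inst = select_cis(disease, bio, region, panel=panel)
        assert "rs2" not in set(inst.table["variant_id"])

    def test_biomarker_p_filter(self, cis_setup):
        ids, panel, disease, region = cis_setup
        bio = make_sumstats(ids, [0.05, 0.01, 0.05, 0.05], [0.02] * 4, trait="hba1c")
        # rs2 biomarker p = 0.617 > 0.05
        inst = select_cis(disease, bio, region, panel=panel)
        assert "rs2" not in set(inst.table["variant_id"])

    def test_empty_set_allowed(self, cis_setup):
        ids, panel, _, region = cis_setup
        disease = make_sumstats(ids, [0.001] * 4, [0.02] * 4, trait="t2d",
                                trait_type="binary")
        bio = make_sumstats(ids, [0.05] * 4, [0.02] * 4, trait="hba1c")
        inst = select_cis(disease, bio, region, panel=panel)
        assert inst.is_empty
        assert inst.provenance  # provenance trail still present

    def test_provenance_counts_sum(self, cis_setup):
        ids, panel, disease, region = cis_setup
        bio = make_sumstats(ids, [0.05, -0.05, 0.01, 0.05], [0.02] * 4, trait="hba1c")
        inst = select_cis(disease, bio, region, panel=panel)
        removed = sum(n for _, n in inst.provenance)
        assert removed == len(disease) - len(inst)

    def test_filters_commute(self, cis_setup):
        # p-threshold and concordance are independent row filters: the final
        # set does not depend on their order; provenance records the order
        ids, panel, disease, region = cis_setup
        bio = make_sumstats(ids, [0.05, -0.05, 0.001, 0.05], [0.02] * 4, trait="hba1c")
        inst = select_cis(disease, bio, region, panel=panel)
        # manual reverse order
        from cismr.sumstats import harmonise_pair, extract_region
        pair = harmonise_pair(extract_region(disease, region), bio)
        m = pair[np.sign(pair["beta_1"]) == np.sign(pair["beta_2"])]
        m = m[(m["pvalue_1"] < 5e-6) & (m["pvalue_2"] < 0.05)]
        assert set(inst.table["variant_id"]) == set(m["variant_id"])


class TestSelectGenomewide:
    def test_excluded_region_variants_absent(self, study_layout):
        study = make_study(3, layout=study_layout)
        inst = select_genomewide(study.disease, study.biomarker, study.regions,
                                 panel=study.panel)
        assert not inst.is_empty
        for region in study.regions:
            assert not region.contains(inst.table["chrom"].to_numpy(object),
                                       inst.table["pos"].to_numpy()).any()

    def test_all_qualifying_inside_exclusions_gives_empty(self, cis_setup):
        ids, panel, disease, region = cis_setup
        bio = make_sumstats(ids, [0.05] * 4, [0.02] * 4, trait="hba1c")
        inst = select_genomewide(disease, bio, [Region("GENE", "1", 1, 10_000)],
                                 panel=panel)
        assert inst.is_empty

    def test_boundary_one_bp_outside(self, cis_setup):
        ids, panel, disease, _ = cis_setup
        bio = make_sumstats(ids, [0.05] * 4, [0.02] * 4, trait="hba1c")
        # exclusion covers pos 100..129; rs4 at 130 is 1 bp outside
        inst = select_genomewide(disease, bio, [Region("GENE", "1", 100, 129)],
                                 panel=panel)
        assert set(inst.table["variant_id"]) == {"rs4"}


class TestFilterPleiotropy:
    def _conditional(self, top):
        return ColocResult(pp=np.array([0, 0, 0, 0.1, 0.9]), labf1=np.array([0.0]),
                           labf2=np.array([0.0]), variant_ids=np.array(["x"], object),
                           positions=np.array([1]), top1="x", top2="x", n_variants=1,
                           masked=(top,), conditioned_on=top)

    def test_no_conditional_is_identity(self, cis_setup):
        ids, panel, disease, region = cis_setup
        bio = make_sumstats(ids, [0.05] * 4, [0.02] * 4, trait="hba1c")
        inst = select_cis(disease, bio, region, panel=panel)
        out = filter_pleiotropy(inst, None, panel=panel)
        pd.testing.assert_frame_equal(out.table, inst.table)
        assert out.provenance[-1] == ("pleiotropy_filter", 0)

    def test_linked_instrument_removed(self):
        ids = ["rs1", "rs2", "rs3"]
        panel = ld_panel_from_r2(ids, {("rs1", "rs2"): 0.5})
        disease = make_sumstats(ids, [0.2] * 3, [0.02] * 3, trait="t2d",
                                trait_type="binary")
        bio = make_sumstats(ids, [0.05] * 3, [0.02] * 3, trait="hba1c")
        inst = select_cis(disease, bio, Region("G", "1", 1, 10_000), panel=panel)
        out = filter_pleiotropy(inst, self._conditional("rs1"), panel=panel, r2_mask=0.2)
        assert set(out.table["variant_id"]) == {"rs3"}

    def test_r2_boundary_retained(self):
        # r = 0.5 gives r2 exactly 0.25: not strictly greater, so retained
        ids = ["rs1", "rs2"]
        panel = ld_panel_from_r2(ids, {("rs1", "rs2"): 0.25})
        disease = make_sumstats(ids, [0.2] * 2, [0.02] * 2, trait="t2d",
                                trait_type="binary")
        bio = make_sumstats(ids, [0.05] * 2, [0.02] * 2, trait="hba1c")
        inst = select_cis(disease, bio, Region("G", "1", 1, 10_000), panel=panel,
                          r2_clump=0.5)
        out = filter_pleiotropy(inst, self._conditional("rs1"), panel=panel,
                                r2_mask=0.25)
        assert set(out.table["variant_id"]) == {"rs2"}

    def test_filter_moves_estimate_toward_truth(self, panel50):
        # one shared causal variant (slope -0.25 per log-odds) plus a stronger
        # outcome-only signal in LD with part of the instrument set: removing
        # instruments that tag the outcome-specific signal should usually move
        # the IVW estimate toward the simulated truth
        import numpy as np
        from cismr.simulate import TraitSpec, simulate_trait
        from cismr.coloc import conditional_coloc
        from cismr.sumstats import harmonise_pair, extract_region
        from cismr.mr import ivw, rescale_per_halving

        region = Region("GENE", "1", int(panel50.positions[0]), int(panel50.positions[-1]))
        d_spec = TraitSpec(1_407_282, "binary", 0.162, "t2d")
        b_spec = TraitSpec(344_182, "quantitative", name="hba1c")
        o_spec = TraitSpec(343_992, "quantitative", name="sbp")
        slope = -0.25
        truth = -slope * np.log(2)
        wins, used = 0, 0
        for rep in range(60):
            rng = np.random.default_rng(10_000 + rep)
            disease = simulate_trait(panel50, d_spec, {25: 0.15}, rng)
            biomark = simulate_trait(panel50, b_spec, {25: 0.045}, rng)
            outcome = simulate_trait(panel50, o_spec,
                                     {25: slope * 0.15, 14: -0.06}, rng)
            pair = harmonise_pair(extract_region(disease, region), outcome)
            cond = conditional_coloc(pair, panel=panel50, r2_mask=0.2)
            pre = select_cis(disease, biomark, region, panel=panel50)
            post = filter_pleiotropy(pre, cond, panel=panel50, r2_mask=0.2)
            pre = attach_outcome(pre, outcome)
            post = attach_outcome(post, outcome)
            if post.is_empty or len(post) == len(pre):
                continue
            used += 1
            e_pre = rescale_per_halving(ivw(pre)).beta
            e_post = rescale_per_halving(ivw(post)).beta
            if abs(e_post - truth) < abs(e_pre - truth):
                wins += 1
        assert used >= 30
        assert wins / used >= 0.7


def test_biomarker_exposure_swap(cis_setup):
    ids, panel, disease, region = cis_setup
    bio = make_sumstats(ids, [0.05] * 4, [0.02] * 4, trait="hba1c")
    inst = select_cis(disease, bio, region, panel=panel)
    swapped = with_biomarker_exposure(inst, "hba1c")
    assert np.allclose(swapped.table["beta_exp"], inst.table["beta_bio"])
    assert swapped.exposure_scale == "per-1-SD-higher-hba1c"


def test_attach_outcome_harmonises_alleles(cis_setup):
    ids, panel, disease, region = cis_setup
    bio = make_sumstats(ids, [0.05] * 4, [0.02] * 4, trait="hba1c")
    inst = select_cis(disease, bio, region, panel=panel)
    # outcome coded on the swapped allele: beta must flip sign on attach
    outcome = make_sumstats(ids, [0.3] * 4, [0.02] * 4, trait="out",
                            ea=["G"] * 4, nea=["A"] * 4, eaf=[0.7] * 4)
    out = attach_outcome(inst, outcome)
    assert np.allclose(out.table["beta_out"], -0.3)
    assert out.outcome_trait == "out"
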