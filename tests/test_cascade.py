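"""Filter-cascade behaviour: stages, oracle equivalence, commuting filters."""

import itertools

import pytest

from trioprior import cascade
from trioprior.cascade import (
    FilterConfig,
    chance_cosegregation_prob,
    classify_predictions,
    frequency_filter,
    panel_filter,
    prioritize,
    segregation_filter,
    segregates_dominant,
)
from trioprior.exceptions import NoScoresError, PedigreeError
from trioprior.model import FrequencyTable, PredictorScores, Variant
from trioprior.simulate import SimConfig, pedigree_for_shape, simulate_family
from tests.conftest import coseg_genotypes, make_family_a_pedigree

GT_STATES = [(0, 0), (0, 1), (1, 1), (None, None)]


def bruteforce_segregates(genotypes, affected, unaffected, policy):
    """Literal rule: present in all affecteds, absent in all unaffecteds."""
    for sid in affected + unaffected:
        if None in genotypes[sid] and policy == "strict":
            return False
    for sid in affected:
        if None in genotypes[sid]:
            continue
        if 1 not in genotypes[sid]:
            return False
    for sid in unaffected:
        if None in genotypes[sid]:
            continue
        if 1 in genotypes[sid]:
            return False
    return True


class TestSegregation:
    def test_trio_patterns(self):
        ped = pedigree_for_shape("trio")
        cfg = FilterConfig()

        def verdict(gts):
            v = Variant("chr1", 100, "A", "G", genotypes=gts)
            return segregates_dominant(v, ped, cfg)[0]

        assert verdict({"I:1": (0, 0), "I:2": (0, 1), "II:1": (0, 1)})
        assert not verdict({"I:1": (0, 0), "I:2": (0, 1), "II:1": (0, 0)})
        assert not verdict({"I:1": (0, 1), "I:2": (0, 1), "II:1": (0, 1)})

    def test_hom_alt_affected_passes(self):
        # presence means >= 1 alt allele; zygosity is not constrained
        ped = pedigree_for_shape("trio")
        v = Variant("chr1", 100, "A", "G",
                    genotypes={"I:1": (0, 0), "I:2": (1, 1), "II:1": (0, 1)})
        assert segregates_dominant(v, ped, FilterConfig())[0]

    def test_no_unaffected_samples_is_hard_error(self):
        from trioprior.model import PedSample, Pedigree

        ped = Pedigree([PedSample("A", None, None, 1, True)])
        v = Variant("chr1", 100, "A", "G", genotypes={"A": (0, 1)})
        with pytest.raises(PedigreeError):
            segregates_dominant(v, ped, FilterConfig())

    @pytest.mark.parametrize("shape", ["trio", "family_c", "family_b"])
    @pytest.mark.parametrize("policy", ["strict", "lenient"])
    def test_exhaustive_equivalence_with_bruteforce_oracle(self, shape, policy):
        ped = pedigree_for_shape(shape)
        cfg = FilterConfig(missing_policy=policy)
        sids = ped.sample_ids
        for states in itertools.product(GT_STATES, repeat=len(sids)):
            gts = dict(zip(sids, states))
            v = Variant("chr1", 100, "A", "G", genotypes=gts)
            expected = bruteforce_segregates(
                gts, ped.affected_ids, ped.unaffected_ids, policy
            )
            assert segregates_dominant(v, ped, cfg)[0] == expected, gts


class TestPanelFilter:
    def test_boundaries_and_summary(self, panel):
        gts = coseg_genotypes()
        inside = Variant("chr1", 147380102, "T", "C", genotypes=gts)
        left = Variant("chr1", 147379240, "T", "C", genotypes=gts)  # 0-based start
        off = Variant("chr7", 5, "T", "C", genotypes=gts)
        hits, summary = panel_filter([inside, left, off], panel)
        assert [(v.pos, g) for v, g in hits] == [(147380102, "GJA8")]
        assert summary == (1, 1)

    def test_empty_input(self, panel):
        assert panel_filter([], panel) == ([], (0, 0))


class TestFrequencyFilter:
    def test_common_variant_excluded_rare_retained(self, family_a):
        kept = frequency_filter(family_a["variants"][:6], family_a["frequencies"])
        assert [v.vid for v in kept] == ["rs28931605"]

    def test_novel_variant_retained(self):
        v = Variant("chr1", 5, "A", "G")
        assert frequency_filter([v], FrequencyTable({})) == [v]

    def test_maf_exactly_at_threshold_retained(self):
        v = Variant("chr1", 5, "A", "G")
        table = FrequencyTable({("chr1", 5, "A", "G"): (1, 10000)})
        cfg = FilterConfig(maf_threshold=1e-4)
        assert frequency_filter([v], table, cfg) == [v]
        just_over = FrequencyTable({("chr1", 5, "A", "G"): (2, 10000)})
        assert frequency_filter([v], just_over, cfg) == []

    def test_maf_is_folded(self):
        # a 54.69% alt fraction is a 45.31% minor allele frequency
        v = Variant("chr4", 6280000, "A", "G")
        table = FrequencyTable({v.key: (4703, 8600)})
        assert table.maf(v) == pytest.approx(1 - 4703 / 8600)


class TestClassifyPredictions:
    def test_gja8_c20_all_tools_damaging(self, published_scores):
        verdicts = classify_predictions(published_scores[("chr1", 147380102, "T", "C")])
        assert verdicts["sift"] == "not tolerated"
        assert verdicts["polyphen2"] == "probably damaging"
        assert verdicts["pmut"] == "pathological"
        assert verdicts["panther"] == "deleterious"
        assert verdicts["ponp2"] == "pathogenic"
        assert verdicts["mutpred"] == "deleterious"
        assert verdicts["damaging_count"] == 6
        assert verdicts["panther_pdel_concordant"] is True

    def test_gja8_c293_damaging_with_ponp2_unknown(self, published_scores):
        verdicts = classify_predictions(published_scores[("chr1", 147380375, "A", "C")])
        assert verdicts["sift"] == "not tolerated"
        assert verdicts["polyphen2"] == "probably damaging"
        assert verdicts["pmut"] == "pathological"
        assert verdicts["ponp2"] == "unknown"  # 0.444 ± 0.090 straddles 0.5
        assert verdicts["damaging_count"] == 5

    def test_crygd_tolerated_benign_neutral(self, published_scores):
        verdicts = classify_predictions(published_scores[("chr2", 208989018, "C", "A")])
        assert verdicts["sift"] == "tolerated"
        assert verdicts["polyphen2"] == "benign"
        assert verdicts["pmut"] == "neutral"
        assert verdicts["panther"] == "neutral"
        assert verdicts["ponp2"] == "unknown"
        assert verdicts["mutpred"] == "deleterious"  # 0.840 > 0.5

    def test_sift_boundary_is_strict(self):
        assert classify_predictions(PredictorScores(sift=0.05))["sift"] == "tolerated"
        assert classify_predictions(PredictorScores(sift=0.049))["sift"] == "not tolerated"

    def test_no_scores_is_typed_error(self):
        with pytest.raises(NoScoresError):
            classify_predictions(PredictorScores())


class TestPrioritize:
    def test_family_a_single_candidate(self, family_a, panel, transcripts):
        trails = prioritize(
            family_a["variants"], family_a["pedigree"], panel,
            family_a["frequencies"], transcripts,
        )
        cands = [t for t in trails if t.final == "candidate"]
        assert len(cands) == 1
        t = cands[0]
        assert t.gene == "CRYGD"
        assert t.consequence.hgvs_c == "c.70C>A"
        assert t.consequence.hgvs_p == "p.Pro24Thr"
        reasons = {t.variant.vid: t.exclusion_reason for t in trails}
        assert reasons["rs1000006"] == "not in panel"
        assert "co-segregate" in reasons["rs1000005"]
        assert "MAF" in reasons["rs3740030"]

    def test_no_panel_overlap_all_excluded(self, family_a):
        from trioprior.model import GenePanel, PanelRegion

        decoy = GenePanel([PanelRegion("ZZZ", "chr22", 1, 2)])
        trails = prioritize(
            family_a["variants"], family_a["pedigree"], decoy, family_a["frequencies"]
        )
        assert all(t.final == "excluded" for t in trails)
        assert all(t.exclusion_reason == "not in panel" for t in trails)

    def test_annotation_stages_never_change_verdict(
        self, family_a, panel, transcripts, alignments, published_scores
    ):
        bare = prioritize(
            family_a["variants"], family_a["pedigree"], panel, family_a["frequencies"]
        )
        full = prioritize(
            family_a["variants"], family_a["pedigree"], panel,
            family_a["frequencies"], transcripts, published_scores, alignments,
        )
        verdict = lambda ts: {t.variant.key: t.final for t in ts}
        assert verdict(bare) == verdict(full)
        # and the advisory fields actually got filled in the full run
        cand = [t for t in full if t.final == "candidate"][0]
        # CRYGD scored tolerated/benign/neutral by all tools except MutPred
        assert cand.predictions["damaging_count"] == 1
        assert cand.conservation == pytest.approx(1 / 6)

    @pytest.mark.parametrize("seed", [3, 11, 27])
    def test_filter_order_independence(self, panel, seed):
        sim = simulate_family(SimConfig(seed=seed, n_background=60,
                                        genotype_error_rate=0.05), panel)
        cfg = FilterConfig()

        def f_panel(vs):
            return [v for v, _ in panel_filter(vs, panel)[0]]

        def f_seg(vs):
            return segregation_filter(vs, sim.pedigree, cfg)

        def f_freq(vs):
            return frequency_filter(vs, sim.frequencies, cfg)

        results = set()
        for order in itertools.permutations([f_panel, f_seg, f_freq]):
            vs = sim.variants
            for f in order:
                vs = f(vs)
            results.add(frozenset(v.key for v in vs))
        assert len(results) == 1

    @pytest.mark.parametrize("seed", [5, 19])
    def test_maf_threshold_monotonicity(self, panel, seed):
        sim = simulate_family(SimConfig(seed=seed, n_background=80), panel)
        prev = None
        for thr in [0.5, 0.05, 1e-3, 1e-4, 0.0]:
            cfg = FilterConfig(maf_threshold=thr)
            cands = {
                t.variant.key
                for t in prioritize(sim.variants, sim.pedigree, panel,
                                    sim.frequencies, cfg=cfg)
                if t.final == "candidate"
            }
            if prev is not None:
                assert cands <= prev
            prev = cands

    def test_adding_unaffected_carrier_never_adds_candidates(self, family_a, panel):
        import dataclasses

        from trioprior.model import PedSample, Pedigree

        ped = family_a["pedigree"]
        base = {
            t.variant.key
            for t in prioritize(family_a["variants"], ped, panel, family_a["frequencies"])
            if t.final == "candidate"
        }
        # new unaffected sample who carries every variant an affected carries
        ped2 = Pedigree(ped.samples + [PedSample("X:1", None, None, 1, False)])
        variants2 = [
            dataclasses.replace(v, genotypes={**v.genotypes, "X:1": v.genotypes["I:2"]})
            for v in family_a["variants"]
        ]
        bigger = {
            t.variant.key
            for t in prioritize(variants2, ped2, panel, family_a["frequencies"])
            if t.final == "candidate"
        }
        assert bigger <= base


class TestChanceCosegregation:
    def test_more_informative_families_have_lower_chance_rate(self):
        trio = pedigree_for_shape("trio")
        fam_b = pedigree_for_shape("family_b")
        for maf in (0.01, 0.1, 0.3, 0.5):
            assert chance_cosegregation_prob(maf, fam_b) < \
                chance_cosegregation_prob(maf, trio)

    def test_zero_maf_never_cosegregates_by_chance(self):
        assert chance_cosegregation_prob(0.0, pedigree_for_shape("trio")) == 0.0
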