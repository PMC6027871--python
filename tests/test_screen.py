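import numpy as np
import pytest

from diagmark.io import (
    GenotypeMatrix,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    MaskedSequence,
    PopMap,
    SiteRecord,
)
from diagmark.screen import (
    Candidate,
    STAGE_FIXED_DIFFERENCE,
    STAGE_FLANK,
    STAGE_HYBRID_HET,
    ScreenConfig,
    fixed_difference_screen,
    flank_filter,
    hybrid_heterozygosity_screen,
    run_screen,
)

CONFIG = ScreenConfig()


def two_species_matrix(col_a, col_b, col_h, pos=100, n_sites=1):
    """7 SK + 6 WT + 17 hybrid individuals at one site."""
    calls = np.array([[c] for c in [col_a] * 7 + [col_b] * 6 + [col_h] * 17],
                     dtype=np.int8)
    individuals = (
        [f"SK{i}" for i in range(7)]
        + [f"WT{i}" for i in range(6)]
        + [f"SW{i}" for i in range(9)]
        + [f"WS{i}" for i in range(8)]
    )
    groups = ["SK"] * 7 + ["WT"] * 6 + ["SW"] * 9 + ["WS"] * 8
    matrix = GenotypeMatrix(
        individuals=individuals,
        sites=[SiteRecord("c1", pos, "s0", "A", "G")],
        calls=calls,
    )
    return matrix, PopMap(assignments=dict(zip(individuals, groups)))


class TestFixedDifferenceScreen:
    def test_reciprocal_fixation_kept_with_allele_assignment(self):
        matrix, popmap = two_species_matrix(HOM_REF, HOM_ALT, HET)
        out = fixed_difference_screen(matrix, popmap, CONFIG)
        assert len(out) == 1
        assert (out[0].allele_species_a, out[0].allele_species_b) == ("A", "G")

    def test_swapped_fixation_assigns_alt_to_species_a(self):
        matrix, popmap = two_species_matrix(HOM_ALT, HOM_REF, HET)
        out = fixed_difference_screen(matrix, popmap, CONFIG)
        assert (out[0].allele_species_a, out[0].allele_species_b) == ("G", "A")

    def test_heterozygous_parental_rejected(self):
        matrix, popmap = two_species_matrix(HOM_REF, HOM_ALT, HET)
        matrix.calls[0, 0] = HET  # one SK individual
        assert fixed_difference_screen(matrix, popmap, CONFIG) == []

    def test_same_allele_in_both_species_rejected(self):
        matrix, popmap = two_species_matrix(HOM_REF, HOM_REF, HET)
        assert fixed_difference_screen(matrix, popmap, CONFIG) == []

    def test_call_rate_gate(self):
        matrix, popmap = two_species_matrix(HOM_REF, HOM_ALT, HET)
        matrix.calls[0:2, 0] = MISSING  # SK call rate 5/7 < 0.85
        assert fixed_difference_screen(matrix, popmap, CONFIG) == []
        one_missing, popmap = two_species_matrix(HOM_REF, HOM_ALT, HET)
        one_missing.calls[0, 0] = MISSING  # 6/7 = 0.857 passes
        assert len(fixed_difference_screen(one_missing, popmap, CONFIG)) == 1

    def test_strict_missing_mode(self):
        matrix, popmap = two_species_matrix(HOM_REF, HOM_ALT, HET)
        matrix.calls[0, 0] = MISSING
        strict = ScreenConfig(require_no_missing=True)
        assert fixed_difference_screen(matrix, popmap, strict) == []


class TestHybridHeterozygosityScreen:
    def _candidates(self, matrix, popmap):
        return fixed_difference_screen(matrix, popmap, CONFIG)

    def test_all_hybrids_het_kept(self):
        matrix, popmap = two_species_matrix(HOM_REF, HOM_ALT, HET)
        cands = self._candidates(matrix, popmap)
        assert len(hybrid_heterozygosity_screen(cands, matrix, popmap, CONFIG)) == 1

    def test_single_homozygous_hybrid_rejected(self):
        matrix, popmap = two_species_matrix(HOM_REF, HOM_ALT, HET)
        cands = self._candidates(matrix, popmap)
        matrix.calls[-1, 0] = HOM_ALT
        assert hybrid_heterozygosity_screen(cands, matrix, popmap, CONFIG) == []

    def test_missing_hybrid_tolerated_under_call_rate_gate(self):
        # one of 17 hybrids missing; per-group rates 9/9 and 7/8 pass 0.85
        matrix, popmap = two_species_matrix(HOM_REF, HOM_ALT, HET)
        cands = self._candidates(matrix, popmap)
        matrix.calls[-1, 0] = MISSING
        kept = hybrid_heterozygosity_screen(cands, matrix, popmap, CONFIG)
        assert len(kept) == 1
        assert kept[0].n_called["WS"] == 7

    def test_strict_missing_rejects_missing_hybrid(self):
        matrix, popmap = two_species_matrix(HOM_REF, HOM_ALT, HET)
        cands = self._candidates(matrix, popmap)
        matrix.calls[-1, 0] = MISSING
        strict = ScreenConfig(require_no_missing=True)
        assert hybrid_heterozygosity_screen(cands, matrix, popmap, strict) == []


def _flank_inputs(pos=100, contig_len=300, other_positions=(), masked=()):
    bases = list("ACGT" * (contig_len // 4 + 1))[:contig_len]
    bases[pos - 1] = "A"
    for p in masked:
        bases[p - 1] = bases[p - 1].lower()
    seq = MaskedSequence("c1", "".join(bases))
    site = SiteRecord("c1", pos, "cand", "A", "G")
    cand = Candidate(site_index=0, site=site, allele_species_a="A",
                     allele_species_b="G")
    all_sites = [site] + [
        SiteRecord("c1", p, f"other{p}", "C", "T") for p in sorted(other_positions)
    ]
    all_sites.sort(key=lambda s: s.pos)
    return [cand], [seq], all_sites


class TestFlankFilter:
    def test_clean_flanks_become_marker(self):
        cands, ref, sites = _flank_inputs()
        markers = flank_filter(cands, ref, sites, CONFIG)
        assert len(markers) == 1
        m = markers[0]
        assert len(m.flank_left) == len(m.flank_right) == 40
        assert m.flank_left == ref[0].bases[59:99]
        assert m.flank_right == ref[0].bases[100:140]

    def test_neighbor_at_40_rejected_at_41_kept(self):
        cands, ref, sites = _flank_inputs(other_positions=(140,))  # distance 40
        assert flank_filter(cands, ref, sites, CONFIG) == []
        cands, ref, sites = _flank_inputs(other_positions=(141,))  # distance 41
        assert len(flank_filter(cands, ref, sites, CONFIG)) == 1

    def test_left_neighbor_boundary(self):
        cands, ref, sites = _flank_inputs(other_positions=(60,))  # distance 40
        assert flank_filter(cands, ref, sites, CONFIG) == []
        cands, ref, sites = _flank_inputs(other_positions=(59,))
        assert len(flank_filter(cands, ref, sites, CONFIG)) == 1

    def test_single_masked_flank_base_rejected(self):
        cands, ref, sites = _flank_inputs(masked=(110,))
        assert flank_filter(cands, ref, sites, CONFIG) == []

    def test_insufficient_left_flank_rejected(self):
        cands, ref, sites = _flank_inputs(pos=30)
        assert flank_filter(cands, ref, sites, CONFIG) == []

    def test_insufficient_right_flank_rejected(self):
        cands, ref, sites = _flank_inputs(pos=280, contig_len=300)
        assert flank_filter(cands, ref, sites, CONFIG) == []

    def test_reference_allele_discordance_warns_and_rejects(self):
        cands, ref, sites = _flank_inputs()
        bases = list(ref[0].bases)
        bases[99] = "C"  # neither ref A nor alt G
        ref[0].bases = "".join(bases)
        with pytest.warns(UserWarning, match="reference base"):
            assert flank_filter(cands, ref, sites, CONFIG) == []

    def test_absent_contig_raises(self):
        cands, _, sites = _flank_inputs()
        with pytest.raises(KeyError, match="c1"):
            flank_filter(cands, [MaskedSequence("c2", "ACGT")], sites, CONFIG)


class TestRunScreen:
    def test_truth_table_recovery(self, clean_sim):
        _, res = clean_sim
        result = run_screen(res.matrix, res.popmap, res.reference)
        found = {m.site.id for m in result.markers}
        expected = set(res.truth.loc[res.truth["verdict"] == "pass", "site_id"])
        assert found == expected

    def test_stage_counts_non_increasing(self, clean_sim):
        _, res = clean_sim
        counts = run_screen(res.matrix, res.popmap, res.reference).stage_counts
        assert (
            counts["input_sites"]
            >= counts[STAGE_FIXED_DIFFERENCE]
            >= counts[STAGE_HYBRID_HET]
            >= counts[STAGE_FLANK]
        )

    def test_each_confounder_rejected_at_its_designed_stage(self, clean_sim):
        _, res = clean_sim
        matrix, popmap, reference = res.matrix, res.popmap, res.reference
        fixed = fixed_difference_screen(matrix, popmap, CONFIG)
        obligate = hybrid_heterozygosity_screen(fixed, matrix, popmap, CONFIG)
        markers = flank_filter(obligate, reference, matrix.sites, CONFIG)
        survived = {
            STAGE_FIXED_DIFFERENCE: {c.site.id for c in fixed},
            STAGE_HYBRID_HET: {c.site.id for c in obligate},
            STAGE_FLANK: {m.site.id for m in markers},
        }
        confounders = res.truth[
            res.truth["category"].isin(
                ["flank_variant", "masked_flank", "contig_edge",
                 "non_het_hybrid", "non_fixed_parental"]
            )
        ]
        order = [STAGE_FIXED_DIFFERENCE, STAGE_HYBRID_HET, STAGE_FLANK]
        for row in confounders.itertuples():
            fail_at = order.index(row.fail_stage)
            for k, stage in enumerate(order):
                if k < fail_at:  # survives every stage before its own
                    assert row.site_id in survived[stage], (row.category, stage)
                else:
                    assert row.site_id not in survived[stage], (row.category, stage)

    def test_emitted_markers_satisfy_screen_postconditions(self, clean_sim):
        _, res = clean_sim
        result = run_screen(res.matrix, res.popmap, res.reference)
        index = {s.id: j for j, s in enumerate(res.matrix.sites)}
        rows_by_group = {
            g: [i for i, ind in enumerate(res.matrix.individuals)
                if res.popmap.assignments[ind] == g]
            for g in ("SK", "WT", "SW", "WS")
        }
        for m in result.markers:
            assert set(m.flank_left + m.flank_right) <= set("ACGT")
            j = index[m.site.id]
            col = res.matrix.calls[:, j]
            for g in ("SK", "WT"):
                called = col[rows_by_group[g]]
                called = called[called != MISSING]
                assert (called != HET).all()
            for g in ("SW", "WS"):
                called = col[rows_by_group[g]]
                called = called[called != MISSING]
                assert (called == HET).all()

    def test_invariant_to_individual_order_and_label_renaming(self, noisy_sim):
        _, res = noisy_sim
        baseline = {
            m.site.id for m in run_screen(res.matrix, res.popmap, res.reference).markers
        }
        rng = np.random.default_rng(0)
        perm = rng.permutation(res.matrix.n_individuals)
        shuffled = GenotypeMatrix(
            individuals=[res.matrix.individuals[i] for i in perm],
            sites=res.matrix.sites,
            calls=res.matrix.calls[perm, :],
        )
        assert baseline == {
            m.site.id for m in run_screen(shuffled, res.popmap, res.reference).markers
        }
        renamed = PopMap(
            assignments={
                ind: {"SK": "sika", "WT": "wapiti", "SW": "f1a", "WS": "f1b"}[g]
                for ind, g in res.popmap.assignments.items()
            }
        )
        config = ScreenConfig(
            species_groups=("sika", "wapiti"), hybrid_groups=("f1a", "f1b")
        )
        assert baseline == {
            m.site.id
            for m in run_screen(res.matrix, renamed, res.reference, config).markers
        }

    def test_empty_matrix_yields_no_markers(self):
        matrix, popmap = two_species_matrix(HOM_REF, HOM_ALT, HET)
        empty = matrix.subset_sites([])
        ref = [MaskedSequence("c1", "ACGT" * 100)]
        assert run_screen(empty, popmap, ref).markers == []
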