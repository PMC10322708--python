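"""Family inference: scenario scoring, MN assignment, yield estimation."""

import numpy as np
import pandas as pd
import pytest

import hapdose as h
from hapdose.core import Family


def run_family(catalog, controls, refset, aneu, scenario, seed,
               include_nieces=True, family_id="F1"):
    fam, _ = h.simulate_family(
        catalog, scenario, n_control=0, seed=seed,
        include_nieces=include_nieces, family_id=family_id,
    )
    summ = h.quantify_cells(fam.cells, controls, catalog)
    states = h.classify_cells(summ, refset, aneu)
    return fam, summ, states


class TestEnumerateScenarios:
    def test_textbook_13_uniquely_supported(self, catalog, controls, refset,
                                            aneuploid_ref):
        sc = h.SegregationScenario("chr3", "B", "1:3", 1, 0.1)
        fam, _, states = run_family(catalog, controls, refset, aneuploid_ref, sc, 51)
        scored = h.enumerate_scenarios(fam, states)
        best = scored.iloc[0]
        assert (best["chrom"], best["haplotype"], best["pattern"]) == ("chr3", "B", "1:3")
        assert best["score"] > scored.iloc[1]["score"] or (
            scored.iloc[1]["chrom"], scored.iloc[1]["haplotype"]
        ) == ("chr3", "B")

    def test_flagless_family_scores_nothing(self, catalog, controls, refset,
                                            aneuploid_ref):
        sc = h.SegregationScenario("chr1", "A", "2:2", 1, 0.5)  # fully normal MN
        fam, _, states = run_family(catalog, controls, refset, aneuploid_ref, sc, 52)
        assert not states["flagged"].any()
        scored = h.enumerate_scenarios(fam, states)
        assert scored["n_informative"].sum() == 0

    def test_gen2_niece_loss_pins_13(self, catalog, controls, refset,
                                     aneuploid_ref):
        sc = h.SegregationScenario("chr5", "B", "1:3", 2, 0.5, split=1.0)
        fam, _, states = run_family(catalog, controls, refset, aneuploid_ref, sc, 53)
        best = h.enumerate_scenarios(fam, states).iloc[0]
        assert (best["chrom"], best["haplotype"], best["pattern"]) == ("chr5", "B", "1:3")
        assert best["n_silent_matches"] == 2  # both nieces

    def test_small_family_rejected(self, catalog, controls, refset, aneuploid_ref):
        sc = h.SegregationScenario("chr1", "A", "1:3", 1, 0.1)
        fam, _, states = run_family(catalog, controls, refset, aneuploid_ref, sc, 54)
        fam_broken = Family.__new__(Family)
        fam_broken.__dict__.update(fam.__dict__)
        fam_broken.cells = fam.cells[:1]
        with pytest.raises(ValueError, match="2 cells"):
            h.enumerate_scenarios(fam_broken, states)


class TestInferMNChromosome:
    def test_textbook_13_direct(self, catalog, controls, refset, aneuploid_ref):
        sc = h.SegregationScenario("chr2", "B", "1:3", 1, 0.0)
        fam, summ, states = run_family(catalog, controls, refset, aneuploid_ref, sc, 55)
        asg = h.infer_mn_chromosome(fam, states)
        assert (asg.chrom, asg.haplotype, asg.pattern) == ("chr2", "B", "1:3")
        assert asg.confidence == "direct"

    def test_invisible_normal(self, catalog):
        # a fully transcribing 2:2 MN chromosome leaves no footprint in any
        # family member: build the flag-free state table explicitly
        sc = h.SegregationScenario("chr4", "A", "2:2", 1, 0.5)
        fam, _ = h.simulate_family(catalog, sc, n_control=0, seed=56)
        rows = [
            {"cell_id": c.cell_id, "group": f"chr{k + 1}", "haplotype": hap,
             "yield": 0.5, "label": "1", "p_mono": 1.0, "p_di": 0.0,
             "flagged": False}
            for c in fam.cells for k in range(5) for hap in "AB"
        ]
        states = pd.DataFrame(rows)
        asg = h.infer_mn_chromosome(fam, states)
        assert asg.confidence == "invisible-normal"
        assert asg.chrom is None

    def test_no_niece_daughter_imbalance_template(self, catalog, controls,
                                                  refset, aneuploid_ref):
        # 1:3 in generation 2 without nieces: one daughter shows the extra,
        # normally transcribing copy (3:2-like imbalance)
        sc = h.SegregationScenario("chr3", "A", "1:3", 2, 0.5, split=1.0)
        fam, summ, states = run_family(
            catalog, controls, refset, aneuploid_ref, sc, 57, include_nieces=False
        )
        asg = h.infer_mn_chromosome(fam, states)
        assert asg.confidence == "inferred-without-nieces"
        assert (asg.chrom, asg.haplotype, asg.pattern) == ("chr3", "A", "1:3")

    def test_no_niece_silent_chromatid_both_daughters_dark(self, catalog,
                                                           controls, refset,
                                                           aneuploid_ref):
        # a ~ 0 in a 2:2 generation-2 family: both daughters lack the MN
        # haplotype; the silenced-chromatid conclusion still goes through
        sc = h.SegregationScenario("chr5", "B", "2:2", 2, 0.0, split=1.0)
        fam, summ, states = run_family(
            catalog, controls, refset, aneuploid_ref, sc, 58, include_nieces=False
        )
        asg = h.infer_mn_chromosome(fam, states)
        assert (asg.chrom, asg.haplotype, asg.pattern) == ("chr5", "B", "2:2")
        assert "silenced" in asg.notes

    def test_two_matching_chromosomes_unresolved(self, catalog, controls,
                                                 refset, aneuploid_ref):
        # adversarial: two simultaneous sister monosomies tie
        cells = [
            h.simulate_cell(
                catalog, {"chr1": (0.0, 0.5), "chr2": (0.5, 0.0)}, seed=59,
                cell_id="Fx_mn_sister", role="mn_sister", generation=1,
            ),
            h.simulate_cell(
                catalog, {"chr1": (1.0, 0.5), "chr2": (0.5, 1.0)}, seed=60,
                cell_id="Fx_mn_cell", role="mn_cell", generation=1,
            ),
        ]
        fam = Family(family_id="Fx", generation=1, cells=cells)
        summ = h.quantify_cells(cells, controls, catalog)
        states = h.classify_cells(summ, refset, aneuploid_ref)
        asg = h.infer_mn_chromosome(fam, states)
        assert asg.confidence == "unresolved"
        loci = {(c, hp) for c, hp, _ in asg.competing}
        assert {("chr1", "A"), ("chr2", "B")} <= loci

    def test_fully_transcribing_13_notes_reciprocal_ambiguity(
        self, catalog, controls, refset, aneuploid_ref
    ):
        sc = h.SegregationScenario("chr1", "A", "1:3", 1, 0.5)
        fam, _, states = run_family(catalog, controls, refset, aneuploid_ref, sc, 61)
        asg = h.infer_mn_chromosome(fam, states)
        assert (asg.chrom, asg.haplotype) == ("chr1", "A")
        assert any(p == "reciprocal" for _, _, p in asg.competing)

    def test_cell_order_invariance(self, catalog, controls, refset, aneuploid_ref):
        sc = h.SegregationScenario("chr2", "B", "2:2", 2, 0.2, split=0.5)
        fam, summ, states = run_family(catalog, controls, refset, aneuploid_ref, sc, 62)
        asg1 = h.infer_mn_chromosome(fam, states)
        fam_rev = Family(
            family_id=fam.family_id, generation=fam.generation,
            cells=list(reversed(fam.cells)), truth=fam.truth,
        )
        states_rev = states.iloc[::-1].reset_index(drop=True)
        asg2 = h.infer_mn_chromosome(fam_rev, states_rev)
        assert (asg1.chrom, asg1.haplotype, asg1.pattern) == (
            asg2.chrom, asg2.haplotype, asg2.pattern
        )


class TestYieldEstimation:
    def test_gen1_22_silent(self, catalog, controls, refset, aneuploid_ref):
        sc = h.SegregationScenario("chr3", "B", "2:2", 1, 0.0)
        fam, summ, states = run_family(catalog, controls, refset, aneuploid_ref, sc, 63)
        asg, est = h.analyze_family(fam, states, summ, refset)
        assert est.basis == "direct-2:2"
        assert est.classification == "near-silent"
        assert est.a == pytest.approx(0.0, abs=0.02)

    def test_gen2_22_combined_daughters(self, catalog, controls, refset,
                                        aneuploid_ref, rng):
        # fragments split across daughters; combined yield recovers a = 0.3
        sc = h.SegregationScenario("chr5", "A", "2:2", 2, 0.3, split=0.5)
        estimates = []
        for i in range(25):
            fam, summ, states = run_family(
                catalog, controls, refset, aneuploid_ref, sc, rng
            )
            asg, est = h.analyze_family(fam, states, summ, refset)
            if asg.confidence != "unresolved":
                estimates.append(est.a)
        assert np.mean(estimates) == pytest.approx(0.3, abs=0.03)
        assert est.basis == "combined-daughters"

    def test_gen2_13_per_daughter(self, catalog, controls, refset, aneuploid_ref):
        # a = 0.5 carried entirely by daughter 1 -> its yield ~1.0, sibling ~0.5
        sc = h.SegregationScenario("chr1", "B", "1:3", 2, 0.5, split=1.0)
        fam, summ, states = run_family(catalog, controls, refset, aneuploid_ref, sc, 65)
        asg, est = h.analyze_family(fam, states, summ, refset)
        assert est.basis == "per-daughter-vs-mono-and-di"
        assert est.a == pytest.approx(0.5, abs=0.05)
        assert est.classification == "normal"

    def test_gen1_13_vs_disomic(self, catalog, controls, refset, aneuploid_ref):
        sc = h.SegregationScenario("chr4", "A", "1:3", 1, 0.0)
        fam, summ, states = run_family(catalog, controls, refset, aneuploid_ref, sc, 66)
        asg, est = h.analyze_family(fam, states, summ, refset)
        assert est.basis == "vs-disomic-3:1"
        assert est.classification == "near-silent"

    def test_invisible_normal_has_no_point_estimate(self, catalog, controls,
                                                    refset, aneuploid_ref):
        sc = h.SegregationScenario("chr2", "A", "2:2", 1, 0.5)
        fam, summ, states = run_family(catalog, controls, refset, aneuploid_ref, sc, 67)
        asg, est = h.analyze_family(fam, states, summ, refset)
        assert asg.confidence == "invisible-normal"
        assert est.a is None and est.classification == "normal"

    def test_unresolved_assignment_rejected(self, refset):
        asg = h.MNAssignment(None, None, None, "unresolved")
        with pytest.raises(ValueError, match="unresolved"):
            h.estimate_mn_yield(None, asg, None, refset)


class TestIdentifiabilityQuick:
    """Small-n preview of the identifiability property (full grid in the
    acceptance suite)."""

    @pytest.mark.parametrize(
        "pattern,a", [("1:3", 0.0), ("1:3", 0.5), ("2:2", 0.0), ("2:2", 0.25)]
    )
    def test_recovery(self, catalog, controls, refset, aneuploid_ref, pattern, a):
        rng = np.random.default_rng(round(a * 100) + (1 if pattern == "1:3" else 2))
        hits = 0
        n = 12
        for i in range(n):
            chrom = f"chr{(i % 5) + 1}"
            hap = "A" if i % 2 == 0 else "B"
            gen = 1 if i % 2 == 0 else 2
            sc = h.SegregationScenario(
                chrom, hap, pattern, gen, a, split=1.0 if gen == 2 else None
            )
            fam, summ, states = run_family(
                catalog, controls, refset, aneuploid_ref, sc, rng
            )
            asg = h.infer_mn_chromosome(fam, states)
            if (asg.chrom, asg.haplotype, asg.pattern) == (chrom, hap, pattern):
                hits += 1
        assert hits >= n - 1
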