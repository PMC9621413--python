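"""Template partitioning, splint design, and the order sheet."""

import itertools

import numpy as np
import pytest

from splintlig.codon_math import DegenerateCodon
from splintlig.design import (
    DesignConstraints,
    LibraryTemplate,
    _candidate_score,
    _solve_partition,
    design_oligo_set,
    design_splints,
    enumerate_junction_candidates,
    parse_order_sheet,
    partition_template,
    render_order_sheet,
)
from splintlig.thermo import DuplexContext, nn_tm, revcomp

from helpers import make_template


class TestTemplateValidation:
    def test_degenerate_letter_outside_randomized_codon_rejected(self):
        t = make_template(10, [2])
        seq = t.full_sequence[:3] + "N" + t.full_sequence[4:]
        with pytest.raises(ValueError, match="position 3"):
            LibraryTemplate(
                full_sequence=seq,
                promoter_span=t.promoter_span,
                rbs_span=t.rbs_span,
                orf_span=t.orf_span,
                randomized_codons=t.randomized_codons,
                three_prime_constant_span=t.three_prime_constant_span,
            )

    def test_orf_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            LibraryTemplate(
                full_sequence="A" * 100,
                promoter_span=(0, 3),
                rbs_span=(3, 6),
                orf_span=(10, 21),
                randomized_codons=[],
                three_prime_constant_span=(30, 40),
            )

    def test_letters_must_match_randomized_code(self):
        t = make_template(10, [])
        with pytest.raises(ValueError, match="does not match"):
            LibraryTemplate(
                full_sequence=t.full_sequence,  # concrete bases at codon 2
                promoter_span=t.promoter_span,
                rbs_span=t.rbs_span,
                orf_span=t.orf_span,
                randomized_codons=[(2, DegenerateCodon("NNK"))],
                three_prime_constant_span=t.three_prime_constant_span,
            )


class TestJunctionCandidates:
    def test_dense_randomization_leaves_no_junctions(self):
        # NNK at every other codon: framework runs of 3 nt can never host
        # two 8-nt arms
        t = make_template(30, range(0, 30, 2), five_prime=6, three_prime=4)
        assert enumerate_junction_candidates(t, DesignConstraints()) == []

    def test_all_constant_template_every_position_qualifies(self):
        t = make_template(96, [], five_prime=6, three_prime=6, seed=3)  # 300 nt
        c = DesignConstraints(arm_tm_window=60.0)
        cands = enumerate_junction_candidates(t, c)
        expected = list(range(c.min_arm_len, t.length - c.min_arm_len + 1))
        assert [x.position for x in cands] == expected

    def test_worked_fixture_junctions_avoid_randomized_codons(self, template, designed):
        # brute-force check of every chosen junction against every interval
        intervals = template.randomized_intervals()
        for sp in designed.splints:
            for arm in (sp.left_arm, sp.right_arm):
                for s, e in intervals:
                    assert not (arm[0] < e and s < arm[1]), (
                        f"{sp.name} arm {arm} overlaps randomized codon ({s},{e})"
                    )


class TestPartition:
    def test_worked_fixture_nine_oligos_three_groups(self, template, designed):
        sense = designed.sense
        assert len(sense) == 9
        assert all(o.length <= 90 for o in sense)
        assert [o.group_index for o in sense] == [1, 1, 1, 2, 2, 2, 3, 3, 3]
        assert [o.name for o in sense] == [f"NF{i}" for i in range(1, 10)]

    def test_tiling_reconstructs_template_exactly(self, template, designed):
        joined = "".join(o.sequence for o in designed.sense)
        assert joined == template.full_sequence  # degenerate letters included

    def test_short_template_is_single_oligo(self):
        t = make_template(20, [5], five_prime=9, three_prime=6)  # 75 nt
        oset = partition_template(t, DesignConstraints())
        assert len(oset.sense) == 1
        assert oset.sense[0].five_prime_phosphate is False
        assert oset.junction_positions == []

    def test_infeasible_template_raises_with_diagnosis(self):
        t = make_template(30, range(0, 30, 2), five_prime=6, three_prime=4)  # 100 nt
        with pytest.raises(ValueError, match="cannot be partitioned"):
            partition_template(t, DesignConstraints())

    def test_dp_matches_exhaustive_search(self):
        # two ~20-nt framework windows in an otherwise randomized ORF give
        # ≤ 12 candidate junctions; compare DP to brute force over all
        # junction pairs under the same lexicographic objective
        nnk = [i for i in range(64) if not (15 <= i <= 21 or 38 <= i <= 44)]
        t = make_template(64, nnk, five_prime=5, three_prime=3, seed=11)
        c = DesignConstraints(arm_tm_window=35.0)
        cands = enumerate_junction_candidates(t, c)
        assert 2 <= len(cands) <= 12
        got = _solve_partition(t.length, cands, 3, c)
        assert got is not None

        best = None
        L = t.length
        for pair in itertools.combinations(cands, 2):
            cuts = [x.position for x in pair]
            segs = [cuts[0], cuts[1] - cuts[0], L - cuts[1]]
            if not all(c.min_oligo_len <= s <= c.max_oligo_len for s in segs):
                continue
            cost = (
                sum(_candidate_score(x, c.target_arm_tm) for x in pair),
                sum(s**2 for s in segs),
                tuple(cuts),
            )
            if best is None or cost < best:
                best = cost
        assert best is not None
        assert [x.position for x in got] == list(best[2])
        assert sum(_candidate_score(x, c.target_arm_tm) for x in got) == pytest.approx(
            best[0]
        )


class TestSplints:
    def test_worked_fixture_eight_splints_with_bridging_pattern(self, designed):
        sps = designed.splints
        assert [sp.name for sp in sps] == [f"SP{i}" for i in range(1, 9)]
        stages = {sp.name: sp.stage for sp in sps}
        assert stages["SP3"] == "bridging"
        assert stages["SP6"] == "bridging"
        assert all(
            stages[n] == "within-group" for n in stages if n not in ("SP3", "SP6")
        )

    def test_phosphorylation_pattern(self, designed):
        unphos = [o.name for o in designed.sense if not o.five_prime_phosphate]
        assert unphos == ["NF1"]
        assert all(sp.three_prime_phosphate for sp in designed.splints)

    def test_splint_is_revcomp_of_junction_window(self, template, designed):
        for sp in designed.splints:
            window = template.full_sequence[sp.left_arm[0] : sp.right_arm[1]]
            assert sp.sequence == revcomp(window)

    def test_arms_rescored_by_thermo_fall_in_window(self, template, designed):
        c = designed.constraints
        for sp in designed.splints:
            for arm in (sp.left_arm, sp.right_arm):
                seq = template.full_sequence[arm[0] : arm[1]]
                tm = nn_tm(DuplexContext(seq))
                assert abs(tm - c.target_arm_tm) <= c.arm_tm_window

    def test_two_oligo_template_gets_single_within_group_splint(self):
        t = make_template(40, [3, 30], five_prime=12, three_prime=12, seed=5)  # 144 nt
        oset = design_oligo_set(t, DesignConstraints(arm_tm_window=25.0))
        if len(oset.sense) == 2:
            assert len(oset.splints) == 1
            assert oset.splints[0].stage == "within-group"
        else:  # partition chose a group-size multiple; splint count follows
            assert len(oset.splints) == len(oset.sense) - 1


class TestOrderSheet:
    def test_row_structure_and_modification_codes(self, designed):
        sheet = render_order_sheet(designed)
        assert list(sheet["name"]) == [f"NF{i}" for i in range(1, 10)] + [
            f"SP{i}" for i in range(1, 9)
        ] + ["CR"]
        nf = sheet[sheet["kind"] == "sense"]
        assert not nf.iloc[0]["order_sequence"].startswith("/5Phos/")
        assert all(s.startswith("/5Phos/") for s in nf.iloc[1:]["order_sequence"])
        sp = sheet[sheet["kind"] == "splint"]
        assert all(s.endswith("/3Phos/") for s in sp["order_sequence"])

    def test_single_oligo_design_has_nf_and_cr_only(self):
        t = make_template(20, [5], five_prime=9, three_prime=6)
        oset = partition_template(t, DesignConstraints())
        sheet = render_order_sheet(oset)
        assert list(sheet["kind"]) == ["sense", "primer"]

    def test_round_trip_reconstructs_oligo_set(self, designed):
        sheet = render_order_sheet(designed)
        back = parse_order_sheet(sheet, designed.constraints)
        assert back.sense == designed.sense
        assert back.splints == designed.splints
        assert back.cr == designed.cr


class TestCRPrimer:
    def test_cr_anneals_to_three_prime_constant(self, template, designed):
        s, e = template.three_prime_constant_span
        assert designed.cr.sequence.endswith(revcomp(template.full_sequence[s:e]))

    def test_cr_tail_is_prepended(self):
        from splintlig.examples import worked_template

        t = worked_template(cr_tail="ACGTACGTAC")
        oset = partition_template(t, DesignConstraints())
        assert oset.cr.sequence.startswith("ACGTACGTAC")
        assert oset.cr.tail == "ACGTACGTAC"
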