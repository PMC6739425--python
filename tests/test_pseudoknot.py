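"""Kissing-loop scanning, compensatory design, conservation, covariation."""

import numpy as np
import pytest

from rnaloops import (
    CoreLayout,
    ScanParams,
    covariation,
    design_all_compensatory,
    design_compensatory,
    find_hairpin_loops,
    gen_core,
    parse_dotbracket,
    repeat_conservation,
    scan_kissing,
    simulate_alignment,
)
from rnaloops.pseudoknot import count_motif_repeats, pair_type, register_to_dotbracket


def hand_built(repeat: str):
    """A hairpin with a GUGAG loop plus one distal candidate window.

    Layout: 6-bp GC stem, 5-nt loop (the motif), 110-nt A linker (cannot pair
    with the C-rich candidate), the candidate, short A tail.
    """
    stem5, stem3 = "GGCGGC", "GCCGCC"
    linker = "A" * 110
    seq = stem5 + "GUGAG" + stem3 + linker + repeat + "AAA"
    db = "((((((.....))))))" + "." * (110 + len(repeat) + 3)
    return seq, parse_dotbracket(db)


class TestFindHairpinLoops:
    @pytest.mark.parametrize(
        "db, loops",
        [
            ("(((...)))", [(4, 6)]),
            ("((..))((...))", [(3, 4), (9, 11)]),
            (".........", []),
            ("((..((...))..))", [(7, 9)]),  # only the innermost loop is terminal
        ],
    )
    def test_examples(self, db, loops):
        assert find_hairpin_loops(parse_dotbracket(db)) == loops


class TestScanKissing:
    def test_six_planted_repeats_recovered(self, default_core):
        seq, structure, truth = default_core
        registers = scan_kissing(seq, structure)
        assert len(registers) == 6
        assert [r.label for r in registers] == [f"TR{i}" for i in range(1, 7)]
        assert {(r.loop_interval, r.repeat_interval) for r in registers} == {
            (r.loop_interval, r.repeat_interval) for r in truth
        }

    def test_registers_are_mutually_exclusive_one_group(self, default_core):
        seq, structure, _ = default_core
        registers = scan_kissing(seq, structure)
        assert {r.group for r in registers} == {0}
        for a in registers:
            for b in registers:
                assert a.loop_positions() & b.loop_positions()

    def test_perfect_complement_inside_helix_rejected(self):
        seq, _ = hand_built("CUCAC")
        # same sequence, but a structure in which the candidate window is
        # base-paired: at zero unpaired-violations it must be rejected
        paired_db = (
            "((((((.....))))))" + "." * 100 + "(((((" + "....." + ")))))" + "..."
        )
        assert len(paired_db) == len(seq)
        structure = parse_dotbracket(paired_db)
        assert scan_kissing(seq, structure) == []

    def test_watson_crick_register(self):
        seq, structure = hand_built("CUCAC")
        registers = scan_kissing(seq, structure)
        assert len(registers) == 1
        assert all(t == "WC" for _, _, t in registers[0].pairs)
        assert registers[0].n_pairs == 5

    def test_wobble_register_requires_wobble_flag(self):
        seq, structure = hand_built("CUCAU")
        with_wobble = scan_kissing(seq, structure)
        assert len(with_wobble) == 1
        types = sorted(t for _, _, t in with_wobble[0].pairs)
        assert types.count("WC") == 4 and types.count("wobble") == 1
        without = scan_kissing(seq, structure, ScanParams(allow_wobble=False))
        assert without == []

    def test_distance_constraint(self):
        seq, structure = hand_built("CUCAC")
        far = scan_kissing(seq, structure, ScanParams(min_distance=100))
        near_forbidden = scan_kissing(seq, structure, ScanParams(min_distance=200))
        assert len(far) == 1 and near_forbidden == []

    def test_recovery_across_seeds(self):
        for seed in range(10):
            seq, structure, truth = gen_core(seed=seed)
            registers = scan_kissing(seq, structure)
            assert {(r.loop_interval, r.repeat_interval) for r in registers} == {
                (r.loop_interval, r.repeat_interval) for r in truth
            }

    def test_two_independent_loops_form_separate_groups(self):
        # two hairpins with different motifs, each complementary to its own
        # distal window: registers must split into two exclusivity groups
        stem5, stem3 = "GGCGGC", "GCCGCC"
        seq = (
            stem5 + "GUGAG" + stem3
            + "A" * 20
            + stem5 + "GGGAG" + stem3
            + "A" * 110
            + "CUCAC" + "AAA" + "CUCCC" + "AA"
        )
        db = (
            "((((((.....))))))"
            + "." * 20
            + "((((((.....))))))"
            + "." * (110 + 15)
        )
        structure = parse_dotbracket(db[: len(seq)])
        registers = scan_kissing(seq, structure)
        assert len(registers) == 2
        assert len({r.group for r in registers}) == 2
        a, b = registers
        assert not (a.loop_positions() & b.loop_positions())


class TestCompensatoryDesign:
    def test_wobble_partner_rescued_to_watson_crick(self):
        """Loop G -> C opposite a wobble-paired U designs U -> G (the published pattern)."""
        layout = CoreLayout(wobble_at=(2,))
        seq, structure, truth = gen_core(layout, seed=2)
        reg = truth[2]  # third repeat, mirroring the TR3 rescue
        loop_g = reg.loop_interval[0] + 2
        partner, typ = reg.partner_of(loop_g)
        assert typ == "wobble" and seq[partner - 1] == "U"
        design = design_compensatory(reg, (loop_g, "G", "C"), seq)
        assert design.repeat_position == partner
        assert design.repeat_from == "U" and design.repeat_to == "G"

    def test_au_pair_rescued_to_ua(self):
        seq, structure = hand_built("CUCAC")
        reg = scan_kissing(seq, structure)[0]
        loop_a = reg.loop_interval[0] + 3  # the A of GUGAG
        design = design_compensatory(reg, (loop_a, "A", "U"), seq)
        assert design.repeat_from == "U" and design.repeat_to == "A"

    def test_one_mutation_yields_six_distinct_double_mutants(self, default_core):
        seq, structure, _ = default_core
        registers = scan_kissing(seq, structure)
        loop_g = registers[0].loop_interval[0] + 2
        designs = design_all_compensatory(registers, (loop_g, seq[loop_g - 1], "C"), seq)
        assert len(designs) == 6
        assert len({d.repeat_position for d in designs}) == 6

    def test_rescue_closure(self, default_core):
        """Every designed double mutant restores its register's full pair count."""
        seq, structure, _ = default_core
        registers = scan_kissing(seq, structure)
        loop_pos = registers[0].loop_interval[0] + 2
        designs = design_all_compensatory(registers, (loop_pos, seq[loop_pos - 1], "C"), seq)
        for design, reg in zip(designs, registers):
            mutated = list(seq)
            mutated[loop_pos - 1] = "C"
            mutated[design.repeat_position - 1] = design.repeat_to
            rescanned = scan_kissing("".join(mutated), structure)
            restored = [
                r
                for r in rescanned
                if r.repeat_interval == reg.repeat_interval
                and r.n_pairs == reg.n_pairs
            ]
            assert restored, f"register {reg.label} not restored by {design.name}"

    def test_unpaired_loop_position_returns_none(self):
        seq, structure = hand_built("CUCAC")
        reg = scan_kissing(seq, structure)[0]
        outside = reg.loop_interval[0]
        mutated_pairs = tuple(p for p in reg.pairs if p[0] != outside)
        from dataclasses import replace

        partial = replace(reg, pairs=mutated_pairs)
        assert design_compensatory(partial, (outside, "G", "C"), seq) is None


class TestConservation:
    @pytest.fixture(scope="class")
    def alignment(self):
        core = gen_core(seed=5)
        aln, meta = simulate_alignment(core, n_species=20, seed=7)
        return core, aln, meta

    def test_all_species_pass_minimum_repeat_count(self, alignment):
        _, aln, _ = alignment
        result = repeat_conservation(aln, "GUGAG", min_count=3)
        assert all(passed for _, passed in result.values())

    def test_zero_match_row_fails(self):
        from Bio.Align import MultipleSeqAlignment
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        aln = MultipleSeqAlignment(
            [SeqRecord(Seq("A" * 40), id="s1"), SeqRecord(Seq("A" * 40), id="s2")]
        )
        result = repeat_conservation(aln, "GUGAG", min_count=3)
        assert result["s1"] == (0, False)

    def test_counts_match_naive_scanner(self, alignment):
        (seq, _, _), aln, _ = alignment

        def naive(row, motif):
            comp = {"A": "U", "U": "AG", "G": "CU", "C": "G"}
            row = row.replace("-", "")
            hits = 0
            for s in range(len(row) - len(motif) + 1):
                window = row[s : s + len(motif)]
                if all(window[len(motif) - 1 - t] in comp[motif[t]] for t in range(len(motif))):
                    hits += 1
            return hits

        for record in aln:
            assert count_motif_repeats(str(record.seq), "GUGAG") == naive(
                str(record.seq).replace("T", "U"), "GUGAG"
            )


class TestCovariation:
    @pytest.fixture(scope="class")
    def planted(self):
        core = gen_core(seed=11)
        aln, meta = simulate_alignment(
            core, n_species=41, sub_prob=0.15, covary_prob=1.0, seed=13
        )
        return core, aln

    def test_invariant_columns_score_one_no_compensation(self, planted):
        (seq, structure, truth), aln = planted
        # motif columns are invariant and unpaired against themselves; use a
        # kissing ground-truth pair: invariant in every row, hence canonical
        reg = truth[0]
        lp, rp, _ = reg.pairs[0]
        (res,) = covariation(aln, [(lp, rp)], n_permutations=10, seed=0)
        assert res.fraction_canonical == pytest.approx(1.0)
        assert res.compensatory_count == 0

    def test_full_covariation_counts_every_substituted_row(self, planted):
        (seq, structure, _), aln = planted
        pair = sorted(structure.nested_pairs())[0]
        i, j = pair
        ancestral = seq[i - 1] + seq[j - 1]
        substituted = sum(
            1
            for rec in aln
            if str(rec.seq)[i - 1] + str(rec.seq)[j - 1] != ancestral
        )
        (res,) = covariation(aln, [pair], n_permutations=10, seed=0)
        assert res.fraction_canonical == pytest.approx(1.0)
        assert res.compensatory_count == substituted

    def test_planted_pairs_rank_above_unpaired_columns(self, planted):
        (seq, structure, _), aln = planted
        planted_pairs = sorted(structure.nested_pairs())[:5]
        table = structure.pair_table()
        unpaired = [i for i in range(1, structure.length) if table[i] == 0]
        decoys = [(unpaired[k], unpaired[k + 40]) for k in range(5)]
        results = covariation(aln, planted_pairs + decoys, n_permutations=30, seed=3)
        planted_scores = [r.score for r in results[:5]]
        decoy_scores = [r.score for r in results[5:]]
        assert min(planted_scores) > max(decoy_scores)

    def test_row_order_invariance(self, planted):
        (seq, structure, _), aln = planted
        pair = sorted(structure.nested_pairs())[0]
        (fwd,) = covariation(aln, [pair], n_permutations=0, seed=0)
        reversed_aln = aln[::-1]
        (rev,) = covariation(reversed_aln, [pair], n_permutations=0, seed=0)
        assert fwd.score == pytest.approx(rev.score)
        assert fwd.compensatory_count == rev.compensatory_count

    def test_column_shuffle_destroys_significance(self, planted):
        """On shuffled (null) columns the planted pair is rarely significant."""
        (seq, structure, _), aln = planted
        i, j = sorted(structure.nested_pairs())[0]
        matrix = np.array([list(str(r.seq)) for r in aln])
        rng = np.random.default_rng(17)
        insignificant = 0
        for _ in range(100):
            from Bio.Align import MultipleSeqAlignment
            from Bio.Seq import Seq
            from Bio.SeqRecord import SeqRecord

            coli = rng.permutation(matrix[:, i - 1])
            colj = rng.permutation(matrix[:, j - 1])
            rows = [
                SeqRecord(Seq(a + b), id=f"r{k}")
                for k, (a, b) in enumerate(zip(coli, colj))
            ]
            shuffled = MultipleSeqAlignment(rows)
            (res,) = covariation(shuffled, [(1, 2)], n_permutations=50, seed=int(rng.integers(2**31)))
            if res.e_value > 0.05:
                insignificant += 1
        assert insignificant >= 95


class TestOutput:
    def test_register_dotbracket_round_trips(self, default_core):
        seq, structure, _ = default_core
        reg = scan_kissing(seq, structure)[0]
        text = register_to_dotbracket(structure, reg)
        parsed = parse_dotbracket(text)
        assert parsed.pseudoknot_pairs() == {(lp, rp) for lp, rp, _ in reg.pairs}
        assert parsed.nested_pairs() == structure.nested_pairs()
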