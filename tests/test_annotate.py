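import numpy as np
import pytest

from sidescan import (
    DnaRecord,
    GenomicInterval,
    breakpoint_logo,
    detect_polya,
    detect_tsd,
    find_breakpoint_microhomology,
    find_homologous_blocks,
    infer_deletion_interval,
    percent_identity,
)
from sidescan.annotate import ElementArchitecture, HomologyBlock
from sidescan.simulate import deletion_interval, p_sub_of_d

from tests.oracles import brute_microhomology, brute_tsd


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestPercentIdentity:
    def test_identical(self):
        assert percent_identity("A" * 100, "A" * 100) == 100.0

    def test_ninety_of_hundred(self):
        a = "A" * 100
        b = "A" * 90 + "C" * 10
        assert percent_identity(a, b) == 90.0

    def test_gap_columns_excluded(self):
        # 100 columns: 5 gapped, 95 gap-free of which 80 match
        a = "A" * 95 + "-" * 5
        b = "A" * 80 + "C" * 15 + "G" * 5
        assert percent_identity(a, b) == pytest.approx(84.21, abs=0.01)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a = "".join(rng.choice(list("ACGT-"), 60))
        b = "".join(rng.choice(list("ACGT-"), 60))
        if all(x == "-" or y == "-" for x, y in zip(a, b)):
            pytest.skip("degenerate draw")
        assert percent_identity(a, b) == percent_identity(b, a)

    def test_no_gap_free_columns_error(self):
        with pytest.raises(ValueError):
            percent_identity("--A", "AA-")


class TestDetectPolya:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("GCGCGCAAAAAA", 6),
            ("GCGCGCAAAAAG", 0),  # must end in the run
            ("GCGCAAAAGAAAAA", 10),  # one mismatch inside the 10 bp window
            ("GCGCGCAAAA", 0),  # below min_run=5
        ],
    )
    def test_examples(self, seq, expected):
        assert detect_polya(seq) == expected

    def test_mismatch_budget_zero(self):
        assert detect_polya("GCAAAAGAAAAA", max_mismatch_per_10=0) == 5

    def test_polyc_mode(self):
        assert detect_polya("ATATATCCCCCCCC", base="C") == 8


class TestDetectTsd:
    def test_planted_t6(self):
        rng = np.random.default_rng(1)
        elem = random_dna(rng, 50)
        g = DnaRecord("g", "GC" + "GCAT" * 5 + "TTTTTT" + elem + "TTTTTT" + "AGCT" * 5)
        s = 2 + 20 + 6
        iv = GenomicInterval("g", s, s + 50)
        rep = detect_tsd(g, iv)
        assert rep is not None and rep.motif == "TTTTTT" and rep.length == 6
        assert rep.left_iv.end == iv.start and rep.right_iv.start == iv.end

    def test_no_duplication(self):
        g = DnaRecord("g", "A" * 20 + "G" * 30 + "C" * 20)
        assert detect_tsd(g, GenomicInterval("g", 20, 50)) is None

    def test_contig_edge(self, caplog):
        import logging

        g = DnaRecord("g", "ACGTACGTAA")
        with caplog.at_level(logging.WARNING, logger="sidescan"):
            assert detect_tsd(g, GenomicInterval("g", 1, 10)) is None

    def test_agrees_with_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = int(rng.integers(40, 100))
            seq = random_dna(rng, n)
            s = int(rng.integers(10, n - 20))
            e = int(rng.integers(s + 5, n - 10))
            g = DnaRecord("g", seq)
            got = detect_tsd(g, GenomicInterval("g", s, e), window=20, len_range=(2, 20))
            exp = brute_tsd(seq, s, e, 20, 2, 20)
            if exp is None:
                assert got is None
            else:
                assert got is not None and (got.motif, got.length) == exp


class TestMicrohomology:
    def test_planted_aggcc(self):
        rng = np.random.default_rng(3)
        line = random_dna(rng, 200) + "AGGCC" + random_dna(rng, 600) + "AGGCC" + random_dna(rng, 200)
        rec = DnaRecord("l", line)
        mhs = find_breakpoint_microhomology(rec, (205, 805))
        assert mhs and mhs[0].motif == "AGGCC" and mhs[0].length == 5
        assert rec.seq[mhs[0].upstream_pos : mhs[0].upstream_pos + 5] == "AGGCC"
        assert rec.seq[mhs[0].downstream_pos : mhs[0].downstream_pos + 5] == "AGGCC"

    def test_no_shared_words(self):
        rec = DnaRecord("l", "A" * 20 + "G" * 40 + "C" * 20)
        assert find_breakpoint_microhomology(rec, (20, 60)) == []

    def test_agrees_with_brute_force(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            seq = random_dna(rng, int(rng.integers(60, 100)))
            s = int(rng.integers(16, len(seq) - 30))
            e = int(rng.integers(s + 5, len(seq) - 16))
            rec = DnaRecord("l", seq)
            got = {m.motif for m in find_breakpoint_microhomology(rec, (s, e), (3, 12), 15)}
            exp = brute_microhomology(seq, s, e, 3, 12, 15)
            assert got == exp

    def test_deleted_interval_must_be_internal(self):
        with pytest.raises(ValueError):
            find_breakpoint_microhomology(DnaRecord("l", "ACGTACGT"), (0, 4))


class TestBreakpointLogo:
    def test_closed_forms(self):
        logo = breakpoint_logo(["AC", "AG", "AT", "AA"])
        assert logo.info_bits[0] == pytest.approx(2.0)
        assert logo.info_bits[1] == pytest.approx(0.0)
        logo2 = breakpoint_logo(["AA", "AC"])
        assert logo2.info_bits[1] == pytest.approx(1.0)

    def test_frequencies_normalised(self):
        rng = np.random.default_rng(5)
        seqs = [random_dna(rng, 12) for _ in range(9)]
        logo = breakpoint_logo(seqs)
        assert np.allclose(logo.freqs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(logo.info_bits >= 0) and np.all(logo.info_bits <= 2)

    def test_empty_input(self):
        with pytest.raises(ValueError):
            breakpoint_logo([])


class TestHomologousBlocks:
    def test_constructed_side(self, scheme):
        rng = np.random.default_rng(6)
        line = DnaRecord("line", random_dna(rng, 2800) + "A" * 10)
        side_seq = line.seq[:120] + random_dna(rng, 100) + line.seq[-140:]
        side = DnaRecord("side", side_seq)
        arch = find_homologous_blocks(side, line, scheme)
        assert arch.five_block is not None and arch.three_block is not None
        assert abs(arch.five_block.line_start - 0) <= 3
        assert abs(arch.five_block.line_end - 120) <= 3
        assert abs(arch.three_block.line_start - (len(line.seq) - 140)) <= 3
        assert arch.polya_len >= 8
        s, e = infer_deletion_interval(arch, len(line.seq))
        assert abs(s - 120) <= 3 and abs(e - (len(line.seq) - 140)) <= 5

    def test_degenerate_side_equals_line(self, scheme):
        rng = np.random.default_rng(7)
        line = DnaRecord("line", random_dna(rng, 400))
        arch = find_homologous_blocks(line, line, scheme)
        assert arch.five_block is not None
        assert arch.five_block.side_start == 0
        assert arch.three_block is None or arch.three_block is arch.five_block
        assert arch.variable_region in (None, (arch.five_block.side_end,) * 2)
        with pytest.raises(ValueError):
            infer_deletion_interval(arch, len(line.seq))

    def test_simulator_pair_identities_track_divergence(self, small_sim, scheme):
        """Block identities of a mutated SIDE reflect the substitution rate."""
        from sidescan.simulate import mutate_copy

        _, _, _, master_line, master_side = small_sim
        rng = np.random.default_rng(8)
        d = 0.05
        side = DnaRecord("s", mutate_copy(master_side.seq, d, rng))
        arch = find_homologous_blocks(side, master_line, scheme)
        assert arch.five_block and arch.three_block
        for block, side_iv in ((arch.five_block, None), (arch.three_block, None)):
            s0, s1 = block.side_start, block.side_end
            observed = sum(
                1
                for x, y in zip(side.seq[s0:s1], master_side.seq[s0:s1])
                if x != y
            ) / (s1 - s0)
            assert block.pct_identity == pytest.approx(100 * (1 - observed), abs=2.0)


class TestInferDeletion:
    def test_arithmetic(self):
        arch = ElementArchitecture(
            five_block=HomologyBlock(0, 120, 0, 350, 99.0, 120),
            variable_region=(120, 220),
            three_block=HomologyBlock(220, 360, 3000, 3340, 99.0, 140),
            polya_len=8,
        )
        assert infer_deletion_interval(arch, 3340) == (350, 3000)

    def test_overlapping_blocks_error(self):
        arch = ElementArchitecture(
            five_block=HomologyBlock(0, 120, 0, 350, 99.0, 120),
            variable_region=None,
            three_block=HomologyBlock(130, 360, 300, 530, 99.0, 230),
            polya_len=0,
        )
        with pytest.raises(ValueError, match="overlap"):
            infer_deletion_interval(arch, 3340)

    def test_simulator_truth(self, small_sim, scheme):
        cfg, _, _, master_line, master_side = small_sim
        arch = find_homologous_blocks(master_side, master_line, scheme)
        s, e = infer_deletion_interval(arch, len(master_line.seq))
        ts, te = deletion_interval(cfg)
        assert abs(s - ts) <= 5 and abs(e - te) <= 5
        mhs = find_breakpoint_microhomology(master_line, (s, e))
        assert mhs and mhs[0].motif == cfg.microhomology_motif
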