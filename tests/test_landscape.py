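import math

import numpy as np
import pandas as pd
import pytest

from sidescan import (
    DnaRecord,
    GenomicInterval,
    Hit,
    PipelineConfig,
    activity_landscape,
    copy_divergence,
    copy_number_correlation,
    filter_fragments,
    genome_coverage,
    jukes_cantor,
    merge_adjacent,
)
from sidescan.landscape import MergedCopy

from tests.oracles import brute_spearman_permutation


def make_hit(start, end, q0, q1, strand="+", family="f", seq_id="g"):
    return Hit(
        family=family,
        genome_iv=GenomicInterval(seq_id, start, end, strand),
        q_start=q0,
        q_end=q1,
        strand=strand,
        score=float(end - start),
        evalue=1e-40,
        pct_identity=95.0,
        aligned_len=end - start,
    )


def make_copy(start, end, d, bp=None, family="f"):
    c = MergedCopy(
        family=family,
        fragments=[],
        genome_iv=GenomicInterval("g", start, end),
        strand="+",
        matched_bp=bp if bp is not None else end - start,
    )
    c.d = d
    c.p = d
    return c


class TestFilterFragments:
    def test_boundary_160(self):
        hits = [make_hit(0, L, 0, L, seq_id=f"s{L}") for L in (120, 159, 160, 300)]
        kept = filter_fragments(hits, 160)
        assert sorted(h.genome_span() for h in kept) == [160, 300]

    def test_boundary_250(self):
        hits = [make_hit(0, L, 0, L, seq_id=f"s{L}") for L in (120, 159, 160, 249, 250, 300)]
        kept = filter_fragments(hits, 250)
        assert sorted(h.genome_span() for h in kept) == [250, 300]

    def test_empty(self):
        assert filter_fragments([], 160) == []


class TestMergeAdjacent:
    def test_two_collinear_fragments_one_copy(self):
        h1 = make_hit(1000, 1150, 0, 150)
        h2 = make_hit(1165, 1315, 160, 310)
        copies = merge_adjacent([h1, h2], PipelineConfig())
        assert len(copies) == 1
        assert copies[0].genome_iv.start == 1000 and copies[0].genome_iv.end == 1315
        assert copies[0].matched_bp == 300

    def test_opposite_strands_not_merged(self):
        h1 = make_hit(1000, 1150, 0, 150, "+")
        h2 = make_hit(1165, 1315, 160, 310, "-")
        assert len(merge_adjacent([h1, h2], PipelineConfig())) == 2

    def test_non_collinear_not_merged(self):
        # second fragment goes backwards on the consensus: a separate copy
        h1 = make_hit(1000, 1150, 160, 310)
        h2 = make_hit(1165, 1315, 0, 150)
        assert len(merge_adjacent([h1, h2], PipelineConfig())) == 2

    def test_minus_strand_consensus_order(self):
        # genome left-to-right walks the consensus right-to-left on '-'
        h1 = make_hit(1000, 1150, 160, 310, "-")
        h2 = make_hit(1165, 1315, 0, 150, "-")
        assert len(merge_adjacent([h1, h2], PipelineConfig())) == 1

    def test_unmerge_mode_one_copy_per_hit(self):
        h1 = make_hit(1000, 1150, 0, 150)
        h2 = make_hit(1165, 1315, 160, 310)
        cfg = PipelineConfig(merge_max_gap=0)
        copies = merge_adjacent([h1, h2], cfg, consensus_gap_allowance=False)
        assert len(copies) == 2

    def test_never_increases_copy_count(self):
        rng = np.random.default_rng(0)
        hits = []
        pos = 0
        for _ in range(40):
            pos += int(rng.integers(10, 400))
            L = int(rng.integers(50, 300))
            q0 = int(rng.integers(0, 200))
            hits.append(make_hit(pos, pos + L, q0, q0 + L))
            pos += L
        copies = merge_adjacent(hits, PipelineConfig())
        assert len(copies) <= len(hits)
        assert sum(len(c.fragments) for c in copies) == len(hits)


class TestJukesCantor:
    def test_zero(self):
        assert jukes_cantor(0.0) == 0.0

    def test_closed_form_at_p_010(self):
        assert jukes_cantor(0.10) == pytest.approx(0.107326, abs=5e-7)

    def test_correction_exceeds_p(self):
        for p in np.linspace(0.01, 0.74, 50):
            assert jukes_cantor(p) >= p

    @pytest.mark.parametrize("p", [-0.01, 0.75, 1.0])
    def test_domain(self, p):
        with pytest.raises(ValueError):
            jukes_cantor(p)


class TestCopyDivergence:
    def test_identical_copy(self):
        rng = np.random.default_rng(1)
        cons = DnaRecord("c", "".join(rng.choice(list("ACGT"), 300)))
        genome = {"g": DnaRecord("g", "ACGT" * 10 + cons.seq + "TTTT" * 10)}
        h = make_hit(40, 340, 0, 300)
        copy = merge_adjacent([h], PipelineConfig())[0]
        copy_divergence(copy, cons, genome)
        assert copy.p == 0.0 and copy.d == 0.0

    def test_planted_twenty_percent(self):
        rng = np.random.default_rng(2)
        cons_seq = "".join(rng.choice(list("ACGT"), 1000))
        mutated = list(cons_seq)
        idx = rng.choice(1000, size=200, replace=False)
        for i in idx:
            mutated[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[i]]
        genome = {"g": DnaRecord("g", "".join(mutated))}
        cons = DnaRecord("c", cons_seq)
        copy = merge_adjacent([make_hit(0, 1000, 0, 1000)], PipelineConfig())[0]
        copy_divergence(copy, cons, genome)
        assert copy.p == pytest.approx(0.20, abs=1e-9)
        assert copy.d == pytest.approx(0.2326, abs=1e-3)


class TestActivityLandscape:
    def test_all_zero_divergence_single_bin(self):
        copies = [make_copy(i * 1000, i * 1000 + 300, 0.0) for i in range(5)]
        table = activity_landscape(copies, PipelineConfig())
        assert table.copies[0] == 5
        assert table.copies.sum() == 5

    def test_bp_conservation(self):
        rng = np.random.default_rng(3)
        copies = [
            make_copy(i * 1000, i * 1000 + int(rng.integers(160, 400)), float(rng.uniform(0, 0.3)))
            for i in range(50)
        ]
        table = activity_landscape(copies, PipelineConfig())
        assert table.bp.sum() == sum(c.matched_bp for c in copies)

    def test_burst_modal_bin(self):
        rng = np.random.default_rng(4)
        copies = [
            make_copy(i * 1000, i * 1000 + 300, max(0.0, rng.normal(0.08, 0.01)))
            for i in range(300)
        ]
        table = activity_landscape(copies, PipelineConfig())
        assert abs(table.modal_bin(by="copies") - 8) <= 1

    def test_two_bursts_bimodal(self):
        rng = np.random.default_rng(5)
        copies = [
            make_copy(i * 1000, i * 1000 + 300, max(0.0, rng.normal(0.03, 0.005)))
            for i in range(120)
        ] + [
            make_copy((200 + i) * 1000, (200 + i) * 1000 + 300, max(0.0, rng.normal(0.15, 0.005)))
            for i in range(120)
        ]
        table = activity_landscape(copies, PipelineConfig())
        counts = table.copies
        peaks = [
            i
            for i in range(len(counts))
            if counts[i] > 0
            and (i == 0 or counts[i] >= counts[i - 1])
            and (i == len(counts) - 1 or counts[i] >= counts[i + 1])
            and counts[i] >= 10
        ]
        assert any(abs(p - 3) <= 1 for p in peaks)
        assert any(abs(p - 15) <= 1 for p in peaks)


class TestGenomeCoverage:
    def test_empty(self):
        assert genome_coverage([], 10_000) == 0.0

    def test_single_copy(self):
        assert genome_coverage([make_copy(100, 200, 0.0)], 10_000) == pytest.approx(0.01)

    def test_overlap_counted_once(self):
        copies = [make_copy(0, 100, 0.0), make_copy(50, 150, 0.0)]
        assert genome_coverage(copies, 1000) == pytest.approx(0.15)


class TestCorrelation:
    def test_perfect_monotone(self):
        t = pd.DataFrame({"side": [1, 5, 20, 90, 400], "line": [2, 7, 30, 100, 900]})
        res = copy_number_correlation(t)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(2 / math.factorial(5))

    def test_anti_monotone(self):
        t = pd.DataFrame({"side": [1, 2, 3, 4], "line": [9, 7, 5, 2]})
        res = copy_number_correlation(t)
        assert res.statistic == pytest.approx(-1.0)

    def test_matches_exhaustive_oracle_n6(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            x = rng.integers(1, 1000, size=6).astype(float)
            y = rng.integers(1, 1000, size=6).astype(float)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            t = pd.DataFrame({"side": x, "line": y})
            res = copy_number_correlation(t)
            exp_rho, exp_p = brute_spearman_permutation(x, y)
            assert res.statistic == pytest.approx(exp_rho, abs=1e-9)
            assert res.p_value == pytest.approx(exp_p, abs=1e-9)

    def test_constant_ranks_error(self):
        t = pd.DataFrame({"side": [3, 3, 3, 3], "line": [1, 2, 3, 4]})
        with pytest.raises(ValueError):
            copy_number_correlation(t)

    def test_too_few_genomes(self):
        t = pd.DataFrame({"side": [1, 2, 3], "line": [1, 2, 3]})
        with pytest.raises(ValueError):
            copy_number_correlation(t)
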