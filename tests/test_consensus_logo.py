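"""Per-column logo statistics, positional scores S and threshold R,
and the one-line consensus renderings."""

import math

import numpy as np
import pytest

from maedeconv.consensus_logo import (
    DEFAULT_GROUPS,
    LogoColumn,
    column_stats,
    positional_scores,
    positional_threshold,
    render_consensus,
    score_alignment,
)
from maedeconv.node_alignment import align_node

LOG2_20 = math.log2(20)


class TestColumnStats:
    def test_pure_column_closed_form(self):
        """100 identical residues: H = 0, so E = log2(20) - 19/(2 ln2 100)."""
        col = column_stats(["L"] * 100, M=100, bootstrap_reps=50, seed=0)
        expected = LOG2_20 - 19 / (2 * math.log(2) * 100)
        assert col.E == pytest.approx(expected)
        assert col.E == pytest.approx(4.185, abs=5e-4)

    def test_uniform_column_clamps_to_zero(self):
        residues = sorted("ACDEFGHIKLMNPQRSTVWY")
        col = column_stats(residues, M=20, bootstrap_reps=50, seed=0)
        assert col.E == 0.0
        assert col.L == 0.0

    def test_weight_is_occupancy(self):
        col = column_stats(["L"] * 4 + ["-"] * 4, M=8, bootstrap_reps=10, seed=0)
        assert col.W == 0.5
        assert col.N_n == 4

    def test_all_gap_column_is_null(self):
        col = column_stats(["-"] * 5, M=5)
        assert col.null and col.is_null

    def test_bootstrap_bound_is_deterministic_and_below_e(self):
        residues = list("LLLLLVVIAA")
        a = column_stats(residues, M=10, bootstrap_reps=200, seed=42)
        b = column_stats(residues, M=10, bootstrap_reps=200, seed=42)
        c = column_stats(residues, M=10, bootstrap_reps=200, seed=43)
        assert a.L == b.L
        assert a.L <= a.E
        assert a.L >= 0.0
        # a different seed is allowed to move the bound, E is unchanged
        assert a.E == c.E

    def test_overfull_column_rejected(self):
        with pytest.raises(ValueError, match="M=2"):
            column_stats(["L", "L", "L"], M=2)


class TestScores:
    def test_eq1_fixed_example(self):
        col = LogoColumn(position=1, counts={"A": 2, "C": 2}, N_n=4, M=8,
                         W=0.5, E=1.5, L=0.0)
        positional_scores(col)
        assert col.S["A"] == pytest.approx(0.375)  # (2/4) * 1.5 * 0.5

    def test_full_column_s_equals_e(self):
        col = LogoColumn(position=1, counts={"L": 7}, N_n=7, M=7,
                         W=1.0, E=2.0, L=0.0)
        positional_scores(col)
        assert col.S["L"] == pytest.approx(2.0)

    def test_sum_of_scores_equals_e_times_w(self):
        """Distributing E*W over residue frequencies is exact."""
        rng = np.random.default_rng(8)
        letters = sorted("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(200):
            m = int(rng.integers(2, 40))
            n = int(rng.integers(1, m + 1))
            col = column_stats(
                list(rng.choice(letters, size=n)) + ["-"] * (m - n),
                M=m, bootstrap_reps=10, seed=int(rng.integers(1 << 30)),
            )
            positional_scores(col)
            assert sum(col.S.values()) == pytest.approx(col.E * col.W, abs=1e-12)

    def test_score_monotone_in_residue_count(self):
        lo = LogoColumn(position=1, counts={"A": 2, "C": 6}, N_n=8, M=8,
                        W=1.0, E=1.2, L=0.0)
        hi = LogoColumn(position=1, counts={"A": 5, "C": 3}, N_n=8, M=8,
                        W=1.0, E=1.2, L=0.0)
        assert positional_scores(hi).S["A"] > positional_scores(lo).S["A"]


class TestThreshold:
    def scored(self, counts, E, L, W=1.0):
        n = sum(counts.values())
        col = LogoColumn(position=1, counts=counts, N_n=n, M=n, W=W, E=E, L=L)
        positional_scores(col)
        return positional_threshold(col)

    def test_eq2_fixed_example(self):
        col = self.scored({"L": 9, "V": 1}, E=1.2, L=0.9)
        assert col.R == pytest.approx(0.3)

    def test_degenerate_bound_makes_everything_significant(self):
        col = self.scored({"L": 5, "V": 5}, E=1.0, L=1.0)
        assert col.R == 0.0
        assert col.significant == {"L", "V"}

    def test_group_rescues_individually_weak_residues(self):
        # S and T each score 0.2 < R = 0.3 but their group sums to 0.4
        col = LogoColumn(position=1, counts={"S": 2, "T": 2, "L": 6}, N_n=10,
                         M=10, W=1.0, E=1.0, L=0.7)
        col.S = {"S": 0.2, "T": 0.2, "L": 0.05}
        positional_threshold(col)
        assert "S" not in col.significant and "T" not in col.significant
        assert frozenset("ST") in col.significant_groups

    def test_group_with_significant_member_not_flagged(self):
        col = LogoColumn(position=1, counts={"S": 8, "T": 2}, N_n=10, M=10,
                         W=1.0, E=1.0, L=0.7)
        col.S = {"S": 0.8, "T": 0.1}
        positional_threshold(col)
        assert "S" in col.significant
        assert col.significant_groups == ()


class TestRenderConsensus:
    def cols(self, spec):
        """spec: list of None or dict residue -> S; E/L chosen so R=0.3."""
        out = []
        for i, entry in enumerate(spec, start=1):
            if entry is None:
                out.append(LogoColumn(position=i, counts={}, N_n=0, M=10, null=True))
                continue
            counts = {aa: 1 for aa in entry}
            col = LogoColumn(position=i, counts=counts, N_n=len(counts), M=10,
                             W=1.0, E=1.0, L=0.7)
            col.S = dict(entry)
            positional_threshold(col)
            out.append(col)
        return out

    def test_full_style_dash_and_letter(self):
        line = render_consensus(
            self.cols([None, {"L": 0.9}, None, None]), style="full"
        )
        assert line.text() == "-L--"

    def test_multiple_significant_residues_bracketed(self):
        line = render_consensus(
            self.cols([{"S": 0.5, "T": 0.4}, None]), style="full"
        )
        assert line.text() == "[ST]-"

    def test_group_only_residues_render_lowercase(self):
        col = LogoColumn(position=1, counts={"S": 5, "T": 5}, N_n=10, M=10,
                         W=1.0, E=1.0, L=0.7)
        col.S = {"S": 0.2, "T": 0.2}
        positional_threshold(col)
        line = render_consensus([col], style="full")
        assert line.text() == "[st]"

    def test_top4_keeps_four_highest_scores(self):
        spec = [{"L": 0.9}, {"V": 0.8}, {"K": 0.7}, {"F": 0.6}, {"M": 0.5}]
        line = render_consensus(self.cols(spec), style="top4")
        text = line.text()
        assert "M" not in text
        for token in ("1L", "2V", "3K", "4F"):
            assert token in text

    def test_top4_dashed_bridges_internal_gaps(self):
        spec = [{"L": 0.9}, None, {"V": 0.8}, {"K": 0.7}, None, {"F": 0.6}, None]
        line = render_consensus(self.cols(spec), style="top4_dashed")
        assert line.text() == "L-VK-F"

    def test_shade_clamped_to_floor_and_cap(self):
        line = render_consensus(self.cols([{"L": 5.0}, {"V": 0.31}]), style="full")
        shades = [line.tokens[0][0].shade, line.tokens[1][0].shade]
        assert shades == [1.0, pytest.approx(0.31)]
        low = render_consensus(self.cols([{"L": 1.0, "V": 0.35}]), style="full")
        assert min(e.shade for e in low.tokens[0]) >= 0.2

    def test_unknown_style_rejected(self):
        with pytest.raises(ValueError, match="style"):
            render_consensus([], style="fancy")


def test_planted_anchor_positions_are_significant():
    """A node of 24 sequences sharing residues at positions 2 and 9 over
    uniform flanks marks exactly those two positions significant."""
    rng = np.random.default_rng(55)
    letters = np.array(sorted("ACDEFGHIKLMNPQRSTVWY"))
    seqs = []
    for _ in range(24):
        s = list(rng.choice(letters, size=9))
        s[1], s[8] = "L", "K"
        seqs.append("".join(s))
    aln = align_node(seqs, max_len=12)
    cols = score_alignment(aln, bootstrap_reps=200, seed=3)
    significant = {c.position for c in cols if c.significant}
    assert {2, 9} <= significant
    # flank positions are uniform noise: at most one should sneak through
    assert len(significant - {2, 9}) <= 1
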