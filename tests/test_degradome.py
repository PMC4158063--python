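"""Degradome stage: T-plots, penalty scoring, categories, target calls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srdk.config import PipelineConfig
from srdk.core import revcomp
from srdk.degradome import (
    TPlot,
    build_tplot,
    call_targets,
    classify_category,
    score_alignment,
)
from srdk.io import CollapsedRead, FastaRecord

from .oracles import naive_alignment_penalty

MIRNA = "TCGGACCAGGCTTCATTCCCC"  # 21 nt


def _tplot(counts):
    return TPlot("t", np.asarray(counts, dtype=np.int64))


class TestBuildTplot:
    def test_tag_counted_at_its_five_prime_offset(self):
        rng = np.random.default_rng(0)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)])
        tr = [FastaRecord("t1", "", seq)]
        tag = seq[99:119]
        tplots = build_tplot([CollapsedRead(tag, 6)], tr)
        assert tplots["t1"].position_counts[99] == 6
        assert tplots["t1"].total_tags == 6

    def test_multi_transcript_tag_counted_in_both(self):
        rng = np.random.default_rng(1)
        core = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 30)])
        tr = [
            FastaRecord("t1", "", "AAAA" + core + "GGGG"),
            FastaRecord("t2", "", core + "TTTTTT"),
        ]
        tag = core[:20]
        tplots = build_tplot([CollapsedRead(tag, 2)], tr)
        assert tplots["t1"].position_counts[4] == 2
        assert tplots["t2"].position_counts[0] == 2

    def test_unmatched_tags_leave_zero_tplot(self):
        tr = [FastaRecord("t1", "", "A" * 100)]
        tplots = build_tplot([CollapsedRead("C" * 20, 5)], tr)
        assert tplots["t1"].total_tags == 0


class TestScoreAlignment:
    def test_perfect_complement_scores_zero(self):
        penalty, marks = score_alignment(MIRNA, revcomp(MIRNA))
        assert penalty == 0.0 and set(marks) == {"|"}

    def test_wobble_in_core_is_doubled(self):
        # G:U at miRNA position 4: miRNA G faces target T
        site = list(revcomp(MIRNA))
        pos = 4
        assert MIRNA[pos - 1] == "G"
        site[len(site) - pos] = "T"
        penalty, marks = score_alignment(MIRNA, "".join(site))
        assert penalty == pytest.approx(1.0)
        assert marks[pos - 1] == "o"

    def test_mismatch_outside_core_single_weight(self):
        site = list(revcomp(MIRNA))
        pos = 20
        m = MIRNA[pos - 1]
        site[len(site) - pos] = m  # same base never pairs
        penalty, marks = score_alignment(MIRNA, "".join(site))
        assert penalty == pytest.approx(1.0)
        assert marks[pos - 1] == "x"

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            score_alignment(MIRNA, MIRNA[:-1])

    @settings(deadline=None, max_examples=100)
    @given(
        st.text(alphabet="ACGT", min_size=18, max_size=24),
        st.data(),
    )
    def test_agrees_with_naive_recomputation(self, mirna, data):
        site = data.draw(st.text(alphabet="ACGT", min_size=len(mirna), max_size=len(mirna)))
        penalty, _ = score_alignment(mirna, site)
        assert penalty == pytest.approx(naive_alignment_penalty(mirna, site))


class TestClassifyCategory:
    @pytest.mark.parametrize(
        "counts,site,expected",
        [
            ([0, 0, 50, 3, 1], 2, "I"),
            ([40, 0, 30, 3], 2, "II"),
            ([40, 0, 5, 3], 2, "III"),
            ([40, 0, 40, 3], 2, "II"),  # shared maximum is not category I
            ([0, 0, 1], 2, "I"),
        ],
    )
    def test_definition_grid(self, counts, site, expected):
        assert classify_category(_tplot(counts), site) == expected

    def test_all_zero_tplot_is_an_error(self):
        with pytest.raises(ValueError):
            classify_category(_tplot([0, 0, 0]), 1)

    def test_monotone_in_site_count(self):
        """Raising the cleavage count never demotes the category."""
        order = {"III": 0, "II": 1, "I": 2}
        previous = -1
        for site_count in range(1, 61):
            counts = [40, 0, site_count, 3]
            rank = order[classify_category(_tplot(counts), 2)]
            assert rank >= previous
            previous = rank


class TestCallTargets:
    def _fixture(self, site_count=50):
        rng = np.random.default_rng(3)
        seq = list("".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)]))
        seq[100:121] = revcomp(MIRNA)
        seq = "".join(seq)
        tr = [FastaRecord("t1", "", seq)]
        cleavage = 100 + 21 - 10
        tags = [CollapsedRead(seq[cleavage:cleavage + 20], site_count)]
        return tr, tags, cleavage

    def test_planted_site_called_category_one(self):
        tr, tags, cleavage = self._fixture()
        tplots = build_tplot(tags, tr)
        calls = call_targets({"mir": MIRNA}, tplots, tr, PipelineConfig(), library="leaf")
        assert len(calls) == 1
        call = calls[0]
        assert call.cleavage_site == cleavage
        assert call.category == "I"
        assert call.penalty == 0.0

    def test_penalty_above_threshold_blocks_call(self):
        # corrupt the site to penalty 7.5: wobble at position 1 (0.5),
        # core mismatches at 3/4/9 (2.0 each), outer mismatch at 16 (1.0)
        site = list(revcomp(MIRNA))
        L = len(MIRNA)
        site[L - 1] = "G"   # faces miRNA position 1 (T) -> wobble
        site[L - 3] = "G"   # faces position 3 (G) -> mismatch, core
        site[L - 4] = "G"   # faces position 4 (G) -> mismatch, core
        site[L - 9] = "G"   # faces position 9 (G) -> mismatch, core
        site[L - 16] = "T"  # faces position 16 (T) -> mismatch, outer
        site = "".join(site)
        penalty, _ = score_alignment(MIRNA, site)
        assert penalty == pytest.approx(7.5)

        rng = np.random.default_rng(4)
        seq = list("".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)]))
        seq[100:121] = site
        tr = [FastaRecord("t1", "", "".join(seq))]
        cleavage = 100 + L - 10
        tags = [CollapsedRead(tr[0].sequence[cleavage:cleavage + 20], 50)]
        tplots = build_tplot(tags, tr)
        assert call_targets({"mir": MIRNA}, tplots, tr, PipelineConfig(penalty_threshold=7.0)) == []
        assert len(call_targets({"mir": MIRNA}, tplots, tr, PipelineConfig(penalty_threshold=7.5))) == 1

    def test_no_tags_at_site_means_no_call(self):
        tr, tags, cleavage = self._fixture()
        away = [CollapsedRead(tr[0].sequence[10:30], 99)]  # abundant tag elsewhere
        tplots = build_tplot(away, tr)
        calls = call_targets({"mir": MIRNA}, tplots, tr, PipelineConfig())
        assert calls == []
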