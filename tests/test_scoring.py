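"""Scoring rules: position dominance, GC monotonicity, strand bonus, ranking."""

import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crispra_design.scan import GuideCandidate
from crispra_design.scoring import (
    DesignConfig,
    apply_filters,
    composite_score,
    gc_score,
    position_score,
    predicted_fold_activation,
    rank_candidates,
    score_candidate,
)

CFG = DesignConfig()


def make_candidate(d_tss=-200, gc_count=10, strand_class="NT", start=0,
                   strand="+", contig="c1", spacer=None):
    spacer = spacer or ("GC" * (gc_count // 2) + "G" * (gc_count % 2)
                        + "AT" * ((20 - gc_count) // 2)
                        + "A" * ((20 - gc_count) % 2))
    return GuideCandidate(
        gene_id="g", contig_id=contig, gene_strand="+", spacer_seq=spacer,
        pam_seq="TGG", protospacer_strand=strand, protospacer_start=start,
        d_tss=d_tss, gc_fraction=gc_count / 20, strand_class=strand_class,
    )


class TestPositionScore:
    @pytest.mark.parametrize(
        "d,expected",
        [
            (-300, 1.0), (-450, 1.0), (-150, 1.0),   # optimal window, closed
            (-100, 0.5), (-1, 0.5),                   # proximal flank
            (-451, 0.5), (-600, 0.5), (-599, 0.5),    # distal flank
            (-601, 0.0), (-1000, 0.0),                # beyond the hard cutoff
            (0, 0.0), (50, 0.0),                      # at/downstream of the TSS
        ],
    )
    def test_piecewise_mapping(self, d, expected):
        assert position_score(d, CFG) == expected

    def test_custom_flank_score(self):
        cfg = DesignConfig(flank_score=0.25)
        assert position_score(-100, cfg) == 0.25


class TestGcScore:
    def test_identity(self):
        assert gc_score(0.75) == 0.75
        assert gc_score(0.0) == 0.0
        assert gc_score(1.0) == 1.0

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            gc_score(1.1)


class TestComposite:
    def test_maximal_candidate_scores_one(self):
        assert composite_score(1.0, 1.0, 1, CFG) == pytest.approx(1.0)

    def test_position_zero_dominates_everything(self):
        assert composite_score(0.0, 0.75, 1, CFG) == 0.0

    def test_weighted_arithmetic(self):
        assert composite_score(1.0, 0.5, 0, CFG) == pytest.approx(0.5)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            DesignConfig(w0=0.5, w_gc=0.6, w_nt=0.2)

    @given(
        st.integers(min_value=-1200, max_value=300),
        st.integers(min_value=0, max_value=20),
        st.sampled_from([0, 1]),
    )
    @settings(max_examples=300, deadline=None)
    def test_composite_bounded_and_dominated(self, d, gc_count, nt):
        p = position_score(d, CFG)
        s = composite_score(p, gc_count / 20, nt, CFG)
        assert 0.0 <= s <= 1.0
        if p == 0.0:
            assert s == 0.0
        else:
            assert s >= p * CFG.w0

    def test_gc_monotonicity_strict_when_placed(self):
        """At fixed distance and strand, score strictly increases with GC."""
        for d in (-200, -500, -100):
            for nt in (0, 1):
                scores = [
                    composite_score(position_score(d, CFG), g / 20, nt, CFG)
                    for g in range(21)
                ]
                assert all(b > a for a, b in zip(scores, scores[1:]))

    def test_nt_strand_bonus(self):
        """At fixed distance and GC, NT beats T by exactly P * w_nt."""
        for d in (-200, -500):
            p = position_score(d, CFG)
            gap = composite_score(p, 0.5, 1, CFG) - composite_score(p, 0.5, 0, CFG)
            assert gap == pytest.approx(p * CFG.w_nt)
            assert gap > 0


class TestFoldCalibration:
    def test_anchors_exact(self):
        assert predicted_fold_activation(0.0) == pytest.approx(2.0, abs=1e-9)
        assert predicted_fold_activation(0.9) == pytest.approx(35.0, abs=1e-9)

    def test_midpoint_is_geometric_mean_of_anchors(self):
        # log-linear: fold(0.45) = sqrt(2 * 35) = 2 * sqrt(17.5)
        assert predicted_fold_activation(0.45) == pytest.approx(
            2 * np.sqrt(17.5), rel=1e-12
        )

    def test_strictly_increasing_and_at_least_the_lower_anchor(self):
        grid = np.linspace(0, 1, 101)
        folds = [predicted_fold_activation(g) for g in grid]
        assert all(b > a for a, b in zip(folds, folds[1:]))
        assert min(folds) >= 1.0


class TestFilters:
    def test_polyt_flagged_but_kept_by_default(self):
        cand = make_candidate(spacer="TTTT" + "A" * 16, gc_count=0)
        flags, keep = apply_filters(cand, CFG)
        assert "polyT" in flags and keep

    def test_polyt_drop_mode(self):
        cand = make_candidate(spacer="TTTT" + "A" * 16, gc_count=0)
        flags, keep = apply_filters(cand, DesignConfig(polyt_filter="drop"))
        assert not keep

    def test_polyt_off_mode(self):
        cand = make_candidate(spacer="TTTT" + "A" * 16, gc_count=0)
        flags, keep = apply_filters(cand, DesignConfig(polyt_filter="off"))
        assert "polyT" not in flags and keep

    def test_extrapolated_gc_flag(self):
        flags, _ = apply_filters(make_candidate(gc_count=19), CFG)
        assert "extrapolated_gc" in flags

    def test_truncated_window_inherited(self):
        flags, _ = apply_filters(make_candidate(), CFG, window_truncated=True)
        assert "truncated_window" in flags

    def test_clean_spacer_unflagged(self):
        flags, keep = apply_filters(make_candidate(spacer="GC" * 10, gc_count=20), CFG)
        # gc 1.0 > 0.9 anchor is still extrapolated; use gc within range
        flags2, _ = apply_filters(make_candidate(spacer="GCAT" * 5, gc_count=10), CFG)
        assert flags2 == frozenset()


class TestRanking:
    def _scored(self, cands):
        return [(c, score_candidate(c, CFG)) for c in cands]

    def test_tiebreak_prefers_distance_near_minus_200(self):
        a = make_candidate(d_tss=-210, gc_count=12, start=100)
        b = make_candidate(d_tss=-350, gc_count=12, start=200)
        ranked = rank_candidates(self._scored([b, a]), CFG)
        assert ranked[0][0].d_tss == -210

    def test_tiebreak_nt_before_t(self):
        a = make_candidate(d_tss=-210, strand_class="T", start=100)
        b = make_candidate(d_tss=-190, strand_class="NT", start=200)
        # same |d + 200|, same gc; the NT bonus already separates composites
        ranked = rank_candidates(self._scored([a, b]), CFG)
        assert ranked[0][0].strand_class == "NT"
        # force equal composite via w_nt = 0: NT still wins on the tiebreak
        cfg0 = DesignConfig(w0=0.4, w_gc=0.6, w_nt=0.0)
        scored = [(c, score_candidate(c, cfg0)) for c in (a, b)]
        assert rank_candidates(scored, cfg0)[0][0].strand_class == "NT"

    def test_order_independent_of_input_permutation(self):
        rng = np.random.default_rng(3)
        cands = [
            make_candidate(
                d_tss=int(rng.integers(-700, 50)),
                gc_count=int(rng.integers(0, 21)),
                strand_class=("NT", "T")[int(rng.integers(2))],
                start=int(rng.integers(0, 5000)),
                strand=("+", "-")[int(rng.integers(2))],
            )
            for _ in range(40)
        ]
        scored = self._scored(cands)
        reference = rank_candidates(scored, CFG)
        for seed in range(5):
            shuffled = scored[:]
            random.Random(seed).shuffle(shuffled)
            assert rank_candidates(shuffled, CFG) == reference

    def test_total_order_is_transitive_and_antisymmetric(self):
        """Sorting twice, and sorting a reversed list, give the same chain."""
        cands = [
            make_candidate(d_tss=d, gc_count=g, strand_class=sc, start=i)
            for i, (d, g, sc) in enumerate(
                [(-200, 10, "NT"), (-200, 10, "T"), (-250, 10, "NT"),
                 (-200, 12, "NT"), (-650, 20, "NT"), (10, 20, "NT")]
            )
        ]
        scored = self._scored(cands)
        once = rank_candidates(scored, CFG)
        assert rank_candidates(once, CFG) == once
        assert rank_candidates(list(reversed(once)), CFG) == once


class TestConfigFile:
    def test_round_trip_overrides(self, tmp_path):
        text = (
            "# design overrides\n"
            "upstream_bp = 800\n"
            "optimal_window = -400, -100\n"
            "w0 = 0.3\nw_gc = 0.5\nw_nt = 0.2\n"
            "polyt_filter = drop\n"
        )
        path = tmp_path / "cfg.txt"
        path.write_text(text)
        cfg = DesignConfig.from_file(path)
        assert cfg.upstream_bp == 800
        assert cfg.optimal_window == (-400, -100)
        assert cfg.w0 == 0.3 and cfg.polyt_filter == "drop"
        # untouched keys keep defaults
        assert cfg.spacer_len == 20

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "cfg.txt"
        path.write_text("upstream_bp 800\n")
        with pytest.raises(ValueError, match="key = value"):
            DesignConfig.from_file(path)

    def test_window_must_be_inside_cutoff(self):
        with pytest.raises(ValueError, match="nested"):
            DesignConfig(optimal_window=(-700, -150))
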