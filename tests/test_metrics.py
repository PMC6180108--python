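"""Arousal parameters: composition, MVV, and the stability-score ladder.

The stability score is checked against an independent brute-force oracle that
literally walks the criteria table (blockwise B / B2/3 / C checks, deepest
criterion first, earliest fulfilling 5-min window) with plain loops.
"""

import numpy as np
import pytest

from vigikit.metrics import (arousal_stability_score, compute_metrics,
                             mean_vigilance_value, stage_composition)
from vigikit.stages import (STAGE_ORDER, STAGE_SCORES, Stage,
                            VigilanceTimecourse, as_stage)


def random_labels(rng, size, probs, stages):
    """Draw a random label list as true Stage members (numpy would coerce to str)."""
    idx = rng.choice(len(stages), size=size, p=probs)
    return [stages[i] for i in idx]

S0, A1, A23, B1, B23, C, ART = (Stage.ZERO, Stage.A1, Stage.A23, Stage.B1,
                                Stage.B23, Stage.C, Stage.ARTIFACT)


def tc_of(labels):
    return VigilanceTimecourse.from_labels(labels)


def ass_oracle(labels):
    """Literal reimplementation of the stability-score table (independent path)."""
    labels = list(labels)
    blocks = [labels[i * 60:(i + 1) * 60] for i in range(15)]

    def window_score(block_idx, base):
        if block_idx < 5:
            return base
        if block_idx < 10:
            return base + 1
        return base + 2

    # level 4: any C segment
    for i, blk in enumerate(blocks):
        seg = [s for s in blk if s is not ART]
        if not seg or (len(blk) - len(seg)) / len(blk) > 0.5:
            continue
        if any(s is C for s in seg):
            return window_score(i, 1)
    # level 3: >= 1/3 B2/3
    for i, blk in enumerate(blocks):
        seg = [s for s in blk if s is not ART]
        if not seg or (len(blk) - len(seg)) / len(blk) > 0.5:
            continue
        if sum(s is B23 for s in seg) / len(seg) >= 1 / 3:
            return window_score(i, 4)
    # level 2: >= 1/3 B
    for i, blk in enumerate(blocks):
        seg = [s for s in blk if s is not ART]
        if not seg or (len(blk) - len(seg)) / len(blk) > 0.5:
            continue
        if sum(s in (B1, B23) for s in seg) / len(seg) >= 1 / 3:
            return window_score(i, 7)
    # level 1
    seg = [s for s in labels if s is not ART]
    outside = sum(s not in (S0, A1) for s in seg) / len(seg)
    return 11 if outside < 1 / 3 else 10


class TestComposition:
    def test_percentages(self):
        counts, pct = stage_composition(tc_of([A1] * 300 + [B1] * 600))
        assert counts["A1"] == 300 and counts["B1"] == 600
        assert pct["A1"] == pytest.approx(100 / 3)
        assert pct["B1"] == pytest.approx(200 / 3)

    def test_artifacts_excluded_from_denominator(self):
        _, pct = stage_composition(tc_of([A1] * 300 + [B1] * 600 + [ART] * 100))
        assert pct["A1"] == pytest.approx(100 / 3)
        assert pct["B1"] == pytest.approx(200 / 3)

    def test_single_stage_is_100_percent(self):
        _, pct = stage_composition(tc_of([B23] * 100))
        assert pct["B2/3"] == 100.0

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(0)
        labels = random_labels(rng, 400, [1 / 7.0] * 7, list(STAGE_ORDER) + [ART])
        _, pct = stage_composition(tc_of(labels))
        assert sum(pct.values()) == pytest.approx(100.0)

    def test_per_minute_blocks(self):
        df = stage_composition(tc_of([A1] * 60 + [C] * 60), per_minute=True)
        assert df[(df.minute == 1) & (df.stage == "A1")].percent.iloc[0] == 100.0
        assert df[(df.minute == 2) & (df.stage == "C")].percent.iloc[0] == 100.0

    def test_all_artifact_rejected(self):
        with pytest.raises(ValueError):
            stage_composition(tc_of([ART] * 60))


class TestMVV:
    def test_bounds(self):
        assert mean_vigilance_value(tc_of([C] * 900)) == 1.0
        assert mean_vigilance_value(tc_of([S0] * 900)) == 6.0

    def test_equal_mix(self):
        assert mean_vigilance_value(tc_of([A1] * 450 + [B1] * 450)) == 4.0

    def test_artifacts_excluded(self):
        assert mean_vigilance_value(tc_of([C] * 10 + [ART] * 5)) == 1.0

    def test_per_minute(self):
        vals = mean_vigilance_value(tc_of([S0] * 60 + [C] * 60 + [ART] * 60),
                                    per_minute=True)
        assert vals[0] == 6.0 and vals[1] == 1.0 and np.isnan(vals[2])

    def test_concatenation_weighted_mean(self):
        a = tc_of([A1] * 100)
        b = tc_of([B23] * 300)
        combined = mean_vigilance_value(a.concat(b))
        expected = (100 * 5 + 300 * 2) / 400
        assert combined == pytest.approx(expected)


class TestStabilityScore:
    def test_rigid_only_high_stages_is_11(self):
        assert arousal_stability_score(tc_of([S0, A1] * 450)) == 11

    def test_b23_emerging_minute_7_without_c_is_5(self):
        labels = [A1] * 360 + ([B23] * 20 + [A1] * 40) + [A1] * 480
        assert arousal_stability_score(tc_of(labels)) == 5

    def test_single_c_in_minute_3_is_1(self):
        labels = [A1] * 900
        labels[130] = C
        assert arousal_stability_score(tc_of(labels)) == 1

    def test_b_emerging_late_is_9(self):
        labels = [A1] * 840 + [B1] * 30 + [A1] * 30
        assert arousal_stability_score(tc_of(labels)) == 9

    def test_mixed_below_two_thirds_high_is_10(self):
        # > 1/3 of segments outside {0, A1} but no block criterion fires
        labels = ([A1] * 36 + [A23] * 19 + [B1] * 5) * 15
        assert arousal_stability_score(tc_of(labels)) == 10

    def test_literal_rule_distinguishes_0a_from_0a1(self):
        only_a = [S0] * 300 + [A1] * 300 + [A23] * 300
        assert arousal_stability_score(tc_of(only_a), level1_rule="literal") == 10
        # fractional default: 1/3 outside {0, A1} is not < 1/3 -> 10 as well
        assert arousal_stability_score(tc_of(only_a)) == 10
        mostly_a1 = [S0] * 400 + [A1] * 400 + [A23] * 100
        assert arousal_stability_score(tc_of(mostly_a1)) == 11

    def test_deepest_level_wins_over_earliest_block(self):
        # B2/3 already in minute 2, single C only in minute 14 -> C band, score 3
        labels = [A1] * 60 + [B23] * 60 + [A1] * 720 + [A1] * 60
        labels[13 * 60 + 5] = C
        assert arousal_stability_score(tc_of(labels)) == 3

    def test_wrong_duration_strict_vs_lenient(self):
        short = tc_of([A1] * 300)
        with pytest.raises(ValueError, match="15"):
            arousal_stability_score(short)
        assert arousal_stability_score(short, strict_duration=False) == 11

    def test_artifact_heavy_block_skipped_with_warning(self):
        labels = [A1] * 900
        labels[60:100] = [ART] * 40   # minute 2: 2/3 artifacts
        labels[100:120] = [C] * 20
        with pytest.warns(UserWarning, match="skipped"):
            score = arousal_stability_score(tc_of(labels))
        assert score == 11

    def test_agrees_with_bruteforce_oracle_on_random_timecourses(self):
        rng = np.random.default_rng(2024)
        stages = list(STAGE_ORDER) + [ART]
        probs = [0.22, 0.26, 0.17, 0.13, 0.1, 0.07, 0.05]
        for _ in range(1000):
            labels = random_labels(rng, 900, probs, stages)
            tc = tc_of(labels)
            with pytest.warns(UserWarning) if _has_heavy_artifact_block(labels) \
                    else _nullcontext():
                got = arousal_stability_score(tc)
            assert got == ass_oracle(labels)

    def test_deepening_never_increases_score_or_mvv(self):
        rng = np.random.default_rng(7)
        depth = {s: i for i, s in enumerate(STAGE_ORDER)}
        for _ in range(200):
            labels = random_labels(rng, 900, [0.3, 0.3, 0.15, 0.12, 0.08, 0.05],
                                   list(STAGE_ORDER))
            i = int(rng.integers(900))
            d = depth[labels[i]]
            if d == 5:
                continue
            deeper = list(labels)
            deeper[i] = STAGE_ORDER[int(rng.integers(d + 1, 6))]
            assert (arousal_stability_score(tc_of(deeper))
                    <= arousal_stability_score(tc_of(labels)))
            assert (mean_vigilance_value(tc_of(deeper))
                    <= mean_vigilance_value(tc_of(labels)))


def _has_heavy_artifact_block(labels):
    for i in range(15):
        blk = labels[i * 60:(i + 1) * 60]
        if sum(s is ART for s in blk) / 60 > 0.5:
            return True
    return False


class _nullcontext:
    def __enter__(self):
        return self

    def __exit__(self, *a):
        return False


def test_compute_metrics_bundle():
    tc = tc_of([A1] * 450 + [B1] * 430 + [ART] * 20)
    m = compute_metrics(tc)
    assert 1.0 <= m.mvv <= 6.0
    assert m.ass in range(1, 12)
    assert m.n_artifact == 20
    assert sum(m.percentages.values()) == pytest.approx(100.0)
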