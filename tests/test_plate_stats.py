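"""Grubbs outlier screening, edge correction and plate Z-scoring."""

import math
from statistics import mean, stdev

import numpy as np
import pytest
from scipy import stats

from y1hscreen import (
    QuartetStatus,
    QuartetValue,
    UnscorablePlateError,
    edge_correction,
    grubbs_critical_value,
    grubbs_screen,
    score_plate,
)
from y1hscreen.plate_stats import is_edge_quartet


def brute_force_grubbs(values, alpha):
    """Independent oracle: recompute the Grubbs statistic from scratch with
    stdlib statistics after every removal."""
    vals = list(map(float, values))
    idx = list(range(len(vals)))
    removed = []
    while len(vals) >= 3:
        m = mean(vals)
        s = stdev(vals)
        if s == 0:
            break
        devs = [abs(v - m) for v in vals]
        i = devs.index(max(devs))
        n = len(vals)
        t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
        crit = (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))
        if devs[i] / s > crit:
            removed.append(idx[i])
            del vals[i]
            del idx[i]
        else:
            break
    return vals, removed


def make_plate_values(grid_values, status=QuartetStatus.OK, bait="b", occ_prefix="TF"):
    """Build QuartetValue objects covering the 16x24 grid from a dict
    (qrow,qcol)->value; missing positions are omitted."""
    out = []
    for (r, c), v in grid_values.items():
        out.append(
            QuartetValue(
                bait_id=bait,
                occupant=f"{occ_prefix}{r:02d}{c:02d}",
                qrow=r,
                qcol=c,
                value=v,
                status=status,
            )
        )
    return out


def uniform_grid(edge_value, interior_value, jitter=0.0, rng=None):
    grid = {}
    for r in range(1, 17):
        for c in range(1, 25):
            v = edge_value if is_edge_quartet(r, c) else interior_value
            if jitter and rng is not None:
                v += rng.normal(0.0, jitter)
            grid[(r, c)] = v
    return grid


class TestGrubbsScreen:
    def test_single_gross_outlier_removed(self):
        values = [1, 1, 1, 1, 1, 1, 1, 1, 1, 5]
        x = np.asarray(values, float)
        g = np.max(np.abs(x - x.mean())) / x.std(ddof=1)
        assert g == pytest.approx(2.846, abs=1e-3)
        assert grubbs_critical_value(10, 0.05) == pytest.approx(2.290, abs=1e-3)
        kept, removed = grubbs_screen(values, alpha=0.05)
        assert removed == [9]
        assert list(kept) == [1.0] * 9

    def test_constant_vector_has_no_outliers(self):
        kept, removed = grubbs_screen([3, 3, 3, 3, 3])
        assert removed == []
        assert list(kept) == [3.0] * 5

    def test_requires_three_values(self):
        with pytest.raises(ValueError):
            grubbs_screen([1.0, 2.0])

    def test_well_behaved_samples_rarely_trimmed(self):
        """On draws with no point beyond |z| = 2 the test should almost never
        remove anything at alpha = 0.05."""
        rng = np.random.default_rng(99)
        no_removal = 0
        n_draws = 100
        for _ in range(n_draws):
            x = rng.normal(0, 1, 50)
            x = x[np.abs(x) < 2.0]
            if x.size < 3:
                continue
            _, removed = grubbs_screen(x, alpha=0.05)
            no_removal += not removed
        assert no_removal >= 0.9 * n_draws

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            n = rng.integers(3, 21)
            x = rng.normal(0, 1, n)
            if rng.random() < 0.3:  # plant a gross outlier
                x[rng.integers(n)] += rng.choice([-1, 1]) * rng.uniform(4, 8)
            kept, removed = grubbs_screen(x, alpha=0.05)
            o_kept, o_removed = brute_force_grubbs(x, 0.05)
            assert removed == o_removed
            assert np.allclose(kept, o_kept)


class TestEdgeCorrection:
    def test_constructed_edge_effect_detected_and_removed(self):
        rng = np.random.default_rng(5)
        grid = uniform_grid(4.0, 3.0, jitter=0.01, rng=rng)
        values = make_plate_values(grid)
        corrected, detected, shift = edge_correction(values, alpha=0.05)
        assert detected
        assert shift == pytest.approx(1.0, abs=0.01)
        edge_vals = [
            corrected[(q.qrow, q.qcol)] for q in values if is_edge_quartet(q.qrow, q.qcol)
        ]
        assert np.mean(edge_vals) == pytest.approx(3.0, abs=0.01)

    def test_post_correction_retest_is_nonsignificant(self):
        rng = np.random.default_rng(5)
        values = make_plate_values(uniform_grid(4.0, 3.0, jitter=0.01, rng=rng))
        corrected, detected, _ = edge_correction(values, alpha=0.05)
        assert detected
        edge = [v for (r, c), v in corrected.items() if is_edge_quartet(r, c)]
        interior = [v for (r, c), v in corrected.items() if not is_edge_quartet(r, c)]
        _, p = stats.ttest_ind(edge, interior, equal_var=False)
        assert p > 0.05

    def test_nominal_false_detection_rate(self):
        """With identical edge/interior distributions the test should fire at
        roughly its alpha level across replicates."""
        rng = np.random.default_rng(11)
        detections = 0
        n_rep = 100
        for _ in range(n_rep):
            values = make_plate_values(uniform_grid(0.0, 0.0, jitter=1.0, rng=rng))
            _, detected, _ = edge_correction(values, alpha=0.05)
            detections += detected
        # 3 binomial SDs around 5 of 100
        assert detections <= 5 + 3 * math.sqrt(100 * 0.05 * 0.95)

    def test_no_detection_leaves_values_untouched(self):
        values = make_plate_values(uniform_grid(3.0, 3.0))
        corrected, detected, shift = edge_correction(values)
        assert not detected and shift == 0.0
        assert all(corrected[(q.qrow, q.qcol)] == q.value for q in values)

    def test_small_strata_skip_correction(self):
        values = make_plate_values({(1, 1): 4.0, (8, 12): 3.0})
        corrected, detected, shift = edge_correction(values)
        assert not detected and shift == 0.0 and len(corrected) == 2


class TestScorePlate:
    @staticmethod
    def _background_plate(rng, mu=3.0, sd=0.1):
        keys = [(r, c) for r in range(1, 17) for c in range(1, 25)]
        return make_plate_values({k: rng.normal(mu, sd) for k in keys})

    def test_z_and_p_examples(self):
        rng = np.random.default_rng(0)
        values = self._background_plate(rng, mu=3.0, sd=0.1)
        plate, scored = score_plate(values, plate_id="px")
        # z = 3 corresponds to one-sided p = 0.00135
        assert stats.norm.sf(3.0) == pytest.approx(0.00135, abs=1e-5)
        for sq in scored:
            assert sq.z == pytest.approx(
                (sq.corrected_value - plate.background_mean) / plate.background_sd
            )
            assert sq.p == pytest.approx(stats.norm.sf(sq.z), rel=1e-12)
        # a quartet sitting exactly at the background mean has z = 0, p = 0.5
        assert stats.norm.sf(0.0) == 0.5

    def test_survivor_z_scores_standardised(self):
        rng = np.random.default_rng(3)
        values = self._background_plate(rng)
        _, scored = score_plate(values)
        z = np.array([s.z for s in scored if not s.is_outlier])
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=1) - 1.0) < 1e-9

    def test_outlier_quartet_still_scored(self):
        rng = np.random.default_rng(4)
        grid = {k: rng.normal(3.0, 0.1) for k in uniform_grid(0, 0)}
        grid[(8, 12)] = 5.0  # gross positive outlier
        _, scored = score_plate(make_plate_values(grid))
        target = next(s for s in scored if (s.qrow, s.qcol) == (8, 12))
        assert target.is_outlier
        assert math.isfinite(target.z) and target.z > 5
        assert 0 < target.p < 1e-6

    def test_p_decreasing_in_z(self):
        rng = np.random.default_rng(6)
        _, scored = score_plate(self._background_plate(rng))
        ordered = sorted(scored, key=lambda s: s.z)
        ps = [s.p for s in ordered]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_excluded_quartets_carry_no_score(self):
        rng = np.random.default_rng(8)
        values = self._background_plate(rng)
        excluded = QuartetValue("b", "TFX", 1, 1, float("nan"),
                                QuartetStatus.EXCLUDED_SINGLE_COLONY)
        values = [v for v in values if (v.qrow, v.qcol) != (1, 1)] + [excluded]
        _, scored = score_plate(values)
        assert all((s.qrow, s.qcol) != (1, 1) for s in scored)
        assert len(scored) == 383

    def test_too_few_ok_quartets_unscorable(self):
        values = make_plate_values({(1, 1): 3.0, (1, 2): 3.1})
        with pytest.raises(UnscorablePlateError):
            score_plate(values)

    def test_degenerate_spread_unscorable(self):
        values = make_plate_values(uniform_grid(3.0, 3.0))
        with pytest.raises(UnscorablePlateError):
            score_plate(values)
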