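"""Tests of the Ktrans PI-RADS update rule and the threshold search."""

import itertools
import math

import numpy as np
import pytest

from qdce_pirads.diagnostic_stats import summarize
from qdce_pirads.pirads_qdce import (
    SENTINEL,
    SearchGrid,
    ThresholdPair,
    brute_force_thresholds,
    relabel_with_qdce,
    update_pirads,
)
from qdce_pirads.radpath_labeling import Criterion, label_lesions
from qdce_pirads.synthetic_cohort import Lesion

AA_THRESHOLDS = ThresholdPair(0.102, 0.206)


class TestUpdateRule:
    def test_upgrade_above_high_threshold(self):
        assert update_pirads(2, 0.250, AA_THRESHOLDS) == 3

    def test_downgrade_below_low_threshold(self):
        assert update_pirads(4, 0.050, AA_THRESHOLDS) == 2

    def test_inside_band_unchanged(self):
        assert update_pirads(3, 0.150, AA_THRESHOLDS) == 3

    def test_occult_lesion_can_be_upgraded(self):
        assert update_pirads(0, 0.250, AA_THRESHOLDS) == 3

    def test_boundary_equality_does_not_rescore(self):
        # strict inequalities: ktrans == threshold leaves the score alone
        assert update_pirads(2, 0.206, AA_THRESHOLDS) == 2
        assert update_pirads(4, 0.102, AA_THRESHOLDS) == 4

    @pytest.mark.parametrize("pirads,ktrans", list(itertools.product(range(6), (0.0, 0.15, 0.3))))
    def test_idempotent(self, pirads, ktrans):
        once = update_pirads(pirads, ktrans, AA_THRESHOLDS)
        assert update_pirads(once, ktrans, AA_THRESHOLDS) == once

    @pytest.mark.parametrize("pirads", range(6))
    def test_monotone_in_ktrans(self, pirads):
        scores = [update_pirads(pirads, k, AA_THRESHOLDS) for k in np.linspace(0, 0.4, 81)]
        assert all(b >= a for a, b in zip(scores, scores[1:]))

    def test_validation(self):
        with pytest.raises(ValueError):
            ThresholdPair(0.3, 0.1)
        with pytest.raises(ValueError):
            update_pirads(2, float("nan"), AA_THRESHOLDS)


class TestRelabel:
    def test_sentinel_is_identity(self, fig2_lesions):
        labeled = label_lesions(fig2_lesions, Criterion(3, 1))
        relabeled = relabel_with_qdce(labeled, SENTINEL, Criterion(3, 1))
        assert [x.label for x in relabeled] == [x.label for x in labeled]
        assert [x.lesion.pirads for x in relabeled] == [x.lesion.pirads for x in labeled]

    def test_occult_high_ktrans_lesion_flips_fn_to_tp(self, fig2_lesions, sector_map):
        # L3 (PI-RADS 0, ISUP 1) has ktrans 0.30 > t_high: FN -> TP, DR 0.5 -> 1.0
        criterion = Criterion(3, 1)
        labeled = label_lesions(fig2_lesions, criterion)
        assert summarize(labeled, sector_map).dr == pytest.approx(0.5)
        updated = relabel_with_qdce(labeled, AA_THRESHOLDS, criterion)
        assert [x.label for x in updated] == ["TP", "FP", "TP"]
        assert summarize(updated, sector_map).dr == pytest.approx(1.0)

    def test_downgraded_fp_leaves_ppv_denominator(self, sector_map):
        lesions = [
            Lesion("tp", "P", 2, 4, "PZ", frozenset({"PZ1"}), ktrans=0.20),
            Lesion("fp", "P", 0, 3, "PZ", frozenset({"PZ2"}), ktrans=0.01),
        ]
        criterion = Criterion(3, 2)
        before = summarize(label_lesions(lesions, criterion), sector_map)
        after = summarize(
            relabel_with_qdce(label_lesions(lesions, criterion), AA_THRESHOLDS, criterion),
            sector_map,
        )
        assert before.ppv == pytest.approx(0.5)
        assert after.ppv == pytest.approx(1.0)

    def test_missing_ktrans_names_the_lesion(self):
        lesion = Lesion("ghost", "P", 2, 4, "PZ", frozenset({"PZ1"}))  # ktrans NaN
        labeled = label_lesions([lesion], Criterion(3, 2))
        with pytest.raises(ValueError, match="ghost"):
            relabel_with_qdce(labeled, AA_THRESHOLDS, Criterion(3, 2))


def _random_labeled(rng, n=40, criterion=Criterion(3, 2)):
    lesions = []
    for i in range(n):
        isup = int(rng.integers(0, 6))
        pirads = int(rng.integers(0, 6)) if isup > 0 else int(rng.integers(3, 6))
        zone = "TZ" if rng.random() < 0.3 else "PZ"
        lesions.append(
            Lesion(f"L{i}", "P", isup, pirads, zone, frozenset({f"{zone}1"}),
                   ktrans=float(rng.gamma(4.0, 0.05)))
        )
    return label_lesions(lesions, criterion)


def _oracle_search(labeled, grid, criterion, sector_map=None):
    """Independent nested-loop search: every pair via relabel + summarize,
    with the documented tie-break (PPV, fewest rescored, smallest t_high,
    smallest t_low)."""
    values = list(grid.values)
    if values[0] > 0.0:
        values = [0.0] + values
    highs = values + [math.inf]
    base = summarize(labeled)
    candidates = []
    for t_low in values:
        for t_high in highs:
            if t_low > t_high:
                continue
            pair = ThresholdPair(t_low, t_high)
            updated = relabel_with_qdce(labeled, pair, criterion)
            s = summarize(updated)
            ppv = s.ppv if s.ppv is not None else float("nan")
            feasible = math.isnan(ppv) or base.ppv is None or ppv >= base.ppv - 1e-12
            if not feasible:
                continue
            n_changed = sum(
                u.lesion.pirads != l.lesion.pirads for u, l in zip(updated, labeled)
            )
            ppv_key = -1.0 if math.isnan(ppv) else ppv
            candidates.append(((-s.dr, -ppv_key, n_changed, t_high, t_low), pair, s))
    key, pair, s = min(candidates, key=lambda c: c[0])
    return pair, s


class TestBruteForce:
    def test_no_improving_move_returns_sentinel(self):
        # all FN ktrans below every grid t_high: nothing to upgrade
        lesions = [
            Lesion("fn", "P", 2, 0, "PZ", frozenset({"PZ1"}), ktrans=0.01),
            Lesion("tp", "P", 2, 4, "PZ", frozenset({"PZ2"}), ktrans=0.25),
        ]
        labeled = label_lesions(lesions, Criterion(3, 2))
        res = brute_force_thresholds(labeled, SearchGrid(0.05, 0.35, 0.05), Criterion(3, 2))
        assert res.dr == res.baseline_dr
        assert res.thresholds.t_low == 0.0

    def test_constructed_cohort_improves_both_metrics(self):
        lesions = (
            [Lesion(f"fn{i}", "P", 2, 2, "PZ", frozenset({"PZ1"}), ktrans=0.30) for i in range(2)]
            + [Lesion("fp", "P", 0, 3, "PZ", frozenset({"PZ2"}), ktrans=0.02)]
            + [Lesion(f"tp{i}", "P", 2, 4, "PZ", frozenset({"PZ3"}), ktrans=0.15) for i in range(3)]
        )
        labeled = label_lesions(lesions, Criterion(3, 2))
        res = brute_force_thresholds(labeled, SearchGrid(0.0, 0.35, 0.01), Criterion(3, 2))
        assert res.thresholds.t_high < 0.30
        assert res.thresholds.t_low > 0.02
        assert res.dr > res.baseline_dr
        assert res.ppv > res.baseline_ppv

    def test_contract_never_below_baseline(self, rng):
        for _ in range(20):
            labeled = _random_labeled(rng)
            res = brute_force_thresholds(labeled, SearchGrid(0.0, 0.35, 0.02), Criterion(3, 2))
            assert res.dr >= res.baseline_dr - 1e-12
            if res.baseline_ppv is not None and res.ppv is not None:
                assert res.ppv >= res.baseline_ppv - 1e-12

    def test_self_consistency_with_relabel_summarize(self, rng, sector_map):
        labeled = _random_labeled(rng)
        res = brute_force_thresholds(labeled, SearchGrid(0.0, 0.35, 0.02), Criterion(3, 2))
        s = summarize(relabel_with_qdce(labeled, res.thresholds, Criterion(3, 2)), sector_map)
        assert s.dr == pytest.approx(res.dr, abs=1e-12)
        assert s.ppv == pytest.approx(res.ppv, abs=1e-12)

    def test_matches_independent_oracle_on_coarse_grid(self, rng):
        grid = SearchGrid(0.0, 0.30, 0.05)
        for _ in range(5):
            labeled = _random_labeled(rng, n=25)
            res = brute_force_thresholds(labeled, grid, Criterion(3, 2))
            pair, s = _oracle_search(labeled, grid, Criterion(3, 2))
            assert res.thresholds == pair
            assert res.dr == pytest.approx(s.dr, abs=1e-12)

    def test_surfaces_shape_and_baseline_cell(self, rng):
        labeled = _random_labeled(rng)
        grid = SearchGrid(0.0, 0.30, 0.1)
        res = brute_force_thresholds(labeled, grid, Criterion(3, 2))
        assert res.dr_surface.shape == (res.t_low_grid.size, res.t_high_grid.size)
        assert math.isinf(res.t_high_grid[-1])
        assert res.dr_surface[0, -1] == pytest.approx(res.baseline_dr)
        # invalid half-plane (t_low > t_high) is masked
        assert math.isnan(res.dr_surface[-1, 0])

    def test_zone_scope_requires_map_and_is_consistent(self, rng, sector_map):
        labeled = _random_labeled(rng)
        with pytest.raises(ValueError):
            brute_force_thresholds(labeled, SearchGrid(0, 0.3, 0.1), Criterion(3, 2), scope="PZ")
        res = brute_force_thresholds(
            labeled, SearchGrid(0, 0.3, 0.1), Criterion(3, 2), scope="PZ", sector_map=sector_map
        )
        s = summarize(
            relabel_with_qdce(labeled, res.thresholds, Criterion(3, 2)), sector_map, "PZ"
        )
        assert s.dr == pytest.approx(res.dr, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            brute_force_thresholds([], SearchGrid(), Criterion(3, 2))
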