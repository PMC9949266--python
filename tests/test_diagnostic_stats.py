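"""Tests of weighted diagnostic summaries and the comparison tests."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from qdce_pirads.diagnostic_stats import (
    cancer_prevalence,
    lesions_per_patient,
    mann_whitney,
    summarize,
    weighted_chisq,
)
from qdce_pirads.radpath_labeling import Criterion, label_lesions
from qdce_pirads.synthetic_cohort import Lesion, SectorMap


def L(lid, isup, pirads, zone, sectors):
    return Lesion(lid, "P", isup, pirads, zone, frozenset(sectors))


class TestSummarize:
    def test_worked_example_whole_gland(self, fig2_lesions, sector_map):
        s = summarize(label_lesions(fig2_lesions, Criterion(3, 1)), sector_map)
        assert (s.tp_w, s.fp_w, s.fn_w) == (1.0, 1.0, 1.0)
        assert s.dr == pytest.approx(0.5)
        assert s.ppv == pytest.approx(0.5)
        strict = summarize(label_lesions(fig2_lesions, Criterion(4, 2)), sector_map)
        assert strict.dr == pytest.approx(1.0)
        assert strict.ppv == pytest.approx(1.0)

    def test_zone_weighted_counts_hand_computed(self, sector_map):
        # TP split across one TZ + one PZ sector; FN wholly in PZ:
        # TZ DR = 0.5/0.5 = 1, PZ DR = 0.5/1.5 = 1/3
        lesions = [
            L("A", 2, 4, "TZ", {"TZ1"}),  # declared TZ but spans into PZ below
            L("B", 2, 0, "PZ", {"PZ2"}),
        ]
        # construct the straddling lesion explicitly (sector map lookup is on
        # sectors, not the zone attribute, for zone scopes)
        straddle = Lesion("A", "P", 2, 4, "TZ", frozenset({"TZ1", "PZ1"}))
        labeled = label_lesions([straddle, lesions[1]], Criterion(3, 2))
        tz = summarize(labeled, sector_map, "TZ")
        pz = summarize(labeled, sector_map, "PZ")
        assert tz.dr == pytest.approx(1.0)
        assert pz.dr == pytest.approx(0.5 / 1.5)

    def test_whole_gland_counts_are_integer(self, rng, sector_map):
        lesions = [
            L(f"x{i}", int(rng.integers(1, 6)), int(rng.integers(0, 6)), "PZ",
              {f"PZ{k+1}" for k in rng.choice(6, rng.integers(1, 4), replace=False)})
            for i in range(40)
        ]
        s = summarize(label_lesions(lesions, Criterion(3, 1)), sector_map)
        for v in (s.tp_w, s.fp_w, s.fn_w):
            assert v == int(v)

    def test_undefined_ratios_are_missing(self, sector_map):
        only_fp = [L("f", 0, 4, "PZ", {"PZ1"})]
        s = summarize(label_lesions(only_fp, Criterion(3, 1)), sector_map)
        assert s.dr is None
        assert s.ppv == pytest.approx(0.0)
        assert s.cp is None

    def test_unknown_sector_rejected(self, sector_map):
        weird = L("w", 2, 4, "PZ", {"APEX9"})
        with pytest.raises(ValueError, match="unknown sector"):
            summarize(label_lesions([weird], Criterion(3, 1)), sector_map, "PZ")


class TestCancerPrevalence:
    def test_degenerate_all_pz(self, sector_map):
        labeled = label_lesions([L("a", 2, 4, "PZ", {"PZ1"})], Criterion(3, 1))
        cp = cancer_prevalence(labeled, sector_map)
        assert cp == {"TZ": 0.0, "PZ": 1.0}

    def test_even_split_lesion(self, sector_map):
        straddle = Lesion("a", "P", 2, 4, "TZ", frozenset({"TZ1", "PZ1"}))
        cp = cancer_prevalence(label_lesions([straddle], Criterion(3, 1)), sector_map)
        assert cp["TZ"] == pytest.approx(0.5)
        assert cp["PZ"] == pytest.approx(0.5)

    def test_no_pathology_positive_is_missing(self, sector_map):
        labeled = label_lesions([L("f", 0, 4, "PZ", {"PZ1"})], Criterion(3, 1))
        cp = cancer_prevalence(labeled, sector_map)
        assert cp["TZ"] is None and cp["PZ"] is None


def test_refining_the_sector_map_leaves_dr_ppv_invariant(sector_map):
    """Splitting every sector into two children within its zone must not
    change any zone-level DR/PPV: weights halve but zone totals persist."""
    lesions = [
        L("a", 2, 4, "TZ", {"TZ1", "TZ2"}),
        L("b", 2, 0, "PZ", {"PZ1"}),
        L("c", 0, 4, "PZ", {"PZ2", "PZ3"}),
        L("d", 3, 5, "PZ", {"PZ4"}),
    ]
    fine_ids = tuple(f"{s}{h}" for s in sector_map.sector_ids for h in ("a", "b"))
    fine_map = SectorMap(fine_ids, {s: s[:2] for s in fine_ids})
    refined = [
        Lesion(l.lesion_id, l.patient_id, l.isup, l.pirads, l.zone,
               frozenset(f"{s}{h}" for s in l.sectors for h in ("a", "b")))
        for l in lesions
    ]
    for zone in ("TZ", "PZ"):
        coarse = summarize(label_lesions(lesions, Criterion(3, 2)), sector_map, zone)
        fine = summarize(label_lesions(refined, Criterion(3, 2)), fine_map, zone)
        assert fine.dr == pytest.approx(coarse.dr) or (fine.dr is None and coarse.dr is None)
        assert fine.ppv == pytest.approx(coarse.ppv) or (fine.ppv is None and coarse.ppv is None)


class TestWeightedChisq:
    def test_identical_proportions_give_zero_statistic(self):
        stat, p = weighted_chisq((30.0, 10.0), (60.0, 20.0))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_integer_table_matches_scipy_oracle(self):
        table = np.array([[32, 9], [64, 19]])
        stat, p = weighted_chisq(tuple(table[0]), tuple(table[1]))
        ref_stat, ref_p, _, _ = sps.chi2_contingency(table, correction=False)
        assert stat == pytest.approx(ref_stat, rel=1e-12)
        assert p == pytest.approx(ref_p, rel=1e-12)

    def test_statistic_scales_linearly_with_weights(self):
        base, _ = weighted_chisq((12.5, 4.25), (20.0, 11.75))
        scaled, _ = weighted_chisq((12.5 * 3, 4.25 * 3), (20.0 * 3, 11.75 * 3))
        assert scaled == pytest.approx(3.0 * base, rel=1e-12)

    def test_zero_expected_cell_warns_and_returns_nan(self):
        with pytest.warns(UserWarning, match="zero expected"):
            stat, p = weighted_chisq((5.0, 0.0), (3.0, 0.0))
        assert math.isnan(stat) and math.isnan(p)

    def test_continuity_correction_shrinks_statistic(self):
        plain, _ = weighted_chisq((8, 2), (3, 7))
        corrected, _ = weighted_chisq((8, 2), (3, 7), continuity=True)
        assert corrected < plain


def _exact_mw_p(x, y):
    """Full-enumeration two-sided Mann-Whitney oracle (no ties)."""
    pooled = sorted(x + y)
    n, m = len(x), len(y)
    u_obs = sum(sum(xi > yj for yj in y) for xi in x)
    us = [
        sum(sum(a > b for b in (set(pooled) - set(combo))) for a in combo)
        for combo in itertools.combinations(pooled, n)
    ]
    mean_u = n * m / 2.0
    dev = abs(u_obs - mean_u)
    extreme = sum(abs(u - mean_u) >= dev - 1e-12 for u in us)
    return extreme / len(us)


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 / C(6,3)

    def test_identical_multisets(self):
        _, p = mann_whitney([1.0, 2.0, 5.0], [5.0, 1.0, 2.0])
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_all_equal(self):
        u, p = mann_whitney([3.0, 3.0], [3.0, 3.0, 3.0])
        assert p == 1.0

    @pytest.mark.parametrize("nx,ny", [(3, 3), (4, 3), (4, 4)])
    def test_exact_p_matches_enumeration(self, rng, nx, ny):
        for _ in range(5):
            pooled = rng.choice(1000, size=nx + ny, replace=False).astype(float)
            x, y = list(pooled[:nx]), list(pooled[nx:])
            _, p = mann_whitney(x, y)
            assert p == pytest.approx(_exact_mw_p(x, y), abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


def test_lesion_rate_arithmetic():
    assert lesions_per_patient(3, 2) == 1.5
    with pytest.raises(ValueError):
        lesions_per_patient(5, 0)
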