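import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from glucest.asym import (
    GluMap,
    age_trend_report,
    glucest_map,
    mtrasym_curve,
    roi_group_table,
)
from glucest.phantom import (
    DEFAULT_POOLS,
    DEFAULT_ROI_TARGETS,
    PoolParams,
    build_glu_amplitude_map,
    simulate_zspectrum,
)
from glucest.zspec import FrequencyAxis, ZSpectrum, cest_axis
from tests.conftest import small_cohort


class TestMtrasymCurve:
    def test_symmetric_spectrum_zero(self):
        spec = simulate_zspectrum([PoolParams("water", 0.0, 2.0, 0.8),
                                   PoolParams("mt", 0.0, 20.0, 0.05)])
        assert np.max(np.abs(mtrasym_curve(spec).value)) < 1e-12

    def test_glutamate_closed_form(self, glu_pool):
        curve = mtrasym_curve(simulate_zspectrum([glu_pool]))
        expected = 0.05 * (1 - 0.25 / (0.25 + 36))
        assert curve.at(3.0) == pytest.approx(expected, abs=1e-12)

    def test_1200hz_equals_3ppm(self, glu_pool):
        curve = mtrasym_curve(simulate_zspectrum([glu_pool]))
        assert curve.at_hz(1200.0) == curve.at(3.0)

    def test_no_symmetric_pairs_raises(self):
        ax = FrequencyAxis(np.array([-1.0, 0.5, 2.0]))
        with pytest.raises(ValueError):
            mtrasym_curve(ZSpectrum(ax, np.ones(3)))

    @given(st.floats(0.005, 0.06), st.floats(0.3, 2.0), st.floats(1.0, 4.0))
    def test_antisymmetry_extension(self, amp, fwhm, center):
        # value(-d) = -value(d) when the formula is extended to negative d
        spec = simulate_zspectrum([PoolParams("p", center, fwhm, amp)])
        offs, z = spec.axis.offsets, spec.z
        for d in (1.0, 2.5, 3.0):
            fwd = z[offs == -d][0] - z[offs == d][0]
            bwd = z[offs == d][0] - z[offs == -d][0]
            assert bwd == pytest.approx(-fwd, abs=1e-15)

    def test_linearity_mean_spectrum_equals_mean_curve(self):
        specs = [simulate_zspectrum([PoolParams("p", 3.0, 1.0, a)])
                 for a in (0.01, 0.03, 0.05)]
        mean_sig = np.mean([s.z for s in specs], axis=0)
        curve_of_mean = mtrasym_curve(ZSpectrum(cest_axis(), mean_sig))
        mean_of_curves = np.mean([mtrasym_curve(s).value for s in specs], axis=0)
        np.testing.assert_allclose(curve_of_mean.value, mean_of_curves,
                                   atol=1e-15)

    def test_monotone_in_glutamate_amplitude(self):
        vals = [mtrasym_curve(simulate_zspectrum(
            list(DEFAULT_POOLS) + [PoolParams("glu", 3.0, 1.0, a)])).at(3.0)
            for a in (0.01, 0.02, 0.03)]
        assert vals[0] < vals[1] < vals[2]


class TestGluCestMap:
    def test_noiseless_zero_b0_matches_analytic(self, label_map_small):
        acq = small_cohort("AD", 2)[0]
        gmap = glucest_map(acq.cest)
        for roi, target in enumerate(DEFAULT_ROI_TARGETS[("AD", 2)], start=1):
            pix = gmap.values[label_map_small.roi_mask(roi)]
            np.testing.assert_allclose(pix, target, atol=1e-6)

    def test_background_missing(self):
        acq = small_cohort()[0]
        gmap = glucest_map(acq.cest)
        assert np.all(np.isnan(gmap.values[~acq.cest.mask]))

    def test_ad_mean_exceeds_wt_at_12_months(self):
        ad = glucest_map(small_cohort("AD", 12)[0].cest)
        wt = glucest_map(small_cohort("WT", 12)[0].cest)
        assert ad.in_mask_mean() > wt.in_mask_mean()

    def test_unsampled_readout_raises(self):
        ax = FrequencyAxis(np.array([-1.0, 0.0, 1.0]))
        from glucest.zspec import ZStack

        stack = ZStack(ax, np.ones((2, 2, 3)), np.ones((2, 2), dtype=bool))
        with pytest.raises(ValueError):
            glucest_map(stack)


def _uniform_map(value, label_map, **meta):
    vals = np.full(label_map.shape, np.nan)
    vals[label_map.brain] = value
    return GluMap(values=vals, mask=label_map.brain, **meta)


class TestRoiGroupTable:
    def test_reproduces_all_40_cells(self, label_map_small):
        maps = []
        for (gt, age), _targets in DEFAULT_ROI_TARGETS.items():
            acq = small_cohort(gt, age)[0]
            maps.append(glucest_map(acq.cest, subject_id=f"{gt}{age}",
                                    genotype=gt, age_group=age))
        table = roi_group_table(maps, label_map_small)
        for (gt, age), targets in DEFAULT_ROI_TARGETS.items():
            for roi, target in enumerate(targets, start=1):
                assert table.loc[f"ROI{roi}", (age, gt)] == pytest.approx(
                    target, abs=1e-4)

    def test_uniform_subject_cell_is_constant(self, label_map_small):
        m = _uniform_map(0.03, label_map_small, subject_id="s1",
                         genotype="AD", age_group=7)
        table = roi_group_table([m], label_map_small)
        assert table.loc["ROI3", (7, "AD")] == pytest.approx(0.03)

    def test_empty_cells_missing_not_zero(self, label_map_small):
        m = _uniform_map(0.02, label_map_small, subject_id="s1",
                         genotype="WT", age_group=2)
        table = roi_group_table([m], label_map_small)
        assert np.isnan(table.loc["ROI1", (12, "AD")])

    def test_subject_equal_weighting(self, label_map_small):
        maps = [_uniform_map(v, label_map_small, subject_id=f"s{k}",
                             genotype="AD", age_group=2)
                for k, v in enumerate((0.01, 0.03))]
        table = roi_group_table(maps, label_map_small)
        assert table.loc["ROI1", (2, "AD")] == pytest.approx(0.02)

    def test_noisy_cells_within_three_standard_errors(self, label_map_small):
        n = 5
        subs = small_cohort("AD", 2, n=n, sigma=0.01, seed=3)
        maps = [glucest_map(s.cest, subject_id=s.subject_id, genotype="AD",
                            age_group=2) for s in subs]
        table = roi_group_table(maps, label_map_small)
        for roi, target in enumerate(DEFAULT_ROI_TARGETS[("AD", 2)], start=1):
            n_pix = int(label_map_small.roi_mask(roi).sum())
            # per-pixel MTRasym noise std = sigma * sqrt(2); ROI+subject mean
            se = 0.01 * np.sqrt(2) / np.sqrt(n_pix * n)
            assert abs(table.loc[f"ROI{roi}", (2, "AD")] - target) < 3 * se

    def test_missing_metadata_raises(self, label_map_small):
        m = _uniform_map(0.02, label_map_small)
        with pytest.raises(ValueError):
            roi_group_table([m], label_map_small)


class TestAgeTrendReport:
    @staticmethod
    def _default_table():
        cols = pd.MultiIndex.from_tuples(
            [(a, g) for a in (2, 4, 7, 12) for g in ("AD", "WT")],
            names=["age_group", "genotype"])
        table = pd.DataFrame(index=[f"ROI{r}" for r in range(1, 6)],
                             columns=cols, dtype=float)
        for (gt, age), targets in DEFAULT_ROI_TARGETS.items():
            table[(age, gt)] = list(targets)
        return table

    def test_ad_exceeds_wt_in_39_of_40_cells(self):
        table = self._default_table()
        report = age_trend_report(table)
        advswt = report[report.comparison.str.startswith("AD_minus_WT")]
        assert len(advswt) == 20  # per-ROI, per-age contrasts
        positive = (advswt.difference > 0).sum()
        ties = (advswt.difference == 0).sum()
        assert positive == 19 and ties == 1
        tie_row = advswt[advswt.difference == 0].iloc[0]
        assert tie_row.roi == "ROI5" and "4m" in tie_row.comparison

    def test_old_minus_young_positive_everywhere(self):
        report = age_trend_report(self._default_table())
        old_young = report[report.comparison.str.startswith("old_minus_young")]
        assert (old_young.difference > 0).all()

    def test_identical_groups_all_zero(self):
        table = self._default_table()
        for col in table.columns:
            table[col] = 0.02
        report = age_trend_report(table)
        assert np.allclose(report.difference, 0.0)

    def test_single_age_group_raises(self):
        table = self._default_table()[[(2, "AD"), (2, "WT")]]
        with pytest.raises(ValueError):
            age_trend_report(table)
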