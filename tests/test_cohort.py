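"""Regional summaries, stage trends, Bland-Altman, cohort pipeline."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import lungmech as lm
from lungmech.cohort import (
    ENTROPY_BINS,
    MEASURES,
    bland_altman,
    cohort_run,
    region_summary,
    stage_trend,
)
from lungmech.phantom import make_cohort


def _lobes_and_map(values_in_region, shape=(8, 8, 8), label=1):
    """A label volume whose region 1 holds the given interior values."""
    g = lm.Grid(shape)
    lab = np.zeros(shape, int)
    data = np.zeros(shape)
    vals = np.asarray(values_in_region, float)
    interior = np.zeros(shape, bool)
    interior[1:-1, 1:-1, 1:-1] = True
    idx = np.argwhere(interior)[: len(vals)]
    assert len(idx) == len(vals), "region larger than interior"
    for (i, j, k), v in zip(idx, vals):
        lab[i, j, k] = label
        data[i, j, k] = v
    return lm.Volume(data, g, "map"), lm.Volume(lab, g, "label")


class TestRegionSummary:
    def test_constant_region(self):
        m, lab = _lobes_and_map(np.full(50, 1.7))
        s = region_summary(m, lab, "RUL", "J")
        assert s.mean == pytest.approx(1.7)
        assert s.std == 0.0
        assert s.entropy == 0.0
        assert s.rms == pytest.approx(1.7)
        assert s.n_valid == 50

    def test_two_level_region(self):
        m, lab = _lobes_and_map([1.0] * 40 + [3.0] * 40)
        s = region_summary(m, lab, "RUL", "J")
        assert s.mean == pytest.approx(2.0)
        assert s.entropy == pytest.approx(1.0)  # two equally filled bins
        assert s.rms == pytest.approx(np.sqrt(5.0))

    def test_uniform_over_all_bins_gives_log2_nbins(self):
        # one value at the centre of each of the 64 J-bins on [0, 4]
        centers = (np.arange(ENTROPY_BINS) + 0.5) * (4.0 / ENTROPY_BINS)
        m, lab = _lobes_and_map(centers)
        s = region_summary(m, lab, "RUL", "J")
        assert s.entropy == pytest.approx(np.log2(ENTROPY_BINS))

    def test_rms_identity_and_entropy_bounds(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.5, 2.5, 100)
        m, lab = _lobes_and_map(vals)
        s = region_summary(m, lab, "RUL", "J")
        assert s.rms**2 == pytest.approx(s.mean**2 + vals.var(ddof=0))
        assert 0.0 <= s.entropy <= np.log2(ENTROPY_BINS)

    def test_nan_voxels_excluded(self):
        vals = np.full(30, 2.0)
        vals[:10] = np.nan
        m, lab = _lobes_and_map(vals)
        s = region_summary(m, lab, "RUL", "J")
        assert s.n_valid == 20
        assert s.mean == pytest.approx(2.0)

    def test_boundary_shell_excluded_by_default(self):
        m, lab = _lobes_and_map(np.full(40, 1.5))
        # paint garbage onto a boundary voxel of the same label
        lab2 = np.asarray(lab.data).copy()
        data2 = np.asarray(m.data).copy()
        lab2[0, 0, 0] = 1
        data2[0, 0, 0] = 1e9
        s = region_summary(
            lm.Volume(data2, m.grid, "map"), lm.Volume(lab2, m.grid, "label"), "RUL", "J"
        )
        assert s.mean == pytest.approx(1.5)

    def test_empty_region_rejected(self):
        m, lab = _lobes_and_map([1.0])
        with pytest.raises(ValueError, match="no valid voxels"):
            region_summary(m, lab, "LLL", "J")


class TestStageTrend:
    def _table(self, stage_values):
        rows = []
        for stage, vals in stage_values.items():
            for i, v in enumerate(vals):
                rows.append(
                    {"stage": stage, "measure": "J_mean", "region": "LUNG",
                     "value": v, "subject_id": f"s{stage}_{i}"}
                )
        return pd.DataFrame(rows)

    def test_strictly_decreasing_detected(self):
        t = stage_trend(self._table({0: [1.8, 1.9], 1: [1.5, 1.4], 2: [1.1, 1.2]}), "J_mean")
        assert t["direction"] == "decreasing"
        assert t["spearman_rho"] < 0
        assert list(t["stage_means"]) == [0, 1, 2]

    def test_increasing_and_nonmonotone(self):
        inc = stage_trend(self._table({0: [1.0], 1: [2.0], 2: [3.0]}), "J_mean")
        assert inc["direction"] == "increasing"
        mix = stage_trend(self._table({0: [1.0], 1: [3.0], 2: [2.0]}), "J_mean")
        assert mix["direction"] == "none"

    def test_missing_rows_rejected(self):
        with pytest.raises(ValueError, match="no rows"):
            stage_trend(self._table({0: [1.0], 1: [2.0]}), "ADI_mean")
        with pytest.raises(ValueError, match="two nonempty stage"):
            stage_trend(self._table({0: [1.0, 1.2]}), "J_mean")


class TestBlandAltman:
    def test_identical_methods_collapse(self):
        x = np.array([1.0, 1.2, 0.9, 1.4])
        ba = bland_altman(x, x)
        assert ba.mean_diff == 0.0 and ba.sd_diff == 0.0
        assert ba.loa_low == 0.0 and ba.loa_high == 0.0

    def test_constant_difference(self):
        x = np.array([1.0, 2.0, 3.0])
        ba = bland_altman(x + 0.2, x)
        assert ba.mean_diff == pytest.approx(0.2)
        assert ba.sd_diff == pytest.approx(0.0, abs=1e-12)
        assert ba.loa_low == pytest.approx(0.2)
        assert ba.loa_high == pytest.approx(0.2)

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=(2, 50))
        f, r = bland_altman(x, y), bland_altman(y, x)
        assert f.mean_diff == pytest.approx(-r.mean_diff)
        assert f.sd_diff == pytest.approx(r.sd_diff)
        assert f.loa_low == pytest.approx(-r.loa_high)
        assert f.loa_high == pytest.approx(-r.loa_low)

    def test_gaussian_coverage_of_limits(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=10_000)
        y = x - rng.normal(scale=0.3, size=10_000)
        ba = bland_altman(x, y)
        inside = np.mean((ba.diffs >= ba.loa_low) & (ba.diffs <= ba.loa_high))
        assert inside == pytest.approx(0.95, abs=0.01)

    def test_validation(self):
        with pytest.raises(ValueError, match="paired"):
            bland_altman(np.zeros(3), np.zeros(4))
        with pytest.raises(ValueError, match="two"):
            bland_altman(np.zeros(1), np.zeros(1))


@pytest.fixture(scope="module")
def small_cohort():
    return make_cohort(
        2, (1.5, 1.2), 0.05, seed=21, shape=(48, 48, 48), with_images=False
    )


class TestCohortRun:
    def test_counting_contract(self, small_cohort):
        table, report = cohort_run(small_cohort, methods=("oracle",))
        # 2 stages x 2 subjects x 6 regions x 6 measures
        assert len(table) == 144
        assert set(table.columns) == {
            "subject_id", "stage", "method", "region", "measure", "value"
        }
        assert set(table["measure"]) == set(MEASURES)
        assert table["region"].nunique() == 6
        assert not report["excluded"]
        assert set(report["trends"]["oracle"]) == set(MEASURES)

    def test_identical_external_method_collapses_agreement(self, small_cohort):
        ext = {(s.subject_id, "ext"): s.true_dvf for s in small_cohort}
        _, report = cohort_run(small_cohort, methods=("oracle", "ext"), external_dvfs=ext)
        ba = report["bland_altman"]["ext_vs_oracle" if "ext_vs_oracle" in report["bland_altman"] else "oracle_vs_ext"]
        assert ba["mean_diff"] == 0.0
        assert ba["sd_diff"] == 0.0
        assert ba["n"] == 4

    def test_failed_subject_excluded_with_reason(self, small_cohort):
        broken = dataclasses.replace(
            small_cohort[0], subject_id="broken", true_dvf=None
        )
        table, report = cohort_run([broken] + list(small_cohort), methods=("oracle",))
        assert len(table) == 144  # intact subjects unaffected
        assert len(report["excluded"]) == 1
        assert report["excluded"][0]["subject_id"] == "broken"
        assert report["excluded"][0]["reason"]

    def test_unknown_method_recorded_as_exclusion(self, small_cohort):
        table, report = cohort_run(small_cohort[:1], methods=("magic",))
        assert table.empty
        assert report["excluded"][0]["reason"].startswith("unknown method")
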