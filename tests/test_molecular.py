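import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gliaquant.imaging import ImageStack, RoiMask
from gliaquant.molecular import (
    ddct_fold_change,
    intensity_partition,
    total_field_intensity,
)
from gliaquant.synthetic import SimConfig, simulate_intensity_image


def make_image(arr):
    return ImageStack(np.asarray(arr, np.float32), "YX", 0.5)


def qpcr_rows(groups: dict[str, tuple[float, float]], n=3) -> pd.DataFrame:
    """groups: label -> (target Cq, reference Cq), n samples each."""
    rows = []
    for g, (tq, rq) in groups.items():
        for i in range(n):
            sid = f"{g}_{i}"
            rows.append({"sample_id": sid, "group": g, "gene": "target", "cq": tq})
            rows.append({"sample_id": sid, "group": g, "gene": "reference", "cq": rq})
    return pd.DataFrame(rows)


class TestIntensityPartition:
    def test_complement_arithmetic(self):
        img = np.full((10, 10), 10.0, np.float32)  # total 1000
        soma = np.zeros((10, 10), bool)
        soma[:5, :5] = True  # 25 px × 10 a.u. = 250 in somas
        part = intensity_partition(make_image(img), [RoiMask(soma)])
        assert part.total_intensity == pytest.approx(1000.0)
        assert part.soma_intensity == pytest.approx(250.0)
        assert part.percent_in_processes == pytest.approx(75.0)

    def test_soma_covering_all_signal(self):
        img = np.zeros((8, 8), np.float32)
        img[2:4, 2:4] = 9.0
        soma = np.zeros((8, 8), bool)
        soma[2:4, 2:4] = True
        assert intensity_partition(make_image(img), [RoiMask(soma)]).percent_in_processes == 0.0

    def test_zero_total_flagged(self):
        soma = np.zeros((4, 4), bool)
        soma[0, 0] = True
        part = intensity_partition(make_image(np.zeros((4, 4))), [RoiMask(soma)])
        assert math.isnan(part.percent_in_processes)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_soma_plus_process_equals_total(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.random((12, 12)).astype(np.float32) * 100
        mask = rng.random((12, 12)) > 0.5
        if not mask.any():
            mask[0, 0] = True
        part = intensity_partition(make_image(img), [RoiMask(mask)])
        assert part.soma_intensity + part.process_intensity == pytest.approx(
            part.total_intensity, rel=1e-6
        )

    def test_simulator_truth_recovery(self):
        cfg = SimConfig(image_shape=(256, 256), seed=1, n_frames=1, background_level=0.0)
        stack, masks, truth = simulate_intensity_image(cfg, 0.25)
        part = intensity_partition(stack, masks)
        assert part.percent_in_processes == pytest.approx(75.0, abs=0.5)

    @pytest.mark.parametrize("frac,expected", [(0.0, 100.0), (1.0, 0.0)])
    def test_simulator_extremes(self, frac, expected):
        cfg = SimConfig(image_shape=(256, 256), seed=2, n_frames=1, background_level=0.0)
        stack, masks, _ = simulate_intensity_image(cfg, frac)
        part = intensity_partition(stack, masks)
        assert part.percent_in_processes == pytest.approx(expected, abs=1e-6)


class TestTotalFieldIntensity:
    def test_uniform_sum_and_mean(self):
        total, mean = total_field_intensity(make_image(np.full((10, 10), 2.0)))
        assert (total, mean) == (200.0, 2.0)

    def test_zero_image(self):
        total, mean = total_field_intensity(make_image(np.zeros((10, 10))))
        assert total == 0.0

    def test_background_subtraction_with_clamping(self):
        total, mean = total_field_intensity(make_image(np.full((10, 10), 2.0)), background=1.0)
        assert mean == pytest.approx(1.0)
        total, mean = total_field_intensity(make_image(np.full((10, 10), 2.0)), background=5.0)
        assert total == 0.0


class TestDdctFoldChange:
    def test_identical_groups_fold_one(self):
        res = ddct_fold_change(qpcr_rows({"E3": (20, 18), "E4": (20, 18)}), "E3")
        assert res.fold_change == {"E3": 1.0, "E4": 1.0}

    def test_one_cycle_halves_expression(self):
        res = ddct_fold_change(qpcr_rows({"E3": (20, 18), "E4": (21, 18)}), "E3")
        assert res.fold_change["E3"] == 1.0
        assert res.fold_change["E4"] == pytest.approx(0.5)
        assert res.ddct["E4"] == pytest.approx(1.0)

    def test_replicates_averaged_before_delta(self):
        rows = []
        for cq in (20.0, 20.2, 19.8):
            rows.append({"sample_id": "s1", "group": "E3", "gene": "target", "cq": cq})
        rows.append({"sample_id": "s1", "group": "E3", "gene": "reference", "cq": 18.0})
        rows += [
            {"sample_id": "s2", "group": "E4", "gene": "target", "cq": 21.0},
            {"sample_id": "s2", "group": "E4", "gene": "reference", "cq": 18.0},
        ]
        res = ddct_fold_change(pd.DataFrame(rows), "E3")
        assert res.per_sample_dct.set_index("sample_id").loc["s1", "dct"] == pytest.approx(2.0)
        assert res.fold_change["E4"] == pytest.approx(0.5)

    def test_global_cq_shift_invariance(self):
        base = qpcr_rows({"E3": (20, 18), "E4": (22.5, 19.0)})
        shifted = base.assign(cq=base["cq"] + 3.7)
        a = ddct_fold_change(base, "E3").fold_change["E4"]
        b = ddct_fold_change(shifted, "E3").fold_change["E4"]
        assert a == pytest.approx(b)

    def test_label_swap_inverts_fold(self):
        tbl = qpcr_rows({"E3": (20, 18), "E4": (21.3, 18)})
        f_e4 = ddct_fold_change(tbl, "E3").fold_change["E4"]
        f_e3 = ddct_fold_change(tbl, "E4").fold_change["E3"]
        assert f_e3 == pytest.approx(1.0 / f_e4)

    def test_sample_missing_reference_excluded_with_warning(self):
        tbl = qpcr_rows({"E3": (20, 18), "E4": (21, 18)})
        tbl = pd.concat(
            [tbl, pd.DataFrame([{"sample_id": "orphan", "group": "E4", "gene": "target", "cq": 25.0}])],
            ignore_index=True,
        )
        with pytest.warns(UserWarning):
            res = ddct_fold_change(tbl, "E3")
        assert "orphan" not in set(res.per_sample_dct["sample_id"])
        assert res.fold_change["E4"] == pytest.approx(0.5)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ddct_fold_change(qpcr_rows({"E3": (20, 18)}), "E4")
        bad = qpcr_rows({"E3": (20, 18)}).assign(cq=0.0)
        with pytest.raises(ValueError):
            ddct_fold_change(bad, "E3")
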