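"""Five-segment tract construction and grid sweep behaviour."""

import dataclasses
import filecmp

import numpy as np
import pytest

from hootube.chimp_tract import (
    ParamGrid,
    TractParams,
    build_tract,
    enumerate_grid,
    run_sweep,
)
from hootube.tube_acoustics import (
    AcousticConstants,
    find_formants,
    transfer_function,
    uniform_tube_resonances,
)


class TestBuildTract:
    def test_segment_order_and_total_length(self):
        params = TractParams(
            sac_length=2.0, sac_area=30.0, protrusion_length=3.8, lip_opening_area=0.2
        )
        seq = build_tract(params)
        assert len(seq) == 5
        lengths = [s.length for s in seq.segments]
        areas = [s.area for s in seq.segments]
        assert lengths == [0.125, 2.0, 18.0, 3.8, 0.2]
        assert areas == [0.125, 30.0, 1.0, 1.0, 0.2]
        assert seq.total_length == pytest.approx(24.125)
        assert params.total_length == pytest.approx(seq.total_length)

    def test_constriction_can_be_disabled(self):
        seq = build_tract(TractParams(constriction_enabled=False))
        assert len(seq) == 4

    def test_no_sac_all_unit_areas_equals_uniform_tube(self):
        """Sac area 1 with unit areas everywhere is just a longer tube."""
        params = TractParams(
            sac_length=1.0, sac_area=1.0, protrusion_length=1.0,
            lip_opening_area=1.0, constriction_enabled=False,
        )
        seq = build_tract(params)
        assert seq.total_length == pytest.approx(20.2)
        est = find_formants(transfer_function(seq), n_formants=2)
        expected = uniform_tube_resonances(20.2, 35_000.0, 2)
        assert np.allclose([est.f1, est.f2], expected, atol=1.0)

    @pytest.mark.parametrize("field", ["protrusion_length", "sac_area", "vtl"])
    def test_non_positive_parameter_names_offending_field(self, field):
        with pytest.raises(ValueError, match=field):
            TractParams(**{field: 0.0})


class TestEnumerateGrid:
    def test_default_grid_cardinality(self):
        grid = ParamGrid()
        combos = list(enumerate_grid(grid))
        assert grid.cardinality == 19 * 3 * 30 * 5 == 8550
        assert len(combos) == 8550

    def test_singletons_give_one_combination(self):
        grid = ParamGrid(
            protrusion_lengths=(1.0,), sac_lengths=(1.0,),
            sac_areas=(5.0,), lip_opening_areas=(0.4,),
        )
        combos = list(enumerate_grid(grid))
        assert len(combos) == 1
        assert combos[0].sac_area == 5.0

    def test_enumeration_order_lip_area_fastest(self):
        grid = ParamGrid(
            protrusion_lengths=(1.0, 2.0), sac_lengths=(1.0,),
            sac_areas=(1.0,), lip_opening_areas=(0.2, 0.4),
        )
        combos = list(enumerate_grid(grid))
        assert [(c.protrusion_length, c.lip_opening_area) for c in combos] == [
            (1.0, 0.2), (1.0, 0.4), (2.0, 0.2), (2.0, 0.4),
        ]

    @pytest.mark.parametrize("field", ["sac_areas", "protrusion_lengths"])
    def test_empty_or_negative_lists_rejected(self, field):
        with pytest.raises(ValueError):
            ParamGrid(**{field: ()})
        with pytest.raises(ValueError):
            ParamGrid(**{field: (1.0, -1.0)})


class TestRunSweep:
    def test_row_count_and_columns(self, small_sweep):
        assert len(small_sweep.rows) == 12
        assert list(small_sweep.rows.columns)[:4] == [
            "protrusion_length_cm", "sac_length_cm", "sac_area_cm2", "lip_area_cm2",
        ]
        ok = small_sweep.ok
        assert (ok["f1_hz"] < ok["f2_hz"]).all()

    def test_uniform_reduction_rows_match_oracle(self):
        """With no sac, no constriction and unit areas, every row is a
        uniform tube whose formants follow the quarter-wave series."""
        grid = ParamGrid(
            protrusion_lengths=(0.5, 1.5, 3.0), sac_lengths=(1.0,),
            sac_areas=(1.0,), lip_opening_areas=(1.0,),
        )
        fixed = TractParams(constriction_enabled=False)
        result = run_sweep(grid, fixed)
        for _, row in result.rows.iterrows():
            expected = uniform_tube_resonances(row["total_length_cm"], 35_000.0, 2)
            assert row["status"] == "ok"
            assert np.allclose([row["f1_hz"], row["f2_hz"]], expected, atol=1.0)

    def test_f1_non_increasing_in_protrusion_length(self):
        grid = ParamGrid(
            protrusion_lengths=tuple(np.round(np.arange(0.2, 3.9, 0.2), 10)),
            sac_lengths=(1.0,), sac_areas=(1.0,), lip_opening_areas=(0.2,),
        )
        rows = run_sweep(grid).ok.sort_values("protrusion_length_cm")
        assert np.all(np.diff(rows["f1_hz"]) <= 1e-9)

    def test_f2_non_increasing_in_sac_area(self):
        grid = ParamGrid(
            protrusion_lengths=(3.8,), sac_lengths=(2.0,),
            sac_areas=tuple(float(a) for a in range(1, 31)),
            lip_opening_areas=(0.2,),
        )
        rows = run_sweep(grid).ok.sort_values("sac_area_cm2")
        assert np.all(np.diff(rows["f2_hz"]) <= 1e-9)

    def test_sweep_is_deterministic_byte_identical(self, tmp_path):
        grid = ParamGrid(
            protrusion_lengths=(0.2, 1.0), sac_lengths=(1.5,),
            sac_areas=(3.0, 7.0), lip_opening_areas=(0.6,),
        )
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        run_sweep(grid).to_csv(a)
        run_sweep(grid).to_csv(b)
        assert filecmp.cmp(a, b, shallow=False)
        assert a.read_bytes() == b.read_bytes()

    def test_failed_configurations_are_flagged_not_dropped(self):
        """A frequency window too narrow to contain two peaks yields
        flagged rows while the sweep continues."""
        grid = ParamGrid(
            protrusion_lengths=(0.2,), sac_lengths=(1.0,),
            sac_areas=(1.0, 2.0), lip_opening_areas=(1.0,),
        )
        result = run_sweep(grid, f_min=50.0, f_max=600.0)
        assert len(result.rows) == 2
        assert (result.rows["status"].str.startswith("failed")).all()
        assert result.rows["f1_hz"].isna().all()
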