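import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rtmeno.dvh import (
    CumulativeDVH,
    DifferentialDVH,
    PatientPair,
    PlanRecord,
    combine_organs,
    max_dose,
    mean_dose,
    ovaries_dvh,
    pair_plans,
    read_dvh_table,
    rebin,
    to_cumulative,
    to_differential,
    write_dvh_table,
)
from rtmeno.errors import SchemaError, ValidationError

from conftest import grid_dvh, random_grid_dvh, uniform_dvh


@st.composite
def differential_dvhs(draw):
    n = draw(st.integers(min_value=1, max_value=40))
    steps = np.array(draw(st.lists(st.floats(0.01, 3.0), min_size=n, max_size=n)))
    start = draw(st.floats(0.0, 1.0))
    edges = start + np.concatenate([[0.0], np.cumsum(steps)])
    vols = np.array(draw(st.lists(st.floats(0.0, 1.0), min_size=n, max_size=n)))
    if vols.sum() == 0:
        vols[0] = 1.0
    return DifferentialDVH("organ", edges, vols / vols.sum())


class TestValidation:
    @pytest.mark.parametrize(
        "edges, vols",
        [
            ([0.0, 1.0, 0.5], [0.5, 0.5]),  # non-monotone edges
            ([-1.0, 0.0], [1.0]),  # negative dose
            ([0.0, 1.0], [-0.1]),  # negative volume
            ([0.0, 1.0, 2.0], [1.0]),  # length mismatch
            ([0.0, 1.0], []),  # empty
        ],
    )
    def test_differential_invariants_rejected(self, edges, vols):
        with pytest.raises(ValidationError):
            DifferentialDVH("ovaries", np.array(edges), np.array(vols))

    def test_cumulative_must_be_non_increasing_from_one(self):
        with pytest.raises(ValidationError):
            CumulativeDVH("o", np.array([0.0, 5.0]), np.array([1.0, 1.5]))
        with pytest.raises(ValidationError):
            CumulativeDVH("o", np.array([0.0, 5.0]), np.array([0.8, 0.4]))

    def test_plan_requires_known_technique(self):
        with pytest.raises(ValidationError):
            PlanRecord("P1", "EFRT", {})

    def test_pair_requires_ovaries_in_both_plans(self):
        d = uniform_dvh(0.0, 1.0, organ="uterus")
        with pytest.raises(ValidationError, match="ovary"):
            PatientPair(
                "P1",
                PlanRecord("P1", "IFRT", {"uterus": d}),
                PlanRecord("P1", "ISRT", {"uterus": d}),
            )


class TestConversions:
    def test_cumulative_to_differential_by_successive_differences(self):
        c = CumulativeDVH("o", np.array([0.0, 10.0, 20.0]), np.array([1.0, 0.4, 0.0]))
        d = to_differential(c)
        np.testing.assert_allclose(d.bin_volume, [0.6, 0.4])
        np.testing.assert_allclose(d.bin_edges, [0.0, 10.0, 20.0])

    def test_step_cumulative_is_uniform_high_bin(self):
        c = CumulativeDVH("o", np.array([0.0, 5.0, 10.0]), np.array([1.0, 1.0, 0.0]))
        d = to_differential(c)
        np.testing.assert_allclose(d.bin_volume, [0.0, 1.0])

    def test_residual_top_volume_is_conserved_in_extra_bin(self):
        c = CumulativeDVH("o", np.array([0.0, 10.0]), np.array([1.0, 0.25]))
        d = to_differential(c)
        assert d.bin_volume.sum() == pytest.approx(1.0, abs=1e-12)
        assert d.bin_edges[-1] == pytest.approx(20.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(differential_dvhs())
    def test_roundtrip_differential_cumulative(self, d):
        back = to_differential(to_cumulative(d))
        np.testing.assert_allclose(back.bin_volume, d.bin_volume, atol=1e-12)
        np.testing.assert_allclose(back.bin_edges, d.bin_edges, atol=1e-12)


class TestRebin:
    def test_uniform_bin_split_in_half(self):
        d = uniform_dvh(0.0, 0.2)
        r = rebin(d, 0.1)
        np.testing.assert_allclose(r.bin_volume, [0.5, 0.5], atol=1e-12)

    def test_offset_bin_apportioned_by_overlap(self):
        # hand computation: [0.05, 0.15) overlaps [0, 0.1) and [0.1, 0.2) equally
        d = uniform_dvh(0.05, 0.15)
        r = rebin(d, 0.1)
        np.testing.assert_allclose(r.bin_volume, [0.5, 0.5], atol=1e-12)
        # asymmetric: [0.02, 0.12) -> 0.8 / 0.2
        r2 = rebin(uniform_dvh(0.02, 0.12), 0.1)
        np.testing.assert_allclose(r2.bin_volume, [0.8, 0.2], atol=1e-9)

    def test_width_must_be_positive(self):
        with pytest.raises(ValueError):
            rebin(uniform_dvh(0.0, 1.0), 0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(differential_dvhs(), st.floats(0.05, 2.0))
    def test_conserves_volume_and_perturbs_mean_at_most_half_width(self, d, width):
        r = rebin(d, width)
        assert r.total_fraction == pytest.approx(d.total_fraction, abs=1e-9)
        assert abs(mean_dose(r) - mean_dose(d)) <= width / 2 + 1e-9


class TestCombine:
    def test_idempotent_on_identical_inputs(self):
        d = grid_dvh([0.2, 0.5, 0.3])
        c = combine_organs(d, d)
        np.testing.assert_allclose(c.bin_volume, d.bin_volume, atol=1e-12)

    def test_equal_volume_mixture(self):
        left = grid_dvh([0.0, 1.0], width=10.0, total_cc=2.0)  # all at 10-20 Gy bin
        right = grid_dvh([1.0, 0.0], width=10.0, total_cc=2.0)  # all at 0-10 Gy bin
        c = combine_organs(left, right)
        np.testing.assert_allclose(c.bin_volume, [0.5, 0.5])
        assert c.total_volume_cc == pytest.approx(4.0)

    def test_volume_weighted_mixture(self):
        left = grid_dvh([0.0, 1.0], width=10.0, total_cc=3.0)
        right = grid_dvh([1.0, 0.0], width=10.0, total_cc=1.0)
        c = combine_organs(left, right)
        np.testing.assert_allclose(c.bin_volume, [0.25, 0.75])

    def test_commutative(self, rng):
        a, b = random_grid_dvh(rng, 30), random_grid_dvh(rng, 30)
        n = max(a.bin_volume.size, b.bin_volume.size)
        a = grid_dvh(np.pad(a.bin_volume, (0, n - a.bin_volume.size)))
        b = grid_dvh(np.pad(b.bin_volume, (0, n - b.bin_volume.size)))
        np.testing.assert_allclose(
            combine_organs(a, b).bin_volume, combine_organs(b, a).bin_volume
        )

    def test_mismatched_grids_instruct_rebin(self):
        with pytest.raises(ValueError, match="rebin"):
            combine_organs(grid_dvh([1.0]), grid_dvh([0.5, 0.5]))


class TestDoseStatistics:
    def test_mean_dose_of_narrow_bin_is_midpoint(self):
        assert mean_dose(uniform_dvh(9.95, 10.05)) == pytest.approx(10.0)

    def test_mean_dose_of_two_point_mixture(self):
        d = DifferentialDVH(
            "o", np.array([0.0, 0.1, 20.0, 20.1]), np.array([0.5, 0.0, 0.5])
        )
        assert mean_dose(d) == pytest.approx(0.5 * 0.05 + 0.5 * 20.05)

    def test_max_dose_ignores_trailing_zero_bins(self):
        d = grid_dvh([0.0, 1.0, 0.0, 0.0], width=5.0)
        assert max_dose(d) == pytest.approx(10.0)

    def test_all_volume_at_zero_dose(self):
        d = grid_dvh([1.0, 0.0, 0.0])
        assert max_dose(d) == pytest.approx(0.1)

    def test_empty_dvh_rejected(self):
        d = grid_dvh([0.0, 0.0])
        with pytest.raises(ValidationError):
            mean_dose(d)
        with pytest.raises(ValidationError):
            max_dose(d)


class TestCsvIO:
    def _write(self, tmp_path, rows, columns=None):
        path = tmp_path / "dvh.csv"
        pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
        return path

    def _base_rows(self, volumes=(0.2, 0.5, 0.3), kind="relative"):
        return [
            {
                "patient_id": "P1",
                "technique": "IFRT",
                "organ": "ovaries",
                "dvh_type": "differential",
                "dose_gy": 0.1 * i,
                "volume": v,
                "volume_kind": kind,
            }
            for i, v in enumerate(volumes)
        ]

    def test_differential_volumes_normalized(self, tmp_path):
        plans = read_dvh_table(self._write(tmp_path, self._base_rows()))
        assert len(plans) == 1
        d = plans[0].organs["ovaries"]
        assert d.total_fraction == pytest.approx(1.0, abs=1e-12)

    def test_absolute_volumes_keep_total_cc(self, tmp_path):
        plans = read_dvh_table(
            self._write(tmp_path, self._base_rows(volumes=(2.0, 5.0, 3.0), kind="absolute"))
        )
        d = plans[0].organs["ovaries"]
        assert d.total_fraction == pytest.approx(1.0, abs=1e-12)
        assert d.total_volume_cc == pytest.approx(10.0)

    def test_cumulative_rows_converted(self, tmp_path):
        rows = [
            dict(patient_id="P1", technique="ISRT", organ="ovaries",
                 dvh_type="cumulative", dose_gy=d, volume=v, volume_kind="relative")
            for d, v in [(0.0, 1.0), (10.0, 0.4), (20.0, 0.0)]
        ]
        plans = read_dvh_table(self._write(tmp_path, rows))
        np.testing.assert_allclose(plans[0].organs["ovaries"].bin_volume, [0.6, 0.4])

    def test_missing_column_names_it(self, tmp_path):
        rows = [{k: v for k, v in r.items() if k != "organ"} for r in self._base_rows()]
        with pytest.raises(SchemaError, match="organ"):
            read_dvh_table(self._write(tmp_path, rows))

    def test_negative_volume_cites_row(self, tmp_path):
        rows = self._base_rows(volumes=(0.5, -0.1, 0.6))
        with pytest.raises(ValidationError, match="row 1"):
            read_dvh_table(self._write(tmp_path, rows))

    def test_unknown_technique_rejected(self, tmp_path):
        rows = self._base_rows()
        rows[0]["technique"] = "EFRT"
        with pytest.raises(ValidationError, match="EFRT"):
            read_dvh_table(self._write(tmp_path, rows))

    def test_write_read_roundtrip(self, tmp_path, rng):
        d = random_grid_dvh(rng, 50)
        rec = PlanRecord("P7", "ISRT", {"ovaries": d})
        path = tmp_path / "out.csv"
        write_dvh_table([rec], path)
        back = read_dvh_table(path)[0].organs["ovaries"]
        np.testing.assert_allclose(back.bin_volume, d.bin_volume, atol=1e-12)
        np.testing.assert_allclose(back.bin_edges, d.bin_edges, atol=1e-9)


class TestPairingAndOvaries:
    def test_pairing_drops_incomplete_patients(self):
        d = uniform_dvh(0.0, 1.0)
        recs = [
            PlanRecord("P1", "IFRT", {"ovaries": d}),
            PlanRecord("P1", "ISRT", {"ovaries": d}),
            PlanRecord("P2", "IFRT", {"ovaries": d}),
        ]
        pairs = pair_plans(recs)
        assert [p.patient_id for p in pairs] == ["P1"]

    def test_left_right_ovaries_combined_volume_weighted(self):
        left = uniform_dvh(9.95, 10.05, organ="ovary_left", total_cc=3.0)
        right = uniform_dvh(0.0, 0.1, organ="ovary_right", total_cc=1.0)
        plan = PlanRecord("P1", "IFRT", {"ovary_left": left, "ovary_right": right})
        combined = ovaries_dvh(plan)
        assert combined.organ == "ovaries"
        assert mean_dose(combined) == pytest.approx(0.75 * 10.0 + 0.25 * 0.05, abs=0.06)
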