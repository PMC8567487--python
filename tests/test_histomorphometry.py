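"""Histomorphometric primitives, ASBMR parameter calculus and Z-scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bonematrix.datasets import load_histo_reference
from bonematrix.errors import (
    AlignmentError,
    InconsistencyError,
    MissingReferenceError,
)
from bonematrix.histomorphometry import (
    ClassRaster,
    Compartment,
    HistoPrimitives,
    LabelTrace,
    ReferenceTable,
    SurfaceAnnotation,
    SurfaceSegment,
    SurfaceState,
    TissueClass,
    compute_parameters,
    dynamic_parameters,
    measure_primitives,
    static_parameters,
    zscore_table,
)
from bonematrix.synthetic import OsteoidModel, SyntheticSpec, generate_histo_scene
from bonematrix.zscore import zscore


def strip_raster(mineral_rows=40, total_rows=100, cols=100, px=10.0, osteoid_rows=0):
    """Horizontal bone slab along the bottom; surface on top of it."""
    classes = np.zeros((total_rows, cols), dtype=np.uint8)
    y0 = total_rows - mineral_rows
    classes[y0:] = TissueClass.MINERALIZED
    classes[y0 : y0 + osteoid_rows] = TissueClass.OSTEOID
    return ClassRaster(classes=classes, pixel_size_um=px), y0


class TestMeasurePrimitives:
    def test_area_fractions_by_counting(self):
        raster, y0 = strip_raster()
        ann = SurfaceAnnotation(
            segments=[SurfaceSegment(SurfaceState.QUIESCENT, [[0, y0 * 10.0], [1000.0, y0 * 10.0]])]
        )
        prim = measure_primitives(raster, ann)
        assert prim.bv_mm2 == pytest.approx(0.4 * prim.tv_mm2)
        assert prim.bs_mm == pytest.approx(1.0)

    def test_osteoid_band_thickness(self):
        raster, y0 = strip_raster(osteoid_rows=5)
        y_um = y0 * 10.0
        ann = SurfaceAnnotation(
            segments=[SurfaceSegment(SurfaceState.OSTEOID, [[0, y_um], [1000.0, y_um]])]
        )
        prim = measure_primitives(raster, ann)
        assert prim.o_th_um == pytest.approx(50.0, abs=10.0)  # 1 px tolerance

    def test_direct_widths_override_ov_os(self):
        raster, y0 = strip_raster(osteoid_rows=5)
        ann = SurfaceAnnotation(
            segments=[SurfaceSegment(SurfaceState.OSTEOID, [[0, y0 * 10.0], [1000.0, y0 * 10.0]])],
            osteoid_widths_um=[47.0, 53.0],
        )
        assert measure_primitives(raster, ann).o_th_um == pytest.approx(50.0)

    def test_polyline_off_boundary_raises(self):
        raster, y0 = strip_raster()
        bad_y = (y0 - 10) * 10.0  # 10 px above the surface
        ann = SurfaceAnnotation(
            segments=[SurfaceSegment(SurfaceState.QUIESCENT, [[0, bad_y], [1000.0, bad_y]])]
        )
        with pytest.raises(AlignmentError):
            measure_primitives(raster, ann)

    def test_cortical_width_and_porosity(self):
        classes = np.full((50, 40), TissueClass.MINERALIZED, dtype=np.uint8)
        classes[:10] = TissueClass.VOID
        comp = np.zeros_like(classes)
        comp[10:30] = Compartment.CORTICAL  # 20 rows of cortex, fully mineralized
        comp[5:10] = Compartment.CORTICAL  # 5 void rows inside the cortex
        raster = ClassRaster(classes=classes, pixel_size_um=10.0, compartments=comp)
        ann = SurfaceAnnotation(
            segments=[SurfaceSegment(SurfaceState.QUIESCENT, [[0, 100.0], [400.0, 100.0]])]
        )
        prim = measure_primitives(raster, ann)
        assert prim.ct_wi_mm == pytest.approx(0.25)  # 25 rows x 10 μm
        assert prim.ct_po_pct == pytest.approx(100 * 5 / 25)

    def test_label_extents_and_interlabel_width(self):
        raster, y0 = strip_raster()
        y_um = y0 * 10.0
        ann = SurfaceAnnotation(
            segments=[SurfaceSegment(SurfaceState.QUIESCENT, [[0, y_um], [1000.0, y_um]])],
            labels=[
                LabelTrace("double", [[0, y_um + 30], [300.0, y_um + 30]], 10.5),
                LabelTrace("single", [[300.0, y_um + 30], [500.0, y_um + 30]]),
            ],
        )
        prim = measure_primitives(raster, ann)
        assert prim.dl_pm_mm == pytest.approx(0.3)
        assert prim.sl_pm_mm == pytest.approx(0.2)
        assert prim.ir_l_wi_um == pytest.approx(10.5)

    def test_csv_round_trip(self, tmp_path):
        prim = HistoPrimitives(tv_mm2=2.0, bv_mm2=0.5, bs_mm=4.0, os_mm=1.0, n_oc=3)
        path = tmp_path / "prim.csv"
        prim.to_csv(path)
        # NaN-valued cortical fields must survive the round trip too
        np.testing.assert_equal(HistoPrimitives.from_csv(path).__dict__, prim.__dict__)


class TestStaticParameters:
    def test_bone_volume_fraction(self):
        p = static_parameters(HistoPrimitives(tv_mm2=1.0, bv_mm2=0.2219, bs_mm=1.0))
        assert p.bv_tv == pytest.approx(22.19)

    def test_full_osteoid_coverage_is_ceiling(self):
        p = static_parameters(HistoPrimitives(tv_mm2=1.0, bv_mm2=0.3, bs_mm=2.0, os_mm=2.0))
        assert p.os_bs == pytest.approx(100.0)

    def test_zero_tissue_flagged_not_raised(self):
        p = static_parameters(HistoPrimitives(tv_mm2=0.0, bv_mm2=0.0, bs_mm=0.0))
        assert p.bv_tv is None and "bv_tv" in p.flags

    def test_plate_model_thickness_on_phantom(self):
        spec = SyntheticSpec(
            seed=0, shape=(1024, 1024), strut_thickness_um=140.0,
            osteoid=OsteoidModel(surface_fraction=0.0, width_um=0.0),
        )
        raster, ann, _ = generate_histo_scene(spec)
        p = static_parameters(measure_primitives(raster, ann))
        assert p.tb_th == pytest.approx(140.0, rel=0.05)


class TestDynamicParameters:
    def test_adjusted_apposition_rate_chain(self):
        # MAR 0.7 μm/day (inter-label 10.5 μm / 15 d), MS/BS 3.8%, OS/BS 50.33%
        prim = HistoPrimitives(
            tv_mm2=1.0, bv_mm2=0.22, bs_mm=1.0, os_mm=0.5033,
            dl_pm_mm=0.038, ir_l_wi_um=10.5, label_interval_days=15.0,
        )
        p = dynamic_parameters(prim)
        assert p.mar == pytest.approx(0.7)
        assert p.ms_bs == pytest.approx(3.8)
        assert round(p.aj_ar, 3) == 0.053
        assert p.bfr_bs == pytest.approx(0.7 * 0.038 * 365)  # 9.709 μm/yr

    def test_mineralization_lag_time_by_division(self):
        prim = HistoPrimitives(
            tv_mm2=1.0, bv_mm2=0.2, bs_mm=1.0, os_mm=0.4, o_th_um=4.22,
            dl_pm_mm=0.4, ir_l_wi_um=0.0865 * 15, label_interval_days=15.0,
        )
        p = dynamic_parameters(prim)
        assert p.aj_ar == pytest.approx(0.0865)
        assert p.mlt == pytest.approx(4.22 / 0.0865, abs=0.01)  # 48.8 days

    def test_single_labels_count_half(self):
        base = dict(tv_mm2=1.0, bv_mm2=0.2, bs_mm=1.0, os_mm=0.5,
                    ir_l_wi_um=10.5, label_interval_days=15.0)
        all_double = dynamic_parameters(HistoPrimitives(dl_pm_mm=0.2, **base))
        all_single = dynamic_parameters(HistoPrimitives(sl_pm_mm=0.2, **base))
        assert all_double.ms_bs == pytest.approx(20.0)
        assert all_single.ms_bs == pytest.approx(10.0)

    def test_mineralizing_without_osteoid_is_inconsistent(self):
        prim = HistoPrimitives(tv_mm2=1.0, bv_mm2=0.2, bs_mm=1.0, os_mm=0.0,
                               dl_pm_mm=0.1, ir_l_wi_um=10.5)
        with pytest.raises(InconsistencyError):
            dynamic_parameters(prim)

    def test_zero_apposition_flags_mlt(self):
        prim = HistoPrimitives(tv_mm2=1.0, bv_mm2=0.2, bs_mm=1.0, os_mm=0.5,
                               o_th_um=4.0)
        p = dynamic_parameters(prim)
        assert p.mlt is None and "mlt" in p.flags

    @given(
        ir=st.floats(0.5, 30),
        interval=st.floats(5, 30),
        dl=st.floats(0.01, 0.4),
        os_frac=st.floats(0.05, 1.0),
        o_th=st.floats(0.5, 20),
    )
    @settings(deadline=None, max_examples=60)
    def test_chain_identities_hold_prerounding(self, ir, interval, dl, os_frac, o_th):
        """Mlt*Aj.Ar = O.Th and BFR/BS = MAR*(MS/BS/100)*365, exactly."""
        prim = HistoPrimitives(
            tv_mm2=1.0, bv_mm2=0.25, bs_mm=1.0, os_mm=os_frac, o_th_um=o_th,
            dl_pm_mm=dl, ir_l_wi_um=ir, label_interval_days=interval,
        )
        p = dynamic_parameters(prim)
        assert p.mlt * p.aj_ar == pytest.approx(o_th, rel=1e-12)
        assert p.bfr_bs == pytest.approx(p.mar * (p.ms_bs / 100.0) * 365.0, rel=1e-12)


class TestZScoring:
    @given(x=st.floats(-50, 50), mu=st.floats(-20, 20), sd=st.floats(0.1, 10),
           a=st.floats(0.1, 100))
    @settings(deadline=None, max_examples=60)
    def test_affine_equivariance(self, x, mu, sd, a):
        assert zscore(a * x, a * mu, a * sd) == pytest.approx(zscore(x, mu, sd), abs=1e-6)

    def test_published_example_rows(self):
        table = ReferenceTable(load_histo_reference())
        zs = zscore_table({"OS/BS": 50.33}, table, sex="M", age=61)
        assert zs["OS/BS"].z2 == 9.03 and zs["OS/BS"].flagged
        zs2 = zscore_table({"ES/BS": 16.25}, table, sex="M", age=29)
        assert zs2["ES/BS"].z2 == 10.46 and zs2["ES/BS"].flagged

    def test_value_at_mean_unflagged(self):
        table = ReferenceTable(load_histo_reference())
        row = zscore_table({"BV/TV": 19.2}, table, sex="M", age=65)["BV/TV"]
        assert row.z2 == 0.0 and not row.flagged

    def test_missing_band_lists_available(self):
        table = ReferenceTable(load_histo_reference())
        with pytest.raises(MissingReferenceError, match="available bands"):
            zscore_table({"BV/TV": 20.0}, table, sex="F", age=40)

    def test_unreferenced_parameters_skipped(self):
        table = ReferenceTable(load_histo_reference())
        zs = zscore_table({"BV/TV": 20.0, "Ct.Po": 4.46}, table, sex="M", age=61)
        assert "BV/TV" in [r.parameter for r in zs]
        with pytest.raises(KeyError):
            zs["Ct.Po"]

    def test_parameter_merge(self):
        prim = HistoPrimitives(
            tv_mm2=1.0, bv_mm2=0.25, bs_mm=1.0, os_mm=0.5, o_th_um=4.0,
            dl_pm_mm=0.05, ir_l_wi_um=10.5,
        )
        p = compute_parameters(prim)
        assert p.bv_tv is not None and p.mar is not None and p.mlt is not None
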