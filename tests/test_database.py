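import numpy as np
import pytest

from insertfactors import (
    DatabaseParseError,
    MeasurementDatabase,
    RecordValidationError,
    coverage_report,
    design_measurement_shapes,
    load_database,
    parameterize_shape,
    save_database,
)
from insertfactors.geometry import write_polygon_file, ellipse_polygon

from conftest import make_record, pa_of


@pytest.fixture
def eight_records(ctx):
    dims = [(2.5, 13.0), (4.0, 12.0), (7.0, 11.0), (5.0, 10.0),
            (9.5, 9.5), (8.0, 8.0), (6.0, 6.0), (4.0, 4.0)]
    return [make_record(ctx, f"s{i}", w, l, 0.95 + 0.005 * i)
            for i, (w, l) in enumerate(dims)]


class TestDatabaseIO:
    def test_group_of_eight_loads_as_one_key(self, tmp_path, eight_records, ctx):
        db = MeasurementDatabase(eight_records)
        path = tmp_path / "db.csv"
        save_database(db, path)
        loaded = load_database(path)
        assert list(loaded.keys()) == [ctx.key]
        assert len(loaded.group(ctx.key)) == 8

    def test_load_save_identity_bit_exact(self, tmp_path, eight_records):
        path1, path2 = tmp_path / "a.csv", tmp_path / "b.csv"
        save_database(MeasurementDatabase(eight_records), path1)
        save_database(load_database(path1), path2)
        assert path1.read_bytes() == path2.read_bytes()

    def test_derived_pa_ratio_matches_formula(self, tmp_path, eight_records):
        path = tmp_path / "db.csv"
        save_database(MeasurementDatabase(eight_records), path)
        for rec in load_database(path).records():
            assert rec.pa_ratio_per_cm == pytest.approx(
                pa_of(rec.width_cm, rec.length_cm), rel=1e-4
            )

    def test_duplicate_shape_id_rejected(self, ctx):
        db = MeasurementDatabase()
        db.add(make_record(ctx, "dup", 4.0, 8.0, 0.95))
        with pytest.raises(RecordValidationError, match="dup"):
            db.add(make_record(ctx, "dup", 5.0, 9.0, 0.96))

    def test_width_exceeding_length_rejected(self, ctx):
        with pytest.raises(RecordValidationError, match="width"):
            make_record(ctx, "bad", 9.0, 4.0, 0.95)

    def test_out_of_bounds_factor_rejected(self, ctx):
        with pytest.raises(RecordValidationError, match="insert factor"):
            make_record(ctx, "hot", 4.0, 8.0, 1.35).validate_factor()

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "machine_id,energy_mev,applicator_cm,ssd_cm,shape_id,"
            "width_cm,length_cm,insert_factor\n"
            "TB,12,10,100,ok,4,8,0.95\n"
            "TB,twelve,10,100,bad,4,8,0.95\n"
        )
        with pytest.raises(DatabaseParseError, match=":3"):
            load_database(path)

    def test_polygon_column_mismatch_warns(self, tmp_path, caplog):
        poly = ellipse_polygon(4.0, 8.0)
        write_polygon_file(poly, tmp_path / "shape.txt")
        path = tmp_path / "db.csv"
        path.write_text(
            "machine_id,energy_mev,applicator_cm,ssd_cm,shape_id,"
            "width_cm,length_cm,insert_factor,polygon_file\n"
            "TB,12,10,100,off,5.0,8.0,0.95,shape.txt\n"  # stored width 5 vs true 4
        )
        with caplog.at_level("WARNING"):
            load_database(path)
        assert any("disagrees" in r.message for r in caplog.records)


class TestDesignShapes:
    def test_smallest_cone_boundary_set(self):
        shapes = design_measurement_shapes(6.0)
        labels = [label for label, _ in shapes]
        assert len(shapes) == 8
        assert "ellipse_2.5x7" in labels
        assert "circle_2.5" in labels
        widths = [parameterize_shape(p).width_cm for _, p in shapes]
        assert min(widths) == pytest.approx(2.5, abs=0.02)
        assert max(widths) == pytest.approx(6.0, abs=0.02)

    def test_largest_cone_includes_interior_rectangles(self):
        shapes = design_measurement_shapes(20.0)
        labels = [label for label, _ in shapes]
        assert len(shapes) >= 10
        assert any(label.startswith("rect_") for label in labels)

    def test_boundary_only_count_is_twice_n_widths(self):
        shapes = design_measurement_shapes(10.0, n_widths=4, augment=False)
        assert len(shapes) == 8

    def test_designed_ellipse_parameterizes_to_its_label(self):
        shapes = dict(design_measurement_shapes(10.0, augment=False))
        e = parameterize_shape(shapes["ellipse_2.5x13"])
        assert e.width_cm == pytest.approx(2.5, rel=0.005)
        assert e.length_cm == pytest.approx(13.0, rel=0.005)

    def test_nonpositive_applicator_rejected(self):
        with pytest.raises(ValueError):
            design_measurement_shapes(-5.0)


class TestCoverage:
    def test_training_point_is_inside_with_zero_distance(self, eight_records):
        import insertfactors

        rec = eight_records[0]
        query = insertfactors.EquivalentEllipse(
            width_cm=rec.width_cm, length_cm=rec.length_cm,
            area_cm2=np.pi * (rec.width_cm / 2) * (rec.length_cm / 2),
            pa_ratio_per_cm=rec.pa_ratio_per_cm,
        )
        report = coverage_report(eight_records, query)
        assert report.in_hull
        assert report.nearest_distance == 0.0

    def test_query_beyond_all_widths_is_outside(self, eight_records):
        query = parameterize_shape(ellipse_polygon(15.0, 18.0))
        report = coverage_report(eight_records, query)
        assert not report.in_hull

    def test_centroid_of_training_points_is_inside(self, eight_records, ctx):
        import insertfactors

        pts = np.array([(r.width_cm, r.pa_ratio_per_cm) for r in eight_records])
        cw, cpa = pts.mean(axis=0)
        ellipse = insertfactors.EquivalentEllipse(
            width_cm=cw, length_cm=cw * 1.5,
            area_cm2=np.pi * (cw / 2) * (cw * 1.5 / 2),
            pa_ratio_per_cm=cpa,
        )
        assert coverage_report(eight_records, ellipse).in_hull
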