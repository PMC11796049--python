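"""BagIt construction/validation, XLSX layout, archive inventory."""

import hashlib
import itertools
import json
import zipfile

import pytest

from cvflow.errors import PackagingError
from cvflow.metadata import SCHEME, MetadataRecord, metadata_to_json
from cvflow.packaging import (
    CurveResult,
    Dataset,
    archive_inventory,
    build_archive,
    build_bagit,
    curve_filename,
    dataset_description,
    export_xlsx,
    validate_bagit,
    zip_directory,
)

META_JSON = metadata_to_json(MetadataRecord())


def make_bag(tmp_path, n=3):
    files = [(f"run-curve{i}_bagit.jdx", f"##TITLE=c{i}\n##END=\n") for i in range(1, n + 1)]
    bag_dir = tmp_path / "bag"
    manifest = build_bagit(files, META_JSON, bag_dir)
    return bag_dir, manifest


class TestBagit:
    def test_three_payload_entries_in_both_manifests(self, tmp_path):
        bag_dir, manifest = make_bag(tmp_path, 3)
        assert len(manifest.entries) == 3
        for algo in ("sha256", "sha512"):
            lines = (bag_dir / f"manifest-{algo}.txt").read_text().strip().splitlines()
            assert len(lines) == 3
            assert all(line.split("  ")[1].startswith("data/") for line in lines)

    def test_root_listing_is_exactly_the_bag_layout(self, tmp_path):
        bag_dir, _ = make_bag(tmp_path)
        assert sorted(p.name for p in bag_dir.iterdir()) == [
            "bagit.txt", "data", "manifest-sha256.txt", "manifest-sha512.txt", "metadata",
        ]
        assert (bag_dir / "metadata" / "metadata.json").is_file()

    def test_sha256_known_answer_vector(self, tmp_path):
        build_bagit([("abc.jdx", "abc")], META_JSON, tmp_path / "b")
        text = (tmp_path / "b" / "manifest-sha256.txt").read_text()
        assert text.split()[0] == (
            "ba7816bf8f01cfea414140de5dae2223b00361a396177a9cb410ff61f20015ad"
        )

    def test_empty_payload_rejected(self, tmp_path):
        with pytest.raises(PackagingError):
            build_bagit([], META_JSON, tmp_path / "b")

    def test_fresh_bag_validates(self, tmp_path):
        bag_dir, _ = make_bag(tmp_path)
        report = validate_bagit(bag_dir)
        assert report.ok
        assert any("tag directory" in w for w in report.warnings)

    def test_single_byte_flip_is_detected_with_file_and_algorithm(self, tmp_path):
        bag_dir, _ = make_bag(tmp_path)
        victim = bag_dir / "data" / "run-curve2_bagit.jdx"
        data = bytearray(victim.read_bytes())
        data[0] ^= 0x01
        victim.write_bytes(bytes(data))
        report = validate_bagit(bag_dir)
        assert not report.ok
        assert any("sha256" in e and "curve2" in e for e in report.errors)
        assert any("sha512" in e and "curve2" in e for e in report.errors)

    def test_missing_manifest_is_detected(self, tmp_path):
        bag_dir, _ = make_bag(tmp_path)
        (bag_dir / "manifest-sha512.txt").unlink()
        report = validate_bagit(bag_dir)
        assert not report.ok
        assert any("manifest-sha512.txt" in e for e in report.errors)

    def test_unmanifested_payload_file_is_detected(self, tmp_path):
        bag_dir, _ = make_bag(tmp_path)
        (bag_dir / "data" / "stray.jdx").write_text("x")
        report = validate_bagit(bag_dir)
        assert any("stray.jdx" in e for e in report.errors)

    def test_zipped_bag_contains_same_entries(self, tmp_path):
        bag_dir, _ = make_bag(tmp_path)
        zp = zip_directory(bag_dir, tmp_path / "bag.zip", reproducible=True)
        names = sorted(zipfile.ZipFile(zp).namelist())
        assert "bag/bagit.txt" in names
        assert sum(1 for n in names if n.startswith("bag/data/")) == 3


class TestXlsx:
    @pytest.mark.parametrize("x", [1, 2, 4, 7, 20])
    def test_sheet_count_is_two_plus_curves(self, tmp_path, x, reversible_cycles):
        from openpyxl import load_workbook

        curves = [CurveResult(k, reversible_cycles[0]) for k in range(1, x + 1)]
        path = tmp_path / f"{x}.xlsx"
        export_xlsx(curves, MetadataRecord(), path)
        wb = load_workbook(path, read_only=True)
        assert len(wb.sheetnames) == 2 + x
        assert wb.sheetnames[:2] == ["Definitions", "Metadata"]

    def test_metadata_sheet_lists_every_scheme_field(self, tmp_path, reversible_cycles):
        from openpyxl import load_workbook

        path = tmp_path / "m.xlsx"
        export_xlsx([CurveResult(1, reversible_cycles[0])], MetadataRecord(), path)
        ws = load_workbook(path)["Metadata"]
        field_ids = [row[0].value for row in ws.iter_rows(min_row=2)]
        for spec in SCHEME:
            assert spec.field_id in field_ids

    def test_zero_curves_rejected(self, tmp_path):
        with pytest.raises(PackagingError):
            export_xlsx([], MetadataRecord(), tmp_path / "x.xlsx")


class TestArchiveInventory:
    def test_naming_dialects(self):
        assert curve_filename("ds", 2, "peak") == "ds-curve2_bagit.peak.jdx"
        assert curve_filename("ds", 2, "peak", naming="dot") == "ds-curve2.bagit.peak.jdx"
        assert curve_filename("ds", 1, "") == "ds-curve1_bagit.jdx"

    @pytest.mark.parametrize("n", [1, 2, 3])
    def test_inventory_is_pure_function_of_shape(self, n):
        for edited in itertools.product([False, True], repeat=n):
            layout = archive_inventory("ds", "ds.DTA", n, list(edited))
            names = [a for a, _ in layout.all_files()]
            assert names[0] == "dataset_description.txt"
            assert f"ds.bag.zip" in names and "ds.xlsx" in names
            assert "ds.combined.png" in names and "ds.new_combined.png" in names
            for k in range(1, n + 1):
                assert curve_filename("ds", k) in names
                peak = curve_filename("ds", k, "peak")
                edit = curve_filename("ds", k, "edit")
                if edited[k - 1]:
                    # the edit file replaces the automatic peak file
                    assert edit in names and peak not in names
                else:
                    assert peak in names and edit not in names
                assert curve_filename("ds", k, "edit", "png") in names
                assert curve_filename("ds", k, "edit", "csv") in names

    def test_no_auto_picks_means_no_peak_file(self):
        layout = archive_inventory("ds", "ds.DTA", 1, [False], auto_picked=[False])
        names = [a for a, _ in layout.all_files()]
        assert curve_filename("ds", 1, "peak") not in names

    def test_description_line_count_is_files_plus_header(self):
        layout = archive_inventory("ds", "ds.DTA", 2, [False, True])
        text = dataset_description("ds", layout, "2026-01-01")
        lines = text.strip().splitlines()
        assert len(lines) == 3 + len(layout.all_files())
        assert lines[0] == "dataset_id: ds"
        assert all("\t" in line for line in lines[3:])

    def test_invalid_shapes_rejected(self):
        with pytest.raises(PackagingError):
            archive_inventory("ds", "ds.DTA", 0, [])
        with pytest.raises(PackagingError):
            archive_inventory("ds", "ds.DTA", 2, [False])


@pytest.fixture(scope="module")
def dataset(reversible_cycles):
    from cvflow.analysis import compute_descriptors, pick_peaks

    curves = []
    for cycle in reversible_cycles:
        pa = pick_peaks(cycle.anodic)
        pc = pick_peaks(cycle.cathodic)
        desc = None
        if pa and pc:
            desc = compute_descriptors(max(pa, key=lambda p: abs(p.i_p)),
                                       max(pc, key=lambda p: abs(p.i_p)))
        curves.append(CurveResult(cycle.ordinal, cycle, pa + pc, desc))
    meta = MetadataRecord()
    meta.set("scan_rate", 0.1, "device")
    return Dataset("run01", "run01.DTA", "RAW\n", meta, curves)


class TestBuildArchive:
    def test_archive_contents_match_inventory(self, dataset, tmp_path):
        layout = build_archive(dataset, tmp_path / "a.zip", reproducible=True)
        names = set(zipfile.ZipFile(tmp_path / "a.zip").namelist())
        assert names == {a for a, _ in layout.all_files()}

    def test_edit_replaces_peak_in_archive(self, dataset, tmp_path):
        dataset.curves[0].edited = True
        try:
            build_archive(dataset, tmp_path / "b.zip", reproducible=True)
            names = set(zipfile.ZipFile(tmp_path / "b.zip").namelist())
            assert "run01-curve1_bagit.edit.jdx" in names
            assert "run01-curve1_bagit.peak.jdx" not in names
            assert "run01-curve2_bagit.peak.jdx" in names
        finally:
            dataset.curves[0].edited = False

    def test_reproducible_archives_are_byte_identical(self, dataset, tmp_path):
        build_archive(dataset, tmp_path / "r1.zip", reproducible=True)
        build_archive(dataset, tmp_path / "r2.zip", reproducible=True)
        assert (tmp_path / "r1.zip").read_bytes() == (tmp_path / "r2.zip").read_bytes()

    def test_nested_bag_validates_after_extraction(self, dataset, tmp_path):
        build_archive(dataset, tmp_path / "c.zip", reproducible=True)
        with zipfile.ZipFile(tmp_path / "c.zip") as zf:
            bag_bytes = zf.read("run01.bag.zip")
        inner = tmp_path / "inner"
        inner.mkdir()
        (inner / "bag.zip").write_bytes(bag_bytes)
        with zipfile.ZipFile(inner / "bag.zip") as zf:
            zf.extractall(inner)
        report = validate_bagit(inner / "run01")
        assert report.ok
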