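"""BagIt bags, XLSX metadata workbooks and the dataset ZIP archive.

A converted experiment is packaged as a BagIt 1.0 bag::

    bag/
      bagit.txt                BagIt version + tag-file encoding
      manifest-sha256.txt      one checksum line per payload file
      manifest-sha512.txt      one checksum line per payload file
      data/                    one JCAMP-DX file per measured cycle
      metadata/metadata.json   the sum of all extracted metadata

``metadata/`` sits beside ``data/`` and is treated as a tag directory:
it is not covered by the payload manifests (the validator notes this).

The human-readable summary is an XLSX workbook with ``2 + x`` sheets for
``x`` curves: one sheet of field definitions, one with the merged
metadata (value, unit, provenance per scheme field), and one analysis
sheet per curve (peak table + descriptors).

The downloadable dataset archive repeats, per curve, the file life
cycle ``<name>-curve<k>_bagit.jdx`` (converted) / ``..._bagit.peak.jdx``
(automatic picks) / ``..._bagit.edit.jdx`` (manual edits replace the
peak file) plus a per-curve PNG and CSV, alongside the dataset-level
description, original vendor file, nested bag zip, workbook and the
combined / new_combined preview images.
"""

from __future__ import annotations

import hashlib
import io
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

from .analysis import DescriptorSet, Peak, export_curve_csv, render_plot
from .convert import Cycle
from .errors import PackagingError
from .jcamp import add_peak_block, parse_jcamp, serialize, write_cycle_jcamp
from .metadata import SCHEME, SCHEME_VERSION, MetadataRecord, metadata_to_json

__all__ = [
    "BagEntry",
    "BagManifest",
    "BagValidationReport",
    "build_bagit",
    "validate_bagit",
    "zip_directory",
    "export_xlsx",
    "CurveResult",
    "Dataset",
    "ArchiveLayout",
    "curve_filename",
    "archive_inventory",
    "build_archive",
    "dataset_description",
]

BAGIT_TXT = "BagIt-Version: 1.0\nTag-File-Character-Encoding: UTF-8\n"
_REPRO_DATE = (1980, 1, 1, 0, 0, 0)  # fixed zip timestamp under --reproducible


# ---------------------------------------------------------------------------
# BagIt


@dataclass
class BagEntry:
    path: str      # bag-relative, e.g. "data/run-curve1_bagit.jdx"
    size: int
    sha256: str
    sha512: str


@dataclass
class BagManifest:
    entries: list[BagEntry] = field(default_factory=list)
    tag_files: list[str] = field(
        default_factory=lambda: ["bagit.txt", "manifest-sha256.txt", "manifest-sha512.txt"]
    )


@dataclass
class BagValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def _digests(data: bytes) -> tuple[str, str]:
    return hashlib.sha256(data).hexdigest(), hashlib.sha512(data).hexdigest()


def build_bagit(
    cycle_files: list[tuple[str, str]],
    metadata_json: str,
    out_dir: str | Path,
) -> BagManifest:
    """Write a bag holding ``cycle_files`` (name, JCAMP text) as payload
    and the experiment metadata JSON under ``metadata/``."""
    if not cycle_files:
        raise PackagingError("bag payload must contain at least one file")
    out = Path(out_dir)
    (out / "data").mkdir(parents=True, exist_ok=True)
    (out / "metadata").mkdir(parents=True, exist_ok=True)
    (out / "bagit.txt").write_text(BAGIT_TXT, encoding="utf-8")
    (out / "metadata" / "metadata.json").write_text(metadata_json, encoding="utf-8")

    manifest = BagManifest()
    lines256, lines512 = [], []
    for name, text in sorted(cycle_files, key=lambda nt: nt[0]):
        data = text.encode("utf-8")
        (out / "data" / name).write_bytes(data)
        h256, h512 = _digests(data)
        rel = f"data/{name}"
        manifest.entries.append(BagEntry(rel, len(data), h256, h512))
        lines256.append(f"{h256}  {rel}")
        lines512.append(f"{h512}  {rel}")
    (out / "manifest-sha256.txt").write_text("\n".join(lines256) + "\n", encoding="utf-8")
    (out / "manifest-sha512.txt").write_text("\n".join(lines512) + "\n", encoding="utf-8")
    return manifest


def _parse_manifest(path: Path) -> dict[str, str]:
    mapping = {}
    for line in path.read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        digest, _, rel = line.partition("  ")
        mapping[rel.strip()] = digest.strip().lower()
    return mapping


def validate_bagit(bag_dir: str | Path) -> BagValidationReport:
    """Verify bag structure and every payload digest (report, never raises)."""
    bag = Path(bag_dir)
    report = BagValidationReport()
    if not bag.is_dir():
        report.errors.append(f"bag directory {bag} not found")
        return report
    for tag in ("bagit.txt", "manifest-sha256.txt", "manifest-sha512.txt"):
        if not (bag / tag).is_file():
            report.errors.append(f"missing tag file {tag}")
    if not (bag / "data").is_dir():
        report.errors.append("missing data/ payload directory")
    if report.errors:
        return report
    if "BagIt-Version" not in (bag / "bagit.txt").read_text(encoding="utf-8"):
        report.errors.append("bagit.txt lacks a BagIt-Version declaration")

    payload = {
        f"data/{p.relative_to(bag / 'data')}": p
        for p in sorted((bag / "data").rglob("*"))
        if p.is_file()
    }
    for algo in ("sha256", "sha512"):
        declared = _parse_manifest(bag / f"manifest-{algo}.txt")
        for rel, digest in declared.items():
            target = bag / rel
            if not target.is_file():
                report.errors.append(f"{algo}: manifest lists missing file {rel}")
                continue
            actual = hashlib.new(algo, target.read_bytes()).hexdigest()
            if actual != digest:
                report.errors.append(f"{algo} mismatch for {rel}")
        for rel in payload:
            if rel not in declared:
                report.errors.append(f"{algo}: payload file {rel} not in manifest")
    if not (bag / "metadata" / "metadata.json").is_file():
        report.warnings.append("metadata/metadata.json not present")
    report.warnings.append(
        "metadata/ treated as a tag directory (not covered by payload manifests)"
    )
    return report


def zip_directory(src: str | Path, zip_path: str | Path, reproducible: bool = False) -> Path:
    """Zip a directory tree (sorted walk; fixed timestamps if reproducible)."""
    src = Path(src)
    zip_path = Path(zip_path)
    with zipfile.ZipFile(zip_path, "w", zipfile.ZIP_DEFLATED) as zf:
        for p in sorted(src.rglob("*")):
            if not p.is_file():
                continue
            arcname = f"{src.name}/{p.relative_to(src)}"
            _write_zip(zf, arcname, p.read_bytes(), reproducible)
    return zip_path


def _normalize_zip_timestamps(data: bytes) -> bytes:
    """Rewrite a zip (e.g. an XLSX) with fixed member timestamps.

    Also pins the OOXML ``dcterms:modified`` stamp, which the workbook
    writer refreshes to the wall clock on every save.
    """
    import re

    out = io.BytesIO()
    with zipfile.ZipFile(io.BytesIO(data)) as src, \
            zipfile.ZipFile(out, "w", zipfile.ZIP_DEFLATED) as dst:
        for name in sorted(src.namelist()):
            blob = src.read(name)
            if name == "docProps/core.xml":
                blob = re.sub(
                    rb"(<dcterms:modified[^>]*>)[^<]*(</dcterms:modified>)",
                    rb"\g<1>1980-01-01T00:00:00Z\g<2>",
                    blob,
                )
            _write_zip(dst, name, blob, reproducible=True)
    return out.getvalue()


def _write_zip(zf: zipfile.ZipFile, arcname: str, data: bytes, reproducible: bool) -> None:
    if reproducible:
        info = zipfile.ZipInfo(arcname, date_time=_REPRO_DATE)
        info.compress_type = zipfile.ZIP_DEFLATED
        info.external_attr = 0o644 << 16
        zf.writestr(info, data)
    else:
        zf.writestr(arcname, data)


# ---------------------------------------------------------------------------
# XLSX workbook


@dataclass
class CurveResult:
    """Everything known about one converted + analyzed curve."""

    ordinal: int
    cycle: Cycle
    peaks: list[Peak] = field(default_factory=list)
    descriptors: DescriptorSet | None = None
    edited: bool = False  # True once a manual peak edit replaced the auto picks


def export_xlsx(
    curves: list[CurveResult],
    merged: MetadataRecord,
    path: str | Path,
) -> None:
    """Write the ``2 + x``-sheet workbook (definitions, metadata, one
    analysis sheet per curve)."""
    import datetime as _dt

    from openpyxl import Workbook

    if not curves:
        raise PackagingError("workbook needs at least one curve")
    wb = Workbook()
    # fixed document timestamps keep workbook bytes reproducible
    wb.properties.created = _dt.datetime(1980, 1, 1)
    wb.properties.modified = _dt.datetime(1980, 1, 1)

    ws = wb.active
    ws.title = "Definitions"
    ws.append(["scheme version", SCHEME_VERSION])
    ws.append(["field id", "label", "unit", "type"])
    for spec in SCHEME:
        ws.append([spec.field_id, spec.label, spec.unit, spec.dtype])

    ws = wb.create_sheet("Metadata")
    ws.append(["field id", "label", "value", "unit", "provenance"])
    for fid, fv in merged.items():
        label = next(s.label for s in SCHEME if s.field_id == fid)
        value = "" if fv.value is None else fv.value
        ws.append([fid, label, value, fv.unit, fv.provenance])
    for key, entry in merged.extensions.items():
        ws.append([key, "(extension)", entry.get("value", ""), "",
                   entry.get("provenance", "")])

    for curve in curves:
        ws = wb.create_sheet(f"Curve {curve.ordinal}")
        ws.append(["peak kind", "E_p / V", "i_p / A", "origin"])
        for p in curve.peaks:
            ws.append([p.kind, p.E_p, p.i_p, p.origin])
        ws.append([])
        d = curve.descriptors
        if d is not None:
            ws.append(["E1/2 / V", d.E_half])
            ws.append(["dEp / mV", d.delta_Ep])
            ws.append(["ipa/ipc", d.ratio])
            ws.append(["ratio mode", d.ratio_mode])
            ws.append(["i_lambda0 / A", d.i_lambda0])
        else:
            ws.append(["descriptors", "not computed"])
    wb.save(path)


# ---------------------------------------------------------------------------
# dataset archive (the downloadable ZIP)


@dataclass
class Dataset:
    """Input to :func:`build_archive`: one converted + analyzed experiment."""

    name: str
    original_filename: str
    original_text: str
    metadata: MetadataRecord
    curves: list[CurveResult]
    selected: set[int] | None = None  # 1-based ordinals for new_combined


@dataclass
class ArchiveLayout:
    dataset_files: list[tuple[str, str]]           # (arcname, role)
    curve_files: dict[int, list[tuple[str, str]]]  # ordinal -> (arcname, role)

    def all_files(self) -> list[tuple[str, str]]:
        out = list(self.dataset_files)
        for k in sorted(self.curve_files):
            out.extend(self.curve_files[k])
        return out


def curve_filename(name: str, ordinal: int, kind: str = "", ext: str = "jdx",
                   naming: str = "underscore") -> str:
    """Per-curve file name; ``naming`` switches between the underscore
    (``-curve1_bagit.peak.jdx``) and dot (``-curve1.bagit.peak.jdx``) dialects."""
    if naming not in ("underscore", "dot"):
        raise PackagingError(f"unknown naming dialect {naming!r}")
    sep = "_" if naming == "underscore" else "."
    stem = f"{name}-curve{ordinal}{sep}bagit"
    if kind:
        stem = f"{stem}.{kind}"
    return f"{stem}.{ext}"


def archive_inventory(
    name: str,
    original_filename: str,
    n_curves: int,
    edited: list[bool],
    auto_picked: list[bool] | None = None,
    naming: str = "underscore",
) -> ArchiveLayout:
    """The archive's file inventory as a pure function of the dataset shape.

    Per curve: the converted JCAMP-DX is always present; the ``.peak``
    file only when automatic picks exist and no manual edit replaced
    them; the ``.edit`` file only after a manual edit.
    """
    if n_curves < 1:
        raise PackagingError("archive needs at least one curve")
    if len(edited) != n_curves:
        raise PackagingError("edited flags must match the curve count")
    if auto_picked is None:
        auto_picked = [True] * n_curves
    dataset_files = [
        ("dataset_description.txt", "dataset description and file list"),
        (original_filename, "original vendor data file"),
        (f"{name}.bag.zip", "BagIt bag from the conversion routine"),
        (f"{name}.xlsx", "metadata and analysis workbook"),
        (f"{name}.combined.png", "preview of all curves"),
        (f"{name}.new_combined.png", "preview of selected curves"),
    ]
    curve_files: dict[int, list[tuple[str, str]]] = {}
    for k in range(1, n_curves + 1):
        files = [(curve_filename(name, k, "", "jdx", naming), "converted curve data")]
        if auto_picked[k - 1] and not edited[k - 1]:
            files.append(
                (curve_filename(name, k, "peak", "jdx", naming), "automatically picked peaks")
            )
        if edited[k - 1]:
            files.append(
                (curve_filename(name, k, "edit", "jdx", naming), "manually edited peaks")
            )
        files.append((curve_filename(name, k, "edit", "png", naming), "curve preview image"))
        files.append((curve_filename(name, k, "edit", "csv", naming), "curve result table"))
        curve_files[k] = files
    return ArchiveLayout(dataset_files, curve_files)


def dataset_description(name: str, layout: ArchiveLayout, created: str) -> str:
    """Key/value header plus one ``<path><TAB><role>`` line per archived file."""
    lines = [
        f"dataset_id: {name}",
        f"created: {created}",
        f"scheme_version: {SCHEME_VERSION}",
    ]
    lines.extend(f"{arcname}\t{role}" for arcname, role in layout.all_files())
    return "\n".join(lines) + "\n"


def build_archive(
    dataset: Dataset,
    out_zip: str | Path,
    naming: str = "underscore",
    reproducible: bool = False,
    created: str | None = None,
) -> ArchiveLayout:
    """Assemble the downloadable ZIP for one dataset."""
    if not dataset.curves:
        raise PackagingError("dataset has no curves")
    if not dataset.original_text:
        raise PackagingError("dataset is missing the original vendor file")
    if dataset.metadata is None:
        raise PackagingError("dataset is missing its metadata record")
    if created is None:
        created = "1980-01-01" if reproducible else __import__("datetime").date.today().isoformat()

    curves = sorted(dataset.curves, key=lambda c: c.ordinal)
    layout = archive_inventory(
        dataset.name,
        dataset.original_filename,
        len(curves),
        [c.edited for c in curves],
        [bool(c.peaks) for c in curves],
        naming,
    )

    # per-curve artifacts
    curve_payload: dict[str, bytes] = {}
    cycle_texts: list[tuple[str, str]] = []
    for c in curves:
        base = write_cycle_jcamp(
            c.cycle, dataset.metadata, title=f"{dataset.name} curve {c.ordinal}"
        )
        cycle_texts.append((curve_filename(dataset.name, c.ordinal, "", "jdx", naming), base))
        curve_payload[curve_filename(dataset.name, c.ordinal, "", "jdx", naming)] = base.encode("utf-8")
        if c.peaks:
            doc = parse_jcamp(base)
            origin = "manual" if c.edited else "auto"
            doc, _suffix = add_peak_block(doc, c.peaks, origin)
            kind = "edit" if c.edited else "peak"
            curve_payload[curve_filename(dataset.name, c.ordinal, kind, "jdx", naming)] = (
                serialize(doc).encode("utf-8")
            )
        png = io.BytesIO()
        render_plot([c.cycle], png, selected=None)
        curve_payload[curve_filename(dataset.name, c.ordinal, "edit", "png", naming)] = png.getvalue()
        if c.descriptors is not None:
            csv_text = export_curve_csv(c.descriptors, c.peaks, dataset.metadata)
        else:
            csv_text = export_curve_csv(
                DescriptorSet(*(float("nan"),) * 5, float("nan"), float("nan"),
                              float("nan"), "direct"),
                c.peaks, dataset.metadata,
            )
        curve_payload[curve_filename(dataset.name, c.ordinal, "edit", "csv", naming)] = (
            csv_text.encode("utf-8")
        )

    # nested bag
    import tempfile

    with tempfile.TemporaryDirectory() as tmp:
        bag_dir = Path(tmp) / dataset.name
        build_bagit(cycle_texts, metadata_to_json(dataset.metadata), bag_dir)
        bag_buf = io.BytesIO()
        with zipfile.ZipFile(bag_buf, "w", zipfile.ZIP_DEFLATED) as zf:
            for p in sorted(bag_dir.rglob("*")):
                if p.is_file():
                    _write_zip(zf, f"{dataset.name}/{p.relative_to(bag_dir)}",
                               p.read_bytes(), reproducible)
        bag_bytes = bag_buf.getvalue()

    xlsx_buf = io.BytesIO()
    export_xlsx(curves, dataset.metadata, xlsx_buf)
    xlsx_bytes = xlsx_buf.getvalue()
    if reproducible:
        xlsx_bytes = _normalize_zip_timestamps(xlsx_bytes)

    combined = io.BytesIO()
    render_plot([c.cycle for c in curves], combined, selected=None)
    selected = dataset.selected or {c.ordinal for c in curves}
    new_combined = io.BytesIO()
    render_plot([c.cycle for c in curves], new_combined, selected=selected)

    description = dataset_description(dataset.name, layout, created)

    with zipfile.ZipFile(out_zip, "w", zipfile.ZIP_DEFLATED) as zf:
        _write_zip(zf, "dataset_description.txt", description.encode("utf-8"), reproducible)
        _write_zip(zf, dataset.original_filename, dataset.original_text.encode("utf-8"),
                   reproducible)
        _write_zip(zf, f"{dataset.name}.bag.zip", bag_bytes, reproducible)
        _write_zip(zf, f"{dataset.name}.xlsx", xlsx_bytes, reproducible)
        _write_zip(zf, f"{dataset.name}.combined.png", combined.getvalue(), reproducible)
        _write_zip(zf, f"{dataset.name}.new_combined.png", new_combined.getvalue(),
                   reproducible)
        for k in sorted(layout.curve_files):
            for arcname, _role in layout.curve_files[k]:
                if arcname in curve_payload:
                    _write_zip(zf, arcname, curve_payload[arcname], reproducible)
    return layout
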