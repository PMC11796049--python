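"""High-level workflow steps: convert -> analyze -> package.

These functions chain the library modules into the on-disk dataset
layout the CLI operates on::

    <workdir>/<dataset>/
        original/<vendor file>          untouched input copy
        bag/                            BagIt bag (data/ = one JCAMP per cycle)
        analysis/                       peak/edit files, CSV, PNG, descriptors.json

Each step is importable and returns plain data so the CLI stays a thin
argument-parsing shell.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

from .analysis import Peak, compute_descriptors, peaks_from_block, pick_peaks, render_plot
from .analysis import export_curve_csv
from .convert import (
    ProfileStore,
    assemble_cycles,
    extract_trace,
    map_metadata,
    match_profile,
    segment_sweeps,
)
from .errors import AnalysisError, CVFlowError, PackagingError
from .jcamp import add_peak_block, parse_jcamp, read_jcamp, serialize, write_cycle_jcamp
from .metadata import MetadataRecord, json_to_metadata, merge_metadata, metadata_to_json
from .packaging import (
    CurveResult,
    Dataset,
    build_archive,
    build_bagit,
    curve_filename,
    validate_bagit,
)
from .readers import read_file

__all__ = ["ConversionResult", "convert_file", "analyze_dataset", "package_dataset"]


@dataclass
class ConversionResult:
    dataset_dir: Path
    bag_dir: Path
    profile_id: str
    n_cycles: int
    cycle_files: list[str] = field(default_factory=list)


def _header_scan_rate(raw, profile) -> float | None:
    """Scan rate from the profile's header mapping, for time synthesis."""
    for entry in profile.metadata_map:
        if entry.target == "scan_rate" and not entry.source.startswith("computed:"):
            value = raw.header_value(entry.source)
            if value is not None:
                try:
                    v = entry.apply(value)
                    return float(v)
                except (TypeError, ValueError):
                    return None
    return None


def convert_file(
    input_path: str | Path,
    store: ProfileStore | None = None,
    workdir: str | Path = ".",
    naming: str = "underscore",
) -> ConversionResult:
    """Read a vendor file, apply its profile, write the per-cycle bag."""
    input_path = Path(input_path)
    if store is None:
        store = ProfileStore.default()
    raw = read_file(input_path)
    profile = match_profile(raw, store)
    trace = extract_trace(raw, profile)
    if trace.t_source == "synthesized-index":
        nu = _header_scan_rate(raw, profile)
        if nu:
            trace = extract_trace(raw, profile, scan_rate=nu)
    cycles = assemble_cycles(segment_sweeps(trace))
    meta = map_metadata(raw, profile, trace)

    name = input_path.stem
    dataset_dir = Path(workdir) / name
    (dataset_dir / "original").mkdir(parents=True, exist_ok=True)
    shutil.copy2(input_path, dataset_dir / "original" / input_path.name)

    cycle_files = []
    for cycle in cycles:
        fname = curve_filename(name, cycle.ordinal, "", "jdx", naming)
        text = write_cycle_jcamp(cycle, meta, title=f"{name} curve {cycle.ordinal}")
        cycle_files.append((fname, text))
    bag_dir = dataset_dir / "bag"
    if bag_dir.exists():
        shutil.rmtree(bag_dir)
    build_bagit(cycle_files, metadata_to_json(meta), bag_dir)
    return ConversionResult(
        dataset_dir=dataset_dir,
        bag_dir=bag_dir,
        profile_id=profile.profile_id,
        n_cycles=len(cycles),
        cycle_files=[f for f, _ in cycle_files],
    )


def _best_peak(peaks: list[Peak], kind: str) -> Peak | None:
    wanted = [p for p in peaks if p.kind == kind]
    if not wanted:
        return None
    return max(wanted, key=lambda p: abs(p.i_p))


def analyze_dataset(
    dataset_dir: str | Path,
    smooth_window: int = 5,
    min_prominence: float = 0.05,
    ratio_mode: str = "direct",
    i_lambda0: float = 0.0,
    manual_peaks: dict[int, list[Peak]] | None = None,
) -> dict[int, dict]:
    """Pick peaks and compute descriptors for every cycle in the bag.

    ``manual_peaks`` maps cycle ordinals to user-chosen peaks; affected
    curves get an ``.edit.jdx`` file replacing the automatic ``.peak.jdx``.
    Returns a per-ordinal summary dict (also written to
    ``analysis/descriptors.json``).
    """
    dataset_dir = Path(dataset_dir)
    bag_dir = dataset_dir / "bag"
    report = validate_bagit(bag_dir)
    if not report.ok:
        raise PackagingError(f"invalid bag: {'; '.join(report.errors)}")
    manual_peaks = manual_peaks or {}
    out_dir = dataset_dir / "analysis"
    out_dir.mkdir(exist_ok=True)

    results: dict[int, dict] = {}
    for jdx_path in sorted((bag_dir / "data").glob("*.jdx")):
        text = jdx_path.read_text(encoding="utf-8")
        cycle, meta_fragment, _ = read_jcamp(text)
        meta = _bag_metadata(bag_dir)
        ordinal = cycle.ordinal
        if ordinal in manual_peaks:
            peaks = list(manual_peaks[ordinal])
            origin = "manual"
        else:
            peaks = []
            for sweep in cycle.sweeps:
                found = pick_peaks(sweep, smooth_window, min_prominence)
                peaks.extend(found)
            origin = "auto"

        doc = parse_jcamp(text)
        doc, suffix = add_peak_block(doc, peaks, origin)
        stem = jdx_path.name[: -len(".jdx")]
        entry: dict = {"peaks": len(peaks), "origin": origin, "file": jdx_path.name}
        if suffix is not None:
            peak_file = out_dir / f"{stem}{suffix}"
            peak_file.write_text(serialize(doc), encoding="utf-8")
            entry["peak_file"] = peak_file.name
            if origin == "manual":
                stale = out_dir / f"{stem}.peak.jdx"
                if stale.exists():
                    stale.unlink()  # the edit file replaces the auto picks

        anodic = _best_peak(peaks, "anodic-max")
        cathodic = _best_peak(peaks, "cathodic-min")
        if anodic is not None and cathodic is not None:
            desc = compute_descriptors(anodic, cathodic, i_lambda0, ratio_mode)
            entry.update(
                E_half=desc.E_half,
                delta_Ep=desc.delta_Ep,
                ratio=desc.ratio,
                ratio_mode=desc.ratio_mode,
            )
            csv_path = out_dir / f"{stem}.edit.csv"
            csv_path.write_text(export_curve_csv(desc, peaks, meta), encoding="utf-8")
        png_path = out_dir / f"{stem}.edit.png"
        render_plot([cycle], png_path)
        results[ordinal] = entry
    if not results:
        raise AnalysisError("bag contains no cycle files")
    (out_dir / "descriptors.json").write_text(
        json.dumps(results, indent=2) + "\n", encoding="utf-8"
    )
    return results


def _bag_metadata(bag_dir: Path) -> MetadataRecord:
    meta_path = bag_dir / "metadata" / "metadata.json"
    if meta_path.is_file():
        return json_to_metadata(meta_path.read_text(encoding="utf-8"))
    return MetadataRecord()


def package_dataset(
    dataset_dir: str | Path,
    out_zip: str | Path | None = None,
    naming: str = "underscore",
    reproducible: bool = False,
    context: MetadataRecord | None = None,
    manual: MetadataRecord | None = None,
):
    """Assemble the downloadable archive for a converted+analyzed dataset."""
    dataset_dir = Path(dataset_dir)
    name = dataset_dir.name
    bag_dir = dataset_dir / "bag"
    meta_path = bag_dir / "metadata" / "metadata.json"
    if not meta_path.is_file():
        raise PackagingError(f"{meta_path} missing; run convert first")
    originals = sorted((dataset_dir / "original").glob("*"))
    if not originals:
        raise PackagingError("original vendor file missing from dataset")
    original = originals[0]

    device_meta = json_to_metadata(meta_path.read_text(encoding="utf-8"))
    analysis_dir = dataset_dir / "analysis"
    desc_file = analysis_dir / "descriptors.json"
    descriptors = json.loads(desc_file.read_text(encoding="utf-8")) if desc_file.is_file() else {}

    analysis_meta = MetadataRecord()
    for ordinal, entry in sorted(descriptors.items(), key=lambda kv: int(kv[0])):
        for key in ("E_half", "delta_Ep", "ratio"):
            if key in entry:
                analysis_meta.set(f"curve{ordinal}_{key}", entry[key], "analysis")
    merged = merge_metadata(
        device=device_meta, context=context, manual=manual, analysis=analysis_meta
    )

    curves = []
    for jdx_path in sorted((bag_dir / "data").glob("*.jdx")):
        cycle, _, _ = read_jcamp(jdx_path.read_text(encoding="utf-8"))
        stem = jdx_path.name[: -len(".jdx")]
        edit_file = analysis_dir / f"{stem}.edit.jdx"
        peak_file = analysis_dir / f"{stem}.peak.jdx"
        peaks: list[Peak] = []
        edited = False
        source = edit_file if edit_file.is_file() else peak_file
        if source.is_file():
            edited = source is edit_file
            _, _, peak_blocks = read_jcamp(source.read_text(encoding="utf-8"))
            for block in peak_blocks:
                peaks.extend(peaks_from_block(block))
        desc = None
        anodic = _best_peak(peaks, "anodic-max")
        cathodic = _best_peak(peaks, "cathodic-min")
        entry = descriptors.get(str(cycle.ordinal), {})
        if anodic is not None and cathodic is not None:
            desc = compute_descriptors(
                anodic, cathodic, mode=entry.get("ratio_mode", "direct")
            )
        curves.append(
            CurveResult(cycle.ordinal, cycle, peaks, desc, edited=edited)
        )
    if not curves:
        raise PackagingError("dataset has no converted curves")

    dataset = Dataset(
        name=name,
        original_filename=original.name,
        original_text=original.read_text(encoding="utf-8"),
        metadata=merged,
        curves=curves,
    )
    if out_zip is None:
        out_zip = dataset_dir / f"{name}.zip"
    layout = build_archive(dataset, out_zip, naming=naming, reproducible=reproducible)
    return Path(out_zip), layout
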