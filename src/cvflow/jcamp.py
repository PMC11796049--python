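"""JCAMP-DX 5.01 writer/reader for cyclic-voltammetry cycles.

One JCAMP-DX file holds one measured cycle (one anodic + one cathodic
sweep).  Because the CV abscissa (potential) is non-monotonic, the data
are written as explicit ``##XYPOINTS=(XY..XY)`` pairs in acquisition
order rather than equal-increment ``##XYDATA``.  Scheme metadata is
embedded as ``##$``-prefixed user labeled-data-records; the authoritative
metadata copy lives in the bag's JSON.

Formatting is canonical — 6 significant digits, ``.`` decimal separator,
LF line endings — so re-serializing a parsed, unmodified document
reproduces identical bytes, and any number of appended peak blocks leaves
the first block (the original cycle data) byte-identical.

Peak tables are appended as additional blocks.  Automatically picked
peaks target a ``.peak.jdx`` file; manual edits target ``.edit.jdx`` and
replace any existing peak block while the original data block is kept
untouched inside the document.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .convert import Cycle, Trace, assemble_cycles, segment_sweeps
from .errors import JcampError, JcampIntegrityError, JcampTruncationError
from .metadata import MetadataRecord

__all__ = [
    "JCAMP_VERSION",
    "fmt6",
    "JcampBlock",
    "JcampDocument",
    "write_cycle_jcamp",
    "parse_jcamp",
    "serialize",
    "read_jcamp",
    "add_peak_block",
    "AUTO_SUFFIX",
    "MANUAL_SUFFIX",
]

JCAMP_VERSION = "5.01"
AUTO_SUFFIX = ".peak.jdx"
MANUAL_SUFFIX = ".edit.jdx"

_DATA_LABELS = ("XYPOINTS", "PEAK TABLE")


def fmt6(x: float) -> str:
    """Canonical 6-significant-digit AFFN formatting (idempotent under
    parse/format round-trips)."""
    s = f"{float(x):.6g}"
    return "0" if s == "-0" else s


@dataclass(eq=False)
class JcampBlock:
    """One ##TITLE..##END block: ordered LDRs plus an optional XY table."""

    ldrs: list[tuple[str, str]] = field(default_factory=list)
    data_label: str | None = None  # "XYPOINTS" | "PEAK TABLE"
    variable_list: str = "(XY..XY)"
    pairs: list[tuple[float, float]] = field(default_factory=list)

    def ldr(self, key: str, default: str | None = None) -> str | None:
        for k, v in self.ldrs:
            if k == key:
                return v
        return default

    @property
    def is_peak_table(self) -> bool:
        return self.data_label == "PEAK TABLE"


@dataclass(eq=False)
class JcampDocument:
    blocks: list[JcampBlock] = field(default_factory=list)

    @property
    def version(self) -> str:
        return self.blocks[0].ldr("JCAMP-DX", JCAMP_VERSION) if self.blocks else JCAMP_VERSION

    @property
    def data_block(self) -> JcampBlock:
        return self.blocks[0]

    @property
    def peak_blocks(self) -> list[JcampBlock]:
        return [b for b in self.blocks if b.is_peak_table]


def _serialize_block(block: JcampBlock) -> str:
    out = [f"##{k}={v}" for k, v in block.ldrs]
    if block.data_label is not None:
        out.append(f"##{block.data_label}={block.variable_list}")
        out.extend(f"{fmt6(x)}, {fmt6(y)}" for x, y in block.pairs)
    out.append("##END=")
    return "\n".join(out) + "\n"


def serialize(doc: JcampDocument) -> str:
    """Canonical text form; byte-stable under parse/serialize."""
    return "".join(_serialize_block(b) for b in doc.blocks)


def parse_jcamp(text: str) -> JcampDocument:
    """Parse one or more concatenated blocks.

    Unknown LDRs are kept verbatim.  A declared NPOINTS that disagrees
    with the actual pair count raises :class:`JcampIntegrityError`; a
    block without ``##END=`` raises :class:`JcampTruncationError`.
    """
    lines = text.splitlines()
    if not lines or not lines[0].startswith("##TITLE="):
        raise JcampError("JCAMP-DX text must start with ##TITLE=")
    blocks: list[JcampBlock] = []
    cur: JcampBlock | None = None

    def finalize(block: JcampBlock) -> None:
        declared = block.ldr("NPOINTS")
        if declared is not None:
            try:
                expected = int(declared)
            except ValueError:
                raise JcampIntegrityError(f"bad NPOINTS value {declared!r}") from None
            if expected != len(block.pairs):
                raise JcampIntegrityError(
                    f"NPOINTS={expected} but block contains {len(block.pairs)} pairs"
                )
        blocks.append(block)

    for raw_line in lines:
        line = raw_line.rstrip("\r")
        if not line.strip():
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            if key == "END":
                if cur is None:
                    raise JcampError("##END= outside of a block")
                finalize(cur)
                cur = None
            elif key == "TITLE":
                if cur is not None:
                    raise JcampTruncationError("new ##TITLE= before ##END=")
                cur = JcampBlock(ldrs=[("TITLE", value)])
            elif cur is None:
                raise JcampError(f"LDR {key!r} outside of a block")
            elif key in _DATA_LABELS:
                cur.data_label = key
                cur.variable_list = value
            else:
                cur.ldrs.append((key, value))
        else:
            if cur is None or cur.data_label is None:
                raise JcampError(f"unexpected data line {line!r}")
            try:
                xs, ys = line.split(",")
                cur.pairs.append((float(xs), float(ys)))
            except ValueError:
                raise JcampError(f"malformed XY pair {line!r}") from None
    if cur is not None:
        raise JcampTruncationError("document ends without ##END=")
    return JcampDocument(blocks)


def write_cycle_jcamp(
    cycle: Cycle,
    meta: MetadataRecord | None = None,
    title: str = "CV cycle",
) -> str:
    """Serialize one cycle (with embedded scheme metadata) to JCAMP-DX text."""
    if cycle is None or not cycle.sweeps or len(cycle) == 0:
        raise JcampError("cannot write an empty cycle")
    E, I, t = cycle.E, cycle.I, cycle.t
    ldrs: list[tuple[str, str]] = [
        ("TITLE", title),
        ("JCAMP-DX", JCAMP_VERSION),
        ("DATA TYPE", "CYCLIC VOLTAMMETRY"),
        ("DATA CLASS", "XYPOINTS"),
        ("XUNITS", "VOLTS"),
        ("YUNITS", "AMPERES"),
    ]
    if meta is not None:
        for fid, fv in meta.items():
            if fv.value is None:
                continue
            if isinstance(fv.value, (int, float)) and not isinstance(fv.value, bool):
                text_value = fmt6(fv.value)
            else:
                text_value = str(fv.value)
            ldrs.append((f"${fid.upper()}", text_value))
    ldrs.append(("$CYCLE_ORDINAL", str(cycle.ordinal)))
    if cycle.partial:
        ldrs.append(("$PARTIAL", "TRUE"))
    dts = np.diff(t)
    if len(dts) and np.allclose(dts, dts[0], rtol=1e-9, atol=1e-12) and dts[0] > 0:
        ldrs.append(("$TFIRST", fmt6(t[0])))
        ldrs.append(("$DELTAT", fmt6(dts[0])))
    ldrs.append(("NPOINTS", str(len(E))))
    block = JcampBlock(ldrs=ldrs, data_label="XYPOINTS", pairs=list(zip(E, I)))
    return serialize(JcampDocument([block]))


def read_jcamp(text: str):
    """Parse JCAMP-DX text back into ``(cycle, meta_fragment, peak_blocks)``.

    ``meta_fragment`` maps the ``##$`` user-LDR names (without the ``$``)
    to their verbatim string values.  The time axis is rebuilt from
    ``$TFIRST``/``$DELTAT`` when present, else as the sample index.
    """
    doc = parse_jcamp(text)
    b0 = doc.data_block
    if b0.data_label != "XYPOINTS":
        raise JcampError("first block must hold the cycle XYPOINTS data")
    meta = {k[1:]: v for k, v in b0.ldrs if k.startswith("$")}
    E = np.array([p[0] for p in b0.pairs])
    I = np.array([p[1] for p in b0.pairs])
    if "TFIRST" in meta and "DELTAT" in meta:
        t0, dt = float(meta["TFIRST"]), float(meta["DELTAT"])
        t = t0 + np.arange(len(E)) * dt
        t_source = "measured"
    else:
        t = np.arange(len(E), dtype=float)
        t_source = "synthesized-index"
    trace = Trace(t, E, I, t_source)
    sweeps = segment_sweeps(trace)
    ordinal = int(meta.get("CYCLE_ORDINAL", "1"))
    partial = meta.get("PARTIAL") == "TRUE" or len(sweeps) < 2
    cycle = Cycle(ordinal=ordinal, sweeps=tuple(sweeps), partial=partial)
    return cycle, meta, doc.peak_blocks


def add_peak_block(doc: JcampDocument, peaks, origin: str):
    """Append a peak-table block and return ``(new_document, file_suffix)``.

    ``origin`` is ``"auto"`` (suffix ``.peak.jdx``) or ``"manual"``
    (suffix ``.edit.jdx``).  Any existing peak block is replaced — a
    manual edit supersedes the automatic picks — and the original data
    block is carried over untouched.  Adding an empty peak list is a
    no-op returning the document unchanged.
    """
    if origin not in ("auto", "manual"):
        raise ValueError(f"peak origin must be 'auto' or 'manual', got {origin!r}")
    if not peaks:
        return doc, None
    if not doc.blocks:
        raise JcampError("document has no data block")
    title = doc.data_block.ldr("TITLE", "CV cycle")
    block = JcampBlock(
        ldrs=[
            ("TITLE", f"{title} peaks"),
            ("JCAMP-DX", JCAMP_VERSION),
            ("DATA TYPE", "CYCLIC VOLTAMMETRY PEAK TABLE"),
            ("XUNITS", "VOLTS"),
            ("YUNITS", "AMPERES"),
            ("$PEAK_ORIGIN", origin),
            ("$PEAK_KINDS", ",".join(p.kind for p in peaks)),
            ("NPOINTS", str(len(peaks))),
        ],
        data_label="PEAK TABLE",
        pairs=[(p.E_p, p.i_p) for p in peaks],
    )
    kept = [b for b in doc.blocks if not b.is_peak_table]
    suffix = AUTO_SUFFIX if origin == "auto" else MANUAL_SUFFIX
    return JcampDocument(kept + [block]), suffix
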