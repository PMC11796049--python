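"""CV metadata scheme, validation, provenance-aware merging, JSON I/O.

There is no community-wide metadata standard for cyclic voltammetry, so
this module defines a versioned target scheme modeled on the ACS
guidelines for reporting electrochemical data: sample and analyte
identity, cell composition (solvent, supporting electrolyte, the three
electrodes, internal reference couple), the potential program (scan rate,
vertex potentials, cycle count), conditions (temperature, atmosphere) and
instrument identity, plus the fixed Chemical Methods Ontology method term
"cyclic voltammetry (CV)".

Every field value carries exactly one provenance tag describing where it
came from:

``device``    extracted from the instrument file by a conversion profile
``computed``  derived from the data itself (e.g. inferred scan rate)
``context``   supplied by the documentation environment (sample, author)
``manual``    entered or corrected by a human
``analysis``  produced by the descriptor computation
``missing``   not available

A full experiment description is the field-wise merge of up to four
record parts with precedence ``manual > analysis > context > device`` —
the human correcting a record must always win.  Records serialize
losslessly to JSON in stable scheme order; unknown field ids survive
round-trips in an ``extensions`` section.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

__all__ = [
    "SCHEME_VERSION",
    "FieldSpec",
    "SCHEME",
    "SCHEME_BY_ID",
    "PROVENANCES",
    "FieldValue",
    "MetadataRecord",
    "ValidationReport",
    "validate_metadata",
    "merge_metadata",
    "metadata_to_json",
    "json_to_metadata",
    "CHMO_METHOD_LABEL",
]

SCHEME_VERSION = "1.0"
CHMO_METHOD_LABEL = "cyclic voltammetry (CV)"

PROVENANCES = frozenset(
    {"device", "context", "manual", "analysis", "computed", "missing"}
)


@dataclass(frozen=True)
class FieldSpec:
    field_id: str
    label: str
    unit: str
    dtype: str  # "str" | "float" | "int"
    minimal: bool = False      # required at the "minimal" validation level
    publication: bool = False  # additionally required at "publication" level


_F = FieldSpec
SCHEME: tuple[FieldSpec, ...] = (
    _F("sample_id", "Sample identifier", "", "str"),
    _F("analyte_name", "Analyte", "", "str"),
    _F("analyte_concentration", "Analyte concentration", "mol/L", "float"),
    _F("solvent", "Solvent", "", "str", publication=True),
    _F("supporting_electrolyte", "Supporting electrolyte", "", "str", publication=True),
    _F("electrolyte_concentration", "Electrolyte concentration", "mol/L", "float"),
    _F("working_electrode", "Working electrode", "", "str", publication=True),
    _F("counter_electrode", "Counter electrode", "", "str", publication=True),
    _F("reference_electrode", "Reference electrode", "", "str", publication=True),
    _F("internal_reference_couple", "Internal reference couple", "", "str", publication=True),
    _F("scan_rate", "Scan rate (nu)", "V/s", "float", minimal=True),
    _F("potential_initial", "Initial potential", "V", "float"),
    _F("potential_vertex1", "First vertex potential", "V", "float", minimal=True),
    _F("potential_vertex2", "Second vertex potential", "V", "float", minimal=True),
    _F("potential_final", "Final potential", "V", "float"),
    _F("step_potential", "Step potential", "V", "float"),
    _F("n_cycles", "Number of cycles", "", "int"),
    _F("temperature", "Temperature", "K", "float"),
    _F("atmosphere", "Atmosphere", "", "str"),
    _F("instrument_vendor", "Instrument vendor", "", "str"),
    _F("instrument_model", "Instrument model", "", "str"),
    _F("software_version", "Software version", "", "str"),
    _F("measurement_date", "Measurement date", "", "str"),
    _F("operator", "Operator", "", "str"),
    _F("method_term_label", "Method term", "", "str"),
    _F("method_term_source", "Method term source", "", "str"),
)
SCHEME_BY_ID = {f.field_id: f for f in SCHEME}


@dataclass
class FieldValue:
    value: object
    unit: str
    provenance: str


class MetadataRecord:
    """A CV metadata record: scheme fields with provenance plus extensions."""

    def __init__(self) -> None:
        self._fields: dict[str, FieldValue] = {}
        self.extensions: dict[str, dict] = {}
        self.conflicts: list[str] = []

    def set(self, field_id: str, value, provenance: str, unit: str | None = None) -> None:
        if provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {provenance!r}")
        spec = SCHEME_BY_ID.get(field_id)
        if spec is None:
            self.extensions[field_id] = {"value": value, "provenance": provenance}
            return
        if spec.dtype in ("float", "int") and isinstance(value, str):
            try:
                value = float(value) if spec.dtype == "float" else int(float(value))
            except ValueError:
                pass  # kept verbatim; flagged by validate_metadata
        self._fields[field_id] = FieldValue(value, unit if unit is not None else spec.unit, provenance)

    def get(self, field_id: str, default=None):
        fv = self._fields.get(field_id)
        return default if fv is None or fv.value is None else fv.value

    def provenance(self, field_id: str) -> str:
        fv = self._fields.get(field_id)
        return "missing" if fv is None else fv.provenance

    def unit(self, field_id: str) -> str:
        fv = self._fields.get(field_id)
        if fv is not None:
            return fv.unit
        spec = SCHEME_BY_ID.get(field_id)
        return spec.unit if spec else ""

    def is_set(self, field_id: str) -> bool:
        fv = self._fields.get(field_id)
        return fv is not None and fv.value is not None

    def items(self):
        """Yield (field_id, FieldValue) in scheme order, missing fields included."""
        for spec in SCHEME:
            fv = self._fields.get(spec.field_id)
            if fv is None:
                fv = FieldValue(None, spec.unit, "missing")
            yield spec.field_id, fv

    def set_fields(self) -> dict[str, FieldValue]:
        return dict(self._fields)

    def copy(self) -> "MetadataRecord":
        out = MetadataRecord()
        out._fields = {k: FieldValue(v.value, v.unit, v.provenance) for k, v in self._fields.items()}
        out.extensions = {k: dict(v) for k, v in self.extensions.items()}
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, MetadataRecord):
            return NotImplemented
        return (
            {k: (v.value, v.unit, v.provenance) for k, v in self._fields.items()}
            == {k: (v.value, v.unit, v.provenance) for k, v in other._fields.items()}
            and self.extensions == other.extensions
        )

    def __repr__(self) -> str:
        n = len(self._fields)
        return f"MetadataRecord({n} fields set, {len(self.extensions)} extensions)"


@dataclass
class ValidationReport:
    missing: list[str] = field(default_factory=list)
    malformed: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.missing and not self.malformed


def _is_number(v) -> bool:
    return isinstance(v, (int, float)) and not isinstance(v, bool)


def validate_metadata(rec: MetadataRecord, level: str = "minimal") -> ValidationReport:
    """Report missing/malformed fields; never raises.

    ``minimal`` requires the scan rate and the potential window (both
    vertices); ``publication`` additionally requires the cell description
    (electrodes, electrolyte, solvent, internal reference couple).
    """
    if level not in ("minimal", "publication"):
        raise ValueError(f"unknown validation level {level!r}")
    report = ValidationReport()
    for spec in SCHEME:
        required = spec.minimal or (level == "publication" and spec.publication)
        if required and not rec.is_set(spec.field_id):
            report.missing.append(spec.field_id)
    for fid, fv in rec.set_fields().items():
        spec = SCHEME_BY_ID[fid]
        if fv.value is None:
            continue
        if spec.dtype in ("float", "int") and not _is_number(fv.value):
            report.malformed.append(f"{fid}: not numeric ({fv.value!r})")
            continue
        if fid == "scan_rate" and fv.value <= 0:
            report.malformed.append(f"scan_rate: must be > 0 (got {fv.value})")
        if fid == "n_cycles" and fv.value < 1:
            report.malformed.append(f"n_cycles: must be >= 1 (got {fv.value})")
        if fid == "temperature" and fv.value <= 0:
            report.malformed.append(f"temperature: must be > 0 K (got {fv.value})")
        if fid.endswith("_concentration") and fv.value < 0:
            report.malformed.append(f"{fid}: must be >= 0 (got {fv.value})")
    return report


def merge_metadata(
    device: MetadataRecord | None = None,
    context: MetadataRecord | None = None,
    manual: MetadataRecord | None = None,
    analysis: MetadataRecord | None = None,
) -> MetadataRecord:
    """Field-wise union of the four record parts.

    Precedence ``manual > analysis > context > device``: later parts refine
    earlier ones, the winning source's provenance is retained, and every
    superseded disagreement is appended to ``result.conflicts``.
    """
    out = MetadataRecord()
    for _name, part in (("device", device), ("context", context),
                        ("analysis", analysis), ("manual", manual)):
        if part is None:
            continue
        for fid, fv in part.set_fields().items():
            if fv.value is None or fv.provenance == "missing":
                continue
            prev = out._fields.get(fid)
            if prev is not None and prev.value != fv.value:
                out.conflicts.append(
                    f"{fid}: {prev.value!r} ({prev.provenance}) superseded by "
                    f"{fv.value!r} ({fv.provenance})"
                )
            out._fields[fid] = FieldValue(fv.value, fv.unit, fv.provenance)
        for k, v in part.extensions.items():
            out.extensions[k] = dict(v)
    return out


def metadata_to_json(rec: MetadataRecord) -> str:
    """Serialize to JSON with stable scheme-ordered keys (lossless)."""
    doc = {
        "scheme_version": SCHEME_VERSION,
        "fields": {
            fid: {"value": fv.value, "unit": fv.unit, "provenance": fv.provenance}
            for fid, fv in rec.items()
        },
        "extensions": rec.extensions,
    }
    return json.dumps(doc, indent=2, ensure_ascii=False) + "\n"


def json_to_metadata(text: str) -> MetadataRecord:
    """Parse the JSON form; unknown field ids are kept in ``extensions``."""
    doc = json.loads(text)
    rec = MetadataRecord()
    for fid, entry in doc.get("fields", {}).items():
        if fid in SCHEME_BY_ID:
            if entry.get("provenance", "missing") == "missing":
                continue
            rec._fields[fid] = FieldValue(
                entry.get("value"), entry.get("unit", SCHEME_BY_ID[fid].unit),
                entry.get("provenance", "missing"),
            )
        else:
            rec.extensions[fid] = dict(entry)
    for k, v in doc.get("extensions", {}).items():
        rec.extensions[k] = dict(v)
    return rec
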