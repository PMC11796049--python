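"""Profile-driven conversion: match, extract, segment, infer, map.

A :class:`ConversionProfile` is the stored, identifier-triggered rule set
that turns one device's :class:`~cvflow.readers.RawFileModel` into a
potential/current/time :class:`Trace`, its monotonic :class:`Sweep`
segments and paired :class:`Cycle` objects, and a device-extracted
metadata record.  The first file from a new device defines the profile;
every later file carrying the same identifiers is converted without
further configuration.

Units are normalized at the profile boundary: potentials are stored in
volts and currents in amperes internally; a profile's ``scale`` transform
converts whatever the vendor writes (e.g. a scan rate in mV/s).
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from .errors import (
    ConversionError,
    NoProfileError,
    NoSweepError,
    ProfileError,
    ScanRateUnavailableError,
)
from .metadata import CHMO_METHOD_LABEL, MetadataRecord
from .readers import RawFileModel, RawTable

__all__ = [
    "Trace",
    "Sweep",
    "Cycle",
    "IdentifierRule",
    "DataMap",
    "MetadataMapEntry",
    "ConversionProfile",
    "ProfileStore",
    "match_profile",
    "extract_trace",
    "segment_sweeps",
    "assemble_cycles",
    "infer_scan_rate",
    "map_metadata",
    "round_sig",
]


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (0.0 stays 0.0)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + sig - 1)


# ---------------------------------------------------------------------------
# trace / sweep / cycle


@dataclass(eq=False)
class Trace:
    """Equal-length time (s), potential (V) and current (A) series.

    ``t_source`` records whether the time axis was measured by the
    instrument or synthesized (``"synthesized-index"`` /
    ``"synthesized-scan-rate"``); scan-rate inference needs a measured axis.
    """

    t: np.ndarray
    E: np.ndarray
    I: np.ndarray
    t_source: str = "measured"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if not (len(self.t) == len(self.E) == len(self.I)):
            raise ConversionError("t, E, I must have equal length")
        if len(self.E) < 4:
            raise ConversionError("trace needs at least 4 samples")
        for name, arr in (("t", self.t), ("E", self.E), ("I", self.I)):
            if not np.all(np.isfinite(arr)):
                raise ConversionError(f"non-finite values in {name}")
        if np.any(np.diff(self.t) < 0):
            raise ConversionError("time axis must be non-decreasing")

    def __len__(self) -> int:
        return len(self.E)


@dataclass(eq=False)
class Sweep:
    """A contiguous monotone-potential slice of a trace.

    ``direction`` is ``"anodic"`` (potential increasing) or ``"cathodic"``
    (decreasing); ``index`` is the 0-based ordinal within the trace.
    """

    trace: Trace
    start: int
    stop: int
    direction: str
    index: int

    @property
    def t(self) -> np.ndarray:
        return self.trace.t[self.start:self.stop]

    @property
    def E(self) -> np.ndarray:
        return self.trace.E[self.start:self.stop]

    @property
    def I(self) -> np.ndarray:
        return self.trace.I[self.start:self.stop]

    def __len__(self) -> int:
        return self.stop - self.start


@dataclass(eq=False)
class Cycle:
    """One anodic + one cathodic sweep; ``partial`` if the trailing sweep
    had no partner."""

    ordinal: int
    sweeps: tuple
    partial: bool = False

    @property
    def t(self) -> np.ndarray:
        return np.concatenate([s.t for s in self.sweeps])

    @property
    def E(self) -> np.ndarray:
        return np.concatenate([s.E for s in self.sweeps])

    @property
    def I(self) -> np.ndarray:
        return np.concatenate([s.I for s in self.sweeps])

    def sweep(self, direction: str):
        for s in self.sweeps:
            if s.direction == direction:
                return s
        return None

    @property
    def anodic(self):
        return self.sweep("anodic")

    @property
    def cathodic(self):
        return self.sweep("cathodic")

    def __len__(self) -> int:
        return sum(len(s) for s in self.sweeps)


def segment_sweeps(trace: Trace, min_run: int = 3) -> list[Sweep]:
    """Split a trace into direction-monotone sweeps.

    A boundary is placed where the sign of ``E[k+1] - E[k]`` changes and the
    new sign persists for at least ``min_run`` samples (a run of ``m``
    equal-sign steps spans ``m + 1`` samples), so single-sample jitter never
    splits a sweep.  Zero-step plateaus inherit the previous sign.  Every
    point belongs to exactly one sweep and concatenating the sweeps in order
    reproduces the trace.
    """
    if min_run < 2:
        raise ConversionError("min_run must be >= 2")
    E = trace.E
    n = len(E)
    steps = np.sign(np.diff(E)).astype(int)
    nz = np.nonzero(steps)[0]
    if nz.size == 0:
        raise NoSweepError("potential is constant; no sweeps found")
    # plateaus inherit the previous sign (leading plateau: the first real sign)
    cur = steps[nz[0]]
    for k in range(len(steps)):
        if steps[k] == 0:
            steps[k] = cur
        else:
            cur = steps[k]

    min_steps = min_run - 1  # persistence in steps, counted in samples

    def persists(k: int, s: int) -> bool:
        end = k
        while end < len(steps) and steps[end] == s:
            end += 1
        return end - k >= min_steps

    # initial direction: first sign that actually persists
    cur_dir = steps[0]
    for k in range(len(steps)):
        if persists(k, steps[k]):
            cur_dir = steps[k]
            break

    bounds: list[tuple[int, int, int]] = []
    seg_start = 0
    for k in range(len(steps)):
        s = steps[k]
        if s != cur_dir and persists(k, s):
            bounds.append((seg_start, k + 1, cur_dir))
            seg_start = k + 1
            cur_dir = s
    bounds.append((seg_start, n, cur_dir))
    return [
        Sweep(trace, a, b, "anodic" if d > 0 else "cathodic", i)
        for i, (a, b, d) in enumerate(bounds)
    ]


def assemble_cycles(sweeps: list[Sweep]) -> list[Cycle]:
    """Pair consecutive sweeps into cycles; an unpaired trailing sweep
    becomes a partial cycle."""
    cycles = []
    for i in range(0, len(sweeps), 2):
        pair = tuple(sweeps[i:i + 2])
        cycles.append(Cycle(ordinal=i // 2 + 1, sweeps=pair, partial=len(pair) < 2))
    return cycles


def infer_scan_rate(trace: Trace, min_run: int = 3) -> float:
    """Scan rate nu (V/s) as the median of |dE/dt| over in-sweep sample
    pairs, reported to 3 significant figures.

    The median is robust to vertex samples and occasional dropped points.
    Raises :class:`ScanRateUnavailableError` if the trace has no measured
    time axis.
    """
    if trace.t_source != "measured":
        raise ScanRateUnavailableError(
            "trace has no measured time axis; scan rate unavailable"
        )
    sweeps = segment_sweeps(trace, min_run=min_run)
    rates = []
    for s in sweeps:
        dE = np.diff(s.E)
        dt = np.diff(s.t)
        mask = dt > 0
        if np.any(mask):
            rates.append(np.abs(dE[mask] / dt[mask]))
    if not rates:
        raise ScanRateUnavailableError("no usable time increments in trace")
    return round_sig(float(np.median(np.concatenate(rates))), 3)


# ---------------------------------------------------------------------------
# profiles


@dataclass(frozen=True)
class IdentifierRule:
    """One identifier: a regex searched in the file name, the header
    (as ``KEY=VALUE`` strings) or the table names."""

    scope: str  # "filename" | "header" | "table-name"
    pattern: str
    required: bool = True

    def matches(self, raw: RawFileModel) -> bool:
        rx = re.compile(self.pattern)
        if self.scope == "filename":
            candidates = [raw.source_name]
        elif self.scope == "header":
            candidates = [f"{k}={v}" for k, v in raw.header]
        elif self.scope == "table-name":
            candidates = [t.name for t in raw.tables]
        else:
            raise ProfileError(f"unknown identifier scope {self.scope!r}")
        return any(rx.search(c) for c in candidates)


@dataclass
class DataMap:
    """Where the trace lives: a table selector (index or name regex) and
    the potential/current/time column labels."""

    table: int | str = 0
    x_column: str = "E"
    y_column: str = "I"
    t_column: str | None = None


@dataclass
class MetadataMapEntry:
    """Map one header key (or ``computed:<name>``) onto a scheme field."""

    source: str
    target: str
    transform: dict = dc_field(default_factory=lambda: {"type": "none"})

    def apply(self, value: str):
        kind = self.transform.get("type", "none")
        if kind == "none":
            return value
        if kind == "scale":
            return float(value) * float(self.transform["factor"])
        if kind == "lookup":
            return self.transform["table"].get(str(value), value)
        raise ProfileError(f"unknown transform {kind!r}")


@dataclass
class ConversionProfile:
    profile_id: str
    identifiers: list[IdentifierRule]
    data_map: DataMap
    metadata_map: list[MetadataMapEntry] = dc_field(default_factory=list)
    output_policy: str = "one-file-per-cycle"

    def validate(self) -> None:
        if not self.profile_id:
            raise ProfileError("profile_id must be non-empty")
        if not any(r.required for r in self.identifiers):
            raise ProfileError(
                f"profile {self.profile_id!r} needs at least one required identifier"
            )
        if self.output_policy != "one-file-per-cycle":
            raise ProfileError(f"unknown output policy {self.output_policy!r}")

    def required_ok(self, raw: RawFileModel) -> bool:
        return all(r.matches(raw) for r in self.identifiers if r.required)

    def satisfied_rules(self, raw: RawFileModel) -> int:
        return sum(1 for r in self.identifiers if r.matches(raw))

    # JSON document form (the on-disk profile store format)

    def to_dict(self) -> dict:
        return {
            "profile_id": self.profile_id,
            "identifiers": [
                {"scope": r.scope, "pattern": r.pattern, "required": r.required}
                for r in self.identifiers
            ],
            "data_map": {
                "table": self.data_map.table,
                "x_column": self.data_map.x_column,
                "y_column": self.data_map.y_column,
                "t_column": self.data_map.t_column,
            },
            "metadata_map": [
                {"source": e.source, "target": e.target, "transform": e.transform}
                for e in self.metadata_map
            ],
            "output_policy": self.output_policy,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ConversionProfile":
        try:
            dm = doc.get("data_map", {})
            profile = cls(
                profile_id=doc["profile_id"],
                identifiers=[
                    IdentifierRule(r["scope"], r["pattern"], bool(r.get("required", True)))
                    for r in doc.get("identifiers", [])
                ],
                data_map=DataMap(
                    table=dm.get("table", 0),
                    x_column=dm.get("x_column", "E"),
                    y_column=dm.get("y_column", "I"),
                    t_column=dm.get("t_column"),
                ),
                metadata_map=[
                    MetadataMapEntry(
                        e["source"], e["target"], e.get("transform", {"type": "none"})
                    )
                    for e in doc.get("metadata_map", [])
                ],
                output_policy=doc.get("output_policy", "one-file-per-cycle"),
            )
        except KeyError as exc:
            raise ProfileError(f"profile document missing key {exc}") from None
        profile.validate()
        return profile

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "ConversionProfile":
        return cls.from_dict(json.loads(text))


class ProfileStore:
    """A set of profiles with unique ids, loadable from a directory of
    JSON documents or from the profiles shipped with the package."""

    def __init__(self, profiles=()):
        self._profiles: dict[str, ConversionProfile] = {}
        for p in profiles:
            self.add(p)

    def add(self, profile: ConversionProfile) -> None:
        profile.validate()
        if profile.profile_id in self._profiles:
            raise ProfileError(f"duplicate profile_id {profile.profile_id!r}")
        self._profiles[profile.profile_id] = profile

    def get(self, profile_id: str) -> ConversionProfile:
        return self._profiles[profile_id]

    def __iter__(self):
        return iter(self._profiles.values())

    def __len__(self) -> int:
        return len(self._profiles)

    @classmethod
    def load_dir(cls, path: str | Path) -> "ProfileStore":
        path = Path(path)
        if not path.is_dir():
            raise ProfileError(f"profile store directory {path} not found")
        store = cls()
        for doc in sorted(path.glob("*.json")):
            store.add(ConversionProfile.from_json(doc.read_text(encoding="utf-8")))
        return store

    @classmethod
    def default(cls) -> "ProfileStore":
        """The profiles shipped with the package (Gamry + PalmSens CV)."""
        from importlib.resources import files

        store = cls()
        root = files("cvflow").joinpath("data/profiles")
        for doc in sorted(root.iterdir(), key=lambda p: p.name):
            if doc.name.endswith(".json"):
                store.add(ConversionProfile.from_json(doc.read_text(encoding="utf-8")))
        return store


def match_profile(raw: RawFileModel, store: ProfileStore) -> ConversionProfile:
    """Return the profile whose required identifiers all match.

    Tie-break: the profile with the most satisfied rules (required or
    optional) wins; remaining ties resolve to the lexicographically
    smallest profile_id, so matching is deterministic.
    """
    if len(store) == 0:
        raise ProfileError("profile store is empty")
    candidates = [p for p in store if p.required_ok(raw)]
    if not candidates:
        raise NoProfileError(
            f"no profile matches {raw.source_name!r}; file parked for manual profiling"
        )
    candidates.sort(key=lambda p: (-p.satisfied_rules(raw), p.profile_id))
    return candidates[0]


def extract_trace(
    raw: RawFileModel,
    profile: ConversionProfile,
    scan_rate: float | None = None,
) -> Trace:
    """Build the trace from the profile's mapped table and columns.

    If the profile names no time column, time is synthesized: from the
    cumulative ``|dE| / nu`` when a scan rate is supplied, otherwise as the
    sample index (leaving the scan rate uninferable).
    """
    dm = profile.data_map
    table: RawTable | None = None
    if isinstance(dm.table, int):
        if 0 <= dm.table < len(raw.tables):
            table = raw.tables[dm.table]
    else:
        rx = re.compile(dm.table)
        for t in raw.tables:
            if rx.search(t.name):
                table = t
                break
    if table is None:
        raise ConversionError(f"table {dm.table!r} not found in {raw.source_name}")

    def column(label: str) -> int:
        idx = table.column_index(label)
        if idx is None:
            raise ConversionError(f"column {label} not found in table {table.name}")
        return idx

    arr = np.asarray(table.rows, dtype=float)
    E = arr[:, column(dm.x_column)]
    I = arr[:, column(dm.y_column)]
    if dm.t_column is not None:
        t = arr[:, column(dm.t_column)]
        t_source = "measured"
    elif scan_rate is not None and scan_rate > 0:
        t = np.concatenate([[0.0], np.cumsum(np.abs(np.diff(E))) / scan_rate])
        t_source = "synthesized-scan-rate"
    else:
        t = np.arange(len(E), dtype=float)
        t_source = "synthesized-index"
    return Trace(t, E, I, t_source)


def map_metadata(
    raw: RawFileModel,
    profile: ConversionProfile,
    trace: Trace,
) -> MetadataRecord:
    """Resolve the profile's metadata map into a device-extracted record.

    Header sources are copied with their transform (provenance ``device``);
    ``computed:*`` sources and the always-available derived quantities
    (scan rate, potential window, cycle count) come from the trace itself
    (provenance ``computed``).  Unresolvable sources leave fields missing —
    conversion still succeeds, mirroring devices whose text exports carry
    no mappable headers.
    """
    rec = MetadataRecord()
    sweeps = segment_sweeps(trace)
    cycles = assemble_cycles(sweeps)

    computed: dict[str, object] = {"n_cycles": len(cycles)}
    try:
        computed["scan_rate"] = infer_scan_rate(trace)
    except ScanRateUnavailableError:
        pass
    first_anodic = sweeps[0].direction == "anodic"
    e_max, e_min = float(trace.E.max()), float(trace.E.min())
    computed["potential_vertex1"] = e_max if first_anodic else e_min
    computed["potential_vertex2"] = e_min if first_anodic else e_max
    computed["potential_initial"] = float(trace.E[0])
    computed["potential_final"] = float(trace.E[-1])

    for entry in profile.metadata_map:
        if entry.source.startswith("computed:"):
            name = entry.source.split(":", 1)[1]
            if name == "potential_window":
                rec.set("potential_vertex1", computed["potential_vertex1"], "computed")
                rec.set("potential_vertex2", computed["potential_vertex2"], "computed")
            elif name in computed:
                rec.set(entry.target, computed[name], "computed")
            # unresolved computed source: field stays missing
        else:
            value = raw.header_value(entry.source)
            if value is None:
                continue
            rec.set(entry.target, entry.apply(value), "device")

    for fid in (
        "scan_rate",
        "n_cycles",
        "potential_vertex1",
        "potential_vertex2",
        "potential_initial",
        "potential_final",
    ):
        if not rec.is_set(fid) and fid in computed:
            rec.set(fid, computed[fid], "computed")
    if not rec.is_set("method_term_label"):
        rec.set("method_term_label", CHMO_METHOD_LABEL, "context")
    if not rec.is_set("method_term_source"):
        rec.set("method_term_source", "CHMO", "context")
    return rec
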