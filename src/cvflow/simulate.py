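"""Synthetic cyclic voltammograms and vendor-dialect fixture files.

The simulator produces physically plausible CV traces for a reversible
(Nernstian) one-step redox couple so that every pipeline stage can be
exercised with known ground truth and no instrument:

* a triangular potential program between two vertex potentials at a
  fixed scan rate nu over ``n_cycles`` cycles;
* faradaic current from 1-D semi-infinite diffusion of the reduced and
  oxidized species, solved with an explicit (FTCS) finite-difference
  scheme under a Nernstian surface condition — the reversible limit, so
  the formal potential E0 and the textbook ~57-59 mV peak separation are
  exact reference points;
* a capacitive background ``+-nu * C_dl`` whose sign flips at the
  vertices;
* optional Gaussian current noise, seeded, applied last — the potential
  program stays exact, matching the dominant noise source of staircase
  instruments.

The same module writes traces out in the vendor fixture dialects
(``gamry-dta`` / ``palmsens-csv``) so the readers, converter, analysis
and packaging layers all see realistic inputs.  Identical parameters
(including the seed) produce byte-identical fixture files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np

from .convert import Trace
from .errors import SimulationError
from .readers import RawFileModel, RawTable

__all__ = [
    "SimParams",
    "REVERSIBLE_PRESET",
    "load_preset",
    "potential_program",
    "simulate_cv",
    "write_fixture",
    "render_raw",
    "fixture_header",
]

FARADAY = 96485.33212  # C/mol
GAS_CONSTANT = 8.314462618  # J/(mol K)

_MAX_STEP_E = 0.002    # V; |dE| per sample must stay at or below this
_FTCS_LIMIT = 0.45     # explicit-scheme stability bound on D*dt/dx^2
_NODES_PER_DELTA = 14  # space nodes per nu-diffusion length sqrt(D*RT/(F*nu))


@dataclass(frozen=True)
class SimParams:
    """Simulator inputs (cm-based electrochemical unit conventions).

    Defaults define the reversible reference condition: a 1 mM couple
    with D = 1e-5 cm^2/s on a 3 mm disc (A = 0.0707 cm^2), formal
    potential E0 = 0.25 V centered in a symmetric 0 -> 0.5 -> 0 V window,
    nu = 0.1 V/s, three cycles at 298.15 K, 1 mV per sample, no added
    noise and no double-layer capacitance.
    """

    E_start: float = 0.0       # V
    E_vertex1: float = 0.5     # V
    E_vertex2: float = 0.0     # V
    scan_rate: float = 0.1     # V/s
    n_cycles: int = 3
    E0: float = 0.25           # V, formal potential
    n_electrons: int = 1
    D: float = 1.0e-5          # cm^2/s
    C_bulk: float = 1.0e-6     # mol/cm^3 (1 mM)
    A: float = 0.0707          # cm^2
    C_dl: float = 0.0          # F
    T: float = 298.15          # K
    dt: float = 0.01           # s
    noise_sigma_I: float = 0.0  # A
    seed: int = 0
    oxidized_fraction: float = 0.5  # bulk fraction of the couple present as O
    t_hold: float = 5.0  # s of equilibration at E_start before the sweep

    def __post_init__(self) -> None:
        if self.scan_rate <= 0:
            raise SimulationError("scan_rate must be > 0")
        if self.n_cycles < 1:
            raise SimulationError("n_cycles must be >= 1")
        if self.E_vertex1 == self.E_vertex2:
            raise SimulationError("vertex potentials must differ")
        if self.dt <= 0:
            raise SimulationError("dt must be > 0")
        if self.scan_rate * self.dt > _MAX_STEP_E + 1e-12:
            raise SimulationError(
                f"dt too coarse: |dE| per step = {self.scan_rate * self.dt * 1e3:.3g} mV > 2 mV"
            )
        if self.n_electrons < 1:
            raise SimulationError("n_electrons must be >= 1")
        if not 0.0 <= self.oxidized_fraction <= 1.0:
            raise SimulationError("oxidized_fraction must lie in [0, 1]")
        if self.t_hold < 0:
            raise SimulationError("t_hold must be >= 0")


REVERSIBLE_PRESET = SimParams()


def load_preset(name: str) -> SimParams:
    """Load a named preset shipped with the package as JSON."""
    from importlib.resources import files

    doc = files("cvflow").joinpath(f"data/presets/{name}.json")
    try:
        text = doc.read_text(encoding="utf-8")
    except FileNotFoundError:
        raise SimulationError(f"unknown preset {name!r}") from None
    return SimParams(**json.loads(text))


def potential_program(p: SimParams) -> np.ndarray:
    """Triangular potential program sampled every ``dt``.

    Segment 1 runs from E_start to the first vertex; thereafter the
    program alternates between the vertices, two sweeps per cycle.
    """
    dE = p.scan_rate * p.dt

    def ramp(a: float, b: float, include_start: bool) -> np.ndarray:
        m = max(1, round(abs(b - a) / dE))
        pts = a + (b - a) * np.arange(0, m + 1) / m
        return pts if include_start else pts[1:]

    segments = [ramp(p.E_start, p.E_vertex1, True)]
    level = p.E_vertex1
    for _ in range(2 * p.n_cycles - 1):
        nxt = p.E_vertex2 if level == p.E_vertex1 else p.E_vertex1
        segments.append(ramp(level, nxt, False))
        level = nxt
    return np.concatenate(segments)


def simulate_cv(p: SimParams) -> Trace:
    """Simulate one CV experiment; deterministic for a fixed seed.

    The faradaic current comes from an explicit (FTCS) finite-difference
    solution of 1-D semi-infinite diffusion for both halves of the couple
    with equal diffusivities.  The space grid resolves the nu-diffusion
    length ``sqrt(D*RT/(F*nu))`` with ~14 nodes and extends over
    ``6*sqrt(D*t_max)``; the solver sub-steps each sample so that
    ``D*dt/dx^2 <= 0.45`` (raising :class:`SimulationError` if no valid
    sub-stepping exists), and the potential ramp is interpolated at
    sub-step resolution so the applied program is the exact triangle, not
    a staircase.  Surface gradients (Nernst flux balance and the measured
    current) use second-order one-sided differences.
    """
    E = potential_program(p)
    n_t = len(E)
    t = np.arange(n_t) * p.dt

    I = np.zeros(n_t)
    if p.C_bulk > 0:
        f = p.n_electrons * FARADAY / (GAS_CONSTANT * p.T)
        delta = math.sqrt(p.D / (f * p.scan_rate))
        dx = delta / _NODES_PER_DELTA
        sub = max(1, math.ceil(p.D * p.dt / (_FTCS_LIMIT * dx * dx)))
        if sub > 10_000:
            raise SimulationError(
                "FTCS stability would need more than 10000 sub-steps per sample; "
                "increase dt or the diffusion coefficient"
            )
        dt_sub = p.dt / sub
        lam = p.D * dt_sub / dx**2
        t_max = (t[-1] if t[-1] > 0 else p.dt) + p.t_hold
        n_x = int(6.0 * math.sqrt(p.D * t_max) / dx) + 1
        c_red_bulk = p.C_bulk * (1.0 - p.oxidized_fraction)
        c_ox_bulk = p.C_bulk * p.oxidized_fraction
        c_red = np.full(n_x + 1, c_red_bulk)
        c_ox = np.full(n_x + 1, c_ox_bulk)

        def apply_surface(theta: float) -> None:
            # zero total flux at the surface (equal D), second order
            total = (4.0 * (c_red[1] + c_ox[1]) - (c_red[2] + c_ox[2])) / 3.0
            c_red[0] = total / (1.0 + theta)
            c_ox[0] = total - c_red[0]

        def current() -> float:
            return (
                p.n_electrons * FARADAY * p.A * p.D
                * (-3.0 * c_red[0] + 4.0 * c_red[1] - c_red[2]) / (2.0 * dx)
            )

        # equilibrate at E_start: the diffusion layer relaxes before the
        # sweep starts, as in a real measurement's initial hold
        theta0 = math.exp(f * (E[0] - p.E0))
        for _ in range(int(round(p.t_hold / dt_sub))):
            apply_surface(theta0)
            c_red[1:-1] += lam * (c_red[2:] - 2 * c_red[1:-1] + c_red[:-2])
            c_ox[1:-1] += lam * (c_ox[2:] - 2 * c_ox[1:-1] + c_ox[:-2])
            c_red[-1] = c_red_bulk
            c_ox[-1] = c_ox_bulk

        apply_surface(theta0)
        I[0] = current()
        for k in range(1, n_t):
            for j in range(1, sub + 1):
                E_j = E[k - 1] + (E[k] - E[k - 1]) * j / sub
                apply_surface(math.exp(f * (E_j - p.E0)))
                c_red[1:-1] += lam * (c_red[2:] - 2 * c_red[1:-1] + c_red[:-2])
                c_ox[1:-1] += lam * (c_ox[2:] - 2 * c_ox[1:-1] + c_ox[:-2])
                c_red[-1] = c_red_bulk
                c_ox[-1] = c_ox_bulk
            apply_surface(math.exp(f * (E[k] - p.E0)))
            I[k] = current()

    if p.C_dl > 0:
        dEdt = np.empty(n_t)
        dEdt[:-1] = np.diff(E) / p.dt
        dEdt[-1] = dEdt[-2]
        I += p.C_dl * dEdt

    if p.noise_sigma_I > 0:
        rng = np.random.default_rng(p.seed)
        I = I + rng.normal(0.0, p.noise_sigma_I, n_t)

    return Trace(t, E, I, t_source="measured")


# ---------------------------------------------------------------------------
# fixture writers


def _cell(x: float) -> float:
    """Quantize a value to the 6-significant-digit fixture precision."""
    return float(f"{float(x):.6g}")


def fixture_header(p: SimParams, dialect: str, name: str = "cv-experiment") -> dict[str, str]:
    """Realistic vendor-style header tags for a simulated run.

    The Gamry dialect reports SCANRATE in mV/s (profiles scale it back);
    the PalmSens dialect reports the scan rate in V/s.
    """
    if dialect == "gamry-dta":
        return {
            "EXPLAIN": "CV",
            "TITLE": name,
            "EXPERIMENTTYPE": "CV",
            "SCANRATE": f"{p.scan_rate * 1000:g}",
            "CYCLES": str(p.n_cycles),
            "VENDOR": "Gamry-like",
        }
    if dialect == "palmsens-csv":
        return {
            "Device": "PalmSens-like",
            "Method": "Cyclic Voltammetry",
            "Title": name,
            "Scan rate": f"{p.scan_rate:g}",
            "Cycles": str(p.n_cycles),
        }
    raise SimulationError(f"unknown dialect {dialect!r}")


def _trace_to_raw(trace: Trace, meta: dict[str, str], dialect: str, name: str) -> RawFileModel:
    rows = [
        [_cell(t), _cell(e), _cell(i)]
        for t, e, i in zip(trace.t, trace.E, trace.I)
    ]
    if dialect == "gamry-dta":
        table = RawTable(
            "CURVE",
            [("T", "s"), ("Vf", "V vs. Ref."), ("Im", "A")],
            rows,
        )
    elif dialect == "palmsens-csv":
        table = RawTable("data", [("t", "s"), ("E", "V"), ("i", "A")], rows)
    else:
        raise SimulationError(f"unknown dialect {dialect!r}")
    return RawFileModel(name, list(meta.items()), [table], dialect)


def _num(x: float) -> str:
    """Shortest exact decimal for a float (round-trips on re-read)."""
    return repr(float(x))


def render_raw(raw: RawFileModel, dialect: str | None = None) -> str:
    """Serialize a RawFileModel in a vendor fixture dialect (exact numbers)."""
    dialect = dialect or raw.dialect_id
    if dialect == "gamry-dta":
        lines = [f"{k}\tLABEL\t{v}" for k, v in raw.header]
        for table in raw.tables:
            lines.append(f"CURVE\tTABLE\t{len(table.rows)}")
            lines.append("\t".join(lab for lab, _u in table.columns))
            lines.append("\t".join(u for _lab, u in table.columns))
            lines.extend("\t".join(_num(c) for c in row) for row in table.rows)
        return "\n".join(lines) + "\n"
    if dialect == "palmsens-csv":
        lines = [f"{k}: {v}" for k, v in raw.header]
        lines.append("")
        for table in raw.tables:
            lines.append(",".join(
                f"{lab} / {u}" if u else lab for lab, u in table.columns
            ))
            lines.extend(",".join(_num(c) for c in row) for row in table.rows)
        return "\n".join(lines) + "\n"
    raise SimulationError(f"unknown dialect {dialect!r}")


def write_fixture(
    trace: Trace,
    meta: dict[str, str],
    dialect: str,
    path: str | Path,
) -> Path:
    """Write a trace as a vendor fixture file that the matching reader
    parses back to the same numeric content (6 significant digits)."""
    path = Path(path)
    raw = _trace_to_raw(trace, meta, dialect, path.name)
    path.write_text(render_raw(raw, dialect), encoding="utf-8", newline="\n")
    return path


def preset_to_json(p: SimParams) -> str:
    return json.dumps(asdict(p), indent=2) + "\n"


def with_overrides(p: SimParams, **kwargs) -> SimParams:
    return replace(p, **kwargs)
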