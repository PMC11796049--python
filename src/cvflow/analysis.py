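"""Peak picking and standardized CV descriptors.

For a redox couple the reported quantities are the anodic/cathodic peak
potentials and currents (E_pa, E_pc, i_pa, i_pc), the half-wave potential
E1/2 = (E_pa + E_pc)/2, the peak separation dEp = |E_pa - E_pc| (reported
in mV; ~59/n mV marks an electrochemically reversible n-electron couple
at 25 C), and the peak-current ratio ipa/ipc (~1 for a chemically
reversible couple).

The ratio is offered in two modes.  ``direct`` divides the zero-line peak
currents — transparent, but the reverse peak rides on the decaying
forward current.  ``nicholson`` applies the classical empirical
correction from the switching-potential current i_lambda0 (also written
i_sp0; measured graphically from the zero-current line by the user):

    ratio = |i_rev,0| / |i_fwd,0| + 0.485 * |i_lambda0| / |i_fwd,0| + 0.086

Peak picking smooths the current with a moving average, locates extrema
with a prominence threshold expressed as a fraction of the sweep's
current range (suppressing capacitive ripple), and reports coordinates
from the unsmoothed data at the located index.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .convert import Cycle, Sweep
from .errors import AnalysisError
from .jcamp import JcampBlock
from .metadata import MetadataRecord

__all__ = [
    "Peak",
    "DescriptorSet",
    "pick_peaks",
    "compute_descriptors",
    "export_curve_csv",
    "inline_notation",
    "render_plot",
    "peaks_from_block",
    "NICHOLSON_SLOPE",
    "NICHOLSON_OFFSET",
]

NICHOLSON_SLOPE = 0.485
NICHOLSON_OFFSET = 0.086


@dataclass
class Peak:
    """A picked extremum: anodic maxima on anodic sweeps, cathodic minima
    on cathodic sweeps."""

    E_p: float
    i_p: float
    kind: str            # "anodic-max" | "cathodic-min"
    origin: str = "auto"  # "auto" | "manual"
    index: int | None = None  # sample index within the sweep


@dataclass
class DescriptorSet:
    """Derived quantities for one anodic/cathodic peak pair."""

    E_pa: float
    E_pc: float
    i_pa: float
    i_pc: float
    i_lambda0: float
    E_half: float      # volts
    delta_Ep: float    # millivolts
    ratio: float
    ratio_mode: str    # "direct" | "nicholson"


def pick_peaks(
    sweep: Sweep,
    smooth_window: int = 5,
    min_prominence: float = 0.05,
    origin: str = "auto",
) -> list[Peak]:
    """Locate peaks on one sweep.

    The current is smoothed with a centered moving average of
    ``smooth_window`` samples (must be odd); extrema with prominence of at
    least ``min_prominence`` times the sweep's current range are kept.
    Peak coordinates come from the unsmoothed data at the located index.
    A flat sweep yields no peaks.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise AnalysisError("smooth_window must be a positive odd count")
    if len(sweep) < smooth_window:
        raise AnalysisError(
            f"sweep has {len(sweep)} points, fewer than smooth_window={smooth_window}"
        )
    I = sweep.I
    E = sweep.E
    rng = float(I.max() - I.min())
    if rng == 0.0:
        return []
    smoothed = uniform_filter1d(I, size=smooth_window, mode="nearest")
    prominence = min_prominence * rng
    kind = "anodic-max" if sweep.direction == "anodic" else "cathodic-min"
    signal = smoothed if kind == "anodic-max" else -smoothed
    idx, _props = find_peaks(signal, prominence=prominence)
    return [
        Peak(E_p=float(E[i]), i_p=float(I[i]), kind=kind, origin=origin, index=int(i))
        for i in idx
    ]


def compute_descriptors(
    anodic: Peak,
    cathodic: Peak,
    i_lambda0: float = 0.0,
    mode: str = "direct",
    forward: str = "anodic",
) -> DescriptorSet:
    """Combine one anodic and one cathodic peak into descriptors.

    ``forward`` names the chronologically first (forward) sweep of the
    couple; it matters only for the Nicholson-corrected ratio, where the
    reverse peak is corrected with the switching-potential current.
    """
    if anodic is None or cathodic is None:
        raise AnalysisError("both an anodic and a cathodic peak are required")
    if anodic.kind != "anodic-max" or cathodic.kind != "cathodic-min":
        raise AnalysisError(
            f"peak kinds mismatch: got {anodic.kind!r} / {cathodic.kind!r}"
        )
    if mode not in ("direct", "nicholson"):
        raise AnalysisError(f"unknown ratio mode {mode!r}")
    if forward not in ("anodic", "cathodic"):
        raise AnalysisError(f"forward must be 'anodic' or 'cathodic', got {forward!r}")

    E_half = (anodic.E_p + cathodic.E_p) / 2.0
    delta_Ep = abs(anodic.E_p - cathodic.E_p) * 1000.0

    if mode == "direct":
        if cathodic.i_p == 0:
            raise AnalysisError("cathodic peak current is zero; ratio undefined")
        ratio = abs(anodic.i_p) / abs(cathodic.i_p)
    else:
        i_fwd, i_rev = (
            (anodic.i_p, cathodic.i_p) if forward == "anodic" else (cathodic.i_p, anodic.i_p)
        )
        if i_fwd == 0:
            raise AnalysisError("forward peak current is zero; ratio undefined")
        r0 = abs(i_rev) / abs(i_fwd)
        s = abs(i_lambda0) / abs(i_fwd)
        ratio = r0 + NICHOLSON_SLOPE * s + NICHOLSON_OFFSET

    return DescriptorSet(
        E_pa=anodic.E_p,
        E_pc=cathodic.E_p,
        i_pa=anodic.i_p,
        i_pc=cathodic.i_p,
        i_lambda0=i_lambda0,
        E_half=E_half,
        delta_Ep=delta_Ep,
        ratio=ratio,
        ratio_mode=mode,
    )


_CSV_HEADER = [
    "entry",
    "peak kind",
    "origin",
    "E_p / V",
    "i_p / A",
    "E1/2 / V",
    "dEp / mV",
    "ipa/ipc",
    "ratio mode",
    "sample",
]


def export_curve_csv(
    desc: DescriptorSet,
    peaks: list[Peak],
    meta: MetadataRecord | None = None,
) -> str:
    """RFC-4180 CSV: one header row, one row per peak, one summary row."""
    sample = "" if meta is None else (meta.get("sample_id") or "")
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\r\n")
    writer.writerow(_CSV_HEADER)
    for p in peaks:
        writer.writerow(
            ["peak", p.kind, p.origin, repr(p.E_p), repr(p.i_p), "", "", "", "", sample]
        )
    writer.writerow([
        "descriptors", "", "", "", "",
        repr(desc.E_half), repr(desc.delta_Ep), repr(desc.ratio), desc.ratio_mode, sample,
    ])
    return buf.getvalue()


def inline_notation(desc: DescriptorSet, meta: MetadataRecord | None = None) -> str:
    """One-line report summary, e.g.

    ``CV (MeCN, TBAPF6, 100 mV s-1): E1/2 = 0.250 V (ΔEp = 60 mV, ipa/ipc = 1.00)``

    Metadata tokens that are missing are elided.
    """
    tokens: list[str] = []
    if meta is not None:
        solvent = meta.get("solvent")
        if solvent:
            tokens.append(str(solvent))
        electrolyte = meta.get("supporting_electrolyte")
        if electrolyte:
            tokens.append(str(electrolyte))
        nu = meta.get("scan_rate")
        if nu:
            tokens.append(f"{nu * 1000:g} mV s-1")
    head = f"CV ({', '.join(tokens)})" if tokens else "CV"
    clauses = [f"ΔEp = {desc.delta_Ep:.0f} mV"]
    if desc.ratio is not None and np.isfinite(desc.ratio):
        clauses.append(f"ipa/ipc = {desc.ratio:.2f}")
    return f"{head}: E1/2 = {desc.E_half:.3f} V ({', '.join(clauses)})"


def render_plot(cycles: list[Cycle], path, selected=None) -> None:
    """Write a PNG voltammogram: potential on x (V), current on y (A).

    ``selected=None`` plots every cycle (the "combined" preview); a
    non-empty set of 1-based cycle ordinals plots only those (the
    "new_combined" selection preview).
    """
    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.figure import Figure

    if not cycles:
        raise AnalysisError("no cycles to plot")
    if selected is None:
        chosen = list(cycles)
    else:
        selected = set(selected)
        if not selected:
            raise AnalysisError("empty cycle selection")
        chosen = [c for c in cycles if c.ordinal in selected]
        if not chosen:
            raise AnalysisError(f"selection {sorted(selected)} matches no cycle")
    fig = Figure(figsize=(6.0, 4.5))
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(111)
    for c in chosen:
        ax.plot(c.E, c.I, linewidth=1.0, label=f"cycle {c.ordinal}")
    ax.set_xlabel("E / V")
    ax.set_ylabel("I / A")
    ax.legend(fontsize=8, loc="best")
    fig.tight_layout()
    fig.savefig(path, format="png", dpi=100)


def peaks_from_block(block: JcampBlock) -> list[Peak]:
    """Rebuild :class:`Peak` objects from a JCAMP peak-table block."""
    origin = block.ldr("$PEAK_ORIGIN", "auto")
    kinds = (block.ldr("$PEAK_KINDS") or "").split(",")
    peaks = []
    for i, (x, y) in enumerate(block.pairs):
        kind = kinds[i] if i < len(kinds) and kinds[i] else (
            "anodic-max" if y >= 0 else "cathodic-min"
        )
        peaks.append(Peak(E_p=x, i_p=y, kind=kind, origin=origin))
    return peaks
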