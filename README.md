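# cvflow

A FAIR-data workflow toolkit for cyclic voltammetry (CV).

Potentiostat vendors (Gamry, PalmSens, Metrohm, ...) each export CV runs
in their own file layouts, usually without a shared metadata standard.
That makes CV data hard to exchange, archive and re-use.  `cvflow`
implements the complete desk-side workflow that turns such vendor
exports into open, standardized, richly annotated datasets:

1. **Ingest** — a folder watcher that transfers an instrument file only
   after its size has been stable for a configurable delay (default
   300 s), so partially written experiments are never shipped.
2. **Convert** — declarative, identifier-triggered *profiles* map one
   device's tagged headers and data tables onto a standardized trace
   (E in V, I in A, t in s).  The trace is segmented into anodic /
   cathodic sweeps and paired into cycles; each measured cycle becomes
   one JCAMP-DX 5.01 file (`##XYPOINTS`, since CV potentials are
   non-monotonic) with the metadata embedded as `##$` user records.
3. **Annotate** — metadata is mapped to a versioned CV scheme (modeled
   on the ACS guidelines for reporting electrochemical data) with
   per-field provenance: `device`, `computed`, `context`, `manual`,
   `analysis`.  Quantities the file does not state — scan rate, vertex
   potentials, cycle count — are computed from the data itself.  Merging
   follows the precedence `manual > analysis > context > device`.
4. **Package** — data + metadata become a BagIt 1.0 bag (`bagit.txt`,
   `data/` payload, sha256 **and** sha512 manifests, `metadata/
   metadata.json`), validated byte-for-byte.
5. **Analyze** — peak picking (moving-average smoothing + prominence
   threshold) and the standard descriptors

   * half-wave potential  E½ = (E_pa + E_pc)/2
   * peak separation      ΔEp = |E_pa − E_pc|  (≈ 59/n mV marks a
     reversible n-electron couple at 25 °C)
   * peak-current ratio   ipa/ipc, either directly from the zero-line
     currents or with the classical switching-current correction
     ratio = |i_rev⁰|/|i_fwd⁰| + 0.485·|i_λ0|/|i_fwd⁰| + 0.086
     where i_λ0 is the user-determined current at the switching
     potential.
6. **Export** — per-curve CSV, a one-line report notation, PNG
   previews, a `2 + x`-sheet XLSX workbook (definitions, merged
   metadata, one analysis sheet per curve) and the downloadable ZIP
   archive with the `*_bagit.jdx` / `*_bagit.peak.jdx` /
   `*_bagit.edit.jdx` file life cycle (a manual edit replaces the
   automatic peak file).

A built-in simulator (1-D semi-infinite diffusion of a reversible
redox couple, explicit finite differences, Nernstian surface condition,
optional capacitive background and seeded noise) generates realistic
vendor-dialect fixtures, so the whole pipeline is testable without an
instrument.

## Worked example

```bash
$ cvflow simulate --preset reversible --dialect gamry-dta -o ferrocene.DTA
wrote ferrocene.DTA (3001 samples, 3 cycles)

$ cvflow convert ferrocene.DTA -o .
{"profile": "gamry-cv", "cycles": 3, "bag": "ferrocene/bag"}

$ cvflow analyze ferrocene
curve 1: E1/2 = 0.249 V, dEp = 61 mV, ipa/ipc = 1.095 (direct)
curve 2: E1/2 = 0.250 V, dEp = 60 mV, ipa/ipc = 1.026 (direct)
curve 3: E1/2 = 0.250 V, dEp = 60 mV, ipa/ipc = 1.013 (direct)

$ cvflow validate ferrocene/bag
warning: metadata/ treated as a tag directory (not covered by payload manifests)
bag is valid

$ cvflow package ferrocene --reproducible
archive: ferrocene/ferrocene.zip
  dataset_description.txt        dataset description and file list
  ferrocene.DTA                  original vendor data file
  ferrocene.bag.zip              BagIt bag from the conversion routine
  ferrocene.xlsx                 metadata and analysis workbook
  ...
```

The simulated couple has formal potential E⁰ = 0.25 V, swept
0 → 0.5 → 0 V at 100 mV/s for three cycles.  The analysis recovers
E½ = 0.250 V (the formal potential), ΔEp = 60 mV (the reversible
one-electron signature) and ipa/ipc ≈ 1.01 on the settled last cycle —
exactly what a textbook reversible couple should give.  The inline
notation for a report reads:

```
CV (MeCN, TBAPF6, 100 mV s-1): E1/2 = 0.250 V (ΔEp = 60 mV, ipa/ipc = 1.01)
```

The same works from Python:

```python
from cvflow import (REVERSIBLE_PRESET, simulate_cv, write_fixture,
                    segment_sweeps, assemble_cycles, pick_peaks,
                    compute_descriptors)

trace = simulate_cv(REVERSIBLE_PRESET)
last = assemble_cycles(segment_sweeps(trace))[-1]
anodic = max(pick_peaks(last.anodic), key=lambda p: abs(p.i_p))
cathodic = max(pick_peaks(last.cathodic), key=lambda p: abs(p.i_p))
print(compute_descriptors(anodic, cathodic))
```

## Layout

```
src/cvflow/
  readers.py     vendor-dialect parsers -> RawFileModel
  convert.py     profiles, Trace/Sweep/Cycle, segmentation, scan-rate
  metadata.py    CV metadata scheme, validation, provenance merge, JSON
  jcamp.py       JCAMP-DX 5.01 writer/reader, peak blocks
  analysis.py    peak picking, descriptors, CSV/notation/plots
  packaging.py   BagIt bags, XLSX workbook, dataset ZIP archive
  watch.py       file-completeness watcher
  simulate.py    finite-difference CV simulator + fixture writers
  pipeline.py    convert -> analyze -> package glue
  cli.py         `cvflow` command
  data/          shipped conversion profiles and simulator presets
```

See `docs/methods.md` for the models, numerical choices and known
limitations.
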