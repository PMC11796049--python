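# Methods

This note documents the models, algorithms, defaults and numerical
choices behind `cvflow`, and what the synthetic tests do and do not
demonstrate about real instrument data.

## Vendor dialects and the raw model

Real potentiostat export layouts vary per vendor and per software
version; the two dialects shipped here are documented stand-ins that
preserve the structural challenges of the real thing:

* **gamry-dta** — tagged text: header lines `KEY<TAB>TYPE<TAB>VALUE`, a
  table introduced by `CURVE<TAB>TABLE<TAB><nrows>` followed by one
  column-label line, one unit line and tab-separated numeric rows.
* **palmsens-csv** — a `key: value` prologue, a blank line, then one
  delimited table with a single header row.  The delimiter is sniffed
  from `{",", ";", "\t"}` and decimal commas are accepted with the
  `";"` delimiter (common on German-locale exports).

Both readers produce the same `RawFileModel`: an ordered header (with
duplicate keys retained; lookups return the first occurrence, matching
instruments that repeat tags) and named numeric tables.  Non-parseable
cells raise errors with the line number — silent NaNs would defeat the
fixity goals of the rest of the pipeline.  Encoding is UTF-8 (BOM
tolerated) with a Latin-1 fallback.  Adapting a real vendor layout
means writing one reader plus one profile; nothing downstream changes.

## Conversion profiles

A profile is matched by identifier rules (regexes over the file name,
`KEY=VALUE` header lines or table names).  All *required* rules must
match; ties between matching profiles go to the one with the most
satisfied rules, then to the lexicographically smallest profile id, so
matching is deterministic.  A file that matches nothing is *parked*
(CLI exit code 2), never half-converted.

Units are normalized at the profile boundary (volts, amperes, V/s);
e.g. the shipped Gamry profile scales the header scan rate from mV/s.
Profiles are JSON documents; the store is a directory of them.

## Sweep segmentation

Sweep boundaries are placed where the sign of ΔE changes **and** the
new sign persists for at least `min_run` samples (default 3; a run of
m equal-sign steps spans m+1 samples).  Zero-ΔE plateaus inherit the
previous direction.  This tolerates single-sample potential jitter
without splitting sweeps, while a true vertex — followed by at least
two steps in the new direction — always starts a new sweep.  Every
sample belongs to exactly one sweep, so concatenating the sweeps
reproduces the trace exactly; cycles are consecutive sweep pairs, with
an unpaired trailing sweep flagged partial.

The scan rate is inferred as the **median** of |ΔE/Δt| over in-sweep
sample pairs (robust to vertex samples and dropped points), reported
to 3 significant figures, and only from a measured time axis — when a
file has no time column, time is synthesized (from Σ|ΔE|/ν if a scan
rate is known, else the sample index) and marked as such, which makes
scan-rate inference refuse rather than report a circular value.

## Metadata scheme and provenance

There is no community metadata standard for CV; the scheme here is a
versioned field list (scheme_version 1.0) covering sample/analyte
identity, cell composition, the potential program, conditions and
instrument identity, plus the Chemical Methods Ontology term
"cyclic voltammetry (CV)".  Two validation levels are distinguished:
*minimal* (scan rate + potential window — enough to interpret the
curve) and *publication* (additionally electrodes, electrolyte,
solvent, internal reference couple).  Which fields a community policy
would mark mandatory is genuinely open; this stratification is the
package's own and is versioned so a community scheme can replace it.

Every field carries exactly one provenance tag.  Merging the four
record parts uses the precedence `manual > analysis > context >
device`: a human correcting a record must win, and every superseded
disagreement is logged.  JSON serialization is lossless (stable scheme
order; unknown keys survive in an `extensions` section).

## JCAMP-DX choices

One file per measured cycle, JCAMP-DX 5.01.  Because CV abscissae are
non-monotonic, data are written as explicit `##XYPOINTS=(XY..XY)`
pairs in acquisition order — never equal-increment `##XYDATA`, and no
NMR/IR compression schemes (DIFDUP/SQZ).  Formatting is canonical
(6 significant digits, `.` decimal, LF endings), which makes
parse → serialize byte-stable and lets golden-file tests assert exact
bytes.  A uniform time axis is preserved via `##$TFIRST`/`##$DELTAT`.

Peak tables are separate blocks appended after the data block, tagged
with their origin (`auto`/`manual`).  A manual edit replaces the peak
block, and the file suffix moves from `.peak.jdx` to `.edit.jdx`; the
original data block is carried over byte-identically, so the measured
data are immutable across any sequence of annotations.

## Peak picking and descriptors

The current is smoothed with a centered moving average (default
5 samples); extrema are located with SciPy's prominence-based peak
finder, thresholded at 5 % of the sweep's current range — enough to
suppress capacitive ripple without hiding quasi-reversible peaks.
Peak coordinates are reported from the *unsmoothed* data at the
located index.  Both knobs are exposed on the CLI.

Descriptors: E½ = (E_pa+E_pc)/2; ΔEp in mV; ipa/ipc either `direct`
(zero-line currents — transparent, the default) or `nicholson`
(empirical reverse-peak correction from the switching-potential
current, constants 0.485 and 0.086).  Whether a given evaluation
pipeline uses baseline-corrected or zero-line currents is not
standardized, so both modes are exposed rather than guessing one.
i_λ0 is a user input — it is conventionally read graphically from the
voltammogram, and no automatic baseline fit is attempted.

## BagIt and the archive

Bags follow BagIt 1.0: `bagit.txt`, `data/` payload (one JCAMP-DX per
cycle) and both sha256 and sha512 manifests.  The experiment metadata
JSON lives in a `metadata/` directory beside `data/`, treated by the
validator as a tag directory: it is not covered by the payload
manifests, and the validator says so in a warning so the choice is
visible.  Validation recomputes every digest and also flags payload
files missing from a manifest.

The downloadable ZIP contains the dataset-level files (description
with a file inventory, original vendor file, nested bag zip, the
`2 + x`-sheet XLSX, combined and new_combined preview PNGs) and, per
curve, the converted `.jdx`, the `.peak.jdx` (only if auto-picked and
not edited) or `.edit.jdx` (if edited — it replaces the peak file),
plus a per-curve PNG and CSV.  Per-curve names default to the
underscore dialect (`name-curve1_bagit.peak.jdx`); a `dot` switch
emits `name-curve1.bagit.peak.jdx` for environments using that
convention.  Under `--reproducible`, all ZIP member timestamps
(including those inside the XLSX) are fixed, making archive builds
byte-identical for identical inputs.

## File-completeness watcher

A file is complete when every observation within the trailing delay
window reports the latest size **and** that size has held for at least
the delay (default 300 s).  A single fresh observation is never
complete — stability must be demonstrated.  Completeness uses size
stability only (no OS file locks) for portability.  Queueing is
deduplicated by (path, sha256), so a burst-written file is transferred
exactly once and never earlier than one delay after its last growth.
The clock is injectable, so this contract is tested in milliseconds.
Transfer targets a local inbox directory; remote protocols are out of
scope here.

## The CV simulator

The simulator provides ground truth for every pipeline stage: a
triangular potential program between two vertices at scan rate ν, and
the faradaic response of a **reversible** (Nernstian) one-step couple
with equal diffusivities, from an explicit (FTCS) finite-difference
solution of 1-D semi-infinite diffusion for both species.  Key
numerical choices:

* space step dx = δ/14 with δ = sqrt(D·RT/(F·ν)) (the ν-diffusion
  length), grid extent 6·sqrt(D·t_max);
* per-sample sub-stepping keeps D·Δt/Δx² ≤ 0.45 (explicit-scheme
  stability), and the potential is interpolated at sub-step resolution
  so the applied program is the exact triangle, not a staircase —
  sampling the current immediately after a potential step would
  capture the divergent t→0⁺ step transient instead of the ramp
  response;
* surface gradients (the Nernst flux balance and the measured current)
  use second-order one-sided differences.

Verification: the scheme reproduces the Cottrell transient to four
digits and the Randles–Ševčík peak current to −2 % at production
resolution; halving the sample interval changes peak currents by
≈ 0.13 %.

The **reversible preset** is a 1 mM couple (D = 1e-5 cm²/s) on a 3 mm
disc (A = 0.0707 cm²), E⁰ = 0.25 V centered in a symmetric
0 → 0.5 → 0 V window, ν = 0.1 V/s, three cycles, 298.15 K, 1 mV per
sample.  The bulk holds the couple **equimolar** (oxidized_fraction
0.5) and the solution is equilibrated at the start potential for 5 s
before the sweep — the way an internal-reference couple such as
Fc/Fc⁺ is ideally measured.  This matters for the zero-line ipa/ipc:
only the symmetric cyclic steady state has a ratio near 1; starting
from a pure single form, the third-cycle zero-line ratio is still
≈ 1.15 because the diffusion layer relaxes as t^(−1/2).  Descriptors
are therefore evaluated on the last full cycle, where the preset gives
ΔEp ≈ 60 mV, E½ = E⁰ to < 1 mV, and ipa/ipc ≈ 1.01.

A capacitive background ±ν·C_dl (sign flipping at the vertices) and
seeded Gaussian current noise can be added; the potential program
itself stays exact, matching the dominant noise source of staircase
instruments.  Identical parameters (including the seed) produce
byte-identical fixture files.

What the simulator does **not** emulate: electrode kinetics
(Butler–Volmer / quasi-reversible couples), coupled chemistry (EC
mechanisms), uncompensated resistance (IR drop), convection, and
vendor-specific quirks such as current autoranging artifacts.  Tests
passing on simulator output therefore demonstrate the correctness of
the data handling, segmentation, formats, fixity and descriptor
arithmetic — not that peak picking is robust to every pathology of
real electrochemical data.

## Problem sizes

The default test and acceptance runs use the 3-cycle reversible preset
(3001 samples, ≈ 900 space nodes, 17 sub-steps per sample — about half
a second to simulate), randomized checksum payloads of ≤ 2 kB, and
workbooks up to 20 curves.  These sizes were chosen as the smallest
that exercise every contract: more cycles or finer grids change the
descriptors by less than the stated tolerances.
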