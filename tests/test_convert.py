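"""Conversion core: segmentation, cycles, scan-rate inference, profiles,
trace extraction and metadata mapping."""

import numpy as np
import pytest

from cvflow.convert import (
    ConversionProfile,
    DataMap,
    IdentifierRule,
    MetadataMapEntry,
    ProfileStore,
    Trace,
    assemble_cycles,
    extract_trace,
    infer_scan_rate,
    map_metadata,
    match_profile,
    segment_sweeps,
)
from cvflow.errors import (
    ConversionError,
    NoProfileError,
    NoSweepError,
    ProfileError,
    ScanRateUnavailableError,
)
from cvflow.readers import RawFileModel, RawTable

from conftest import make_triangle


class TestSegmentSweeps:
    def test_hand_traced_double_triangle(self):
        E = [0, 0.1, 0.2, 0.1, 0, 0.1, 0.2, 0.1, 0]
        trace = Trace(np.arange(9.0), E, np.zeros(9))
        sweeps = segment_sweeps(trace)
        assert [s.direction for s in sweeps] == ["anodic", "cathodic", "anodic", "cathodic"]
        assert [(s.start, s.stop) for s in sweeps] == [(0, 3), (3, 5), (5, 7), (7, 9)]

    @pytest.mark.parametrize("n_cycles", [1, 3, 5])
    def test_ideal_triangle_gives_two_sweeps_per_cycle(self, n_cycles):
        sweeps = segment_sweeps(make_triangle(n_cycles))
        assert len(sweeps) == 2 * n_cycles

    def test_conservation_concatenation_reproduces_trace(self, reversible_trace):
        sweeps = segment_sweeps(reversible_trace)
        E = np.concatenate([s.E for s in sweeps])
        I = np.concatenate([s.I for s in sweeps])
        assert np.array_equal(E, reversible_trace.E)
        assert np.array_equal(I, reversible_trace.I)

    def test_noise_on_potential_does_not_change_sweep_count(self):
        clean = make_triangle(3, dt=0.01)  # 1 mV steps
        rng = np.random.default_rng(42)
        noisy = Trace(clean.t, clean.E + rng.normal(0, 1e-4, len(clean)), clean.I)
        assert len(segment_sweeps(noisy, min_run=3)) == len(segment_sweeps(clean))

    def test_plateau_inherits_previous_direction(self):
        E = [0, 0.1, 0.1, 0.2, 0.3, 0.2, 0.1, 0.0]
        sweeps = segment_sweeps(Trace(np.arange(8.0), E, np.zeros(8)))
        assert [s.direction for s in sweeps] == ["anodic", "cathodic"]
        assert sweeps[0].stop == 5

    def test_constant_potential_raises(self):
        with pytest.raises(NoSweepError):
            segment_sweeps(Trace(np.arange(5.0), np.ones(5), np.zeros(5)))

    def test_segmentation_is_idempotent_on_reassembled_trace(self, reversible_trace):
        sweeps = segment_sweeps(reversible_trace)
        rebuilt = Trace(
            reversible_trace.t,
            np.concatenate([s.E for s in sweeps]),
            np.concatenate([s.I for s in sweeps]),
        )
        again = segment_sweeps(rebuilt)
        assert [(s.start, s.stop, s.direction) for s in again] == [
            (s.start, s.stop, s.direction) for s in sweeps
        ]


class TestAssembleCycles:
    def test_pairing_counts(self):
        sweeps = segment_sweeps(make_triangle(3))
        cycles = assemble_cycles(sweeps)
        assert len(cycles) == 3
        assert all(not c.partial for c in cycles)
        assert [c.ordinal for c in cycles] == [1, 2, 3]

    def test_trailing_sweep_marks_partial_cycle(self):
        sweeps = segment_sweeps(make_triangle(3))
        cycles = assemble_cycles(sweeps[:5])
        assert len(cycles) == 3
        assert cycles[-1].partial and len(cycles[-1].sweeps) == 1

    def test_empty_input_gives_empty_output(self):
        assert assemble_cycles([]) == []

    def test_each_cycle_has_anodic_and_cathodic_sweep(self, reversible_cycles):
        for c in reversible_cycles:
            assert c.anodic is not None and c.cathodic is not None


class TestInferScanRate:
    def test_ideal_triangle_exact(self):
        # 0 -> 0.5 -> 0 V at 0.1 V/s, 10 Hz sampling
        assert infer_scan_rate(make_triangle(1, scan_rate=0.1, dt=0.1)) == 0.1

    def test_noisy_potential_within_one_percent(self):
        clean = make_triangle(2, scan_rate=0.1, dt=0.1)
        rng = np.random.default_rng(7)
        noisy = Trace(clean.t, clean.E + rng.normal(0, 1e-6, len(clean)), clean.I)
        assert abs(infer_scan_rate(noisy) - 0.1) <= 0.001

    def test_simulator_parameter_recovery(self):
        from cvflow.simulate import REVERSIBLE_PRESET, simulate_cv
        from dataclasses import replace

        trace = simulate_cv(replace(REVERSIBLE_PRESET, scan_rate=0.05, n_cycles=1))
        assert infer_scan_rate(trace) == 0.05

    def test_synthetic_time_axis_is_rejected(self):
        tri = make_triangle(1)
        trace = Trace(np.arange(len(tri), dtype=float), tri.E, tri.I,
                      t_source="synthesized-index")
        with pytest.raises(ScanRateUnavailableError):
            infer_scan_rate(trace)


def _profile(pid, rules, metadata_map=(), table=0, x="Vf", y="Im", t="T"):
    return ConversionProfile(
        profile_id=pid,
        identifiers=rules,
        data_map=DataMap(table=table, x_column=x, y_column=y, t_column=t),
        metadata_map=list(metadata_map),
    )


@pytest.fixture
def gamry_raw():
    rows = [[i * 0.1, 0.01 * min(i, 6 - i), 1e-7 * i] for i in range(7)]
    return RawFileModel(
        source_name="exp.DTA",
        header=[("EXPERIMENTTYPE", "CV"), ("SCANRATE", "100"), ("TITLE", "sample-1")],
        tables=[RawTable("CURVE", [("T", "s"), ("Vf", "V"), ("Im", "A")], rows)],
        dialect_id="gamry-dta",
    )


class TestMatchProfile:
    def test_single_match(self, gamry_raw):
        store = ProfileStore([
            _profile("gamry-cv", [IdentifierRule("filename", r"\.DTA$")]),
        ])
        assert match_profile(gamry_raw, store).profile_id == "gamry-cv"

    def test_header_identifier(self, gamry_raw):
        store = ProfileStore([
            _profile("cv", [IdentifierRule("header", r"^EXPERIMENTTYPE=CV$")]),
        ])
        assert match_profile(gamry_raw, store).profile_id == "cv"

    def test_no_match_parks_the_file(self, gamry_raw):
        store = ProfileStore([
            _profile("other", [IdentifierRule("filename", r"\.csv$")]),
        ])
        with pytest.raises(NoProfileError, match="parked"):
            match_profile(gamry_raw, store)

    def test_more_specific_profile_wins(self, gamry_raw):
        generic = _profile("z-generic", [IdentifierRule("filename", r"\.DTA$")])
        specific = _profile("a-specific", [
            IdentifierRule("filename", r"\.DTA$"),
            IdentifierRule("header", r"^EXPERIMENTTYPE=CV$", required=False),
        ])
        store = ProfileStore([generic, specific])
        assert match_profile(gamry_raw, store).profile_id == "a-specific"

    def test_equal_specificity_resolves_lexicographically(self, gamry_raw):
        a = _profile("alpha", [IdentifierRule("filename", r"\.DTA$")])
        b = _profile("beta", [IdentifierRule("filename", r"DTA$")])
        assert match_profile(gamry_raw, ProfileStore([a, b])).profile_id == "alpha"

    def test_duplicate_profile_ids_rejected_at_store(self):
        p = _profile("x", [IdentifierRule("filename", ".")])
        with pytest.raises(ProfileError, match="duplicate"):
            ProfileStore([p, p])

    def test_profile_needs_a_required_identifier(self):
        with pytest.raises(ProfileError, match="required"):
            _profile("x", [IdentifierRule("filename", ".", required=False)]).validate()


class TestExtractTrace:
    def test_three_column_mapping(self, gamry_raw):
        profile = _profile("g", [IdentifierRule("filename", ".")])
        trace = extract_trace(gamry_raw, profile)
        assert len(trace) == 7
        assert trace.t_source == "measured"
        assert trace.E[1] == pytest.approx(0.01)

    def test_missing_column_names_column_and_table(self, gamry_raw):
        profile = _profile("g", [IdentifierRule("filename", ".")], y="Missing")
        with pytest.raises(ConversionError, match="column Missing not found in table CURVE"):
            extract_trace(gamry_raw, profile)

    def test_table_selector_by_name_regex(self, gamry_raw):
        gamry_raw.tables.append(
            RawTable("CURVE2", [("T", "s"), ("Vf", "V"), ("Im", "A")],
                     [[0, 0, 0], [1, 0.1, 1e-6], [2, 0.2, 2e-6], [3, 0.1, 1e-6]])
        )
        profile = _profile("g", [IdentifierRule("filename", ".")], table="CURVE2")
        trace = extract_trace(gamry_raw, profile)
        assert list(trace.I) == [0.0, 1e-6, 2e-6, 1e-6]

    def test_time_synthesis_from_scan_rate(self, gamry_raw):
        profile = _profile("g", [IdentifierRule("filename", ".")], t=None)
        trace = extract_trace(gamry_raw, profile, scan_rate=0.1)
        assert trace.t_source == "synthesized-scan-rate"
        assert trace.t[0] == 0.0
        assert np.all(np.diff(trace.t) >= 0)


class TestMapMetadata:
    def test_header_source_with_scale_transform(self, gamry_raw):
        profile = _profile(
            "g", [IdentifierRule("filename", ".")],
            metadata_map=[MetadataMapEntry("SCANRATE", "scan_rate",
                                           {"type": "scale", "factor": 0.001})],
        )
        trace = extract_trace(gamry_raw, profile)
        rec = map_metadata(gamry_raw, profile, trace)
        assert rec.get("scan_rate") == pytest.approx(0.1)
        assert rec.provenance("scan_rate") == "device"

    def test_missing_header_falls_back_to_computed(self):
        tri = make_triangle(2, scan_rate=0.1, dt=0.1)
        raw = RawFileModel("x.DTA", [], [RawTable("CURVE", [("Vf", "V")], [[0.0]])], "gamry-dta")
        profile = _profile("g", [IdentifierRule("filename", ".")],
                           metadata_map=[MetadataMapEntry("NOPE", "scan_rate")])
        rec = map_metadata(raw, profile, tri)
        assert rec.get("scan_rate") == 0.1
        assert rec.provenance("scan_rate") == "computed"

    def test_empty_map_yields_computed_fields_only(self):
        tri = make_triangle(2, scan_rate=0.1, dt=0.1)
        raw = RawFileModel("x.DTA", [("K", "v")], [], "gamry-dta")
        rec = map_metadata(raw, _profile("g", [IdentifierRule("filename", ".")]), tri)
        device_fields = [fid for fid, fv in rec.set_fields().items()
                         if fv.provenance == "device"]
        assert device_fields == []
        assert rec.get("n_cycles") == 2
        assert rec.get("potential_vertex1") == pytest.approx(0.5)
        assert rec.get("potential_vertex2") == pytest.approx(0.0)
        assert rec.get("method_term_label") == "cyclic voltammetry (CV)"
        assert rec.get("method_term_source") == "CHMO"

    def test_generator_parameters_recovered_exactly(self, reversible_trace):
        raw = RawFileModel("r.DTA", [], [], "gamry-dta")
        rec = map_metadata(raw, _profile("g", [IdentifierRule("filename", ".")]),
                           reversible_trace)
        assert rec.get("scan_rate") == 0.1
        assert rec.get("n_cycles") == 3
        assert rec.get("potential_vertex1") == pytest.approx(0.5)
        assert rec.get("potential_vertex2") == pytest.approx(0.0)


def test_profile_json_round_trip():
    profile = _profile(
        "gamry-cv",
        [IdentifierRule("filename", r"\.DTA$"), IdentifierRule("header", "CV", False)],
        metadata_map=[MetadataMapEntry("SCANRATE", "scan_rate",
                                       {"type": "scale", "factor": 0.001})],
    )
    back = ConversionProfile.from_json(profile.to_json())
    assert back == profile


def test_default_store_ships_gamry_and_palmsens():
    store = ProfileStore.default()
    ids = sorted(p.profile_id for p in store)
    assert ids == ["gamry-cv", "palmsens-cv"]
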