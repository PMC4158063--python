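"""Phasing stage: register arithmetic, naming, triggers, TAS flags."""

import numpy as np
import pytest

from srdk.catalog import collapse_and_filter, tpm_normalize
from srdk.config import PipelineConfig
from srdk.degradome import TargetCall
from srdk.io import CollapsedRead, FastaRecord
from srdk.phasing import (
    enumerate_phases,
    flag_candidate_tas,
    make_name,
    parse_name,
    quantify_phases,
    select_triggers,
)

TRIGGER = "T" + "ACGTACGTACGTACGTACGTA"  # 22 nt, 5' U


def _call(mirna_id, transcript_id="T1", site=100):
    return TargetCall(
        mirna_id=mirna_id, transcript_id=transcript_id, alignment="|" * 21,
        penalty=0.0, cleavage_site=site, cleavage_count=10, category="I",
        library="leaf",
    )


class TestEnumeratePhases:
    def test_windows_tile_in_exact_21_nt_steps(self):
        windows = enumerate_phases("A" * 200, 100)
        assert [w[0] for w in windows] == [100, 121, 142, 163]
        assert all(b - a == 21 for a, b in windows)
        starts = [w[0] for w in windows]
        assert all(b - a == 21 for a, b in zip(starts, starts[1:]))

    def test_ninth_register_starts_168_nt_past_cleavage(self):
        windows = enumerate_phases("A" * 400, 50)
        assert windows[8][0] == 50 + 168

    def test_cleavage_at_last_position_gives_no_windows(self):
        assert enumerate_phases("A" * 100, 99) == []

    def test_cleavage_outside_transcript_rejected(self):
        with pytest.raises(ValueError):
            enumerate_phases("A" * 100, 100)


class TestNaming:
    def test_round_trip_with_hyphenated_trigger(self):
        name = make_name("csi-miR3954a", "Cs1g09635.1", 9)
        assert name == "csi-miR3954a-Cs1g09635.1-9"
        assert parse_name(name, ["csi-miR3954a", "csi-miR482a-3p"]) == (
            "csi-miR3954a", "Cs1g09635.1", 9,
        )

    def test_round_trip_simple(self):
        assert parse_name(make_name("mirX", "T07", 3)) == ("mirX", "T07", 3)

    def test_invalid_name_rejected(self):
        with pytest.raises(ValueError):
            parse_name("not-a-phase-name-x")


class TestSelectTriggers:
    def test_all_criteria_met(self, config):
        triggers = select_triggers({"t22": TRIGGER}, [_call("t22")], config)
        assert triggers == {"t22": TRIGGER}

    def test_wrong_length_excluded(self, config):
        triggers = select_triggers({"t21": TRIGGER[:21]}, [_call("t21")], config)
        assert triggers == {}

    def test_no_validated_target_excluded(self, config):
        assert select_triggers({"t22": TRIGGER}, [], config) == {}

    def test_five_prime_u_requirement_is_switchable(self):
        no_u = "A" + TRIGGER[1:]
        strict = PipelineConfig(require_trigger_5pU=True)
        relaxed = PipelineConfig(require_trigger_5pU=False)
        assert select_triggers({"x": no_u}, [_call("x")], strict) == {}
        assert select_triggers({"x": no_u}, [_call("x")], relaxed) == {"x": no_u}


class TestQuantifyAndTas:
    def _setup(self, config, populated=(1, 2, 3)):
        rng = np.random.default_rng(6)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
        transcript = FastaRecord("T1", "", seq)
        c = 60
        reads = [
            CollapsedRead(seq[c + 21 * (k - 1):c + 21 * k], 30) for k in populated
        ]
        catalog, stats = collapse_and_filter({"leaf": reads}, config)
        tpm_normalize(catalog, stats)
        return transcript, c, catalog

    def test_supported_registers_only_in_main_report(self, config):
        transcript, c, catalog = self._setup(config)
        phases = quantify_phases("trig", transcript, c, catalog, config)
        supported = [p for p in phases if p.supported]
        assert [p.k for p in supported] == [1, 2, 3]
        assert all(p.per_library_tpm["leaf"] > 0 for p in supported)
        assert len(phases) > len(supported)  # unsupported kept as diagnostics

    def test_register_sequences_match_windows(self, config):
        transcript, c, catalog = self._setup(config)
        for p in quantify_phases("trig", transcript, c, catalog, config):
            a, b = p.window
            assert transcript.sequence[a:b] == p.sequence
            assert parse_name(p.name, ["trig"]) == ("trig", "T1", p.k)

    def test_tas_requires_noncoding_and_min_registers(self, config):
        transcript, c, catalog = self._setup(config, populated=(1, 2, 3, 4))
        phases = quantify_phases("trig", transcript, c, catalog, config)
        flagged = flag_candidate_tas(
            {"trig": TRIGGER}, phases, {"T1": "non_coding"}, min_registers=3
        )
        assert bool(flagged.iloc[0]["candidate_tas"])
        coding = flag_candidate_tas({"trig": TRIGGER}, phases, {"T1": "coding"}, 3)
        assert not bool(coding.iloc[0]["candidate_tas"])

    def test_single_register_not_flagged(self, config):
        transcript, c, catalog = self._setup(config, populated=(1,))
        phases = quantify_phases("trig", transcript, c, catalog, config)
        flagged = flag_candidate_tas({"trig": TRIGGER}, phases, {"T1": "non_coding"}, 3)
        assert not bool(flagged.iloc[0]["candidate_tas"])
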