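"""Patient-data loading, validation, analysis sets and endpoint derivation."""

import io

import pytest

from neobasket.patients import (
    PatientValidationError,
    assign_analysis_sets,
    derive_endpoints,
    efs_input,
    fixture_path,
    load_patients,
    stage1_counts,
    tts_values,
    write_patients,
)


def test_fixture_loads_with_expected_cohort_sizes(records):
    assert len(records) == 22
    assert sum(r.cohort == "colon" for r in records) == 14
    assert sum(r.cohort == "rectum" for r in records) == 8


def test_analysis_set_sizes(records, sets):
    assert len(sets.members("colon", "fas")) == 14
    assert len(sets.members("colon", "pps")) == 12
    assert len(sets.members("rectum", "fas")) == 8
    assert len(sets.members("rectum", "pps")) == 6
    assert len(sets.members("colon", "ss")) + len(sets.members("rectum", "ss")) == 22
    for cohort in ("colon", "rectum"):
        assert sets.members(cohort, "pps") <= sets.members(cohort, "fas")


@pytest.mark.parametrize(
    "cohort,aset,pcr_x,pcr_n",
    [
        ("colon", "fas", 8, 14),
        ("colon", "pps", 8, 12),
        ("rectum", "fas", 6, 8),
        ("rectum", "pps", 6, 6),
    ],
)
def test_pcr_counts(records, sets, cohort, aset, pcr_x, pcr_n):
    ep = derive_endpoints(records, sets, cohort, aset)
    assert (ep.pcr_x, ep.pcr_n) == (pcr_x, pcr_n)


def test_colon_trg_distribution(records, sets):
    ep = derive_endpoints(records, sets, "colon", "fas")
    assert dict(ep.trg_counts) == {0: 8, 1: 2, 2: 1, 3: 1}
    assert sum(ep.trg_counts.values()) == ep.surgery_x == 12


def test_pooled_kras_mutation_rate(records, sets):
    ep = derive_endpoints(records, sets, "pooled", "fas")
    assert (ep.kras_mutant_x, ep.kras_known_n) == (13, 16)


def test_pps_pcr_numerator_equals_fas_numerator(records, sets):
    """Non-operated patients can never be pathological complete responders."""
    for cohort in ("colon", "rectum"):
        fas = derive_endpoints(records, sets, cohort, "fas")
        pps = derive_endpoints(records, sets, cohort, "pps")
        assert fas.pcr_x == pps.pcr_x
        assert sum(pps.trg_counts.values()) == len(sets.members(cohort, "pps"))


def test_stage1_counts(records, sets):
    counts = stage1_counts(records, sets)
    assert (counts["colon"].x, counts["colon"].n) == (8, 14)
    assert (counts["rectum"].x, counts["rectum"].n) == (6, 8)


def test_empty_file_with_valid_header(tmp_path):
    header = fixture_path().read_text().splitlines()
    header = next(line for line in header if not line.startswith("#"))
    path = tmp_path / "empty.csv"
    path.write_text(header + "\n")
    assert load_patients(path) == []


def test_unknown_cohort_and_set_rejected(records, sets):
    with pytest.raises(ValueError):
        derive_endpoints(records, sets, "duodenum", "fas")
    with pytest.raises(ValueError):
        sets.members("colon", "itt")


def test_validation_collects_row_and_field(tmp_path, records):
    # corrupt one record: TRG present without surgery
    bad = records[0]
    import dataclasses

    broken = dataclasses.replace(bad, surgery=False, tts_months=None, yp_t=None,
                                 yp_n=None, dfs_months=None, trg=2)
    path = tmp_path / "bad.csv"
    write_patients([broken], path)
    with pytest.raises(PatientValidationError) as err:
        load_patients(path)
    issues = err.value.issues
    assert any(i.patient_id == bad.id and i.field == "trg" for i in issues)
    assert all(i.row is not None for i in issues)


def test_missing_column_reported(tmp_path):
    path = tmp_path / "short.csv"
    path.write_text("id,cohort\nX1,colon\n")
    with pytest.raises(PatientValidationError) as err:
        load_patients(path)
    assert any(i.message == "missing column" for i in err.value.issues)


def test_round_trip(tmp_path, records):
    path = tmp_path / "copy.csv"
    write_patients(records, path)
    assert load_patients(path) == records


def test_single_nonoperated_patient_sets(records):
    solo = [r for r in records if not r.surgery][:1]
    sets = assign_analysis_sets(solo)
    assert sets.members(solo[0].cohort, "fas") == {solo[0].id}
    assert sets.members(solo[0].cohort, "pps") == frozenset()


def test_rectum_tts_values(records):
    assert sorted(tts_values(records, "rectum")) == [4.0, 4.4, 5.5, 6.4, 7.3, 9.7]


def test_efs_censor_floor_only_lifts_event_free_patients(records):
    raw = efs_input(records, "rectum", "fas")
    floored = efs_input(records, "rectum", "fas", censor_floor=12.0)
    assert sum(raw.events) == sum(floored.events) == 1
    for t_raw, t_fl, event in zip(raw.times, floored.times, raw.events):
        if event:
            assert t_fl == t_raw  # the progression time is data, never adjusted
        else:
            assert t_fl == max(t_raw, 12.0)
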