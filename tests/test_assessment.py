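"""Row assembly, overrides, qualitative import, and report round-trips."""

import pytest

from conftest import assess_bundle
from fairmi import (
    ConfigurationError,
    ConsistencyError,
    IndicatorId,
    RetrievalMode,
    build_matrix,
    builtin_profiles,
    convert_label,
    generate_evidence,
    import_qualitative,
    read_report,
    write_report,
)

CODES_15 = [i.code for i in IndicatorId]


# ---------------------------------------------------------------------------
# assess_use_case
# ---------------------------------------------------------------------------

def test_chembl_row_matches_the_published_findings(bundles):
    row = assess_bundle(bundles["TiO2_ChEMBL"])
    assert row["F1"].value == 1.0   # only ChEMBL has the DOI badge
    assert row["I3"].value == 1.0
    assert row["R1.2"].value == 0.5  # authors+title, no email
    assert row["A2"].value == 0.0


def test_arrayexpress_row_matches_the_published_findings(bundles):
    row = assess_bundle(bundles["Parkinsons_AE"])
    assert row["A2"].value == 1.0   # the only repository with a policy
    assert row["R1.2"].value == 1.0
    assert row["F1"].value == 0.0
    assert row["I3"].value == 0.0


def test_override_replaces_value_and_forces_manual_mode(bundles):
    row = assess_bundle(bundles["Parkinsons_AE"], overrides={"F4": 0})
    assert row["F4"].value == 0.0
    assert row["F4"].mode is RetrievalMode.MANUAL
    assert row["F4"].evidence == "manual override"


def test_mismatched_repository_ids_raise(bundles):
    ae = bundles["Parkinsons_AE"]
    geo = bundles["NBIA_GEO"]
    with pytest.raises(ConsistencyError):
        assess_bundle(type(ae)(query=geo.query, metadata=ae.metadata,
                               registry=ae.registry, retrieval=ae.retrieval,
                               f4_flag=True))


def test_every_row_is_total_over_15_indicators(canonical_matrix):
    for row in canonical_matrix.rows:
        assert len(row.scores) == 15
        assert [s.indicator.code for s in row.in_order()] == CODES_15


# ---------------------------------------------------------------------------
# build_matrix
# ---------------------------------------------------------------------------

def test_matrix_preserves_order_and_size(canonical_matrix):
    assert len(canonical_matrix) == 6
    assert canonical_matrix.use_cases == (
        "Parkinsons_AE", "NBIA_GEO", "TiO2_eNanoMapper", "TiO2_caNanoLab",
        "TiO2_ChEMBL", "TiO2_NanoCommons")
    assert canonical_matrix.to_dataframe().shape == (6, 15)


def test_single_row_matrix(bundles):
    matrix = build_matrix([assess_bundle(bundles["NBIA_GEO"])])
    assert len(matrix) == 1


def test_duplicate_labels_rejected(bundles):
    row = assess_bundle(bundles["NBIA_GEO"])
    with pytest.raises(ConfigurationError, match="duplicate"):
        build_matrix([row, row])


def test_empty_matrix_rejected():
    with pytest.raises(ConfigurationError):
        build_matrix([])


# ---------------------------------------------------------------------------
# Qualitative labels
# ---------------------------------------------------------------------------

def test_convert_label_is_a_bijection_onto_the_three_scores():
    mapping = {"complies completely": 1.0, "just about/maybe not": 0.5,
               "fails to comply": 0.0}
    assert {l: convert_label(l) for l in mapping} == mapping
    values = [convert_label(l) for l in mapping]
    assert len(set(values)) == 3


def test_convert_label_unclear_is_missing_not_zero():
    assert convert_label("unclear") is None


def test_convert_label_rejects_unknown_labels():
    with pytest.raises(ConfigurationError, match="meh"):
        convert_label("meh")


def toy_table():
    return (
        "repository,F1,F2,A1,R1.1\n"
        "RepoA,complies completely,just about/maybe not,fails to comply,unclear\n"
        "RepoB,unclear,complies completely,complies completely,fails to comply\n"
    )


def test_import_qualitative_converts_cell_wise():
    matrix = import_qualitative(toy_table())
    a, b = matrix.rows
    assert a.use_case == "RepoA"
    assert [a[c].value for c in ("F1", "F2", "A1", "R1.1")] == \
        [1.0, 0.5, 0.0, None]
    assert [b[c].value for c in ("F1", "F2", "A1", "R1.1")] == \
        [None, 1.0, 1.0, 0.0]
    # everything imported is a manual judgement
    assert all(s.mode is RetrievalMode.MANUAL
               for row in matrix.rows for s in row.in_order())
    # "unclear" and uncovered columns are missing marks, not zeros
    assert a["R1.1"].is_missing
    assert a["I2"].is_missing


def test_import_qualitative_empty_table_is_an_error():
    with pytest.raises(ConfigurationError):
        import_qualitative("")
    with pytest.raises(ConfigurationError, match="no data rows"):
        import_qualitative("repository,F1\n")


def test_import_qualitative_names_the_offending_cell():
    table = "repository,F1\nRepoA,meh\n"
    with pytest.raises(ConfigurationError, match=r"RepoA.*F1|F1.*RepoA"):
        import_qualitative(table)


def test_import_qualitative_rejects_unknown_indicator_column():
    with pytest.raises(ConfigurationError, match="F99"):
        import_qualitative("repository,F99\nRepoA,unclear\n")


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def test_csv_report_shape(canonical_matrix, tmp_path):
    path = write_report(canonical_matrix, str(tmp_path / "m.csv"))
    lines = open(path).read().splitlines()
    assert len(lines) == 1 + 6
    assert all(len(line.split(",")) == 31 for line in lines)


@pytest.mark.parametrize("fmt", ["csv", "json"])
def test_report_round_trip_is_lossless(canonical_matrix, tmp_path, fmt):
    path = write_report(canonical_matrix, str(tmp_path / f"m.{fmt}"))
    again = read_report(path)
    assert again.same_scores(canonical_matrix)
    # not-assessed cells come back as not-assessed, not as zeros or missing
    for row in again.rows:
        assert row["I2"].mode is RetrievalMode.NOT_ASSESSED
        assert row["I2"].value is None


def test_report_round_trip_keeps_the_three_no_value_states(tmp_path):
    matrix = import_qualitative(toy_table())
    for fmt in ("csv", "json"):
        again = read_report(
            write_report(matrix, str(tmp_path / f"q.{fmt}")))
        assert again.same_scores(matrix)
        row = again["RepoA"]
        assert row["A1"].value == 0.0            # scored zero
        assert row["R1.1"].is_missing            # unclear
        assert row["R1.1"].mode is RetrievalMode.MANUAL


def test_json_report_keeps_evidence(canonical_matrix, tmp_path):
    path = write_report(canonical_matrix, str(tmp_path / "m.json"))
    again = read_report(path)
    score = again["TiO2_ChEMBL"]["R1.2"]
    assert "provenance" in score.evidence


def test_unwritable_destination_is_an_io_error(canonical_matrix, tmp_path):
    with pytest.raises(IOError):
        write_report(canonical_matrix,
                     str(tmp_path / "no" / "such" / "dir" / "m.csv"))
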