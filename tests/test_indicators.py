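"""Unit tests for the per-indicator scoring rules."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from fairmi import (
    CANONICAL_MODES,
    CANONICAL_ORDER,
    DatasetMetadata,
    DatasetQuery,
    EvidenceUnavailableError,
    FairCategory,
    IndicatorId,
    IndicatorScore,
    Provenance,
    RegistryRecord,
    RetrievalMode,
    RetrievalResult,
    CrossReference,
    not_assessed_scores,
    score_a1_family,
    score_a2,
    score_f1,
    score_f2,
    score_f3,
    score_f4,
    score_i1,
    score_i3,
    score_r1,
    score_r1_1,
    score_r1_2,
)


def make_meta(**kwargs):
    defaults = dict(repository_id="repo", format="XML", raw_text="")
    defaults.update(kwargs)
    return DatasetMetadata(**defaults)


def make_registry(**kwargs):
    defaults = dict(repository_id="repo", pid_doi=False)
    defaults.update(kwargs)
    return RegistryRecord(**defaults)


def make_query(keywords=("alpha",), dataset_id="DS-1"):
    return DatasetQuery("case", "repo", keywords, dataset_id)


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------

def test_fifteen_indicators_in_canonical_order():
    codes = [i.code for i in CANONICAL_ORDER]
    assert codes == ["F1", "F2", "F3", "F4", "A1", "A1.1", "A1.2", "A2",
                     "I1", "I2", "I3", "R1", "R1.1", "R1.2", "R1.3"]


def test_category_derives_from_leading_letter():
    expected = {"F": FairCategory.FINDABLE, "A": FairCategory.ACCESSIBLE,
                "I": FairCategory.INTEROPERABLE, "R": FairCategory.REUSABLE}
    for indicator in IndicatorId:
        assert indicator.category is expected[indicator.code[0]]


def test_canonical_retrieval_modes():
    manual = {"F1", "F4", "I1", "I3"}
    not_assessed = {"I2", "R1.3"}
    for indicator, mode in CANONICAL_MODES.items():
        if indicator.code in manual:
            assert mode is RetrievalMode.MANUAL
        elif indicator.code in not_assessed:
            assert mode is RetrievalMode.NOT_ASSESSED
        else:
            assert mode is RetrievalMode.AUTOMATIC


def test_score_value_range_is_enforced():
    with pytest.raises(ValueError):
        IndicatorScore(IndicatorId.F3, 1.5, RetrievalMode.AUTOMATIC)
    with pytest.raises(ValueError):
        IndicatorScore(IndicatorId.I2, 1.0, RetrievalMode.NOT_ASSESSED)


# ---------------------------------------------------------------------------
# F1 / F4 / A2 / R1.1 — registry and manual evidence
# ---------------------------------------------------------------------------

def test_f1_follows_the_doi_badge():
    assert score_f1(make_registry(pid_doi=True)).value == 1.0
    assert score_f1(make_registry(pid_doi=False)).value == 0.0
    # only the badge matters, other fields may be empty
    assert score_f1(RegistryRecord("repo", True)).value == 1.0
    assert score_f1(make_registry()).mode is RetrievalMode.MANUAL


def test_f1_missing_registry_is_an_error_not_a_zero():
    with pytest.raises(EvidenceUnavailableError):
        score_f1(None)


@pytest.mark.parametrize("flag,expected", [(True, 1.0), (False, 0.0)])
def test_f4_manual_flag(flag, expected):
    score = score_f4(flag)
    assert score.value == expected
    assert score.mode is RetrievalMode.MANUAL


def test_f4_absent_flag_is_an_error_not_a_zero():
    with pytest.raises(EvidenceUnavailableError):
        score_f4(None)


@pytest.mark.parametrize("policy,expected", [
    ("Metadata stay available.", 1.0),
    (None, 0.0),
    ("   ", 0.0),  # whitespace-only is not a policy
])
def test_a2_policy_presence(policy, expected):
    assert score_a2(make_registry(data_availability_policy=policy)).value \
        == expected


@pytest.mark.parametrize("name,url,expected", [
    ("CC-BY", "https://example.org/license", 1.0),
    ("CC-BY", None, 0.0),   # the rule is a conjunction
    (None, "https://example.org/license", 0.0),
    (None, None, 0.0),
])
def test_r1_1_requires_license_name_and_url(name, url, expected):
    registry = make_registry(license_name=name, license_url=url)
    assert score_r1_1(registry).value == expected


# ---------------------------------------------------------------------------
# F2 — keyword ratio
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("keywords,text,expected", [
    (("alpha", "beta", "gamma"), "ALPHA beta and Gamma here", 1.0),
    (("alpha", "beta", "gamma", "delta"), "only alpha", 0.25),
    (("alpha",), "", 0.0),
])
def test_f2_ratio(keywords, text, expected):
    meta = make_meta(raw_text=text or " ")
    meta.raw_text = text
    query = make_query(keywords=keywords)
    assert score_f2(query, meta).value == expected


def test_f2_matches_multiword_phrases():
    meta = make_meta(raw_text="chronic oxidative stress in cells")
    query = make_query(keywords=("oxidative stress", "stress in plants"))
    assert score_f2(query, meta).value == 0.5


def test_f2_empty_keywords_rejected_at_query_construction():
    with pytest.raises(ValueError):
        make_query(keywords=("", "  "))


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.text(alphabet="abcdefgh", min_size=3, max_size=6),
                min_size=1, max_size=8, unique_by=str.lower),
       st.data())
def test_f2_monotone_and_exact_ratio(keywords, data):
    """F2 equals matched/total and grows as more keywords are embedded."""
    n = len(keywords)
    m = data.draw(st.integers(0, n))
    query = make_query(keywords=keywords)
    kws = list(query.keywords)
    previous = -1.0
    for count in range(0, m + 1):
        # a text containing exactly `count` keywords; "|" never occurs in them
        meta = make_meta(raw_text="|".join(kws[:count]) or "|")
        value = score_f2(query, meta).value
        assert value == count / n
        assert value >= previous
        previous = value
    assert (previous == 1.0) == (m == n)


# ---------------------------------------------------------------------------
# F3 — identifier in metadata
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("identifiers,query_id,expected", [
    (["E-GEOD-7621"], "E-GEOD-7621", 1.0),
    ([], "E-GEOD-7621", 0.0),
    (["  E-GEOD-7621  "], "E-GEOD-7621", 1.0),  # trimming convention
    (["e-geod-7621"], "E-GEOD-7621", 1.0),      # case-insensitive
    (["E-GEOD-762"], "E-GEOD-7621", 0.0),       # no fuzzy prefix matching
])
def test_f3_exact_identifier_match(identifiers, query_id, expected):
    meta = make_meta(identifiers=identifiers)
    assert score_f3(make_query(dataset_id=query_id), meta).value == expected


# ---------------------------------------------------------------------------
# A1 family
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("scheme,status,expected", [
    ("http", 200, (1.0, 1.0, 1.0)),
    ("https", 200, (1.0, 1.0, 1.0)),  # HTTPS is HTTP-family
    ("http", 404, (0.0, 1.0, 1.0)),
    ("ftp", 200, (1.0, 0.0, 0.0)),
    ("http", None, (0.0, 1.0, 1.0)),  # failure: scheme still scoreable
])
def test_a1_family(scheme, status, expected):
    result = RetrievalResult(f"{scheme}://x.example.org/d", scheme, status)
    values = tuple(s.value for s in score_a1_family(result))
    assert values == expected
    codes = tuple(s.indicator.code for s in score_a1_family(result))
    assert codes == ("A1", "A1.1", "A1.2")


# ---------------------------------------------------------------------------
# I1 / I3 / R1
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("text,expected", [
    ("<root><a>1</a></root>", 1.0),
    ('{"a": 1}', 1.0),
    ("just some free text, no structure", 0.0),
    ("<root><unclosed></root>", 0.0),
])
def test_i1_structured_document(text, expected):
    assert score_i1(make_meta(raw_text=text)).value == expected


def test_i3_cross_references():
    with_ref = make_meta(identifiers=["DS-1"],
                         cross_references=[CrossReference("DS-2", "host")])
    assert score_i3(with_ref).value == 1.0
    assert score_i3(make_meta()).value == 0.0
    # a reference to itself is not a reference to *other* metadata
    self_ref = make_meta(identifiers=["DS-1"],
                         cross_references=[CrossReference("DS-1", "host")])
    assert score_i3(self_ref).value == 0.0


def test_r1_requires_information_beyond_keywords():
    query = make_query(keywords=("alpha", "beta"))
    rich = make_meta(attributes={"organism": ["human"],
                                 "keywords": ["alpha"]})
    assert score_r1(query, rich).value == 1.0
    bare = make_meta(attributes={"keywords": ["alpha", "Beta "]})
    assert score_r1(query, bare).value == 0.0
    assert score_r1(query, make_meta()).value == 0.0


# ---------------------------------------------------------------------------
# R1.2 — graded provenance, checked against brute-force enumeration
# ---------------------------------------------------------------------------

def brute_force_r1_2(fields: frozenset) -> float:
    """Independent oracle: enumerate the piecewise rule by counting."""
    k = len(fields)
    if k == 0:
        return 0.0
    if k == 3:
        return 1.0
    return 0.5


@pytest.mark.parametrize("present", [
    frozenset(s) for r in range(4)
    for s in itertools.combinations(("authors", "email", "title"), r)
])
def test_r1_2_all_eight_subsets(present):
    provenance = Provenance(
        authors="A et al." if "authors" in present else None,
        email="a@example.org" if "email" in present else None,
        title="A title" if "title" in present else None)
    meta = make_meta(provenance=provenance)
    assert score_r1_2(meta).value == brute_force_r1_2(present)


def test_r1_2_blank_fields_do_not_count():
    meta = make_meta(provenance=Provenance(authors="  ", email="", title="T"))
    assert score_r1_2(meta).value == 0.5  # only title is filled


def test_r1_2_no_provenance_record_at_all():
    assert score_r1_2(make_meta(provenance=None)).value == 0.0


# ---------------------------------------------------------------------------
# Not-assessed placeholders and purity
# ---------------------------------------------------------------------------

def test_not_assessed_placeholders():
    i2, r1_3 = not_assessed_scores()
    assert i2.indicator is IndicatorId.I2
    assert r1_3.indicator is IndicatorId.R1_3
    for score in (i2, r1_3):
        assert score.value is None
        assert score.mode is RetrievalMode.NOT_ASSESSED
        assert not score.is_missing  # not-assessed != missing


def test_scoring_is_pure():
    registry = make_registry(pid_doi=True)
    meta = make_meta(raw_text="alpha beta", identifiers=["DS-1"])
    query = make_query(keywords=("alpha", "beta"))
    assert score_f1(registry) == score_f1(registry)
    assert score_f2(query, meta) == score_f2(query, meta)
    assert score_f3(query, meta) == score_f3(query, meta)
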