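"""FAIR maturity-indicator taxonomy and scoring rules.

The 15 FAIR sub-principles (F1..R1.3) each get a concrete, testable maturity
indicator. Thirteen are evaluated; I2 (FAIR vocabularies) and R1.3 (community
standards) are emitted as not-assessed placeholders so every assessment row
is total over the 15 columns.

Scores are binary (criterion met / not met) with two exceptions:

* F2 — the fraction of the researcher's search keywords found in the dataset
  metadata, a rational in [0, 1];
* R1.2 — graded provenance: 1 if all of {authors, email, title} are filled,
  0.5 if one or two are, 0 if none is.

Each indicator also carries its canonical retrieval mode: whether its
evidence is gathered automatically (API) or manually (human inspection).
The mode tags follow the published rubric even where this implementation
automates the check (F1, F4, I1, I3), so rendered plots keep the canonical
diamond/circle shapes; pass ``mode=`` explicitly to re-tag.
"""

from __future__ import annotations

import enum
import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping, Optional

from .errors import EvidenceUnavailableError

if TYPE_CHECKING:  # pragma: no cover - import cycle guard for type hints
    from .acquisition import RetrievalResult
    from .metadata import DatasetMetadata, DatasetQuery
    from .registry import RegistryRecord

__all__ = [
    "IndicatorId",
    "FairCategory",
    "RetrievalMode",
    "IndicatorScore",
    "CANONICAL_MODES",
    "score_f1",
    "score_f2",
    "score_f3",
    "score_f4",
    "score_a1_family",
    "score_a2",
    "score_i1",
    "score_i3",
    "score_r1",
    "score_r1_1",
    "score_r1_2",
    "not_assessed_scores",
]


class FairCategory(enum.Enum):
    """The four groups of the FAIR acronym."""

    FINDABLE = "Findable"
    ACCESSIBLE = "Accessible"
    INTEROPERABLE = "Interoperable"
    REUSABLE = "Reusable"


class IndicatorId(enum.Enum):
    """The 15 FAIR sub-principles in canonical column order."""

    F1 = "F1"
    F2 = "F2"
    F3 = "F3"
    F4 = "F4"
    A1 = "A1"
    A1_1 = "A1.1"
    A1_2 = "A1.2"
    A2 = "A2"
    I1 = "I1"
    I2 = "I2"
    I3 = "I3"
    R1 = "R1"
    R1_1 = "R1.1"
    R1_2 = "R1.2"
    R1_3 = "R1.3"

    @property
    def code(self) -> str:
        return self.value

    @property
    def category(self) -> FairCategory:
        return _CATEGORY_BY_LETTER[self.value[0]]

    @classmethod
    def from_code(cls, code: str) -> "IndicatorId":
        for member in cls:
            if member.value == code:
                return member
        raise KeyError(f"unknown indicator code {code!r}")


_CATEGORY_BY_LETTER = {
    "F": FairCategory.FINDABLE,
    "A": FairCategory.ACCESSIBLE,
    "I": FairCategory.INTEROPERABLE,
    "R": FairCategory.REUSABLE,
}

#: Canonical column order of an assessment row.
CANONICAL_ORDER: tuple[IndicatorId, ...] = tuple(IndicatorId)


class RetrievalMode(enum.Enum):
    AUTOMATIC = "automatic"
    MANUAL = "manual"
    NOT_ASSESSED = "not_assessed"


#: How each indicator's evidence was gathered in the published rubric.
CANONICAL_MODES: Mapping[IndicatorId, RetrievalMode] = {
    IndicatorId.F1: RetrievalMode.MANUAL,
    IndicatorId.F2: RetrievalMode.AUTOMATIC,
    IndicatorId.F3: RetrievalMode.AUTOMATIC,
    IndicatorId.F4: RetrievalMode.MANUAL,
    IndicatorId.A1: RetrievalMode.AUTOMATIC,
    IndicatorId.A1_1: RetrievalMode.AUTOMATIC,
    IndicatorId.A1_2: RetrievalMode.AUTOMATIC,
    IndicatorId.A2: RetrievalMode.AUTOMATIC,
    IndicatorId.I1: RetrievalMode.MANUAL,
    IndicatorId.I2: RetrievalMode.NOT_ASSESSED,
    IndicatorId.I3: RetrievalMode.MANUAL,
    IndicatorId.R1: RetrievalMode.AUTOMATIC,
    IndicatorId.R1_1: RetrievalMode.AUTOMATIC,
    IndicatorId.R1_2: RetrievalMode.AUTOMATIC,
    IndicatorId.R1_3: RetrievalMode.NOT_ASSESSED,
}


@dataclass(frozen=True)
class IndicatorScore:
    """One maturity-indicator result.

    ``value`` is None either when the indicator is not assessed
    (``mode == NOT_ASSESSED``) or when an imported qualitative cell was
    "unclear" (then ``mode`` is MANUAL and :attr:`is_missing` is true).
    """

    indicator: IndicatorId
    value: Optional[float]
    mode: RetrievalMode
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.value is not None and not 0.0 <= self.value <= 1.0:
            raise ValueError(
                f"{self.indicator.code}: score {self.value} outside [0, 1]")
        if self.mode is RetrievalMode.NOT_ASSESSED and self.value is not None:
            raise ValueError(
                f"{self.indicator.code}: not-assessed indicators carry no value")

    @property
    def is_missing(self) -> bool:
        """True for an assessed cell with no value (qualitative "unclear")."""
        return self.value is None and self.mode is not RetrievalMode.NOT_ASSESSED


def _binary(condition: bool) -> float:
    return 1.0 if condition else 0.0


def _score(indicator: IndicatorId, value: Optional[float], evidence: str,
           mode: RetrievalMode | None = None) -> IndicatorScore:
    return IndicatorScore(indicator, value,
                          mode or CANONICAL_MODES[indicator], evidence)


# ---------------------------------------------------------------------------
# Findable
# ---------------------------------------------------------------------------

def score_f1(registry: "RegistryRecord",
             mode: RetrievalMode | None = None) -> IndicatorScore:
    """F1 — metadata are assigned a persistent identifier.

    Evidence is the DOI/persistent-identifier badge of the repository's
    registry entry, not the dataset metadata itself.
    """
    if registry is None:
        raise EvidenceUnavailableError("F1: registry evidence unavailable")
    return _score(
        IndicatorId.F1, _binary(bool(registry.pid_doi)),
        f"registry {registry.repository_id}: pid/DOI badge={registry.pid_doi}",
        mode)


def score_f2(query: "DatasetQuery", meta: "DatasetMetadata",
             mode: RetrievalMode | None = None) -> IndicatorScore:
    """F2 — rich metadata: fraction of search keywords found in the metadata.

    Each keyword phrase is matched case-insensitively as a substring of the
    serialized metadata text; the score is matched / total keywords.
    """
    keywords = query.keywords
    if not keywords:
        raise ValueError("F2: keyword list is empty, ratio undefined")
    haystack = meta.search_text().lower()
    matched = [kw for kw in keywords if kw.lower() in haystack]
    value = len(matched) / len(keywords)
    return _score(
        IndicatorId.F2, value,
        f"{len(matched)}/{len(keywords)} keywords found: {matched!r}", mode)


def score_f3(query: "DatasetQuery", meta: "DatasetMetadata",
             mode: RetrievalMode | None = None) -> IndicatorScore:
    """F3 — metadata include the dataset identifier (exact accession match)."""
    if not query.dataset_id.strip():
        raise ValueError("F3: blank dataset id")
    wanted = query.dataset_id.strip().lower()
    hit = any(ident.strip().lower() == wanted for ident in meta.identifiers)
    return _score(IndicatorId.F3, _binary(hit),
                  f"dataset id {query.dataset_id!r} "
                  f"{'found' if hit else 'not found'} in {meta.identifiers!r}",
                  mode)


def score_f4(found_in_search_resource: Optional[bool],
             mode: RetrievalMode | None = None) -> IndicatorScore:
    """F4 — dataset title is indexed in a searchable resource.

    The flag comes from a manual check (or a pluggable checker); an absent
    flag is an error, not a 0 — unknown is not failed.
    """
    if found_in_search_resource is None:
        raise EvidenceUnavailableError("F4: manual evidence required")
    return _score(IndicatorId.F4, _binary(found_in_search_resource),
                  f"listed in searchable resource: {found_in_search_resource}",
                  mode)


# ---------------------------------------------------------------------------
# Accessible
# ---------------------------------------------------------------------------

_HTTP_FAMILY = {"http", "https"}


def score_a1_family(retrieval: "RetrievalResult",
                    mode: RetrievalMode | None = None,
                    ) -> tuple[IndicatorScore, IndicatorScore, IndicatorScore]:
    """A1, A1.1, A1.2 from one retrieval attempt.

    A1: the HTTP request returned 200. A1.1/A1.2: the protocol is
    HTTP-family (open, free, universally implementable; supports
    authentication) — judged from the URL scheme alone, so a failed request
    still scores the protocol.
    """
    ok = retrieval.status == 200
    http = retrieval.scheme in _HTTP_FAMILY
    status_note = ("request failed" if retrieval.status is None
                   else f"status={retrieval.status}")
    a1 = _score(IndicatorId.A1, _binary(ok),
                f"GET {retrieval.url}: {status_note}", mode)
    a1_1 = _score(IndicatorId.A1_1, _binary(http),
                  f"scheme={retrieval.scheme}", mode)
    a1_2 = _score(IndicatorId.A1_2, _binary(http),
                  f"scheme={retrieval.scheme}", mode)
    return a1, a1_1, a1_2


def score_a2(registry: "RegistryRecord",
             mode: RetrievalMode | None = None) -> IndicatorScore:
    """A2 — the registry entry states a data availability policy."""
    if registry is None:
        raise EvidenceUnavailableError("A2: registry evidence unavailable")
    filled = _filled(registry.data_availability_policy)
    return _score(IndicatorId.A2, _binary(filled),
                  f"registry {registry.repository_id}: availability policy "
                  f"{'present' if filled else 'absent'}", mode)


# ---------------------------------------------------------------------------
# Interoperable
# ---------------------------------------------------------------------------

def score_i1(meta: "DatasetMetadata",
             mode: RetrievalMode | None = None) -> IndicatorScore:
    """I1 — metadata use a structured representation (well-formed XML/JSON)."""
    structured = _is_structured(meta.raw_text)
    evidence = (f"raw document well-formed {structured}"
                if structured else "not well-formed XML or JSON")
    return _score(IndicatorId.I1, _binary(bool(structured)), evidence, mode)


def _is_structured(text: str) -> Optional[str]:
    try:
        json.loads(text)
        return "JSON"
    except (ValueError, TypeError):
        pass
    try:
        ET.fromstring(text)
        return "XML"
    except ET.ParseError:
        return None


def score_i3(meta: "DatasetMetadata",
             mode: RetrievalMode | None = None) -> IndicatorScore:
    """I3 — metadata reference *other* datasets.

    Self-references (a cross-reference equal to one of the dataset's own
    identifiers) do not count.
    """
    own = {ident.strip().lower() for ident in meta.identifiers}
    others = [ref for ref in meta.cross_references
              if ref.target_id.strip().lower() not in own]
    return _score(IndicatorId.I3, _binary(bool(others)),
                  f"{len(others)} cross-reference(s) to other datasets", mode)


# ---------------------------------------------------------------------------
# Reusable
# ---------------------------------------------------------------------------

def score_r1(query: "DatasetQuery", meta: "DatasetMetadata",
             mode: RetrievalMode | None = None) -> IndicatorScore:
    """R1 — metadata carry information beyond the search keywords.

    Passes if at least one attribute value is not simply one of the query
    keywords (case-insensitive, trimmed).
    """
    keywords = {kw.strip().lower() for kw in query.keywords}
    surplus = [v for values in meta.attributes.values() for v in values
               if v.strip() and v.strip().lower() not in keywords]
    return _score(IndicatorId.R1, _binary(bool(surplus)),
                  f"{len(surplus)} attribute value(s) beyond the keywords",
                  mode)


def score_r1_1(registry: "RegistryRecord",
               mode: RetrievalMode | None = None) -> IndicatorScore:
    """R1.1 — the registry entry names a data usage license (name AND url)."""
    if registry is None:
        raise EvidenceUnavailableError("R1.1: registry evidence unavailable")
    filled = _filled(registry.license_name) and _filled(registry.license_url)
    return _score(IndicatorId.R1_1, _binary(filled),
                  f"registry {registry.repository_id}: license "
                  f"name={registry.license_name!r} url={registry.license_url!r}",
                  mode)


def score_r1_2(meta: "DatasetMetadata",
               mode: RetrievalMode | None = None) -> IndicatorScore:
    """R1.2 — graded provenance score.

    k = number of filled fields among {authors, email, title}:
    k=3 -> 1.0, k in {1, 2} -> 0.5, k=0 -> 0.0.
    """
    prov = meta.provenance
    fields = {"authors": prov.authors if prov else None,
              "email": prov.email if prov else None,
              "title": prov.title if prov else None}
    filled = sorted(name for name, val in fields.items() if _filled(val))
    k = len(filled)
    value = 1.0 if k == 3 else (0.5 if k >= 1 else 0.0)
    return _score(IndicatorId.R1_2, value,
                  f"provenance fields filled ({k}/3): {filled}", mode)


def not_assessed_scores() -> tuple[IndicatorScore, IndicatorScore]:
    """I2 and R1.3 placeholders — evaluated by none of the rubrics."""
    return (
        IndicatorScore(IndicatorId.I2, None, RetrievalMode.NOT_ASSESSED,
                       "FAIRness of vocabularies not evaluated"),
        IndicatorScore(IndicatorId.R1_3, None, RetrievalMode.NOT_ASSESSED,
                       "community metadata standards not evaluated"),
    )


def _filled(value: Optional[str]) -> bool:
    """A field counts as filled only if present and nonblank after trimming."""
    return value is not None and bool(value.strip())
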