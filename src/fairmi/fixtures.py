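"""Synthetic evidence bundles with dialled-in FAIRness.

A :class:`FixtureProfile` states, declaratively, how FAIR a use case should
look — DOI badge on or off, availability policy present or absent, which
provenance attributes the repository exposes, what fraction of the search
keywords its metadata contains — and :func:`generate_evidence` produces a
mutually consistent bundle (query, metadata document, registry record,
retrieval result, search-resource flag) that scores *exactly* as the
profile dictates. That self-consistency is the generator's contract and is
validated at generation time.

The six builtin profiles describe the six evaluated use cases: a
Parkinson's disease expression study (ArrayExpress), a WDR45 mutation study
(Gene Expression Omnibus), and a TiO2 nanoparticle toxicity question asked
of eNanoMapper, caNanoLab, ChEMBL and NanoCommons. All documents are
synthetic stand-ins shaped like each repository's API output; the keyword
lists paraphrase the research questions and are not the researchers'
literal queries.
"""

from __future__ import annotations

import os
import random
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .acquisition import ReplayStore, RetrievalResult
from .errors import ProfileError
from .metadata import (
    CrossReference,
    DatasetMetadata,
    DatasetQuery,
    Provenance,
    build_document,
    parse_metadata,
)
from .metadata import _dialect_config  # shared field maps
from .registry import RegistryRecord, parse_registry_record

__all__ = [
    "FixtureProfile",
    "EvidenceBundle",
    "generate_evidence",
    "builtin_profiles",
    "write_fixture_tree",
]

_PROVENANCE_FIELDS = ("authors", "email", "title")

# Filler vocabulary for attribute values: distinctive nonsense tokens,
# disjoint (case-insensitively) from any sensible keyword or accession, so
# filler can never fake a keyword match (F2) or an identifier (F3).
_FILLER_WORDS = (
    "zelquor", "brontexa", "quvandric", "mollivant", "xerpathic",
    "dranvoli", "cravexin", "plorvine", "stequarn", "velgorith",
    "ambrosqil", "torvexal", "unglomeric", "hyxalene", "crostivan",
    "pelvagrim", "onduleth", "fravikos", "melquorid", "zantheric",
)


@dataclass(frozen=True)
class FixtureProfile:
    """Declarative FAIRness configuration for one synthetic use case."""

    use_case: str
    repository_id: str
    dialect: str
    keywords: tuple[str, ...]
    dataset_id: str
    keyword_coverage: float = 1.0
    has_doi_badge: bool = False
    has_policy: bool = False
    has_license: bool = True
    provenance_fields: tuple[str, ...] = ()
    has_cross_reference: bool = False
    in_search_resource: bool = True
    extra_attributes: int = 3
    format: str = "XML"

    def __post_init__(self) -> None:
        object.__setattr__(self, "keywords", tuple(self.keywords))
        object.__setattr__(self, "provenance_fields",
                           tuple(self.provenance_fields))
        if not self.keywords:
            raise ProfileError(f"{self.use_case}: profile needs keywords")
        if not 0.0 <= self.keyword_coverage <= 1.0:
            raise ProfileError(
                f"{self.use_case}: coverage {self.keyword_coverage} "
                f"outside [0, 1]")
        n = len(self.keywords)
        m = self.keyword_coverage * n
        if abs(m - round(m)) > 1e-9:
            raise ProfileError(
                f"{self.use_case}: coverage {self.keyword_coverage} is not "
                f"expressible as m/{n} keywords")
        unknown = set(self.provenance_fields) - set(_PROVENANCE_FIELDS)
        if unknown:
            raise ProfileError(
                f"{self.use_case}: unknown provenance fields "
                f"{sorted(unknown)}")
        if self.extra_attributes < 0:
            raise ProfileError(f"{self.use_case}: negative attribute count")
        if self.format.upper() not in ("XML", "JSON"):
            raise ProfileError(f"{self.use_case}: format must be XML or JSON")

    @property
    def matched_keyword_count(self) -> int:
        return round(self.keyword_coverage * len(self.keywords))

    def expected_values(self) -> dict[str, Optional[float]]:
        """The scores a bundle generated from this profile must earn."""
        n = len(self.keywords)
        k = len(set(self.provenance_fields))
        return {
            "F1": 1.0 if self.has_doi_badge else 0.0,
            "F2": self.matched_keyword_count / n,
            "F3": 1.0,  # the generated metadata always carries its accession
            "F4": 1.0 if self.in_search_resource else 0.0,
            "A1": 1.0, "A1.1": 1.0, "A1.2": 1.0,  # replayed HTTPS 200
            "A2": 1.0 if self.has_policy else 0.0,
            "I1": 1.0,  # generated documents are well-formed by construction
            "I2": None,
            "I3": 1.0 if self.has_cross_reference else 0.0,
            "R1": 1.0 if self.extra_attributes > 0 else 0.0,
            "R1.1": 1.0 if self.has_license else 0.0,
            "R1.2": 1.0 if k == 3 else (0.5 if k >= 1 else 0.0),
            "R1.3": None,
        }


@dataclass(frozen=True)
class EvidenceBundle:
    """Everything :func:`fairmi.assessment.assess_use_case` needs."""

    query: DatasetQuery
    metadata: DatasetMetadata
    registry: RegistryRecord
    retrieval: RetrievalResult
    f4_flag: bool
    metadata_document: str = ""
    registry_document: str = ""


def generate_evidence(profile: FixtureProfile, seed: int = 0) -> EvidenceBundle:
    """Generate a self-consistent evidence bundle for one profile.

    Deterministic for a fixed (profile, seed). Raises
    :class:`~fairmi.errors.ProfileError` when the profile cannot be realised
    — a coverage not expressible with the keyword count, provenance fields
    the dialect has no attributes for, or keywords that collide with the
    document structure or with each other.
    """
    rng = random.Random(f"{seed}:{profile.use_case}")
    dialect_cfg = _dialect_config(profile.dialect)

    prov_map = dialect_cfg.get("provenance") or {}
    missing = [f for f in profile.provenance_fields if f not in prov_map]
    if missing:
        raise ProfileError(
            f"{profile.use_case}: dialect {profile.dialect!r} has no "
            f"attributes for provenance field(s) {missing}")

    n = len(profile.keywords)
    matched_idx = sorted(rng.sample(range(n), profile.matched_keyword_count))
    matched = [profile.keywords[i] for i in matched_idx]
    unmatched = [kw for i, kw in enumerate(profile.keywords)
                 if i not in matched_idx]

    attr_prefix = dialect_cfg["identifier_paths"][0].rsplit(".", 1)[0] \
        if "." in dialect_cfg["identifier_paths"][0] else ""

    def _path(name: str) -> str:
        return f"{attr_prefix}.{name}" if attr_prefix else name

    attributes: dict[str, list[str]] = {}
    if matched:
        attributes[_path("keywords")] = list(matched)
    for i in range(profile.extra_attributes):
        words = rng.sample(_FILLER_WORDS, 3)
        attributes[_path(f"attribute{i + 1}")] = [" ".join(words)]

    provenance = None
    if prov_map:
        filler = {
            "authors": f"{rng.choice(_FILLER_WORDS).title()} QX et al.",
            "email": f"{rng.choice(_FILLER_WORDS)}@example.org",
            "title": " ".join(rng.sample(_FILLER_WORDS, 4)).title(),
        }
        provenance = Provenance(**{
            name: (filler[name] if name in profile.provenance_fields else None)
            for name in _PROVENANCE_FIELDS})

    cross_references = []
    if profile.has_cross_reference:
        cross_references.append(CrossReference(
            target_id=f"{profile.dataset_id}-REL1",
            target_host=f"data.{profile.repository_id}.example.org"))

    document = build_document(
        dialect_cfg,
        fmt=profile.format,
        identifiers=[profile.dataset_id],
        cross_references=cross_references,
        provenance=provenance,
        attributes=attributes,
    )
    _check_keyword_consistency(profile, document, matched, unmatched)

    meta = parse_metadata(document, profile.dialect,
                          repository_id=profile.repository_id)

    registry_document = _registry_document(profile)
    registry = parse_registry_record(registry_document,
                                     expected_repository_id=profile.repository_id)

    url = (f"https://api.{profile.repository_id}.example.org/"
           f"datasets/{profile.dataset_id}")
    retrieval = RetrievalResult(url=url, scheme="https", status=200)

    query = DatasetQuery(
        use_case=profile.use_case,
        repository_id=profile.repository_id,
        keywords=profile.keywords,
        dataset_id=profile.dataset_id,
    )
    return EvidenceBundle(
        query=query,
        metadata=meta,
        registry=registry,
        retrieval=retrieval,
        f4_flag=profile.in_search_resource,
        metadata_document=document,
        registry_document=registry_document,
    )


def _check_keyword_consistency(profile: FixtureProfile, document: str,
                               matched: list[str],
                               unmatched: list[str]) -> None:
    text = document.lower()
    ghosts = [kw for kw in unmatched if kw.lower() in text]
    if ghosts:
        raise ProfileError(
            f"{profile.use_case}: keyword(s) {ghosts} collide with the "
            f"generated document although the profile excludes them "
            f"(coverage {profile.keyword_coverage})")
    lost = [kw for kw in matched if kw.lower() not in text]
    if lost:  # pragma: no cover - would indicate a builder defect
        raise ProfileError(
            f"{profile.use_case}: keyword(s) {lost} were not embedded")


def _registry_document(profile: FixtureProfile) -> str:
    lines = [
        "<re3data>",
        "  <repository>",
        f"    <id>{profile.repository_id}</id>",
        f"    <repositoryName>{profile.repository_id}</repositoryName>",
        f"    <pidSystem>{'DOI' if profile.has_doi_badge else 'none'}"
        f"</pidSystem>",
    ]
    if profile.has_policy:
        lines.append(
            "    <dataAvailabilityPolicy>Metadata remain accessible when "
            "datasets are withdrawn.</dataAvailabilityPolicy>")
    if profile.has_license:
        lines.append("    <dataLicenseName>CC-BY 4.0</dataLicenseName>")
        lines.append(
            "    <dataLicenseURL>https://creativecommons.org/licenses/by/4.0/"
            "</dataLicenseURL>")
    lines += ["  </repository>", "</re3data>", ""]
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# The six builtin use cases
# ---------------------------------------------------------------------------

def builtin_profiles() -> list[FixtureProfile]:
    """The six evaluated use cases with their published score pattern.

    All six: every keyword found (F2=1), accession in the metadata (F3=1),
    HTTPS retrieval with status 200 (A1 family = 1), structured documents
    (I1=1), attributes beyond the keywords (R1=1), and a registry license
    (R1.1=1). They differ exactly where the published assessment differed:
    only ArrayExpress states an availability policy (A2); only ChEMBL has
    the DOI badge (F1); only caNanoLab and ChEMBL reference other datasets
    (I3); only the GEO dataset was absent from the dataset search engine
    (F4); provenance is full for ArrayExpress (R1.2=1), partial for ChEMBL
    (authors+title, 0.5) and absent elsewhere (0).
    """
    common = dict(keyword_coverage=1.0, has_license=True, extra_attributes=4)
    return [
        FixtureProfile(
            use_case="Parkinsons_AE", repository_id="arrayexpress",
            dialect="arrayexpress", format="XML",
            keywords=("Parkinson disease", "frontal lobe",
                      "differential gene expression"),
            dataset_id="E-GEOD-7621",
            has_policy=True,
            provenance_fields=("authors", "email", "title"),
            **common),
        FixtureProfile(
            use_case="NBIA_GEO", repository_id="geo",
            dialect="geo", format="XML",
            keywords=("WDR45 mutation", "brain", "gene expression profiling"),
            dataset_id="GSE97713",
            in_search_resource=False,
            **common),
        FixtureProfile(
            use_case="TiO2_eNanoMapper", repository_id="enanomapper",
            dialect="enanomapper", format="JSON",
            keywords=("titanium dioxide", "nanoparticle", "oxidative stress"),
            dataset_id="ENM-TIO2-0042",
            **common),
        FixtureProfile(
            use_case="TiO2_caNanoLab", repository_id="cananolab",
            dialect="cananolab", format="JSON",
            keywords=("titanium dioxide", "nanoparticle", "cytotoxicity"),
            dataset_id="CANANO-1987",
            has_cross_reference=True,
            **common),
        FixtureProfile(
            use_case="TiO2_ChEMBL", repository_id="chembl",
            dialect="chembl", format="JSON",
            keywords=("titanium dioxide", "nanoparticle", "genotoxicity"),
            dataset_id="CHEMBL3989231",
            has_doi_badge=True, has_cross_reference=True,
            provenance_fields=("authors", "title"),
            **common),
        FixtureProfile(
            use_case="TiO2_NanoCommons", repository_id="nanocommons",
            dialect="nanocommons", format="XML",
            keywords=("titanium dioxide", "nanoparticle", "immunotoxicity"),
            dataset_id="NC-TIO2-007",
            **common),
    ]


# ---------------------------------------------------------------------------
# On-disk fixture trees (for the CLI's offline mode)
# ---------------------------------------------------------------------------

def write_fixture_tree(directory: str,
                       profiles: Optional[list[FixtureProfile]] = None,
                       seed: int = 0) -> str:
    """Write generated evidence to ``directory`` in the offline layout:
    ``metadata/``, ``registry/``, ``replay/`` and a ready ``config.yaml``
    for ``fairmi assess``. Returns the config path.
    """
    profiles = profiles if profiles is not None else builtin_profiles()
    os.makedirs(os.path.join(directory, "metadata"), exist_ok=True)
    os.makedirs(os.path.join(directory, "registry"), exist_ok=True)

    replay_entries: dict[str, Optional[int]] = {}
    config: dict = {"use_cases": []}
    for profile in profiles:
        bundle = generate_evidence(profile, seed)
        ext = ".xml" if profile.format.upper() == "XML" else ".json"
        meta_rel = os.path.join("metadata", profile.use_case + ext)
        with open(os.path.join(directory, meta_rel), "w",
                  encoding="utf-8") as fh:
            fh.write(bundle.metadata_document)
        registry_path = os.path.join(
            directory, "registry", f"{profile.repository_id}.xml")
        with open(registry_path, "w", encoding="utf-8") as fh:
            fh.write(bundle.registry_document)
        replay_entries[bundle.retrieval.url] = bundle.retrieval.status
        config["use_cases"].append({
            "use_case": profile.use_case,
            "repository_id": profile.repository_id,
            "dialect": profile.dialect,
            "keywords": list(profile.keywords),
            "dataset_id": profile.dataset_id,
            "metadata": meta_rel.replace(os.sep, "/"),
            "retrieval_url": bundle.retrieval.url,
            "f4": bool(profile.in_search_resource),
        })

    ReplayStore.write(replay_entries, os.path.join(directory, "replay"))
    config_path = os.path.join(directory, "config.yaml")
    with open(config_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return config_path
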