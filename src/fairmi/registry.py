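"""Registry-of-repositories records (re3data-style).

A registry entry describes a *repository*, not a dataset: whether its data
get persistent identifiers (the DOI badge behind F1), whether it states a
data availability policy (A2), and the data usage license name/URL (R1.1).

The element names the registry uses for those three evidence groups are
configuration, not code — registries rename fields, and the published UI
badge ("doi" icon) has no officially documented API counterpart. The
defaults below read a simplified re3data-like XML record; JSON records with
the same keys parse identically.
"""

from __future__ import annotations

import json
import os
import urllib.request
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from typing import Optional

from .errors import ConsistencyError, EvidenceUnavailableError, MetadataParseError

__all__ = [
    "RegistryRecord",
    "RegistryFieldConfig",
    "parse_registry_record",
    "fetch_registry_record",
]


@dataclass(frozen=True)
class RegistryFieldConfig:
    """Where the three evidence groups live in a registry record.

    ``pid_true_values``: a repository earns the persistent-identifier badge
    when its pid element holds one of these tokens (case-insensitive); the
    explicit token "none" never does.
    """

    repository_id_element: str = "id"
    pid_element: str = "pidSystem"
    pid_true_values: tuple[str, ...] = ("doi", "hdl", "ark", "purl", "urn", "true")
    policy_element: str = "dataAvailabilityPolicy"
    license_name_element: str = "dataLicenseName"
    license_url_element: str = "dataLicenseURL"


DEFAULT_FIELDS = RegistryFieldConfig()


@dataclass(frozen=True)
class RegistryRecord:
    """One repository's registry entry, reduced to the scored evidence."""

    repository_id: str
    pid_doi: Optional[bool]  # None: the source record lacked the element
    data_availability_policy: Optional[str] = None
    license_name: Optional[str] = None
    license_url: Optional[str] = None

    @property
    def complete(self) -> bool:
        return self.pid_doi is not None


def _blank_to_none(value: Optional[str]) -> Optional[str]:
    if value is None:
        return None
    value = value.strip()
    return value or None


def parse_registry_record(document: str,
                          fields: RegistryFieldConfig = DEFAULT_FIELDS,
                          expected_repository_id: Optional[str] = None,
                          ) -> RegistryRecord:
    """Parse one registry record (XML or JSON) into a :class:`RegistryRecord`.

    Absent elements yield absent fields — the parser never guesses. If
    ``expected_repository_id`` is given and the record names a different
    repository, that's a mismatch error, not a silent acceptance.
    """
    values = _extract(document, fields)
    repo_id = values["repository_id"] or ""
    if expected_repository_id and repo_id and \
            repo_id.lower() != expected_repository_id.lower():
        raise ConsistencyError(
            f"registry record is for {repo_id!r}, "
            f"not {expected_repository_id!r}")

    pid_raw = values["pid"]
    if pid_raw is None:
        pid_doi: Optional[bool] = None  # incomplete record, not "false"
    else:
        tokens = {tok.strip().lower() for tok in pid_raw.replace(";", ",").split(",")}
        pid_doi = bool(tokens & {v.lower() for v in fields.pid_true_values})

    return RegistryRecord(
        repository_id=repo_id or (expected_repository_id or ""),
        pid_doi=pid_doi,
        data_availability_policy=values["policy"],
        license_name=values["license_name"],
        license_url=values["license_url"],
    )


def _extract(document: str, fields: RegistryFieldConfig) -> dict:
    wanted = {
        "repository_id": fields.repository_id_element,
        "pid": fields.pid_element,
        "policy": fields.policy_element,
        "license_name": fields.license_name_element,
        "license_url": fields.license_url_element,
    }
    try:
        data = json.loads(document)
    except (ValueError, TypeError):
        data = None
    if isinstance(data, dict):
        flat: dict[str, Optional[str]] = {}
        def _walk(node):
            if isinstance(node, dict):
                for key, val in node.items():
                    if isinstance(val, (dict, list)):
                        _walk(val)
                    else:
                        flat.setdefault(key, None if val is None else str(val))
            elif isinstance(node, list):
                for item in node:
                    _walk(item)
        _walk(data)
        return {name: _blank_to_none(flat.get(elem))
                for name, elem in wanted.items()}

    try:
        root = ET.fromstring(document)
    except ET.ParseError as exc:
        raise MetadataParseError(f"malformed registry record: {exc}",
                                 dialect="registry",
                                 position=exc.position) from exc
    found: dict[str, Optional[str]] = {}
    for element in root.iter():
        tag = element.tag.split("}")[-1]
        for name, elem in wanted.items():
            if tag == elem and name not in found:
                found[name] = element.text
    return {name: _blank_to_none(found.get(name)) for name in wanted}


def fetch_registry_record(repository_id: str, source: str,
                          fields: RegistryFieldConfig = DEFAULT_FIELDS,
                          timeout: float = 10.0) -> RegistryRecord:
    """Fetch a repository's registry record.

    ``source`` is either a fixture directory holding
    ``registry/<repository_id>.xml`` (or ``.json``, or the same files
    directly in ``source``) — the offline path — or an HTTP(S) URL template
    with a ``{repository_id}`` placeholder for live retrieval. Offline and
    live records parse identically.
    """
    if source.startswith(("http://", "https://")):
        url = source.format(repository_id=repository_id)
        try:
            with urllib.request.urlopen(url, timeout=timeout) as response:
                document = response.read().decode("utf-8")
        except OSError as exc:
            raise EvidenceUnavailableError(
                f"registry evidence unavailable for {repository_id!r}: "
                f"{exc}") from exc
        return parse_registry_record(document, fields, repository_id)

    candidates = [
        os.path.join(source, "registry", f"{repository_id}{ext}")
        for ext in (".xml", ".json")
    ] + [
        os.path.join(source, f"{repository_id}{ext}")
        for ext in (".xml", ".json")
    ]
    for path in candidates:
        if os.path.isfile(path):
            with open(path, encoding="utf-8") as fh:
                return parse_registry_record(fh.read(), fields, repository_id)
    raise EvidenceUnavailableError(
        f"registry evidence unavailable for {repository_id!r} "
        f"(no record under {source!r})")
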