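"""Retrieval evidence for the accessibility indicators and F4.

The A1 family is scored from one retrieval attempt per use case: the HTTP
status answers A1, the URL scheme answers A1.1/A1.2. Retrievals run either
live (one GET) or — the default everywhere in this package — replayed from
a recorded store, so assessments are deterministic and fully offline.

The replay store is a plain text file or directory of files with one
``url<TAB>status`` line per recorded retrieval (status ``-`` for a recorded
connection failure).

F4 (indexed in a searchable resource, e.g. a dataset search engine) is a
manual flag by design: scraping a search engine is neither stable nor
permitted, so the evidence is an override value or a pluggable checker.
"""

from __future__ import annotations

import os
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass
from typing import Callable, Optional

from .errors import ConfigurationError, EvidenceUnavailableError

__all__ = [
    "RetrievalResult",
    "ReplayStore",
    "retrieve",
    "check_search_resource",
]

REPLAY_FILENAME = "retrievals.tsv"


@dataclass(frozen=True)
class RetrievalResult:
    """Outcome of retrieving one URL."""

    url: str
    scheme: str  # http | https | ftp | other
    status: Optional[int]  # None: the request failed outright

    @property
    def failed(self) -> bool:
        return self.status is None


def _scheme_of(url: str) -> str:
    scheme = urllib.parse.urlsplit(url).scheme.lower()
    if scheme in ("http", "https", "ftp"):
        return scheme
    if not scheme:
        raise ConfigurationError(f"malformed url (no scheme): {url!r}")
    return "other"


class ReplayStore:
    """Recorded retrievals keyed by URL, in a line-based text format."""

    def __init__(self, path: str):
        self._entries: dict[str, Optional[int]] = {}
        files = []
        if os.path.isdir(path):
            direct = os.path.join(path, REPLAY_FILENAME)
            nested = os.path.join(path, "replay", REPLAY_FILENAME)
            files = [p for p in (direct, nested) if os.path.isfile(p)]
            if not files:
                raise EvidenceUnavailableError(
                    f"no replay store ({REPLAY_FILENAME}) under {path!r}")
        elif os.path.isfile(path):
            files = [path]
        else:
            raise EvidenceUnavailableError(f"no replay store at {path!r}")
        for file_path in files:
            with open(file_path, encoding="utf-8") as fh:
                for line_no, line in enumerate(fh, 1):
                    line = line.rstrip("\n")
                    if not line or line.startswith("#"):
                        continue
                    try:
                        url, status = line.split("\t")
                    except ValueError:
                        raise ConfigurationError(
                            f"{file_path}:{line_no}: expected "
                            f"'url<TAB>status'") from None
                    self._entries[url] = None if status == "-" else int(status)

    def lookup(self, url: str) -> Optional[int]:
        if url not in self._entries:
            raise EvidenceUnavailableError(
                f"no recorded retrieval for {url!r}")
        return self._entries[url]

    @staticmethod
    def write(entries: dict[str, Optional[int]], path: str) -> str:
        """Write a replay store file; returns its path."""
        os.makedirs(path, exist_ok=True)
        file_path = os.path.join(path, REPLAY_FILENAME)
        with open(file_path, "w", encoding="utf-8") as fh:
            for url, status in entries.items():
                fh.write(f"{url}\t{'-' if status is None else status}\n")
        return file_path


def retrieve(url: str, mode: str = "replay",
             replay_store: Optional[str | ReplayStore] = None,
             timeout: float = 10.0) -> RetrievalResult:
    """Retrieve (or replay the retrieval of) one URL.

    ``mode="replay"`` looks the URL up in the recorded store; a miss is an
    evidence error, never a fabricated status. ``mode="live"`` performs one
    GET; a connection failure is recorded as ``status=None`` (the scheme is
    still scoreable from the URL).
    """
    scheme = _scheme_of(url)
    if mode == "replay":
        if replay_store is None:
            raise ConfigurationError("replay mode needs a replay store")
        store = (replay_store if isinstance(replay_store, ReplayStore)
                 else ReplayStore(replay_store))
        return RetrievalResult(url, scheme, store.lookup(url))
    if mode != "live":
        raise ConfigurationError(f"unknown retrieval mode {mode!r}")
    try:
        with urllib.request.urlopen(url, timeout=timeout) as response:
            status = getattr(response, "status", 200)
    except urllib.error.HTTPError as exc:
        status = exc.code
    except OSError:
        status = None
    return RetrievalResult(url, scheme, status)


def check_search_resource(dataset_title: str,
                          override: Optional[bool] = None,
                          checker: Optional[Callable[[str], bool]] = None,
                          ) -> bool:
    """Was the dataset title found in the searchable resource?

    The manual override wins when present; otherwise a pluggable checker is
    consulted. With neither, the evidence simply does not exist.
    """
    if override is not None:
        return bool(override)
    if checker is not None:
        return bool(checker(dataset_title))
    raise EvidenceUnavailableError(
        f"manual evidence required for F4 (dataset {dataset_title!r})")
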