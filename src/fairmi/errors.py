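"""Exception hierarchy shared across the assessment workflow.

The distinction between *failing* a criterion (score 0) and *not being able
to gather the evidence* is load-bearing: missing evidence raises, it never
silently scores 0.
"""


class FairmiError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FairmiError):
    """Invalid run configuration, unknown dialect, bad profile, bad label."""


class EvidenceUnavailableError(FairmiError):
    """Required evidence (registry record, manual flag, replay entry) is absent.

    Distinct from a criterion scoring 0: "not determined" is not "failed".
    """


class MetadataParseError(FairmiError):
    """A metadata or registry document could not be parsed."""

    def __init__(self, message: str, dialect: str | None = None,
                 position: object | None = None):
        detail = message
        if dialect is not None:
            detail = f"[dialect={dialect}] {detail}"
        if position is not None:
            detail = f"{detail} (at {position})"
        super().__init__(detail)
        self.dialect = dialect
        self.position = position


class ConsistencyError(FairmiError):
    """Evidence objects for one use case disagree (e.g., repository ids)."""


class ProfileError(ConfigurationError):
    """A fixture profile is internally unsatisfiable."""
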