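"""Document retrieval with interchangeable live-HTTP and fixture backends.

Every stage of the pipeline consumes :class:`RawDocument` objects obtained
through a single ``fetch(accession, doc_kind)`` contract.  Two backends
implement it:

* :class:`LiveBackend` — REST requests against configurable URL templates
  (defaults point at the public ENA browser, BioSamples, and ArrayExpress
  XML retrieval endpoints).
* :class:`FixtureBackend` — reads ``<accession>.<doc_kind>.xml`` files from a
  local directory, so the whole pipeline runs byte-deterministically with no
  network.  The directory may also be set via the ``OMICSPAPER_FIXTURES``
  environment variable.

The failure taxonomy is closed: every fetch failure maps to exactly one of
:class:`MissingRecordError`, :class:`NetworkFailureError`,
:class:`MalformedPayloadError`.
"""

from __future__ import annotations

import logging
import os
import urllib.error
import urllib.request
from dataclasses import dataclass, field
from datetime import datetime, timezone
from enum import Enum
from pathlib import Path

from lxml import etree

from .accessions import Accession

__all__ = [
    "DocKind",
    "RawDocument",
    "EndpointConfig",
    "TransportError",
    "MissingRecordError",
    "NetworkFailureError",
    "MalformedPayloadError",
    "FixtureBackend",
    "LiveBackend",
    "FIXTURE_DIR_ENV",
]

logger = logging.getLogger(__name__)

#: Environment variable overriding the fixture directory.
FIXTURE_DIR_ENV = "OMICSPAPER_FIXTURES"


class DocKind(str, Enum):
    STUDY = "study"
    PROJECT = "project"
    EXPERIMENT = "experiment"
    SAMPLE = "sample"
    BIOSAMPLE = "biosample"
    ARRAYEXPRESS_EXPERIMENT = "arrayexpress_experiment"
    ARRAYEXPRESS_PROTOCOL = "arrayexpress_protocol"


class TransportError(Exception):
    """Base class for the closed fetch-failure taxonomy."""


class MissingRecordError(TransportError):
    """The record does not exist at the source (distinct from unreachable)."""


class NetworkFailureError(TransportError):
    """The source could not be reached after the configured retries."""


class MalformedPayloadError(TransportError):
    """The source answered with something that is not well-formed XML."""


@dataclass(frozen=True)
class RawDocument:
    """A fetched XML document plus provenance."""

    accession: Accession
    doc_kind: DocKind
    xml_text: str
    source: str  # "live" | "fixture"
    retrieved_at: datetime

    @property
    def name(self) -> str:
        """Self-describing document name, also the fixture file stem."""
        return f"{self.accession.value}.{self.doc_kind.value}"


_DEFAULT_TEMPLATES: dict[DocKind, str] = {
    DocKind.STUDY: "https://www.ebi.ac.uk/ena/browser/api/xml/{accession}",
    DocKind.PROJECT: "https://www.ebi.ac.uk/ena/browser/api/xml/{accession}",
    DocKind.EXPERIMENT: "https://www.ebi.ac.uk/ena/browser/api/xml/{accession}",
    DocKind.SAMPLE: "https://www.ebi.ac.uk/ena/browser/api/xml/{accession}",
    DocKind.BIOSAMPLE: "https://www.ebi.ac.uk/biosamples/samples/{accession}.xml",
    DocKind.ARRAYEXPRESS_EXPERIMENT: (
        "https://www.ebi.ac.uk/arrayexpress/xml/v3/experiments/{accession}"
    ),
    DocKind.ARRAYEXPRESS_PROTOCOL: (
        "https://www.ebi.ac.uk/arrayexpress/xml/v3/experiments/{accession}/protocols"
    ),
}


@dataclass(frozen=True)
class EndpointConfig:
    """URL templates and retry policy for the live backend.

    Each doc kind maps to exactly one template containing the literal
    ``{accession}`` placeholder exactly once.

    Config-file schema (plain ``key=value`` lines, ``#`` comments allowed)::

        study_url=https://example.org/xml/{accession}
        biosample_url=https://example.org/biosamples/{accession}.xml
        timeout=10
        retry_count=3

    Recognized URL keys are ``<doc_kind>_url`` for every :class:`DocKind`
    value; unspecified kinds keep their defaults.
    """

    templates: dict[DocKind, str] = field(
        default_factory=lambda: dict(_DEFAULT_TEMPLATES)
    )
    timeout: float = 10.0
    retry_count: int = 3

    def __post_init__(self) -> None:
        for kind in DocKind:
            template = self.templates.get(kind)
            if template is None:
                raise ValueError(f"no URL template for doc kind {kind.value!r}")
            if template.count("{accession}") != 1:
                raise ValueError(
                    f"template for {kind.value!r} must contain "
                    f"'{{accession}}' exactly once: {template!r}"
                )

    @classmethod
    def from_file(cls, path: str | Path) -> "EndpointConfig":
        """Load a config file in the documented key=value schema."""
        templates = dict(_DEFAULT_TEMPLATES)
        timeout, retry_count = 10.0, 3
        valid_url_keys = {f"{kind.value}_url": kind for kind in DocKind}
        for lineno, raw in enumerate(Path(path).read_text("utf-8").splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key in valid_url_keys:
                templates[valid_url_keys[key]] = value
            elif key == "timeout":
                timeout = float(value)
            elif key == "retry_count":
                retry_count = int(value)
            else:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        return cls(templates=templates, timeout=timeout, retry_count=retry_count)

    def url_for(self, accession: Accession, doc_kind: DocKind) -> str:
        return self.templates[doc_kind].format(accession=accession.value)


def _check_well_formed(text: str, context: str) -> None:
    try:
        etree.fromstring(text.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise MalformedPayloadError(f"{context}: payload is not well-formed XML: {exc}")


class FixtureBackend:
    """Fetch documents from a local fixture directory.

    Files are named ``<accession>.<doc_kind>.xml``.  Reads go to disk on every
    call (no caching) so that re-import operations observe fixture edits; for
    unchanged files the backend is byte-deterministic.
    """

    source = "fixture"

    def __init__(self, directory: str | Path | None = None):
        if directory is None:
            directory = os.environ.get(FIXTURE_DIR_ENV)
        if directory is None:
            raise ValueError(
                f"no fixture directory given and {FIXTURE_DIR_ENV} is unset"
            )
        self.directory = Path(directory)

    def fetch(self, accession: Accession, doc_kind: DocKind) -> RawDocument:
        path = self.directory / f"{accession.value}.{doc_kind.value}.xml"
        if not path.is_file():
            logger.info(
                "fetch accession=%s kind=%s backend=fixture outcome=missing-record",
                accession.value, doc_kind.value,
            )
            raise MissingRecordError(f"no fixture file {path}")
        text = path.read_text("utf-8")
        _check_well_formed(text, str(path))
        logger.info(
            "fetch accession=%s kind=%s backend=fixture outcome=ok",
            accession.value, doc_kind.value,
        )
        return RawDocument(
            accession=accession,
            doc_kind=doc_kind,
            xml_text=text,
            source=self.source,
            retrieved_at=datetime.now(timezone.utc),
        )


class LiveBackend:
    """Fetch documents over HTTP with retries and a per-run in-memory cache."""

    source = "live"

    def __init__(self, config: EndpointConfig | None = None):
        self.config = config or EndpointConfig()
        self._cache: dict[tuple[str, DocKind], RawDocument] = {}

    def fetch(self, accession: Accession, doc_kind: DocKind) -> RawDocument:
        key = (accession.value, doc_kind)
        if key in self._cache:
            return self._cache[key]
        url = self.config.url_for(accession, doc_kind)
        last_error: Exception | None = None
        for attempt in range(1, self.config.retry_count + 1):
            try:
                with urllib.request.urlopen(url, timeout=self.config.timeout) as resp:
                    text = resp.read().decode("utf-8")
                break
            except urllib.error.HTTPError as exc:
                if exc.code in (404, 410):
                    logger.info(
                        "fetch accession=%s kind=%s backend=live outcome=missing-record",
                        accession.value, doc_kind.value,
                    )
                    raise MissingRecordError(f"{url}: HTTP {exc.code}")
                last_error = exc
            except (urllib.error.URLError, OSError) as exc:
                last_error = exc
        else:
            logger.info(
                "fetch accession=%s kind=%s backend=live outcome=network-failure",
                accession.value, doc_kind.value,
            )
            raise NetworkFailureError(
                f"{url}: unreachable after {self.config.retry_count} attempts "
                f"({last_error})"
            )
        _check_well_formed(text, url)
        logger.info(
            "fetch accession=%s kind=%s backend=live outcome=ok attempt=%d",
            accession.value, doc_kind.value, attempt,
        )
        doc = RawDocument(
            accession=accession,
            doc_kind=doc_kind,
            xml_text=text,
            source=self.source,
            retrieved_at=datetime.now(timezone.utc),
        )
        self._cache[key] = doc
        return doc
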