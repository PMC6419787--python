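"""Asynchronous annotation-server protocol.

Requests are JSON documents POSTed to the server, carrying a ``method``
field: ``getStatus`` answers synchronously from the fast stage, while
``getAnnotations`` is acknowledged as soon as it parses and then flows
through download → tag → deliver stages.  Document text is never part of
the request — documents are fetched by identifier from document servers,
and results are pushed back via one ``saveAnnotations``-style callback.

Two routing extensions remove any hardwired endpoints: the mapping from
a document ``source`` name to its server URL may be supplied per request
under ``custom_parameters.servers`` (falling back to configured
defaults), and the callback URL under ``custom_parameters.apiurl``.

Wire schema (a documented dialect of this package; adapters for other
dialects can wrap :func:`parse_annotation_request` / :func:`build_payload`):

* request::

    {"method": "getAnnotations", "communication_id": "...",
     "types": ["GENE", ...],
     "documents": [{"document_id": "...", "source": "..."}],
     "custom_parameters": {"servers": {"SRC": "http://..."},
                           "apiurl": "http://..."}}

* document-server exchange: POST ``{"ids": [...]}`` to the source's base
  URL; the response is ``{"documents": [{"document_id", "title",
  "abstract"}]}`` listing the ids it knows (missing ids are simply
  absent and become per-document fetch failures).

* callback payload: ``{"communication_id", "state", "documents":
  [{"document_id", "source", "fetch_failed", "annotations": [...]}]}``
  where each annotation is ``{"document_id", "section", "init", "end",
  "annotated_text", "type", "database_ids"}``; ``init``/``end`` are
  0-based half-open by default, with a config switch for inclusive ends.
"""

from __future__ import annotations

import json
import logging
import threading
import time
import urllib.error
import urllib.request
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from pydantic import BaseModel, Field, ValidationError, field_validator

from .config import ServiceConfig
from .dictionary import Dictionary, EntityType
from .documents import Document
from .http_intake import HttpRequest, IntakeLoop, Responder
from .ner import Annotation, tag
from .service import RejectedRequest, StageEngine, Task

__all__ = [
    "ProtocolError",
    "SourceResolutionError",
    "FetchFailure",
    "DocumentRef",
    "AnnotationRequest",
    "parse_annotation_request",
    "fetch_documents",
    "build_payload",
    "deliver_annotations",
    "AnnotationServer",
]

logger = logging.getLogger(__name__)

VERSION = "0.1.0"

STATUS_METHODS = {"getstatus", "getstate", "status"}
ANNOTATE_METHODS = {"getannotations", "annotate"}

_VALID_TYPE_LABELS = {t.value for t in EntityType}


class ProtocolError(ValueError):
    """A request the client got wrong; carries the HTTP status to answer."""

    def __init__(self, status: int, message: str):
        super().__init__(message)
        self.status = status


class SourceResolutionError(KeyError):
    """A document source with no URL in the request or the configuration."""


class DocumentRef(BaseModel):
    document_id: str = Field(min_length=1)
    source: str = ""


class CustomParameters(BaseModel):
    servers: dict[str, str] = Field(default_factory=dict)
    apiurl: Optional[str] = None


class AnnotationRequest(BaseModel):
    """A validated getAnnotations request."""

    method: str = "getAnnotations"
    communication_id: str = Field(min_length=1)
    types: list[str] = Field(default_factory=lambda: sorted(_VALID_TYPE_LABELS))
    documents: list[DocumentRef] = Field(min_length=1)
    custom_parameters: CustomParameters = Field(default_factory=CustomParameters)

    @field_validator("communication_id", mode="before")
    @classmethod
    def _coerce_id(cls, v):
        return str(v)

    @field_validator("types")
    @classmethod
    def _check_types(cls, v: list[str]) -> list[str]:
        if not v:
            return sorted(_VALID_TYPE_LABELS)
        for label in v:
            if label == "PROTEIN":
                raise ValueError(
                    "the PROTEIN annotation type is not supported; gene/protein "
                    "mentions are annotated as GENE (the gene dictionary is "
                    "locus-based and includes ncRNAs)"
                )
            if label not in _VALID_TYPE_LABELS:
                raise ValueError(
                    f"unknown annotation type {label!r}; valid types: "
                    f"{', '.join(sorted(_VALID_TYPE_LABELS))}"
                )
        return v

    def entity_types(self) -> frozenset[EntityType]:
        return frozenset(EntityType(label) for label in self.types)


def parse_annotation_request(data: dict) -> AnnotationRequest:
    try:
        return AnnotationRequest.model_validate(data)
    except ValidationError as exc:
        raise ProtocolError(400, f"invalid annotation request: {exc.errors()[0]['msg']}") from exc


@dataclass(frozen=True)
class FetchFailure:
    """Marker for a document that could not be retrieved."""

    document_id: str
    source: str
    reason: str


FetchResult = Union[Document, FetchFailure]


def _http_post_json(url: str, obj: dict, timeout: float) -> dict:
    body = json.dumps(obj).encode("utf-8")
    req = urllib.request.Request(
        url, data=body, headers={"Content-Type": "application/json"}, method="POST"
    )
    with urllib.request.urlopen(req, timeout=timeout) as resp:
        return json.loads(resp.read().decode("utf-8"))


def fetch_documents(
    refs: Sequence[DocumentRef],
    servers_map: dict[str, str],
    batch_size: int = 100,
    timeout: float = 10.0,
) -> list[FetchResult]:
    """Fetch documents by identifier, one HTTP request per id batch.

    Output order matches ``refs``.  A failing batch yields
    :class:`FetchFailure` markers for its refs only; an unresolvable
    source raises :class:`SourceResolutionError` (a request-level error).
    """
    for ref in refs:
        if ref.source not in servers_map:
            raise SourceResolutionError(
                f"no document server configured for source {ref.source!r}"
            )
    results: dict[int, FetchResult] = {}
    # batch per source, preserving ref order within each source
    by_source: dict[str, list[int]] = {}
    for i, ref in enumerate(refs):
        by_source.setdefault(ref.source, []).append(i)
    for source, indices in by_source.items():
        url = servers_map[source]
        for b in range(0, len(indices), batch_size):
            batch = indices[b : b + batch_size]
            ids = [refs[i].document_id for i in batch]
            try:
                payload = _http_post_json(url, {"ids": ids}, timeout)
                found = {
                    d["document_id"]: Document(
                        document_id=d["document_id"],
                        title=d.get("title", ""),
                        abstract=d.get("abstract", ""),
                        source=source,
                    )
                    for d in payload.get("documents", [])
                }
                reason = "document not found"
            except (urllib.error.URLError, OSError, ValueError, KeyError) as exc:
                found = {}
                reason = f"fetch failed: {exc}"
            for i in batch:
                doc_id = refs[i].document_id
                if doc_id in found:
                    results[i] = found[doc_id]
                else:
                    logger.warning("document %s from %r: %s", doc_id, source, reason)
                    results[i] = FetchFailure(doc_id, source, reason)
    return [results[i] for i in range(len(refs))]


def annotation_to_wire(a: Annotation, inclusive_end: bool = False) -> dict:
    return {
        "document_id": a.document_id,
        "section": a.section,
        "init": a.start,
        "end": a.end - 1 if inclusive_end else a.end,
        "annotated_text": a.matched_text,
        "type": a.entity_type.value,
        "database_ids": [identifier for _code, identifier in a.identifiers],
    }


def build_payload(
    communication_id: str,
    results: Sequence[FetchResult],
    annotations: Sequence[list[Annotation]],
    state: str = "done",
    failure: Optional[str] = None,
    inclusive_end: bool = False,
) -> dict:
    """Assemble the callback body; every requested document is present,
    with an empty annotation list if nothing matched or its fetch failed."""
    documents = []
    for result, anns in zip(results, annotations):
        failed = isinstance(result, FetchFailure)
        documents.append(
            {
                "document_id": result.document_id,
                "source": result.source,
                "fetch_failed": failed,
                "annotations": [annotation_to_wire(a, inclusive_end) for a in anns],
            }
        )
    payload = {"communication_id": communication_id, "state": state, "documents": documents}
    if failure:
        payload["error"] = failure
    return payload


def deliver_annotations(
    url: str,
    payload: dict,
    retries: int = 3,
    backoff: float = 1.0,
    timeout: float = 10.0,
) -> bool:
    """POST the callback; up to ``retries`` attempts with doubling backoff."""
    delay = backoff
    for attempt in range(1, max(1, retries) + 1):
        try:
            body = json.dumps(payload).encode("utf-8")
            req = urllib.request.Request(
                url, data=body, headers={"Content-Type": "application/json"}, method="POST"
            )
            with urllib.request.urlopen(req, timeout=timeout) as resp:
                if 200 <= resp.status < 300:
                    return True
        except (urllib.error.URLError, OSError) as exc:
            logger.warning("callback to %s failed (attempt %d): %s", url, attempt, exc)
        if attempt < retries:
            time.sleep(delay)
            delay *= 2
    return False


@dataclass
class TagRequestState:
    """Runtime record of one annotation request moving through the stages."""

    communication_id: str
    request: AnnotationRequest
    state: str = "received"  # received|fetching|tagging|delivering|done|failed
    failure: Optional[str] = None
    results: list[FetchResult] = field(default_factory=list)
    annotations: list[list[Annotation]] = field(default_factory=list)
    delivered = None


class _ClientError(Exception):
    """Raised after the client has already been answered; fails the task."""


class AnnotationServer:
    """The full service: intake loop + staged engine + NER + protocol.

    The dictionary is loaded once, before the listen socket opens, and
    shared read-only by all tagging workers.
    """

    def __init__(self, dictionary: Dictionary, config: ServiceConfig | None = None):
        self.dictionary = dictionary
        self.config = config or ServiceConfig()
        self.engine = StageEngine(self.config.queue_config())
        for stage, handler in (
            ("parse", self._stage_parse),
            ("status", self._stage_status),
            ("download", self._stage_download),
            ("tag", self._stage_tag),
            ("deliver", self._stage_deliver),
        ):
            self.engine.register(stage, handler)
        self.intake = IntakeLoop(
            self.config.host,
            self.config.port,
            self._on_request,
            client_id_header=self.config.client_id_header,
        )
        self.requests: dict[str, TagRequestState] = {}
        self._requests_lock = threading.Lock()
        self.started_at: Optional[float] = None

    # -- lifecycle -----------------------------------------------------------

    def start(self) -> None:
        self.engine.start()
        self.intake.start()  # dictionary already in RAM before the port opens
        self.started_at = time.time()

    def stop(self, drain: bool = True, timeout: float = 30.0) -> None:
        self.intake.stop()
        self.engine.stop(drain=drain, timeout=timeout)

    @property
    def port(self) -> int:
        assert self.intake.port is not None, "server not started"
        return self.intake.port

    def __enter__(self) -> "AnnotationServer":
        self.start()
        return self

    def __exit__(self, *exc) -> None:
        self.stop()

    # -- intake --------------------------------------------------------------

    def _on_request(self, request: HttpRequest, respond: Responder) -> None:
        """Runs on the intake thread: admission + enqueue only."""
        try:
            task = self.engine.create_task(
                client_id=request.client_ip,
                payload={"respond": respond, "http": request},
                cost=len(request.body),
                on_finish=self._on_finish,
            )
        except RejectedRequest as exc:
            respond(exc.status, json.dumps({"error": exc.reason}).encode())
            return
        self.engine.submit(task, "parse")

    def _on_finish(self, task: Task) -> None:
        respond: Responder = task.payload["respond"]
        if not respond.answered:
            status = 500 if task.state == "failed" else 200
            message = str(task.error) if task.error else task.state
            respond(status, json.dumps({"error": message}).encode())

    # -- stage handlers --------------------------------------------------------

    def _stage_parse(self, task: Task) -> Optional[str]:
        respond: Responder = task.payload["respond"]
        http: HttpRequest = task.payload["http"]
        try:
            data = json.loads(http.body.decode("utf-8"))
            if not isinstance(data, dict):
                raise ValueError("request body must be a JSON object")
        except (ValueError, UnicodeDecodeError) as exc:
            respond(400, json.dumps({"error": f"invalid JSON: {exc}"}).encode())
            raise _ClientError(str(exc))
        method = str(data.get("method", "")).lower()
        if method in STATUS_METHODS or (not method and http.path.rstrip("/").endswith("status")):
            return "status"
        if method not in ANNOTATE_METHODS:
            respond(400, json.dumps({"error": f"unknown method {data.get('method')!r}"}).encode())
            raise _ClientError(f"unknown method {method!r}")
        try:
            req = parse_annotation_request(data)
        except ProtocolError as exc:
            respond(exc.status, json.dumps({"error": str(exc)}).encode())
            raise _ClientError(str(exc))
        extra = len(req.documents) * self.config.per_document_cost
        if not self.engine.add_cost(task, extra):
            respond(
                self.config.reject_limit_status,
                json.dumps({"error": "per-client memory budget exceeded"}).encode(),
            )
            raise _ClientError("memory budget exceeded")
        state = TagRequestState(communication_id=req.communication_id, request=req)
        task.payload["state"] = state
        with self._requests_lock:
            self.requests[req.communication_id] = state
        respond(
            200,
            json.dumps(
                {"communication_id": req.communication_id, "status": "accepted"}
            ).encode(),
        )
        return "download"

    def _stage_status(self, task: Task) -> None:
        respond: Responder = task.payload["respond"]
        respond(
            200,
            json.dumps(
                {
                    "state": "Running",
                    "version": VERSION,
                    "entities": len(self.dictionary),
                    "uptime_s": round(time.time() - (self.started_at or time.time()), 3),
                }
            ).encode(),
        )
        return None

    def _stage_download(self, task: Task) -> str:
        state: TagRequestState = task.payload["state"]
        state.state = "fetching"
        servers = {**self.config.servers, **state.request.custom_parameters.servers}
        try:
            state.results = fetch_documents(
                state.request.documents,
                servers,
                batch_size=self.config.fetch_batch_size,
                timeout=self.config.fetch_timeout,
            )
        except SourceResolutionError as exc:
            state.state = "failed"
            state.failure = str(exc)
            state.results = [
                FetchFailure(ref.document_id, ref.source, "source not resolved")
                for ref in state.request.documents
            ]
            state.annotations = [[] for _ in state.results]
        return "tag"

    def _stage_tag(self, task: Task) -> str:
        state: TagRequestState = task.payload["state"]
        if state.state != "failed":
            state.state = "tagging"
            types = state.request.entity_types()
            state.annotations = [
                tag(result, self.dictionary, types)
                if isinstance(result, Document)
                else []
                for result in state.results
            ]
        return "deliver"

    def _stage_deliver(self, task: Task) -> None:
        state: TagRequestState = task.payload["state"]
        url = state.request.custom_parameters.apiurl or self.config.apiurl
        if url is None:
            state.state = "failed"
            state.failure = "no apiurl in request or configuration"
            raise RuntimeError(state.failure)
        final_state = "failed" if state.state == "failed" else "done"
        payload = build_payload(
            state.communication_id,
            state.results,
            state.annotations,
            state=final_state,
            failure=state.failure,
            inclusive_end=self.config.inclusive_end,
        )
        if state.state != "failed":
            state.state = "delivering"
        ok = deliver_annotations(
            url,
            payload,
            retries=self.config.deliver_retries,
            backoff=self.config.deliver_backoff,
            timeout=self.config.fetch_timeout,
        )
        if ok and final_state == "done":
            state.state = "done"
        elif not ok:
            state.state = "failed"
            state.failure = state.failure or f"callback to {url} failed"
            raise RuntimeError(state.failure)
        return None
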