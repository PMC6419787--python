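"""In-process HTTP test doubles for the annotation pipeline.

:class:`MockDocumentServer` serves a synthetic corpus by identifier in
the document-server dialect; :class:`MockReceiver` records delivered
``saveAnnotations`` payloads and can be scripted to fail a number of
attempts first (for callback-retry tests).  Both bind an ephemeral port
and are context managers.
"""

from __future__ import annotations

import json
import threading
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from typing import Iterable

from .documents import Document

__all__ = ["MockDocumentServer", "MockReceiver"]


class _SilentHandler(BaseHTTPRequestHandler):
    def log_message(self, fmt, *args):  # keep test output clean
        pass

    def _read_json(self) -> dict:
        length = int(self.headers.get("Content-Length", "0"))
        return json.loads(self.rfile.read(length).decode("utf-8"))

    def _send_json(self, status: int, obj) -> None:
        body = json.dumps(obj).encode("utf-8")
        self.send_response(status)
        self.send_header("Content-Type", "application/json")
        self.send_header("Content-Length", str(len(body)))
        self.end_headers()
        self.wfile.write(body)


class MockDocumentServer:
    """Serves documents by id; unknown-only requests get a 404.

    ``fail_ids`` are withheld from responses (simulating per-document
    404s); ``fail_all`` makes every request answer 500.
    """

    def __init__(self, corpus: Iterable[Document]):
        self.corpus = {d.document_id: d for d in corpus}
        self.fail_ids: set[str] = set()
        self.fail_all = False
        self.delay = 0.0  # seconds to stall each response (for in-flight tests)
        self.request_count = 0
        self.requested_ids: list[list[str]] = []
        self._lock = threading.Lock()
        outer = self

        class Handler(_SilentHandler):
            def do_POST(self):
                with outer._lock:
                    outer.request_count += 1
                if outer.delay:
                    import time

                    time.sleep(outer.delay)
                if outer.fail_all:
                    self._send_json(500, {"error": "document server down"})
                    return
                try:
                    ids = self._read_json().get("ids", [])
                except (ValueError, KeyError):
                    self._send_json(400, {"error": "bad request"})
                    return
                with outer._lock:
                    outer.requested_ids.append(list(ids))
                found = [
                    outer.corpus[i]
                    for i in ids
                    if i in outer.corpus and i not in outer.fail_ids
                ]
                if ids and not found:
                    self._send_json(404, {"error": "no such documents"})
                    return
                self._send_json(
                    200,
                    {
                        "documents": [
                            {
                                "document_id": d.document_id,
                                "title": d.title,
                                "abstract": d.abstract,
                            }
                            for d in found
                        ]
                    },
                )

        self._server = ThreadingHTTPServer(("127.0.0.1", 0), Handler)
        self._thread = threading.Thread(target=self._server.serve_forever, daemon=True)

    @property
    def url(self) -> str:
        host, port = self._server.server_address[:2]
        return f"http://{host}:{port}/documents"

    def __enter__(self) -> "MockDocumentServer":
        self._thread.start()
        return self

    def __exit__(self, *exc) -> None:
        self._server.shutdown()
        self._server.server_close()


class MockReceiver:
    """Records callback payloads; optionally fails the first N attempts."""

    def __init__(self, fail_first: int = 0, fail_status: int = 500):
        self.payloads: list[dict] = []
        self.attempts = 0
        self._fail_remaining = fail_first
        self._fail_status = fail_status
        self._lock = threading.Lock()
        self._event = threading.Event()
        outer = self

        class Handler(_SilentHandler):
            def do_POST(self):
                with outer._lock:
                    outer.attempts += 1
                    fail = outer._fail_remaining > 0
                    if fail:
                        outer._fail_remaining -= 1
                if fail:
                    self._send_json(outer._fail_status, {"error": "scripted failure"})
                    return
                payload = self._read_json()
                with outer._lock:
                    outer.payloads.append(payload)
                outer._event.set()
                self._send_json(200, {"received": True})

        self._server = ThreadingHTTPServer(("127.0.0.1", 0), Handler)
        self._thread = threading.Thread(target=self._server.serve_forever, daemon=True)

    @property
    def url(self) -> str:
        host, port = self._server.server_address[:2]
        return f"http://{host}:{port}/saveAnnotations"

    def wait(self, n: int = 1, timeout: float = 30.0) -> bool:
        """Block until at least n payloads have been received."""
        deadline = threading.Event()
        import time

        end = time.monotonic() + timeout
        while time.monotonic() < end:
            with self._lock:
                if len(self.payloads) >= n:
                    return True
            self._event.wait(0.05)
            self._event.clear()
        with self._lock:
            return len(self.payloads) >= n

    def __enter__(self) -> "MockReceiver":
        self._thread.start()
        return self

    def __exit__(self, *exc) -> None:
        self._server.shutdown()
        self._server.server_close()
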