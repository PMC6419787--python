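"""Single-dispatcher HTTP intake built on ``selectors``.

One event loop owns the listening socket and every client connection:
it accumulates bytes per connection and hands a request to the
application callback only once the request is complete (headers plus
declared body), so no task can exist for a half-received request.
Responses queued by worker threads are written back through the same
selector, woken via a socket pair.  A connection that closes before its
request is complete is simply discarded — no task, buffers freed.

Deliberately minimal: HTTP/1.0-style one request per connection,
Content-Length bodies only (no chunked encoding), which is all the
annotation protocol needs.
"""

from __future__ import annotations

import logging
import selectors
import socket
import threading
from dataclasses import dataclass
from http import HTTPStatus
from typing import Callable, Optional

__all__ = ["HttpRequest", "Responder", "IntakeLoop"]

logger = logging.getLogger(__name__)

_MAX_HEADER_BYTES = 64 * 1024
_DEFAULT_MAX_BODY = 64 * 1024 * 1024


@dataclass
class HttpRequest:
    method: str
    path: str
    headers: dict[str, str]  # lower-cased keys
    body: bytes
    client_ip: str


class _Conn:
    __slots__ = ("sock", "addr", "inbuf", "outbuf", "request", "responded", "closing")

    def __init__(self, sock: socket.socket, addr):
        self.sock = sock
        self.addr = addr
        self.inbuf = b""
        self.outbuf = b""
        self.request: Optional[HttpRequest] = None
        self.responded = False
        self.closing = False


def _render_response(status: int, body: bytes, content_type: str) -> bytes:
    reason = HTTPStatus(status).phrase if status in HTTPStatus._value2member_map_ else "Status"
    head = (
        f"HTTP/1.1 {status} {reason}\r\n"
        f"Content-Type: {content_type}\r\n"
        f"Content-Length: {len(body)}\r\n"
        "Connection: close\r\n\r\n"
    )
    return head.encode("ascii") + body


class Responder:
    """Thread-safe handle for answering one request exactly once."""

    def __init__(self, loop: "IntakeLoop", conn: _Conn):
        self._loop = loop
        self._conn = conn
        self._sent = threading.Event()

    def __call__(
        self, status: int, body: bytes = b"", content_type: str = "application/json"
    ) -> None:
        if self._sent.is_set():
            return
        self._sent.set()
        self._loop._queue_response(self._conn, _render_response(status, body, content_type))

    @property
    def answered(self) -> bool:
        return self._sent.is_set()


class IntakeLoop:
    """The single event-driven reader/writer multiplexing all connections."""

    def __init__(
        self,
        host: str,
        port: int,
        on_request: Callable[[HttpRequest, Responder], None],
        client_id_header: Optional[str] = None,
        max_body_bytes: int = _DEFAULT_MAX_BODY,
    ):
        self._host = host
        self._requested_port = port
        self.on_request = on_request
        self.client_id_header = client_id_header.lower() if client_id_header else None
        self.max_body_bytes = max_body_bytes
        self._sel = selectors.DefaultSelector()
        self._listener: Optional[socket.socket] = None
        self._wake_r, self._wake_w = socket.socketpair()
        self._wake_r.setblocking(False)
        self._pending: list[tuple[_Conn, bytes]] = []
        self._pending_lock = threading.Lock()
        self._thread: Optional[threading.Thread] = None
        self._stop = threading.Event()
        self.port: Optional[int] = None

    # -- lifecycle -----------------------------------------------------------

    def start(self) -> None:
        lst = socket.socket(socket.AF_INET, socket.SOCK_STREAM)
        lst.setsockopt(socket.SOL_SOCKET, socket.SO_REUSEADDR, 1)
        lst.bind((self._host, self._requested_port))  # bind failure propagates
        lst.listen(128)
        lst.setblocking(False)
        self._listener = lst
        self.port = lst.getsockname()[1]
        self._sel.register(lst, selectors.EVENT_READ, ("accept", None))
        self._sel.register(self._wake_r, selectors.EVENT_READ, ("wake", None))
        self._thread = threading.Thread(target=self._run, name="intake", daemon=True)
        self._thread.start()

    def stop(self) -> None:
        self._stop.set()
        try:
            self._wake_w.send(b"x")
        except OSError:
            pass
        if self._thread is not None:
            self._thread.join(timeout=5.0)

    # -- worker-side ---------------------------------------------------------

    def _queue_response(self, conn: _Conn, payload: bytes) -> None:
        with self._pending_lock:
            self._pending.append((conn, payload))
        try:
            self._wake_w.send(b"x")
        except OSError:
            pass

    # -- event loop ----------------------------------------------------------

    def _run(self) -> None:
        try:
            while not self._stop.is_set():
                for key, events in self._sel.select(timeout=0.1):
                    kind, conn = key.data
                    if kind == "accept":
                        self._accept()
                    elif kind == "wake":
                        try:
                            self._wake_r.recv(4096)
                        except BlockingIOError:
                            pass
                        self._flush_pending()
                    else:
                        if events & selectors.EVENT_READ:
                            self._readable(key, conn)
                        if events & selectors.EVENT_WRITE and key.fd in self._sel.get_map():
                            self._writable(key, conn)
        finally:
            for key in list(self._sel.get_map().values()):
                if key.data and key.data[0] == "conn":
                    self._close(key.fileobj)
            if self._listener is not None:
                self._sel.unregister(self._listener)
                self._listener.close()
            self._sel.unregister(self._wake_r)
            self._wake_r.close()
            self._wake_w.close()
            self._sel.close()

    def _accept(self) -> None:
        assert self._listener is not None
        while True:
            try:
                sock, addr = self._listener.accept()
            except (BlockingIOError, OSError):
                return
            sock.setblocking(False)
            conn = _Conn(sock, addr)
            self._sel.register(sock, selectors.EVENT_READ, ("conn", conn))

    def _flush_pending(self) -> None:
        with self._pending_lock:
            pending, self._pending = self._pending, []
        for conn, payload in pending:
            if conn.sock.fileno() < 0:
                continue  # client went away before the response was ready
            conn.outbuf += payload
            conn.responded = True
            try:
                self._sel.modify(
                    conn.sock, selectors.EVENT_READ | selectors.EVENT_WRITE, ("conn", conn)
                )
            except KeyError:
                pass

    def _readable(self, key, conn: _Conn) -> None:
        try:
            data = conn.sock.recv(65536)
        except BlockingIOError:
            return
        except OSError:
            self._close(conn.sock)
            return
        if not data:
            # EOF: if the request never completed, discard silently
            if conn.request is None and not conn.responded:
                self._close(conn.sock)
            elif conn.responded and not conn.outbuf:
                self._close(conn.sock)
            return
        conn.inbuf += data
        if conn.request is not None:
            return  # trailing bytes after a complete request are ignored
        self._try_parse(conn)

    def _try_parse(self, conn: _Conn) -> None:
        buf = conn.inbuf
        head_end = buf.find(b"\r\n\r\n")
        if head_end < 0:
            if len(buf) > _MAX_HEADER_BYTES:
                self._reject(conn, 431)
            return
        head = buf[:head_end]
        try:
            lines = head.decode("iso-8859-1").split("\r\n")
            method, path, version = lines[0].split(" ", 2)
            if not version.startswith("HTTP/"):
                raise ValueError(version)
            headers: dict[str, str] = {}
            for line in lines[1:]:
                name, _, value = line.partition(":")
                if not _:
                    raise ValueError(line)
                headers[name.strip().lower()] = value.strip()
            length = int(headers.get("content-length", "0"))
            if length < 0:
                raise ValueError(length)
        except (ValueError, IndexError):
            self._reject(conn, 400)
            return
        if length > self.max_body_bytes:
            self._reject(conn, 413)
            return
        body_start = head_end + 4
        if len(buf) - body_start < length:
            return  # body incomplete; keep accumulating
        body = buf[body_start : body_start + length]
        conn.inbuf = b""
        client_ip = conn.addr[0]
        if self.client_id_header and self.client_id_header in headers:
            client_ip = headers[self.client_id_header]
        conn.request = HttpRequest(method, path, headers, body, client_ip)
        responder = Responder(self, conn)
        try:
            self.on_request(conn.request, responder)
        except Exception:
            logger.exception("request dispatch failed")
            responder(500, b'{"error": "internal server error"}')

    def _reject(self, conn: _Conn, status: int) -> None:
        conn.request = HttpRequest("", "", {}, b"", conn.addr[0])  # stop further parsing
        conn.outbuf += _render_response(status, b"", "text/plain")
        conn.responded = True
        try:
            self._sel.modify(
                conn.sock, selectors.EVENT_READ | selectors.EVENT_WRITE, ("conn", conn)
            )
        except KeyError:
            pass

    def _writable(self, key, conn: _Conn) -> None:
        if not conn.outbuf:
            return
        try:
            sent = conn.sock.send(conn.outbuf)
        except BlockingIOError:
            return
        except OSError:
            self._close(conn.sock)
            return
        conn.outbuf = conn.outbuf[sent:]
        if not conn.outbuf and conn.responded:
            self._close(conn.sock)

    def _close(self, sock: socket.socket) -> None:
        try:
            self._sel.unregister(sock)
        except (KeyError, ValueError):
            pass
        try:
            sock.close()
        except OSError:
            pass
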