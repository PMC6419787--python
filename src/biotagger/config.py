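"""Service configuration: flat INI file mapped onto one dataclass.

Example::

    [server]
    host = 127.0.0.1
    port = 8765

    [limits]
    per_client_max_requests = 8
    per_client_memory_budget = 67108864
    reject_limit_status = 429
    reject_queue_status = 503

    [stages]
    ; name = workers,capacity   (order here is the stage order)
    parse = 2,64
    status = 2,64
    download = 8,128
    tag = 2,128
    deliver = 4,128

    [fetch]
    batch_size = 100
    timeout = 10.0
    per_document_cost = 10240

    [deliver]
    retries = 3
    backoff = 1.0
    inclusive_end = false
    apiurl =

    [servers]
    ; default source -> document-server base URL routing
    ; ABSTRACT = http://example.org/docs
"""

from __future__ import annotations

import configparser
import os
from dataclasses import dataclass, field, replace

from .service import QueueConfig, StageConfig

__all__ = ["ServiceConfig", "DEFAULT_STAGES", "load_config"]

#: Stage order and default (workers, capacity): parsing and status
#: queries are cheap and must stay responsive; document downloads are
#: I/O-bound so many run in parallel; tagging is the CPU-heavy part and
#: is capped low; delivery is I/O again.
DEFAULT_STAGES: tuple[StageConfig, ...] = (
    StageConfig("parse", 2, 64),
    StageConfig("status", 2, 64),
    StageConfig("download", 8, 128),
    StageConfig("tag", 2, 128),
    StageConfig("deliver", 4, 128),
)

FAST_STAGES = frozenset({"status"})


@dataclass(frozen=True)
class ServiceConfig:
    host: str = "127.0.0.1"
    port: int = 8765
    client_id_header: str | None = None
    stages: tuple[StageConfig, ...] = DEFAULT_STAGES
    per_client_max_requests: int = 8
    per_client_memory_budget: int = 64 * 1024 * 1024
    reject_limit_status: int = 429
    reject_queue_status: int = 503
    fetch_batch_size: int = 100
    fetch_timeout: float = 10.0
    per_document_cost: int = 10 * 1024
    deliver_retries: int = 3
    deliver_backoff: float = 1.0
    inclusive_end: bool = False
    apiurl: str | None = None
    servers: dict[str, str] = field(default_factory=dict)

    def queue_config(self) -> QueueConfig:
        return QueueConfig(
            stages=self.stages,
            per_client_max_requests=self.per_client_max_requests,
            per_client_memory_budget=self.per_client_memory_budget,
            reject_limit_status=self.reject_limit_status,
            reject_queue_status=self.reject_queue_status,
            fast_stages=FAST_STAGES & {s.name for s in self.stages},
        )


def load_config(path: str | os.PathLike) -> ServiceConfig:
    parser = configparser.ConfigParser()
    parser.optionxform = str  # keep source names and header case intact
    read = parser.read(path, encoding="utf-8")
    if not read:
        raise FileNotFoundError(path)
    cfg = ServiceConfig()
    kwargs: dict = {}
    if parser.has_section("server"):
        s = parser["server"]
        kwargs["host"] = s.get("host", cfg.host)
        kwargs["port"] = s.getint("port", cfg.port)
        header = s.get("client_id_header", "").strip()
        kwargs["client_id_header"] = header or None
    if parser.has_section("limits"):
        s = parser["limits"]
        kwargs["per_client_max_requests"] = s.getint(
            "per_client_max_requests", cfg.per_client_max_requests
        )
        kwargs["per_client_memory_budget"] = s.getint(
            "per_client_memory_budget", cfg.per_client_memory_budget
        )
        kwargs["reject_limit_status"] = s.getint("reject_limit_status", cfg.reject_limit_status)
        kwargs["reject_queue_status"] = s.getint("reject_queue_status", cfg.reject_queue_status)
    if parser.has_section("stages"):
        stages = []
        for name, value in parser.items("stages"):
            workers, _, capacity = value.partition(",")
            stages.append(StageConfig(name, int(workers), int(capacity or 64)))
        kwargs["stages"] = tuple(stages)
    if parser.has_section("fetch"):
        s = parser["fetch"]
        kwargs["fetch_batch_size"] = s.getint("batch_size", cfg.fetch_batch_size)
        kwargs["fetch_timeout"] = s.getfloat("timeout", cfg.fetch_timeout)
        kwargs["per_document_cost"] = s.getint("per_document_cost", cfg.per_document_cost)
    if parser.has_section("deliver"):
        s = parser["deliver"]
        kwargs["deliver_retries"] = s.getint("retries", cfg.deliver_retries)
        kwargs["deliver_backoff"] = s.getfloat("backoff", cfg.deliver_backoff)
        kwargs["inclusive_end"] = s.getboolean("inclusive_end", cfg.inclusive_end)
        apiurl = s.get("apiurl", "").strip()
        kwargs["apiurl"] = apiurl or None
    if parser.has_section("servers"):
        kwargs["servers"] = dict(parser.items("servers"))
    return replace(cfg, **kwargs)
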