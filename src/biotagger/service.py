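"""Staged task queues with bounded worker pools and admission control.

A request moves through an ordered list of *stages* (e.g. parse →
download → tag → deliver), each backed by its own FIFO queue and a fixed
pool of worker threads.  Separate pools are the resource-control lever:
many cheap download tasks may run in parallel while CPU-heavy tagging is
capped at a small count, and fast stages (status queries) are never
queued behind heavy work.

Admission control enforces per-client budgets *before* a task exists:
a client exceeding its simultaneous-request count or memory budget, or
arriving while the entry queue is full, is rejected with a configurable
HTTP status code.  A supervisor thread restarts worker threads that
crash; the task a dead worker was running is marked failed and its
client's accounting is released exactly once.
"""

from __future__ import annotations

import itertools
import logging
import queue
import threading
import time
from dataclasses import dataclass
from typing import Callable, Optional

__all__ = [
    "StageConfig",
    "QueueConfig",
    "Task",
    "RejectedRequest",
    "WorkerCrash",
    "StageEngine",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StageConfig:
    name: str
    workers: int = 1
    capacity: int = 64

    def __post_init__(self):
        if self.workers < 1 or self.capacity < 1:
            raise ValueError("stage worker count and capacity must be >= 1")


@dataclass(frozen=True)
class QueueConfig:
    """Worker counts, queue capacities, and per-client budgets."""

    stages: tuple[StageConfig, ...]
    per_client_max_requests: int = 8
    per_client_memory_budget: int = 64 * 1024 * 1024  # bytes
    reject_limit_status: int = 429  # per-client budget breached
    reject_queue_status: int = 503  # entry queue full
    fast_stages: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.stages:
            raise ValueError("at least one stage is required")
        if self.per_client_max_requests < 1 or self.per_client_memory_budget < 1:
            raise ValueError("per-client limits must be >= 1")
        names = [s.name for s in self.stages]
        if len(set(names)) != len(names):
            raise ValueError("duplicate stage names")
        unknown_fast = self.fast_stages - set(names)
        if unknown_fast:
            raise ValueError(f"fast_stages not in stages: {sorted(unknown_fast)}")


class RejectedRequest(Exception):
    """Admission refused; carries the HTTP status to answer with."""

    def __init__(self, status: int, reason: str):
        super().__init__(f"{status}: {reason}")
        self.status = status
        self.reason = reason


class WorkerCrash(BaseException):
    """Escapes the per-task exception guard and kills the worker thread.

    Raised by fault-injection tests (and nothing else) to exercise the
    supervisor's restart path; derives from BaseException on purpose.
    """


class Task:
    """One admitted request moving through the stage order."""

    __slots__ = (
        "task_id", "client_id", "payload", "cost", "stage", "state",
        "error", "on_finish", "timings", "_released",
    )

    def __init__(self, task_id: int, client_id: str, payload, cost: int, on_finish=None):
        self.task_id = task_id
        self.client_id = client_id
        self.payload = payload
        self.cost = cost
        self.stage: Optional[str] = None
        self.state = "queued"  # queued | running | done | failed | rejected
        self.error: Optional[BaseException] = None
        self.on_finish: Optional[Callable[["Task"], None]] = on_finish
        self.timings: list[tuple[str, float, float]] = []
        self._released = False


class _StageRuntime:
    def __init__(self, cfg: StageConfig):
        self.cfg = cfg
        self.queue: queue.Queue = queue.Queue(maxsize=cfg.capacity)
        self.workers: list[threading.Thread] = []
        self.running = 0
        self.peak_running = 0


class StageEngine:
    """The queue/worker machinery; handlers are registered per stage.

    A handler receives the task and returns the name of the next stage
    to advance to, or ``None`` when the task is finished.  Advancing may
    skip stages but never go backward in the configured order.
    """

    _SENTINEL = object()

    def __init__(self, config: QueueConfig):
        self.config = config
        self._order = {s.name: i for i, s in enumerate(config.stages)}
        self._stages = {s.name: _StageRuntime(s) for s in config.stages}
        self._entry_stage = config.stages[0].name
        self._handlers: dict[str, Callable[[Task], Optional[str]]] = {}
        self._lock = threading.Lock()
        self._ids = itertools.count(1)
        self._inflight: dict[str, int] = {}
        self._memory: dict[str, int] = {}
        self._accepted = 0
        self._done = 0
        self._failed = 0
        self._quiescent = threading.Condition(self._lock)
        self._stop = threading.Event()
        self._supervisor: Optional[threading.Thread] = None
        self._current: dict[threading.Thread, Optional[Task]] = {}

    # -- lifecycle ---------------------------------------------------------

    def register(self, stage: str, handler: Callable[[Task], Optional[str]]) -> None:
        if stage not in self._stages:
            raise KeyError(f"unknown stage {stage!r}")
        self._handlers[stage] = handler

    def start(self) -> None:
        self._stop.clear()
        for rt in self._stages.values():
            while len(rt.workers) < rt.cfg.workers:
                self._spawn_worker(rt)
        self._supervisor = threading.Thread(
            target=self._supervise, name="supervisor", daemon=True
        )
        self._supervisor.start()

    def stop(self, drain: bool = True, timeout: float = 30.0) -> None:
        if drain:
            self.wait_quiescent(timeout)
        self._stop.set()
        for rt in self._stages.values():
            for _ in rt.workers:
                try:
                    rt.queue.put_nowait(self._SENTINEL)
                except queue.Full:
                    pass
        for rt in self._stages.values():
            for w in rt.workers:
                w.join(timeout=2.0)
        if self._supervisor is not None:
            self._supervisor.join(timeout=2.0)

    # -- admission ---------------------------------------------------------

    def admit(self, client_id: str, estimated_cost: int = 0) -> Optional[int]:
        """Return None to accept, or the rejection HTTP status."""
        with self._lock:
            return self._admit_locked(client_id, estimated_cost)

    def _admit_locked(self, client_id: str, estimated_cost: int) -> Optional[int]:
        cfg = self.config
        if self._inflight.get(client_id, 0) >= cfg.per_client_max_requests:
            return cfg.reject_limit_status
        if self._memory.get(client_id, 0) + estimated_cost > cfg.per_client_memory_budget:
            return cfg.reject_limit_status
        if self._stages[self._entry_stage].queue.full():
            return cfg.reject_queue_status
        return None

    def create_task(
        self,
        client_id: str,
        payload,
        cost: int = 0,
        on_finish: Optional[Callable[[Task], None]] = None,
    ) -> Task:
        """Atomically admit and account a new task (not yet submitted)."""
        with self._lock:
            status = self._admit_locked(client_id, cost)
            if status is not None:
                raise RejectedRequest(status, "admission refused")
            self._inflight[client_id] = self._inflight.get(client_id, 0) + 1
            self._memory[client_id] = self._memory.get(client_id, 0) + cost
            self._accepted += 1
            return Task(next(self._ids), client_id, payload, cost, on_finish)

    def add_cost(self, task: Task, extra: int) -> bool:
        """Grow a task's tracked memory; False if the budget is exceeded."""
        with self._lock:
            if (
                self._memory.get(task.client_id, 0) + extra
                > self.config.per_client_memory_budget
            ):
                return False
            self._memory[task.client_id] = self._memory.get(task.client_id, 0) + extra
            task.cost += extra
        return True

    # -- queue movement ----------------------------------------------------

    def submit(self, task: Task, stage: Optional[str] = None) -> None:
        stage = stage or self._entry_stage
        if stage not in self._stages:
            raise KeyError(f"unknown stage {stage!r}")
        task.stage = stage
        task.state = "queued"
        self._stages[stage].queue.put(task)

    def _advance(self, task: Task, next_stage: str) -> None:
        if next_stage not in self._stages:
            raise ValueError(f"unknown stage {next_stage!r}")
        if self._order[next_stage] <= self._order[task.stage]:
            raise ValueError(
                f"cannot advance from {task.stage!r} to earlier/same stage {next_stage!r}"
            )
        task.stage = next_stage
        task.state = "queued"
        self._stages[next_stage].queue.put(task)

    def _finish(self, task: Task, state: str, error: Optional[BaseException] = None) -> None:
        with self._lock:
            if task._released:
                return
            task._released = True
            task.state = state
            task.error = error
            self._inflight[task.client_id] = max(0, self._inflight.get(task.client_id, 0) - 1)
            self._memory[task.client_id] = max(0, self._memory.get(task.client_id, 0) - task.cost)
            if state == "done":
                self._done += 1
            else:
                self._failed += 1
            self._quiescent.notify_all()
        if task.on_finish is not None:
            try:
                task.on_finish(task)
            except Exception:
                logger.exception("on_finish callback failed for task %d", task.task_id)

    # -- workers and supervision -------------------------------------------

    def _spawn_worker(self, rt: _StageRuntime) -> None:
        w = threading.Thread(
            target=self._worker_loop,
            args=(rt,),
            name=f"worker-{rt.cfg.name}-{len(rt.workers)}",
            daemon=True,
        )
        rt.workers.append(w)
        w.start()

    def _worker_loop(self, rt: _StageRuntime) -> None:
        me = threading.current_thread()
        try:
            self._worker_loop_inner(rt, me)
        except WorkerCrash:
            pass  # the thread dies; the supervisor replaces it
        finally:
            # normal shutdown or crash: if we died holding a task, fail it
            task = self._current.get(me)
            if task is not None:
                self._finish(task, "failed", RuntimeError("worker crashed mid-task"))
                self._current[me] = None

    def _worker_loop_inner(self, rt: _StageRuntime, me: threading.Thread) -> None:
        while not self._stop.is_set():
            try:
                task = rt.queue.get(timeout=0.05)
            except queue.Empty:
                continue
            if task is self._SENTINEL:
                return
            self._current[me] = task
            task.state = "running"
            t0 = time.monotonic()
            with self._lock:
                rt.running += 1
                rt.peak_running = max(rt.peak_running, rt.running)
            try:
                handler = self._handlers.get(rt.cfg.name)
                if handler is None:
                    raise RuntimeError(f"no handler registered for stage {rt.cfg.name!r}")
                next_stage = handler(task)
                if next_stage is None:
                    self._finish(task, "done")
                else:
                    self._advance(task, next_stage)
            except WorkerCrash:
                raise  # dies mid-task; _worker_loop's finally fails the task
            except Exception as exc:
                logger.warning(
                    "task %d failed in stage %s: %r", task.task_id, rt.cfg.name, exc
                )
                self._finish(task, "failed", exc)
            finally:
                with self._lock:
                    rt.running -= 1
                task.timings.append((rt.cfg.name, t0, time.monotonic()))
                if task.state != "running":
                    self._current[me] = None

    def _supervise(self) -> None:
        """Replace dead workers so each pool keeps its configured size."""
        while not self._stop.is_set():
            for rt in self._stages.values():
                dead = [w for w in rt.workers if not w.is_alive()]
                if dead:
                    for w in dead:
                        rt.workers.remove(w)
                        self._current.pop(w, None)
                    while len(rt.workers) < rt.cfg.workers:
                        self._spawn_worker(rt)
            self._stop.wait(0.02)

    # -- introspection -----------------------------------------------------

    def wait_quiescent(self, timeout: float = 30.0) -> bool:
        """Block until accepted == done + failed (or timeout)."""
        deadline = time.monotonic() + timeout
        with self._quiescent:
            while self._accepted != self._done + self._failed:
                remaining = deadline - time.monotonic()
                if remaining <= 0:
                    return False
                self._quiescent.wait(remaining)
        return True

    @property
    def counters(self) -> dict:
        with self._lock:
            return {
                "accepted": self._accepted,
                "done": self._done,
                "failed": self._failed,
                "inflight": dict(self._inflight),
                "memory": dict(self._memory),
            }

    def peak_concurrency(self, stage: str) -> int:
        return self._stages[stage].peak_running

    def pool_size(self, stage: str) -> int:
        return sum(1 for w in self._stages[stage].workers if w.is_alive())
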