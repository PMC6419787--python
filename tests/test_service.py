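"""Staged queue engine: admission, concurrency caps, conservation,
supervision, and responsiveness ordering."""

import threading
import time

import pytest

from biotagger.service import (
    QueueConfig,
    RejectedRequest,
    StageConfig,
    StageEngine,
    WorkerCrash,
)


def two_stage_config(**kw):
    return QueueConfig(
        stages=(StageConfig("download", 8, 600), StageConfig("tag", 2, 600)),
        **kw,
    )


@pytest.fixture()
def engine():
    eng = StageEngine(two_stage_config())
    yield eng
    eng.stop(drain=False, timeout=2.0)


class TestAdmission:
    def test_per_client_request_limit(self):
        eng = StageEngine(two_stage_config(per_client_max_requests=2))
        t1 = eng.create_task("10.0.0.1", {})
        t2 = eng.create_task("10.0.0.1", {})
        with pytest.raises(RejectedRequest) as exc:
            eng.create_task("10.0.0.1", {})
        assert exc.value.status == 429

    def test_distinct_clients_independent(self):
        eng = StageEngine(two_stage_config(per_client_max_requests=1))
        eng.create_task("10.0.0.1", {})
        eng.create_task("10.0.0.2", {})  # must not raise

    def test_memory_budget(self):
        eng = StageEngine(two_stage_config(per_client_memory_budget=1000))
        eng.create_task("c", {}, cost=800)
        with pytest.raises(RejectedRequest) as exc:
            eng.create_task("c", {}, cost=300)
        assert exc.value.status == 429
        eng.create_task("other", {}, cost=900)  # other client unaffected

    def test_full_entry_queue_rejects(self):
        cfg = QueueConfig(stages=(StageConfig("only", 1, 2),), reject_queue_status=503)
        eng = StageEngine(cfg)
        # not started: nothing drains the queue
        for i in range(2):
            eng.submit(eng.create_task(f"c{i}", {}))
        assert eng.admit("anyone") == 503

    def test_configured_status_codes(self):
        eng = StageEngine(two_stage_config(per_client_max_requests=1, reject_limit_status=420))
        eng.create_task("c", {})
        with pytest.raises(RejectedRequest) as exc:
            eng.create_task("c", {})
        assert exc.value.status == 420


class TestStageFlow:
    def test_concurrency_caps_under_storm(self):
        """500 tasks through download(8) -> tag(2): caps never exceeded,
        everything completes, client accounting returns to zero."""
        eng = StageEngine(two_stage_config(per_client_max_requests=600))
        eng.register("download", lambda task: "tag")

        def do_tag(task):
            time.sleep(0.0005)
            return None

        eng.register("tag", do_tag)
        eng.start()
        try:
            for i in range(500):
                eng.submit(eng.create_task(f"client{i % 5}", {"i": i}))
            assert eng.wait_quiescent(timeout=60.0)
            counters = eng.counters
            assert counters["done"] == 500 and counters["failed"] == 0
            assert all(v == 0 for v in counters["inflight"].values())
            assert all(v == 0 for v in counters["memory"].values())
            assert eng.peak_concurrency("tag") <= 2
            assert eng.peak_concurrency("download") <= 8
        finally:
            eng.stop(drain=False)

    def test_backward_advance_fails_task(self):
        eng = StageEngine(two_stage_config())
        # a handler advancing to an earlier stage is a programming error
        eng.register("tag", lambda task: "download")
        eng.register("download", lambda task: None)
        eng.start()
        try:
            t = eng.create_task("c", {})
            eng.submit(t, "tag")
            assert eng.wait_quiescent(5.0)
            assert t.state == "failed"
        finally:
            eng.stop(drain=False)

    def test_completion_releases_exactly_one_slot(self):
        eng = StageEngine(two_stage_config())
        eng.register("download", lambda task: None)
        eng.start()
        try:
            t = eng.create_task("c", {})
            assert eng.counters["inflight"]["c"] == 1
            eng.submit(t)
            assert eng.wait_quiescent(5.0)
            assert eng.counters["inflight"]["c"] == 0
        finally:
            eng.stop(drain=False)


class TestSupervision:
    def test_handler_exception_fails_only_that_task(self):
        eng = StageEngine(two_stage_config())
        results = []

        def handler(task):
            if task.payload["i"] == 2:
                raise ValueError("plugin bug")
            results.append(task.payload["i"])
            return None

        eng.register("download", handler)
        eng.start()
        try:
            tasks = [eng.create_task("c", {"i": i}) for i in range(5)]
            for t in tasks:
                eng.submit(t)
            assert eng.wait_quiescent(5.0)
            counters = eng.counters
            assert counters["done"] == 4 and counters["failed"] == 1
            assert sorted(results) == [0, 1, 3, 4]
            assert tasks[2].state == "failed"
            assert eng.pool_size("download") == 8
        finally:
            eng.stop(drain=False)

    def test_worker_crash_restores_pool_and_fails_task(self):
        eng = StageEngine(two_stage_config())

        def handler(task):
            if task.payload.get("kill"):
                raise WorkerCrash("injected")
            return None

        eng.register("download", handler)
        eng.start()
        try:
            # kill a worker twice in a row
            for _ in range(2):
                t = eng.create_task("c", {"kill": True})
                eng.submit(t)
                assert eng.wait_quiescent(5.0)
                assert t.state == "failed"
            deadline = time.monotonic() + 5.0
            while eng.pool_size("download") != 8 and time.monotonic() < deadline:
                time.sleep(0.02)
            assert eng.pool_size("download") == 8
            # pool still works afterwards
            ok = eng.create_task("c", {})
            eng.submit(ok)
            assert eng.wait_quiescent(5.0)
            assert ok.state == "done"
            assert eng.counters["inflight"]["c"] == 0
        finally:
            eng.stop(drain=False)


class TestResponsiveness:
    def test_fast_stage_completes_before_saturated_batch(self):
        cfg = QueueConfig(
            stages=(StageConfig("status", 1, 64), StageConfig("tag", 1, 600)),
            fast_stages=frozenset({"status"}),
            per_client_max_requests=600,
        )
        eng = StageEngine(cfg)
        order = []
        lock = threading.Lock()

        def slow_tag(task):
            time.sleep(0.005)
            with lock:
                order.append(("tag", task.payload["i"]))
            return None

        def fast_status(task):
            with lock:
                order.append(("status", task.payload["i"]))
            return None

        eng.register("tag", slow_tag)
        eng.register("status", fast_status)
        eng.start()
        try:
            for i in range(100):
                eng.submit(eng.create_task("batch", {"i": i}), "tag")
            status_task = eng.create_task("interactive", {"i": -1})
            eng.submit(status_task, "status")
            assert eng.wait_quiescent(30.0)
            status_pos = order.index(("status", -1))
            last_tag_pos = max(i for i, e in enumerate(order) if e[0] == "tag")
            assert status_pos < last_tag_pos, "status answered before the batch finished"
        finally:
            eng.stop(drain=False)
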