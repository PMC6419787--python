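"""Annotation protocol: status, async pipeline, routing overrides,
callback retries, partial failures, end-to-end equivalence."""

import json
import urllib.error
import urllib.request

import pytest

from biotagger.config import ServiceConfig
from biotagger.dictionary import EntityType
from biotagger.fixtures import FixtureSpec, make_corpus, make_dictionary
from biotagger.mocks import MockDocumentServer, MockReceiver
from biotagger.ner import tag
from biotagger.protocol import (
    AnnotationServer,
    DocumentRef,
    FetchFailure,
    ProtocolError,
    SourceResolutionError,
    fetch_documents,
    parse_annotation_request,
)


def post_json(url: str, obj: dict, client: str | None = None):
    headers = {"Content-Type": "application/json"}
    if client:
        headers["X-Client-Id"] = client
    req = urllib.request.Request(url, data=json.dumps(obj).encode(), headers=headers)
    try:
        with urllib.request.urlopen(req, timeout=15) as resp:
            return resp.status, json.loads(resp.read().decode())
    except urllib.error.HTTPError as exc:
        body = exc.read().decode() or "{}"
        return exc.code, json.loads(body)


def annotation_request(docs, ds_url, rx_url, comm_id="c1", types=None, source="SYN"):
    req = {
        "method": "getAnnotations",
        "communication_id": comm_id,
        "documents": [{"document_id": d.document_id, "source": source} for d in docs],
        "custom_parameters": {"servers": {source: ds_url}, "apiurl": rx_url},
    }
    if types is not None:
        req["types"] = types
    return req


class TestRequestParsing:
    def test_protein_type_rejected(self):
        with pytest.raises(ProtocolError, match="PROTEIN.*not supported"):
            parse_annotation_request(
                {
                    "communication_id": "x",
                    "types": ["PROTEIN"],
                    "documents": [{"document_id": "d", "source": "S"}],
                }
            )

    def test_zero_documents_rejected(self):
        with pytest.raises(ProtocolError):
            parse_annotation_request({"communication_id": "x", "documents": []})

    def test_unknown_type_rejected(self):
        with pytest.raises(ProtocolError, match="unknown annotation type"):
            parse_annotation_request(
                {
                    "communication_id": "x",
                    "types": ["RIBOSOME"],
                    "documents": [{"document_id": "d", "source": "S"}],
                }
            )

    def test_types_default_to_all_six(self):
        req = parse_annotation_request(
            {"communication_id": "x", "documents": [{"document_id": "d", "source": "S"}]}
        )
        assert req.entity_types() == frozenset(EntityType)


class TestFetchDocuments:
    def test_batching_one_request_per_batch(self, seed7_corpus):
        docs, _ = seed7_corpus
        refs = [DocumentRef(document_id=d.document_id, source="SYN") for d in docs[:10]]
        with MockDocumentServer(docs) as ds:
            out = fetch_documents(refs, {"SYN": ds.url}, batch_size=10)
            assert ds.request_count == 1
            out2 = fetch_documents(refs, {"SYN": ds.url}, batch_size=3)
            assert ds.request_count == 1 + 4
        assert [d.document_id for d in out] == [r.document_id for r in refs]
        assert out == out2

    def test_missing_id_fails_only_itself(self, seed7_corpus):
        docs, _ = seed7_corpus
        refs = [
            DocumentRef(document_id=docs[0].document_id, source="SYN"),
            DocumentRef(document_id="NO-SUCH-DOC", source="SYN"),
            DocumentRef(document_id=docs[1].document_id, source="SYN"),
        ]
        with MockDocumentServer(docs) as ds:
            out = fetch_documents(refs, {"SYN": ds.url})
        assert out[0].title == docs[0].title
        assert isinstance(out[1], FetchFailure)
        assert out[2].title == docs[1].title

    def test_unresolvable_source_raises(self):
        with pytest.raises(SourceResolutionError):
            fetch_documents([DocumentRef(document_id="d", source="MYSTERY")], {})

    def test_server_error_marks_batch_failed(self, seed7_corpus):
        docs, _ = seed7_corpus
        refs = [DocumentRef(document_id=d.document_id, source="SYN") for d in docs[:3]]
        with MockDocumentServer(docs) as ds:
            ds.fail_all = True
            out = fetch_documents(refs, {"SYN": ds.url})
        assert all(isinstance(r, FetchFailure) for r in out)


class TestServerPipeline:
    def test_status_ok_and_malformed_json(self, seed7_dictionary, fast_config):
        with AnnotationServer(seed7_dictionary, fast_config) as srv:
            url = f"http://127.0.0.1:{srv.port}/"
            status, body = post_json(url, {"method": "getStatus"})
            assert status == 200 and body["state"] == "Running"
            req = urllib.request.Request(
                url, data=b"this is not json", headers={"Content-Type": "application/json"}
            )
            with pytest.raises(urllib.error.HTTPError) as exc:
                urllib.request.urlopen(req, timeout=10)
            assert exc.value.code == 400

    def test_end_to_end_equals_direct_tagging(self, seed7_dictionary, seed7_corpus, fast_config):
        docs, _ = seed7_corpus
        with MockDocumentServer(docs) as ds, MockReceiver() as rx, AnnotationServer(
            seed7_dictionary, fast_config
        ) as srv:
            url = f"http://127.0.0.1:{srv.port}/"
            status, ack = post_json(url, annotation_request(docs, ds.url, rx.url))
            assert status == 200 and ack["status"] == "accepted"
            assert rx.wait(1, timeout=30)
        payload = rx.payloads[0]
        assert payload["communication_id"] == "c1"
        assert payload["state"] == "done"
        assert len(payload["documents"]) == len(docs)
        # protocol output must equal direct engine output, document by document
        for doc, entry in zip(docs, payload["documents"]):
            direct = tag(doc, seed7_dictionary)
            assert entry["document_id"] == doc.document_id
            got = [
                (a["section"], a["init"], a["end"], a["annotated_text"], a["type"], tuple(a["database_ids"]))
                for a in entry["annotations"]
            ]
            want = [
                (
                    a.section,
                    a.start,
                    a.end,
                    a.matched_text,
                    a.entity_type.value,
                    tuple(i for _c, i in a.identifiers),
                )
                for a in direct
            ]
            assert got == want

    def test_type_restriction_honored(self, seed7_dictionary, seed7_corpus, fast_config):
        docs, _ = seed7_corpus
        with MockDocumentServer(docs) as ds, MockReceiver() as rx, AnnotationServer(
            seed7_dictionary, fast_config
        ) as srv:
            url = f"http://127.0.0.1:{srv.port}/"
            post_json(url, annotation_request(docs[:5], ds.url, rx.url, types=["CHEMICAL"]))
            assert rx.wait(1, timeout=30)
        for entry in rx.payloads[0]["documents"]:
            assert all(a["type"] == "CHEMICAL" for a in entry["annotations"])

    def test_fetch_failure_isolated_to_affected_documents(
        self, seed7_dictionary, seed7_corpus, fast_config
    ):
        docs, _ = seed7_corpus
        with MockDocumentServer(docs) as ds, MockReceiver() as rx, AnnotationServer(
            seed7_dictionary, fast_config
        ) as srv:
            ds.fail_ids = {docs[2].document_id}
            url = f"http://127.0.0.1:{srv.port}/"
            post_json(url, annotation_request(docs[:5], ds.url, rx.url))
            assert rx.wait(1, timeout=30)
        entries = rx.payloads[0]["documents"]
        assert entries[2]["fetch_failed"] is True and entries[2]["annotations"] == []
        for i in (0, 1, 3, 4):
            assert entries[i]["fetch_failed"] is False
            assert len(entries[i]["annotations"]) == len(tag(docs[i], seed7_dictionary))

    def test_unknown_source_reports_failed_state_to_callback(
        self, seed7_dictionary, seed7_corpus, fast_config
    ):
        docs, _ = seed7_corpus
        with MockReceiver() as rx, AnnotationServer(seed7_dictionary, fast_config) as srv:
            url = f"http://127.0.0.1:{srv.port}/"
            req = {
                "method": "getAnnotations",
                "communication_id": "cX",
                "documents": [{"document_id": docs[0].document_id, "source": "UNROUTED"}],
                "custom_parameters": {"apiurl": rx.url},
            }
            status, _ = post_json(url, req)
            assert status == 200  # parse succeeded; failure is asynchronous
            assert rx.wait(1, timeout=30)
        assert rx.payloads[0]["state"] == "failed"
        assert "UNROUTED" in rx.payloads[0]["error"]

    def test_callback_retries_until_success(self, seed7_dictionary, seed7_corpus, fast_config):
        docs, _ = seed7_corpus
        with MockDocumentServer(docs) as ds, MockReceiver(fail_first=2) as rx, AnnotationServer(
            seed7_dictionary, fast_config
        ) as srv:
            url = f"http://127.0.0.1:{srv.port}/"
            post_json(url, annotation_request(docs[:2], ds.url, rx.url, comm_id="retry1"))
            assert rx.wait(1, timeout=30)
            assert srv.engine.wait_quiescent(10.0)
            assert rx.attempts == 3
            assert srv.requests["retry1"].state == "done"

    def test_servers_and_apiurl_overrides_are_observed(
        self, seed7_dictionary, seed7_corpus, fast_config
    ):
        """Fetches hit the per-request server URL and the callback hits the
        per-request apiurl, even when the config names different defaults."""
        from dataclasses import replace

        docs, _ = seed7_corpus
        config = replace(
            fast_config,
            servers={"SYN": "http://127.0.0.1:1/nowhere"},
            apiurl="http://127.0.0.1:1/nowhere",
        )
        with MockDocumentServer(docs) as ds, MockReceiver() as rx, AnnotationServer(
            seed7_dictionary, config
        ) as srv:
            url = f"http://127.0.0.1:{srv.port}/"
            post_json(url, annotation_request(docs[:3], ds.url, rx.url, comm_id="ovr"))
            assert rx.wait(1, timeout=30)
            assert ds.request_count == 1, "override server URL was used for the fetch"
        assert rx.payloads[0]["communication_id"] == "ovr"

    def test_admission_limit_then_distinct_client_ok(self, seed7_dictionary, seed7_corpus):
        docs, _ = seed7_corpus
        config = ServiceConfig(
            port=0,
            per_client_max_requests=1,
            client_id_header="X-Client-Id",
            deliver_backoff=0.05,
        )
        with MockDocumentServer(docs) as ds, MockReceiver() as rx, AnnotationServer(
            seed7_dictionary, config
        ) as srv:
            ds.delay = 1.0  # keep alice's first request in flight
            url = f"http://127.0.0.1:{srv.port}/"
            status1, _ = post_json(
                url, annotation_request(docs[:2], ds.url, rx.url, comm_id="slot"), client="alice"
            )
            assert status1 == 200
            # second simultaneous request from the same client: rejected
            status2, body2 = post_json(
                url, annotation_request(docs[:2], ds.url, rx.url, comm_id="s2"), client="alice"
            )
            assert status2 == 429
            # a different client is unaffected
            status3, _ = post_json(
                url, annotation_request(docs[:2], ds.url, rx.url, comm_id="s3"), client="bob"
            )
            assert status3 == 200
            assert rx.wait(2, timeout=30)
            assert srv.engine.wait_quiescent(10.0)
            inflight = srv.engine.counters["inflight"]
            assert inflight.get("alice", 0) == 0 and inflight.get("bob", 0) == 0
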