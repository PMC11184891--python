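"""Proxy coordination: polling, authorization, dispatch, balancing, outputs."""

import os

import pytest

from rwdsandbox.fixtures import CohortQuery, Predicate, generate_datamart, \
    default_patient_schema
from rwdsandbox.harness import ReferenceClient
from rwdsandbox.proxy import ProcessorState
from rwdsandbox.token_core import CadenceSpec, parse_token


class TestPolling:
    def test_two_new_entries_yield_two_requests_and_acks(self, deployment, client):
        client.submit("p1")
        client.submit("p2")
        requests = deployment.proxy.poll_channels()
        assert sorted(r.job_id for r in requests) == ["p1", "p2"]
        acks = [m for m in client.poll() if m.code == "info.queued.ack"]
        assert len(acks) == 2

    def test_repoll_without_new_entries_is_empty(self, deployment, client):
        client.submit("p1")
        deployment.proxy.poll_channels()
        assert deployment.proxy.poll_channels() == []

    def test_missing_detail_file_poisons_only_its_entry(self, deployment, client):
        client.submit("ok1")
        # simulate a GUI that lists an entry whose detail file vanished
        from rwdsandbox.gui_protocol import MmtEntry
        client.channel.entries.append(MmtEntry(
            entry_id="e-broken", job_id="gone", message_type="job-request",
            detail_file="job_gone.xml", created_at=deployment.clock()))
        requests = deployment.proxy.poll_channels()
        assert [r.job_id for r in requests] == ["ok1"]
        errors = [m for m in client.poll() if m.code == "error.request"]
        assert len(errors) == 1 and errors[0].job_id == "gone"


class TestAuthorization:
    def test_ungranted_user_denied_no_token_deposited(self, deployment):
        deployment.perm.add_user("mallory", "pw")
        mallory = ReferenceClient(deployment, "mallory", "pw", "chan-m")
        mallory.submit("m1")
        deployment.proxy.run_cycle()
        codes = [m.code for m in mallory.poll()]
        assert "error.permission" in codes
        handle = next(iter(deployment.proxy.processors.values()))
        assert os.listdir(handle.input_folder) == []
        assert deployment.proxy.jobs["m1"].state == "denied"

    def test_revoked_session_gets_auth_required_not_denial(self, deployment,
                                                           client):
        deployment.perm.revoke_session(client.ticket)
        client.submit("a1")
        deployment.proxy.run_cycle()
        codes = [m.code for m in client.poll()]
        assert "error.auth" in codes
        assert "error.permission" not in codes


class TestDatamartResolution:
    def test_no_query_preserves_row_count(self, deployment):
        entry = deployment.proxy.datamarts["dm-patients"]
        csv = deployment.proxy.resolve_datamart(entry)
        assert len(csv.splitlines()) == 50 + 1  # header + rows

    def test_query_selects_exactly_matching_rows(self, deployment):
        entry = deployment.proxy.datamarts["dm-patients"]
        frame = generate_datamart(default_patient_schema(seed=7), 50)
        expected = sum(1 for _, row in frame.iterrows() if row["age"] >= 60)
        csv = deployment.proxy.resolve_datamart(
            entry, CohortQuery(predicates=[Predicate("age", ">=", 60)]))
        assert len(csv.splitlines()) == expected + 1
        assert 0 < expected < 50

    def test_unregistered_connector_dialect_errors(self, deployment):
        from rwdsandbox.errors import ConfigurationError
        from rwdsandbox.proxy import ConnectorSpec, DatamartEntry
        entry = DatamartEntry(item_id="dm-sql", name="x",
                              source=ConnectorSpec("sqlserver"))
        with pytest.raises(ConfigurationError):
            deployment.proxy.resolve_datamart(entry)


class TestLoadBalancing:
    def test_ongoing_counter_identity(self):
        state = ProcessorState("P1", forwarded=5, completed=3, failed=1)
        assert state.ongoing == 1

    def test_selection_rules(self, tmp_path, fake_clock):
        from rwdsandbox.harness import build_deployment
        dep = build_deployment(str(tmp_path / "lb"), clock=fake_clock,
                               n_processors=3, seed=1)
        proxy = dep.proxy
        proxy.states["P1"].forwarded = 2
        proxy.states["P2"].forwarded = 0
        proxy.states["P3"].forwarded = 2
        proxy.states["P3"].completed = 2
        # ongoing: P1=2, P2=0, P3=0 -> tie P2/P3 broken by least forwarded
        assert proxy.select_processor() == "P2"
        proxy.states["P2"].forwarded = 2
        # all-equal tie broken lexically
        proxy.states["P1"].completed = 2
        proxy.states["P2"].completed = 2
        assert proxy.select_processor() == "P1"
        dep.shutdown()

    def test_no_live_processor_holds_job_with_warning(self, tmp_path, fake_clock):
        from rwdsandbox.harness import build_deployment
        dep = build_deployment(str(tmp_path / "nl"), clock=fake_clock,
                               n_processors=1, seed=1)
        client = ReferenceClient(dep, "alice", "wonderland")
        fake_clock.advance(1000)  # heartbeat goes stale
        client.submit("h1")
        dep.proxy.run_cycle()
        assert dep.proxy.jobs["h1"].state == "held"
        warned = [m for m in client.poll()
                  if m.code == "info.status.job" and "warning" in m.payload]
        assert warned
        # heartbeat returns -> retried and dispatched on the next cycle
        dep.processors[0].poll_once()
        dep.proxy.run_cycle()
        assert dep.proxy.jobs["h1"].state == "dispatched"
        dep.shutdown()


class TestDispatch:
    def test_request_notarised_before_token_deposited(self, deployment, client):
        client.submit("d1")
        deployment.proxy.run_cycle()
        codes = deployment.proxy.event_codes("d1")
        assert codes.index("request.notarised") < codes.index("token.deposited")
        # ledger holds the request entry while no output exists yet
        assert len(deployment.notary) == 1

    def test_token_carries_cohort_filtered_payload(self, deployment, client):
        client.submit("d2", cohort_query=CohortQuery(
            predicates=[Predicate("gender", "=", "F")]))
        for req in deployment.proxy.poll_channels():
            deployment.proxy.process_request(req)
        handle = next(iter(deployment.proxy.processors.values()))
        path = os.path.join(handle.input_folder, "token_d2.zip")
        token = parse_token(open(path, "rb").read())
        rows = token.read_member("data.csv").decode().splitlines()[1:]
        frame = generate_datamart(default_patient_schema(seed=7), 50)
        assert len(rows) == (frame["gender"] == "F").sum()

    def test_scheduled_request_handed_to_scheduler_no_token(self, deployment,
                                                            client):
        client.submit("s1", schedule=CadenceSpec("interval", "60"))
        deployment.proxy.run_cycle()
        handle = next(iter(deployment.proxy.processors.values()))
        assert os.listdir(handle.input_folder) == []
        assert len(deployment.scheduler.tasks) == 1
        assert "scheduler.handoff" in deployment.proxy.event_codes("s1")

    def test_scheduled_task_fires_fresh_jobs_through_proxy(self, deployment,
                                                           client):
        client.submit("s2", schedule=CadenceSpec("interval", "60"))
        deployment.proxy.run_cycle()
        deployment.clock.advance(60)
        deployment.pump(cycles=2)
        fired = [j for j in deployment.proxy.jobs if j.startswith("task-")]
        assert len(fired) == 1
        assert deployment.proxy.jobs[fired[0]].state == "completed"


class TestOutputs:
    def test_orphan_output_quarantined_never_forwarded(self, deployment, client):
        handle = next(iter(deployment.proxy.processors.values()))
        orphan = os.path.join(handle.output_folder, "out_zzz.zip")
        with open(orphan, "wb") as fh:
            fh.write(b"mystery")
        deployment.proxy.monitor_outputs()
        assert not os.path.exists(orphan)
        assert os.path.exists(os.path.join(deployment.proxy.quarantine_dir,
                                           "out_zzz.zip"))
        assert all(m.job_id != "zzz" for m in client.poll())

    def test_failed_job_returns_logs_without_signing(self, deployment, client):
        # sleeper with an unparseable duration makes the script fail
        client.submit("f1", algorithm="alg-sleeper",
                      run_settings={"duration": "not-a-number"})
        deployment.pump()
        msgs = client.poll()
        errors = [m for m in msgs if m.code == "error.job"]
        assert errors and errors[0].payload["logs"]
        assert all(m.code != "result.ready" for m in msgs)
        assert deployment.proxy.jobs["f1"].report is None


class TestPlatformInfo:
    def test_processor_count_and_degraded_flag(self, deployment, fake_clock):
        info = deployment.proxy.platform_info("processor-count")
        assert info == {"count": 1, "degraded": False}
        fake_clock.advance(1000)
        info = deployment.proxy.platform_info("processor-count")
        assert info == {"count": 0, "degraded": True}

    def test_catalog_version_strictly_increases(self, deployment):
        from rwdsandbox.proxy import DatamartEntry
        before = deployment.proxy.platform_info("catalog-update")["version"]
        deployment.proxy.register_datamart(DatamartEntry(
            item_id="dm-new", name="new", source="/dev/null"))
        after = deployment.proxy.platform_info("catalog-update")["version"]
        assert after > before


class TestConservation:
    def test_requests_split_into_denials_schedules_and_deposits(self, deployment):
        deployment.perm.add_user("mallory", "pw")
        alice = ReferenceClient(deployment, "alice", "wonderland", "chan-a")
        mallory = ReferenceClient(deployment, "mallory", "pw", "chan-m")
        alice.submit("c1")
        alice.submit("c2", schedule=CadenceSpec("interval", "3600"))
        mallory.submit("c3")
        deployment.proxy.run_cycle()
        c = deployment.proxy.counters
        assert c["consumed"] == 3
        assert c["consumed"] == c["denied"] + c["scheduled"] + c["deposited"]
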