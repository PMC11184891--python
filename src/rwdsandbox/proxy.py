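"""The central coordinator of the sandbox.

The proxy is the only component that touches both worlds: it polls the
GUI channels outside the hospital perimeter for new job requests, and it
owns the data, the algorithm repository and the processors inside it.  For
every request it:

1. reads and acknowledges the MMT entry and its ``job_<jobID>.xml`` detail,
2. checks the (datamart, algorithm) pair against the permission agent,
3. notarises the request metadata — user, datamart, algorithm, timestamp,
   deliberately devoid of data — *before* anything executes,
4. resolves the datamart (CSV store or pluggable connector, with an
   optional cohort query), builds the token and deposits it in the input
   folder of the least-loaded live processor,
5. monitors output and sync folders, notarises result hashes, routes
   reports through sandbox signing and the user countersignature, and
   forwards status messages, logs and result artefacts back to the
   originating channel.

Datamarts and algorithms offered to users are exactly those registered in
the catalog — certified-by-configuration — and container algorithms only
ever resolve against the local image store.  Everything the proxy does is
appended to an event log so protocol conformance is checkable after the
fact.
"""

from __future__ import annotations

import base64
import itertools
import json
import os
import shutil
from dataclasses import dataclass, field

import pandas as pd

from rwdsandbox._clock import system_clock, to_iso
from rwdsandbox.errors import (
    ConfigurationError,
    ContractError,
    SandboxError,
)
from rwdsandbox.fixtures import CohortQuery, apply_cohort_query, to_csv_bytes
from rwdsandbox.gui_protocol import JobRequest, StatusMessage, parse_mmt
from rwdsandbox.notary import Notary, SignedReport
from rwdsandbox.perm_agent import ALLOW, AUTH_REQUIRED, PermAgent
from rwdsandbox.token_core import (
    AlgorithmRef,
    DatamartRef,
    TokenDescriptor,
    build_token,
    parse_output_token,
)

# -- registry types -------------------------------------------------------


@dataclass(frozen=True)
class ConnectorSpec:
    dialect: str  # "csv" built in; sql dialects are extension points
    params: tuple = ()
    table: str = ""


@dataclass
class DatamartEntry:
    item_id: str
    name: str
    source: str | ConnectorSpec  # CSV path or connector spec
    fields: dict[str, str] = field(default_factory=dict)  # name -> type
    description: str = ""


@dataclass
class AlgorithmEntry:
    item_id: str
    name: str
    kind: str  # "script" | "image"
    locator: str  # repository locator or image name — always local
    input_hints: dict[str, str] = field(default_factory=dict)
    description: str = ""

    def __post_init__(self):
        if self.kind not in ("script", "image"):
            raise ContractError(f"unknown algorithm kind {self.kind!r}")


@dataclass
class ProcessorHandle:
    processor_id: str
    input_folder: str
    output_folder: str
    sync_folder: str


@dataclass
class ProcessorState:
    processor_id: str
    forwarded: int = 0
    completed: int = 0
    failed: int = 0

    @property
    def ongoing(self) -> int:
        return self.forwarded - self.completed - self.failed


# -- connectors -----------------------------------------------------------


class Connector:
    """Relational-connector contract: fetch one table as a DataFrame."""

    def fetch_table(self, spec: ConnectorSpec) -> pd.DataFrame:  # pragma: no cover
        raise NotImplementedError


class CsvConnector(Connector):
    def fetch_table(self, spec: ConnectorSpec) -> pd.DataFrame:
        params = dict(spec.params)
        return pd.read_csv(params["path"])


# -- job bookkeeping ------------------------------------------------------


@dataclass
class JobRecord:
    request: JobRequest
    channel: object
    state: str = "queued"  # queued/dispatched/completed/failed/denied/issued
    processor_id: str | None = None
    report: SignedReport | None = None
    officially_issued: bool = False
    request_notarised: bool = False


class Proxy:
    def __init__(self, root: str, perm_agent: PermAgent, notary: Notary,
                 clock=system_clock, scheduler=None,
                 channel_poll_interval: float = 2.0,
                 heartbeat_window: float = 30.0):
        self.root = root
        self.perm = perm_agent
        self.notary = notary
        self.clock = clock
        self.scheduler = scheduler
        self.channel_poll_interval = channel_poll_interval
        self.heartbeat_window = heartbeat_window
        self.quarantine_dir = os.path.join(root, "quarantine")
        os.makedirs(self.quarantine_dir, exist_ok=True)

        self.datamarts: dict[str, DatamartEntry] = {}
        self.algorithms: dict[str, AlgorithmEntry] = {}
        self.catalog_version = 0
        self.connectors: dict[str, Connector] = {"csv": CsvConnector()}
        self.channels: list = []
        self.processors: dict[str, ProcessorHandle] = {}
        self.states: dict[str, ProcessorState] = {}
        self.jobs: dict[str, JobRecord] = {}
        self._seen_entries: set[tuple[str, str]] = set()
        self._held: list[JobRecord] = []
        self._seq = itertools.count(1)
        self.events: list[dict] = []
        self.counters = {"consumed": 0, "denied": 0, "scheduled": 0,
                         "deposited": 0}

    # -- event log --------------------------------------------------------

    def _log(self, code: str, job_id: str = "", **detail) -> None:
        self.events.append({"seq": next(self._seq), "time": self.clock(),
                            "code": code, "job_id": job_id, **detail})

    def event_codes(self, job_id: str | None = None) -> list[str]:
        return [e["code"] for e in self.events
                if job_id is None or e["job_id"] == job_id]

    # -- registry ---------------------------------------------------------

    def register_datamart(self, entry: DatamartEntry) -> None:
        self.datamarts[entry.item_id] = entry
        self.perm.add_item(entry.item_id, "datamart")
        self.catalog_version += 1

    def register_algorithm(self, entry: AlgorithmEntry) -> None:
        self.algorithms[entry.item_id] = entry
        self.perm.add_item(entry.item_id, "algorithm")
        self.catalog_version += 1

    def register_connector(self, dialect: str, connector: Connector) -> None:
        self.connectors[dialect] = connector

    def register_processor(self, handle: ProcessorHandle) -> None:
        self.processors[handle.processor_id] = handle
        self.states[handle.processor_id] = ProcessorState(handle.processor_id)

    def register_channel(self, channel) -> None:
        self.channels.append(channel)

    # -- channel polling ---------------------------------------------------

    def poll_channels(self) -> list[JobRequest]:
        """Fetch every not-yet-seen MMT entry from every channel, read its
        detail file, acknowledge it, and return the parsed requests.
        Re-polling with nothing new returns an empty list; a broken detail
        file poisons only its own entry."""
        requests = []
        for channel in self.channels:
            try:
                entries = parse_mmt(channel.fetch_mmt())
            except SandboxError:
                continue
            self._log("channel.mmt.read", channel=channel.channel_id)
            for entry in entries:
                key = (channel.channel_id, entry.entry_id)
                if key in self._seen_entries or entry.message_type != "job-request":
                    continue
                self._seen_entries.add(key)
                try:
                    detail = channel.fetch_detail(entry.detail_file)
                    request = JobRequest.from_xml(detail)
                except (KeyError, SandboxError) as exc:
                    self._post(channel, "error.request", entry.job_id,
                               {"error": f"unreadable job detail: {exc}"})
                    continue
                self._log("request.read", request.job_id,
                          detail=entry.detail_file)
                channel.acknowledge(entry.entry_id)
                self._post(channel, "info.queued.ack", request.job_id, {})
                self.counters["consumed"] += 1
                self.jobs[request.job_id] = JobRecord(request=request,
                                                      channel=channel)
                requests.append(request)
        return requests

    def _post(self, channel, code: str, job_id: str, payload: dict) -> None:
        channel.post_message(StatusMessage(code=code, job_id=job_id,
                                           payload=payload,
                                           timestamp=self.clock()))
        self._log(f"status.sent.{code}", job_id)

    # -- authorization -----------------------------------------------------

    def authorize(self, request: JobRequest) -> str:
        decision = self.perm.check_pair(request.ticket, request.datamart_item,
                                        request.algorithm_item)
        self._log("permission.checked", request.job_id, decision=decision)
        return decision

    # -- datamart resolution ----------------------------------------------

    def resolve_datamart(self, entry: DatamartEntry,
                         query: CohortQuery | None = None) -> bytes:
        """Fetch the table through its connector, apply the cohort query,
        and serialise the selected rows as the CSV token payload."""
        if isinstance(entry.source, ConnectorSpec):
            connector = self.connectors.get(entry.source.dialect)
            if connector is None:
                raise ConfigurationError(
                    f"no connector registered for dialect "
                    f"{entry.source.dialect!r}")
            frame = connector.fetch_table(entry.source)
        else:
            frame = pd.read_csv(entry.source)
        if query is not None:
            frame = apply_cohort_query(frame, query)
        return to_csv_bytes(frame)

    # -- load balancing ----------------------------------------------------

    def _live_processors(self) -> list[str]:
        live = []
        for pid, handle in self.processors.items():
            hb = os.path.join(handle.sync_folder, f"heartbeat_{pid}.txt")
            if not os.path.exists(hb):
                continue
            try:
                from rwdsandbox._clock import from_iso
                with open(hb) as fh:
                    ts = from_iso(fh.read().strip())
            except (ValueError, OSError):
                continue
            if self.clock() - ts <= self.heartbeat_window:
                live.append(pid)
        return live

    def select_processor(self) -> str | None:
        """Least-ongoing processor; ties broken by least forwarded, then
        lexically smallest id.  None when nothing is live."""
        live = self._live_processors()
        if not live:
            return None
        return min(live, key=lambda pid: (self.states[pid].ongoing,
                                          self.states[pid].forwarded, pid))

    # -- dispatch ----------------------------------------------------------

    def process_request(self, request: JobRequest) -> None:
        """Authorize and route one consumed request: deny, hand to the
        scheduler, or dispatch a token."""
        record = self.jobs[request.job_id]
        decision = self.authorize(request)
        if decision == AUTH_REQUIRED:
            record.state = "denied"
            self.counters["denied"] += 1
            self._post(record.channel, "error.auth", request.job_id,
                       {"reason": "session expired or revoked; please log in"})
            return
        if decision != ALLOW:
            record.state = "denied"
            self.counters["denied"] += 1
            self._post(record.channel, "error.permission", request.job_id,
                       {"reason": "pair (datamart, algorithm) not granted"})
            return
        if request.schedule is not None:
            if self.scheduler is None:
                record.state = "denied"
                self.counters["denied"] += 1
                self._post(record.channel, "error.request", request.job_id,
                           {"reason": "no scheduler configured"})
                return
            template = {k: v for k, v in request.__dict__.items()
                        if k not in ("job_id", "schedule", "cohort_query")}
            template["channel_id"] = record.channel.channel_id
            self.scheduler.add_task(template, request.schedule)
            record.state = "scheduled"
            self.counters["scheduled"] += 1
            self._log("scheduler.handoff", request.job_id)
            self._post(record.channel, "info.status.job", request.job_id,
                       {"status": "scheduled"})
            return
        self.dispatch(record)

    def dispatch(self, record: JobRecord) -> None:
        """Notarise the request, build the token, deposit it on the least
        loaded processor.  A notarisation failure holds the job for retry;
        it never executes un-notarised."""
        request = record.request
        job_id = request.job_id
        if not record.request_notarised:
            try:
                request_meta = json.dumps(
                    {"user_id": request.user_id,
                     "datamart": request.datamart_item,
                     "algorithm": request.algorithm_item,
                     "timestamp": to_iso(self.clock())},
                    separators=(",", ":")).encode()
                self.notary.notarize(request_meta,
                                     {"job_id": job_id, "role": "request",
                                      "user": request.user_id})
            except SandboxError as exc:
                record.state = "held"
                self._held.append(record)
                self._log("job.held", job_id, reason=str(exc))
                return
            record.request_notarised = True
            self._log("request.notarised", job_id)

        dm_entry = self.datamarts.get(request.datamart_item)
        alg_entry = self.algorithms.get(request.algorithm_item)
        if dm_entry is None or alg_entry is None:
            record.state = "denied"
            self.counters["denied"] += 1
            self._post(record.channel, "error.request", job_id,
                       {"reason": "datamart or algorithm not in catalog"})
            return
        try:
            payload_csv = self.resolve_datamart(dm_entry, request.cohort_query)
        except SandboxError as exc:
            record.state = "denied"
            self.counters["denied"] += 1
            self._post(record.channel, "error.request", job_id,
                       {"reason": f"datamart resolution failed: {exc}"})
            return

        algorithm_ref = (AlgorithmRef("image", alg_entry.locator)
                         if alg_entry.kind == "image"
                         else AlgorithmRef("repository", alg_entry.locator))
        descriptor = TokenDescriptor(
            job_id=job_id,
            user_id=request.user_id,
            algorithm_ref=algorithm_ref,
            datamart_ref=DatamartRef("payload", "data.csv"),
            column_roles=request.column_roles,
            run_settings=request.run_settings,
            notarise=request.notarise,
            sign=request.sign,
            created_at=self.clock(),
        )
        token = build_token(descriptor, [("data.csv", payload_csv)])

        pid = self.select_processor()
        if pid is None:
            record.state = "held"
            self._held.append(record)
            self._log("job.held", job_id, reason="no live processor")
            self._post(record.channel, "info.status.job", job_id,
                       {"status": "queued", "warning": "no live processor"})
            return
        handle = self.processors[pid]
        final = os.path.join(handle.input_folder, f"token_{job_id}.zip")
        tmp = final + ".part"
        with open(tmp, "wb") as fh:
            fh.write(token.archive)
        os.rename(tmp, final)
        self.states[pid].forwarded += 1
        self.counters["deposited"] += 1
        record.state = "dispatched"
        record.processor_id = pid
        self._log("token.deposited", job_id, processor=pid)
        self._post(record.channel, "info.assigned.proc", job_id,
                   {"processor": pid})
        self._post(record.channel, "info.status.job", job_id,
                   {"status": "running"})

    def submit_trigger(self, trigger) -> None:
        """Scheduler-facing entry point: each periodic trigger becomes a
        fresh job request with a new job_id, dispatched like any other."""
        template = dict(trigger.template)
        channel_id = template.pop("channel_id", None)
        channel = next((c for c in self.channels
                        if c.channel_id == channel_id), None)
        if channel is None and self.channels:
            channel = self.channels[0]
        request = JobRequest(job_id=trigger.job_id, **template)
        self.jobs[request.job_id] = JobRecord(request=request, channel=channel)
        self.counters["consumed"] += 1
        self._log("scheduler.trigger.received", request.job_id,
                  task=trigger.task_id)
        self.process_request(request)

    def retry_held(self) -> None:
        held, self._held = self._held, []
        for record in held:
            if record.state == "held":
                record.state = "queued"
                self.dispatch(record)

    # -- output monitoring -------------------------------------------------

    def monitor_outputs(self) -> list[str]:
        """Scan every processor's output folder; match output tokens to
        their requests by job_id, notarise result hashes, route reports
        through signing, forward artefacts and logs to the originating
        channel.  Orphans are quarantined, never forwarded."""
        completed = []
        for pid, handle in self.processors.items():
            for name in sorted(os.listdir(handle.output_folder)):
                if not (name.startswith("out_") and name.endswith(".zip")):
                    continue
                path = os.path.join(handle.output_folder, name)
                job_id = name[len("out_"):-len(".zip")]
                record = self.jobs.get(job_id)
                if record is None or record.state != "dispatched":
                    shutil.move(path, os.path.join(self.quarantine_dir, name))
                    self._log("orphan.quarantined", job_id, file=name)
                    continue
                with open(path, "rb") as fh:
                    archive = fh.read()
                os.remove(path)
                self._handle_output(record, archive)
                completed.append(job_id)
        return completed

    def _handle_output(self, record: JobRecord, archive: bytes) -> None:
        request = record.request
        job_id = request.job_id
        out = parse_output_token(archive)
        self._log("output.received", job_id, status=out.status)
        state = self.states[record.processor_id]

        if request.notarise:
            try:
                self.notary.notarize(archive, {"job_id": job_id, "role": "result",
                                               "user": request.user_id})
                self._log("result.notarised", job_id)
            except SandboxError as exc:
                self._log("result.notarise-failed", job_id, reason=str(exc))

        logs = {p: base64.b64encode(out.read_member(p)).decode()
                for p in out.logs}
        if out.status != "success":
            record.state = "failed"
            state.failed += 1
            self._post(record.channel, "error.job", job_id,
                       {"status": "failure", "logs": logs})
            return

        record.state = "completed"
        state.completed += 1
        results = {p: base64.b64encode(out.read_member(p)).decode()
                   for p in out.results}
        payload = {"status": "success", "results": results, "logs": logs}
        if request.sign:
            report = json.dumps(
                {"job_id": job_id, "user": request.user_id,
                 "finished_at": to_iso(out.finished_at), "results": results},
                sort_keys=True, separators=(",", ":")).encode()
            record.report = self.notary.sign_report(job_id, report)
            self._log("report.signed", job_id)
            payload["report"] = base64.b64encode(report).decode()
            payload["sandbox_signature"] = record.report.sandbox_signature.hex()
        self._post(record.channel, "info.status.job", job_id,
                   {"status": "done"})
        self._post(record.channel, "result.ready", job_id, payload)
        self._log("result.delivered", job_id)

    # -- countersignature --------------------------------------------------

    def submit_countersignature(self, job_id: str,
                                user_signature: bytes) -> SignedReport:
        """Accept the user's countersignature; on success the report is
        officially issued and all three report artefacts notarised."""
        record = self.jobs.get(job_id)
        if record is None or record.report is None:
            raise ContractError(f"no signed report pending for job {job_id!r}")
        report = self.notary.countersign(record.report,
                                         record.request.user_id,
                                         user_signature)
        record.officially_issued = True
        self._log("report.countersigned", job_id)
        self._post(record.channel, "info.status.job", job_id,
                   {"status": "issued"})
        return report

    # -- platform info -----------------------------------------------------

    def platform_info(self, kind: str) -> dict:
        if kind == "processor-count":
            live = self._live_processors()
            return {"count": len(live), "degraded": len(live) == 0}
        if kind == "catalog-update":
            return {
                "version": self.catalog_version,
                "datamarts": {
                    i: {"name": e.name, "fields": e.fields,
                        "description": e.description}
                    for i, e in self.datamarts.items()},
                "algorithms": {
                    i: {"name": e.name, "kind": e.kind,
                        "hints": e.input_hints, "description": e.description}
                    for i, e in self.algorithms.items()},
            }
        raise ContractError(f"unknown info kind {kind!r}")

    # -- one full proxy cycle ---------------------------------------------

    def run_cycle(self) -> None:
        """Poll channels, route new requests, retry held jobs, scheduler
        tick, collect outputs — the proxy's steady-state loop body."""
        for request in self.poll_channels():
            self.process_request(request)
        self.retry_held()
        if self.scheduler is not None:
            self.scheduler.tick(self.clock())
        self.monitor_outputs()
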