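"""The polled XML message protocol between a GUI and the proxy.

The GUI never calls into the hospital zone.  It publishes its requests as
XML files — a Message Master Table (MMT) listing every submitted job, plus
one detail file ``job_<jobID>.xml`` per job — and the proxy polls the
channel, reads new entries, acknowledges them, and later posts status
messages and result artefacts to the channel's outbox.  All traffic flows
through the proxy's own polls/pushes on a single declared transport, so the
hospital side keeps complete control of the communication.

The channel itself is authenticated and has a maximum duration set by the
proxy; a nested user session (a permission-agent ticket) rides on top of
it.  Two transports implement the same contract: an in-process
:class:`GuiChannel` and an HTTP pair (:class:`HttpGuiServer` /
:class:`HttpChannelClient`) on one port, with the proxy initiating every
HTTP request.
"""

from __future__ import annotations

import itertools
import json
import threading
from dataclasses import dataclass, field

from lxml import etree

from rwdsandbox._clock import from_iso, system_clock, to_iso
from rwdsandbox.errors import (
    ChannelExpiredError,
    ContractError,
    DescriptorSchemaError,
    DuplicateJobError,
)
from rwdsandbox.fixtures import CohortQuery, JoinSpec, Predicate
from rwdsandbox.token_core import CadenceSpec

STATUS_CODES = (
    "info.queued.ack",
    "info.assigned.proc",
    "info.status.job",
    "result.ready",
    "error.auth",
    "error.permission",
    "error.request",
    "error.job",
)

DEFAULT_CHANNEL_DURATION = 3600.0  # seconds, set by the proxy


@dataclass
class ChannelSession:
    channel_id: str
    established_at: float
    max_duration: float
    user_ticket: str | None = None  # nested user session

    def expired(self, now: float) -> bool:
        return now >= self.established_at + self.max_duration


@dataclass
class MmtEntry:
    entry_id: str
    job_id: str
    message_type: str  # "job-request" | "control"
    detail_file: str
    created_at: float
    consumed: bool = False


@dataclass
class JobRequest:
    job_id: str
    ticket: str
    user_id: str
    datamart_item: str
    algorithm_item: str
    cohort_query: CohortQuery | None = None
    column_roles: dict[str, str] = field(default_factory=dict)
    run_settings: dict[str, str] = field(default_factory=dict)
    schedule: CadenceSpec | None = None
    notarise: bool = True
    sign: bool = True

    # -- XML --------------------------------------------------------------

    def to_xml(self) -> bytes:
        root = etree.Element("job-request", format_version="1.0")
        etree.SubElement(root, "job-id").text = self.job_id
        etree.SubElement(root, "ticket").text = self.ticket
        etree.SubElement(root, "user-id").text = self.user_id
        etree.SubElement(root, "datamart").text = self.datamart_item
        etree.SubElement(root, "algorithm").text = self.algorithm_item
        if self.cohort_query is not None:
            q = etree.SubElement(root, "cohort-query")
            if self.cohort_query.join is not None:
                j = self.cohort_query.join
                etree.SubElement(q, "join", left=j.left_table,
                                 right=j.right_table, key=j.key)
            for p in self.cohort_query.predicates:
                lit = p.literal
                if isinstance(lit, (list, tuple, set)):
                    kind, text = "list", json.dumps(list(lit))
                elif isinstance(lit, bool):
                    kind, text = "bool", str(lit).lower()
                elif isinstance(lit, int):
                    kind, text = "int", str(lit)
                elif isinstance(lit, float):
                    kind, text = "float", repr(lit)
                else:
                    kind, text = "str", str(lit)
                el = etree.SubElement(q, "predicate", field=p.fld, op=p.op,
                                      type=kind)
                el.text = text
        roles = etree.SubElement(root, "column-roles")
        for name, role in self.column_roles.items():
            etree.SubElement(roles, "column", name=name, role=role)
        settings = etree.SubElement(root, "run-settings")
        for key, value in self.run_settings.items():
            etree.SubElement(settings, "setting", key=key).text = value
        if self.schedule is not None:
            etree.SubElement(root, "schedule",
                             kind=self.schedule.kind).text = self.schedule.value
        etree.SubElement(root, "notarise").text = "true" if self.notarise else "false"
        etree.SubElement(root, "sign").text = "true" if self.sign else "false"
        return etree.tostring(root, xml_declaration=True, encoding="UTF-8")

    @classmethod
    def from_xml(cls, data: bytes) -> "JobRequest":
        try:
            root = etree.fromstring(data)
        except etree.XMLSyntaxError as exc:
            raise DescriptorSchemaError(f"malformed job-request XML: {exc}") from exc

        def text(tag: str) -> str:
            el = root.find(tag)
            return (el.text or "") if el is not None else ""

        if not text("job-id"):
            raise DescriptorSchemaError("job-request lacks job-id")
        query = None
        q = root.find("cohort-query")
        if q is not None:
            join_el = q.find("join")
            join = None
            if join_el is not None:
                join = JoinSpec(join_el.get("left", ""), join_el.get("right", ""),
                                join_el.get("key", ""))
            preds = []
            for el in q.findall("predicate"):
                kind, raw = el.get("type", "str"), el.text or ""
                if kind == "list":
                    lit: object = json.loads(raw)
                elif kind == "int":
                    lit = int(raw)
                elif kind == "float":
                    lit = float(raw)
                elif kind == "bool":
                    lit = raw == "true"
                else:
                    lit = raw
                preds.append(Predicate(el.get("field", ""), el.get("op", "="), lit))
            query = CohortQuery(predicates=preds, join=join)
        sched_el = root.find("schedule")
        schedule = None
        if sched_el is not None:
            schedule = CadenceSpec(sched_el.get("kind", ""), sched_el.text or "")
        return cls(
            job_id=text("job-id"),
            ticket=text("ticket"),
            user_id=text("user-id"),
            datamart_item=text("datamart"),
            algorithm_item=text("algorithm"),
            cohort_query=query,
            column_roles={c.get("name", ""): c.get("role", "")
                          for c in root.findall("column-roles/column")},
            run_settings={s.get("key", ""): s.text or ""
                          for s in root.findall("run-settings/setting")},
            schedule=schedule,
            notarise=text("notarise") != "false",
            sign=text("sign") != "false",
        )


@dataclass
class StatusMessage:
    code: str
    job_id: str
    payload: dict
    timestamp: float

    def __post_init__(self):
        if self.code not in STATUS_CODES:
            raise ContractError(f"unknown status code {self.code!r}")

    def to_xml(self) -> bytes:
        root = etree.Element("status-message", code=self.code)
        etree.SubElement(root, "job-id").text = self.job_id
        etree.SubElement(root, "payload").text = json.dumps(self.payload)
        etree.SubElement(root, "timestamp").text = to_iso(self.timestamp)
        return etree.tostring(root, xml_declaration=True, encoding="UTF-8")

    @classmethod
    def from_xml(cls, data: bytes) -> "StatusMessage":
        root = etree.fromstring(data)
        return cls(
            code=root.get("code", ""),
            job_id=root.findtext("job-id", ""),
            payload=json.loads(root.findtext("payload", "{}")),
            timestamp=from_iso(root.findtext("timestamp")),
        )


def _mmt_to_xml(entries: list[MmtEntry]) -> bytes:
    root = etree.Element("message-master-table", format_version="1.0")
    for e in entries:
        etree.SubElement(
            root, "entry", entry_id=e.entry_id, job_id=e.job_id,
            type=e.message_type, detail=e.detail_file,
            created_at=to_iso(e.created_at),
            consumed="true" if e.consumed else "false",
        )
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8")


def _mmt_from_xml(data: bytes) -> list[MmtEntry]:
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise DescriptorSchemaError(f"malformed MMT XML: {exc}") from exc
    return [
        MmtEntry(
            entry_id=e.get("entry_id", ""),
            job_id=e.get("job_id", ""),
            message_type=e.get("type", ""),
            detail_file=e.get("detail", ""),
            created_at=from_iso(e.get("created_at")),
            consumed=e.get("consumed") == "true",
        )
        for e in root.findall("entry")
    ]


class GuiChannel:
    """GUI-side channel state: the MMT, the detail files, and an outbox the
    proxy posts into.  Every payload that crosses the channel, in either
    direction, is recorded in ``transcript`` for the mediation property.
    """

    def __init__(self, channel_id: str, clock=system_clock,
                 max_duration: float = DEFAULT_CHANNEL_DURATION,
                 user_ticket: str | None = None):
        self.clock = clock
        self.session = ChannelSession(channel_id, clock(), max_duration,
                                      user_ticket)
        self.entries: list[MmtEntry] = []
        self.details: dict[str, bytes] = {}
        self.outbox: list[bytes] = []
        self.transcript: list[tuple[str, bytes]] = []  # (direction, payload)
        self._ids = itertools.count(1)
        self._lock = threading.Lock()

    def _check_live(self) -> None:
        if self.session.expired(self.clock()):
            raise ChannelExpiredError(
                f"channel {self.session.channel_id} expired")

    # -- GUI side ---------------------------------------------------------

    def write_job(self, request: JobRequest) -> MmtEntry:
        """Publish a job: write the detail file and atomically append one
        MMT entry.  Idempotence: a duplicate job_id is refused outright."""
        self._check_live()
        with self._lock:
            if any(e.job_id == request.job_id for e in self.entries):
                raise DuplicateJobError(f"job {request.job_id!r} already submitted")
            detail = f"job_{request.job_id}.xml"
            self.details[detail] = request.to_xml()
            entry = MmtEntry(
                entry_id=f"e{next(self._ids)}",
                job_id=request.job_id,
                message_type="job-request",
                detail_file=detail,
                created_at=self.clock(),
            )
            self.entries.append(entry)
        return entry

    def read_status(self) -> list[StatusMessage]:
        """Drain the outbox; messages arrive in per-job causal order."""
        self._check_live()
        with self._lock:
            raw, self.outbox = self.outbox, []
        return [StatusMessage.from_xml(r) for r in raw]

    # -- proxy side (the transport contract) ------------------------------

    def fetch_mmt(self) -> bytes:
        self._check_live()
        with self._lock:
            data = _mmt_to_xml(self.entries)
        self.transcript.append(("gui->proxy", data))
        return data

    def fetch_detail(self, name: str) -> bytes:
        self._check_live()
        with self._lock:
            if name not in self.details:
                raise KeyError(name)
            data = self.details[name]
        self.transcript.append(("gui->proxy", data))
        return data

    def acknowledge(self, entry_id: str) -> None:
        with self._lock:
            for e in self.entries:
                if e.entry_id == entry_id:
                    e.consumed = True

    def post_message(self, message: StatusMessage) -> None:
        data = message.to_xml()
        self.transcript.append(("proxy->gui", data))
        with self._lock:
            self.outbox.append(data)

    @property
    def channel_id(self) -> str:
        return self.session.channel_id


# -- HTTP transport (stdlib only, single port, proxy initiates) -----------

class HttpGuiServer:
    """Serve a GuiChannel over HTTP on one port.

    Routes: ``GET /mmt``, ``GET /detail/<name>``, ``POST /ack/<entry_id>``,
    ``POST /outbox``.  The GUI process hosts this; only the proxy ever
    opens connections.
    """

    def __init__(self, channel: GuiChannel, host: str = "127.0.0.1",
                 port: int = 0):
        import http.server

        chan = channel

        class Handler(http.server.BaseHTTPRequestHandler):
            def log_message(self, *args):  # quiet
                pass

            def _send(self, code: int, body: bytes = b""):
                self.send_response(code)
                self.send_header("Content-Length", str(len(body)))
                self.end_headers()
                self.wfile.write(body)

            def do_GET(self):
                try:
                    if self.path == "/mmt":
                        self._send(200, chan.fetch_mmt())
                    elif self.path.startswith("/detail/"):
                        self._send(200, chan.fetch_detail(self.path[len("/detail/"):]))
                    else:
                        self._send(404)
                except KeyError:
                    self._send(404)
                except ChannelExpiredError:
                    self._send(410)

            def do_POST(self):
                length = int(self.headers.get("Content-Length", 0))
                body = self.rfile.read(length)
                if self.path.startswith("/ack/"):
                    chan.acknowledge(self.path[len("/ack/"):])
                    self._send(204)
                elif self.path == "/outbox":
                    chan.transcript.append(("proxy->gui", body))
                    with chan._lock:
                        chan.outbox.append(body)
                    self._send(204)
                else:
                    self._send(404)

        self._server = http.server.ThreadingHTTPServer((host, port), Handler)
        self.port = self._server.server_address[1]
        self._thread = threading.Thread(target=self._server.serve_forever,
                                        daemon=True)
        self._thread.start()

    def close(self) -> None:
        self._server.shutdown()
        self._server.server_close()


class HttpChannelClient:
    """Proxy-side view of an HTTP-served channel; same contract as
    :class:`GuiChannel`'s proxy-side methods."""

    def __init__(self, base_url: str, channel_id: str):
        self.base_url = base_url.rstrip("/")
        self.channel_id = channel_id

    def _get(self, path: str) -> bytes:
        import urllib.error
        import urllib.request
        try:
            with urllib.request.urlopen(self.base_url + path) as resp:
                return resp.read()
        except urllib.error.HTTPError as exc:
            if exc.code == 404:
                raise KeyError(path) from exc
            if exc.code == 410:
                raise ChannelExpiredError(path) from exc
            raise

    def _post(self, path: str, body: bytes = b"") -> None:
        import urllib.request
        req = urllib.request.Request(self.base_url + path, data=body,
                                     method="POST")
        with urllib.request.urlopen(req):
            pass

    def fetch_mmt(self) -> bytes:
        return self._get("/mmt")

    def fetch_detail(self, name: str) -> bytes:
        return self._get("/detail/" + name)

    def acknowledge(self, entry_id: str) -> None:
        self._post("/ack/" + entry_id)

    def post_message(self, message: StatusMessage) -> None:
        self._post("/outbox", message.to_xml())


def parse_mmt(data: bytes) -> list[MmtEntry]:
    """Proxy-side MMT parsing."""
    return _mmt_from_xml(data)
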