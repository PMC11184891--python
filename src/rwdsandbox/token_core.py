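"""The token archive format.

A *token* is the unit of execution passed from the proxy to a processor: a zip
archive containing at least one XML member — the descriptor, which
characterises the task run and the structure of the token itself — plus
optional data/script payload members.  A completed run is reported back as an
*output token*: a zip with a result descriptor, result members and log members.

The descriptor XML schema is versioned (``format_version`` attribute on the
root); unknown elements are ignored on parse so older readers tolerate newer
writers.  The descriptor member name is fixed to ``descriptor.xml`` and the
output token's result descriptor to ``result.xml``.
"""

from __future__ import annotations

import hashlib
import io
import posixpath
import zipfile
from dataclasses import dataclass, field

from lxml import etree

from rwdsandbox._clock import from_iso, to_iso
from rwdsandbox.errors import (
    ContractError,
    DescriptorSchemaError,
    MissingDescriptorError,
    PathSafetyError,
)

DESCRIPTOR_MEMBER = "descriptor.xml"
RESULT_MEMBER = "result.xml"
FORMAT_VERSION = "1.0"

ALGORITHM_REF_KINDS = ("script", "image", "repository")
DATAMART_REF_KINDS = ("payload", "repository")
COLUMN_ROLES = ("input", "target")


@dataclass(frozen=True)
class AlgorithmRef:
    """What to run: exactly one of a script member path, a container image
    name, or a locator into the proxy's local algorithm repository."""

    kind: str  # one of ALGORITHM_REF_KINDS
    value: str

    def __post_init__(self):
        if self.kind not in ALGORITHM_REF_KINDS:
            raise ContractError(f"unknown algorithm_ref kind {self.kind!r}")
        if not self.value:
            raise ContractError("algorithm_ref value must be non-empty")


@dataclass(frozen=True)
class DatamartRef:
    """Where the data is: a payload member path inside the archive or a
    locator into the proxy's local data repository."""

    kind: str  # one of DATAMART_REF_KINDS
    value: str

    def __post_init__(self):
        if self.kind not in DATAMART_REF_KINDS:
            raise ContractError(f"unknown datamart_ref kind {self.kind!r}")
        if not self.value:
            raise ContractError("datamart_ref value must be non-empty")


@dataclass(frozen=True)
class CadenceSpec:
    """Periodic-run cadence: a fixed interval in seconds, or a daily
    calendar rule at a fixed UTC time of day ("HH:MM")."""

    kind: str  # "interval" | "daily"
    value: str

    def __post_init__(self):
        if self.kind == "interval":
            try:
                iv = float(self.value)
            except ValueError:
                raise ContractError(f"bad interval {self.value!r}") from None
            if iv <= 0:
                raise ContractError("interval must be positive")
        elif self.kind == "daily":
            parts = self.value.split(":")
            ok = len(parts) == 2 and all(p.isdigit() for p in parts)
            if not ok or not (0 <= int(parts[0]) < 24 and 0 <= int(parts[1]) < 60):
                raise ContractError(f"bad daily time {self.value!r}")
        else:
            raise ContractError(f"unknown cadence kind {self.kind!r}")

    @property
    def interval_seconds(self) -> float:
        if self.kind != "interval":
            raise ContractError("not an interval cadence")
        return float(self.value)


@dataclass
class TokenDescriptor:
    """The descriptor XML: job identity, what to run on what, and flags."""

    job_id: str
    user_id: str
    algorithm_ref: AlgorithmRef
    datamart_ref: DatamartRef
    column_roles: dict[str, str] = field(default_factory=dict)
    run_settings: dict[str, str] = field(default_factory=dict)
    notarise: bool = True
    sign: bool = True
    schedule: CadenceSpec | None = None
    created_at: float = 0.0  # POSIX seconds, UTC

    def __post_init__(self):
        if not self.job_id:
            raise ContractError("job_id must be non-empty")
        if not self.user_id:
            raise ContractError("user_id must be non-empty")
        for name, role in self.column_roles.items():
            if role not in COLUMN_ROLES:
                raise ContractError(f"column {name!r} has unknown role {role!r}")

    # -- XML (de)serialisation -------------------------------------------

    def to_xml(self) -> bytes:
        root = etree.Element("token-descriptor", format_version=FORMAT_VERSION)
        etree.SubElement(root, "job-id").text = self.job_id
        etree.SubElement(root, "user-id").text = self.user_id
        alg = etree.SubElement(root, "algorithm", kind=self.algorithm_ref.kind)
        alg.text = self.algorithm_ref.value
        dm = etree.SubElement(root, "datamart", kind=self.datamart_ref.kind)
        dm.text = self.datamart_ref.value
        roles = etree.SubElement(root, "column-roles")
        for name, role in self.column_roles.items():
            etree.SubElement(roles, "column", name=name, role=role)
        settings = etree.SubElement(root, "run-settings")
        for key, value in self.run_settings.items():
            etree.SubElement(settings, "setting", key=key).text = value
        etree.SubElement(root, "notarise").text = "true" if self.notarise else "false"
        etree.SubElement(root, "sign").text = "true" if self.sign else "false"
        if self.schedule is not None:
            etree.SubElement(
                root, "schedule", kind=self.schedule.kind
            ).text = self.schedule.value
        etree.SubElement(root, "created-at").text = to_iso(self.created_at)
        return etree.tostring(root, xml_declaration=True, encoding="UTF-8")

    @classmethod
    def from_xml(cls, data: bytes) -> "TokenDescriptor":
        try:
            root = etree.fromstring(data)
        except etree.XMLSyntaxError as exc:
            raise DescriptorSchemaError(f"malformed descriptor XML: {exc}") from exc
        if root.tag != "token-descriptor":
            raise DescriptorSchemaError(f"unexpected root element {root.tag!r}")

        def text(tag: str) -> str | None:
            el = root.find(tag)
            return None if el is None else (el.text or "")

        job_id = text("job-id")
        user_id = text("user-id")
        if not job_id:
            raise DescriptorSchemaError("descriptor lacks job-id")
        if not user_id:
            raise DescriptorSchemaError("descriptor lacks user-id")
        alg = root.find("algorithm")
        dm = root.find("datamart")
        if alg is None or dm is None:
            raise DescriptorSchemaError("descriptor lacks algorithm/datamart refs")
        roles: dict[str, str] = {}
        roles_el = root.find("column-roles")
        if roles_el is not None:
            for col in roles_el.findall("column"):
                roles[col.get("name", "")] = col.get("role", "")
        settings: dict[str, str] = {}
        settings_el = root.find("run-settings")
        if settings_el is not None:
            for st in settings_el.findall("setting"):
                settings[st.get("key", "")] = st.text or ""
        sched_el = root.find("schedule")
        schedule = None
        if sched_el is not None:
            schedule = CadenceSpec(sched_el.get("kind", ""), sched_el.text or "")
        created_el = text("created-at")
        try:
            return cls(
                job_id=job_id,
                user_id=user_id,
                algorithm_ref=AlgorithmRef(alg.get("kind", ""), alg.text or ""),
                datamart_ref=DatamartRef(dm.get("kind", ""), dm.text or ""),
                column_roles=roles,
                run_settings=settings,
                notarise=text("notarise") != "false",
                sign=text("sign") != "false",
                schedule=schedule,
                created_at=from_iso(created_el) if created_el else 0.0,
            )
        except ContractError as exc:
            raise DescriptorSchemaError(str(exc)) from exc


@dataclass
class Token:
    """A built token: the zip byte stream, its parsed descriptor, and the
    exact member list."""

    archive: bytes
    descriptor: TokenDescriptor
    manifest: list[str]

    def read_member(self, path: str) -> bytes:
        with zipfile.ZipFile(io.BytesIO(self.archive)) as zf:
            return zf.read(path)


@dataclass
class OutputToken:
    """The processor's report of one run: outcome plus result/log members."""

    archive: bytes
    job_id: str
    status: str  # "success" | "failure"
    results: list[str]
    logs: list[str]
    finished_at: float

    def read_member(self, path: str) -> bytes:
        with zipfile.ZipFile(io.BytesIO(self.archive)) as zf:
            return zf.read(path)


@dataclass(frozen=True)
class Digest:
    """A content digest, self-describing so ledger records remain
    interpretable if the algorithm ever changes."""

    algorithm_id: str
    hex: str

    def __post_init__(self):
        expected = hashlib.new(self.algorithm_id).digest_size * 2
        if len(self.hex) != expected or self.hex != self.hex.lower():
            raise ContractError(
                f"{self.algorithm_id} digest must be {expected} lowercase hex chars"
            )


DEFAULT_HASH = "sha256"


def hash_artifact(data: bytes, algorithm_id: str = DEFAULT_HASH) -> Digest:
    """Digest arbitrary bytes; deterministic, collision-resistant."""
    return Digest(algorithm_id, hashlib.new(algorithm_id, data).hexdigest())


def _check_payload_paths(paths: list[str], reserved: str) -> None:
    seen: set[str] = set()
    for p in paths:
        if not p or p.startswith("/") or p.startswith("\\") or (len(p) > 1 and p[1] == ":"):
            raise PathSafetyError(f"absolute or empty payload path {p!r}")
        norm = posixpath.normpath(p.replace("\\", "/"))
        if norm.startswith("..") or "/../" in f"/{norm}/":
            raise PathSafetyError(f"payload path {p!r} escapes the archive root")
        if norm in seen:
            raise PathSafetyError(f"duplicate payload path {p!r}")
        if norm == reserved:
            raise PathSafetyError(f"payload path {p!r} collides with the descriptor")
        seen.add(norm)


def _zip_write(payload: list[tuple[str, bytes]], descriptor_member: str,
               descriptor_xml: bytes) -> bytes:
    buf = io.BytesIO()
    with zipfile.ZipFile(buf, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr(descriptor_member, descriptor_xml)
        for path, data in payload:
            zf.writestr(path, data)
    return buf.getvalue()


def build_token(descriptor: TokenDescriptor,
                payload: list[tuple[str, bytes]] | None = None) -> Token:
    """Pack a descriptor plus payload members into a token archive.

    Payload paths must be unique, relative, and free of traversal components;
    ``parse_token(build_token(d, p).archive)`` reproduces ``d`` and the
    member list exactly.
    """
    payload = payload or []
    _check_payload_paths([p for p, _ in payload], DESCRIPTOR_MEMBER)
    archive = _zip_write(payload, DESCRIPTOR_MEMBER, descriptor.to_xml())
    manifest = [DESCRIPTOR_MEMBER] + [p for p, _ in payload]
    return Token(archive=archive, descriptor=descriptor, manifest=manifest)


def parse_token(archive: bytes) -> Token:
    """Read a token archive back into its descriptor and manifest."""
    try:
        zf = zipfile.ZipFile(io.BytesIO(archive))
    except zipfile.BadZipFile as exc:
        raise MissingDescriptorError(f"not a readable zip archive: {exc}") from exc
    with zf:
        manifest = zf.namelist()
        if DESCRIPTOR_MEMBER not in manifest:
            raise MissingDescriptorError(
                f"archive has no {DESCRIPTOR_MEMBER} member (members: {manifest})"
            )
        descriptor = TokenDescriptor.from_xml(zf.read(DESCRIPTOR_MEMBER))
    return Token(archive=archive, descriptor=descriptor, manifest=manifest)


def build_output_token(job_id: str, status: str,
                       results: list[tuple[str, bytes]],
                       logs: list[tuple[str, bytes]],
                       finished_at: float) -> OutputToken:
    """Pack an execution outcome into an output token.

    A failure must always carry at least one log member so the upper layers
    can surface what went wrong.
    """
    if not job_id:
        raise ContractError("job_id must be non-empty")
    if status not in ("success", "failure"):
        raise ContractError(f"status must be success|failure, got {status!r}")
    if status == "failure" and not logs:
        raise ContractError("failure output token requires non-empty logs")
    members = results + logs
    _check_payload_paths([p for p, _ in members], RESULT_MEMBER)

    root = etree.Element("result-descriptor", format_version=FORMAT_VERSION)
    etree.SubElement(root, "job-id").text = job_id
    etree.SubElement(root, "status").text = status
    res_el = etree.SubElement(root, "results")
    for path, _ in results:
        etree.SubElement(res_el, "member").text = path
    log_el = etree.SubElement(root, "logs")
    for path, _ in logs:
        etree.SubElement(log_el, "member").text = path
    etree.SubElement(root, "finished-at").text = to_iso(finished_at)
    xml = etree.tostring(root, xml_declaration=True, encoding="UTF-8")

    archive = _zip_write(members, RESULT_MEMBER, xml)
    return OutputToken(
        archive=archive,
        job_id=job_id,
        status=status,
        results=[p for p, _ in results],
        logs=[p for p, _ in logs],
        finished_at=finished_at,
    )


def parse_output_token(archive: bytes) -> OutputToken:
    """Read an output token archive back; inverse of :func:`build_output_token`."""
    try:
        zf = zipfile.ZipFile(io.BytesIO(archive))
    except zipfile.BadZipFile as exc:
        raise MissingDescriptorError(f"not a readable zip archive: {exc}") from exc
    with zf:
        if RESULT_MEMBER not in zf.namelist():
            raise MissingDescriptorError(f"archive has no {RESULT_MEMBER} member")
        try:
            root = etree.fromstring(zf.read(RESULT_MEMBER))
        except etree.XMLSyntaxError as exc:
            raise DescriptorSchemaError(f"malformed result XML: {exc}") from exc
    job_el = root.find("job-id")
    status_el = root.find("status")
    if job_el is None or not job_el.text or status_el is None:
        raise DescriptorSchemaError("result descriptor lacks job-id/status")
    results = [m.text or "" for m in root.findall("results/member")]
    logs = [m.text or "" for m in root.findall("logs/member")]
    fin_el = root.find("finished-at")
    return OutputToken(
        archive=archive,
        job_id=job_el.text,
        status=status_el.text or "",
        results=results,
        logs=logs,
        finished_at=from_iso(fin_el.text) if fin_el is not None and fin_el.text else 0.0,
    )
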