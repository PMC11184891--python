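"""Notarisation and certification agent.

Two responsibilities:

1. **Notarisation** — every artefact (request metadata, result token, report
   files) is hashed, the blob stored off-chain in a content-addressed
   directory, and the digest appended to a hash-chained, append-only ledger
   (JSON-lines file).  Each ledger entry's digest covers its index,
   timestamp, payload digest and the previous entry's digest, so any
   in-place mutation is detectable by recomputation; the ledger stands in
   for a single-node blockchain deployment behind a pluggable backend
   contract.

2. **Certification** — the dual-signature workflow.  The sandbox signs the
   report with its private key; the user verifies, countersigns with their
   own key, and uploads the countersignature.  The report is not officially
   issued until both signatures verify, at which point all three report
   artefacts (initial, sandbox-signed, countersigned) are stored off-chain
   and notarised in the ledger.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

from rwdsandbox import signing
from rwdsandbox._clock import system_clock, to_iso
from rwdsandbox.errors import (
    ConfigurationError,
    ContractError,
    DuplicateNotarisationError,
    SignatureError,
    StateMachineError,
)
from rwdsandbox.token_core import DEFAULT_HASH, Digest, hash_artifact

ROLES = (
    "request",
    "result",
    "report-initial",
    "report-sandbox-signed",
    "report-countersigned",
)

GENESIS_DIGEST = "0" * 64


@dataclass(frozen=True)
class LedgerEntry:
    index: int
    timestamp: str  # ISO-8601 UTC
    payload_digest: Digest
    prev_entry_digest: str
    entry_digest: str

    def body(self) -> dict:
        # field order fixed: the entry digest is computed over this exact JSON
        return {
            "index": self.index,
            "timestamp": self.timestamp,
            "payload_algorithm": self.payload_digest.algorithm_id,
            "payload_digest": self.payload_digest.hex,
            "prev_entry_digest": self.prev_entry_digest,
        }


def _entry_digest(body: dict) -> str:
    canon = json.dumps(body, sort_keys=False, separators=(",", ":")).encode()
    return hash_artifact(canon).hex


@dataclass
class OffChainRecord:
    payload_digest: Digest
    blob_path: str
    metadata: dict  # job_id, role, user, timestamp


@dataclass
class SignedReport:
    """Report state machine: issued -> sandbox_signed -> countersigned."""

    job_id: str
    report: bytes
    sandbox_signature: bytes | None = None
    user_signature: bytes | None = None
    state: str = "issued"

    def sandbox_signed_bytes(self) -> bytes:
        """Canonical artefact the user countersigns: report + sandbox
        signature, binding the user's signature to both."""
        if self.sandbox_signature is None:
            raise StateMachineError("report is not sandbox-signed yet")
        return json.dumps(
            {
                "job_id": self.job_id,
                "report": self.report.hex(),
                "sandbox_signature": self.sandbox_signature.hex(),
            },
            separators=(",", ":"),
        ).encode()

    def countersigned_bytes(self) -> bytes:
        if self.user_signature is None:
            raise StateMachineError("report is not countersigned yet")
        return json.dumps(
            {
                "job_id": self.job_id,
                "report": self.report.hex(),
                "sandbox_signature": self.sandbox_signature.hex(),
                "user_signature": self.user_signature.hex(),
            },
            separators=(",", ":"),
        ).encode()


class Notary:
    """Ledger + off-chain store + signature workflow, rooted in a directory.

    Layout::

        <root>/ledger.jsonl          append-only hash chain
        <root>/offchain/<digest>     content-addressed blobs
        <root>/offchain/index.jsonl  (job_id, role) -> digest metadata
    """

    def __init__(self, root: str, clock=system_clock,
                 sandbox_private_key: bytes | None = None,
                 hash_algorithm: str = DEFAULT_HASH):
        self.root = root
        self.clock = clock
        self.hash_algorithm = hash_algorithm
        self._sandbox_key = sandbox_private_key
        self._user_keys: dict[str, bytes] = {}
        self.ledger_path = os.path.join(root, "ledger.jsonl")
        self.offchain_dir = os.path.join(root, "offchain")
        self.index_path = os.path.join(self.offchain_dir, "index.jsonl")
        os.makedirs(self.offchain_dir, exist_ok=True)
        self._seen: set[tuple[str, str]] = set()
        self._first_index: dict[str, int] = {}
        self._length = 0
        self._head = GENESIS_DIGEST
        self._replay()

    # -- key management ---------------------------------------------------

    @property
    def sandbox_public_key(self) -> bytes:
        if self._sandbox_key is None:
            raise ConfigurationError("sandbox keypair not configured")
        return signing.public_key(self._sandbox_key)

    def register_user_key(self, user_id: str, public_key: bytes) -> None:
        self._user_keys[user_id] = public_key

    # -- ledger -----------------------------------------------------------

    def _replay(self) -> None:
        for entry in self.read_ledger():
            self._length = entry.index + 1
            self._head = entry.entry_digest
            self._first_index.setdefault(entry.payload_digest.hex, entry.index)
        if os.path.exists(self.index_path):
            with open(self.index_path) as fh:
                for line in fh:
                    rec = json.loads(line)
                    self._seen.add((rec["job_id"], rec["role"]))

    def read_ledger(self) -> list[LedgerEntry]:
        entries = []
        if os.path.exists(self.ledger_path):
            with open(self.ledger_path) as fh:
                for line in fh:
                    rec = json.loads(line)
                    entries.append(
                        LedgerEntry(
                            index=rec["index"],
                            timestamp=rec["timestamp"],
                            payload_digest=Digest(rec["payload_algorithm"],
                                                  rec["payload_digest"]),
                            prev_entry_digest=rec["prev_entry_digest"],
                            entry_digest=rec["entry_digest"],
                        )
                    )
        return entries

    @property
    def head_digest(self) -> str:
        """Digest of the latest entry — export it to an external anchor to
        make truncation of the single-file ledger detectable."""
        return self._head

    def __len__(self) -> int:
        return self._length

    def notarize(self, payload: bytes, metadata: dict) -> tuple[OffChainRecord, LedgerEntry]:
        """Hash the payload, store it off-chain, then append to the ledger.

        The off-chain write happens strictly before the ledger append.  One
        record per (job_id, role); a second attempt is an error.
        """
        role = metadata.get("role")
        job_id = metadata.get("job_id")
        if role not in ROLES:
            raise ContractError(f"unknown notarisation role {role!r}")
        if not job_id:
            raise ContractError("metadata requires a job_id")
        if (job_id, role) in self._seen:
            raise DuplicateNotarisationError(f"({job_id}, {role}) already notarised")

        ts = to_iso(self.clock())
        digest = hash_artifact(payload, self.hash_algorithm)

        # 1. off-chain: content-addressed blob + index record
        blob_path = os.path.join(self.offchain_dir, digest.hex)
        if not os.path.exists(blob_path):
            with open(blob_path, "wb") as fh:
                fh.write(payload)
        meta = dict(metadata, timestamp=ts, digest=digest.hex,
                    algorithm=digest.algorithm_id)
        with open(self.index_path, "a") as fh:
            fh.write(json.dumps(meta, separators=(",", ":")) + "\n")
        record = OffChainRecord(payload_digest=digest, blob_path=blob_path,
                                metadata=meta)

        # 2. ledger append
        body = {
            "index": self._length,
            "timestamp": ts,
            "payload_algorithm": digest.algorithm_id,
            "payload_digest": digest.hex,
            "prev_entry_digest": self._head,
        }
        entry = LedgerEntry(
            index=self._length,
            timestamp=ts,
            payload_digest=digest,
            prev_entry_digest=self._head,
            entry_digest=_entry_digest(body),
        )
        with open(self.ledger_path, "a") as fh:
            fh.write(json.dumps(dict(body, entry_digest=entry.entry_digest),
                                separators=(",", ":")) + "\n")
        self._length += 1
        self._head = entry.entry_digest
        self._seen.add((job_id, role))
        self._first_index.setdefault(digest.hex, entry.index)
        return record, entry

    def verify_ledger(self) -> tuple[bool, int | None]:
        """Recompute every entry digest and chain link.

        Returns ``(True, None)`` for an intact chain, else ``(False, i)``
        with the earliest violated index.  A truncated tail is not
        detectable from the file alone (append-only model); anchor
        :attr:`head_digest` externally for that.
        """
        prev = GENESIS_DIGEST
        if not os.path.exists(self.ledger_path):
            return True, None
        with open(self.ledger_path) as fh:
            lines = [ln for ln in fh.read().splitlines() if ln.strip()]
        for i, line in enumerate(lines):
            try:
                rec = json.loads(line)
                entry = LedgerEntry(
                    index=rec["index"],
                    timestamp=rec["timestamp"],
                    payload_digest=Digest(rec["payload_algorithm"],
                                          rec["payload_digest"]),
                    prev_entry_digest=rec["prev_entry_digest"],
                    entry_digest=rec["entry_digest"],
                )
            except (ValueError, KeyError, TypeError, ContractError):
                return False, i  # unparseable line is tampering too
            if entry.index != i:
                return False, i
            if entry.prev_entry_digest != prev:
                return False, i
            if _entry_digest(entry.body()) != entry.entry_digest:
                return False, i
            prev = entry.entry_digest
        return True, None

    def verify_offchain(self) -> tuple[bool, str | None]:
        """Check every off-chain blob still matches its recorded digest."""
        if os.path.exists(self.index_path):
            with open(self.index_path) as fh:
                for line in fh:
                    rec = json.loads(line)
                    blob_path = os.path.join(self.offchain_dir, rec["digest"])
                    if not os.path.exists(blob_path):
                        return False, rec["digest"]
                    with open(blob_path, "rb") as bf:
                        actual = hash_artifact(bf.read(), rec["algorithm"]).hex
                    if actual != rec["digest"]:
                        return False, rec["digest"]
        return True, None

    def proof_of_existence(self, digest: Digest | str) -> tuple[bool, int | None, str | None]:
        """Was this digest ever notarised?  Returns the earliest entry."""
        hexd = digest.hex if isinstance(digest, Digest) else digest
        idx = self._first_index.get(hexd)
        if idx is None:
            return False, None, None
        return True, idx, self.read_ledger()[idx].timestamp

    # -- dual-signature workflow ------------------------------------------

    def sign_report(self, job_id: str, report: bytes) -> SignedReport:
        """Sandbox-sign the report bytes (detached Ed25519 signature)."""
        if self._sandbox_key is None:
            raise ConfigurationError("sandbox keypair not configured")
        sig = signing.sign(self._sandbox_key, report)
        return SignedReport(job_id=job_id, report=report,
                            sandbox_signature=sig, state="sandbox_signed")

    def countersign(self, report: SignedReport, user_id: str,
                    user_signature: bytes) -> SignedReport:
        """Verify the user's countersignature and officially issue the report.

        The user signs the canonical sandbox-signed artefact.  On success the
        three report artefacts — initial, sandbox-signed, countersigned — are
        each stored off-chain and appended to the ledger.
        """
        if report.state != "sandbox_signed":
            raise StateMachineError(
                f"countersign requires state sandbox_signed, got {report.state}"
            )
        pub = self._user_keys.get(user_id)
        if pub is None:
            raise ConfigurationError(f"no public key registered for {user_id!r}")
        if not signing.verify(pub, report.sandbox_signed_bytes(), user_signature):
            raise SignatureError(f"user countersignature for job {report.job_id} "
                                 "does not verify; report not issued")
        report.user_signature = user_signature
        report.state = "countersigned"
        base = {"job_id": report.job_id, "user": user_id}
        self.notarize(report.report, dict(base, role="report-initial"))
        self.notarize(report.sandbox_signed_bytes(),
                      dict(base, role="report-sandbox-signed"))
        self.notarize(report.countersigned_bytes(),
                      dict(base, role="report-countersigned"))
        return report

    def verify_report(self, report: SignedReport, user_id: str | None = None) -> bool:
        """Check whichever signatures the report's state claims to have."""
        if report.state == "issued":
            return True
        if report.sandbox_signature is None or not signing.verify(
            self.sandbox_public_key, report.report, report.sandbox_signature
        ):
            return False
        if report.state == "countersigned":
            pub = self._user_keys.get(user_id or "")
            if pub is None or report.user_signature is None:
                return False
            return signing.verify(pub, report.sandbox_signed_bytes(),
                                  report.user_signature)
        return True

    def report_files(self, job_id: str) -> list[dict]:
        """Off-chain index records of the report artefacts for one job."""
        out = []
        if os.path.exists(self.index_path):
            with open(self.index_path) as fh:
                for line in fh:
                    rec = json.loads(line)
                    if rec["job_id"] == job_id and rec["role"].startswith("report-"):
                        out.append(rec)
        return out
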