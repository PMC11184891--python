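"""Identity and access management agent.

Principals authenticate through pluggable *profiles* (several logical
profiles per physical user: a built-in local password profile, plus an
injectable directory-service stub for tests).  Successful authentication
issues a time-limited *session ticket* — a 256-bit random URL-safe string —
which every subsequent permission check must present, so revocation and
expiry act centrally on this one agent.

Resources are generic *items* (datamarts, algorithms, explicit pairs).
Grants attach items to principals or to groups; groups form an acyclic
parent hierarchy, and a grant anywhere along the membership/parent closure
applies.  Checks fail closed: unknown items and missing paths deny; dead
tickets report auth-required, distinct from denial.

State persists in a single-file embedded relational database (sqlite).
"""

from __future__ import annotations

import hashlib
import hmac
import secrets
import sqlite3
from dataclasses import dataclass

from rwdsandbox._clock import system_clock
from rwdsandbox.errors import ContractError

DEFAULT_TTL = 8 * 3600.0  # seconds
PBKDF2_ITERATIONS = 50_000
ITEM_KINDS = ("datamart", "algorithm", "pair", "other")

ALLOW, DENY, AUTH_REQUIRED = "allow", "deny", "auth-required"


def pair_item_id(datamart_item: str, algorithm_item: str) -> str:
    """Canonical item id for an explicit (datamart, algorithm) pair grant."""
    return f"pair::{datamart_item}::{algorithm_item}"


@dataclass
class Session:
    ticket: str
    user_id: str
    issued_at: float
    expires_at: float
    revoked: bool = False


class AuthProfile:
    """Authentication backend contract: verify credentials for a user."""

    kind = "abstract"

    def verify(self, user_id: str, credentials: str) -> bool:  # pragma: no cover
        raise NotImplementedError


class LocalProfile(AuthProfile):
    """Salted, iterated password hashes stored in the agent's database."""

    kind = "local"

    def __init__(self, agent: "PermAgent"):
        self._agent = agent

    def verify(self, user_id: str, credentials: str) -> bool:
        row = self._agent._db.execute(
            "SELECT salt, pw_hash, iterations FROM local_credentials WHERE user_id=?",
            (user_id,),
        ).fetchone()
        if row is None:
            # burn the same work as a real check so unknown-user and
            # bad-password failures are indistinguishable
            hashlib.pbkdf2_hmac("sha256", credentials.encode(),
                                b"\x00" * 16, PBKDF2_ITERATIONS)
            return False
        salt, stored, iterations = row
        candidate = hashlib.pbkdf2_hmac("sha256", credentials.encode(),
                                        salt, iterations)
        return hmac.compare_digest(candidate, stored)


class PermAgent:
    """The permission agent: users, groups, items, grants, sessions."""

    def __init__(self, db_path: str = ":memory:", clock=system_clock,
                 session_ttl: float = DEFAULT_TTL):
        self.clock = clock
        self.session_ttl = session_ttl
        self._db = sqlite3.connect(db_path, check_same_thread=False)
        self._db.executescript(
            """
            CREATE TABLE IF NOT EXISTS principals (user_id TEXT PRIMARY KEY);
            CREATE TABLE IF NOT EXISTS local_credentials (
                user_id TEXT PRIMARY KEY, salt BLOB, pw_hash BLOB,
                iterations INTEGER);
            CREATE TABLE IF NOT EXISTS groups (
                group_id TEXT PRIMARY KEY, parent TEXT);
            CREATE TABLE IF NOT EXISTS memberships (
                user_id TEXT, group_id TEXT,
                UNIQUE(user_id, group_id));
            CREATE TABLE IF NOT EXISTS items (
                item_id TEXT PRIMARY KEY, kind TEXT);
            CREATE TABLE IF NOT EXISTS grants (
                subject_type TEXT, subject_id TEXT, item_id TEXT,
                effect TEXT, granted_at REAL,
                UNIQUE(subject_type, subject_id, item_id));
            CREATE TABLE IF NOT EXISTS sessions (
                ticket TEXT PRIMARY KEY, user_id TEXT,
                issued_at REAL, expires_at REAL, revoked INTEGER);
            """
        )
        self._profiles: dict[str, AuthProfile] = {"local": LocalProfile(self)}

    def register_profile(self, profile: AuthProfile) -> None:
        self._profiles[profile.kind] = profile

    # -- directory management --------------------------------------------

    def add_user(self, user_id: str, password: str | None = None) -> None:
        if not user_id:
            raise ContractError("user_id must be non-empty")
        self._db.execute("INSERT OR IGNORE INTO principals VALUES (?)", (user_id,))
        if password is not None:
            salt = secrets.token_bytes(16)
            pw_hash = hashlib.pbkdf2_hmac("sha256", password.encode(), salt,
                                          PBKDF2_ITERATIONS)
            self._db.execute(
                "INSERT OR REPLACE INTO local_credentials VALUES (?,?,?,?)",
                (user_id, salt, pw_hash, PBKDF2_ITERATIONS),
            )
        self._db.commit()

    def add_group(self, group_id: str, parent: str | None = None) -> None:
        if parent is not None:
            # reject cycles before insert: walk up from the proposed parent
            seen, cur = {group_id}, parent
            while cur is not None:
                if cur in seen:
                    raise ContractError(
                        f"group {group_id!r} with parent {parent!r} forms a cycle"
                    )
                seen.add(cur)
                row = self._db.execute(
                    "SELECT parent FROM groups WHERE group_id=?", (cur,)
                ).fetchone()
                cur = row[0] if row else None
        self._db.execute("INSERT OR REPLACE INTO groups VALUES (?,?)",
                         (group_id, parent))
        self._db.commit()

    def add_member(self, user_id: str, group_id: str) -> None:
        self._db.execute("INSERT OR IGNORE INTO memberships VALUES (?,?)",
                         (user_id, group_id))
        self._db.commit()

    def add_item(self, item_id: str, kind: str = "other") -> None:
        if kind not in ITEM_KINDS:
            raise ContractError(f"unknown item kind {kind!r}")
        self._db.execute("INSERT OR IGNORE INTO items VALUES (?,?)",
                         (item_id, kind))
        self._db.commit()

    def grant(self, subject: str, item_id: str, *, group: bool = False,
              effect: str = ALLOW) -> None:
        if effect not in (ALLOW, DENY):
            raise ContractError(f"grant effect must be allow|deny, got {effect!r}")
        self._db.execute(
            "INSERT OR REPLACE INTO grants VALUES (?,?,?,?,?)",
            ("group" if group else "user", subject, item_id, effect, self.clock()),
        )
        self._db.commit()

    def revoke_grant(self, subject: str, item_id: str, *, group: bool = False) -> bool:
        cur = self._db.execute(
            "DELETE FROM grants WHERE subject_type=? AND subject_id=? AND item_id=?",
            ("group" if group else "user", subject, item_id),
        )
        self._db.commit()
        return cur.rowcount > 0

    # -- sessions ---------------------------------------------------------

    def authenticate(self, user_id: str, credentials: str,
                     profile_kind: str = "local") -> Session | None:
        """Verify credentials; on success issue a fresh session ticket.

        Every login creates an independent session.  Failures (unknown user,
        wrong password, unknown profile) all return None with the same work
        done, leaking nothing about which part failed.
        """
        profile = self._profiles.get(profile_kind)
        if profile is None or not profile.verify(user_id, credentials):
            return None
        now = self.clock()
        session = Session(
            ticket=secrets.token_urlsafe(32),  # 256 bits
            user_id=user_id,
            issued_at=now,
            expires_at=now + self.session_ttl,
        )
        self._db.execute(
            "INSERT INTO sessions VALUES (?,?,?,?,0)",
            (session.ticket, user_id, session.issued_at, session.expires_at),
        )
        self._db.commit()
        return session

    def session_user(self, ticket: str) -> str | None:
        """User id behind a live ticket, or None if dead/unknown."""
        row = self._db.execute(
            "SELECT user_id, expires_at, revoked FROM sessions WHERE ticket=?",
            (ticket,),
        ).fetchone()
        if row is None or row[2] or row[1] <= self.clock():
            return None
        return row[0]

    def revoke_session(self, ticket: str) -> bool:
        cur = self._db.execute(
            "UPDATE sessions SET revoked=1 WHERE ticket=?", (ticket,)
        )
        self._db.commit()
        return cur.rowcount > 0

    # -- permission checks -------------------------------------------------

    def _group_closure(self, user_id: str) -> set[str]:
        """Direct memberships plus all ancestor groups."""
        direct = {
            g for (g,) in self._db.execute(
                "SELECT group_id FROM memberships WHERE user_id=?", (user_id,)
            )
        }
        closure: set[str] = set()
        stack = list(direct)
        while stack:
            g = stack.pop()
            if g in closure:
                continue
            closure.add(g)
            row = self._db.execute(
                "SELECT parent FROM groups WHERE group_id=?", (g,)
            ).fetchone()
            if row and row[0] is not None:
                stack.append(row[0])
        return closure

    def _granted(self, user_id: str, item_id: str, effect: str) -> bool:
        if self._db.execute(
            "SELECT 1 FROM grants WHERE subject_type='user' AND subject_id=? "
            "AND item_id=? AND effect=?", (user_id, item_id, effect),
        ).fetchone():
            return True
        closure = self._group_closure(user_id)
        if not closure:
            return False
        marks = ",".join("?" * len(closure))
        return self._db.execute(
            f"SELECT 1 FROM grants WHERE subject_type='group' AND subject_id "
            f"IN ({marks}) AND item_id=? AND effect=?",
            (*closure, item_id, effect),
        ).fetchone() is not None

    def check_permission(self, ticket: str, item_id: str) -> str:
        """allow | deny | auth-required.

        Allow iff the ticket is live and a grant reaches the item through
        the user or the group closure; unknown items deny (fail closed);
        dead tickets report auth-required regardless of grants.
        """
        user_id = self.session_user(ticket)
        if user_id is None:
            return AUTH_REQUIRED
        if self._db.execute("SELECT 1 FROM items WHERE item_id=?",
                            (item_id,)).fetchone() is None:
            return DENY
        if self._granted(user_id, item_id, DENY):
            return DENY
        return ALLOW if self._granted(user_id, item_id, ALLOW) else DENY

    def check_pair(self, ticket: str, datamart_item: str,
                   algorithm_item: str) -> str:
        """Authorise an analysis pair: both items must be allowed; an
        explicit pair item may override either way, deny winning."""
        user_id = self.session_user(ticket)
        if user_id is None:
            return AUTH_REQUIRED
        pid = pair_item_id(datamart_item, algorithm_item)
        if self._db.execute("SELECT 1 FROM items WHERE item_id=?",
                            (pid,)).fetchone() is not None:
            if self._granted(user_id, pid, DENY):
                return DENY
            if self._granted(user_id, pid, ALLOW):
                return ALLOW
        dm = self.check_permission(ticket, datamart_item)
        alg = self.check_permission(ticket, algorithm_item)
        return ALLOW if dm == ALLOW and alg == ALLOW else DENY
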