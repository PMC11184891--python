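"""Periodic task scheduler.

Holds the list of scheduled job templates and fires triggers at fixed
instants.  GUI-originated controls add, freeze, resume or remove tasks; a
removed task is terminal.  Due instants are anchored to the task's creation
time (interval cadence) or the calendar rule (daily cadence).  Missed
instants are not back-filled: after a clock jump the task fires once and
resumes from the next cadence point, since analytics jobs are snapshot-like
and a backlog of identical runs has no value.

Fires are exactly-once per (task, due instant): a trigger whose submission
fails is retried on the next tick, deduplicated by its due instant.  The
task list is journaled to disk (JSON-lines) so a restart reloads it.
"""

from __future__ import annotations

import itertools
import json
import math
import os
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone

from rwdsandbox._clock import system_clock
from rwdsandbox.errors import ContractError, StateMachineError
from rwdsandbox.token_core import CadenceSpec

ACTIVE, FROZEN, REMOVED = "active", "frozen", "removed"


@dataclass
class ScheduledTask:
    task_id: str
    template: dict  # a job request minus job_id
    cadence: CadenceSpec
    anchor: float
    next_fire_at: float
    state: str = ACTIVE
    fired_instants: set = field(default_factory=set)
    fire_count: int = 0


def _next_instant(cadence: CadenceSpec, anchor: float, after: float) -> float:
    """Smallest due instant strictly after ``after``."""
    if cadence.kind == "interval":
        iv = cadence.interval_seconds
        k = max(1, math.floor((after - anchor) / iv) + 1)
        t = anchor + k * iv
        while t <= after:  # guard float rounding
            k += 1
            t = anchor + k * iv
        return t
    # daily HH:MM UTC
    hh, mm = (int(x) for x in cadence.value.split(":"))
    dt = datetime.fromtimestamp(after, tz=timezone.utc)
    candidate = dt.replace(hour=hh, minute=mm, second=0, microsecond=0)
    if candidate.timestamp() <= after:
        candidate += timedelta(days=1)
    return candidate.timestamp()


@dataclass
class Trigger:
    task_id: str
    job_id: str
    due_at: float
    template: dict


class Scheduler:
    """Task list + tick loop.  ``submit`` is the proxy-facing callback
    receiving each Trigger; raise from it to signal the proxy unreachable
    (the trigger is retried next tick)."""

    def __init__(self, submit, clock=system_clock, journal_path: str | None = None):
        self.submit = submit
        self.clock = clock
        self.journal_path = journal_path
        self.tasks: dict[str, ScheduledTask] = {}
        self._ids = itertools.count(1)
        self._pending_retry: list[Trigger] = []
        if journal_path and os.path.exists(journal_path):
            self._replay_journal()

    # -- journal ----------------------------------------------------------

    def _journal(self, event: dict) -> None:
        if self.journal_path:
            with open(self.journal_path, "a") as fh:
                fh.write(json.dumps(event, separators=(",", ":")) + "\n")

    def _replay_journal(self) -> None:
        with open(self.journal_path) as fh:
            for line in fh:
                ev = json.loads(line)
                kind = ev["event"]
                if kind == "add":
                    task = ScheduledTask(
                        task_id=ev["task_id"],
                        template=ev["template"],
                        cadence=CadenceSpec(ev["cadence_kind"], ev["cadence_value"]),
                        anchor=ev["anchor"],
                        next_fire_at=ev["next_fire_at"],
                    )
                    self.tasks[task.task_id] = task
                    n = int(ev["task_id"].split("-")[-1])
                    self._ids = itertools.count(max(n + 1, next(self._ids)))
                elif kind == "control":
                    t = self.tasks.get(ev["task_id"])
                    if t:
                        t.state = ev["state"]
                        if "next_fire_at" in ev:
                            t.next_fire_at = ev["next_fire_at"]
                elif kind == "fire":
                    t = self.tasks.get(ev["task_id"])
                    if t:
                        t.fired_instants.add(ev["due_at"])
                        t.fire_count = ev["fire_count"]
                        t.next_fire_at = ev["next_fire_at"]

    # -- task management ---------------------------------------------------

    def add_task(self, template: dict, cadence: CadenceSpec) -> str:
        """Register an active task; next_fire_at computed from the cadence
        anchor (now)."""
        if not isinstance(cadence, CadenceSpec):
            raise ContractError("cadence must be a CadenceSpec")
        now = self.clock()
        task_id = f"task-{next(self._ids)}"
        task = ScheduledTask(
            task_id=task_id,
            template=dict(template),
            cadence=cadence,
            anchor=now,
            next_fire_at=_next_instant(cadence, now, now),
        )
        self.tasks[task_id] = task
        self._journal({"event": "add", "task_id": task_id,
                       "template": task.template,
                       "cadence_kind": cadence.kind,
                       "cadence_value": cadence.value,
                       "anchor": now, "next_fire_at": task.next_fire_at})
        return task_id

    def control_task(self, task_id: str, action: str) -> str:
        """freeze | resume | remove.  Transitions: active<->frozen,
        {active,frozen}->removed; removed is terminal."""
        task = self.tasks.get(task_id)
        if task is None:
            raise ContractError(f"unknown task {task_id!r}")
        if task.state == REMOVED:
            raise StateMachineError(f"task {task_id} is removed (terminal)")
        if action == "freeze":
            task.state = FROZEN
            self._journal({"event": "control", "task_id": task_id, "state": FROZEN})
        elif action == "resume":
            # no catch-up: resume from the next cadence point after now
            task.state = ACTIVE
            task.next_fire_at = _next_instant(task.cadence, task.anchor, self.clock())
            self._journal({"event": "control", "task_id": task_id,
                           "state": ACTIVE, "next_fire_at": task.next_fire_at})
        elif action == "remove":
            task.state = REMOVED
            self._journal({"event": "control", "task_id": task_id, "state": REMOVED})
        else:
            raise ContractError(f"unknown action {action!r}")
        return task.state

    # -- firing ------------------------------------------------------------

    def tick(self, now: float | None = None) -> list[Trigger]:
        """Fire every active task whose next due instant has passed.

        Each due instant fires at most once per task; with the no-catch-up
        policy a jump over several instants yields a single fire.  Failed
        submissions are retried on the next tick.
        """
        now = self.clock() if now is None else now
        fired: list[Trigger] = []

        retries, self._pending_retry = self._pending_retry, []
        for trig in retries:
            task = self.tasks.get(trig.task_id)
            if task is None or task.state != ACTIVE:
                continue
            self._deliver(task, trig, fired)

        for task_id in sorted(self.tasks):  # deterministic same-instant order
            task = self.tasks[task_id]
            if task.state != ACTIVE or task.next_fire_at > now:
                continue
            due = task.next_fire_at
            task.next_fire_at = _next_instant(task.cadence, task.anchor, now)
            if due in task.fired_instants:
                continue
            trig = Trigger(
                task_id=task_id,
                job_id=f"{task_id}-run{task.fire_count + 1}",
                due_at=due,
                template=task.template,
            )
            self._deliver(task, trig, fired)
        return fired

    def _deliver(self, task: ScheduledTask, trig: Trigger,
                 fired: list[Trigger]) -> None:
        if trig.due_at in task.fired_instants:
            return
        try:
            self.submit(trig)
        except Exception:
            self._pending_retry.append(trig)
            return
        task.fired_instants.add(trig.due_at)
        task.fire_count += 1
        fired.append(trig)
        self._journal({"event": "fire", "task_id": task.task_id,
                       "due_at": trig.due_at, "fire_count": task.fire_count,
                       "next_fire_at": task.next_fire_at})
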