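"""The black-box task executor.

A processor watches one or more input folders.  When a token archive
appears it is *claimed* — atomically renamed into a per-processor
``processing/`` directory so no second watcher can take it — executed
through a backend chosen by the descriptor's algorithm reference, and the
outcome deposited in the output folder as a fresh output token.  Execution
failures never crash the watcher: a corrupt or unrunnable token always
yields a failure output token with the error in its logs.

Backends:

* ``script`` — the algorithm is an executable script carried in the token
  or resolved from the local algorithm repository.  ``.py`` runs under the
  Python interpreter, ``.R``/``.r`` under Rscript, anything else directly.
* ``image`` — a container image name.  Images must already be present in
  the configured local store; pulling from remote registries is disabled by
  policy, so an unknown image is refused rather than fetched.  The built-in
  :class:`LocalImageStore` is a simulated OCI-style store mapping image
  names to locally loaded bundles (an entrypoint script); pointing the
  contract at a real container engine is an extension point.

Each job gets its own working directory (payload extracted, ``results/``
prepared, run settings as ``settings.json``) and its own log file — logs
are never shared between jobs.  Polling rather than filesystem events keeps
behaviour portable and lets tests drive the loop deterministically.
"""

from __future__ import annotations

import io
import json
import os
import queue
import subprocess
import sys
import threading
import zipfile
from dataclasses import dataclass, field

from rwdsandbox._clock import system_clock, to_iso
from rwdsandbox.errors import ContractError, RemotePullRefusedError, SandboxError
from rwdsandbox.token_core import (
    OutputToken,
    Token,
    build_output_token,
    parse_token,
)

DEFAULT_TIMEOUT = 3600.0  # seconds per job


@dataclass
class ProcessorConfig:
    processor_id: str
    input_folders: list[str]
    output_folder: str
    sync_folder: str
    work_folder: str
    poll_interval: float = 2.0
    max_parallel: int = 1
    job_timeout: float = DEFAULT_TIMEOUT

    def __post_init__(self):
        if self.max_parallel < 1:
            raise ContractError("max_parallel must be >= 1")
        folders = [*self.input_folders, self.output_folder, self.sync_folder,
                   self.work_folder]
        if len(set(map(os.path.abspath, folders))) != len(folders):
            raise ContractError("processor folders must be distinct")
        for f in folders:
            os.makedirs(f, exist_ok=True)
        os.makedirs(self.processing_folder, exist_ok=True)
        os.makedirs(self.done_folder, exist_ok=True)

    @property
    def processing_folder(self) -> str:
        return os.path.join(self.work_folder, "processing")

    @property
    def done_folder(self) -> str:
        return os.path.join(self.work_folder, "done")


@dataclass
class ExecutionRecord:
    job_id: str
    backend: str
    started_at: float
    finished_at: float | None = None
    exit_status: int | None = None
    log_path: str = ""


class ImageStore:
    """Local container-image store contract."""

    def resolve(self, image: str) -> str:  # pragma: no cover - contract
        """Entrypoint path for a locally present image; raise
        RemotePullRefusedError if absent (never pull)."""
        raise NotImplementedError


class LocalImageStore(ImageStore):
    """Simulated OCI-style local store: image name -> loaded bundle.

    ``load(name, entrypoint)`` corresponds to side-loading an image into
    the hospital zone; anything not loaded is refused, enforcing the
    no-remote-pull policy.
    """

    def __init__(self):
        self._images: dict[str, str] = {}

    def load(self, image: str, entrypoint: str) -> None:
        self._images[image] = entrypoint

    def resolve(self, image: str) -> str:
        if image not in self._images:
            raise RemotePullRefusedError(
                f"image {image!r} not in the local store; "
                "pulling from external repositories is not enabled"
            )
        return self._images[image]


class AlgorithmRepository:
    """Local script repository: locator -> script path on disk."""

    def __init__(self, scripts: dict[str, str] | None = None):
        self._scripts = dict(scripts or {})

    def register(self, locator: str, path: str) -> None:
        self._scripts[locator] = path

    def resolve(self, locator: str) -> str:
        if locator not in self._scripts:
            raise SandboxError(f"locator {locator!r} not in the local repository")
        return self._scripts[locator]


def _interpreter_for(path: str) -> list[str]:
    if path.endswith(".py"):
        return [sys.executable, path]
    if path.lower().endswith(".r"):
        return ["Rscript", path]
    return [path]


def run_backend(kind: str, entrypoint: str, workdir: str, log_path: str,
                timeout: float = DEFAULT_TIMEOUT) -> int:
    """Run one backend invocation in an isolated working directory.

    stdout/stderr are captured into the per-job log file; returns the exit
    status.  A timeout kills the process and reports exit status -1 with a
    timeout marker in the log.
    """
    if kind == "script":
        cmd = _interpreter_for(entrypoint)
    elif kind == "image":
        # entrypoint is the bundle entrypoint resolved by the image store
        cmd = _interpreter_for(entrypoint)
    else:
        raise SandboxError(f"unknown backend kind {kind!r}")
    with open(log_path, "ab") as log:
        try:
            proc = subprocess.run(
                cmd, cwd=workdir, stdout=subprocess.PIPE,
                stderr=subprocess.STDOUT, timeout=timeout,
            )
            log.write(proc.stdout)
            return proc.returncode
        except subprocess.TimeoutExpired as exc:
            if exc.stdout:
                log.write(exc.stdout)
            log.write(f"\n[timeout] job exceeded {timeout} s and was killed\n".encode())
            return -1
        except OSError as exc:
            log.write(f"[backend error] {exc}\n".encode())
            return -1


class Processor:
    """Folder-watching executor.

    ``poll_once()`` performs one watch cycle (claim new tokens, start
    executions up to ``max_parallel``, write heartbeat); ``run(stop_event)``
    loops it at the configured interval.  ``wait_idle()`` blocks until all
    claimed tokens have produced output tokens — tests drive the processor
    with ``poll_once()`` + ``wait_idle()`` for determinism.
    """

    def __init__(self, config: ProcessorConfig, clock=system_clock,
                 image_store: ImageStore | None = None,
                 algorithm_repository: AlgorithmRepository | None = None):
        self.config = config
        self.clock = clock
        self.image_store = image_store or LocalImageStore()
        self.algorithm_repository = algorithm_repository or AlgorithmRepository()
        self.records: list[ExecutionRecord] = []
        self._queue: queue.Queue[str] = queue.Queue()
        self._lock = threading.Lock()
        self._active = 0
        self._claimed = 0
        self._deposited = 0
        self.max_concurrent_observed = 0
        self._workers: list[threading.Thread] = []
        self._stop = threading.Event()
        self._ensure_workers()

    # -- worker pool ------------------------------------------------------

    def _ensure_workers(self) -> None:
        while len(self._workers) < self.config.max_parallel:
            t = threading.Thread(target=self._worker_loop, daemon=True)
            t.start()
            self._workers.append(t)

    def _worker_loop(self) -> None:
        while not self._stop.is_set():
            try:
                claimed_path = self._queue.get(timeout=0.05)
            except queue.Empty:
                continue
            with self._lock:
                self._active += 1
                self.max_concurrent_observed = max(
                    self.max_concurrent_observed, self._active)
            try:
                self._process_claimed(claimed_path)
            finally:
                with self._lock:
                    self._active -= 1
                self._queue.task_done()

    # -- watch cycle ------------------------------------------------------

    def poll_once(self) -> int:
        """One poll: claim every token file in the input folders (atomic
        rename into processing/), queue them in claim order, refresh the
        heartbeat.  Returns the number of tokens claimed."""
        claimed = 0
        for folder in self.config.input_folders:
            for name in sorted(os.listdir(folder)):
                if not (name.startswith("token_") and name.endswith(".zip")):
                    continue
                src = os.path.join(folder, name)
                dst = os.path.join(self.config.processing_folder, name)
                try:
                    os.rename(src, dst)  # atomic claim; loser raises
                except OSError:
                    continue
                with self._lock:
                    self._claimed += 1
                self._queue.put(dst)
                claimed += 1
        self._heartbeat()
        return claimed

    def _heartbeat(self) -> None:
        path = os.path.join(self.config.sync_folder,
                            f"heartbeat_{self.config.processor_id}.txt")
        with open(path, "w") as fh:
            fh.write(to_iso(self.clock()) + "\n")

    def _status(self, job_id: str, state: str) -> None:
        path = os.path.join(self.config.sync_folder, f"{job_id}.status")
        with open(path, "w") as fh:
            fh.write(json.dumps({"job_id": job_id, "state": state,
                                 "processor": self.config.processor_id,
                                 "at": to_iso(self.clock())}) + "\n")

    def wait_idle(self, timeout: float = 60.0) -> None:
        import time
        deadline = time.monotonic() + timeout
        while time.monotonic() < deadline:
            with self._lock:
                idle = self._active == 0 and self._queue.empty()
            if idle:
                return
            time.sleep(0.01)
        raise TimeoutError("processor did not drain in time")

    def stop(self) -> None:
        self._stop.set()

    def run(self, stop_event: threading.Event | None = None) -> None:
        """Continuous watch loop for CLI use."""
        import time
        stop_event = stop_event or threading.Event()
        while not stop_event.is_set():
            self.poll_once()
            time.sleep(self.config.poll_interval)

    # -- execution --------------------------------------------------------

    def _process_claimed(self, claimed_path: str) -> None:
        name = os.path.basename(claimed_path)
        job_id = name[len("token_"):-len(".zip")] or "unknown"
        try:
            with open(claimed_path, "rb") as fh:
                data = fh.read()
            token = parse_token(data)
            out = self.execute_token(token)
        except SandboxError as exc:
            out = build_output_token(
                job_id, "failure", [],
                [("logs/parse-error.log",
                  f"token could not be parsed: {exc}\n".encode())],
                self.clock(),
            )
        self._deposit(out)
        done = os.path.join(self.config.done_folder, name)
        try:
            os.rename(claimed_path, done)
        except OSError:
            pass

    def _deposit(self, out: OutputToken) -> None:
        final = os.path.join(self.config.output_folder, f"out_{out.job_id}.zip")
        tmp = final + ".tmp"
        with open(tmp, "wb") as fh:
            fh.write(out.archive)
        os.rename(tmp, final)
        with self._lock:
            self._deposited += 1
        self._status(out.job_id, "done" if out.status == "success" else "failed")

    @property
    def counters(self) -> dict:
        with self._lock:
            return {"claimed": self._claimed, "deposited": self._deposited}

    def execute_token(self, token: Token) -> OutputToken:
        """Resolve the backend, run the task in a fresh working directory,
        and collect results/ and the per-job log into an output token."""
        desc = token.descriptor
        job_id = desc.job_id
        workdir = os.path.abspath(
            os.path.join(self.config.work_folder, f"job_{job_id}"))
        os.makedirs(workdir, exist_ok=True)
        results_dir = os.path.join(workdir, "results")
        os.makedirs(results_dir, exist_ok=True)
        log_path = os.path.join(workdir, f"{job_id}.log")
        self._status(job_id, "running")

        started = self.clock()
        record = ExecutionRecord(job_id=job_id, backend=desc.algorithm_ref.kind,
                                 started_at=started, log_path=log_path)
        self.records.append(record)

        def fail(reason: str) -> OutputToken:
            with open(log_path, "a") as fh:
                fh.write(reason + "\n")
            record.finished_at = self.clock()
            record.exit_status = -1
            with open(log_path, "rb") as fh:
                log_bytes = fh.read()
            return build_output_token(job_id, "failure", [],
                                      [(f"logs/{job_id}.log", log_bytes)],
                                      record.finished_at)

        # unpack payload members into the working directory
        with zipfile.ZipFile(io.BytesIO(token.archive)) as zf:
            for member in token.manifest:
                target = os.path.normpath(os.path.join(workdir, member))
                if not target.startswith(os.path.abspath(workdir) + os.sep) \
                        and target != os.path.abspath(workdir):
                    return fail(f"[safety] member {member!r} escapes the workdir")
                os.makedirs(os.path.dirname(target), exist_ok=True)
                with open(target, "wb") as fh:
                    fh.write(zf.read(member))
        with open(os.path.join(workdir, "settings.json"), "w") as fh:
            json.dump(desc.run_settings, fh)

        # resolve the backend
        ref = desc.algorithm_ref
        try:
            if ref.kind == "script":
                entry = os.path.join(workdir, ref.value)
                if not os.path.exists(entry):
                    return fail(f"[backend] script member {ref.value!r} missing")
                kind = "script"
            elif ref.kind == "image":
                entry = self.image_store.resolve(ref.value)
                kind = "image"
            elif ref.kind == "repository":
                entry = self.algorithm_repository.resolve(ref.value)
                kind = "script"
            else:
                return fail(f"[backend] unknown backend kind {ref.kind!r}")
        except SandboxError as exc:
            return fail(f"[backend] {exc}")

        with open(log_path, "a") as fh:
            fh.write(f"[{job_id}] backend={kind} entry={os.path.basename(entry)} "
                     f"started={to_iso(started)}\n")
        exit_status = run_backend(kind, entry, workdir, log_path,
                                  timeout=self.config.job_timeout)
        record.finished_at = self.clock()
        record.exit_status = exit_status

        with open(log_path, "rb") as fh:
            log_bytes = fh.read()
        logs = [(f"logs/{job_id}.log", log_bytes)]
        results: list[tuple[str, bytes]] = []
        for dirpath, _, files in os.walk(results_dir):
            for fname in sorted(files):
                full = os.path.join(dirpath, fname)
                rel = os.path.relpath(full, workdir).replace(os.sep, "/")
                with open(full, "rb") as fh:
                    results.append((rel, fh.read()))
        status = "success" if exit_status == 0 else "failure"
        return build_output_token(job_id, status, results, logs,
                                  record.finished_at)
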