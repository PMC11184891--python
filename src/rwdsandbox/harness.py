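"""In-process deployment harness and headless reference client.

Wires a complete platform — permission agent, notary, one or more
processors, proxy, GUI channels — into a directory tree, so end-to-end
scenarios (submit → execute → sign → countersign) run in a single process
with an injectable clock.  This is both the test double for a real
deployment and the quickest way to demo the platform.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from rwdsandbox import signing
from rwdsandbox._clock import system_clock
from rwdsandbox.fixtures import (
    default_patient_schema,
    generate_datamart,
    to_csv_bytes,
    toy_algorithm_catalog,
)
from rwdsandbox.gui_protocol import GuiChannel, JobRequest, StatusMessage
from rwdsandbox.notary import Notary, SignedReport
from rwdsandbox.perm_agent import PermAgent
from rwdsandbox.processor import (
    AlgorithmRepository,
    LocalImageStore,
    Processor,
    ProcessorConfig,
)
from rwdsandbox.proxy import (
    AlgorithmEntry,
    DatamartEntry,
    ProcessorHandle,
    Proxy,
)
from rwdsandbox.scheduler import Scheduler


@dataclass
class Deployment:
    root: str
    perm: PermAgent
    notary: Notary
    proxy: Proxy
    processors: list[Processor]
    scheduler: Scheduler
    clock: object
    user_keys: dict[str, bytes] = field(default_factory=dict)

    def pump(self, cycles: int = 4, drain: bool = True) -> None:
        """Run proxy cycles and processor polls until work settles."""
        for _ in range(cycles):
            self.proxy.run_cycle()
            for proc in self.processors:
                proc.poll_once()
            if drain:
                for proc in self.processors:
                    proc.wait_idle()
            self.proxy.monitor_outputs()

    def shutdown(self) -> None:
        for proc in self.processors:
            proc.stop()


def build_deployment(root: str, clock=system_clock, n_processors: int = 1,
                     max_parallel: int = 2, n_rows: int = 100,
                     seed: int = 0, users: dict[str, str] | None = None,
                     session_ttl: float = 8 * 3600.0) -> Deployment:
    """Stand up a full platform under ``root``.

    Registers the default synthetic patient datamart, the toy algorithm
    catalog, ``n_processors`` processors, a scheduler and a notary with a
    fresh sandbox keypair.  ``users`` maps user_id -> password; each user
    gets an Ed25519 keypair (seeded deterministically from ``seed``) whose
    public half is registered for countersigning, and a grant on every
    catalog item.
    """
    users = users or {"alice": "wonderland"}
    os.makedirs(root, exist_ok=True)

    perm = PermAgent(os.path.join(root, "perm.sqlite"), clock=clock,
                     session_ttl=session_ttl)
    sandbox_seed = signing.generate_keypair(
        seed.to_bytes(4, "big") * 8)[0]
    notary = Notary(os.path.join(root, "notary"), clock=clock,
                    sandbox_private_key=sandbox_seed)
    scheduler = Scheduler(submit=None, clock=clock,
                          journal_path=os.path.join(root, "scheduler.jsonl"))
    proxy = Proxy(os.path.join(root, "proxy"), perm, notary, clock=clock,
                  scheduler=scheduler)
    scheduler.submit = proxy.submit_trigger

    # datamart: synthetic patients, stored as CSV inside the proxy
    schema = default_patient_schema(seed=seed)
    frame = generate_datamart(schema, n_rows)
    dm_path = os.path.join(root, "proxy", "datamarts")
    os.makedirs(dm_path, exist_ok=True)
    csv_path = os.path.join(dm_path, "patients.csv")
    with open(csv_path, "wb") as fh:
        fh.write(to_csv_bytes(frame))
    proxy.register_datamart(DatamartEntry(
        item_id="dm-patients", name="Synthetic Patients", source=csv_path,
        fields={f.name: f.kind for f in schema.fields},
        description="seeded synthetic analysis-ready patient table",
    ))

    # algorithms: toy scripts in the certified local repository
    alg_dir = os.path.join(root, "proxy", "algorithms")
    repo = AlgorithmRepository()
    image_store = LocalImageStore()
    for item_id, path in toy_algorithm_catalog(alg_dir).items():
        repo.register(item_id, path)
        proxy.register_algorithm(AlgorithmEntry(
            item_id=item_id, name=item_id, kind="script", locator=item_id))

    # processors
    processors = []
    for i in range(n_processors):
        pid = f"P{i + 1}"
        base = os.path.join(root, f"processor_{pid}")
        config = ProcessorConfig(
            processor_id=pid,
            input_folders=[os.path.join(base, "input")],
            output_folder=os.path.join(base, "output"),
            sync_folder=os.path.join(base, "sync"),
            work_folder=os.path.join(base, "work"),
            max_parallel=max_parallel,
        )
        proc = Processor(config, clock=clock, image_store=image_store,
                         algorithm_repository=repo)
        proc.poll_once()  # first heartbeat so the proxy sees it live
        processors.append(proc)
        proxy.register_processor(ProcessorHandle(
            processor_id=pid,
            input_folder=config.input_folders[0],
            output_folder=config.output_folder,
            sync_folder=config.sync_folder,
        ))

    # users: credentials, grants on all items, countersignature keys
    user_keys = {}
    for i, (user_id, password) in enumerate(sorted(users.items())):
        perm.add_user(user_id, password)
        for item in list(proxy.datamarts) + list(proxy.algorithms):
            perm.grant(user_id, item)
        key_seed = bytes([(seed + 17 * (i + 1)) % 256]) * 32
        priv, pub = signing.generate_keypair(key_seed)
        notary.register_user_key(user_id, pub)
        user_keys[user_id] = priv

    return Deployment(root=root, perm=perm, notary=notary, proxy=proxy,
                      processors=processors, scheduler=scheduler,
                      clock=clock, user_keys=user_keys)


class ReferenceClient:
    """Headless GUI-side client: logs in, opens a channel, submits jobs,
    collects status messages, verifies the sandbox signature and
    countersigns the report."""

    def __init__(self, deployment: Deployment, user_id: str, password: str,
                 channel_id: str = "chan-1"):
        self.dep = deployment
        self.user_id = user_id
        session = deployment.perm.authenticate(user_id, password)
        if session is None:
            raise PermissionError("authentication failed")
        self.ticket = session.ticket
        self.channel = GuiChannel(channel_id, clock=deployment.clock,
                                  user_ticket=self.ticket)
        deployment.proxy.register_channel(self.channel)
        self.messages: list[StatusMessage] = []

    def submit(self, job_id: str, datamart: str = "dm-patients",
               algorithm: str = "alg-row-counter", **kwargs) -> JobRequest:
        request = JobRequest(job_id=job_id, ticket=self.ticket,
                             user_id=self.user_id, datamart_item=datamart,
                             algorithm_item=algorithm, **kwargs)
        self.channel.write_job(request)
        return request

    def poll(self) -> list[StatusMessage]:
        new = self.channel.read_status()
        self.messages.extend(new)
        return new

    def messages_for(self, job_id: str) -> list[StatusMessage]:
        return [m for m in self.messages if m.job_id == job_id]

    def countersign(self, job_id: str) -> SignedReport:
        """Verify the sandbox signature on the delivered report, then sign
        the sandbox-signed artefact with the user's private key and upload
        the countersignature."""
        import base64

        ready = [m for m in self.messages_for(job_id) if m.code == "result.ready"]
        if not ready:
            raise LookupError(f"no result delivered yet for {job_id}")
        payload = ready[-1].payload
        report = base64.b64decode(payload["report"])
        sandbox_sig = bytes.fromhex(payload["sandbox_signature"])
        if not signing.verify(self.dep.notary.sandbox_public_key, report,
                              sandbox_sig):
            raise ValueError("sandbox signature does not verify; refusing "
                             "to countersign")
        staged = SignedReport(job_id=job_id, report=report,
                              sandbox_signature=sandbox_sig,
                              state="sandbox_signed")
        user_sig = signing.sign(self.dep.user_keys[self.user_id],
                                staged.sandbox_signed_bytes())
        return self.dep.proxy.submit_countersignature(job_id, user_sig)


def run_signed_job(deployment: Deployment, client: ReferenceClient,
                   job_id: str, **submit_kwargs) -> SignedReport:
    """Convenience: submit one job, pump to completion, countersign."""
    client.submit(job_id, **submit_kwargs)
    deployment.pump()
    client.poll()
    return client.countersign(job_id)
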