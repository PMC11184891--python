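# rwdsandbox

A multi-agent sandbox for **privacy-preserving distributed analytics on
hospital real-world data**.  External researchers submit analysis jobs
against curated hospital datamarts and get back aggregate results, signed
and notarised — while patient-level rows never leave the institution.

It is aimed at health-informatics teams who need a self-contained,
auditable job-execution pipeline: a GUI-facing **polled XML protocol**
(Message Master Table + per-job detail files), a coordinating **proxy**
inside the trust zone, black-box **processors** that execute zip *tokens*
(descriptor XML + data + algorithm reference) dropped into watched
folders, an **IAM agent** with group hierarchies and session tickets, a
**scheduler** for periodic jobs, and a **notary** providing hash-chain
notarisation plus a dual digital-signature workflow (sandbox signs, user
countersigns, three notarised report artefacts per issued result).

## Worked example

Run one full job cycle — submit, execute, notarise, sign, countersign —
against an ephemeral in-process deployment with a synthetic 100-row
patient datamart:

```bash
$ sandbox demo --seed 3
report state: countersigned
report files notarised: 3
ledger: 5 entries, intact
result summary (aggregates only):
  age: {'mean': 62.08689999999999, 'n': 100}
  biomarker: {'mean': 4.286999999999999, 'n': 100}
  gender: {'n_distinct': 2, 'top_counts': {'F': 46, 'M': 54}}
  person_id: {'n_distinct': 100, 'top_counts': {}}
  visit_year: {'mean': 2019.21, 'n': 100}
```

Reading the output: the report reached the `countersigned` state, meaning
the sandbox signature verified on the user side and the user's
countersignature verified on the sandbox side — only then is a result
officially issued.  Exactly **3 report files** (initial, sandbox-signed,
countersigned) were stored off-chain and appended to the ledger, which
together with the request and result entries gives **5 ledger entries**
for the job, all hash-chain intact.  The delivered result contains only
aggregates (means, counts) computed inside the hospital zone; the
per-patient rows, including their sentinel pseudonyms, never appear on
the channel.

The same flow from Python:

```python
from rwdsandbox.harness import build_deployment, ReferenceClient, run_signed_job

dep = build_deployment("deploy/", n_processors=2, seed=1)
client = ReferenceClient(dep, "alice", "wonderland")
report = run_signed_job(dep, client, "job-1", algorithm="alg-row-counter")
assert report.state == "countersigned"
ok, _ = dep.notary.verify_ledger()
```

Other CLI entry points: `sandbox processor --config …` and
`sandbox proxy --config …` run the continuous loops, `sandbox
verify-ledger --root …` recomputes the hash chain and off-chain digests,
`sandbox keygen` / `sandbox countersign` handle the user-side key
ceremony.

## Layout

```
src/rwdsandbox/
  token_core.py    token/output-token archive format, descriptor XML, hashing
  processor.py     folder-watching executor, script/image backends
  proxy.py         coordinator: polling, authorisation, dispatch, monitoring
  gui_protocol.py  MMT/MMD protocol, channels, HTTP transport
  perm_agent.py    IAM: profiles, groups, grants, session tickets (sqlite)
  scheduler.py     periodic tasks, freeze/resume/remove, journaling
  notary.py        hash-chain ledger, off-chain store, dual signatures
  signing.py       Ed25519 + PEM
  fixtures.py      synthetic datamarts, OMOP-lite, cohort queries, toy algorithms
  harness.py       in-process full deployment + headless reference client
  cli.py           `sandbox` command group
```

See `docs/methods.md` for the design rationale, parameter defaults and
known limitations.
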