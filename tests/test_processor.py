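"""Processor: claiming, backends, failure handling, parallelism, conservation."""

import os
import random
import time

import pytest

from rwdsandbox.errors import ContractError, RemotePullRefusedError
from rwdsandbox.processor import (
    AlgorithmRepository,
    LocalImageStore,
    Processor,
    ProcessorConfig,
)
from rwdsandbox.token_core import (
    AlgorithmRef,
    DatamartRef,
    TokenDescriptor,
    build_token,
    parse_output_token,
)

WRITER = """\
with open("results/answer.txt", "w") as fh:
    fh.write("42\\n")
"""

FAILER = """\
import sys
sys.stderr.write("deliberate failure for job\\n")
sys.exit(3)
"""

SLEEPER = """\
import json, time
with open("settings.json") as fh:
    time.sleep(float(json.load(fh).get("duration", 0.1)))
with open("results/done.txt", "w") as fh:
    fh.write("ok\\n")
"""


def make_config(tmp_path, pid="P1", **kwargs):
    base = tmp_path / pid
    return ProcessorConfig(
        processor_id=pid,
        input_folders=[str(base / "input")],
        output_folder=str(base / "output"),
        sync_folder=str(base / "sync"),
        work_folder=str(base / "work"),
        **kwargs,
    )


def script_token(job_id, source, settings=None):
    desc = TokenDescriptor(
        job_id=job_id, user_id="u",
        algorithm_ref=AlgorithmRef("script", "run.py"),
        datamart_ref=DatamartRef("payload", "data.csv"),
        run_settings=settings or {},
        created_at=0.0,
    )
    return build_token(desc, [("run.py", source.encode()),
                              ("data.csv", b"a\n1\n")])


def drop(config, token_or_bytes, job_id):
    data = token_or_bytes if isinstance(token_or_bytes, bytes) \
        else token_or_bytes.archive
    path = os.path.join(config.input_folders[0], f"token_{job_id}.zip")
    with open(path, "wb") as fh:
        fh.write(data)


def read_output(config, job_id):
    path = os.path.join(config.output_folder, f"out_{job_id}.zip")
    with open(path, "rb") as fh:
        return parse_output_token(fh.read())


class TestWatchAndDispatch:
    def test_token_removed_from_input_and_output_deposited(self, tmp_path):
        config = make_config(tmp_path)
        proc = Processor(config)
        drop(config, script_token("j1", WRITER), "j1")
        proc.poll_once()
        assert os.listdir(config.input_folders[0]) == []  # claimed away
        proc.wait_idle()
        out = read_output(config, "j1")
        assert out.status == "success"
        assert out.read_member("results/answer.txt") == b"42\n"
        proc.stop()

    def test_corrupt_zip_yields_failure_token_with_parse_log(self, tmp_path):
        config = make_config(tmp_path)
        proc = Processor(config)
        drop(config, b"not a zip at all", "bad1")
        proc.poll_once()
        proc.wait_idle()
        out = read_output(config, "bad1")
        assert out.status == "failure"
        assert out.logs
        assert b"could not be parsed" in out.read_member(out.logs[0])
        proc.stop()

    def test_failing_script_surfaces_stderr_in_logs(self, tmp_path):
        config = make_config(tmp_path)
        proc = Processor(config)
        drop(config, script_token("jf", FAILER), "jf")
        proc.poll_once()
        proc.wait_idle()
        out = read_output(config, "jf")
        assert out.status == "failure"
        assert b"deliberate failure" in out.read_member(out.logs[0])
        proc.stop()

    def test_unknown_backend_kind_fails_cleanly(self, tmp_path):
        config = make_config(tmp_path)
        proc = Processor(config)
        desc = TokenDescriptor(
            job_id="jj", user_id="u",
            algorithm_ref=AlgorithmRef("image", "jvm-thing:latest"),
            datamart_ref=DatamartRef("payload", "data.csv"), created_at=0.0)
        drop(config, build_token(desc, [("data.csv", b"a\n")]), "jj")
        proc.poll_once()
        proc.wait_idle()
        out = read_output(config, "jj")
        assert out.status == "failure"
        assert b"not in the local store" in out.read_member(out.logs[0])
        proc.stop()

    def test_timeout_kills_job_and_flags_failure(self, tmp_path):
        config = make_config(tmp_path, job_timeout=0.5)
        proc = Processor(config)
        drop(config, script_token("slow", "import time; time.sleep(30)"), "slow")
        proc.poll_once()
        proc.wait_idle(timeout=10)
        out = read_output(config, "slow")
        assert out.status == "failure"
        assert b"timeout" in out.read_member(out.logs[0])
        proc.stop()

    def test_max_parallel_bounds_concurrency_and_all_complete(self, tmp_path):
        config = make_config(tmp_path, max_parallel=2)
        proc = Processor(config)
        for i in range(5):
            drop(config, script_token(f"s{i}", SLEEPER,
                                      {"duration": "0.3"}), f"s{i}")
        proc.poll_once()
        proc.wait_idle(timeout=30)
        assert proc.max_concurrent_observed <= 2
        assert proc.counters == {"claimed": 5, "deposited": 5}
        assert all(r.exit_status == 0 for r in proc.records)
        proc.stop()


class TestBackends:
    def test_local_image_store_runs_loaded_bundle(self, tmp_path):
        entry = tmp_path / "bundle.py"
        entry.write_text(WRITER)
        store = LocalImageStore()
        store.load("hospital/toolbox:1.0", str(entry))
        config = make_config(tmp_path)
        proc = Processor(config, image_store=store)
        desc = TokenDescriptor(
            job_id="img1", user_id="u",
            algorithm_ref=AlgorithmRef("image", "hospital/toolbox:1.0"),
            datamart_ref=DatamartRef("payload", "data.csv"), created_at=0.0)
        drop(config, build_token(desc, [("data.csv", b"a\n")]), "img1")
        proc.poll_once()
        proc.wait_idle()
        assert read_output(config, "img1").status == "success"
        proc.stop()

    def test_absent_image_refused_never_pulled(self):
        store = LocalImageStore()
        with pytest.raises(RemotePullRefusedError):
            store.resolve("dockerhub.io/evil:latest")

    def test_repository_locator_resolves_local_script(self, tmp_path):
        script = tmp_path / "counter.py"
        script.write_text(WRITER)
        repo = AlgorithmRepository({"alg-1": str(script)})
        config = make_config(tmp_path)
        proc = Processor(config, algorithm_repository=repo)
        desc = TokenDescriptor(
            job_id="r1", user_id="u",
            algorithm_ref=AlgorithmRef("repository", "alg-1"),
            datamart_ref=DatamartRef("payload", "data.csv"), created_at=0.0)
        drop(config, build_token(desc, [("data.csv", b"a\n")]), "r1")
        proc.poll_once()
        proc.wait_idle()
        assert read_output(config, "r1").status == "success"
        proc.stop()


class TestInvariants:
    def test_config_rejects_shared_folders_and_zero_parallel(self, tmp_path):
        with pytest.raises(ContractError):
            ProcessorConfig("P", [str(tmp_path / "a")], str(tmp_path / "a"),
                            str(tmp_path / "s"), str(tmp_path / "w"))
        with pytest.raises(ContractError):
            make_config(tmp_path, pid="PX", max_parallel=0)

    def test_conservation_over_random_token_mix(self, tmp_path):
        """#claimed == #deposited over a randomized batch including corrupt
        archives; every failure token carries logs."""
        rng = random.Random(3)
        config = make_config(tmp_path, max_parallel=4)
        proc = Processor(config)
        n = 30
        for i in range(n):
            kind = rng.random()
            if kind < 0.2:
                drop(config, rng.randbytes(rng.randint(1, 200)), f"c{i}")
            elif kind < 0.4:
                drop(config, script_token(f"c{i}", FAILER), f"c{i}")
            else:
                drop(config, script_token(f"c{i}", WRITER), f"c{i}")
        while proc.poll_once():
            pass
        proc.wait_idle(timeout=60)
        assert proc.counters == {"claimed": n, "deposited": n}
        outputs = [read_output(config, f"c{i}") for i in range(n)]
        for out in outputs:
            if out.status == "failure":
                assert out.logs and out.read_member(out.logs[0])
        proc.stop()

    def test_concurrent_jobs_have_disjoint_logs_with_own_job_id(self, tmp_path):
        config = make_config(tmp_path, max_parallel=3)
        proc = Processor(config)
        ids = [f"d{i}" for i in range(4)]
        for job_id in ids:
            drop(config, script_token(job_id, SLEEPER, {"duration": "0.1"}),
                 job_id)
        proc.poll_once()
        proc.wait_idle(timeout=30)
        log_paths = {r.job_id: r.log_path for r in proc.records}
        assert len(set(log_paths.values())) == len(ids)
        for job_id, path in log_paths.items():
            content = open(path).read()
            assert f"[{job_id}]" in content
            for other in ids:
                if other != job_id:
                    assert f"[{other}]" not in content
        proc.stop()
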