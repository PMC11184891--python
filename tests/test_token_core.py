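"""Token archive format: build/parse round-trips, path safety, hashing."""

import subprocess
import zipfile
import io

import pytest
from hypothesis import given, settings, strategies as st

from rwdsandbox.errors import (
    ContractError,
    DescriptorSchemaError,
    MissingDescriptorError,
    PathSafetyError,
)
from rwdsandbox.token_core import (
    AlgorithmRef,
    CadenceSpec,
    DatamartRef,
    TokenDescriptor,
    build_output_token,
    build_token,
    hash_artifact,
    parse_output_token,
    parse_token,
)


def minimal_descriptor(job_id="j1", **kwargs):
    defaults = dict(
        job_id=job_id,
        user_id="alice",
        algorithm_ref=AlgorithmRef("repository", "alg-row-counter"),
        datamart_ref=DatamartRef("payload", "data.csv"),
        created_at=1_700_000_000.0,
    )
    defaults.update(kwargs)
    return TokenDescriptor(**defaults)


class TestBuildParse:
    def test_empty_payload_yields_single_member_archive(self):
        token = build_token(minimal_descriptor(), [])
        assert token.manifest == ["descriptor.xml"]
        with zipfile.ZipFile(io.BytesIO(token.archive)) as zf:
            assert zf.namelist() == ["descriptor.xml"]

    def test_round_trip_with_payload(self):
        desc = minimal_descriptor(
            column_roles={"age": "input", "outcome": "target"},
            run_settings={"alpha": "0.05"},
            schedule=CadenceSpec("interval", "60"),
        )
        payload = [("data.csv", b"a,b\n1,2\n"), ("scripts/run.py", b"print(1)\n")]
        token = build_token(desc, payload)
        parsed = parse_token(token.archive)
        assert parsed.descriptor == desc
        assert sorted(parsed.manifest) == sorted(token.manifest)
        assert parsed.read_member("data.csv") == b"a,b\n1,2\n"

    @pytest.mark.parametrize("bad_path", [
        "../x", "a/../../x", "/etc/passwd", "", "descriptor.xml",
    ])
    def test_unsafe_payload_paths_rejected(self, bad_path):
        with pytest.raises(PathSafetyError):
            build_token(minimal_descriptor(), [(bad_path, b"x")])

    def test_duplicate_payload_path_rejected(self):
        with pytest.raises(PathSafetyError):
            build_token(minimal_descriptor(), [("a.csv", b"1"), ("a.csv", b"2")])

    def test_zip_without_descriptor_is_missing_descriptor_error(self):
        buf = io.BytesIO()
        with zipfile.ZipFile(buf, "w") as zf:
            zf.writestr("whatever.csv", "a,b\n")
        with pytest.raises(MissingDescriptorError):
            parse_token(buf.getvalue())

    def test_not_a_zip_is_missing_descriptor_error(self):
        with pytest.raises(MissingDescriptorError):
            parse_token(b"this is not a zip")

    def test_descriptor_without_job_id_is_schema_error(self):
        xml = (b"<?xml version='1.0'?><token-descriptor format_version='1.0'>"
               b"<user-id>u</user-id></token-descriptor>")
        buf = io.BytesIO()
        with zipfile.ZipFile(buf, "w") as zf:
            zf.writestr("descriptor.xml", xml)
        with pytest.raises(DescriptorSchemaError):
            parse_token(buf.getvalue())

    def test_unknown_elements_are_ignored_forward_compat(self):
        token = build_token(minimal_descriptor(), [])
        xml = token.read_member("descriptor.xml").replace(
            b"</token-descriptor>",
            b"<future-extension>ignored</future-extension></token-descriptor>")
        buf = io.BytesIO()
        with zipfile.ZipFile(buf, "w") as zf:
            zf.writestr("descriptor.xml", xml)
        assert parse_token(buf.getvalue()).descriptor == token.descriptor


def _descriptor_strategy():
    names = st.text(
        alphabet="abcdefghijklmnopqrstuvwxyz0123456789-_", min_size=1,
        max_size=12)
    return st.builds(
        TokenDescriptor,
        job_id=names,
        user_id=names,
        algorithm_ref=st.builds(
            AlgorithmRef,
            kind=st.sampled_from(["script", "image", "repository"]),
            value=names),
        datamart_ref=st.builds(
            DatamartRef,
            kind=st.sampled_from(["payload", "repository"]),
            value=names),
        column_roles=st.dictionaries(
            names, st.sampled_from(["input", "target"]), max_size=4),
        run_settings=st.dictionaries(
            names,
            # XML cannot carry control characters or surrogates
            st.text(alphabet=st.characters(blacklist_categories=("Cs", "Cc")),
                    max_size=20),
            max_size=4),
        notarise=st.booleans(),
        sign=st.booleans(),
        schedule=st.one_of(
            st.none(),
            st.builds(CadenceSpec, kind=st.just("interval"),
                      value=st.sampled_from(["1", "60", "3600.5"])),
            st.builds(CadenceSpec, kind=st.just("daily"),
                      value=st.sampled_from(["02:00", "23:59"]))),
        created_at=st.floats(min_value=0, max_value=4_000_000_000,
                             allow_nan=False),
    )


@settings(max_examples=200)
@given(desc=_descriptor_strategy(),
       payload=st.lists(
           st.tuples(
               st.text(alphabet="abcdefghijklmnopqrstuvwxyz", min_size=1,
                       max_size=8).map(lambda s: s + ".dat"),
               st.binary(max_size=64)),
           max_size=3, unique_by=lambda t: t[0]))
def test_build_parse_identity_property(desc, payload):
    """build -> parse reproduces descriptor and payload for random inputs."""
    token = build_token(desc, payload)
    parsed = parse_token(token.archive)
    # timestamps survive at microsecond precision (ISO-8601 serialisation)
    assert abs(parsed.descriptor.created_at - desc.created_at) < 1e-5
    parsed.descriptor.created_at = desc.created_at
    assert parsed.descriptor == desc
    for path, data in payload:
        assert parsed.read_member(path) == data


class TestHashing:
    def test_empty_input_matches_external_utility(self, tmp_path):
        f = tmp_path / "empty"
        f.write_bytes(b"")
        expected = subprocess.run(["sha256sum", str(f)], capture_output=True,
                                  text=True, check=True).stdout.split()[0]
        assert hash_artifact(b"").hex == expected

    def test_digests_match_external_utility_on_random_payloads(self, tmp_path):
        import random
        rng = random.Random(42)
        for i in range(50):
            data = rng.randbytes(rng.randint(0, 4096))
            f = tmp_path / f"p{i}"
            f.write_bytes(data)
            expected = subprocess.run(
                ["sha256sum", str(f)], capture_output=True, text=True,
                check=True).stdout.split()[0]
            digest = hash_artifact(data)
            assert digest.hex == expected
            assert digest.algorithm_id == "sha256"

    def test_single_bit_flips_change_the_digest(self):
        import random
        rng = random.Random(7)
        data = rng.randbytes(256)
        base = hash_artifact(data)
        for _ in range(100):
            pos, bit = rng.randrange(len(data)), 1 << rng.randrange(8)
            mutated = bytearray(data)
            mutated[pos] ^= bit
            assert hash_artifact(bytes(mutated)) != base

    def test_determinism_on_large_payload(self):
        import random
        data = random.Random(1).randbytes(1 << 20)
        assert hash_artifact(data) == hash_artifact(data)


class TestOutputToken:
    def test_success_archive_round_trips(self):
        out = build_output_token(
            "j1", "success", [("results/report.txt", b"42\n")],
            [("logs/run.log", b"ok\n")], 1_700_000_000.0)
        parsed = parse_output_token(out.archive)
        assert parsed.job_id == "j1"
        assert parsed.status == "success"
        assert parsed.results == ["results/report.txt"]
        assert parsed.read_member("logs/run.log") == b"ok\n"
        assert len(parsed.results) + len(parsed.logs) + 1 == 3

    def test_failure_status_is_machine_readable(self):
        out = build_output_token("j1", "failure", [],
                                 [("logs/err.log", b"boom\n")], 0.0)
        assert parse_output_token(out.archive).status == "failure"

    def test_failure_without_logs_is_contract_error(self):
        with pytest.raises(ContractError):
            build_output_token("j1", "failure", [], [], 0.0)

    def test_empty_job_id_is_contract_error(self):
        with pytest.raises(ContractError):
            build_output_token("", "success", [], [], 0.0)
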