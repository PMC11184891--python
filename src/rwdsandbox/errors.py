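"""Exception hierarchy shared by all agents."""


class SandboxError(Exception):
    """Base class for every error raised by the platform."""


class PathSafetyError(SandboxError):
    """A payload member path is absolute, duplicated, or escapes the archive root."""


class MissingDescriptorError(SandboxError):
    """A token archive contains no descriptor XML member."""


class DescriptorSchemaError(SandboxError):
    """A descriptor (or result descriptor) XML violates the schema."""


class ContractError(SandboxError):
    """An operation precondition was violated by the caller."""


class DuplicateNotarisationError(SandboxError):
    """The (job_id, role) pair was already notarised."""


class SignatureError(SandboxError):
    """A digital signature failed verification or a key is missing."""


class StateMachineError(SandboxError):
    """An operation was attempted from an illegal state."""


class ChannelExpiredError(SandboxError):
    """Traffic on a GUI channel after its maximum duration elapsed."""


class DuplicateJobError(SandboxError):
    """A job_id was submitted twice on the same channel."""


class QueryError(SandboxError):
    """A cohort query references an unknown field or mismatched type."""


class ConfigurationError(SandboxError):
    """A registry/connector/key configuration problem."""


class RemotePullRefusedError(SandboxError):
    """A container image is not in the local store; remote pulls are disabled."""
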