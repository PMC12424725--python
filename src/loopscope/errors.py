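"""Exception hierarchy shared across the package."""


class LoopscopeError(Exception):
    """Base class for all loopscope errors."""


class ConfigError(LoopscopeError):
    """A configuration file is syntactically or semantically invalid."""


class PlanError(LoopscopeError):
    """Schedule, positions and per-position configs cannot be combined."""


class CapabilityError(LoopscopeError):
    """A requested backend (e.g. an external segmenter) is unavailable."""


class StorageError(LoopscopeError):
    """The outbox could not persist an artifact."""
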