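"""Exception hierarchy.

``ConfigError`` signals an invalid configuration or contract violation the
caller can fix; ``PedigreeError`` a structurally broken pedigree;
``InputError`` inconsistent data handed to an analysis step.
"""


class PoolGwasError(Exception):
    """Base class for all package errors."""


class ConfigError(PoolGwasError):
    """Invalid configuration value or violated call contract."""


class PedigreeError(PoolGwasError):
    """Cyclic pedigree, unknown parent id, or cross-family parentage."""


class InputError(PoolGwasError):
    """Inconsistent or malformed analysis inputs."""
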