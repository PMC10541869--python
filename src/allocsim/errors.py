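"""Exception hierarchy for allocsim."""


class AllocsimError(Exception):
    """Base class for all allocsim errors."""


class ValidationError(AllocsimError):
    """A value violated a domain invariant (range, enumeration, ordering)."""


class SchemaError(AllocsimError):
    """A table is missing a required column or holds an unparseable cell."""


class ConfigError(AllocsimError):
    """A configuration file or override is malformed or inconsistent."""
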