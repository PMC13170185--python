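"""Exception hierarchy.

Validation errors signal inconsistent in-memory objects or configs;
format errors signal malformed on-disk inputs. The CLI maps both to
exit code 1 and everything else to 2.
"""


class XomapError(Exception):
    """Base class for all package errors."""


class ValidationError(XomapError, ValueError):
    """An object violates one of its invariants."""


class FormatError(XomapError, ValueError):
    """An input file does not conform to the expected format."""


class ConfigError(XomapError, ValueError):
    """A configuration value is out of its legal range."""
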