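"""Exception types shared across the pipeline.

``ParameterError`` signals an invalid argument value (a usage error at the
CLI level); ``LoadError`` signals a malformed or inconsistent input file.
Both derive from ``ValueError`` so callers may catch broadly.
"""


class ParameterError(ValueError):
    """An argument value violates a precondition; the message names it."""


class LoadError(ValueError):
    """An input file is malformed or internally inconsistent."""
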