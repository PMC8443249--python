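"""Exception hierarchy shared across the package.

Two failure classes are distinguished because the CLI maps them to
different exit codes: malformed input (exit 2) versus statistically
infeasible requests on well-formed input (exit 3).
"""


class ValidationError(ValueError):
    """Input data or parameters are malformed (CLI exit code 2)."""


class InfeasibleError(RuntimeError):
    """The requested computation is statistically infeasible on this
    input, e.g. an empty conditioning set (CLI exit code 3)."""
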