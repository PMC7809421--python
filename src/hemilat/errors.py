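"""Exception hierarchy.

The CLI maps :class:`InputError` / :class:`ConfigurationError` to exit code 2
(validation) and :class:`GenerationError` / :class:`ComputationError` to exit
code 3 (computation).
"""


class HemilatError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HemilatError):
    """A configuration value is invalid or inconsistent."""


class InputError(HemilatError):
    """User-supplied data violates a documented schema or invariant."""


class GenerationError(HemilatError):
    """Synthetic-data generation failed (e.g. connectivity retries exhausted)."""


class ComputationError(HemilatError):
    """A quantity is undefined for the given input (e.g. path length of an
    edgeless graph, or a vanishing random-reference clustering coefficient)."""
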