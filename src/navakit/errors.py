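"""Exception hierarchy shared by all pipeline stages."""


class NavaError(Exception):
    """Base class for all navakit errors."""


class FormatError(NavaError):
    """A file does not conform to the expected columnar format."""


class ValidationError(NavaError):
    """An input violates a stated precondition or invariant."""


class NumericalError(NavaError):
    """A numerical procedure failed (rank deficiency, collapsed mixture, ...)."""


class NoTitrationFound(NavaError):
    """No titration staircase could be located in the NAVA-level trace."""


class DegenerateSignal(NavaError):
    """A signal carries no classifiable structure (e.g. constant EAdi)."""


class DomainError(NavaError):
    """Evaluation requested outside the domain a model was fitted on."""
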