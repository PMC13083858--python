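"""Exception hierarchy shared by all graviflux modules."""


class GravifluxError(Exception):
    """Base class for all errors raised by graviflux."""


class ConfigError(GravifluxError):
    """Invalid configuration value or unknown key."""


class TemplateError(GravifluxError):
    """Invalid template specification or template structure."""


class ParseError(GravifluxError):
    """Malformed input file."""


class AssemblyError(GravifluxError):
    """Inconsistent template / carrier map / parameters during system assembly."""


class NoSteadyStateError(GravifluxError):
    """The linear system admits no (unique) steady state."""


class StructuralError(GravifluxError):
    """A required structural feature of the template is missing."""


class DomainError(GravifluxError):
    """Input outside the mathematical domain of a formula."""


class IntegrationError(GravifluxError):
    """The ODE integrator failed to produce a solution."""
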