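"""Exception hierarchy for chokelab.

All errors derive from :class:`ChokelabError` so callers can catch the
package's failures with one except clause; the subclasses mirror the
stages at which things can go wrong (configuration, input domain,
design construction, model fitting, inference, file parsing).
"""


class ChokelabError(Exception):
    """Base class for all chokelab errors."""


class ConfigurationError(ChokelabError, ValueError):
    """Invalid run or cohort configuration; message names the field."""


class DomainError(ChokelabError, ValueError):
    """Input outside the documented domain (e.g. incentive not on the grid)."""


class DesignError(ChokelabError, ValueError):
    """Design matrix cannot be built or is rank deficient."""


class FitError(ChokelabError, RuntimeError):
    """Model fitting failed in a way that is not a flagged non-convergence."""


class NonIdentifiableError(FitError):
    """The likelihood carries no information about the parameters
    (e.g. every choking score censored at zero)."""


class InferenceError(ChokelabError, RuntimeError):
    """Inference requested on degenerate inputs (zero variance, n too small)."""


class ParseError(ChokelabError, ValueError):
    """Malformed row in a tabular input file; message carries the line number."""


class FormatError(ChokelabError, ValueError):
    """File-level format violation (units, rates, non-finite samples)."""
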