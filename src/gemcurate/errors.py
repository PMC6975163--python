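"""Exception hierarchy shared across the package.

The classes map onto the CLI exit codes: validation problems → 2,
infeasibility / degenerate ensembles → 3, solver faults → 4.
"""


class GemcurateError(Exception):
    """Base class for all package errors."""


class ValidationError(GemcurateError, ValueError):
    """Invalid input data or violated model invariant."""


class GeneRuleError(ValidationError):
    """Malformed gene rule expression."""


class GapfillInfeasibleError(GemcurateError):
    """No gap-fill solution exists even with the full universal bag."""


class DegenerateEnsembleError(GemcurateError):
    """Too few unique gap-fill solutions to form a useful ensemble."""


class SolverError(GemcurateError):
    """The LP backend failed for a reason other than infeasibility."""
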