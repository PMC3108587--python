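"""Exception hierarchy shared across the package."""


class ParvapopError(Exception):
    """Base class for all package errors."""


class InputError(ParvapopError):
    """Malformed or inconsistent input data."""


class AlignmentError(InputError):
    """Sequences that do not form a valid alignment (ragged, empty)."""


class DegenerateAlignmentError(AlignmentError):
    """No analysable columns remain after filtering."""


class ParameterError(ParvapopError):
    """Invalid analysis parameter (k > n, B < 1, mu <= 0, ...)."""


class UndefinedStatisticError(ParvapopError):
    """A statistic requested on too small a sample (e.g. H with n < 2)."""


class SaturationError(ParvapopError):
    """K2P correction undefined: log argument non-positive (saturated pair)."""


class ScenarioError(ParvapopError):
    """Inconsistent demographic scenario specification."""
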