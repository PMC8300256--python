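"""Exception hierarchy separating bad data from inapplicable analysis.

The CLI maps these to distinct exit codes (1 and 2) so shell pipelines can
tell a malformed input file apart from a dataset that is simply too short
or too degenerate for a given statistic.
"""


class RickerTNRError(Exception):
    """Base class for all package errors."""


class DataValidationError(RickerTNRError):
    """The input data violate a structural invariant (duplicate years,
    negative counts, unknown fixture names, malformed CSV...)."""


class AnalysisPreconditionError(RickerTNRError):
    """The data are well-formed but an analysis precondition fails
    (too few points, all-identical predictor, R_m <= p, ...)."""
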