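"""Exception hierarchy for maexp."""


class MAExpError(Exception):
    """Base class for all maexp errors."""


class InvalidSpecError(MAExpError, ValueError):
    """A genome or experiment specification is infeasible or malformed."""


class DegenerateExperimentError(MAExpError, ValueError):
    """An experiment has no observable site-generations (zero denominator)."""


class MissingMetadataError(MAExpError, KeyError):
    """A call set has no matching row in the line-metadata table."""


class CallSetParseError(MAExpError, ValueError):
    """A variant record could not be parsed into a MutationCall."""


class AnnotationError(MAExpError, ValueError):
    """A CDS annotation is inconsistent (e.g. length not a multiple of 3)."""


class CoordinateError(MAExpError, ValueError):
    """A genomic coordinate falls outside the reference sequence."""
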