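"""Exception hierarchy for the CNV-calling pipeline."""


class CnvCallError(Exception):
    """Base class for all package errors."""


class ProbeTableParseError(CnvCallError):
    """A probe table row could not be parsed; message names the line."""


class NonFiniteRatioError(CnvCallError):
    """A probe log2 ratio is NaN or infinite."""


class DuplicateProbeError(CnvCallError):
    """Two probes share the same (chromosome, position)."""


class IntervalError(CnvCallError):
    """A genomic interval violates start < end or start >= 0."""


class InsufficientDataError(CnvCallError):
    """A chromosome has too few probes for the requested operation."""


class DegenerateVarianceError(CnvCallError):
    """A chromosome has zero variance; z-scores are undefined."""


class ConfigError(CnvCallError):
    """A run-configuration value is out of its allowed range."""


class AlignmentError(CnvCallError):
    """State track and probe track differ in length on some chromosome."""


class OrderingError(CnvCallError):
    """Segments were not sorted by (chromosome, start) where required."""


class SimSpecError(CnvCallError):
    """A simulation spec is internally inconsistent or infeasible."""
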