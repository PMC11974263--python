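"""Exception hierarchy shared across the screening pipeline."""


class TsqScreenError(Exception):
    """Base class for all package errors."""


class XYZParseError(TsqScreenError):
    """Malformed XYZ file (bad count line, truncated atom block...)."""


class UnknownElementError(XYZParseError):
    """Element symbol not in the periodic table."""


class RingIndexError(TsqScreenError):
    """Ring atom list invalid: out of range, duplicated, or wrong size."""


class DegenerateGeometryError(TsqScreenError):
    """Three consecutive ring atoms are collinear; torsions undefined."""


class PairingError(TsqScreenError):
    """S0/T1 geometries do not belong to the same compound/ring."""


class ConfigurationError(TsqScreenError):
    """Missing or invalid model parameters (e.g. HOMA bond types)."""


class AOMFormatError(TsqScreenError):
    """Atomic-overlap-matrix files malformed or mutually inconsistent."""


class DomainError(TsqScreenError):
    """Physically out-of-domain input (negative SOC, lambda <= 0, ...)."""


class FitError(TsqScreenError):
    """Nonlinear fit failed to converge or preconditions not met."""


class SchemaError(TsqScreenError):
    """Portfolio table does not match the expected column schema/units."""


class IncompleteRecordError(TsqScreenError):
    """An enforced screening criterion needs a datum the record lacks."""
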