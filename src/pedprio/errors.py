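"""Exception hierarchy for pedprio."""


class PedprioError(Exception):
    """Base class for all pedprio errors."""


class PedigreeFormatError(PedprioError):
    """Malformed PED input (bad column count, duplicate id, unknown code)."""


class PedigreeStructureError(PedprioError):
    """Structurally invalid pedigree (missing parent, parentage cycle, no founders)."""


class VCFParseError(PedprioError):
    """Malformed or schema-incomplete VCF input."""


class SampleMismatchError(PedprioError):
    """Sample sets of VCF and pedigree disagree."""


class ConfigError(PedprioError):
    """Invalid pipeline configuration (unknown key, bad value)."""


class ExpressionInputError(PedprioError):
    """Invalid expression table or degenerate group (zero variance, n too small)."""
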