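"""Exception hierarchy shared across the package."""


class GeneBurdenError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(GeneBurdenError):
    """An input file is missing a mandatory column or field."""


class InputValidationError(GeneBurdenError):
    """A value in an input file violates its documented constraints."""


class RosterError(GeneBurdenError):
    """Sample ids in a genotype file do not match the individual roster."""


class EmptyPanelError(GeneBurdenError):
    """A gene panel file contained no gene symbols."""


class DegenerateTableError(GeneBurdenError):
    """A 2x2 table has an empty row margin and no test can be computed."""
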