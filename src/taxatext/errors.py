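"""Exception hierarchy shared by all taxatext modules."""


class TaxatextError(Exception):
    """Base class for all package errors."""


class ParseError(TaxatextError):
    """A record in an input file could not be parsed."""


class IntegrityError(TaxatextError):
    """An input violates a structural invariant (duplicate ids, dangling references...)."""


class UsageError(TaxatextError, ValueError):
    """An operation was called with arguments outside its contract."""


class ConfigurationError(TaxatextError):
    """A configuration is internally inconsistent or incomplete."""


class UndefinedKappaError(TaxatextError):
    """Fleiss' kappa is undefined (chance agreement equals 1)."""
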