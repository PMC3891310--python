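"""Exception hierarchy for the gwps package."""


class GwpsError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(GwpsError, ValueError):
    """A configuration value is outside its documented range."""


class ParseError(GwpsError, ValueError):
    """A file could not be parsed; the message names the offending location."""


class MafUndefinedError(GwpsError, ValueError):
    """Minor allele frequency requested for a column with no called genotypes."""


class EmptyControlsError(GwpsError, ValueError):
    """HWE must be assessed in controls, but no control genotypes are available."""


class EmptyPanelError(GwpsError, ValueError):
    """Every SNP was removed by quality control; downstream steps cannot run."""


class SingleClassError(GwpsError, ValueError):
    """An operation requiring both cases and controls received only one class."""
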