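"""Exception hierarchy for summary-panel handling and model fitting."""


class PanelError(ValueError):
    """Base class for all panel / model construction failures."""


class SchemaError(PanelError):
    """A TSV input is missing a required column or has a malformed value."""


class IntegrityError(PanelError):
    """Duplicate keys or references to unknown SNPs/variables."""


class ConsistencyError(PanelError):
    """Two redundant statistics in a panel disagree beyond tolerance."""


class CompletenessError(PanelError):
    """A statistic required by the requested model is absent from the panel."""


class SingularModelError(PanelError):
    """The reconstructed normal-equation matrix is singular or ill-conditioned."""


class DegreesOfFreedomError(PanelError):
    """The model has no residual degrees of freedom (n <= p + 1)."""
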