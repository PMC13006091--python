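"""Exception hierarchy shared across the pipeline."""


class GvitGpError(Exception):
    """Base class for all package errors."""


class FormatError(GvitGpError):
    """A genotype/phenotype file does not parse under the declared dialect."""


class ValidationError(GvitGpError):
    """An in-memory object violates its invariants (duplicate ids, shape mismatch...)."""


class ConfigError(GvitGpError):
    """An infeasible or contradictory configuration."""


class UndefinedMarkerError(GvitGpError):
    """A per-marker statistic is undefined (e.g. all genotypes missing)."""


class EmptyPanelError(GvitGpError):
    """No markers survive a filter; downstream stages cannot run."""


class DegeneratePanelError(GvitGpError):
    """The marker panel carries no variation (e.g. VanRaden denominator 0)."""


class LeakageError(GvitGpError):
    """Held-out samples reached a training-only computation. Hard failure."""


class EmptySelectionError(GvitGpError):
    """A locus selector retained no markers."""


class ContractError(GvitGpError):
    """Mismatched shapes/lengths between pipeline stages."""


class DivergenceError(GvitGpError):
    """Training loss became non-finite."""
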