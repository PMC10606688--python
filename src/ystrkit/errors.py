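"""Exception hierarchy shared across the package."""


class YstrError(Exception):
    """Base class for all package-specific errors."""


class AlleleParseError(YstrError):
    """An allele label could not be interpreted."""


class TableFormatError(YstrError):
    """A haplotype table violates the expected dialect."""


class IncompleteHaplotypeError(YstrError):
    """A haplotype lacks loci required by the requested panel."""

    def __init__(self, sample_id: str, missing: list[str]):
        self.sample_id = sample_id
        self.missing = list(missing)
        super().__init__(
            f"haplotype {sample_id!r} is missing loci: {', '.join(self.missing)}"
        )


class UndefinedStatisticError(YstrError):
    """A statistic is undefined for the given input (e.g. N < 2)."""


class EmptyDatasetError(YstrError):
    """An operation received a dataset with no usable haplotypes."""


class ConfigError(YstrError):
    """Invalid configuration value."""


class InfeasibleSpectrumError(YstrError):
    """A requested multiplicity spectrum cannot be realised exactly."""
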