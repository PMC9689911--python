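"""Exception hierarchy shared across the pipeline stages."""


class PrscapeError(Exception):
    """Base class for all package-specific errors."""


class CatalogError(PrscapeError):
    """Malformed or unusable association table (missing columns, empty result)."""


class DegenerateModelError(PrscapeError):
    """A risk model, genotype vector or regression input is unusable
    (empty intersection, all-missing dosages, constant predictor...)."""


class MissingSnpError(PrscapeError, KeyError):
    """The requested rsid is absent from a counts container."""

    def __str__(self) -> str:  # KeyError quotes its message otherwise
        return Exception.__str__(self)


class ZeroTotalError(PrscapeError):
    """The rsid is present but has a zero total allele count."""


class UntestableTableError(PrscapeError):
    """A 2x2 table with an empty row cannot be exact-tested."""


class ConfigError(PrscapeError):
    """Invalid run configuration; ``errors`` collects every problem found."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


class StageError(PrscapeError):
    """A pipeline stage failed; carries the stage name and a machine code."""

    def __init__(self, stage: str, code: str, message: str):
        self.stage = stage
        self.code = code
        super().__init__(f"[{stage}/{code}] {message}")
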