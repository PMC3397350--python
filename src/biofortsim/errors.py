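"""Exception hierarchy shared across the package."""


class BiofortsimError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(BiofortsimError):
    """An input file is structurally malformed (missing column, missing stratum)."""


class ValidationError(BiofortsimError):
    """A value violates a domain invariant (negative intake, inconsistent zinc)."""


class UnknownFoodError(BiofortsimError):
    """Recall lines reference food items absent from the composition table."""

    def __init__(self, items):
        self.items = sorted(set(items))
        super().__init__(
            "food items missing from the composition table: " + ", ".join(self.items)
        )


class UndefinedRatioError(BiofortsimError):
    """Phytate:zinc molar ratio requested for a food with zero zinc."""
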