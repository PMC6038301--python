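"""Exception hierarchy used across the package."""


class NitroyieldError(Exception):
    """Base class for all package errors."""


class UnknownIdentifierError(NitroyieldError, KeyError):
    """A reaction or species id was referenced that is not in the model."""


class MissingMassError(NitroyieldError):
    """A biomass species is missing the molar mass needed for Eq.-style balancing."""

    def __init__(self, species_id: str):
        self.species_id = species_id
        super().__init__(f"no molar mass available for biomass species {species_id!r}")


class NormalizationError(NitroyieldError):
    """Biomass normalization is degenerate (zero net scalable mass)."""


class EquationParseError(NitroyieldError):
    """A reaction-equation string does not follow the grammar."""

    def __init__(self, message: str, column: int | None = None):
        self.column = column
        if column is not None:
            message = f"{message} (column {column})"
        super().__init__(message)


class ModelIOError(NitroyieldError):
    """A model file is missing, malformed, or structurally inconsistent."""


class InfeasiblePathwayError(NitroyieldError):
    """A pathway LP has no feasible flux; carries the offending species."""

    def __init__(self, message: str, unbalanced: list[str] | None = None):
        self.unbalanced = unbalanced or []
        super().__init__(message)


class GenerationError(NitroyieldError):
    """A synthetic-model specification is contradictory."""
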