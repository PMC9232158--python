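"""Exception hierarchy for dispmed."""


class DispmedError(Exception):
    """Base class for all package errors."""


class SchemaError(DispmedError):
    """A variable-role schema is inconsistent or does not match the data."""


class CodingError(DispmedError):
    """A cell value violates the declared variable coding."""

    def __init__(self, column: str, row: int, value) -> None:
        self.column = column
        self.row = row
        self.value = value
        super().__init__(
            f"column {column!r}, row {row}: value {value!r} is not a valid code"
        )


class DegenerateDataError(DispmedError):
    """The data are degenerate for the requested operation (e.g. no rows left)."""


class ModelError(DispmedError):
    """A regression model could not be fitted or used."""


class CollinearityError(ModelError):
    """Design matrix is rank deficient."""

    def __init__(self, columns) -> None:
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(self.columns)
        )


class ConvergenceError(ModelError):
    """A model did not converge and no fallback was enabled."""


class ConfigError(DispmedError):
    """A run configuration is invalid."""
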