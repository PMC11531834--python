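"""Exception hierarchy shared across the pipeline."""


class GranulefitError(Exception):
    """Base class for all package errors."""


class ContractError(GranulefitError):
    """An operation was called on an input of the wrong kind."""


class EmptyDistributionError(GranulefitError):
    """No usable mass: all-zero counts or an empty population."""


class InsufficientDataError(GranulefitError):
    """Too few informative bins to attempt the requested operation."""


class ParseError(GranulefitError):
    """A file failed validation; message carries path and row context."""

    def __init__(self, message: str, path=None, row=None):
        ctx = []
        if path is not None:
            ctx.append(f"file={path}")
        if row is not None:
            ctx.append(f"row={row}")
        if ctx:
            message = f"{message} ({', '.join(ctx)})"
        super().__init__(message)
        self.path = path
        self.row = row


class UnconvergedFitError(GranulefitError):
    """Phenotype extraction requested from a fit that did not converge."""
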