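"""Exception types shared across the package."""


class KinasignError(Exception):
    """Base class for all package errors."""


class ValidationError(KinasignError):
    """A value violates a documented contract (range, shape, uniqueness)."""


class ParseError(KinasignError):
    """A file could not be parsed; carries file, line and field context.

    Parameters
    ----------
    message:
        Human-readable description of the problem.
    path:
        File being parsed, if known.
    line:
        1-based line (or row) number where the problem was found.
    field:
        Column or field name involved.
    """

    def __init__(self, message, path=None, line=None, field=None):
        self.path = path
        self.line = line
        self.field = field
        ctx = []
        if path is not None:
            ctx.append(f"file={path}")
        if line is not None:
            ctx.append(f"line={line}")
        if field is not None:
            ctx.append(f"field={field}")
        if ctx:
            message = f"{message} ({', '.join(ctx)})"
        super().__init__(message)


class ConvergenceError(KinasignError):
    """An iterative fit failed to converge; carries diagnostic detail."""
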