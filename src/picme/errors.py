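"""Exception hierarchy shared across the package."""


class PicmeError(Exception):
    """Base class for all picme errors."""


class InputError(PicmeError):
    """Malformed or inconsistent user input (files, tables, pairs)."""


class DegenerateDataError(PicmeError):
    """Data that is syntactically valid but unusable (single class, empty...)."""
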