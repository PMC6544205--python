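"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes (usage errors are handled by
click itself): :class:`FormatError` -> 3, :class:`IntegrityError` -> 4.
"""


class UKBKitError(Exception):
    """Base class for all errors raised by ukbkit."""


class FormatError(UKBKitError):
    """A file does not conform to its expected dialect (malformed HTML
    dictionary, bad UDI, wrong column count, missing fileset member...)."""


class IntegrityError(UKBKitError):
    """The data violate an integrity constraint (duplicate eid, coding
    level/label length mismatch, undeclared coding reference...)."""
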