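"""Exceptions and warnings shared across fermbalance."""


class ValidationError(ValueError):
    """Raised when an input value or table violates a domain constraint."""


class UnknownGeneError(KeyError):
    """Raised when a requested gene is absent from a coverage table."""


class CarbonBalanceWarning(UserWarning):
    """Emitted when measured product carbon exceeds the substrate carbon.

    A conversion above ~100% means the products contain more carbon than the
    substrate could supply — a data inconsistency (mis-measured concentration,
    wrong substrate loading), not a physical outcome. Values are flagged, never
    clipped, because measurement noise can legitimately push a near-complete
    fermentation slightly past 100.
    """
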