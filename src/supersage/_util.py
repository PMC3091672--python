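"""Small shared helpers: DNA string utilities and rounding conventions."""

from __future__ import annotations

import math

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: NlaIII recognition site anchoring every tag.  Note CATG is its own
#: reverse complement, so any sequence containing it does so on both strands.
ANCHOR = "CATG"

#: Length of the printed tag (anchor excluded).
TAG_CORE_LEN = 22

#: Full tag length including the CATG anchor.
TAG_LEN = 26


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of printed report tables).

    Python's built-in ``round`` uses banker's rounding, which would turn
    e.g. 0.5 into 0; report tables round 0.5 up.
    """
    scale = 10.0 ** ndigits
    v = math.floor(abs(x) * scale + 0.5) / scale
    return -v if x < 0 else v


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage rounded half away from zero to ``ndigits`` decimals."""
    if denominator == 0:
        return 0.0
    return round_half_away(100.0 * numerator / denominator, ndigits)


def is_dna(seq: str) -> bool:
    return all(c in "ACGT" for c in seq)
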