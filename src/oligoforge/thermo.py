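"""Buffer-corrected DNA duplex melting temperatures (Wetmur model).

Tm = 81.5 + 16.6 log10([Na_equiv] / (1 + 0.7 [Na_equiv]))
     + 0.41 %GC - 500 / L - %MM

with the von Ahsen sodium equivalent

[Na_equiv] = [Na+] + [K+] + [Tris]/2 + 3.79 sqrt([Mg2+] - [dNTP]).

All concentrations are molar; temperatures are in deg C and carried at full
precision (display rounding happens only in the reporting layer).  This is a
GC/length/salt model: no nearest-neighbour correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

_PURE = frozenset("ACGT")


@dataclass(frozen=True)
class BufferConditions:
    """Assembly-buffer ion concentrations, molar."""

    na: float = 0.05
    k: float = 0.0
    tris: float = 0.0
    mg: float = 0.002
    dntp: float = 0.0002

    def __post_init__(self):
        for name in ("na", "k", "tris", "mg", "dntp"):
            if getattr(self, name) < 0:
                raise ValueError(f"concentration {name} must be >= 0")
        if self.mg < self.dntp:
            raise ValueError(
                "[Mg2+] must be >= [dNTP] (sqrt of a negative otherwise)"
            )


#: Typical PCR buffer, used when no concentrations are supplied.
DEFAULT_BUFFER = BufferConditions()


@dataclass(frozen=True)
class DuplexQuery:
    """A duplex to melt: top-strand sequence plus percentage mismatch."""

    sequence: str
    mismatch_percent: float = 0.0

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("duplex sequence must be nonempty")
        bad = set(self.sequence.upper()) - _PURE
        if bad:
            raise ValueError(
                f"duplex sequence contains non-pure symbols {sorted(bad)}"
            )
        if self.mismatch_percent < 0:
            raise ValueError("%MM must be >= 0")


def sodium_equivalent(buffer: BufferConditions) -> float:
    """von Ahsen monovalent-cation equivalent of a PCR buffer, molar."""
    return (
        buffer.na
        + buffer.k
        + buffer.tris / 2.0
        + 3.79 * math.sqrt(buffer.mg - buffer.dntp)
    )


def gc_fraction(sequence: str) -> float:
    """GC content of a pure-base sequence, as a percentage in [0, 100]."""
    seq = sequence.upper()
    if not seq:
        raise ValueError("cannot compute GC content of an empty sequence")
    bad = set(seq) - _PURE
    if bad:
        raise ValueError(f"sequence contains non-pure symbols {sorted(bad)}")
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def wetmur_salt_term(buffer: BufferConditions) -> float:
    """81.5 + 16.6 log10(Na_eq/(1+0.7 Na_eq)): the sequence-free part of Tm."""
    na_eq = sodium_equivalent(buffer)
    if na_eq <= 0:
        raise ValueError("sodium equivalent must be > 0 (log undefined)")
    return 81.5 + 16.6 * math.log10(na_eq / (1.0 + 0.7 * na_eq))


def tm_from_counts(gc_count: int, length: int, salt_term: float,
                   mismatch_percent: float = 0.0) -> float:
    """Wetmur Tm from a GC count and length, given a precomputed salt term."""
    return salt_term + 41.0 * gc_count / length - 500.0 / length - mismatch_percent


def melting_temperature(
    query: DuplexQuery | str,
    buffer: BufferConditions = DEFAULT_BUFFER,
    mismatch_percent: float = 0.0,
) -> float:
    """Melting temperature (deg C) of a duplex under the Wetmur formula.

    ``query`` may be a :class:`DuplexQuery` or a plain top-strand sequence
    (in which case ``mismatch_percent`` applies).
    """
    if isinstance(query, str):
        query = DuplexQuery(query, mismatch_percent)
    seq = query.sequence.upper()
    gc = seq.count("G") + seq.count("C")
    return tm_from_counts(
        gc, len(seq), wetmur_salt_term(buffer), query.mismatch_percent
    )
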