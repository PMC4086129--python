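"""Genetic code, IUPAC degenerate codons, codon-usage tables and the CAI.

The Codon Adaptation Index (CAI) of a coding sequence is the geometric mean
of the relative adaptiveness ``w_i`` of its codons, where ``w_i`` is the
codon's usage frequency divided by that of the most frequent synonymous
codon in the host table.  Codons containing degenerate (mixed-base) symbols
are excluded from the CAI, since they represent a mixture of sequences.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

STOP = "*"
DNA_BASES = "ACGT"
_PURE = frozenset(DNA_BASES)

#: IUPAC nucleotide symbols -> the set of pure bases each represents,
#: stored as lexicographically sorted strings.
IUPAC_DNA: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class InvalidCodonError(ValueError):
    """A codon contains a symbol outside the IUPAC nucleotide alphabet."""


def _standard_code() -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[1]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = STOP
    return code


#: The standard genetic code: 64 pure codons -> amino-acid letter or ``*``.
STANDARD_CODE: dict[str, str] = _standard_code()

#: Amino acid (or ``*``) -> sorted tuple of synonymous codons.
SYNONYMS: dict[str, tuple[str, ...]] = {
    aa: tuple(sorted(c for c, a in STANDARD_CODE.items() if a == aa))
    for aa in sorted(set(STANDARD_CODE.values()))
}

AMINO_ACIDS: tuple[str, ...] = tuple(aa for aa in SYNONYMS if aa != STOP)


def expand_degenerate_codon(codon: str) -> tuple[str, ...]:
    """Expand a 3-symbol IUPAC codon into its pure codons, lexicographically.

    ``TNT`` -> ``(TAT, TCT, TGT, TTT)``; a pure codon expands to itself.
    """
    if len(codon) != 3:
        raise InvalidCodonError(f"codon must have 3 symbols, got {codon!r}")
    sets = []
    for symbol in codon:
        try:
            sets.append(IUPAC_DNA[symbol.upper()])
        except KeyError:
            raise InvalidCodonError(
                f"{symbol!r} in codon {codon!r} is not an IUPAC nucleotide symbol"
            ) from None
    return tuple("".join(bases) for bases in itertools.product(*sets))


def encoded_amino_acids(
    codon: str, code: dict[str, str] = STANDARD_CODE
) -> tuple[str, ...]:
    """Distinct amino acids (stop included) encoded by a degenerate codon.

    Ordered by first appearance over the lexicographic codon expansion.
    """
    seen: dict[str, None] = {}
    for pure in expand_degenerate_codon(codon):
        seen.setdefault(code[pure], None)
    return tuple(seen)


def variant_library_size(
    variant_codons, code: dict[str, str] = STANDARD_CODE
) -> int:
    """Number of protein variants generated by a set of variant codons.

    A codon encoding x amino acids at each of y independent sites yields a
    library of x**y protein variants; the general case is the product of
    per-site distinct amino-acid counts (stop counted as an outcome).
    """
    size = 1
    for codon in variant_codons:
        size *= len(encoded_amino_acids(codon, code))
    return size


@dataclass
class CodonUsageTable:
    """Per-codon usage of a host organism, normalized per synonymous family.

    ``fraction[codon]`` sums to 1 within each synonymous family (input may
    be per-thousand frequencies, raw counts or fractions: only ratios within
    a family matter for relative adaptiveness and Monte-Carlo sampling).
    """

    organism: str
    fraction: dict[str, float]
    _samplers: dict = field(default_factory=dict, repr=False, compare=False)

    @classmethod
    def from_frequencies(
        cls, frequencies: dict[str, float], organism: str = "unknown"
    ) -> "CodonUsageTable":
        """Build a table from any {codon: weight} mapping.

        Keys are case-insensitive, U is accepted for T, missing codons are
        filled with 0.  Every non-stop synonymous family must keep at least
        one codon with positive weight.
        """
        cleaned: dict[str, float] = {}
        for key, value in frequencies.items():
            codon = key.upper().replace("U", "T")
            if len(codon) != 3 or any(b not in _PURE for b in codon):
                raise ValueError(f"invalid codon {key!r} in usage table")
            value = float(value)
            if value < 0:
                raise ValueError(f"negative frequency for codon {key!r}")
            cleaned[codon] = value
        fraction = {codon: cleaned.get(codon, 0.0) for codon in STANDARD_CODE}
        for aa, family in SYNONYMS.items():
            total = sum(fraction[c] for c in family)
            if total <= 0:
                if aa == STOP:
                    continue  # stop usage is irrelevant to protein design
                raise ValueError(
                    f"codon usage table has no data for amino acid {aa!r}"
                )
            for c in family:
                fraction[c] /= total
        return cls(organism=organism, fraction=fraction)

    def sampler(self, amino_acid: str):
        """(codons, cumulative weights) for frequency-weighted sampling."""
        cached = self._samplers.get(amino_acid)
        if cached is not None:
            return cached
        family = SYNONYMS.get(amino_acid)
        if family is None or amino_acid == STOP:
            raise ValueError(f"unknown amino acid {amino_acid!r}")
        codons = tuple(c for c in family if self.fraction[c] > 0)
        weights = np.array([self.fraction[c] for c in codons], dtype=float)
        cumulative = np.cumsum(weights / weights.sum())
        cumulative[-1] = 1.0
        self._samplers[amino_acid] = (codons, cumulative)
        return codons, cumulative


def relative_adaptiveness(table: CodonUsageTable) -> dict[str, float]:
    """w_i = f_i / max(f_j) over each synonymous family; stops excluded."""
    w: dict[str, float] = {}
    for aa, family in SYNONYMS.items():
        if aa == STOP:
            continue
        fmax = max(table.fraction[c] for c in family)
        for c in family:
            w[c] = table.fraction[c] / fmax
    return w


def sample_codon(
    amino_acid: str, table: CodonUsageTable, rng: np.random.Generator
) -> str:
    """Monte-Carlo draw of a synonymous codon, weighted by usage frequency."""
    codons, cumulative = table.sampler(amino_acid)
    if len(codons) == 1:
        return codons[0]
    return codons[int(np.searchsorted(cumulative, rng.random(), side="right"))]


def cai(coding_dna: str, w: dict[str, float]) -> float:
    """CAI = exp(mean ln w_i) over the pure codons of a coding sequence.

    Codons containing degenerate symbols are skipped and do not count toward
    the mean.  Returns 0.0 if any counted codon has w = 0 (zero-usage codon).
    """
    seq = coding_dna.upper()
    if len(seq) % 3:
        raise ValueError(
            f"coding sequence length {len(seq)} is not a multiple of 3"
        )
    total = 0.0
    counted = 0
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if any(b not in _PURE for b in codon):
            continue  # degenerate variant codon: excluded from CAI
        value = w.get(codon)
        if value is None:
            raise ValueError(f"stop codon {codon} inside coding region")
        if value <= 0.0:
            return 0.0
        total += math.log(value)
        counted += 1
    if counted == 0:
        raise ValueError("CAI undefined: every codon contains degenerate bases")
    return math.exp(total / counted)
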