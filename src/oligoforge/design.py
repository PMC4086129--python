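"""Candidate-solution model: construct sequence, oligo boundaries, variants.

A design is a full double-stranded construct (5' cloning sequence + coding
region + 3' cloning sequence) tiled by overlapping oligos on alternating
strands.  Coordinates are 0-based half-open everywhere internally; display
layers convert to 1-based inclusive.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from . import codons as cm
from . import thermo

_PURE = frozenset("ACGT")
_AA_LETTERS = frozenset(cm.AMINO_ACIDS)

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def reverse_complement(sequence: str) -> str:
    """IUPAC-aware reverse complement."""
    return sequence.translate(_COMPLEMENT)[::-1]


def longest_repeat_run(sequence: str) -> int:
    """Length of the longest homopolymer run of any single symbol."""
    if not sequence:
        raise ValueError("empty sequence")
    return max(len(list(g)) for _, g in itertools.groupby(sequence))


@dataclass(frozen=True)
class VariantCodonSpec:
    """A user-fixed (possibly degenerate) codon at a protein position.

    ``position`` is the 1-based amino-acid index; ``original_amino_acid`` is
    the residue of the input protein at that position, used when the variant
    must be reverted because it falls inside an oligo overlap.
    """

    position: int
    codon: str
    original_amino_acid: str


@dataclass
class DesignInput:
    """The immutable job definition: sequences, variants and all parameters."""

    protein: str
    target_tm: float
    table: cm.CodonUsageTable
    five_prime: str = ""
    three_prime: str = ""
    variants: tuple[VariantCodonSpec, ...] = ()
    max_oligo_length: int = 60
    max_repeat: int = 5
    min_overlap: int = 10
    iterations: int = 50_000
    codon_mutation_rate: float = 0.02
    oligo_mutation_rate: float = 0.1
    buffer: thermo.BufferConditions = thermo.DEFAULT_BUFFER
    seed: int = 1
    name: str = "design"

    def __post_init__(self):
        self.protein = self.protein.upper()
        self.five_prime = self.five_prime.upper()
        self.three_prime = self.three_prime.upper()
        self.variants = tuple(self.variants)

    def validate(self) -> None:
        if not self.protein:
            raise ValueError("protein sequence is empty")
        bad = set(self.protein) - _AA_LETTERS
        if bad:
            raise ValueError(f"invalid amino-acid letters {sorted(bad)}")
        for label, seq in (("5'", self.five_prime), ("3'", self.three_prime)):
            if set(seq) - _PURE:
                raise ValueError(
                    f"{label} cloning sequence must contain pure bases only"
                )
        if self.target_tm <= 0:
            raise ValueError("target melting temperature must be > 0")
        if self.max_oligo_length <= 2 * self.min_overlap:
            raise ValueError(
                "max oligo length must exceed twice the minimum overlap"
            )
        if self.min_overlap < 1:
            raise ValueError("minimum overlap must be >= 1")
        if self.max_repeat < 1:
            raise ValueError("max repeat run must be >= 1")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        for label, rate in (
            ("codon", self.codon_mutation_rate),
            ("oligo", self.oligo_mutation_rate),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{label} mutation rate must be in [0, 1]")
        seen = set()
        for spec in self.variants:
            if not 1 <= spec.position <= len(self.protein):
                raise ValueError(
                    f"variant position {spec.position} outside protein "
                    f"(1..{len(self.protein)})"
                )
            if spec.position in seen:
                raise ValueError(f"duplicate variant position {spec.position}")
            seen.add(spec.position)
            cm.expand_degenerate_codon(spec.codon)  # raises on bad symbols
            if spec.original_amino_acid != self.protein[spec.position - 1]:
                raise ValueError(
                    f"variant at {spec.position}: original amino acid "
                    f"{spec.original_amino_acid!r} does not match protein "
                    f"({self.protein[spec.position - 1]!r})"
                )

    @property
    def coding_offset(self) -> int:
        return len(self.five_prime)

    @property
    def construct_length(self) -> int:
        return len(self.five_prime) + 3 * len(self.protein) + len(self.three_prime)


@dataclass
class GeneDesign:
    """A candidate solution.

    ``codons`` holds the current *pure* backbone codon per protein position
    (the codon retained for reversion at variant positions); ``variant_active``
    says which variant specs are currently substituted into ``dna``;
    ``boundaries`` are the oligo intervals, 0-based half-open over ``dna``.
    """

    codons: list[str]
    variant_active: list[bool]
    boundaries: list[tuple[int, int]]
    five_prime: str
    three_prime: str
    specs: tuple[VariantCodonSpec, ...]
    dna: str = ""

    def clone(self) -> "GeneDesign":
        return GeneDesign(
            list(self.codons),
            list(self.variant_active),
            list(self.boundaries),
            self.five_prime,
            self.three_prime,
            self.specs,
            self.dna,
        )


@dataclass(frozen=True)
class Oligo:
    index: int  # 1-based; odd = forward, even = reverse
    name: str
    direction: str  # "forward" | "reverse"
    sequence: str
    length: int


@dataclass(frozen=True)
class Overlap:
    index: int  # 1-based junction number between oligo index and index+1
    interval: tuple[int, int]
    tm: float


def backbone_dna(design: GeneDesign) -> str:
    """The construct with every variant reverted to its retained pure codon."""
    return design.five_prime + "".join(design.codons) + design.three_prime


def build_dna(design: GeneDesign) -> str:
    """Rebuild ``design.dna`` from codons, active variants and cloning ends."""
    coding = list(design.codons)
    for active, spec in zip(design.variant_active, design.specs):
        if active:
            coding[spec.position - 1] = spec.codon
    design.dna = design.five_prime + "".join(coding) + design.three_prime
    return design.dna


def spec_interval(design: GeneDesign, spec: VariantCodonSpec) -> tuple[int, int]:
    """0-based half-open interval of a variant codon within ``dna``."""
    start = len(design.five_prime) + 3 * (spec.position - 1)
    return start, start + 3


def overlap_intervals(boundaries) -> list[tuple[int, int]]:
    """Junction intervals: intersection of each consecutive oligo pair."""
    return [
        (boundaries[i + 1][0], boundaries[i][1])
        for i in range(len(boundaries) - 1)
    ]


def variant_viability(design: GeneDesign) -> list[bool]:
    """A spec is viable iff its codon is disjoint from every overlap.

    Degenerate bases inside an overlap would prevent the two oligos sharing
    it from annealing as perfect complements.
    """
    overlaps = overlap_intervals(design.boundaries)
    flags = []
    for spec in design.specs:
        a, b = spec_interval(design, spec)
        flags.append(all(b <= s or a >= e for s, e in overlaps))
    return flags


def set_variant_states(design: GeneDesign) -> GeneDesign:
    """Substitute viable variant codons, revert unviable ones; rebuild dna."""
    design.variant_active = variant_viability(design)
    build_dna(design)
    return design


def oligos_of(design: GeneDesign, name: str = "design") -> list[Oligo]:
    """The oligo set: alternating strands starting forward.

    Reverse oligos carry the reverse complement of their top-strand interval.
    """
    result = []
    for i, (start, end) in enumerate(design.boundaries):
        index = i + 1
        forward = index % 2 == 1
        top = design.dna[start:end]
        result.append(
            Oligo(
                index=index,
                name=f"{name}_{index}_{'F' if forward else 'R'}",
                direction="forward" if forward else "reverse",
                sequence=top if forward else reverse_complement(top),
                length=end - start,
            )
        )
    return result


def overlaps_of(
    design: GeneDesign,
    buffer: thermo.BufferConditions = thermo.DEFAULT_BUFFER,
) -> list[Overlap]:
    """Junction overlaps with their perfect-complement (%MM = 0) Tm."""
    salt = thermo.wetmur_salt_term(buffer)
    result = []
    for j, (a, b) in enumerate(overlap_intervals(design.boundaries)):
        seg = design.dna[a:b]
        gc = seg.count("G") + seg.count("C")
        result.append(
            Overlap(index=j + 1, interval=(a, b),
                    tm=thermo.tm_from_counts(gc, b - a, salt))
        )
    return result


def boundaries_valid(
    boundaries, dna_length: int, max_oligo_length: int, min_overlap: int
) -> bool:
    """Full legality check of an oligo boundary set.

    Anchored ends, coverage, max length, minimum overlap, strictly increasing
    starts/ends, and pairwise-disjoint junction overlaps (no base may belong
    to three oligos).
    """
    if not boundaries:
        return False
    if boundaries[0][0] != 0 or boundaries[-1][1] != dna_length:
        return False
    for i, (s, e) in enumerate(boundaries):
        if not (0 <= s < e <= dna_length) or e - s > max_oligo_length:
            return False
        if i > 0:
            ps, pe = boundaries[i - 1]
            if s <= ps or e <= pe:
                return False
            if pe - s < min_overlap:  # overlap length
                return False
        if i > 1 and s < boundaries[i - 2][1]:
            return False  # junction would collide with the previous overlap
    return True


def translate_backbone(design: GeneDesign) -> str:
    """Protein encoded by the retained pure codons (variants reverted)."""
    return "".join(cm.STANDARD_CODE[c] for c in design.codons)


def validate_design(design: GeneDesign, inp: DesignInput) -> None:
    """Assert every structural invariant; raises AssertionError otherwise."""
    n = len(inp.protein)
    assert len(design.codons) == n
    assert all(len(c) == 3 and set(c) <= _PURE for c in design.codons)
    assert translate_backbone(design) == inp.protein
    assert len(design.dna) == inp.construct_length
    assert boundaries_valid(
        design.boundaries, len(design.dna), inp.max_oligo_length, inp.min_overlap
    )
    assert design.variant_active == variant_viability(design)
    for active, spec in zip(design.variant_active, design.specs):
        a, b = spec_interval(design, spec)
        if active:
            assert design.dna[a:b] == spec.codon
        else:
            assert cm.STANDARD_CODE[design.dna[a:b]] == spec.original_amino_acid
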