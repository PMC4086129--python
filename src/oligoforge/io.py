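"""Readers, writers, alignment rendering and job configuration.

Formats: FASTA (protein in, oligos out), CSV (oligo table, progress log),
Kazusa-style codon-usage text or two-column TSV, and a YAML key-value job
configuration.
"""

from __future__ import annotations

import csv
import io as _io
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import codons as cm
from . import design as dm

_AA_LETTERS = frozenset(cm.AMINO_ACIDS)

# compact Kazusa layout: "UUU 17.6( 714298)" repeated across lines
_COMPACT = re.compile(r"([ACGTUacgtu]{3})\s+([0-9.]+)\s*\(\s*([0-9]+)\s*\)")


def read_protein(source: str | Path) -> str:
    """Protein sequence from a FASTA file/text or a raw sequence literal.

    Uppercased, whitespace-stripped, a single terminal ``*`` removed;
    invalid letters raise with their 1-based positions.
    """
    text = None
    if isinstance(source, Path):
        text = source.read_text()
    else:
        candidate = Path(source)
        try:
            if candidate.is_file():
                text = candidate.read_text()
        except OSError:
            pass
        if text is None:
            text = source
    if text.lstrip().startswith(">"):
        record = next(SeqIO.parse(_io.StringIO(text), "fasta"))
        sequence = str(record.seq)
    else:
        sequence = text
    sequence = "".join(sequence.split()).upper()
    if sequence.endswith("*"):
        sequence = sequence[:-1]
    bad = [
        f"{ch!r} at position {i + 1}"
        for i, ch in enumerate(sequence)
        if ch not in _AA_LETTERS
    ]
    if bad:
        raise ValueError("invalid amino-acid letters: " + ", ".join(bad))
    if not sequence:
        raise ValueError("empty protein sequence")
    return sequence


def parse_codon_usage(text: str, organism: str = "unknown") -> cm.CodonUsageTable:
    """Parse Kazusa-style (standard or compact) or two-column TSV usage text."""
    matches = _COMPACT.findall(text)
    if len(matches) >= 32:
        freqs = {codon: float(per_thousand) for codon, per_thousand, _ in matches}
        return cm.CodonUsageTable.from_frequencies(freqs, organism)
    freqs: dict[str, float] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        try:
            if len(tokens) == 2:
                # two-column TSV: codon <TAB> frequency
                freqs[tokens[0]] = float(tokens[1])
            elif len(tokens) >= 5 and len(tokens[1]) == 1:
                # Kazusa standard: codon  amino-acid  fraction  frequency  count
                freqs[tokens[0]] = float(tokens[3])
            else:
                raise ValueError("unrecognized layout")
        except ValueError as exc:
            raise ValueError(
                f"malformed codon-usage line {lineno}: {line!r} ({exc})"
            ) from None
    return cm.CodonUsageTable.from_frequencies(freqs, organism)


def read_codon_usage(path: str | Path, organism: str | None = None
                     ) -> cm.CodonUsageTable:
    path = Path(path)
    return parse_codon_usage(path.read_text(), organism or path.stem)


def parse_variant_specs(spec_texts, protein: str) -> tuple[dm.VariantCodonSpec, ...]:
    """Parse ``position:codon`` variant specifications against a protein."""
    specs = []
    seen = set()
    for text in spec_texts:
        try:
            pos_text, codon = text.split(":")
            position = int(pos_text)
        except ValueError:
            raise ValueError(
                f"variant spec {text!r} is not of the form <position>:<codon>"
            ) from None
        if not 1 <= position <= len(protein):
            raise ValueError(
                f"variant position {position} outside protein (1..{len(protein)})"
            )
        if position in seen:
            raise ValueError(f"duplicate variant position {position}")
        seen.add(position)
        codon = codon.upper()
        cm.expand_degenerate_codon(codon)  # raises on non-IUPAC symbols
        specs.append(
            dm.VariantCodonSpec(
                position=position,
                codon=codon,
                original_amino_acid=protein[position - 1],
            )
        )
    return tuple(specs)


def write_oligo_table(result, path: str | Path) -> None:
    """CSV oligo table: number,name,direction,sequence,length."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["number", "name", "direction", "sequence", "length"])
        for oligo in result.oligos:
            writer.writerow(
                [oligo.index, oligo.name, oligo.direction,
                 oligo.sequence.upper(), oligo.length]
            )


def write_oligos_fasta(result, path: str | Path) -> None:
    """FASTA of oligo sequences, headers = oligo names, 60-column wrap."""
    records = [
        SeqRecord(Seq(o.sequence.upper()), id=o.name, description="")
        for o in result.oligos
    ]
    SeqIO.write(records, str(path), "fasta")


def write_progress_csv(result, path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(
            ["iteration", "temperature", "cai_s", "tm_s", "mis_s", "fixed_s",
             "composite", "best_composite"]
        )
        for r in result.progress:
            writer.writerow(
                [r.iteration, r.temperature, r.cai_s, r.tm_s, r.mis_s,
                 r.fixed_s, r.composite, r.best_composite]
            )


def render_alignment(result, width: int = 60) -> str:
    """Fixed-width text alignment of the oligo set over the construct.

    Forward oligos print above the top strand, reverse oligos print their
    complement below it (read 3'->5' on screen); ``=`` marks overlap
    columns, ``_`` marks the fixed cloning sequences, and variant codons
    are tagged ``[+]`` (viable) or ``[-]`` (reverted).  Per-overlap Tms
    and any misanneal sites follow the alignment block.
    """
    design = result.best
    dna = design.dna
    length = len(dna)
    overlaps = dm.overlap_intervals(design.boundaries)

    forward_row = [" "] * length
    reverse_row = [" "] * length
    for i, (s, e) in enumerate(design.boundaries):
        row = forward_row if (i + 1) % 2 == 1 else reverse_row
        seg = dna[s:e]
        if row is reverse_row:
            seg = seg.translate(dm._COMPLEMENT)  # shown 3'->5' under the top strand
        for j, ch in enumerate(seg):
            row[s + j] = ch
    marker_row = [" "] * length
    for a, b in overlaps:
        for j in range(a, b):
            marker_row[j] = "="
    anno_row = [" "] * length
    for j in range(len(design.five_prime)):
        anno_row[j] = "_"
    for j in range(length - len(design.three_prime), length):
        anno_row[j] = "_"
    for active, spec in zip(design.variant_active, design.specs):
        a, b = dm.spec_interval(design, spec)
        tag = "+" if active else "-"
        for j in range(a, b):
            anno_row[j] = tag

    lines = []
    for chunk in range(0, length, width):
        hi = min(chunk + width, length)
        prefix = f"{chunk + 1:>6} "
        pad = " " * len(prefix)
        lines.append(pad + "".join(forward_row[chunk:hi]) + "  (forward oligos 5'->3')")
        lines.append(prefix + dna[chunk:hi] + "  (top strand)")
        lines.append(pad + "".join(reverse_row[chunk:hi]) + "  (reverse oligos, complement)")
        lines.append(pad + "".join(marker_row[chunk:hi]) + "  (= overlap)")
        lines.append(pad + "".join(anno_row[chunk:hi]) + "  (_ cloning, +/- variant)")
        lines.append("")

    for overlap in result.overlaps:
        a, b = overlap.interval
        lines.append(
            f"overlap {overlap.index}: {a + 1}-{b} Tm {overlap.tm:.1f} C"
        )
    for active, spec in zip(design.variant_active, design.specs):
        tag = "[+]" if active else "[-]"
        lines.append(
            f"variant {spec.position}:{spec.codon} {tag} "
            + ("specified" if active else
               f"reverted to {spec.original_amino_acid}")
        )
    if result.misanneals.sites:
        lines.append("misanneal sites:")
        for site in result.misanneals.sites:
            a, b = site.interval
            pa, pb = site.partner
            lines.append(
                f"  {a + 1}-{b} ~ {pa + 1}-{pb} ({site.orientation}) "
                f"Tm {site.tm:.1f} C"
            )
    else:
        lines.append("misanneal sites: none")
    for a, b, base in result.misanneals.repeat_runs:
        lines.append(f"repeat run: {base} x {b - a} at {a + 1}-{b}")
    return "\n".join(lines)


@dataclass
class JobConfig:
    """Round-trippable job description (paths and primitives only)."""

    protein: str
    target_tm: float
    table_path: str
    five_prime: str = ""
    three_prime: str = ""
    variants: list = field(default_factory=list)  # ["66:YAT", ...]
    max_oligo_length: int = 60
    max_repeat: int = 5
    min_overlap: int = 10
    iterations: int = 50_000
    codon_mutation_rate: float = 0.02
    oligo_mutation_rate: float = 0.1
    na: float = 0.05
    k: float = 0.0
    tris: float = 0.0
    mg: float = 0.002
    dntp: float = 0.0002
    seed: int = 1
    name: str = "design"
    out_dir: str = "."
    progress_every: int = 0
    extended_misanneal_scan: bool = False

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "JobConfig":
        return cls(**yaml.safe_load(text))


def save_config(config: JobConfig, path: str | Path) -> None:
    Path(path).write_text(config.to_yaml())


def load_config(path: str | Path) -> JobConfig:
    return JobConfig.from_yaml(Path(path).read_text())
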