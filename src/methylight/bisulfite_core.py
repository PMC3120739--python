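"""In-silico bisulfite conversion of double-stranded DNA.

Bisulfite treatment deaminates unmethylated cytosine to uracil (read as
thymine after PCR) while 5-methylcytosine is protected.  Because the two
genomic strands are converted independently, a double-stranded region is
transformed into two non-complementary single strands, and each strand has
two idealised outcomes depending on the methylation state of its CpG sites.
This module produces those four templates and the sequence primitives
(reverse complement, CpG enumeration, base composition) used everywhere
else in the toolkit.

Converted sequences are written with T, not U, matching what PCR products
and Sanger reads of cloned amplicons actually contain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlphabetError, BisulfiteWarning

Strand = Literal["sense", "antisense"]
Assumption = Literal["methylated", "unmethylated"]

STRANDS: tuple[Strand, ...] = ("sense", "antisense")
ASSUMPTIONS: tuple[Assumption, ...] = ("methylated", "unmethylated")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


def check_dna(seq: str, context: str = "sequence") -> str:
    """Normalise to uppercase and reject anything outside {A, C, G, T}.

    Ambiguity codes (N, Y, R, ...) are rejected rather than guessed: the
    templates this toolkit reasons about are fully resolved sequences.
    """
    s = seq.upper()
    for i, ch in enumerate(s):
        if ch not in _VALID:
            raise AlphabetError(ch, i, context)
    return s


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement. Involution: rc(rc(s)) == s."""
    return check_dna(seq).translate(_COMPLEMENT)[::-1]


def enumerate_cpg_sites(seq: str) -> list[int]:
    """0-based indices of the C of every CpG dinucleotide in ``seq``."""
    s = check_dna(seq)
    return [i for i in range(len(s) - 1) if s[i] == "C" and s[i + 1] == "G"]


def convert(seq: str, assumption: Assumption) -> str:
    """Apply idealised bisulfite conversion to a single strand.

    unmethylated
        every C -> T (complete conversion, no protection anywhere);
    methylated
        C in CpG context is retained, every other C -> T.

    A cytosine at the last position has unknown CpG context (its 3'
    neighbour is outside the region); it is conservatively treated as
    non-CpG and converted, with a warning.  Length is always preserved
    and the operation is idempotent under a fixed assumption.
    """
    s = check_dna(seq)
    if assumption == "unmethylated":
        return s.replace("C", "T")
    if assumption != "methylated":
        raise ValueError(f"unknown conversion assumption: {assumption!r}")
    if s.endswith("C"):
        warnings.warn(
            "terminal C has unknown CpG context; treating it as non-CpG (converted)",
            BisulfiteWarning,
            stacklevel=2,
        )
    out = []
    for i, ch in enumerate(s):
        if ch == "C" and not (i + 1 < len(s) and s[i + 1] == "G"):
            out.append("T")
        else:
            out.append(ch)
    return "".join(out)


def base_composition(seq: str) -> dict[str, int]:
    """Counts of A, C, G and T; the four values sum to ``len(seq)``."""
    s = check_dna(seq)
    return {b: s.count(b) for b in "ACGT"}


@dataclass(frozen=True)
class GenomicRegion:
    """An unconverted genomic region with a declared transcription start site.

    ``tss_offset`` is the 0-based index of the base numbered +1 in
    TSS-relative coordinates (there is no position 0 in that numbering).
    """

    name: str
    sequence: str
    tss_offset: int = 0

    def __post_init__(self) -> None:
        seq = check_dna(self.sequence, context=f"region {self.name!r}")
        if not seq:
            raise ValueError(f"region {self.name!r} has an empty sequence")
        object.__setattr__(self, "sequence", seq)
        if not 0 <= self.tss_offset < len(seq):
            raise ValueError(
                f"tss_offset {self.tss_offset} outside region of length {len(seq)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BisulfiteTemplate:
    """One of the four converted single strands of a :class:`GenomicRegion`.

    The antisense template is the conversion of the reverse complement of
    the region; its position 0 therefore corresponds to the *last* genomic
    base of the region.
    """

    source: GenomicRegion
    strand: Strand
    assumption: Assumption
    converted: str

    @property
    def record_name(self) -> str:
        return f"{self.source.name}|{self.strand}|{self.assumption}"

    def __len__(self) -> int:
        return len(self.converted)

    def genomic_offset(self, template_pos: int) -> int:
        """Map a 0-based template position to a 0-based offset in the region."""
        if self.strand == "sense":
            return template_pos
        return len(self.source) - 1 - template_pos


TemplateSet = dict[tuple[Strand, Assumption], BisulfiteTemplate]


def four_templates(region: GenomicRegion) -> TemplateSet:
    """The four single-stranded templates: {sense, antisense} x {M, U}.

    For any region with at least one non-CpG cytosine on either strand the
    sense and antisense conversions are no longer reverse complements of
    each other — conversion breaks strand complementarity, which is why a
    bisulfite assay must commit to one strand.
    """
    strands = {
        "sense": region.sequence,
        "antisense": reverse_complement(region.sequence),
    }
    out: TemplateSet = {}
    for strand, seq in strands.items():
        for assumption in ASSUMPTIONS:
            out[(strand, assumption)] = BisulfiteTemplate(
                source=region,
                strand=strand,  # type: ignore[arg-type]
                assumption=assumption,
                converted=convert(seq, assumption),
            )
    return out


# ---------------------------------------------------------------------------
# FASTA I/O


def read_region(path, name: str | None = None, tss_offset: int = 0) -> GenomicRegion:
    """Read the first record of a FASTA file as a :class:`GenomicRegion`."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return GenomicRegion(
        name=name or record.id, sequence=str(record.seq), tss_offset=tss_offset
    )


def write_region(region: GenomicRegion, path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(region.sequence), id=region.name, description="")],
        str(path),
        "fasta",
    )


def write_templates(templates: Iterable[BisulfiteTemplate], path) -> None:
    """Write templates as FASTA, one record per strand/assumption combination."""
    records = [
        SeqRecord(Seq(t.converted), id=t.record_name, description="")
        for t in templates
    ]
    SeqIO.write(records, str(path), "fasta")
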