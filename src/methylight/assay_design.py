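"""Placement and validation of methylation-specific PCR/MethyLight assays.

An assay is a forward primer, a reverse primer and a TaqMan probe designed
against one bisulfite-converted strand.  Methylation specificity comes from
bases that derive from CpG cytosines: on the methylated template they read
C (or G on a reverse-orientation oligo), on the fully converted
unmethylated template they read T (or A), so an oligo covering CpG sites
anneals only to the methylated product.

Oligo sequences are written in the mixed-case dialect used in assay
publications: lowercase for conversion-invariant bases, uppercase C/G for
the CpG-derived discriminating bases.  An explicit index list is accepted
for oligos supplied in plain case.  Published oligos are printed 5'->3'
for whichever face of the amplicon they anneal to; the ``opposite`` flag
records a probe (or primer pair) designed against the face opposite the
usual one for its role, which is recognisable in print because such an
oligo carries lowercase ``c`` residues that could never survive
conversion on the assayed strand itself.

Coordinates are TSS-relative, 1-based and inclusive at both ends, with no
position 0: +1 is the first transcribed base and -1 the base immediately
upstream.  Under this convention an amplicon printed as (+238 ~ +307)
spans exactly 70 bp.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Sequence

import yaml

from .bisulfite_core import (
    BisulfiteTemplate,
    Strand,
    TemplateSet,
    check_dna,
    reverse_complement,
)
from .errors import DesignError, DesignWarning, OligoParseError

Role = Literal["forward", "reverse", "probe"]

# strip whitespace, 5'/3' decorations and hyphens from printed oligo text
_DECORATION = re.compile(r"5'|3'|[\s\-]+")


# ---------------------------------------------------------------------------
# Oligos


@dataclass(frozen=True)
class Oligo:
    """A primer or probe with CpG-discriminating positions annotated.

    ``discriminating`` holds 0-based indices into ``sequence`` of the
    CpG-derived bases that differ between methylated and unmethylated
    templates.  ``opposite`` marks an oligo printed for the face of the
    amplicon opposite the conventional one for its role.
    """

    name: str
    sequence: str
    role: Role
    discriminating: tuple[int, ...] = ()
    label: str | None = None
    opposite: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence", check_dna(self.sequence, context=f"oligo {self.name!r}")
        )
        if not self.sequence:
            raise OligoParseError(f"oligo {self.name!r} is empty")
        for i in self.discriminating:
            if not 0 <= i < len(self.sequence):
                raise OligoParseError(
                    f"discriminating index {i} outside oligo {self.name!r}"
                )

    @property
    def scans_revcomp(self) -> bool:
        """Whether the template carries the reverse complement of this oligo."""
        return (self.role == "reverse") != self.opposite

    def __len__(self) -> int:
        return len(self.sequence)


def parse_oligo(
    text: str,
    role: Role,
    name: str,
    label: str | None = None,
    discriminating: Sequence[int] | None = None,
    opposite: bool = False,
) -> Oligo:
    """Parse annotated oligo text into an :class:`Oligo`.

    Whitespace, hyphens and 5'/3' decorations are stripped.  Unless an
    explicit ``discriminating`` index list is given, uppercase C and G
    mark the CpG-derived bases.  Uppercase A/T carry no methylation
    information and are ignored with a warning.
    """
    stripped = _DECORATION.sub("", text)
    if not re.fullmatch(r"[acgtACGT]*", stripped):
        bad = re.search(r"[^acgtACGT]", stripped)
        assert bad is not None
        raise OligoParseError(
            f"non-base character {bad.group()!r} in oligo {name!r} after "
            "stripping decorations"
        )
    if discriminating is None:
        disc = []
        for i, ch in enumerate(stripped):
            if ch.isupper():
                if ch in "CG":
                    disc.append(i)
                else:
                    warnings.warn(
                        f"uppercase {ch} in oligo {name!r} is not a CpG-derived "
                        "base; ignored",
                        DesignWarning,
                        stacklevel=2,
                    )
        discriminating = disc
    return Oligo(
        name=name,
        sequence=stripped.upper(),
        role=role,
        discriminating=tuple(discriminating),
        label=label,
        opposite=opposite,
    )


def oligo_cpg_count(oligo: Oligo) -> int:
    """Number of distinct CpG-derived discriminating bases in the oligo."""
    _, disc = scan_sequence(oligo)
    return len(disc)


# ---------------------------------------------------------------------------
# Assays


@dataclass(frozen=True)
class Assay:
    """A primer pair plus probe targeting one strand of one region.

    ``reference=True`` marks a methylation-neutral control assay (the
    COL2A1-style reference amplified from a CpG-free region, used to
    quantify the amount of converted DNA independently of methylation).
    ``nominal_length_bp`` is the amplicon length the assay is named for
    in its source publication, kept separate from the computed length so
    a discrepancy is reported rather than silently resolved.
    """

    name: str
    forward: Oligo
    reverse: Oligo
    probe: Oligo
    target_strand: Strand
    reference: bool = False
    nominal_length_bp: int | None = None

    def __post_init__(self) -> None:
        for oligo, role in (
            (self.forward, "forward"),
            (self.reverse, "reverse"),
            (self.probe, "probe"),
        ):
            if oligo.role != role:
                raise DesignError(
                    f"assay {self.name!r}: oligo {oligo.name!r} has role "
                    f"{oligo.role!r}, expected {role!r}"
                )
        total = sum(oligo_cpg_count(o) for o in self.oligos)
        if self.reference and total > 0:
            raise DesignError(
                f"reference assay {self.name!r} must not contain discriminating "
                f"CpG bases (found {total})"
            )
        if not self.reference and total == 0:
            warnings.warn(
                f"assay {self.name!r} has no methylation discrimination "
                "(zero CpG-derived bases in all oligos)",
                DesignWarning,
                stacklevel=2,
            )

    @property
    def oligos(self) -> tuple[Oligo, Oligo, Oligo]:
        return (self.forward, self.reverse, self.probe)

    @property
    def upstream_primer(self) -> Oligo:
        """The primer whose printed sequence appears as-is in the template."""
        up, _ = _oriented_primers(self)
        return up

    @property
    def downstream_primer(self) -> Oligo:
        """The primer whose reverse complement appears in the template."""
        _, down = _oriented_primers(self)
        return down


def _oriented_primers(assay: Assay) -> tuple[Oligo, Oligo]:
    primers = (assay.forward, assay.reverse)
    as_is = [o for o in primers if not o.scans_revcomp]
    rc = [o for o in primers if o.scans_revcomp]
    if len(as_is) != 1 or len(rc) != 1:
        raise DesignError(
            f"assay {assay.name!r}: primers must anneal to opposite faces "
            "(one as-is, one reverse-complement)"
        )
    return as_is[0], rc[0]


def load_assays(path) -> list[Assay]:
    """Load assay definitions from a YAML config file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _assays_from_doc(doc)


def builtin_assays() -> list[Assay]:
    """The three published p16/CDKN2A MethyLight assays shipped with the toolkit.

    Two methylated-p16 assays (a 70-bp antisense-strand design and a
    115-bp sense-strand design) plus the COL2A1 reference.
    """
    text = resources.files("methylight").joinpath("data/assays.yml").read_text()
    return _assays_from_doc(yaml.safe_load(text))


def _assays_from_doc(doc: dict) -> list[Assay]:
    assays = []
    for entry in doc["assays"]:
        oligos = {}
        for role in ("forward", "reverse", "probe"):
            spec = entry[role]
            oligos[role] = parse_oligo(
                spec["sequence"],
                role=role,  # type: ignore[arg-type]
                name=spec.get("name", f"{entry['name']}-{role}"),
                label=spec.get("label"),
                discriminating=spec.get("discriminating"),
                opposite=spec.get("orientation", "standard") == "opposite",
            )
        assays.append(
            Assay(
                name=entry["name"],
                forward=oligos["forward"],
                reverse=oligos["reverse"],
                probe=oligos["probe"],
                target_strand=entry.get("target_strand", "sense"),
                reference=bool(entry.get("reference", False)),
                nominal_length_bp=entry.get("nominal_length_bp"),
            )
        )
    return assays


# ---------------------------------------------------------------------------
# Oligo placement


@dataclass(frozen=True)
class OligoHit:
    """One alignment of an oligo onto a template (gap-free scan)."""

    oligo: Oligo
    template: BisulfiteTemplate
    position: int
    orientation: Literal["as-is", "reverse-complement"]
    mismatches: int
    mismatch_at_cpg: int


def scan_sequence(oligo: Oligo) -> tuple[str, list[int]]:
    """Sequence searched on the template plus the scan-frame indices of
    the discriminating bases.

    Published annotations may uppercase either member of a CpG
    dinucleotide (reverse primers conventionally mark the G, which is
    the complement of the template's CpG cytosine).  In scan frame only
    the C of a CpG actually differs between methylated and unmethylated
    templates, so a marked position that lands on the G of a scan-frame
    CpG is resolved to its C partner.
    """
    if oligo.scans_revcomp:
        seq = reverse_complement(oligo.sequence)
        n = len(seq)
        raw = [n - 1 - i for i in oligo.discriminating]
    else:
        seq = oligo.sequence
        raw = list(oligo.discriminating)
    disc = set()
    for j in raw:
        if seq[j] == "G" and j >= 1 and seq[j - 1] == "C":
            disc.add(j - 1)
        else:
            disc.add(j)
    return seq, sorted(disc)


def _hit_at(oligo: Oligo, template: BisulfiteTemplate, pos: int) -> OligoHit:
    scan, disc = scan_sequence(oligo)
    window = template.converted[pos : pos + len(scan)]
    mism = sum(1 for a, b in zip(scan, window) if a != b)
    mism_cpg = sum(1 for i in disc if scan[i] != window[i])
    return OligoHit(
        oligo=oligo,
        template=template,
        position=pos,
        orientation="reverse-complement" if oligo.scans_revcomp else "as-is",
        mismatches=mism,
        mismatch_at_cpg=mism_cpg,
    )


def locate_oligo(
    oligo: Oligo, template: BisulfiteTemplate, max_mismatches: int = 0
) -> list[OligoHit]:
    """All gap-free placements of the oligo with at most ``max_mismatches``.

    Hits are sorted by position.  An oligo longer than the template yields
    an empty result with a warning.
    """
    scan, _ = scan_sequence(oligo)
    if len(scan) > len(template):
        warnings.warn(
            f"oligo {oligo.name!r} ({len(scan)} nt) is longer than template "
            f"{template.record_name!r} ({len(template)} nt)",
            DesignWarning,
            stacklevel=2,
        )
        return []
    hits = []
    for pos in range(len(template) - len(scan) + 1):
        hit = _hit_at(oligo, template, pos)
        if hit.mismatches <= max_mismatches:
            hits.append(hit)
    return hits


def best_hit(oligo: Oligo, template: BisulfiteTemplate) -> OligoHit | None:
    """The minimum-mismatch placement (lowest position on ties)."""
    scan, _ = scan_sequence(oligo)
    if len(scan) > len(template):
        return None
    best: OligoHit | None = None
    for pos in range(len(template) - len(scan) + 1):
        hit = _hit_at(oligo, template, pos)
        if best is None or hit.mismatches < best.mismatches:
            best = hit
    return best


# ---------------------------------------------------------------------------
# TSS coordinate arithmetic


def offset_to_tss(offset: int, tss_offset: int) -> int:
    """0-based region offset -> TSS-relative coordinate (skipping 0)."""
    d = offset - tss_offset
    return d + 1 if d >= 0 else d


def tss_to_offset(coord: int, tss_offset: int) -> int:
    """TSS-relative coordinate -> 0-based region offset."""
    if coord == 0:
        raise ValueError("TSS numbering has no position 0")
    return tss_offset + (coord - 1 if coord > 0 else coord)


def _axis(coord: int) -> int:
    """Collapse TSS coordinates onto a contiguous integer axis (drop the 0 gap)."""
    if coord == 0:
        raise ValueError("TSS numbering has no position 0")
    return coord - 1 if coord > 0 else coord


@dataclass(frozen=True)
class AmpliconInterval:
    """A closed interval in TSS-relative coordinates on one strand."""

    start_tss: int
    end_tss: int
    strand: Strand

    def __post_init__(self) -> None:
        if self.start_tss == 0 or self.end_tss == 0:
            raise ValueError("TSS numbering has no position 0")
        if self.start_tss > self.end_tss:
            raise ValueError(
                f"interval start {self.start_tss:+d} after end {self.end_tss:+d}"
            )


def interval_length(iv: AmpliconInterval) -> int:
    """Inclusive length in bp; spans crossing the TSS skip the absent 0."""
    return _axis(iv.end_tss) - _axis(iv.start_tss) + 1


def interval_overlap(a: AmpliconInterval, b: AmpliconInterval) -> int:
    """Number of genomic positions shared by two intervals (strand-agnostic)."""
    lo = max(_axis(a.start_tss), _axis(b.start_tss))
    hi = min(_axis(a.end_tss), _axis(b.end_tss))
    return max(0, hi - lo + 1)


def amplicon_of(assay: Assay, template: BisulfiteTemplate) -> AmpliconInterval:
    """Amplicon interval of an assay on a template, in TSS coordinates.

    Both primers must have exactly one exact (0-mismatch) hit and point
    toward each other.  The interval runs from one primer's 5' base to
    the other primer's 5' base inclusive — the standard qPCR amplicon
    convention.  A probe not strictly inside the primer footprints raises
    a warning.
    """
    up, down = _oriented_primers(assay)
    up_hits = locate_oligo(up, template, max_mismatches=0)
    down_hits = locate_oligo(down, template, max_mismatches=0)
    if len(up_hits) != 1 or len(down_hits) != 1:
        raise DesignError(
            f"assay {assay.name!r} on {template.record_name!r}: need exactly one "
            f"exact hit per primer, got {up.name}={len(up_hits)}, "
            f"{down.name}={len(down_hits)}"
        )
    t5_up = up_hits[0].position  # 5' base of the as-is primer
    t5_down = down_hits[0].position + len(down) - 1  # 5' base of the rc primer
    if not (
        t5_up < down_hits[0].position and t5_up + len(up) - 1 < t5_down
    ):
        raise DesignError(
            f"assay {assay.name!r} on {template.record_name!r}: primers are "
            "inverted or overlapping (do not point toward each other)"
        )
    p_hits = locate_oligo(assay.probe, template, max_mismatches=0)
    probe_scan, _ = scan_sequence(assay.probe)
    inner_lo = t5_up + len(up)
    inner_hi = down_hits[0].position - 1
    if not any(
        h.position >= inner_lo and h.position + len(probe_scan) - 1 <= inner_hi
        for h in p_hits
    ):
        warnings.warn(
            f"assay {assay.name!r}: probe does not lie strictly between the "
            "primers on this template",
            DesignWarning,
            stacklevel=2,
        )
    g1 = template.genomic_offset(t5_up)
    g2 = template.genomic_offset(t5_down)
    lo, hi = sorted((g1, g2))
    tss = template.source.tss_offset
    return AmpliconInterval(
        start_tss=offset_to_tss(lo, tss),
        end_tss=offset_to_tss(hi, tss),
        strand=template.strand,
    )


# ---------------------------------------------------------------------------
# Specificity reporting


@dataclass
class SpecificityEntry:
    strand: Strand
    assumption: str
    oligo_name: str
    position: int | None
    mismatches: int | None
    mismatch_at_cpg: int | None


@dataclass
class SpecificityReport:
    """Best hit of every oligo on all four templates, plus a verdict.

    Verdicts:

    ``methylation-specific``
        every oligo matches the methylated target-strand template exactly
        and every discriminating base mismatches on the unmethylated one;
    ``methylation-neutral``
        no discriminating bases and identical placement on methylated and
        unmethylated templates (the behaviour expected of a reference
        assay);
    ``not-specific``
        anything else.
    """

    assay: Assay
    entries: list[SpecificityEntry] = field(default_factory=list)
    verdict: str = "not-specific"
    warnings: list[str] = field(default_factory=list)


def specificity_report(assay: Assay, templates: TemplateSet) -> SpecificityReport:
    report = SpecificityReport(assay=assay)
    for (strand, assumption), template in sorted(templates.items()):
        for oligo in assay.oligos:
            hit = best_hit(oligo, template)
            report.entries.append(
                SpecificityEntry(
                    strand=strand,
                    assumption=assumption,
                    oligo_name=oligo.name,
                    position=None if hit is None else hit.position,
                    mismatches=None if hit is None else hit.mismatches,
                    mismatch_at_cpg=None if hit is None else hit.mismatch_at_cpg,
                )
            )

    m_tmpl = templates[(assay.target_strand, "methylated")]
    u_tmpl = templates[(assay.target_strand, "unmethylated")]
    total_disc = sum(oligo_cpg_count(o) for o in assay.oligos)

    if total_disc == 0:
        if not assay.reference:
            report.warnings.append("no methylation discrimination")
        neutral = all(
            (bm := best_hit(o, m_tmpl)) is not None
            and (bu := best_hit(o, u_tmpl)) is not None
            and (bm.position, bm.mismatches) == (bu.position, bu.mismatches)
            for o in assay.oligos
        )
        report.verdict = "methylation-neutral" if neutral else "not-specific"
        return report

    specific = True
    for oligo in assay.oligos:
        exact = locate_oligo(oligo, m_tmpl, max_mismatches=0)
        if not exact:
            specific = False
            break
        # at the methylated hit position every CpG-derived base must fail
        # on the unmethylated template
        need = oligo_cpg_count(oligo)
        if not all(
            _hit_at(oligo, u_tmpl, h.position).mismatch_at_cpg == need for h in exact
        ):
            specific = False
            break
    report.verdict = "methylation-specific" if specific else "not-specific"
    return report
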