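"""Scoring of bisulfite clone sequences against their unconverted reference.

Each sequenced clone of a bisulfite-PCR amplicon carries two signals:

* at reference CpG cytosines, a retained C indicates the site was
  methylated (protected from conversion) while a T indicates it was not —
  the methylation signal;
* at reference non-CpG cytosines, a T indicates successful chemical
  conversion while a retained C indicates incomplete bisulfite treatment —
  the conversion-efficiency QC signal.

Comparison is positional (gap-free): clones are fixed-length amplicon
inserts and anything with an indel is rejected rather than mis-scored.
Aggregate percentages are computed from pooled counts across clones, not
as a mean of per-clone percentages, and rounded half-up to one decimal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .bisulfite_core import check_dna
from .errors import CloneScoringError

MethylationCall = str  # "fully-methylated" | "partially-methylated" | "unmethylated"


def classify_cytosines(reference: str) -> tuple[list[int], list[int]]:
    """Partition every C position of the unconverted reference into
    (CpG positions, non-CpG positions).

    A terminal C has no 3' neighbour and is classed non-CpG.
    """
    ref = check_dna(reference, context="reference")
    cpg, noncpg = [], []
    for i, ch in enumerate(ref):
        if ch != "C":
            continue
        if i + 1 < len(ref) and ref[i + 1] == "G":
            cpg.append(i)
        else:
            noncpg.append(i)
    return cpg, noncpg


@dataclass(frozen=True)
class CloneScore:
    """Per-clone retention/conversion counts.

    ``other_at_cpg``/``other_at_noncpg`` count bases other than C or T
    observed at reference cytosine positions (cloning or sequencing
    artefacts); they enter neither numerator and are reported separately.
    """

    clone_id: str
    cpg_retained: int
    cpg_total: int
    noncpg_converted: int
    noncpg_total: int
    other_at_cpg: int = 0
    other_at_noncpg: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.cpg_retained <= self.cpg_total:
            raise CloneScoringError("cpg_retained outside [0, cpg_total]")
        if not 0 <= self.noncpg_converted <= self.noncpg_total:
            raise CloneScoringError("noncpg_converted outside [0, noncpg_total]")

    @property
    def other_mismatches(self) -> int:
        return self.other_at_cpg + self.other_at_noncpg


def score_clone(clone: str, reference: str, clone_id: str = "clone") -> CloneScore:
    """Score one clone against the unconverted reference strand.

    At a CpG cytosine a clone C counts as retained and a T as converted;
    at a non-CpG cytosine a T counts as converted and a C as a conversion
    failure.  Any other base at a cytosine position is tallied as an
    ``other`` mismatch.
    """
    c = check_dna(clone, context=f"clone {clone_id!r}")
    ref = check_dna(reference, context="reference")
    if len(c) != len(ref):
        raise CloneScoringError(
            f"clone {clone_id!r} length {len(c)} != reference length {len(ref)}; "
            "positional scoring requires equal lengths (indels unsupported)"
        )
    cpg, noncpg = classify_cytosines(ref)
    retained = sum(1 for i in cpg if c[i] == "C")
    other_cpg = sum(1 for i in cpg if c[i] not in "CT")
    converted = sum(1 for i in noncpg if c[i] == "T")
    other_noncpg = sum(1 for i in noncpg if c[i] not in "CT")
    return CloneScore(
        clone_id=clone_id,
        cpg_retained=retained,
        cpg_total=len(cpg),
        noncpg_converted=converted,
        noncpg_total=len(noncpg),
        other_at_cpg=other_cpg,
        other_at_noncpg=other_noncpg,
    )


def percent(numerator: int, denominator: int) -> float | None:
    """Pooled percentage to one decimal, round-half-up; None if undefined."""
    if denominator == 0:
        return None
    q = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    return float(q)


@dataclass
class SampleCloneReport:
    """Pooled clone scores for one sample."""

    sample_id: str
    n_clones: int
    cpg_retention_pct: float | None
    noncpg_conversion_pct: float | None
    per_clone: list[CloneScore]
    methylation_call: MethylationCall | None = None
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "n_clones": self.n_clones,
            "cpg_retained": sum(s.cpg_retained for s in self.per_clone),
            "cpg_total": sum(s.cpg_total for s in self.per_clone),
            "cpg_retention_pct": self.cpg_retention_pct,
            "noncpg_converted": sum(s.noncpg_converted for s in self.per_clone),
            "noncpg_total": sum(s.noncpg_total for s in self.per_clone),
            "noncpg_conversion_pct": self.noncpg_conversion_pct,
            "methylation_call": self.methylation_call,
            "flags": self.flags,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def aggregate_clones(scores: list[CloneScore], sample_id: str) -> SampleCloneReport:
    """Pool numerators and denominators across clones for one sample."""
    if not scores:
        raise CloneScoringError(f"sample {sample_id!r}: no clones to aggregate")
    cpg_num = sum(s.cpg_retained for s in scores)
    cpg_den = sum(s.cpg_total for s in scores)
    nc_num = sum(s.noncpg_converted for s in scores)
    nc_den = sum(s.noncpg_total for s in scores)
    return SampleCloneReport(
        sample_id=sample_id,
        n_clones=len(scores),
        cpg_retention_pct=percent(cpg_num, cpg_den),
        noncpg_conversion_pct=percent(nc_num, nc_den),
        per_clone=list(scores),
    )


def call_sample(
    report: SampleCloneReport,
    high_threshold: float = 90.0,
    low_threshold: float = 10.0,
    conversion_qc_floor: float = 70.0,
) -> MethylationCall:
    """Classify the sample's methylation state from pooled CpG retention.

    Retention >= ``high_threshold`` % calls fully-methylated, <=
    ``low_threshold`` % calls unmethylated, anything between is
    partially-methylated.  Samples whose pooled non-CpG conversion falls
    below ``conversion_qc_floor`` % are flagged (incomplete bisulfite
    treatment inflates apparent retention) but still called: published
    clone sets with conversion in the high 70s remain interpretable when
    CpG retention is near-total.
    """
    if report.cpg_retention_pct is None:
        report.flags.append("no CpG sites in reference; methylation call impossible")
        report.methylation_call = None
        return "uncallable"
    if (
        report.noncpg_conversion_pct is not None
        and report.noncpg_conversion_pct < conversion_qc_floor
    ):
        report.flags.append(
            f"non-CpG conversion {report.noncpg_conversion_pct}% below QC floor "
            f"{conversion_qc_floor}%"
        )
    if report.cpg_retention_pct >= high_threshold:
        call = "fully-methylated"
    elif report.cpg_retention_pct <= low_threshold:
        call = "unmethylated"
    else:
        call = "partially-methylated"
    report.methylation_call = call
    return call


def methylation_matrix(clones: list[tuple[str, str]], reference: str) -> str:
    """Plain-text lollipop-style matrix: one row per clone, one column per
    CpG site; '#' = retained (methylated), '.' = converted, '?' = other."""
    cpg, _ = classify_cytosines(reference)
    width = max((len(cid) for cid, _ in clones), default=0)
    lines = []
    for cid, seq in clones:
        if len(seq) != len(reference):
            raise CloneScoringError(f"clone {cid!r} length mismatch")
        row = "".join(
            "#" if seq[i] == "C" else "." if seq[i] == "T" else "?" for i in cpg
        )
        lines.append(f"{cid:<{width}} {row}")
    return "\n".join(lines)
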