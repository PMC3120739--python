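"""Seeded generators for CpG islands, bisulfite clone sets and qPCR Ct tables.

Everything here is synthetic: the generators emulate the *statistical
structure* of methylation-assay data (CpG-dense regions, per-site
Bernoulli retention/conversion in clones, duplicate-well Ct measurements
separated by a methylation-dependent dCt shift) so every other module can
be exercised without any external download.  One integer seed drives all
randomness through independent spawned streams per artifact, so regions,
clones and Ct tables can be regenerated independently yet reproducibly;
identical spec + seed gives byte-identical files.

The region builder works backwards from published oligo sequences: given
an assay and a placement, it solves for an unconverted double-stranded
region whose methylated bisulfite template contains each oligo's scan
sequence exactly.  This is the standard way to obtain a concrete test
region when a CpG island's sequence is published only as a figure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .assay_design import (
    Assay,
    builtin_assays,
    scan_sequence,
    tss_to_offset,
)
from .bisulfite_core import GenomicRegion, convert, four_templates, reverse_complement
from .clone_qc import classify_cytosines
from .errors import FixtureError

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic study.

    Defaults mirror the published study layout: 44 gold-standard-positive
    and 58 negative samples, duplicate qPCR wells, a 45-cycle ceiling,
    and clone sets of 16 clones.  ``delta_ct_positive`` (0.4 cycles,
    standardized RCN near 0.76) and ``delta_ct_shift`` (5.2 further
    cycles for negatives, RCN near 0.02) reproduce the order of magnitude
    of the reported positive/negative RCN medians.
    """

    seed: int
    island_length: int = 500
    cpg_density: float = 0.10
    island_tss_offset: int = 0
    n_clones: int = 16
    retention_prob: float = 0.95
    conversion_efficiency: float = 0.95
    n_pos: int = 44
    n_neg: int = 58
    delta_ct_positive: float = 0.4
    delta_ct_shift: float = 5.2
    ct_noise_sd: float = 0.5
    ct_reference_mean: float = 28.0
    max_cycles: float = 45.0
    negatives_not_detected: bool = False
    target_name: str = "methylated-p16"
    reference_name: str = "COL2A1"
    positive_id: str = "RKO"
    negative_id: str = "MGC803"

    def __post_init__(self) -> None:
        for name in ("cpg_density", "retention_prob", "conversion_efficiency"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise FixtureError(f"{name} {v} outside [0, 1]")
        if self.ct_noise_sd < 0:
            raise FixtureError("ct_noise_sd must be non-negative")


_STREAMS = {"island": 0, "clones": 1, "ct": 2, "region": 3}


def _rng(seed: int, artifact: str) -> np.random.Generator:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS[artifact]])


# ---------------------------------------------------------------------------
# Islands


def simulate_island(spec: FixtureSpec) -> GenomicRegion:
    """A random region with approximately the requested CpG density.

    ``cpg_density`` is the expected fraction of dinucleotide positions
    that are CpG; all CpGs are planted deliberately, single-base fills
    never create one.  Densities >= 0.5 are geometrically infeasible
    (CpGs cannot tile more densely than every other position).
    """
    d = spec.cpg_density
    if d >= 0.5:
        raise FixtureError(f"cpg_density {d} infeasible (must be < 0.5)")
    rng = _rng(spec.seed, "island")
    q = d / (1.0 - d)  # per-step probability of emitting a CG token
    out: list[str] = []
    L = spec.island_length
    while len(out) < L:
        if len(out) < L - 1 and rng.random() < q:
            out.append("C")
            out.append("G")
        else:
            choices = "ACT" if out and out[-1] == "C" else "ACGT"
            out.append(choices[rng.integers(len(choices))])
    return GenomicRegion(
        name=f"island-s{spec.seed}",
        sequence="".join(out),
        tss_offset=spec.island_tss_offset,
    )


def island_with_c_counts(
    n_cpg: int = 14,
    n_noncpg_c: int = 44,
    seed: int = 0,
    name: str = "clone-reference",
    tss_offset: int = 0,
) -> GenomicRegion:
    """A reference region with an exact cytosine census.

    Built from shuffled CG / CA / CT tokens so it contains exactly
    ``n_cpg`` CpG cytosines and ``n_noncpg_c`` non-CpG cytosines — the
    layout of a clone-sequenced amplicon with a known site count.
    """
    rng = np.random.default_rng(seed)
    tokens = ["CG"] * n_cpg + [
        "CA" if rng.random() < 0.5 else "CT" for _ in range(n_noncpg_c)
    ]
    rng.shuffle(tokens)
    seq = "".join(tokens)
    return GenomicRegion(name=name, sequence=seq, tss_offset=tss_offset)


# ---------------------------------------------------------------------------
# Regions embedding published assays


@dataclass(frozen=True)
class AssayPlacement:
    """Where an assay's amplicon sits on the region being built.

    ``amplicon_start_tss`` is the TSS coordinate of the genomically
    leftmost amplicon base; ``amplicon_length`` is the genomic span in bp.
    """

    assay: Assay
    amplicon_start_tss: int
    amplicon_length: int
    probe_gap: int | None = None  # bases between upstream primer and probe


def build_assay_region(
    placements: list[AssayPlacement],
    length: int,
    tss_offset: int,
    seed: int = 0,
    name: str = "synthetic-region",
) -> GenomicRegion:
    """Solve for an unconverted region realizing the given assay placements.

    Each oligo's scan sequence pins down the methylated bisulfite
    template over its footprint; those template characters are propagated
    back through the conversion rules to per-position allowed base sets
    on the double-stranded region (a template T is ambiguous — original T
    or converted non-CpG C — and is resolved to T inside assay windows).
    Unconstrained positions are filled randomly.  The result is verified
    by re-converting and matching every scan before it is returned.
    """
    allowed: list[set[str]] = [set("ACGT") for _ in range(length)]

    def constrain(strand: str, t: int, bases: set[str]) -> None:
        if strand == "sense":
            pos, mapped = t, bases
        else:
            pos, mapped = length - 1 - t, {_COMP[b] for b in bases}
        if not 0 <= pos < length:
            raise FixtureError(f"constraint at position {pos} outside region")
        s = allowed[pos] & mapped
        if not s:
            raise FixtureError(
                f"conflicting placements: no base allowed at region position {pos}"
            )
        allowed[pos] = s

    embeddings: list[tuple[str, int, str]] = []  # (strand, template pos, scan)
    for pl in placements:
        assay = pl.assay
        strand = assay.target_strand
        g_lo = tss_to_offset(pl.amplicon_start_tss, tss_offset)
        g_hi = g_lo + pl.amplicon_length - 1
        if not (0 <= g_lo and g_hi < length):
            raise FixtureError(
                f"assay {assay.name!r} amplicon [{g_lo}, {g_hi}] outside region "
                f"of length {length}"
            )
        t_lo, t_hi = (
            (g_lo, g_hi) if strand == "sense" else (length - 1 - g_hi, length - 1 - g_lo)
        )
        up_scan, _ = scan_sequence(assay.upstream_primer)
        down_scan, _ = scan_sequence(assay.downstream_primer)
        probe_scan, _ = scan_sequence(assay.probe)
        inner = pl.amplicon_length - len(up_scan) - len(down_scan)
        if inner < len(probe_scan):
            raise FixtureError(
                f"assay {assay.name!r}: amplicon of {pl.amplicon_length} bp cannot "
                "hold both primers and the probe"
            )
        gap = (inner - len(probe_scan)) // 2 if pl.probe_gap is None else pl.probe_gap
        layout = [
            (t_lo, up_scan),
            (t_lo + len(up_scan) + gap, probe_scan),
            (t_hi - len(down_scan) + 1, down_scan),
        ]
        for start, scan in layout:
            embeddings.append((strand, start, scan))
            for k, ch in enumerate(scan):
                t = start + k
                if ch in "AG":
                    constrain(strand, t, {ch})
                elif ch == "C":
                    constrain(strand, t, {"C"})
                    constrain(strand, t + 1, {"G"})  # retained C must be CpG
                else:  # T: original T, or a non-CpG C that converted
                    constrain(strand, t, {"T", "C"})

    rng = np.random.default_rng(seed)
    bases = []
    for s in allowed:
        if len(s) == 4:
            bases.append("ACGT"[rng.integers(4)])
        elif len(s) == 1:
            bases.append(next(iter(s)))
        elif "T" in s:
            bases.append("T")  # resolve template-T ambiguity conservatively
        elif "A" in s:
            bases.append("A")
        else:
            bases.append(sorted(s)[0])
    region = GenomicRegion(name=name, sequence="".join(bases), tss_offset=tss_offset)

    strands = {
        "sense": region.sequence,
        "antisense": reverse_complement(region.sequence),
    }
    for strand, start, scan in embeddings:
        template = convert(strands[strand], "methylated")
        if template[start : start + len(scan)] != scan:
            raise FixtureError(
                "region construction failed verification: an oligo scan does "
                "not match the methylated template (overlapping placements?)"
            )
    return region


def demo_region(seed: int = 0) -> GenomicRegion:
    """A p16-exon-1-like synthetic region carrying both methylated-p16 assays.

    The 115-bp-named sense-strand assay is placed at its published
    coordinates (+157 ~ +272); the 70-bp antisense assay is placed
    downstream at +301 ~ +370 so the two constraint sets cannot collide
    (on the true genomic sequence they overlap, but a synthetic region
    cannot satisfy both oligo sets over shared bases).
    """
    by_name = {a.name: a for a in builtin_assays()}
    placements = [
        AssayPlacement(by_name["p16-ML-115bp"], amplicon_start_tss=157, amplicon_length=116),
        AssayPlacement(by_name["p16-ML-70bp"], amplicon_start_tss=301, amplicon_length=70),
    ]
    return build_assay_region(
        placements, length=480, tss_offset=60, seed=seed, name="p16-synthetic"
    )


def reference_region(seed: int = 0) -> GenomicRegion:
    """A CpG-free COL2A1-like synthetic region carrying the reference assay."""
    by_name = {a.name: a for a in builtin_assays()}
    placements = [
        AssayPlacement(by_name["COL2A1-reference"], amplicon_start_tss=31, amplicon_length=100)
    ]
    return build_assay_region(
        placements, length=200, tss_offset=0, seed=seed, name="COL2A1-synthetic"
    )


# ---------------------------------------------------------------------------
# Clones


def simulate_clones(
    region: GenomicRegion, spec: FixtureSpec
) -> list[tuple[str, str]]:
    """Bisulfite clones of the region's sense strand.

    Each CpG cytosine independently retains C with probability
    ``retention_prob`` (i.e. was methylated and protected); each non-CpG
    cytosine converts to T with probability ``conversion_efficiency``.
    All other bases are copied unchanged.
    """
    rng = _rng(spec.seed, "clones")
    cpg, noncpg = classify_cytosines(region.sequence)
    clones = []
    for i in range(spec.n_clones):
        seq = list(region.sequence)
        for p in cpg:
            if rng.random() >= spec.retention_prob:
                seq[p] = "T"
        for p in noncpg:
            if rng.random() < spec.conversion_efficiency:
                seq[p] = "T"
        clones.append((f"{region.name}-clone{i + 1:03d}", "".join(seq)))
    return clones


def clone_set_with_pooled_counts(
    region: GenomicRegion,
    n_clones: int,
    cpg_retained: int,
    noncpg_converted: int,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Clones whose pooled counts are exact, events placed at random sites.

    Starts every clone fully methylated and fully converted, then flips
    exactly ``total_cpg - cpg_retained`` CpG sites to converted and
    ``total_noncpg - noncpg_converted`` non-CpG sites back to unconverted
    C, distributed uniformly over (clone, site) pairs.
    """
    rng = np.random.default_rng(seed)
    cpg, noncpg = classify_cytosines(region.sequence)
    total_cpg = n_clones * len(cpg)
    total_noncpg = n_clones * len(noncpg)
    if not 0 <= cpg_retained <= total_cpg:
        raise FixtureError(f"cpg_retained {cpg_retained} outside [0, {total_cpg}]")
    if not 0 <= noncpg_converted <= total_noncpg:
        raise FixtureError(
            f"noncpg_converted {noncpg_converted} outside [0, {total_noncpg}]"
        )
    base = convert(region.sequence, "methylated")
    clones = [list(base) for _ in range(n_clones)]
    for idx in rng.choice(total_cpg, size=total_cpg - cpg_retained, replace=False):
        clones[idx // len(cpg)][cpg[idx % len(cpg)]] = "T"
    for idx in rng.choice(
        total_noncpg, size=total_noncpg - noncpg_converted, replace=False
    ):
        clones[idx // len(noncpg)][noncpg[idx % len(noncpg)]] = "C"
    return [
        (f"{region.name}-clone{i + 1:03d}", "".join(c)) for i, c in enumerate(clones)
    ]


def write_clones_fasta(clones: list[tuple[str, str]], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=cid, description="") for cid, seq in clones],
        str(path),
        "fasta",
    )


def read_clones_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


# ---------------------------------------------------------------------------
# Ct tables


def simulate_ct_table(spec: FixtureSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Duplicate-well Ct table plus gold-standard labels.

    Reference Ct is ``ct_reference_mean`` plus a per-sample DNA-amount
    offset and per-well noise.  The methylation target trails the
    reference by ``delta_ct_positive`` cycles in positive samples and by
    ``delta_ct_positive + delta_ct_shift`` in negatives (or is emitted
    not-detected when ``negatives_not_detected``).  The positive control
    runs at dCt 0 (fully methylated) and the negative control never
    amplifies the target.  Simulated Ct values beyond ``max_cycles``
    become not-detected.  Returns (wells, labels) data frames.
    """
    rng = _rng(spec.seed, "ct")
    rows = []
    labels = []

    def emit(sample: str, delta: float | None, ref_base: float) -> None:
        for rep in (1, 2):
            rows.append(
                {
                    "sample_id": sample,
                    "target": spec.reference_name,
                    "replicate": rep,
                    "ct": ref_base + rng.normal(0.0, spec.ct_noise_sd),
                }
            )
        for rep in (1, 2):
            if delta is None:
                ct = math.nan
            else:
                ct = ref_base + delta + rng.normal(0.0, spec.ct_noise_sd)
                if ct > spec.max_cycles:
                    ct = math.nan
            rows.append(
                {
                    "sample_id": sample,
                    "target": spec.target_name,
                    "replicate": rep,
                    "ct": ct,
                }
            )

    emit(spec.positive_id, 0.0, spec.ct_reference_mean + rng.normal(0.0, 1.0))
    emit(spec.negative_id, None, spec.ct_reference_mean + rng.normal(0.0, 1.0))
    for i in range(spec.n_pos):
        sample = f"pos{i + 1:03d}"
        emit(sample, spec.delta_ct_positive, spec.ct_reference_mean + rng.normal(0.0, 1.0))
        labels.append({"sample_id": sample, "label": "positive"})
    for i in range(spec.n_neg):
        sample = f"neg{i + 1:03d}"
        delta = (
            None
            if spec.negatives_not_detected
            else spec.delta_ct_positive + spec.delta_ct_shift
        )
        emit(sample, delta, spec.ct_reference_mean + rng.normal(0.0, 1.0))
        labels.append({"sample_id": sample, "label": "negative"})
    return pd.DataFrame(rows), pd.DataFrame(labels)


def write_ct_table(wells: pd.DataFrame, path) -> None:
    """Write a Ct table as TSV with not-detected wells encoded as ND."""
    out = wells.copy()
    out["ct"] = out["ct"].map(lambda v: "ND" if pd.isna(v) else f"{v:.3f}")
    out.to_csv(path, sep="\t", index=False)


def write_labels(labels: pd.DataFrame, path) -> None:
    labels.to_csv(path, sep="\t", index=False)
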