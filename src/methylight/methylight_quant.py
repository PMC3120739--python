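"""Relative copy number (RCN) quantification from MethyLight Ct tables.

The methylated target is quantified against a methylation-neutral
reference gene (COL2A1-style) by the comparative-Ct model

    RCN = 2^-dCt,   dCt = Ct(target) - Ct(reference)

with replicate wells collapsed by averaging Ct values (not RCNs — the two
differ, and the Ct average is the published convention).  Per-sample RCNs
are standardized to the fully methylated positive-control sample run in
the same batch, so the positive control reads exactly 1.0.

Not-detected wells are encoded explicitly (never as Ct = max cycles).  A
sample whose methylation target never amplifies gets RCN 0 with a flag; a
sample whose *reference* never amplifies is unquantifiable and is flagged
invalid.  A batch is rejected outright when its negative control amplifies
the methylation target well before the cycle ceiling (contamination) or
its positive control does not amplify at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ControlFailureError, QuantificationError

ND_TOKENS = {"ND", "N.D.", "NA", "NAN", "UNDETERMINED", ""}


@dataclass(frozen=True)
class WellRecord:
    """One qPCR well: a (sample, target, replicate) Ct measurement.

    ``ct`` is None for a not-detected well.
    """

    sample_id: str
    target: str
    replicate: int
    ct: float | None


@dataclass
class RCNResult:
    """Per-sample quantification outcome."""

    sample_id: str
    ct_target: float | None
    ct_reference: float | None
    rcn_raw: float | None
    rcn_standardized: float | None
    flags: list[str] = field(default_factory=list)


def read_ct_table(path, sep: str = "\t") -> pd.DataFrame:
    """Read a delimited Ct table with columns sample_id, target, replicate, ct.

    The ct column accepts "ND" (case-insensitive) for not-detected wells,
    which become NaN in the returned frame.
    """
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "target": str})
    missing = {"sample_id", "target", "replicate", "ct"} - set(df.columns)
    if missing:
        raise QuantificationError(f"Ct table missing columns: {sorted(missing)}")
    ct = df["ct"].astype(str).str.strip().str.upper()
    df["ct"] = pd.to_numeric(ct.mask(ct.isin(ND_TOKENS)), errors="raise")
    return df


def wells_to_frame(wells: list[WellRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [w.sample_id for w in wells],
            "target": [w.target for w in wells],
            "replicate": [w.replicate for w in wells],
            "ct": [np.nan if w.ct is None else w.ct for w in wells],
        }
    )


def collapse_replicates(
    table: pd.DataFrame,
    max_cycles: float = 45.0,
    replicate_spread_warn: float = 1.5,
) -> pd.DataFrame:
    """Average detected Ct values per (sample, target).

    Returns one row per (sample_id, target) with columns ``ct`` (NaN when
    every replicate was not-detected), ``n_detected``, ``n_wells`` and
    ``flags``.  Detected Ct values must lie in (0, max_cycles].  Wells
    disagreeing by more than ``replicate_spread_warn`` cycles are flagged,
    not rejected.
    """
    bad = table["ct"].dropna()
    offenders = bad[(bad <= 0) | (bad > max_cycles)]
    if len(offenders):
        raise QuantificationError(
            f"Ct values outside (0, {max_cycles}]: {offenders.tolist()[:5]}"
        )
    rows = []
    for (sample, target), grp in table.groupby(["sample_id", "target"], sort=True):
        detected = grp["ct"].dropna()
        flags = []
        if len(detected) == 0:
            ct = math.nan
            flags.append("all replicates not-detected")
        else:
            ct = float(detected.mean())
            if len(detected) >= 2 and detected.max() - detected.min() > replicate_spread_warn:
                flags.append(
                    f"replicate spread {detected.max() - detected.min():.2f} cycles "
                    f"exceeds {replicate_spread_warn}"
                )
        rows.append(
            {
                "sample_id": sample,
                "target": target,
                "ct": ct,
                "n_detected": int(len(detected)),
                "n_wells": int(len(grp)),
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(rows)


def relative_copy_number(
    ct_target: float | None,
    ct_reference: float | None,
    efficiency: float = 2.0,
) -> float:
    """RCN = efficiency^-(ct_target - ct_reference); 0 for a not-detected target.

    ``efficiency`` is the per-cycle amplification factor; the pure
    comparative-Ct model uses 2.0 (perfect doubling).
    """
    if ct_reference is None or (isinstance(ct_reference, float) and math.isnan(ct_reference)):
        raise QuantificationError(
            "reference Ct not detected: quantification impossible"
        )
    if ct_target is None or (isinstance(ct_target, float) and math.isnan(ct_target)):
        return 0.0
    return float(efficiency ** -(ct_target - ct_reference))


def standardize(rcn_sample: float, rcn_positive_control: float) -> float:
    """Express an RCN relative to the batch's fully methylated positive control."""
    if rcn_positive_control <= 0:
        raise ControlFailureError(
            f"positive-control RCN {rcn_positive_control} is not positive"
        )
    return rcn_sample / rcn_positive_control


def _infer_targets(
    table: pd.DataFrame, target: str | None, reference: str | None
) -> tuple[str, str]:
    names = sorted(table["target"].unique())
    if target is not None and reference is not None:
        return target, reference
    if len(names) != 2:
        raise QuantificationError(
            f"cannot infer target/reference from targets {names}; pass them explicitly"
        )
    refs = [n for n in names if "COL2A1" in n.upper() or "REF" in n.upper()]
    if reference is None and len(refs) == 1:
        reference = refs[0]
    if reference is None:
        raise QuantificationError(
            f"cannot identify the reference assay among {names}; pass it explicitly"
        )
    if target is None:
        target = next(n for n in names if n != reference)
    return target, reference


def quantify_batch(
    table: pd.DataFrame,
    positive_id: str = "RKO",
    negative_id: str = "MGC803",
    target: str | None = None,
    reference: str | None = None,
    max_cycles: float = 45.0,
    negative_margin: float = 5.0,
    efficiency: float = 2.0,
    replicate_spread_warn: float = 1.5,
) -> list[RCNResult]:
    """Quantify every sample in a Ct table against the batch controls.

    The batch is validated before any sample is quantified: the negative
    control must not amplify the methylation target more than
    ``negative_margin`` cycles below ``max_cycles`` (an early negative-
    control signal is a contamination signature and voids the run), and
    the positive control must amplify.  Each sample's raw RCN is then
    standardized to the positive control's raw RCN.
    """
    collapsed = collapse_replicates(
        table, max_cycles=max_cycles, replicate_spread_warn=replicate_spread_warn
    )
    target, reference = _infer_targets(table, target, reference)
    ct = {
        (r.sample_id, r.target): (None if math.isnan(r.ct) else r.ct, r.flags)
        for r in collapsed.itertuples()
    }
    samples = sorted(collapsed["sample_id"].unique())
    for ctrl in (positive_id, negative_id):
        if ctrl not in samples:
            raise ControlFailureError(f"control sample {ctrl!r} missing from batch")

    neg_ct, _ = ct.get((negative_id, target), (None, ""))
    if neg_ct is not None and neg_ct < max_cycles - negative_margin:
        raise ControlFailureError(
            f"negative control {negative_id!r} amplified the methylation target at "
            f"Ct {neg_ct:.2f} (< {max_cycles - negative_margin:.1f}): run rejected "
            "as contaminated"
        )
    pos_ct, _ = ct.get((positive_id, target), (None, ""))
    if pos_ct is None:
        raise ControlFailureError(
            f"positive control {positive_id!r} did not amplify the methylation "
            "target: run rejected"
        )
    pos_ref, _ = ct.get((positive_id, reference), (None, ""))
    if pos_ref is None:
        raise ControlFailureError(
            f"positive control {positive_id!r} has no detected reference Ct"
        )
    rcn_pos = relative_copy_number(pos_ct, pos_ref, efficiency)

    results = []
    for sample in samples:
        flags: list[str] = []
        if (sample, reference) not in ct:
            raise QuantificationError(
                f"sample {sample!r} has no reference ({reference!r}) wells"
            )
        t_ct, t_flags = ct.get((sample, target), (None, "missing target wells"))
        r_ct, r_flags = ct[(sample, reference)]
        flags.extend(f for f in (t_flags, r_flags) if f)
        if r_ct is None:
            flags.append("invalid: reference not detected")
            results.append(
                RCNResult(sample, t_ct, None, None, None, flags)
            )
            continue
        if t_ct is None:
            flags.append("methylation target not detected; RCN set to 0")
        raw = relative_copy_number(t_ct, r_ct, efficiency)
        results.append(
            RCNResult(
                sample_id=sample,
                ct_target=t_ct,
                ct_reference=r_ct,
                rcn_raw=raw,
                rcn_standardized=standardize(raw, rcn_pos),
                flags=flags,
            )
        )
    return results


def results_to_frame(results: list[RCNResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "ct_target": [r.ct_target for r in results],
            "ct_reference": [r.ct_reference for r in results],
            "rcn_raw": [r.rcn_raw for r in results],
            "rcn_standardized": [r.rcn_standardized for r in results],
            "flags": [";".join(r.flags) for r in results],
        }
    )
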