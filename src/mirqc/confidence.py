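"""High/low-confidence classification of microRNA hairpin annotations.

A genuine microRNA locus carries a distinctive read signature left by
Drosha and Dicer processing: reads on both arms, a mature:star duplex with
short 3' overhangs (canonically 2 nt), and highly consistent 5' ends.  The
high-confidence call requires all of:

1. mature sequences annotated on both arms;
2. duplex 3' overhangs within [0, 4] nt (at both duplex ends by default);
3. >= 20 assigned reads on each arm;
4. >= 50% of each arm's reads sharing the modal 5' end.

The low-confidence call flags loci that have plenty of data but the wrong
shape: more than 100 total mapped reads while fewer than 30% of the reads
on the more abundant arm share a 5' end (both strict).  A locus can never
be both; high takes precedence.  All thresholds are parameters carried by
:class:`ClassifierParams` so boundary behaviour can be driven through the
public interface.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

from .read_profile import LocusProfile, build_profile
from .records_io import (
    HIGH_CRITERIA,
    LOW_CRITERIA,
    ConfidenceReport,
    HairpinRecord,
    MatureAnnotation,
    ReadStack,
    SecondaryStructure,
)

__all__ = [
    "ClassifierParams",
    "DuplexGeometry",
    "duplex_overhangs",
    "high_confidence_call",
    "low_confidence_call",
    "classify",
    "DEFAULT_PARAMS",
]


@dataclass(frozen=True)
class ClassifierParams:
    """All decision thresholds, at their published defaults."""

    min_reads: int = 20            # per-arm assigned reads, inclusive
    min_modal_fraction: float = 0.5  # per-arm 5' homogeneity, inclusive
    min_overhang: int = 0          # duplex 3' overhang window, inclusive
    max_overhang: int = 4
    low_min_total_reads: int = 100   # low call needs total > this (strict)
    low_max_modal_fraction: float = 0.30  # and dominant-arm fraction < this (strict)
    overhang_mode: Literal["both", "either"] = "both"
    scan_window: int = 5           # nt scanned past a mature 5' end for a paired base
    extension: int = 2             # read-assignment interval extension
    min_overlap_fraction: float = 0.5


DEFAULT_PARAMS = ClassifierParams()


@dataclass(frozen=True)
class DuplexGeometry:
    """Signed 3'-overhang lengths at the two ends of the mature:star duplex.

    The Drosha end is the hairpin-base end (overhang of the 3p mature's 3'
    terminus); the Dicer end is the loop end (overhang of the 5p mature's 3'
    terminus).  Negative values mean a recessed 3' end.  An end is undefined
    when no paired base lies within the scan window of the relevant mature
    5' terminus.
    """

    overhang_drosha_end: int | None
    overhang_dicer_end: int | None

    @property
    def drosha_defined(self) -> bool:
        return self.overhang_drosha_end is not None

    @property
    def dicer_defined(self) -> bool:
        return self.overhang_dicer_end is not None


def _first_paired_at_or_after(
    structure: SecondaryStructure, start: int, scan_window: int
) -> int | None:
    for i in range(start, min(start + scan_window, structure.length)):
        if structure.partner(i) is not None:
            return i
    return None


def duplex_overhangs(
    structure: SecondaryStructure,
    mature_5p: MatureAnnotation,
    mature_3p: MatureAnnotation,
    scan_window: int = 5,
) -> DuplexGeometry:
    """Measure the duplex 3' overhangs implied by the pair table.

    Each mature's 5' end is anchored at its first paired base within
    ``scan_window`` nt; the overhang at the opposite duplex end is how far
    the partner mature's 3' terminus extends past that anchor's pairing
    partner, corrected for the anchor offset.  For a perfect duplex both
    values equal the canonical 2 nt.
    """
    if mature_5p.end > mature_3p.start:
        raise ValueError("5p and 3p matures overlap; not a valid duplex")
    if mature_3p.end > structure.length:
        raise ValueError("mature annotation exceeds structure length")

    drosha: int | None = None
    i = _first_paired_at_or_after(structure, mature_5p.start, scan_window)
    if i is not None:
        j = structure.partner(i)
        assert j is not None
        drosha = (mature_3p.end3 - j) - (i - mature_5p.start)

    dicer: int | None = None
    u = _first_paired_at_or_after(structure, mature_3p.start, scan_window)
    if u is not None:
        v = structure.partner(u)
        assert v is not None
        dicer = (mature_5p.end3 - v) - (u - mature_3p.start)

    return DuplexGeometry(overhang_drosha_end=drosha, overhang_dicer_end=dicer)


def _overhang_criterion(geometry: DuplexGeometry | None, params: ClassifierParams) -> bool:
    """Undefined overhangs fail: high confidence must not rest on unmeasurable geometry."""
    if geometry is None:
        return False

    def end_ok(value: int | None) -> bool:
        return value is not None and params.min_overhang <= value <= params.max_overhang

    checks = [end_ok(geometry.overhang_drosha_end), end_ok(geometry.overhang_dicer_end)]
    return all(checks) if params.overhang_mode == "both" else any(checks)


def high_confidence_call(
    profile: LocusProfile,
    annotations: Sequence[MatureAnnotation],
    geometry: DuplexGeometry | None,
    params: ClassifierParams = DEFAULT_PARAMS,
) -> dict[str, bool]:
    """Evaluate the six high-confidence booleans; missing data fails a criterion."""
    arms = {a.arm for a in annotations}
    criteria = {"both_arms_annotated": arms == {"5p", "3p"}}
    criteria["overhang_ok"] = _overhang_criterion(geometry, params)
    for arm in ("5p", "3p"):
        ap = profile.arm_profiles.get(arm)  # type: ignore[arg-type]
        depth = ap.assigned_reads if ap else 0
        criteria[f"depth_ok_{arm}"] = depth >= params.min_reads
        frac = ap.modal_fraction if ap else None
        criteria[f"homogeneity_ok_{arm}"] = frac is not None and frac >= params.min_modal_fraction
    return criteria


def dominant_arm_fraction(profile: LocusProfile) -> float | None:
    """Modal 5' fraction on the more abundant arm (5p wins an exact tie)."""
    best = None
    for arm in ("5p", "3p"):
        ap = profile.arm_profiles.get(arm)  # type: ignore[arg-type]
        if ap is None or ap.assigned_reads == 0:
            continue
        if best is None or ap.assigned_reads > best.assigned_reads:
            best = ap
    return None if best is None else best.modal_fraction


def low_confidence_call(
    profile: LocusProfile, params: ClassifierParams = DEFAULT_PARAMS
) -> dict[str, bool]:
    """Evaluate the two low-confidence booleans (both strict inequalities)."""
    frac = dominant_arm_fraction(profile)
    return {
        "low_total_reads_gt_threshold": profile.total_reads > params.low_min_total_reads,
        "low_homogeneity_lt_threshold": frac is not None
        and frac < params.low_max_modal_fraction,
    }


def classify(
    hairpin: HairpinRecord,
    annotations: Sequence[MatureAnnotation],
    structure: SecondaryStructure | None,
    read_stack: ReadStack,
    params: ClassifierParams = DEFAULT_PARAMS,
) -> ConfidenceReport:
    """Full classification of one locus; high takes precedence over low.

    Loci passing neither rule set are ``undetermined`` — typically for lack
    of data, which by itself is never evidence against an annotation.  The
    report carries the measured metrics so users can see why.
    """
    for ann in annotations:
        ann.validate_against(hairpin)
    profile = build_profile(
        read_stack, annotations, params.extension, params.min_overlap_fraction
    )

    by_arm = {a.arm: a for a in annotations}
    geometry: DuplexGeometry | None = None
    if structure is not None and "5p" in by_arm and "3p" in by_arm:
        geometry = duplex_overhangs(
            structure, by_arm["5p"], by_arm["3p"], params.scan_window
        )

    criteria = high_confidence_call(profile, annotations, geometry, params)
    criteria.update(low_confidence_call(profile, params))

    is_high = all(criteria[k] for k in HIGH_CRITERIA)
    is_low = all(criteria[k] for k in LOW_CRITERIA) and not is_high
    call = "high" if is_high else ("low" if is_low else "undetermined")

    def frac_of(arm: str) -> float | None:
        ap = profile.arm_profiles.get(arm)  # type: ignore[arg-type]
        return ap.modal_fraction if ap else None

    metrics: dict[str, float | int | None] = {
        "total_reads": profile.total_reads,
        "assigned_5p": profile.assigned("5p"),
        "assigned_3p": profile.assigned("3p"),
        "modal_fraction_5p": frac_of("5p"),
        "modal_fraction_3p": frac_of("3p"),
        "overhang_drosha_end": geometry.overhang_drosha_end if geometry else None,
        "overhang_dicer_end": geometry.overhang_dicer_end if geometry else None,
    }
    return ConfidenceReport(
        accession=hairpin.accession, criteria=criteria, call=call, metrics=metrics
    )
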