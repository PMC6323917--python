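"""Per-arm read-stack statistics for the confidence rules.

The canonical Drosha/Dicer processing pathway stacks reads tightly on each
arm of the hairpin with nearly identical 5' ends.  This module reduces a
:class:`~mirqc.records_io.ReadStack` to the quantities the classifier
consumes: per-arm assigned depth and the 5'-start histogram from which the
modal 5' fraction (5' homogeneity) is computed.

A read is assigned to the arm whose interval, extended by ``extension``
(default 2 nt) on each side, overlaps at least half of the read; the
extension tolerates templated 3' trimming/tailing while loop-spanning
fragments stay unassigned.  The homogeneity statistic uses the *modal*
observed 5' end — reads are compared with each other, not with the
annotated end, so the statistic can also critique a mis-annotated mature.
Counts are collapse counts, not distinct sequences: the confidence criteria
are read-depth thresholds.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

from .records_io import HairpinRecord, MatureAnnotation, ReadStack

__all__ = [
    "ArmProfile",
    "LocusProfile",
    "assign_read",
    "build_profile",
    "modal_five_prime_fraction",
    "render_stack",
    "write_profile_tsv",
    "write_profile_json",
]

Arm = Literal["5p", "3p"]
Assignment = Literal["5p", "3p", "unassigned"]

DEFAULT_EXTENSION = 2
DEFAULT_MIN_OVERLAP_FRACTION = 0.5


@dataclass
class ArmProfile:
    """Read support for one arm: total assigned count and 5'-start histogram."""

    arm: Arm
    assigned_reads: int = 0
    start_histogram: dict[int, int] = field(default_factory=dict)

    @property
    def modal_start(self) -> int | None:
        if not self.start_histogram:
            return None
        # deterministic tie-break: smallest position among maximal counts
        best = max(self.start_histogram.values())
        return min(p for p, c in self.start_histogram.items() if c == best)

    @property
    def modal_fraction(self) -> float | None:
        """Fraction of assigned reads sharing the modal 5' end; None if no data."""
        if self.assigned_reads == 0:
            return None
        return max(self.start_histogram.values()) / self.assigned_reads


@dataclass
class LocusProfile:
    """Whole-locus read summary: total depth, per-arm profiles, unassigned count."""

    accession: str
    total_reads: int = 0
    arm_profiles: dict[Arm, ArmProfile] = field(default_factory=dict)
    unassigned_reads: int = 0

    def assigned(self, arm: Arm) -> int:
        prof = self.arm_profiles.get(arm)
        return prof.assigned_reads if prof else 0


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def assign_read(
    read_interval: tuple[int, int],
    mature_intervals: Mapping[Arm, tuple[int, int]],
    extension: int = DEFAULT_EXTENSION,
    min_overlap_fraction: float = DEFAULT_MIN_OVERLAP_FRACTION,
) -> Assignment:
    """Assign a read interval to 5p, 3p or unassigned.

    An arm qualifies when its interval extended by ``extension`` nt on each
    side covers at least ``min_overlap_fraction`` of the read's length.  If
    both arms qualify the larger overlap wins; an exact tie is unassigned.
    """
    r_start, r_end = read_interval
    read_len = r_end - r_start
    if read_len <= 0:
        return "unassigned"
    qualifying: list[tuple[int, Arm]] = []
    for arm, (m_start, m_end) in mature_intervals.items():
        ov = _overlap(r_start, r_end, m_start - extension, m_end + extension)
        if ov >= min_overlap_fraction * read_len:
            qualifying.append((ov, arm))
    if not qualifying:
        return "unassigned"
    if len(qualifying) == 1:
        return qualifying[0][1]
    (ov_a, arm_a), (ov_b, arm_b) = qualifying
    if ov_a == ov_b:
        return "unassigned"
    return arm_a if ov_a > ov_b else arm_b


def build_profile(
    read_stack: ReadStack,
    annotations: Sequence[MatureAnnotation],
    extension: int = DEFAULT_EXTENSION,
    min_overlap_fraction: float = DEFAULT_MIN_OVERLAP_FRACTION,
) -> LocusProfile:
    """Accumulate a :class:`LocusProfile` from a collapsed read stack.

    Count conservation holds by construction:
    ``assigned(5p) + assigned(3p) + unassigned == total_reads``.
    """
    intervals: dict[Arm, tuple[int, int]] = {
        a.arm: (a.start, a.end) for a in annotations
    }
    profile = LocusProfile(accession=read_stack.hairpin_accession)
    for arm in intervals:
        profile.arm_profiles[arm] = ArmProfile(arm=arm)
    for seq, start, count in read_stack.entries:
        profile.total_reads += count
        target = assign_read(
            (start, start + len(seq)), intervals, extension, min_overlap_fraction
        )
        if target == "unassigned":
            profile.unassigned_reads += count
        else:
            arm_prof = profile.arm_profiles[target]
            arm_prof.assigned_reads += count
            arm_prof.start_histogram[start] = arm_prof.start_histogram.get(start, 0) + count
    return profile


def modal_five_prime_fraction(arm_profile: ArmProfile) -> float:
    """Largest histogram mass over assigned reads.

    Raises ``ValueError`` when the arm has no assigned reads; callers treat
    that as the criterion failing for lack of data.
    """
    if arm_profile.assigned_reads == 0:
        raise ValueError(f"arm {arm_profile.arm}: no assigned reads, fraction undefined")
    return max(arm_profile.start_histogram.values()) / arm_profile.assigned_reads


# ---------------------------------------------------------------------------
# Rendering / dumps


def render_stack(
    hairpin: HairpinRecord,
    read_stack: ReadStack,
    max_rows: int = 40,
) -> str:
    """ASCII read-stack view: reads stacked under the hairpin sequence.

    Mirrors the website-style read-mapping profile for terminal inspection.
    Entries are drawn most-abundant first, one row each, annotated with
    their collapse count.
    """
    lines = [hairpin.sequence]
    entries = sorted(read_stack.entries, key=lambda e: (-e[2], e[1], e[0]))
    for seq, start, count in entries[:max_rows]:
        lines.append("." * start + seq + "." * (hairpin.length - start - len(seq)) + f"  x{count}")
    if len(entries) > max_rows:
        lines.append(f"... {len(entries) - max_rows} more distinct reads")
    return "\n".join(lines)


def write_profile_tsv(profiles: Sequence[LocusProfile], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["accession", "arm", "assigned_reads", "modal_start", "modal_fraction", "total_reads", "unassigned_reads"]
        )
        for prof in profiles:
            for arm in ("5p", "3p"):
                ap = prof.arm_profiles.get(arm)  # type: ignore[arg-type]
                if ap is None:
                    continue
                frac = ap.modal_fraction
                writer.writerow(
                    [
                        prof.accession,
                        arm,
                        ap.assigned_reads,
                        "NA" if ap.modal_start is None else ap.modal_start + 1,
                        "NA" if frac is None else f"{frac:.6g}",
                        prof.total_reads,
                        prof.unassigned_reads,
                    ]
                )


def write_profile_json(profiles: Sequence[LocusProfile], path: str | Path) -> None:
    payload = []
    for prof in profiles:
        payload.append(
            {
                "accession": prof.accession,
                "total_reads": prof.total_reads,
                "unassigned_reads": prof.unassigned_reads,
                "arms": {
                    arm: {
                        "assigned_reads": ap.assigned_reads,
                        "start_histogram": {str(k): v for k, v in sorted(ap.start_histogram.items())},
                        "modal_start": ap.modal_start,
                        "modal_fraction": ap.modal_fraction,
                    }
                    for arm, ap in prof.arm_profiles.items()
                },
            }
        )
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=2)
        handle.write("\n")
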