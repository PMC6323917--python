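"""Boundary sweeps that recover the classifier decision thresholds.

Each sweep builds deterministic fixture loci around one rule and walks the
relevant quantity across its decision boundary, reporting where the call
flips.  They serve as end-to-end calibration checks: the recovered values
must equal the published thresholds (20 reads per arm, 50% 5' homogeneity,
>100 total reads, <30% dominant-arm homogeneity).
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

from .confidence import DEFAULT_PARAMS, ClassifierParams, classify
from .records_io import HairpinRecord, MatureAnnotation, ReadStack, SecondaryStructure
from .simulate import SimulationParams, make_locus

__all__ = [
    "min_reads_for_high",
    "min_modal_percent_for_high",
    "max_total_reads_not_low",
    "min_modal_percent_not_low",
]

Locus = tuple[HairpinRecord, SecondaryStructure, tuple[MatureAnnotation, MatureAnnotation]]


def _fixture_locus(seed: int) -> Locus:
    # wide flanks so shifted 5' starts stay on the hairpin
    return make_locus(SimulationParams(seed=seed, flank=12))


def _stack_from_histograms(
    locus: Locus, histograms: dict[str, dict[int, int]]
) -> ReadStack:
    """Build a collapsed stack placing reads of mature length at given 5' starts."""
    hairpin, _, matures = locus
    by_arm = {m.arm: m for m in matures}
    entries = []
    for arm, hist in histograms.items():
        mature = by_arm[arm]
        length = mature.end - mature.start
        for start, count in sorted(hist.items()):
            if count <= 0:
                continue
            seq = hairpin.sequence[start : start + length]
            entries.append((seq, start, count))
    return ReadStack(hairpin_accession=hairpin.accession, entries=entries)


def _classify_stack(locus: Locus, stack: ReadStack, params: ClassifierParams):
    hairpin, structure, matures = locus
    return classify(hairpin, list(matures), structure, stack, params)


def min_reads_for_high(
    max_depth: int = 40,
    params: ClassifierParams = DEFAULT_PARAMS,
    seed: int = 0,
) -> int:
    """Smallest per-arm depth classified high, all other rules passing.

    k identical reads sit exactly on each mature (100% 5' homogeneity) of a
    perfect-stem locus with 2-nt overhangs at both duplex ends.
    """
    locus = _fixture_locus(seed)
    _, _, (m5, m3) = locus
    for k in range(1, max_depth + 1):
        stack = _stack_from_histograms(locus, {"5p": {m5.start: k}, "3p": {m3.start: k}})
        if _classify_stack(locus, stack, params).call == "high":
            return k
    raise RuntimeError(f"no high call up to depth {max_depth}")


def min_modal_percent_for_high(
    depth_per_arm: int = 1000,
    percents: Sequence[int] = range(40, 61, 1),
    params: ClassifierParams = DEFAULT_PARAMS,
    seed: int = 0,
) -> int:
    """Smallest modal-5'-end percentage classified high at abundant depth.

    Per arm, m reads start at the canonical 5' end and the rest one
    position downstream.  The histogram has two bins, so its true modal
    fraction is max(m, depth-m)/depth; the sweep reports the smallest such
    modal percentage over the points where the call is high.
    """
    locus = _fixture_locus(seed)
    _, _, (m5, m3) = locus
    best: int | None = None
    for pct in sorted(percents):
        m = depth_per_arm * pct // 100
        hists = {
            "5p": {m5.start: m, m5.start + 1: depth_per_arm - m},
            "3p": {m3.start: m, m3.start + 1: depth_per_arm - m},
        }
        stack = _stack_from_histograms(locus, hists)
        if _classify_stack(locus, stack, params).call == "high":
            modal_pct = max(m, depth_per_arm - m) * 100 // depth_per_arm
            best = modal_pct if best is None else min(best, modal_pct)
    if best is None:
        raise RuntimeError("no high call across the swept homogeneity range")
    return best


def _scattered_histogram(
    canonical: int, total: int, n_positions: int = 20, max_left: int = 10
) -> dict[int, int]:
    """Spread ``total`` reads near-evenly over ``n_positions`` 5' starts.

    Offsets stay within the assignable window around the mature so every
    read lands on its arm; the modal fraction is ~1/n_positions (5%).
    """
    offsets = [o for o in range(-max_left, n_positions - max_left)]
    base, rem = divmod(total, n_positions)
    hist = {}
    for idx, off in enumerate(offsets):
        count = base + (1 if idx < rem else 0)
        if count:
            hist[canonical + off] = count
    return hist


def max_total_reads_not_low(
    totals: Sequence[int] = range(50, 151),
    params: ClassifierParams = DEFAULT_PARAMS,
    seed: int = 0,
) -> int:
    """Largest total depth at which a maximally scattered locus escapes the low flag.

    All reads sit on the 5p arm, spread over 20 start positions (modal
    fraction ~5%, far below the homogeneity cut), so the total-reads rule
    alone decides.
    """
    locus = _fixture_locus(seed)
    _, _, (m5, _) = locus
    best = None
    for total in sorted(totals):
        stack = _stack_from_histograms(
            locus, {"5p": _scattered_histogram(m5.start, total)}
        )
        if _classify_stack(locus, stack, params).call != "low":
            best = total
    if best is None:
        raise RuntimeError("every swept total was flagged low")
    return best


def min_modal_percent_not_low(
    total: int = 1000,
    percents: Sequence[int] = range(20, 41),
    params: ClassifierParams = DEFAULT_PARAMS,
    seed: int = 0,
) -> int:
    """Smallest dominant-arm modal percentage no longer flagged low.

    1000 reads on the dominant arm: the modal start holds p% and the rest
    spread thinly over nearby starts, so the homogeneity rule alone flips.
    """
    locus = _fixture_locus(seed)
    _, _, (m5, _) = locus
    side_offsets = [o for o in range(-10, 14) if o != 0]
    for pct in sorted(percents):
        modal = total * pct // 100
        rest = total - modal
        hist = {m5.start: modal}
        base, rem = divmod(rest, len(side_offsets))
        for idx, off in enumerate(side_offsets):
            count = base + (1 if idx < rem else 0)
            if count:
                hist[m5.start + off] = count
        stack = _stack_from_histograms(locus, {"5p": hist})
        if _classify_stack(locus, stack, params).call != "low":
            return pct
    raise RuntimeError("every swept percentage was flagged low")
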