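"""Synthetic hairpin loci and read stacks with known ground truth.

The generator builds a perfect-stem hairpin (3p arm = reverse complement of
the 5p arm) with an analytically constructed pair table — no folding — and
places the two matures so the requested duplex 3' overhangs hold exactly.
Reads are then drawn per arm: a read starts at the canonical 5' end with
probability ``homogeneity``, otherwise at a uniformly chosen non-zero shift
within ``shift_range``; its length jitters uniformly within ``trim_range``.
Every read is an exact hairpin substring, and the same seed always yields
the same stack (seeded pseudo-randomness is part of the contract).

This emulates the read signature of canonical Drosha/Dicer processing — or
deliberately breaks it — so every classifier path and threshold boundary is
testable without downloading any sequencing data.  It does not model
sequencing errors, non-templated tailing, or realistic cross-locus
expression distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .records_io import (
    HairpinRecord,
    MatureAnnotation,
    ReadStack,
    SecondaryStructure,
    write_alignments_tsv,
    write_hairpin_fasta,
    write_matures_tsv,
    write_structures,
)

__all__ = ["SimulationParams", "make_locus", "simulate_reads", "write_fixture", "PRESETS"]

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class SimulationParams:
    """Generative parameters for one synthetic locus.

    Defaults describe a typical well-supported animal microRNA: 22-nt
    matures on a perfect stem, 12-nt loop, canonical 2-nt 3' overhangs at
    both duplex ends, a couple of hundred reads per arm with ~90% 5'
    homogeneity and modest 5'/3' heterogeneity.
    """

    arm_length: int = 22
    loop_length: int = 12
    depth_5p: int = 200
    depth_3p: int = 200
    homogeneity_5p: float = 0.9
    homogeneity_3p: float = 0.9
    shift_range: int = 3
    trim_range: int = 2
    overhang_drosha: int = 2
    overhang_dicer: int = 2
    seed: int = 0
    flank: int = 6

    def __post_init__(self) -> None:
        if not (0.0 <= self.homogeneity_5p <= 1.0 and 0.0 <= self.homogeneity_3p <= 1.0):
            raise ValueError("homogeneities must be in [0, 1]")
        if self.arm_length <= 0 or self.loop_length < 3:
            raise ValueError("arm_length must be positive and loop_length >= 3")
        if self.shift_range < 0 or self.trim_range < 0:
            raise ValueError("ranges must be non-negative")


PRESETS: dict[str, SimulationParams] = {
    # canonical locus passing every high-confidence rule
    "high": SimulationParams(),
    # deep but scattered 5' ends: the low-confidence signature
    "low": SimulationParams(
        depth_5p=600, depth_3p=600, homogeneity_5p=0.05, homogeneity_3p=0.05, shift_range=5
    ),
    # too few reads to determine anything
    "sparse": SimulationParams(depth_5p=5, depth_3p=3),
}


def make_locus(
    params: SimulationParams,
) -> tuple[HairpinRecord, SecondaryStructure, tuple[MatureAnnotation, MatureAnnotation]]:
    """Build a perfect-stem hairpin realizing the requested overhangs exactly.

    Construction is the inverse of measurement: ``duplex_overhangs`` on the
    returned locus recovers ``(overhang_drosha, overhang_dicer)`` for any
    request the arm geometry allows.
    """
    m, loop, f5 = params.arm_length, params.loop_length, params.flank
    f3 = max(params.overhang_drosha, 0) + params.flank
    if params.overhang_dicer < -(params.loop_length):
        raise ValueError("dicer overhang recessed past the loop")
    if params.overhang_dicer >= m + params.overhang_drosha:
        raise ValueError("requested overhangs leave a non-positive 3p mature")

    rng = np.random.default_rng(params.seed)
    bases = np.array(list("ACGU"))
    front = "".join(rng.choice(bases, size=f5 + m))
    loop_seq = "".join(rng.choice(bases, size=loop))
    stem5 = front[f5:]
    stem3 = "".join(_COMPLEMENT[b] for b in reversed(stem5))
    tail = "".join(rng.choice(bases, size=f3))
    sequence = front + loop_seq + stem3 + tail
    length = len(sequence)

    pair_table: dict[int, int] = {}
    for k in range(m):
        i, j = f5 + k, f5 + 2 * m + loop - 1 - k
        pair_table[i] = j
        pair_table[j] = i
    structure = SecondaryStructure(pair_table=pair_table, length=length, source="provided")

    name = f"sim-mir-{params.seed}"
    hairpin = HairpinRecord(
        accession=f"SIM{params.seed % 10**7:07d}", name=name, sequence=sequence
    )

    s5, e5 = f5, f5 + m
    s3 = f5 + m + loop + params.overhang_dicer
    e3 = f5 + 2 * m + loop + params.overhang_drosha
    mature_5p = MatureAnnotation(
        mature_name=f"{name}-5p", arm="5p", start=s5, end=e5, sequence=sequence[s5:e5]
    )
    mature_3p = MatureAnnotation(
        mature_name=f"{name}-3p", arm="3p", start=s3, end=e3, sequence=sequence[s3:e3]
    )
    return hairpin, structure, (mature_5p, mature_3p)


def _draw_arm_reads(
    rng: np.random.Generator,
    hairpin: HairpinRecord,
    mature: MatureAnnotation,
    depth: int,
    homogeneity: float,
    shift_range: int,
    trim_range: int,
    counter: dict[tuple[str, int], int],
) -> None:
    canonical = mature.start
    base_len = mature.end - mature.start
    shifts = [s for s in range(-shift_range, shift_range + 1) if s != 0]
    for _ in range(depth):
        start = canonical
        if shifts and rng.random() >= homogeneity:
            start = canonical + shifts[rng.integers(len(shifts))]
        start = max(0, min(start, hairpin.length - 1))
        length = base_len
        if trim_range:
            length += int(rng.integers(-trim_range, trim_range + 1))
        end = max(start + 1, min(start + length, hairpin.length))
        seq = hairpin.sequence[start:end]
        counter[(seq, start)] = counter.get((seq, start), 0) + 1


def simulate_reads(
    locus: tuple[HairpinRecord, SecondaryStructure, tuple[MatureAnnotation, MatureAnnotation]],
    params: SimulationParams,
) -> ReadStack:
    """Draw a collapsed read stack for a locus from :func:`make_locus`."""
    hairpin, _, (mature_5p, mature_3p) = locus
    rng = np.random.default_rng(params.seed + 1)
    counter: dict[tuple[str, int], int] = {}
    _draw_arm_reads(
        rng, hairpin, mature_5p, params.depth_5p, params.homogeneity_5p,
        params.shift_range, params.trim_range, counter,
    )
    _draw_arm_reads(
        rng, hairpin, mature_3p, params.depth_3p, params.homogeneity_3p,
        params.shift_range, params.trim_range, counter,
    )
    entries = [(seq, start, count) for (seq, start), count in sorted(counter.items())]
    return ReadStack(hairpin_accession=hairpin.accession, entries=entries)


def write_fixture(params: SimulationParams, out_prefix: str | Path) -> dict[str, Path]:
    """Emit a complete on-disk fixture set: FASTA, structures, matures, alignments."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    locus = make_locus(params)
    hairpin, structure, matures = locus
    stack = simulate_reads(locus, params)
    paths = {
        "hairpins": out_prefix.with_suffix(".hairpins.fa"),
        "structures": out_prefix.with_suffix(".structures.txt"),
        "matures": out_prefix.with_suffix(".matures.tsv"),
        "alignments": out_prefix.with_suffix(".alignments.tsv"),
    }
    write_hairpin_fasta([hairpin], paths["hairpins"])
    write_structures({hairpin.name: (hairpin.sequence, structure)}, paths["structures"])
    write_matures_tsv({hairpin.accession: list(matures)}, paths["matures"])
    write_alignments_tsv([stack], paths["alignments"])
    return paths
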