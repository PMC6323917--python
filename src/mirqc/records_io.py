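"""On-disk representations of hairpins, structures, annotations and alignments.

Coordinate convention: everything in memory is 0-based half-open; every
tabular file on disk is 1-based inclusive (the miRBase/GFF convention).
FASTA/structure/TSV writers and readers round-trip bit-identically on valid
records.
"""

from __future__ import annotations

import csv
import io
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "HairpinRecord",
    "SecondaryStructure",
    "MatureAnnotation",
    "ReadStack",
    "ConfidenceReport",
    "RejectionReport",
    "ParseError",
    "MatureNotFoundError",
    "AmbiguousMatureError",
    "read_hairpin_fasta",
    "write_hairpin_fasta",
    "parse_dot_bracket",
    "render_dot_bracket",
    "read_structures",
    "write_structures",
    "locate_mature",
    "read_matures_tsv",
    "write_matures_tsv",
    "read_alignments",
    "write_alignments_tsv",
    "write_reports_tsv",
    "write_reports_json",
]

_RNA_ALPHABET = frozenset("ACGU")


class ParseError(ValueError):
    """An on-disk file violates its format contract."""


class MatureNotFoundError(KeyError):
    """A mature sequence has no exact occurrence in its hairpin."""


class AmbiguousMatureError(ValueError):
    """A mature sequence occurs more than once and no arm hint was given."""


def _normalize_rna(seq: str) -> str:
    return seq.strip().upper().replace("T", "U")


@dataclass(frozen=True)
class HairpinRecord:
    """A microRNA hairpin precursor (pre-miRNA) sequence.

    ``name`` follows miRBase style (e.g. ``hsa-mir-21``); ``species_code``
    is the 3-4 letter organism prefix of the name when present.
    """

    accession: str
    name: str
    sequence: str
    species_code: str = ""

    def __post_init__(self) -> None:
        seq = _normalize_rna(self.sequence)
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError(f"hairpin {self.name!r}: empty sequence")
        bad = set(seq) - _RNA_ALPHABET
        if bad:
            raise ValueError(f"hairpin {self.name!r}: non-ACGU characters {sorted(bad)}")
        if not self.species_code:
            head = self.name.split("-", 1)[0]
            if 3 <= len(head) <= 4 and head.isalpha():
                object.__setattr__(self, "species_code", head.lower())

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SecondaryStructure:
    """Base pairing of a hairpin as a symmetric partial pair table.

    ``pair_table[i] == j`` means positions i and j (0-based) are paired;
    unpaired positions are absent.
    """

    pair_table: Mapping[int, int]
    length: int
    source: Literal["provided", "folded"] = "provided"

    def __post_init__(self) -> None:
        for i, j in self.pair_table.items():
            if i == j:
                raise ValueError(f"position {i} pairs with itself")
            if not (0 <= i < self.length and 0 <= j < self.length):
                raise ValueError(f"pair {i}-{j} outside [0, {self.length})")
            if self.pair_table.get(j) != i:
                raise ValueError(f"pair table not symmetric at {i}-{j}")

    def partner(self, i: int) -> int | None:
        return self.pair_table.get(i)


@dataclass(frozen=True)
class MatureAnnotation:
    """A mature microRNA's interval on its hairpin, 0-based half-open."""

    mature_name: str
    arm: Literal["5p", "3p"]
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _normalize_rna(self.sequence))
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.mature_name}: bad interval [{self.start}, {self.end})")
        if self.end - self.start != len(self.sequence):
            raise ValueError(f"{self.mature_name}: interval length != sequence length")
        if self.arm not in ("5p", "3p"):
            raise ValueError(f"{self.mature_name}: arm must be 5p or 3p")

    @property
    def end3(self) -> int:
        """Last (inclusive) hairpin position of the mature — its 3' terminus."""
        return self.end - 1

    def validate_against(self, hairpin: HairpinRecord) -> None:
        if self.end > hairpin.length:
            raise ValueError(f"{self.mature_name}: interval exceeds hairpin length")
        if hairpin.sequence[self.start : self.end] != self.sequence:
            raise ValueError(f"{self.mature_name}: sequence mismatch with hairpin")


@dataclass
class ReadStack:
    """Collapsed small-RNA reads aligned to one hairpin.

    Each entry is (read_sequence, 0-based start, count).  The invariant —
    every read is an exact substring of the hairpin at its start — is
    enforced at load time by :func:`read_alignments`.
    """

    hairpin_accession: str
    entries: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def total_count(self) -> int:
        return sum(c for _, _, c in self.entries)


@dataclass
class RejectionReport:
    """Rows dropped while loading alignments, with reasons."""

    n_rejected: int = 0
    reasons: list[str] = field(default_factory=list)

    def add(self, reason: str) -> None:
        self.n_rejected += 1
        self.reasons.append(reason)


HIGH_CRITERIA = (
    "both_arms_annotated",
    "overhang_ok",
    "depth_ok_5p",
    "depth_ok_3p",
    "homogeneity_ok_5p",
    "homogeneity_ok_3p",
)
LOW_CRITERIA = ("low_total_reads_gt_threshold", "low_homogeneity_lt_threshold")


@dataclass
class ConfidenceReport:
    """Per-hairpin classification with the per-criterion booleans behind it.

    ``call`` is ``high`` iff all six high-confidence booleans hold, ``low``
    iff both low-confidence booleans hold and the locus is not high, and
    ``undetermined`` otherwise.  ``metrics`` keeps the measured quantities
    (per-arm depth, modal 5' fractions, overhangs, total reads) so a user
    can see *why* a call was made — lack of data alone never condemns an
    annotation, it just leaves it undetermined.
    """

    accession: str
    criteria: dict[str, bool]
    call: Literal["high", "low", "undetermined"]
    metrics: dict[str, float | int | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        is_high = all(self.criteria.get(k, False) for k in HIGH_CRITERIA)
        is_low = all(self.criteria.get(k, False) for k in LOW_CRITERIA) and not is_high
        expected = "high" if is_high else ("low" if is_low else "undetermined")
        if self.call != expected:
            raise ValueError(
                f"{self.accession}: call {self.call!r} inconsistent with criteria ({expected!r})"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_hairpin_fasta(path: str | Path) -> list[HairpinRecord]:
    """Read hairpin precursors from FASTA.

    The header is parsed as ``name accession ...`` with graceful fallback to
    name-only (accession = name).  T is normalized to U; entries with empty
    sequences are rejected with a warning.
    """
    path = Path(path)
    with open(path) as handle:
        first = handle.readline()
        if first and not first.startswith(">"):
            raise ParseError(f"{path}:1: expected FASTA header line starting with '>'")
    records: list[HairpinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _normalize_rna(str(rec.seq))
        if not seq:
            warnings.warn(f"{path}: entry {rec.id!r} has empty sequence; rejected")
            continue
        parts = rec.description.split()
        name = parts[0]
        accession = parts[1] if len(parts) > 1 else name
        records.append(HairpinRecord(accession=accession, name=name, sequence=seq))
    return records


def write_hairpin_fasta(records: Iterable[HairpinRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.name, description=r.accession)
        for r in records
    ]
    with open(path, "w") as handle:
        SeqIO.write(seqs, handle, "fasta-2line")


# ---------------------------------------------------------------------------
# Dot-bracket structures


def parse_dot_bracket(structure: str, length: int) -> SecondaryStructure:
    """Build a pair table from dot-bracket notation by stack matching.

    Raises :class:`ParseError` at the first unbalanced index, or on a length
    mismatch.
    """
    if len(structure) != length:
        raise ParseError(f"structure length {len(structure)} != expected {length}")
    stack: list[int] = []
    table: dict[int, int] = {}
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ParseError(f"unbalanced ')' at index {i}")
            j = stack.pop()
            table[j] = i
            table[i] = j
        elif ch != ".":
            raise ParseError(f"invalid character {ch!r} at index {i}")
    if stack:
        raise ParseError(f"unbalanced '(' at index {stack[-1]}")
    return SecondaryStructure(pair_table=table, length=length, source="provided")


def render_dot_bracket(structure: SecondaryStructure) -> str:
    chars = ["."] * structure.length
    for i, j in structure.pair_table.items():
        if i < j:
            chars[i] = "("
            chars[j] = ")"
    return "".join(chars)


def read_structures(path: str | Path) -> dict[str, SecondaryStructure]:
    """Read a FASTA-like structure file: header, sequence line, structure line.

    Returns a map keyed by the first header token (hairpin name).
    """
    out: dict[str, SecondaryStructure] = {}
    with open(path) as handle:
        lines = [ln.rstrip("\n") for ln in handle if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ParseError(f"{path}: expected '>' header at block starting line {i + 1}")
        if i + 2 >= len(lines):
            raise ParseError(f"{path}: truncated record {lines[i][1:]!r}")
        name = lines[i][1:].split()[0]
        seq, struct = lines[i + 1], lines[i + 2]
        out[name] = parse_dot_bracket(struct, len(seq))
        i += 3
    return out


def write_structures(
    items: Mapping[str, tuple[str, SecondaryStructure]], path: str | Path
) -> None:
    """Write ``{name: (sequence, structure)}`` as a FASTA-like structure file."""
    with open(path, "w") as handle:
        for name, (seq, structure) in items.items():
            handle.write(f">{name}\n{seq}\n{render_dot_bracket(structure)}\n")


# ---------------------------------------------------------------------------
# Mature annotations


def locate_mature(
    hairpin: HairpinRecord,
    mature_sequence: str,
    arm_hint: Literal["5p", "3p", None] = None,
    mature_name: str = "",
) -> MatureAnnotation:
    """Recover a mature's hairpin coordinates by exact substring search.

    If the mature occurs more than once, a 5p hint selects the leftmost
    occurrence and a 3p hint the rightmost; with no hint this is an error.
    """
    mature = _normalize_rna(mature_sequence)
    if not mature:
        raise ValueError("empty mature sequence")
    hits: list[int] = []
    pos = hairpin.sequence.find(mature)
    while pos != -1:
        hits.append(pos)
        pos = hairpin.sequence.find(mature, pos + 1)
    if not hits:
        raise MatureNotFoundError(
            f"{mature_name or mature!r} not found in hairpin {hairpin.name}"
        )
    if len(hits) == 1:
        start = hits[0]
    elif arm_hint == "5p":
        start = hits[0]
    elif arm_hint == "3p":
        start = hits[-1]
    else:
        raise AmbiguousMatureError(
            f"{mature_name or mature!r} occurs {len(hits)} times in {hairpin.name}; "
            "pass arm_hint to disambiguate"
        )
    end = start + len(mature)
    if arm_hint is None:
        mid = (start + end) / 2
        arm: Literal["5p", "3p"] = "5p" if mid <= hairpin.length / 2 else "3p"
    else:
        arm = arm_hint
    return MatureAnnotation(
        mature_name=mature_name or f"{hairpin.name}-{arm}",
        arm=arm,
        start=start,
        end=end,
        sequence=mature,
    )


_MATURE_COLS = ["hairpin_accession", "mature_name", "arm", "start", "end", "sequence"]


def read_matures_tsv(path: str | Path) -> dict[str, list[MatureAnnotation]]:
    """Read mature annotations keyed by hairpin accession (file is 1-based inclusive)."""
    out: dict[str, list[MatureAnnotation]] = {}
    with open(path) as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            ann = MatureAnnotation(
                mature_name=row["mature_name"],
                arm=row["arm"],  # type: ignore[arg-type]
                start=int(row["start"]) - 1,
                end=int(row["end"]),
                sequence=row["sequence"],
            )
            out.setdefault(row["hairpin_accession"], []).append(ann)
    return out


def write_matures_tsv(
    annotations: Mapping[str, Sequence[MatureAnnotation]], path: str | Path
) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_MATURE_COLS)
        for acc, anns in annotations.items():
            for a in anns:
                writer.writerow([acc, a.mature_name, a.arm, a.start + 1, a.end, a.sequence])


# ---------------------------------------------------------------------------
# Alignments


def _finish_stacks(
    grouped: dict[str, dict[tuple[str, int], int]]
) -> list[ReadStack]:
    stacks = []
    for acc, counter in grouped.items():
        entries = [(seq, start, count) for (seq, start), count in sorted(counter.items())]
        stacks.append(ReadStack(hairpin_accession=acc, entries=entries))
    return stacks


def read_alignments(
    path: str | Path,
    format: Literal["tsv", "sam"],
    hairpins: Mapping[str, HairpinRecord],
) -> tuple[list[ReadStack], RejectionReport]:
    """Load collapsed read alignments grouped per hairpin.

    TSV columns: hairpin_accession, read_sequence, start (1-based in the
    file), count.  SAM is accepted in a single-reference-per-hairpin dialect
    where only flag 0 records are used; flag 16 (reverse strand) is rejected
    with a warning since hairpins are single-stranded.  Duplicate
    (sequence, start) rows are summed.  Entries whose read sequence does not
    match the hairpin at their start are dropped and counted in the
    rejection report.
    """
    by_name = {h.name: h for h in hairpins.values()}
    rejections = RejectionReport()
    grouped: dict[str, dict[tuple[str, int], int]] = {}

    def add_entry(acc_or_name: str, seq: str, start0: int, count: int, where: str) -> None:
        hp = hairpins.get(acc_or_name) or by_name.get(acc_or_name)
        if hp is None:
            rejections.add(f"{where}: unknown hairpin {acc_or_name!r}")
            return
        if count < 1:
            rejections.add(f"{where}: non-positive count {count}")
            return
        seq = _normalize_rna(seq)
        if start0 < 0 or hp.sequence[start0 : start0 + len(seq)] != seq:
            rejections.add(f"{where}: read does not match hairpin {hp.accession} at {start0}")
            return
        counter = grouped.setdefault(hp.accession, {})
        counter[(seq, start0)] = counter.get((seq, start0), 0) + count

    if format == "tsv":
        with open(path) as handle:
            reader = csv.DictReader(handle, delimiter="\t")
            for lineno, row in enumerate(reader, start=2):
                try:
                    add_entry(
                        row["hairpin_accession"],
                        row["read_sequence"],
                        int(row["start"]) - 1,
                        int(row["count"]),
                        f"{path}:{lineno}",
                    )
                except (KeyError, TypeError, ValueError) as exc:
                    rejections.add(f"{path}:{lineno}: malformed row ({exc})")
    elif format == "sam":
        import pysam

        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            for aln in sam:
                if aln.is_unmapped or aln.reference_name is None:
                    continue
                if aln.is_reverse:
                    warnings.warn(
                        f"{path}: reverse-strand alignment {aln.query_name!r} rejected "
                        "(hairpins are single-stranded)"
                    )
                    rejections.add(f"{aln.query_name}: reverse strand")
                    continue
                count = 1
                if aln.query_name and "-x" in aln.query_name:
                    # collapsed-read convention: name ends in -x<count>
                    tail = aln.query_name.rsplit("-x", 1)[-1]
                    if tail.isdigit():
                        count = int(tail)
                add_entry(
                    aln.reference_name,
                    aln.query_sequence or "",
                    aln.reference_start,
                    count,
                    aln.query_name or "?",
                )
    else:
        raise ValueError(f"unknown alignment format {format!r}")
    return _finish_stacks(grouped), rejections


def write_alignments_tsv(stacks: Iterable[ReadStack], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["hairpin_accession", "read_sequence", "start", "count"])
        for stack in stacks:
            for seq, start, count in stack.entries:
                writer.writerow([stack.hairpin_accession, seq, start + 1, count])


# ---------------------------------------------------------------------------
# Confidence reports

_REPORT_METRICS = [
    "total_reads",
    "assigned_5p",
    "assigned_3p",
    "modal_fraction_5p",
    "modal_fraction_3p",
    "overhang_drosha_end",
    "overhang_dicer_end",
]


def write_reports_tsv(reports: Iterable[ConfidenceReport], path: str | Path) -> None:
    cols = ["accession", "call", *HIGH_CRITERIA, *LOW_CRITERIA, *_REPORT_METRICS]
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(cols)
        for rep in reports:
            row: list[object] = [rep.accession, rep.call]
            row += [int(rep.criteria.get(k, False)) for k in (*HIGH_CRITERIA, *LOW_CRITERIA)]
            for m in _REPORT_METRICS:
                v = rep.metrics.get(m)
                row.append("NA" if v is None else v)
            writer.writerow(row)


def write_reports_json(reports: Iterable[ConfidenceReport], path: str | Path) -> None:
    payload = [
        {
            "accession": r.accession,
            "call": r.call,
            "criteria": r.criteria,
            "metrics": r.metrics,
        }
        for r in reports
    ]
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=2)
        handle.write("\n")
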