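"""Transcript coordinate models and splice-variant construction.

All coordinates are 1-based and intervals are inclusive at both ends, following
the convention used for transcript annotation in the RNA-structure literature
(an interval (a, b) covers b - a + 1 nucleotides).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CoordinateError, SequenceError, SpecificationError

Interval = tuple[str, int, int]

_RNA = set("ACGU")
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def reverse_complement(seq: str) -> str:
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq))
    except KeyError as exc:  # pragma: no cover - message formatting
        raise SequenceError(f"non-RNA base in sequence: {exc}") from exc


def clean_rna(seq: str) -> str:
    """Uppercase, map T->U, and validate the alphabet."""
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - _RNA
    if bad:
        raise SequenceError(f"invalid characters in RNA sequence: {sorted(bad)}")
    return seq


def _check_intervals(intervals, length, what):
    prev_end = 0
    for item in intervals:
        label, start, end = item
        if not (1 <= start <= end <= length):
            raise CoordinateError(
                f"{what} {label!r} ({start}-{end}) outside 1..{length}"
            )
        if start <= prev_end:
            raise SpecificationError(
                f"{what} intervals must be sorted and non-overlapping (at {label!r})"
            )
        prev_end = end


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript with labelled exon and structural-domain intervals.

    Parameters
    ----------
    name : str
        Transcript identifier (e.g. ``"v1"``).
    length : int
        Transcript length in nucleotides.
    exons, domains : list of (label, start, end)
        1-based inclusive, sorted, non-overlapping intervals.
    """

    name: str
    length: int
    exons: tuple[Interval, ...] = ()
    domains: tuple[Interval, ...] = ()

    def __post_init__(self):
        if self.length < 1:
            raise SpecificationError("transcript length must be positive")
        object.__setattr__(self, "exons", tuple(self.exons))
        object.__setattr__(self, "domains", tuple(self.domains))
        _check_intervals(self.exons, self.length, "exon")
        _check_intervals(self.domains, self.length, "domain")

    def domain(self, label: str) -> tuple[int, int]:
        for lab, start, end in self.domains:
            if lab == label:
                return start, end
        raise KeyError(label)


@dataclass(frozen=True)
class Insertion:
    """An opaque insertion of known length after a base-coordinate position.

    Used for splice variants whose inserted exon sequence is unknown: the
    insertion contributes length but its positions have no base coordinate.
    """

    after: int
    length: int
    label: str = "insertion"


@dataclass(frozen=True)
class VariantSpec:
    """Edits applied to a base transcript: deletions, substitutions, insertions."""

    base: TranscriptModel
    deletions: tuple[tuple[int, int], ...] = ()
    substitutions: tuple[tuple[int, str], ...] = ()
    insertions: tuple[Insertion, ...] = ()
    name: str = "variant"

    def __post_init__(self):
        object.__setattr__(self, "deletions", tuple(tuple(d) for d in self.deletions))
        object.__setattr__(self, "substitutions", tuple(self.substitutions))
        object.__setattr__(self, "insertions", tuple(self.insertions))
        length = self.base.length
        prev_end = 0
        for start, end in sorted(self.deletions):
            if not (1 <= start <= end <= length):
                raise CoordinateError(f"deletion {start}-{end} outside 1..{length}")
            if start <= prev_end:
                raise SpecificationError("deletion intervals overlap")
            prev_end = end
        for pos, base in self.substitutions:
            if not 1 <= pos <= length:
                raise CoordinateError(f"substitution position {pos} outside 1..{length}")
            if base.upper().replace("T", "U") not in _RNA:
                raise SequenceError(f"substitution base {base!r} is not A/C/G/U")
            if any(s <= pos <= e for s, e in self.deletions):
                raise SpecificationError(
                    f"substitution at {pos} lies inside a deleted interval"
                )
        for ins in self.insertions:
            if not 0 <= ins.after <= length:
                raise CoordinateError(f"insertion point {ins.after} outside 0..{length}")
            if ins.length < 1:
                raise SpecificationError("insertion length must be positive")


@dataclass(frozen=True)
class VariantTranscript:
    """A constructed splice variant with its per-position map to base coordinates.

    ``to_base[k]`` (0-based k) holds the 1-based base coordinate of variant
    position k + 1, or 0 for positions created by an opaque insertion.
    """

    name: str
    length: int
    base: TranscriptModel
    to_base: np.ndarray = field(repr=False)

    def map_position(self, pos: int) -> int:
        """Map a 1-based variant position to its 1-based base coordinate."""
        if not 1 <= pos <= self.length:
            raise CoordinateError(f"position {pos} outside 1..{self.length}")
        base_pos = int(self.to_base[pos - 1])
        if base_pos == 0:
            raise CoordinateError(
                f"position {pos} lies in an inserted segment with no base coordinate"
            )
        return base_pos

    def inverse_map(self, base_pos: int) -> int:
        """Map a base coordinate back to the variant (undefined for deleted positions)."""
        if not 1 <= base_pos <= self.base.length:
            raise CoordinateError(f"position {base_pos} outside base 1..{self.base.length}")
        hits = np.nonzero(self.to_base == base_pos)[0]
        if hits.size == 0:
            raise CoordinateError(f"base position {base_pos} is deleted in {self.name}")
        return int(hits[0]) + 1


def build_variant(
    model: TranscriptModel, spec: VariantSpec, sequence: str
) -> tuple[str, VariantTranscript]:
    """Apply a :class:`VariantSpec` to a base sequence.

    Returns the variant sequence and a :class:`VariantTranscript` retaining the
    variant -> base coordinate map. The output length equals
    ``len(base) - sum(deletion lengths) + sum(insertion lengths)``.
    """
    sequence = clean_rna(sequence)
    if len(sequence) != model.length:
        raise SpecificationError(
            f"sequence length {len(sequence)} != model length {model.length}"
        )
    seq = list(sequence)
    for pos, base in spec.substitutions:
        seq[pos - 1] = base.upper().replace("T", "U")

    deleted = np.zeros(model.length + 1, dtype=bool)
    for start, end in spec.deletions:
        deleted[start : end + 1] = True

    inserts_after: dict[int, list[Insertion]] = {}
    for ins in spec.insertions:
        inserts_after.setdefault(ins.after, []).append(ins)

    out_seq: list[str] = []
    to_base: list[int] = []

    def _emit_insertions(after: int):
        for ins in inserts_after.get(after, ()):  # opaque: filled with N placeholder
            out_seq.extend("N" * ins.length)
            to_base.extend([0] * ins.length)

    _emit_insertions(0)
    for pos in range(1, model.length + 1):
        if not deleted[pos]:
            out_seq.append(seq[pos - 1])
            to_base.append(pos)
        _emit_insertions(pos)

    variant = VariantTranscript(
        name=spec.name,
        length=len(out_seq),
        base=model,
        to_base=np.asarray(to_base, dtype=np.int64),
    )
    return "".join(out_seq), variant


def map_position(variant: VariantTranscript, pos: int) -> int:
    """Functional alias for :meth:`VariantTranscript.map_position`."""
    return variant.map_position(pos)


# ---------------------------------------------------------------------------
# Published human MEG3 coordinate models (transcript coordinates of variant v1)
# ---------------------------------------------------------------------------

MEG3_V1_LENGTH = 1595
MEG3_E5 = (936, 1049)
MEG3_DOMAINS: tuple[Interval, ...] = (
    ("D1", 2, 196),
    ("D2", 230, 410),
    ("D3", 471, 902),
    ("D4", 951, 1113),
    ("D5", 1116, 1486),
)
H11_LOOP = (366, 373)
H11_MOTIF = (368, 372)  # GUGAG
H27_REPEAT_REGION = (857, 885)  # six tandem repeats TR1-TR6


def meg3_v1_model() -> TranscriptModel:
    """Coordinate model of MEG3 variant v1 (1,595 nt, domains D1-D5)."""
    return TranscriptModel(name="v1", length=MEG3_V1_LENGTH, domains=MEG3_DOMAINS)


def meg3_v9_spec(model: TranscriptModel | None = None) -> VariantSpec:
    """v9: v1 minus exon E5 (nt 936-1049) -> 1,481 nt."""
    return VariantSpec(base=model or meg3_v1_model(), deletions=(MEG3_E5,), name="v9")


def meg3_v3_spec(model: TranscriptModel | None = None, e6_length: int = 141) -> VariantSpec:
    """v3: starts 24 nt downstream of v1 and carries variable exon E6.

    The E6 sequence is not modelled; it is stored as an opaque insertion whose
    default length (141 nt) reproduces the published v3 length of 1,712 nt.
    """
    return VariantSpec(
        base=model or meg3_v1_model(),
        deletions=((1, 24),),
        insertions=(Insertion(after=1049, length=e6_length, label="E6"),),
        name="v3",
    )
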