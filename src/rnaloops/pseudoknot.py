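"""Kissing-loop pseudoknot discovery and compensatory-mutant design.

A kissing loop is a pseudoknot formed by base pairing between a hairpin
terminal loop and a distal single-stranded region. The scanner enumerates
antiparallel complementary matches (Watson-Crick plus, optionally, G.U
wobble) between hairpin-loop windows and distal single-stranded windows,
reports each match as a pairing register, labels registers TR1..TRn in
5'->3' order of the repeat copies, and groups registers that compete for the
same loop nucleotides into mutually exclusive groups. Compensatory
(rescue) double mutants are designed by restoring Watson-Crick
complementarity at the repeat position paired with a mutated loop position.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, ParameterError
from .structure import SecondaryStructure
from .transcript import clean_rna

WC_PAIRS = {"AU", "UA", "GC", "CG"}
WOBBLE_PAIRS = {"GU", "UG"}
CANONICAL_PAIRS = WC_PAIRS | WOBBLE_PAIRS

_WC_PARTNER = {"A": "U", "U": "A", "G": "C", "C": "G"}


def pair_type(a: str, b: str, allow_wobble: bool = True) -> str | None:
    """"WC", "wobble", or None for an (a, b) base combination."""
    duo = a + b
    if duo in WC_PAIRS:
        return "WC"
    if allow_wobble and duo in WOBBLE_PAIRS:
        return "wobble"
    return None


@dataclass(frozen=True)
class ScanParams:
    """Scanner settings.

    k : window (motif) length.
    min_distance : minimum number of nucleotides between the loop window and
        the repeat window (long-range constraint).
    allow_wobble : accept G.U pairs in a register.
    max_unpaired_violations : paired positions tolerated inside a repeat
        window (0 demands a fully single-stranded repeat).
    max_mismatches : unpairable positions tolerated within a register.
    """

    k: int = 5
    min_distance: int = 100
    allow_wobble: bool = True
    max_unpaired_violations: int = 0
    max_mismatches: int = 0

    def __post_init__(self):
        if self.k < 3:
            raise ParameterError("motif length k must be >= 3")
        if self.min_distance < 0:
            raise ParameterError("min distance must be >= 0")


@dataclass(frozen=True)
class KissingRegister:
    """One loop <-> repeat pairing register (all coordinates 1-based).

    ``pairs`` holds (loop_pos, repeat_pos, type) with type "WC" or "wobble";
    the pairing is antiparallel and one-to-one. Registers sharing any loop
    position belong to one mutual-exclusivity group.
    """

    loop_interval: tuple[int, int]
    repeat_interval: tuple[int, int]
    pairs: tuple[tuple[int, int, str], ...]
    label: str = ""
    group: int = 0

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def loop_positions(self) -> set[int]:
        return set(range(self.loop_interval[0], self.loop_interval[1] + 1))

    def partner_of(self, loop_pos: int) -> tuple[int, str] | None:
        for lp, rp, typ in self.pairs:
            if lp == loop_pos:
                return rp, typ
        return None


def find_hairpin_loops(structure: SecondaryStructure) -> list[tuple[int, int]]:
    """Terminal (hairpin) loop intervals: the unpaired run closed by each
    innermost nested pair."""
    loops = []
    nested = structure.nested_pairs()
    for i, j in sorted(nested):
        if not any(i < a and b < j for a, b in nested):
            if j - i > 1:
                loops.append((i + 1, j - 1))
    return loops


def _window_register(
    seq: str,
    loop_window: tuple[int, int],
    repeat_window: tuple[int, int],
    params: ScanParams,
) -> tuple[tuple[int, int, str], ...] | None:
    """Pair list for an antiparallel alignment of two windows, or None."""
    k = params.k
    ls, rs = loop_window[0], repeat_window[0]
    pairs = []
    mismatches = 0
    for t in range(k):
        lp = ls + t
        rp = rs + (k - 1 - t)
        typ = pair_type(seq[lp - 1], seq[rp - 1], params.allow_wobble)
        if typ is None:
            mismatches += 1
            if mismatches > params.max_mismatches:
                return None
        else:
            pairs.append((lp, rp, typ))
    return tuple(pairs)


def scan_kissing(
    sequence: str,
    structure: SecondaryStructure,
    params: ScanParams | None = None,
) -> list[KissingRegister]:
    """Scan hairpin loops against distal single-stranded windows.

    Returns registers sorted 5'->3' by repeat start and labelled TR1..TRn;
    registers that overlap on loop positions share an exclusivity group.
    """
    params = params or ScanParams()
    seq = clean_rna(sequence)
    if len(seq) != structure.length:
        raise DataError("sequence/structure length mismatch")
    k = params.k
    table = structure.pair_table()
    paired = table[1:] > 0  # 0-based position -> paired?

    found: list[tuple[tuple[int, int], tuple[int, int], tuple]] = []
    for loop_start, loop_end in find_hairpin_loops(structure):
        if loop_end - loop_start + 1 < k:
            continue  # loop shorter than the motif: skipped
        for ls in range(loop_start, loop_end - k + 2):
            loop_win = (ls, ls + k - 1)
            for rs in range(1, len(seq) - k + 2):
                repeat_win = (rs, rs + k - 1)
                gap = max(rs - loop_win[1] - 1, loop_win[0] - repeat_win[1] - 1)
                if gap < params.min_distance:
                    continue
                violations = int(paired[rs - 1 : rs + k - 1].sum())
                if violations > params.max_unpaired_violations:
                    continue
                pairs = _window_register(seq, loop_win, repeat_win, params)
                if pairs is not None:
                    found.append((loop_win, repeat_win, pairs))

    found.sort(key=lambda item: (item[1][0], item[0][0]))

    # exclusivity groups: union-find over shared loop positions
    parents = list(range(len(found)))

    def root(x):
        while parents[x] != x:
            parents[x] = parents[parents[x]]
            x = parents[x]
        return x

    for a in range(len(found)):
        for b in range(a + 1, len(found)):
            la, lb = found[a][0], found[b][0]
            if la[0] <= lb[1] and lb[0] <= la[1]:
                parents[root(a)] = root(b)

    group_ids: dict[int, int] = {}
    registers = []
    for idx, (loop_win, repeat_win, pairs) in enumerate(found):
        r = root(idx)
        gid = group_ids.setdefault(r, len(group_ids))
        registers.append(
            KissingRegister(
                loop_interval=loop_win,
                repeat_interval=repeat_win,
                pairs=pairs,
                label=f"TR{idx + 1}",
                group=gid,
            )
        )
    return registers


@dataclass(frozen=True)
class CompensatoryDesign:
    """A repeat-side substitution restoring a register broken by a loop mutation."""

    register_label: str
    loop_position: int
    loop_from: str
    loop_to: str
    repeat_position: int
    repeat_from: str
    repeat_to: str

    @property
    def name(self) -> str:
        return (
            f"{self.loop_from}{self.loop_position}{self.loop_to}/"
            f"{self.repeat_from}{self.repeat_position}{self.repeat_to}"
        )


def design_compensatory(
    register: KissingRegister,
    loop_mutation: tuple[int, str, str],
    sequence: str | None = None,
) -> CompensatoryDesign | None:
    """Design the unique repeat-side rescue for a loop point mutation.

    The repeat base paired with the mutated loop position is replaced by the
    Watson-Crick complement of the new loop base. Returns None when the loop
    position is unpaired in this register.
    """
    pos, from_base, to_base = loop_mutation
    from_base = from_base.upper().replace("T", "U")
    to_base = to_base.upper().replace("T", "U")
    if not register.loop_interval[0] <= pos <= register.loop_interval[1]:
        raise ParameterError(
            f"mutation position {pos} outside loop interval {register.loop_interval}"
        )
    hit = register.partner_of(pos)
    if hit is None:
        return None
    repeat_pos, _ = hit
    repeat_from = sequence[repeat_pos - 1].upper().replace("T", "U") if sequence else "N"
    return CompensatoryDesign(
        register_label=register.label,
        loop_position=pos,
        loop_from=from_base,
        loop_to=to_base,
        repeat_position=repeat_pos,
        repeat_from=repeat_from,
        repeat_to=_WC_PARTNER[to_base],
    )


def design_all_compensatory(registers, loop_mutation, sequence=None):
    """One rescue design per register of a group (None entries dropped)."""
    designs = []
    for reg in registers:
        try:
            d = design_compensatory(reg, loop_mutation, sequence)
        except ParameterError:
            continue
        if d is not None:
            designs.append(d)
    return designs


# ---------------------------------------------------------------------------
# Alignment-based conservation and covariation
# ---------------------------------------------------------------------------

def _degap(row: str) -> str:
    return row.replace("-", "").replace(".", "").upper().replace("T", "U")


def count_motif_repeats(
    sequence: str, motif: str, allow_wobble: bool = True
) -> int:
    """Number of windows complementary (antiparallel, WC/wobble) to ``motif``."""
    seq = clean_rna(sequence)
    motif = clean_rna(motif)
    k = len(motif)
    count = 0
    for s in range(len(seq) - k + 1):
        ok = True
        for t in range(k):
            if pair_type(motif[t], seq[s + k - 1 - t], allow_wobble) is None:
                ok = False
                break
        if ok:
            count += 1
    return count


def repeat_conservation(
    alignment, motif: str, min_count: int = 3, allow_wobble: bool = True
) -> dict[str, tuple[int, bool]]:
    """Per-species motif-complement repeat counts and pass/fail at ``min_count``.

    ``alignment`` is a Biopython MultipleSeqAlignment; rows are degapped
    before counting.
    """
    if len(alignment) == 0:
        raise DataError("empty alignment")
    out: dict[str, tuple[int, bool]] = {}
    for record in alignment:
        n = count_motif_repeats(_degap(str(record.seq)), motif, allow_wobble)
        out[record.id] = (n, n >= min_count)
    return out


@dataclass(frozen=True)
class PairCovariation:
    """Covariation statistics for one alignment column pair (1-based columns)."""

    columns: tuple[int, int]
    fraction_canonical: float
    compensatory_count: int
    score: float
    e_value: float


def _column_pair_stats(col_i: np.ndarray, col_j: np.ndarray, weight: float):
    valid = np.array(
        [a in "ACGU" and b in "ACGU" for a, b in zip(col_i, col_j)], dtype=bool
    )
    n = int(valid.sum())
    if n == 0:
        return 0.0, 0, 0.0
    duos = [a + b for a, b, v in zip(col_i, col_j, valid) if v]
    canonical = [d in CANONICAL_PAIRS for d in duos]
    frac = sum(canonical) / n
    modal = Counter(duos).most_common(1)[0][0]
    comp = sum(
        1
        for d, c in zip(duos, canonical)
        if c and d[0] != modal[0] and d[1] != modal[1]
    )
    score = frac + weight * comp / n
    return frac, comp, score


def covariation(
    alignment,
    pairs,
    n_permutations: int = 200,
    weight: float = 2.0,
    seed: int = 0,
) -> list[PairCovariation]:
    """Score candidate column pairs for structure-supporting covariation.

    For each (i, j): the fraction of rows forming a canonical (WC or wobble)
    pair, the count of compensatory rows (canonical but differing from the
    modal pair at both columns), and a score ``fraction + weight *
    compensatory_fraction``. Significance comes from a permutation null that
    shuffles each column independently (preserving per-column composition);
    the E-value is the expected number of tested pairs reaching the observed
    score under the null (per-pair permutation p-value times the number of
    pairs tested).
    """
    if len(alignment) == 0:
        raise DataError("empty alignment")
    pairs = list(pairs)
    n_cols = alignment.get_alignment_length()
    for i, j in pairs:
        if not (1 <= i <= n_cols and 1 <= j <= n_cols):
            raise DataError(f"column pair ({i},{j}) outside alignment of {n_cols}")
    rows = [str(rec.seq).upper().replace("T", "U") for rec in alignment]
    matrix = np.array([list(r) for r in rows])
    rng = np.random.default_rng(seed)
    results = []
    n_pairs = len(pairs)
    for i, j in pairs:
        col_i = matrix[:, i - 1]
        col_j = matrix[:, j - 1]
        frac, comp, score = _column_pair_stats(col_i, col_j, weight)
        null_ge = 0
        for _ in range(n_permutations):
            pi = rng.permutation(col_i)
            pj = rng.permutation(col_j)
            _, _, null_score = _column_pair_stats(pi, pj, weight)
            if null_score >= score:
                null_ge += 1
        p_perm = null_ge / n_permutations if n_permutations else 1.0
        results.append(
            PairCovariation(
                columns=(i, j),
                fraction_canonical=frac,
                compensatory_count=comp,
                score=score,
                e_value=p_perm * n_pairs,
            )
        )
    return results


def registers_to_table(registers) -> str:
    lines = ["# label\tgroup\tloop_start\tloop_end\trepeat_start\trepeat_end\tpairs"]
    for r in registers:
        pair_str = ",".join(f"{lp}-{rp}:{typ}" for lp, rp, typ in r.pairs)
        lines.append(
            f"{r.label}\t{r.group}\t{r.loop_interval[0]}\t{r.loop_interval[1]}"
            f"\t{r.repeat_interval[0]}\t{r.repeat_interval[1]}\t{pair_str}"
        )
    return "\n".join(lines) + "\n"


def register_to_dotbracket(
    structure: SecondaryStructure, register: KissingRegister
) -> str:
    """Layered dot-bracket with the register's kissing pairs as '[]'."""
    from .structure import write_dotbracket

    decorated = structure.add_pseudoknot_pairs(
        (lp, rp) for lp, rp, _ in register.pairs
    )
    return write_dotbracket(decorated)
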