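"""Secondary-structure container and dot-bracket / CT text formats.

Structures hold a nested (secondary-structure) pair layer plus one optional
pseudoknot layer for kissing-loop output. Dot-bracket uses ``()`` for the
nested layer and ``[]`` for the pseudoknot layer; readers tolerate comment
lines starting with ``#``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError

NESTED = "nested"
PSEUDOKNOT = "pseudoknot"


@dataclass
class SecondaryStructure:
    """A set of base pairs (i, j), i < j, 1-based, in two layers.

    Invariants: every position occurs in at most one pair; nested-layer pairs
    are non-crossing among themselves; pseudoknot-layer pairs may cross nested
    pairs (that is what makes them a pseudoknot).
    """

    length: int
    pairs: set[tuple[int, int]] = field(default_factory=set)
    layer: dict[tuple[int, int], str] = field(default_factory=dict)

    def __post_init__(self):
        self.pairs = {(min(i, j), max(i, j)) for (i, j) in self.pairs}
        for p in self.pairs:
            self.layer.setdefault(p, NESTED)
        self._validate()

    def _validate(self):
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= self.length):
                raise FormatError(f"pair ({i},{j}) outside 1..{self.length}")
            if i in seen or j in seen:
                raise FormatError(f"position paired twice at pair ({i},{j})")
            seen.update((i, j))
        # stack check: nested-layer pairs must be non-crossing
        stack: list[int] = []
        for i, j in sorted(self.nested_pairs()):
            while stack and stack[-1] < i:
                stack.pop()
            if stack and j > stack[-1]:
                raise FormatError(f"nested-layer pair ({i},{j}) crosses another pair")
            stack.append(j)

    # -- queries ---------------------------------------------------------
    def nested_pairs(self) -> set[tuple[int, int]]:
        return {p for p in self.pairs if self.layer[p] == NESTED}

    def pseudoknot_pairs(self) -> set[tuple[int, int]]:
        return {p for p in self.pairs if self.layer[p] == PSEUDOKNOT}

    def pair_table(self) -> np.ndarray:
        """1-based partner table; ``table[i] == 0`` means unpaired; index 0 unused."""
        table = np.zeros(self.length + 1, dtype=np.int64)
        for i, j in self.pairs:
            table[i] = j
            table[j] = i
        return table

    def is_paired(self, pos: int) -> bool:
        return any(pos in p for p in self.pairs)

    def add_pseudoknot_pairs(self, pairs) -> "SecondaryStructure":
        """Return a copy with additional pseudoknot-layer pairs."""
        new_pairs = set(self.pairs)
        new_layer = dict(self.layer)
        for i, j in pairs:
            p = (min(i, j), max(i, j))
            new_pairs.add(p)
            new_layer[p] = PSEUDOKNOT
        return SecondaryStructure(self.length, new_pairs, new_layer)


_OPEN = {"(": NESTED, "[": PSEUDOKNOT}
_CLOSE = {")": "(", "]": "["}


def parse_dotbracket(text: str, length: int | None = None) -> SecondaryStructure:
    """Parse Vienna dot-bracket notation (``.()`` plus ``[]`` pseudoknot layer)."""
    text = "".join(
        line.strip() for line in text.splitlines() if not line.lstrip().startswith("#")
    )
    stacks: dict[str, list[int]] = {"(": [], "[": []}
    pairs: set[tuple[int, int]] = set()
    layer: dict[tuple[int, int], str] = {}
    for pos, char in enumerate(text, start=1):
        if char == ".":
            continue
        if char in _OPEN:
            stacks[char].append(pos)
        elif char in _CLOSE:
            opener = _CLOSE[char]
            if not stacks[opener]:
                raise FormatError(f"unbalanced {char!r} at position {pos}")
            i = stacks[opener].pop()
            pairs.add((i, pos))
            layer[(i, pos)] = _OPEN[opener]
        else:
            raise FormatError(f"invalid dot-bracket character {char!r} at {pos}")
    for opener, stack in stacks.items():
        if stack:
            raise FormatError(f"unbalanced {opener!r} at position {stack[-1]}")
    n = length if length is not None else len(text)
    if length is not None and len(text) != length:
        raise FormatError(f"dot-bracket length {len(text)} != expected {length}")
    return SecondaryStructure(n, pairs, layer)


def write_dotbracket(structure: SecondaryStructure) -> str:
    chars = ["."] * structure.length
    for (i, j), lay in structure.layer.items():
        if (i, j) in structure.pairs:
            if lay == NESTED:
                chars[i - 1], chars[j - 1] = "(", ")"
            else:
                chars[i - 1], chars[j - 1] = "[", "]"
    return "".join(chars)


def read_ct(text: str) -> tuple[str, SecondaryStructure]:
    """Read a connect-table (CT) file; returns (sequence, structure).

    Pseudoknot layering is reconstructed greedily: pairs crossing an already
    accepted nested pair go to the pseudoknot layer.
    """
    lines = [
        ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise FormatError("empty CT file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise FormatError("CT header must start with the sequence length") from exc
    if len(lines) - 1 < n:
        raise FormatError(f"CT body has fewer than {n} rows")
    seq = []
    raw_pairs: set[tuple[int, int]] = set()
    for ln in lines[1 : n + 1]:
        fields = ln.split()
        if len(fields) < 6:
            raise FormatError(f"CT row too short: {ln!r}")
        idx, base, partner = int(fields[0]), fields[1], int(fields[4])
        seq.append(base)
        if partner:
            raw_pairs.add((min(idx, partner), max(idx, partner)))
    nested: list[tuple[int, int]] = []
    layer: dict[tuple[int, int], str] = {}
    for i, j in sorted(raw_pairs):
        crossing = any(a < i <= b < j or i < a <= j < b for a, b in nested)
        if crossing:
            layer[(i, j)] = PSEUDOKNOT
        else:
            nested.append((i, j))
            layer[(i, j)] = NESTED
    return "".join(seq), SecondaryStructure(n, raw_pairs, layer)


def write_ct(sequence: str, structure: SecondaryStructure, name: str = "structure") -> str:
    if len(sequence) != structure.length:
        raise FormatError("sequence/structure length mismatch")
    table = structure.pair_table()
    rows = [f"{structure.length} {name}"]
    for i, base in enumerate(sequence, start=1):
        rows.append(f"{i} {base} {i - 1} {i + 1 if i < structure.length else 0} {table[i]} {i}")
    return "\n".join(rows) + "\n"
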