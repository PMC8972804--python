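"""Greedy conflict resolution and secondary-structure serialization.

Candidate pairs scoring at or above the cutoff (default 0.5) are sorted
by descending score and accepted greedily: a pair is kept only if
neither of its nucleotides belongs to an already-accepted pair.  There
is no dynamic programming and no planarity constraint, so crossing
(pseudoknotted) pairs survive; the dot-bracket writer spreads crossing
pairs over bracket levels () [] {} <> Aa Bb ...
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .scoring import DEFAULT_CUTOFF, PairScore
from .structure_io import StructureIndex

__all__ = [
    "SecondaryStructure",
    "assign",
    "to_dotbracket",
    "parse_dotbracket",
    "write_dbn", "read_dbn",
    "write_ct", "read_ct",
    "write_bpseq", "read_bpseq",
    "write_pairs", "read_pairs",
]

_OPEN = "([{<" + "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
_CLOSE = ")]}>" + "abcdefghijklmnopqrstuvwxyz"


@dataclass
class SecondaryStructure:
    """A conflict-free set of base pairs over one or more chains.

    Positions are global 0-based indices over the concatenated chains;
    ``chain_lengths`` records where chain breaks fall.
    """

    sequence: str
    pairs: set[tuple[int, int]] = field(default_factory=set)
    chain_lengths: tuple[int, ...] | None = None
    scores: dict[tuple[int, int], float] | None = None

    def __post_init__(self):
        if self.chain_lengths is None:
            self.chain_lengths = (len(self.sequence),)
        if sum(self.chain_lengths) != len(self.sequence):
            raise ValueError("chain_lengths do not sum to sequence length")
        self.pairs = {(min(i, j), max(i, j)) for (i, j) in self.pairs}
        used: set[int] = set()
        for i, j in self.pairs:
            if i == j:
                raise ValueError(f"self-pair at position {i}")
            if not (0 <= i < len(self.sequence) and 0 <= j < len(self.sequence)):
                raise ValueError(f"pair ({i}, {j}) out of range")
            for p in (i, j):
                if p in used:
                    raise ValueError(
                        f"position {p} occurs in more than one pair")
                used.add(p)

    def __len__(self) -> int:
        return len(self.sequence)

    def partner_array(self) -> list[int]:
        """partner[i] = paired position, or -1 if unpaired."""
        partner = [-1] * len(self.sequence)
        for i, j in self.pairs:
            partner[i] = j
            partner[j] = i
        return partner


def assign(scores: Iterable[PairScore], structure: StructureIndex | str,
           cutoff: float = DEFAULT_CUTOFF) -> SecondaryStructure:
    """Greedy conflict-free base-pair selection.

    Pairs with score >= cutoff are ranked by descending score (ties
    broken by smaller i, then smaller j, for determinism) and accepted
    iff neither nucleotide is already used by a higher-ranked pair.
    """
    if isinstance(structure, StructureIndex):
        sequence = structure.sequence
        chain_lengths = structure.chain_lengths
    else:
        sequence = structure
        chain_lengths = (len(structure),)
    ranked = sorted((s for s in scores if s.score >= cutoff),
                    key=lambda s: (-s.score, s.i, s.j))
    used: set[int] = set()
    accepted: set[tuple[int, int]] = set()
    accepted_scores: dict[tuple[int, int], float] = {}
    for s in ranked:
        if s.i in used or s.j in used:
            continue
        used.add(s.i)
        used.add(s.j)
        accepted.add((s.i, s.j))
        accepted_scores[(s.i, s.j)] = s.score
    return SecondaryStructure(sequence=sequence, pairs=accepted,
                              chain_lengths=chain_lengths,
                              scores=accepted_scores)


def _crosses(p: tuple[int, int], q: tuple[int, int]) -> bool:
    (i, j), (k, l) = p, q
    return (i < k < j < l) or (k < i < l < j)


def to_dotbracket(ss: SecondaryStructure) -> str:
    """Dot-bracket string, chains joined by '&'.

    Each pair goes to the lowest bracket level at which it crosses no
    already-assigned pair; nested pairs share level 0 and only genuine
    pseudoknots consume higher levels.
    """
    levels: list[list[tuple[int, int]]] = []
    for pair in sorted(ss.pairs):
        for lev, members in enumerate(levels):
            if not any(_crosses(pair, q) for q in members):
                members.append(pair)
                break
        else:
            if len(levels) >= len(_OPEN):
                raise ValueError("structure needs more bracket levels than "
                                 "the notation provides")
            levels.append([pair])
    chars = ["."] * len(ss.sequence)
    for lev, members in enumerate(levels):
        for i, j in members:
            chars[i] = _OPEN[lev]
            chars[j] = _CLOSE[lev]
    out = []
    pos = 0
    for li, ln in enumerate(ss.chain_lengths):
        if li:
            out.append("&")
        out.append("".join(chars[pos:pos + ln]))
        pos += ln
    return "".join(out)


def parse_dotbracket(db: str, sequence: str | None = None) -> SecondaryStructure:
    """Parse dot-bracket notation (with '&' chain separators) back into
    a :class:`SecondaryStructure`.  If ``sequence`` is omitted, 'N' is
    used for every position."""
    chain_lengths = tuple(len(part) for part in db.split("&"))
    flat = db.replace("&", "")
    if sequence is None:
        sequence = "N" * len(flat)
    else:
        sequence = sequence.replace("&", "")
        if len(sequence) != len(flat):
            raise ValueError("sequence and dot-bracket lengths differ")
    stacks: dict[int, list[int]] = {}
    pairs: set[tuple[int, int]] = set()
    for pos, ch in enumerate(flat):
        if ch == ".":
            continue
        if ch in _OPEN:
            stacks.setdefault(_OPEN.index(ch), []).append(pos)
        elif ch in _CLOSE:
            lev = _CLOSE.index(ch)
            if not stacks.get(lev):
                raise ValueError(f"unbalanced {ch!r} at position {pos}")
            pairs.add((stacks[lev].pop(), pos))
        else:
            raise ValueError(f"unexpected character {ch!r} at position {pos}")
    for lev, stack in stacks.items():
        if stack:
            raise ValueError(f"unclosed {_OPEN[lev]!r} at position {stack[-1]}")
    return SecondaryStructure(sequence=sequence, pairs=pairs,
                              chain_lengths=chain_lengths)


def _header_lines(header: str | None) -> list[str]:
    if not header:
        return []
    return [f"# {line}" for line in header.splitlines()]


def write_dbn(ss: SecondaryStructure, path: str | Path, name: str = "cssr",
              header: str | None = None) -> None:
    lines = _header_lines(header)
    seq = []
    pos = 0
    for li, ln in enumerate(ss.chain_lengths):
        if li:
            seq.append("&")
        seq.append(ss.sequence[pos:pos + ln])
        pos += ln
    lines += [f">{name}", "".join(seq), to_dotbracket(ss)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_dbn(path: str | Path) -> SecondaryStructure:
    lines = [ln for ln in Path(path).read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    if len(lines) >= 3 and lines[0].startswith(">"):
        return parse_dotbracket(lines[2], sequence=lines[1])
    if len(lines) >= 2 and not lines[0].startswith(">"):
        return parse_dotbracket(lines[1], sequence=lines[0])
    raise ValueError(f"{path}: malformed dot-bracket file")


def write_ct(ss: SecondaryStructure, path: str | Path, name: str = "cssr",
             header: str | None = None) -> None:
    """Standard 6-column connectivity-table format (1-based, 0 = unpaired).

    Chain breaks are encoded the usual way: the 3rd/4th columns (previous
    and next index) are 0 at chain boundaries.
    """
    partner = ss.partner_array()
    lines = _header_lines(header)
    lines.append(f"{len(ss.sequence):5d} {name}")
    starts = set()
    ends = set()
    pos = 0
    for ln in ss.chain_lengths:
        starts.add(pos)
        ends.add(pos + ln - 1)
        pos += ln
    for i, base in enumerate(ss.sequence):
        prev_i = 0 if i in starts else i
        next_i = 0 if i in ends else i + 2
        lines.append(f"{i + 1:5d} {base} {prev_i:5d} {next_i:5d} "
                     f"{partner[i] + 1:5d} {i + 1:5d}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_ct(path: str | Path) -> SecondaryStructure:
    lines = [ln for ln in Path(path).read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty CT file")
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise ValueError(f"{path}: malformed CT header") from exc
    if len(lines) - 1 < n:
        raise ValueError(f"{path}: CT file truncated ({len(lines) - 1} of {n} rows)")
    bases: list[str] = []
    pairs: set[tuple[int, int]] = set()
    breaks: list[int] = []
    for row, line in enumerate(lines[1:n + 1], start=1):
        f = line.split()
        if len(f) < 6:
            raise ValueError(f"{path}: row {row}: expected 6 columns")
        idx, base, prev_i, _next_i, pair = int(f[0]), f[1], int(f[2]), int(f[3]), int(f[4])
        if idx != row:
            raise ValueError(f"{path}: row {row}: unexpected index {idx}")
        bases.append(base)
        if prev_i == 0 and row > 1:
            breaks.append(row - 1)
        if pair and pair > idx:
            pairs.add((idx - 1, pair - 1))
    bounds = breaks + [n]
    chain_lengths = tuple(b - a for a, b in zip([0] + bounds[:-1], bounds))
    return SecondaryStructure(sequence="".join(bases), pairs=pairs,
                              chain_lengths=chain_lengths)


def write_bpseq(ss: SecondaryStructure, path: str | Path,
                header: str | None = None) -> None:
    """3-column BPSEQ (1-based position, base, partner or 0)."""
    partner = ss.partner_array()
    lines = _header_lines(header)
    for i, base in enumerate(ss.sequence):
        lines.append(f"{i + 1} {base} {partner[i] + 1}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_bpseq(path: str | Path) -> SecondaryStructure:
    bases: list[str] = []
    pairs: set[tuple[int, int]] = set()
    rows = [ln for ln in Path(path).read_text().splitlines()
            if ln.strip() and not ln.startswith("#")]
    for row, line in enumerate(rows, start=1):
        f = line.split()
        if len(f) != 3:
            raise ValueError(f"{path}: row {row}: expected 3 columns")
        idx, base, pair = int(f[0]), f[1], int(f[2])
        if idx != row:
            raise ValueError(f"{path}: row {row}: unexpected index {idx}")
        bases.append(base)
        if pair and pair > idx:
            pairs.add((idx - 1, pair - 1))
    return SecondaryStructure(sequence="".join(bases), pairs=pairs)


def write_pairs(ss: SecondaryStructure, path: str | Path,
                header: str | None = None) -> None:
    """List format: 1-based i, j and the assignment score of each pair."""
    lines = _header_lines(header)
    lines.append(f"# sequence: {ss.sequence}")
    lines.append(f"# chain_lengths: {','.join(map(str, ss.chain_lengths))}")
    lines.append("i\tj\tscore")
    for i, j in sorted(ss.pairs):
        score = (ss.scores or {}).get((i, j), float("nan"))
        lines.append(f"{i + 1}\t{j + 1}\t{score:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pairs(path: str | Path) -> SecondaryStructure:
    sequence = None
    chain_lengths = None
    pairs: set[tuple[int, int]] = set()
    scores: dict[tuple[int, int], float] = {}
    for line in Path(path).read_text().splitlines():
        if line.startswith("# sequence:"):
            sequence = line.split(":", 1)[1].strip()
        elif line.startswith("# chain_lengths:"):
            chain_lengths = tuple(int(x) for x in
                                  line.split(":", 1)[1].strip().split(","))
        elif line.startswith("#") or not line.strip() or line.startswith("i\t"):
            continue
        else:
            f = line.split("\t")
            i, j = int(f[0]) - 1, int(f[1]) - 1
            pairs.add((i, j))
            if len(f) > 2:
                scores[(i, j)] = float(f[2])
    if sequence is None:
        raise ValueError(f"{path}: missing '# sequence:' line")
    return SecondaryStructure(sequence=sequence, pairs=pairs,
                              chain_lengths=chain_lengths, scores=scores)
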