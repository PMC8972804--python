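"""Read and write coarse-grained RNA structures.

The tool represents each nucleotide by a sparse subset of ten atom types:
the phosphate P, the backbone/sugar heavy atoms C5', C4', C3', C2', C1',
O5', O4', O3', and the glycosidic nitrogen N (N9 in purines, N1 in
pyrimidines).  Any nucleotide carrying at least one of these atoms is
retained; everything else (bases' ring atoms, protein, water, ligands) is
discarded.  Parsing of PDB and mmCIF is delegated to gemmi.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "ATOM_TYPES",
    "UNKNOWN",
    "CoarseNucleotide",
    "RnaChain",
    "StructureIndex",
    "StructureParseError",
    "NoRnaError",
    "read_structure",
    "write_structure",
]

logger = logging.getLogger(__name__)

#: The ten recognized atom types.  "N" is the glycosidic nitrogen.
ATOM_TYPES: tuple[str, ...] = (
    "P", "C5'", "C4'", "C3'", "C2'", "C1'", "O5'", "O4'", "O3'", "N",
)

UNKNOWN = "X"

#: Modified-residue names mapped to parent bases, for components absent
#: from gemmi's tabulated list (gemmi resolves most, e.g. PSU -> u).
MODIFIED_RESIDUES: dict[str, str] = {
    "5MC": "C",
    "4SU": "U",
    "2MU": "U",
    "70U": "U",
    "I": "G",   # inosine pairs like G for canonical purposes
}

_STANDARD = {"A": "A", "C": "C", "G": "G", "U": "U"}


class StructureParseError(ValueError):
    """A structure file could not be parsed."""


class NoRnaError(ValueError):
    """The file parsed but contains no RNA residues."""


@dataclass
class CoarseNucleotide:
    """One residue: identity, position in the chain, sparse coordinates."""

    chain_id: str
    seq_index: int
    residue_number: str   # author residue number + insertion code
    base: str             # A, C, G, U or UNKNOWN ("X")
    coords: dict[str, np.ndarray] = field(default_factory=dict)

    def has(self, atom: str) -> bool:
        return atom in self.coords


@dataclass
class RnaChain:
    """An ordered RNA chain of coarse nucleotides.

    ``breaks`` holds local indices *i* such that adjacency between
    nucleotides i-1 and i is broken (a residue with no retained atoms was
    dropped between them).
    """

    chain_id: str
    nucleotides: list[CoarseNucleotide] = field(default_factory=list)
    breaks: set[int] = field(default_factory=set)

    @property
    def sequence(self) -> str:
        return "".join(nt.base for nt in self.nucleotides)

    def __len__(self) -> int:
        return len(self.nucleotides)

    def adjacent(self, i: int, j: int) -> bool:
        """True if local positions i and j are sequence neighbors."""
        if abs(i - j) != 1:
            return False
        return max(i, j) not in self.breaks


class StructureIndex:
    """Flat view over a list of chains with global 0-based positions."""

    def __init__(self, chains: Sequence[RnaChain]):
        self.chains = list(chains)
        self._nts: list[CoarseNucleotide] = []
        self._chain_of: list[int] = []
        self._local: list[int] = []
        self._start: list[int] = []
        pos = 0
        for ci, chain in enumerate(self.chains):
            self._start.append(pos)
            for li, nt in enumerate(chain.nucleotides):
                self._nts.append(nt)
                self._chain_of.append(ci)
                self._local.append(li)
                pos += 1
        self.sequence = "".join(c.sequence for c in self.chains)
        self.chain_lengths = tuple(len(c) for c in self.chains)

    def __len__(self) -> int:
        return len(self._nts)

    def nucleotide(self, pos: int) -> CoarseNucleotide:
        return self._nts[pos]

    def base(self, pos: int) -> str:
        return self._nts[pos].base

    def chain_index(self, pos: int) -> int:
        return self._chain_of[pos]

    def coord(self, pos: int | None, atom: str) -> np.ndarray | None:
        if pos is None:
            return None
        return self._nts[pos].coords.get(atom)

    def neighbor(self, pos: int, step: int) -> int | None:
        """Global position of the sequence neighbor at ±1, or None."""
        q = pos + step
        if q < 0 or q >= len(self._nts):
            return None
        ci = self._chain_of[pos]
        if self._chain_of[q] != ci:
            return None
        chain = self.chains[ci]
        if not chain.adjacent(self._local[pos], self._local[q]):
            return None
        return q


def _normalize_atom_name(name: str) -> str:
    return name.strip().replace("*", "'")


def _map_base(resname: str) -> str:
    resname = resname.strip().upper()
    if resname in _STANDARD:
        return _STANDARD[resname]
    if resname in MODIFIED_RESIDUES:
        return MODIFIED_RESIDUES[resname]
    info = gemmi.find_tabulated_residue(resname)
    if info is not None and info.found() and info.kind == gemmi.ResidueKind.RNA:
        code = info.one_letter_code.upper()
        if code in _STANDARD:
            return code
        return UNKNOWN
    return UNKNOWN


def _is_rna_candidate(res: gemmi.Residue) -> bool:
    """Heuristic: residue is RNA-like (not protein/DNA/water/ligand)."""
    name = res.name.strip().upper()
    info = gemmi.find_tabulated_residue(name)
    if info is not None and info.found():
        if info.is_water() or info.is_amino_acid():
            return False
        if info.kind == gemmi.ResidueKind.DNA:
            return False
        if info.kind == gemmi.ResidueKind.RNA:
            return True
        if info.is_standard():
            return False
    if name.startswith("D") and name[1:] in _STANDARD:
        return False
    # unknown component: accept only if it has a ribose-like atom inventory
    names = {_normalize_atom_name(a.name) for a in res}
    return bool({"C1'", "C2'", "C3'", "C4'", "O4'", "O2'"} & names)


def _retained_atoms(res: gemmi.Residue, base: str,
                    atom_subset: set[str] | None) -> dict[str, np.ndarray]:
    # glycosidic N: N9 for purines, N1 for pyrimidines; for unknown bases
    # prefer N9 when present (purine-like), else N1
    raw: dict[str, list[gemmi.Atom]] = {}
    for atom in res:
        raw.setdefault(_normalize_atom_name(atom.name), []).append(atom)

    if base in ("A", "G"):
        n_source = "N9"
    elif base in ("C", "U"):
        n_source = "N1"
    else:
        n_source = "N9" if "N9" in raw else "N1"

    coords: dict[str, np.ndarray] = {}
    for atype in ATOM_TYPES:
        if atom_subset is not None and atype not in atom_subset:
            continue
        source = n_source if atype == "N" else atype
        candidates = raw.get(source)
        if not candidates:
            continue
        # alternate locations: highest occupancy wins, ties -> first in file
        best = max(candidates, key=lambda a: a.occ if a.occ is not None else 1.0)
        coords[atype] = np.array([best.pos.x, best.pos.y, best.pos.z], dtype=float)
    return coords


def read_structure(path: str | Path, model_index: int = 0,
                   atom_subset: Iterable[str] | None = None) -> list[RnaChain]:
    """Parse a PDB or mmCIF file into coarse-grained RNA chains.

    Parameters
    ----------
    path:
        PDB or mmCIF file; the dialect is auto-detected.
    model_index:
        Which model of a multi-model file to use (default: first).
    atom_subset:
        Optional subset of :data:`ATOM_TYPES` to retain, e.g. ``{"P"}``
        for a phosphate-only trace.  ``None`` keeps all ten types.

    Returns
    -------
    list of :class:`RnaChain`, one per chain containing at least one
    ribonucleotide with at least one retained atom.
    """
    path = Path(path)
    subset = None
    if atom_subset is not None:
        subset = set(atom_subset)
        bad = subset - set(ATOM_TYPES)
        if bad:
            raise ValueError(f"unrecognized atom types: {sorted(bad)}")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{path}: file contains no models")
    if model_index >= len(st):
        raise ValueError(
            f"model_index {model_index} out of range: file has {len(st)} model(s)")
    model = st[model_index]

    chains: list[RnaChain] = []
    saw_rna = False
    for gchain in model:
        chain = RnaChain(chain_id=gchain.name)
        pending_break = False
        for res in gchain:
            if not _is_rna_candidate(res):
                continue
            saw_rna = True
            base = _map_base(res.name)
            coords = _retained_atoms(res, base, subset)
            resnum = f"{res.seqid.num}{res.seqid.icode}".strip()
            if not coords:
                logger.warning(
                    "dropping residue %s %s/%s: no retained atoms",
                    res.name, gchain.name, resnum)
                if chain.nucleotides:
                    pending_break = True
                continue
            idx = len(chain.nucleotides)
            if pending_break:
                chain.breaks.add(idx)
                pending_break = False
            chain.nucleotides.append(CoarseNucleotide(
                chain_id=gchain.name, seq_index=idx,
                residue_number=resnum, base=base, coords=coords))
        if chain.nucleotides:
            chains.append(chain)
    if not chains:
        if saw_rna:
            raise NoRnaError(
                f"{path}: RNA residues found but none retained any of the "
                f"recognized atom types")
        raise NoRnaError(f"{path}: no RNA residues found")
    return chains


def _pdb_atom_name(atype: str, base: str) -> str:
    if atype == "N":
        return "N9" if base in ("A", "G") else "N1"
    return atype


def write_structure(chains: Sequence[RnaChain], path: str | Path) -> None:
    """Write chains as a PDB file (ATOM/TER records, fixed-width columns)."""
    chains = list(chains)
    if not chains:
        raise ValueError("cannot write an empty chain list")
    for chain in chains:
        for nt in chain.nucleotides:
            if not nt.coords:
                raise ValueError(
                    f"nucleotide {chain.chain_id}/{nt.residue_number} has no "
                    f"coordinates")
    lines: list[str] = []
    serial = 1
    for chain in chains:
        cid = (chain.chain_id or "A")[0]
        last = None
        for nt in chain.nucleotides:
            resname = nt.base if nt.base in _STANDARD else "UNK"
            try:
                resseq = int("".join(ch for ch in nt.residue_number
                                     if ch.isdigit() or ch == "-"))
            except ValueError:
                resseq = nt.seq_index + 1
            icode = nt.residue_number[-1] if nt.residue_number[-1:].isalpha() else " "
            for atype in ATOM_TYPES:
                if atype not in nt.coords:
                    continue
                name = _pdb_atom_name(atype, nt.base)
                x, y, z = nt.coords[atype]
                # single-character elements: name starts in column 14
                lines.append(
                    f"ATOM  {serial:5d}  {name:<3s} {resname:>3s} {cid}"
                    f"{resseq:4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"  1.00  0.00          {name[0]:>2s}")
                serial += 1
            last = (resname, resseq, icode)
        if last is not None:
            resname, resseq, icode = last
            lines.append(
                f"TER   {serial:5d}      {resname:>3s} {cid}{resseq:4d}{icode}")
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
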