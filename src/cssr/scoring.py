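"""Base-pairing scores for candidate nucleotide pairs.

For a candidate pair (i, j) the score averages, with equal weight, one
Gaussian agreement kernel per evaluable geometry sub-term:

    contribution = exp(-delta^2 / (2 sigma^2))

where delta is the deviation of the observed sub-term value from its
calibrated mean (on the circle for angles and dihedrals) and sigma the
calibrated spread.  The score is 1 for perfect helix-like geometry and
decays towards 0; sub-terms that cannot be evaluated because of missing
atoms or neighbors are skipped and the mean renormalizes over what is
left, which is what makes the score usable down to one atom per
nucleotide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .geometry import GeometryError, angle, angular_difference, dihedral, distance
from .params import GeometryParams, TERM_KINDS, is_angular, pair_class
from .structure_io import ATOM_TYPES, RnaChain, StructureIndex

__all__ = [
    "PairScore",
    "candidate_pairs",
    "term_value",
    "cssr_score",
    "score_structure",
]

DEFAULT_MIN_SEPARATION = 4
DEFAULT_CUTOFF = 0.5


@dataclass(frozen=True)
class PairScore:
    """A scored candidate pair (global 0-based positions, i < j)."""

    i: int
    j: int
    score: float
    n_terms: int
    pair_class: str


def candidate_pairs(chains: Sequence[RnaChain] | StructureIndex,
                    min_separation: int = DEFAULT_MIN_SEPARATION,
                    inter_chain: bool = False) -> list[tuple[int, int]]:
    """Enumerate nucleotide pairs eligible for scoring.

    A pair qualifies when both nucleotides carry at least one recognized
    atom, the two bases are compatible with canonical (Watson–Crick or
    wobble) pairing, and — within a chain — the positions are at least
    ``min_separation`` apart.  Pairs between different chains are
    included only with ``inter_chain=True``.
    """
    index = chains if isinstance(chains, StructureIndex) else StructureIndex(chains)
    n = len(index)
    out: list[tuple[int, int]] = []
    for i in range(n):
        if not index.nucleotide(i).coords:
            continue
        for j in range(i + 1, n):
            if not index.nucleotide(j).coords:
                continue
            same_chain = index.chain_index(i) == index.chain_index(j)
            if same_chain:
                sep = (index.nucleotide(j).seq_index
                       - index.nucleotide(i).seq_index)
                if abs(sep) < min_separation:
                    continue
            elif not inter_chain:
                continue
            if pair_class(index.base(i), index.base(j)) is None:
                continue
            out.append((i, j))
    return out


def term_value(index: StructureIndex, i: int, j: int,
               atom: str, kind: str) -> float | None:
    """Raw value of one geometry sub-term, or None when not evaluable.

    A sub-term is not evaluable when a required atom is missing from a
    nucleotide, a required sequence neighbor does not exist (chain end or
    break), or the configuration is geometrically degenerate.
    """
    a_i = index.coord(i, atom)
    a_j = index.coord(j, atom)
    if a_i is None or a_j is None:
        return None
    ip1 = index.coord(index.neighbor(i, +1), atom)
    im1 = index.coord(index.neighbor(i, -1), atom)
    jp1 = index.coord(index.neighbor(j, +1), atom)
    jm1 = index.coord(index.neighbor(j, -1), atom)
    try:
        if kind == "dis0":
            return distance(a_i, a_j)
        if kind == "dis_up":
            return None if ip1 is None or jm1 is None else distance(ip1, jm1)
        if kind == "dis_down":
            return None if im1 is None or jp1 is None else distance(im1, jp1)
        if kind == "ang_i":
            return None if ip1 is None else angle(ip1, a_i, a_j)
        if kind == "ang_j":
            return None if jm1 is None else angle(jm1, a_j, a_i)
        if kind == "dih_i":
            if ip1 is None or jm1 is None:
                return None
            return dihedral(ip1, a_i, a_j, jm1)
        if kind == "dih_j":
            if jp1 is None or im1 is None:
                return None
            return dihedral(jp1, a_j, a_i, im1)
    except GeometryError:
        return None
    raise ValueError(f"unknown sub-term kind {kind!r}")


def _kernel(value: float, mean: float, sigma: float, angular: bool) -> float:
    delta = angular_difference(value, mean) if angular else value - mean
    return math.exp(-(delta * delta) / (2.0 * sigma * sigma))


def cssr_score(index: StructureIndex, i: int, j: int,
               params: GeometryParams,
               nested_mean: bool = False) -> PairScore | None:
    """Score one candidate pair against calibrated geometry statistics.

    Returns None when the pair's bases are not canonically compatible or
    when no sub-term is evaluable with the given parameters.  The pair is
    canonicalized to i < j internally, so the score is exactly symmetric.

    ``nested_mean=True`` averages per atom type first and then across
    atom types, instead of the default flat mean over all sub-terms.
    """
    if i == j:
        raise ValueError("a nucleotide cannot pair with itself")
    if i > j:
        i, j = j, i
    cls = pair_class(index.base(i), index.base(j))
    if cls is None:
        return None
    contributions_by_atom: list[list[float]] = []
    n_terms = 0
    for atom in ATOM_TYPES:
        atom_contribs: list[float] = []
        for kind in TERM_KINDS:
            stats = params.get(cls, atom, kind)
            if stats is None:
                continue
            v = term_value(index, i, j, atom, kind)
            if v is None:
                continue
            atom_contribs.append(_kernel(v, stats.mean, stats.sigma,
                                         is_angular(kind)))
        if atom_contribs:
            contributions_by_atom.append(atom_contribs)
            n_terms += len(atom_contribs)
    if n_terms == 0:
        return None
    if nested_mean:
        score = sum(sum(c) / len(c) for c in contributions_by_atom) \
            / len(contributions_by_atom)
    else:
        score = sum(sum(c) for c in contributions_by_atom) / n_terms
    return PairScore(i=i, j=j, score=score, n_terms=n_terms, pair_class=cls)


def score_structure(chains: Sequence[RnaChain] | StructureIndex,
                    params: GeometryParams,
                    min_separation: int = DEFAULT_MIN_SEPARATION,
                    inter_chain: bool = False,
                    min_terms: int = 1,
                    nested_mean: bool = False) -> list[PairScore]:
    """Score every candidate pair of a structure.

    ``min_terms`` discards pairs whose score rests on fewer than that
    many evaluable sub-terms.
    """
    index = chains if isinstance(chains, StructureIndex) else StructureIndex(chains)
    scores: list[PairScore] = []
    for i, j in candidate_pairs(index, min_separation=min_separation,
                                inter_chain=inter_chain):
        ps = cssr_score(index, i, j, params, nested_mean=nested_mean)
        if ps is not None and ps.n_terms >= min_terms:
            scores.append(ps)
    return scores
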