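"""Synthetic RNA coordinate fixtures with known secondary structure.

The generator places nucleotides on an idealized, exactly periodic
double helix described by cylindrical per-atom templates: atom type *a*
of the nucleotide at helix step *k* sits at

    angle = k * twist + phase_a        (leading strand)
    angle = k * twist + pair_phase - phase_a   (complementary strand)
    z     = k * rise  ± z_a
    (x, y) = radius_a * (cos angle, sin angle)

The template constants are A-form-like (rise 2.81 Å, twist 32.7°) but
idealized: the pipeline only requires that calibration and test
fixtures share internally consistent geometry, not that the fixtures
reproduce literature atomic coordinates.  G:U wobble pairs displace the
U nucleotide slightly (phase and rise offsets), giving the wobble class
its own geometry statistics, as in real helices.

Hairpins and H-type pseudoknots are assembled from duplex blocks; the
single-stranded residues flanking each stem are pinned to the exact
helix-continuation positions, so stem-edge pairs keep ideal geometry,
while remaining linker/loop residues are arched between the pinned
anchors.  Gaussian coordinate noise emulates the coordinate uncertainty
of low-resolution experimental structures.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .assignment import SecondaryStructure
from .params import pair_class
from .structure_io import ATOM_TYPES, CoarseNucleotide, RnaChain

__all__ = [
    "HelixSpec", "DEFAULT_HELIX",
    "make_duplex", "make_hairpin", "make_pseudoknot",
    "add_noise", "subset_atoms", "random_stem",
    "make_benchmark", "make_calibration_set",
]

_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class HelixSpec:
    """Geometry of the ideal helix: global constants plus one
    (radius Å, phase °, z-offset Å) template per atom type."""

    rise: float = 2.81
    twist: float = 32.7
    pair_phase: float = 154.0
    templates: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_TEMPLATES))
    #: extra phase (degrees) and rise (Å) applied to the U of a G:U pair
    wobble_phase_shift: float = 4.0
    wobble_z_shift: float = 0.3


_DEFAULT_TEMPLATES: dict[str, tuple[float, float, float]] = {
    "P":   (9.2,  0.0,  1.0),
    "O5'": (8.9,  6.0,  0.8),
    "C5'": (8.9, 12.0,  0.6),
    "C4'": (9.1, 18.0,  0.4),
    "C3'": (9.4, 10.0, -0.2),
    "O3'": (9.7, 14.0, -0.7),
    "C2'": (9.0, 26.0,  0.1),
    "O4'": (8.6, 24.0,  0.7),
    "C1'": (8.9, 32.0,  0.3),
    "N":   (7.2, 40.0,  0.1),
}

DEFAULT_HELIX = HelixSpec()


def _atom_coords(spec: HelixSpec, step: float, sense: int,
                 wobble: bool) -> dict[str, np.ndarray]:
    coords = {}
    for atom, (radius, phase, dz) in spec.templates.items():
        ang = step * spec.twist + (phase if sense > 0
                                   else spec.pair_phase - phase)
        z = step * spec.rise + sense * dz
        if wobble:
            ang += spec.wobble_phase_shift
            z += spec.wobble_z_shift
        rad = math.radians(ang)
        coords[atom] = np.array([radius * math.cos(rad),
                                 radius * math.sin(rad), z])
    return coords


def _nt(chain: RnaChain, base: str, coords: dict[str, np.ndarray]) -> None:
    chain.nucleotides.append(CoarseNucleotide(
        chain_id=chain.chain_id, seq_index=len(chain.nucleotides),
        residue_number=str(len(chain.nucleotides) + 1), base=base,
        coords=coords))


def _pair_coords(spec: HelixSpec, step: float, base5: str, base3: str):
    """Coordinates for the two partners of one helix step; the U of a
    G:U wobble pair carries the wobble displacement."""
    wob = pair_class(base5, base3) == "WOBBLE"
    c5 = _atom_coords(spec, step, +1, wobble=wob and base5 == "U")
    c3 = _atom_coords(spec, step, -1, wobble=wob and base3 == "U")
    return c5, c3


def make_duplex(seq_a: str, seq_b: str | None = None,
                spec: HelixSpec = DEFAULT_HELIX,
                ) -> tuple[list[RnaChain], SecondaryStructure]:
    """An ideal antiparallel duplex of two chains.

    ``seq_b`` (5'→3') defaults to the Watson–Crick reverse complement of
    ``seq_a``.  Position k of chain A pairs position L-1-k of chain B;
    every step must form a canonical (WC or wobble) pair.
    """
    L = len(seq_a)
    if L < 2:
        raise ValueError("duplex needs length >= 2")
    if seq_b is None:
        seq_b = "".join(_COMPLEMENT[b] for b in reversed(seq_a))
    if len(seq_b) != L:
        raise ValueError("strand lengths differ")
    chain_a = RnaChain(chain_id="A")
    chain_b = RnaChain(chain_id="B")
    coords_b: list[dict[str, np.ndarray]] = []
    for k, base5 in enumerate(seq_a):
        base3 = seq_b[L - 1 - k]
        if pair_class(base5, base3) is None:
            raise ValueError(
                f"step {k}: {base5}:{base3} is not a canonical pair")
        c5, c3 = _pair_coords(spec, k, base5, base3)
        _nt(chain_a, base5, c5)
        coords_b.append(c3)
    for m, base in enumerate(seq_b):          # chain B runs 5'→3', step L-1-m
        _nt(chain_b, base, coords_b[L - 1 - m])
    gt = SecondaryStructure(
        sequence=seq_a + seq_b, chain_lengths=(L, L),
        pairs={(k, 2 * L - 1 - k) for k in range(L)})
    return [chain_a, chain_b], gt


def _bridge(first: dict[str, np.ndarray], last: dict[str, np.ndarray],
            n_mid: int, bulge: float = 5.0) -> list[dict[str, np.ndarray]]:
    """Arched interpolation between two pinned anchor residues."""
    d = last["P"] - first["P"] if "P" in first else None
    if d is None:
        any_atom = next(iter(first))
        d = last[any_atom] - first[any_atom]
    # bulge direction: perpendicular component of z-axis, else x-axis
    zhat = np.array([0.0, 0.0, 1.0])
    norm_d = np.linalg.norm(d)
    perp = zhat - (np.dot(zhat, d) / norm_d**2) * d if norm_d > 1e-9 else zhat
    if np.linalg.norm(perp) < 1e-6:
        perp = np.array([1.0, 0.0, 0.0])
    perp = perp / np.linalg.norm(perp)
    out = []
    for t in range(1, n_mid + 1):
        u = t / (n_mid + 1)
        offset = bulge * math.sin(math.pi * u) * perp
        out.append({a: (1 - u) * first[a] + u * last[a] + offset
                    for a in first})
    return out


def make_hairpin(stem_length: int, loop_length: int,
                 spec: HelixSpec = DEFAULT_HELIX,
                 stem_pairs: Sequence[tuple[str, str]] | None = None,
                 loop_seq: str | None = None,
                 rng: np.random.Generator | int | None = None,
                 wobble_frac: float = 0.0,
                 ) -> tuple[list[RnaChain], SecondaryStructure]:
    """A single-chain stem-loop: ideal-duplex stem plus an arched loop.

    The first and last loop residues sit exactly at the helix
    continuation of the two stem strands, so the loop-closing pair keeps
    ideal geometry; interior loop residues are arched between them.
    ``stem_pairs`` lists (5'-base, 3'-base) per stem step, outermost
    first; when omitted the stem is drawn randomly from ``rng`` with a
    ``wobble_frac`` chance of G:U per step.  The loop sequence defaults
    to all-A (self-incompatible, so it cannot introduce phantom pairs).
    """
    if loop_length < 3:
        raise ValueError("loop_length must be >= 3")
    if stem_length < 1:
        raise ValueError("stem_length must be >= 1")
    if stem_pairs is None:
        stem_pairs = random_stem(stem_length, rng=rng, wobble_frac=wobble_frac)
    if len(stem_pairs) != stem_length:
        raise ValueError("stem_pairs length mismatch")
    if loop_seq is None:
        loop_seq = "A" * loop_length
    if len(loop_seq) != loop_length:
        raise ValueError("loop_seq length mismatch")

    chain = RnaChain(chain_id="A")
    coords3: list[dict[str, np.ndarray]] = []
    for k, (b5, b3) in enumerate(stem_pairs):
        if pair_class(b5, b3) is None:
            raise ValueError(f"stem step {k}: {b5}:{b3} not canonical")
        c5, c3 = _pair_coords(spec, k, b5, b3)
        _nt(chain, b5, c5)
        coords3.append(c3)
    s = stem_length
    first = _atom_coords(spec, s, +1, wobble=False)
    last = _atom_coords(spec, s, -1, wobble=False)
    _nt(chain, loop_seq[0], first)
    for t, coords in enumerate(_bridge(first, last, loop_length - 2)):
        _nt(chain, loop_seq[1 + t], coords)
    _nt(chain, loop_seq[-1], last)
    for k in range(s - 1, -1, -1):
        _nt(chain, stem_pairs[k][1], coords3[k])
    gt = SecondaryStructure(
        sequence=chain.sequence, chain_lengths=(len(chain),),
        pairs={(t, 2 * s + loop_length - 1 - t) for t in range(s)})
    return [chain], gt


def _transform(coords: dict[str, np.ndarray], rot: np.ndarray,
               trans: np.ndarray) -> dict[str, np.ndarray]:
    return {a: rot @ p + trans for a, p in coords.items()}


def make_pseudoknot(stem1: int, stem2: int,
                    linkers: tuple[int, int, int] = (3, 3, 3),
                    spec: HelixSpec = DEFAULT_HELIX,
                    rng: np.random.Generator | int | None = None,
                    wobble_frac: float = 0.0,
                    ) -> tuple[list[RnaChain], SecondaryStructure]:
    """A single-chain H-type pseudoknot with crossing ground-truth pairs.

    Layout 5'→3': stem1-5' | linker1 | stem2-5' | linker2 | stem1-3' |
    linker3 | stem2-3'.  Each stem is an ideal duplex block; block 2 is
    rigidly rotated and translated away from block 1.  Linker residues
    adjacent to stem ends are pinned to helix-continuation positions
    (preserving ideal stem-edge geometry); the rest are arched.
    """
    if stem1 < 2 or stem2 < 2:
        raise ValueError("stems must be >= 2 bp")
    l1, l2, l3 = linkers
    if min(linkers) < 2:
        raise ValueError("linkers must be >= 2 nt so both ends can be pinned")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    pairs1 = random_stem(stem1, rng=rng, wobble_frac=wobble_frac)
    pairs2 = random_stem(stem2, rng=rng, wobble_frac=wobble_frac)

    theta = math.radians(75.0)
    rot2 = np.array([[math.cos(theta), 0.0, math.sin(theta)],
                     [0.0, 1.0, 0.0],
                     [-math.sin(theta), 0.0, math.cos(theta)]])
    trans2 = np.array([38.0, 7.0, -11.0])

    def coords1(step: float, sense: int, wobble: bool = False):
        return _atom_coords(spec, step, sense, wobble)

    def coords2(step: float, sense: int, wobble: bool = False):
        return _transform(_atom_coords(spec, step, sense, wobble), rot2, trans2)

    def stem_coords(pairs, coords_fn):
        c5s, c3s = [], []
        for k, (b5, b3) in enumerate(pairs):
            wob = pair_class(b5, b3) == "WOBBLE"
            c5s.append(coords_fn(k, +1, wob and b5 == "U"))
            c3s.append(coords_fn(k, -1, wob and b3 == "U"))
        return c5s, c3s

    c5_1, c3_1 = stem_coords(pairs1, coords1)
    c5_2, c3_2 = stem_coords(pairs2, coords2)

    chain = RnaChain(chain_id="A")

    def add_linker(n: int, first: dict, last: dict) -> None:
        _nt(chain, "A", first)
        for coords in _bridge(first, last, n - 2):
            _nt(chain, "A", coords)
        _nt(chain, "A", last)

    for k in range(stem1):                      # stem1 5' side
        _nt(chain, pairs1[k][0], c5_1[k])
    add_linker(l1, coords1(stem1, +1), coords2(-1, +1))
    for k in range(stem2):                      # stem2 5' side
        _nt(chain, pairs2[k][0], c5_2[k])
    add_linker(l2, coords2(stem2, +1), coords1(stem1, -1))
    s1p_start = stem1 + l1 + stem2 + l2
    for k in range(stem1 - 1, -1, -1):          # stem1 3' side
        _nt(chain, pairs1[k][1], c3_1[k])
    add_linker(l3, coords1(-1, -1), coords2(stem2, -1))
    s2p_start = s1p_start + stem1 + l3
    for k in range(stem2 - 1, -1, -1):          # stem2 3' side
        _nt(chain, pairs2[k][1], c3_2[k])

    pairs = {(t, s1p_start + stem1 - 1 - t) for t in range(stem1)}
    pairs |= {(stem1 + l1 + u, s2p_start + stem2 - 1 - u)
              for u in range(stem2)}
    gt = SecondaryStructure(sequence=chain.sequence,
                            chain_lengths=(len(chain),), pairs=pairs)
    return [chain], gt


def random_stem(n: int, rng: np.random.Generator | int | None = None,
                wobble_frac: float = 0.0) -> list[tuple[str, str]]:
    """Random (5'-base, 3'-base) stem steps; each step is G:U with
    probability ``wobble_frac``, otherwise a uniform Watson–Crick pair."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    wc = [("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")]
    wob = [("G", "U"), ("U", "G")]
    out = []
    for _ in range(n):
        if wobble_frac and rng.random() < wobble_frac:
            out.append(wob[rng.integers(2)])
        else:
            out.append(wc[rng.integers(4)])
    return out


def add_noise(chains: Sequence[RnaChain], sigma: float,
              seed: int | None = None) -> list[RnaChain]:
    """Isotropic i.i.d. Gaussian displacement (SD ``sigma`` Å per axis)
    of every atom; ``sigma=0`` returns an identical deep copy."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    out = copy.deepcopy(list(chains))
    for chain in out:
        for nt in chain.nucleotides:
            for atom in list(nt.coords):
                if sigma > 0:
                    nt.coords[atom] = nt.coords[atom] + rng.normal(0.0, sigma, 3)
    return out


def subset_atoms(chains: Sequence[RnaChain],
                 atoms: Iterable[str]) -> list[RnaChain]:
    """Restrict every nucleotide to the given atom types (ablation)."""
    keep = set(atoms)
    bad = keep - set(ATOM_TYPES)
    if bad:
        raise ValueError(f"unrecognized atom types: {sorted(bad)}")
    out = copy.deepcopy(list(chains))
    for chain in out:
        for nt in chain.nucleotides:
            nt.coords = {a: c for a, c in nt.coords.items() if a in keep}
    return out


def make_benchmark(n_targets: int = 50, sigma: float = 0.5,
                   seed: int = 0, wobble_frac: float = 0.1,
                   spec: HelixSpec = DEFAULT_HELIX,
                   ) -> list[tuple[list[RnaChain], SecondaryStructure]]:
    """A simulated benchmark: seeded, noise-perturbed hairpins and
    pseudoknots of varied sizes with known ground truth."""
    rng = np.random.default_rng(seed)
    out = []
    for t in range(n_targets):
        if t % 2 == 0:
            chains, gt = make_hairpin(
                stem_length=int(rng.integers(4, 11)),
                loop_length=int(rng.integers(3, 7)),
                spec=spec, rng=rng, wobble_frac=wobble_frac)
        else:
            chains, gt = make_pseudoknot(
                stem1=int(rng.integers(3, 6)), stem2=int(rng.integers(3, 6)),
                linkers=(int(rng.integers(3, 6)), int(rng.integers(3, 6)),
                         int(rng.integers(3, 6))),
                spec=spec, rng=rng, wobble_frac=wobble_frac)
        noisy = add_noise(chains, sigma, seed=int(rng.integers(2**31)))
        out.append((noisy, gt))
    return out


def make_calibration_set(n_helices: int = 40, length: int = 20,
                         sigma: float = 0.5, seed: int = 12345,
                         wobble_frac: float = 0.1,
                         spec: HelixSpec = DEFAULT_HELIX):
    """Noisy duplex ensemble for calibration.

    Returns ``(structures, reference_pairs)`` ready for
    :func:`cssr.params.calibrate`: duplexes with random sequences (a
    ``wobble_frac`` share of G:U steps) and seeded coordinate noise.
    """
    rng = np.random.default_rng(seed)
    structures, references = [], []
    for _ in range(n_helices):
        steps = random_stem(length, rng=rng, wobble_frac=wobble_frac)
        seq_a = "".join(b5 for b5, _ in steps)
        seq_b = "".join(b3 for _, b3 in reversed(steps))
        chains, gt = make_duplex(seq_a, seq_b, spec=spec)
        noisy = add_noise(chains, sigma, seed=int(rng.integers(2**31)))
        structures.append(noisy)
        references.append(sorted(gt.pairs))
    return structures, references
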