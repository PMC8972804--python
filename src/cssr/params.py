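"""Geometry-statistics model: calibration, storage and lookup.

The score for a candidate base pair compares observed pseudo-bond
geometry against reference statistics gathered from structures with
annotated canonical pairs.  For every combination of

* pair class — Watson–Crick (A:U, C:G) or wobble (G:U),
* atom type — one of the ten recognized types, and
* geometry sub-term — three distances, two angles, two dihedrals,

the model holds a mean, a spread and the number of observations behind
them.  Angular sub-terms use circular statistics.  Cells may be missing
(that sub-term is then skipped during scoring), so at most
2 × 10 × 7 = 140 cells are populated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .geometry import circular_mean_sd
from .structure_io import ATOM_TYPES, RnaChain

__all__ = [
    "WC", "WOBBLE", "PAIR_CLASSES",
    "TERM_KINDS", "is_angular", "pair_class",
    "TermStats", "GeometryParams",
    "calibrate", "save_params", "load_params", "default_params",
]

WC = "WC"
WOBBLE = "WOBBLE"
PAIR_CLASSES = (WC, WOBBLE)

#: The seven geometry sub-terms evaluated per atom type.
#: dis0: distance i..j; dis_up: i+1..j-1; dis_down: i-1..j+1;
#: ang_i: angle (i+1, i, j); ang_j: angle (j-1, j, i);
#: dih_i: dihedral (i+1, i, j, j-1); dih_j: dihedral (j+1, j, i, i-1).
TERM_KINDS: tuple[str, ...] = (
    "dis0", "dis_up", "dis_down", "ang_i", "ang_j", "dih_i", "dih_j",
)

_WC_SET = frozenset({frozenset("AU"), frozenset("CG")})
_WOBBLE_SET = frozenset({frozenset("GU")})

DEFAULT_SIGMA_FLOOR = 1e-2


def is_angular(kind: str) -> bool:
    """True for sub-terms measured in degrees (angles and dihedrals)."""
    return not kind.startswith("dis")


def pair_class(base1: str, base2: str) -> str | None:
    """Canonical pair class of two bases, or None if incompatible.

    A:U and C:G are Watson–Crick; G:U is wobble; everything else
    (including any pair involving an unknown base) has no class.
    """
    key = frozenset((base1, base2))
    if key in _WC_SET:
        return WC
    if key in _WOBBLE_SET:
        return WOBBLE
    return None


@dataclass(frozen=True)
class TermStats:
    """Mean/spread/count for one (class, atom, sub-term) cell."""

    mean: float
    sigma: float
    n_obs: int

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.n_obs < 2:
            raise ValueError(f"n_obs must be >= 2, got {self.n_obs}")


@dataclass
class GeometryParams:
    """Calibrated geometry statistics, keyed (pair class, atom, sub-term)."""

    table: dict[tuple[str, str, str], TermStats] = field(default_factory=dict)
    provenance: str = ""
    sigma_floor: float = DEFAULT_SIGMA_FLOOR

    def get(self, cls: str, atom: str, kind: str) -> TermStats | None:
        return self.table.get((cls, atom, kind))

    def __len__(self) -> int:
        return len(self.table)

    def has_class(self, cls: str) -> bool:
        return any(k[0] == cls for k in self.table)


def calibrate(structures: Sequence[Sequence[RnaChain]],
              reference_pairs: Sequence[Iterable[tuple[int, int]]],
              sigma_floor: float = DEFAULT_SIGMA_FLOOR,
              provenance: str = "calibrated in-session") -> GeometryParams:
    """Estimate geometry statistics from structures with known base pairs.

    Parameters
    ----------
    structures:
        One chain list per structure.
    reference_pairs:
        For each structure, its annotated canonical pairs as global
        0-based ``(i, j)`` positions over the concatenated chains.
    sigma_floor:
        Lower clamp for the spread (Å or degrees).  Protects against
        zero variance on degenerate (noise-free) calibration sets.

    Returns
    -------
    :class:`GeometryParams` with one cell per (pair class, atom type,
    sub-term) bucket that collected at least two observations.
    """
    from .scoring import term_value  # deferred: scoring imports this module
    from .structure_io import StructureIndex

    if len(structures) != len(reference_pairs):
        raise ValueError("structures and reference_pairs differ in length")
    if not structures:
        raise ValueError("empty calibration set")

    buckets: dict[tuple[str, str, str], list[float]] = {}
    n_pairs = 0
    for chains, pairs in zip(structures, reference_pairs):
        index = StructureIndex(chains)
        for i, j in pairs:
            i, j = (i, j) if i < j else (j, i)  # canonical orientation
            cls = pair_class(index.base(i), index.base(j))
            if cls is None:
                raise ValueError(
                    f"reference pair ({i}, {j}) with bases "
                    f"{index.base(i)}:{index.base(j)} is not canonical")
            n_pairs += 1
            for atom in ATOM_TYPES:
                for kind in TERM_KINDS:
                    v = term_value(index, i, j, atom, kind)
                    if v is not None:
                        buckets.setdefault((cls, atom, kind), []).append(v)
    if n_pairs == 0:
        raise ValueError("no reference pairs supplied")

    table: dict[tuple[str, str, str], TermStats] = {}
    for key, values in buckets.items():
        if len(values) < 2:
            continue
        _, _, kind = key
        if is_angular(kind):
            mean, sd = circular_mean_sd(values)
        else:
            arr = np.asarray(values)
            mean = float(arr.mean())
            sd = float(arr.std(ddof=1))
        table[key] = TermStats(mean=mean, sigma=max(sd, sigma_floor),
                               n_obs=len(values))
    return GeometryParams(table=table, provenance=provenance,
                          sigma_floor=sigma_floor)


_HEADER = "# cssr-params v1"
_COLUMNS = "class\tatom\tkind\tmean\tsigma\tn_obs"


def save_params(params: GeometryParams, path: str | Path) -> None:
    """Write parameters as versioned tab-separated text (round-trips)."""
    lines = [_HEADER]
    if params.provenance:
        for pline in params.provenance.splitlines():
            lines.append(f"# provenance: {pline}")
    lines.append(f"# sigma_floor: {params.sigma_floor!r}")
    lines.append(_COLUMNS)
    for (cls, atom, kind) in sorted(params.table):
        st = params.table[(cls, atom, kind)]
        lines.append(f"{cls}\t{atom}\t{kind}\t{st.mean!r}\t{st.sigma!r}\t{st.n_obs}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_params(path: str | Path) -> GeometryParams:
    """Read a parameter file written by :func:`save_params`."""
    path = Path(path)
    return _parse_params(path.read_text().splitlines(), source=str(path))


def _parse_params(lines: list[str], source: str) -> GeometryParams:
    path = source
    if not lines or not lines[0].startswith(_HEADER):
        raise ValueError(f"{path}: not a cssr parameter file (bad header)")
    table: dict[tuple[str, str, str], TermStats] = {}
    provenance_lines: list[str] = []
    sigma_floor = DEFAULT_SIGMA_FLOOR
    seen_columns = False
    for lineno, line in enumerate(lines[1:], start=2):
        if line.startswith("# provenance:"):
            provenance_lines.append(line.split(":", 1)[1].strip())
            continue
        if line.startswith("# sigma_floor:"):
            sigma_floor = float(line.split(":", 1)[1])
            continue
        if line.startswith("#") or not line.strip():
            continue
        if not seen_columns:
            if line != _COLUMNS:
                raise ValueError(f"{path}:{lineno}: unexpected column header")
            seen_columns = True
            continue
        fields = line.split("\t")
        if len(fields) != 6:
            raise ValueError(f"{path}:{lineno}: expected 6 columns, "
                             f"got {len(fields)}")
        cls, atom, kind, mean, sigma, n_obs = fields
        if cls not in PAIR_CLASSES:
            raise ValueError(f"{path}:{lineno}: unknown pair class {cls!r}")
        if atom not in ATOM_TYPES:
            raise ValueError(f"{path}:{lineno}: unknown atom type {atom!r}")
        if kind not in TERM_KINDS:
            raise ValueError(f"{path}:{lineno}: unknown sub-term {kind!r}")
        try:
            table[(cls, atom, kind)] = TermStats(
                mean=float(mean), sigma=float(sigma), n_obs=int(n_obs))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return GeometryParams(table=table,
                          provenance="\n".join(provenance_lines),
                          sigma_floor=sigma_floor)


def default_params() -> GeometryParams:
    """Parameters shipped with the package.

    Calibrated on the bundled synthetic helix ensemble (see the
    ``synthetic`` module) with 0.5 Å coordinate noise, emulating the
    spread seen in experimental structures.  For production use on real
    data, calibrate on annotated experimental structures and pass the
    resulting file instead.
    """
    from importlib.resources import files
    text = (files("cssr") / "data" / "default_params.tsv").read_text()
    return _parse_params(text.splitlines(), source="packaged default_params.tsv")
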