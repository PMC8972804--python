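"""Independent reference implementations used only by tests.

Everything here is written with explicit loops and the ``math`` module,
sharing no code with the package, so that agreement between the two
routes is meaningful.
"""

import math

# ---------------------------------------------------------------- vectors

def _sub(p, q):
    return (p[0] - q[0], p[1] - q[1], p[2] - q[2])


def _dot(p, q):
    return p[0] * q[0] + p[1] * q[1] + p[2] * q[2]


def _cross(p, q):
    return (p[1] * q[2] - p[2] * q[1],
            p[2] * q[0] - p[0] * q[2],
            p[0] * q[1] - p[1] * q[0])


def _norm(p):
    return math.sqrt(_dot(p, p))


def dist(p, q):
    d = _sub(p, q)
    return math.sqrt(d[0] * d[0] + d[1] * d[1] + d[2] * d[2])


def ang(a, v, c):
    u = _sub(a, v)
    w = _sub(c, v)
    cosv = _dot(u, w) / (_norm(u) * _norm(w))
    cosv = max(-1.0, min(1.0, cosv))
    return math.degrees(math.acos(cosv))


def dih(p1, p2, p3, p4):
    b1 = _sub(p2, p1)
    b2 = _sub(p3, p2)
    b3 = _sub(p4, p3)
    n1 = _cross(b1, b2)
    n2 = _cross(b2, b3)
    x = _dot(n1, n2) * _norm(b2)
    y = _dot(_cross(n1, n2), b2)
    val = math.degrees(math.atan2(y, x))
    if val <= -180.0:
        val += 360.0
    return val


def wrap_diff(x, y):
    return min(abs(x - y + 360.0 * k) for k in (-1, 0, 1))


# ------------------------------------------------------- score recomputation

_ATOMS = ("P", "C5'", "C4'", "C3'", "C2'", "C1'", "O5'", "O4'", "O3'", "N")
_WC = ({"A", "U"}, {"C", "G"})
_WOBBLE = ({"G", "U"},)


def pair_class(b1, b2):
    s = {b1, b2}
    if s in _WC:
        return "WC"
    if s in _WOBBLE:
        return "WOBBLE"
    return None


def score_pair(nts, i, j, table):
    """Recompute the pair score with explicit loops.

    ``nts`` is a list of (chain_tag, base, {atom: (x, y, z)}) tuples in
    global order; adjacency holds between consecutive entries with the
    same chain tag.  ``table`` maps (class, atom, kind) -> (mean, sigma).
    Returns (score, n_terms) or None.
    """
    if i > j:
        i, j = j, i
    cls = pair_class(nts[i][1], nts[j][1])
    if cls is None:
        return None

    def atom_at(pos, atom):
        if pos is None or pos < 0 or pos >= len(nts):
            return None
        return nts[pos][2].get(atom)

    def nbr(pos, step):
        q = pos + step
        if q < 0 or q >= len(nts) or nts[q][0] != nts[pos][0]:
            return None
        return q

    total = 0.0
    n_terms = 0
    for atom in _ATOMS:
        ai = atom_at(i, atom)
        aj = atom_at(j, atom)
        if ai is None or aj is None:
            continue
        ip1 = atom_at(nbr(i, 1), atom)
        im1 = atom_at(nbr(i, -1), atom)
        jp1 = atom_at(nbr(j, 1), atom)
        jm1 = atom_at(nbr(j, -1), atom)
        values = {
            "dis0": dist(ai, aj),
            "dis_up": dist(ip1, jm1) if ip1 is not None and jm1 is not None else None,
            "dis_down": dist(im1, jp1) if im1 is not None and jp1 is not None else None,
            "ang_i": ang(ip1, ai, aj) if ip1 is not None else None,
            "ang_j": ang(jm1, aj, ai) if jm1 is not None else None,
            "dih_i": dih(ip1, ai, aj, jm1) if ip1 is not None and jm1 is not None else None,
            "dih_j": dih(jp1, aj, ai, im1) if jp1 is not None and im1 is not None else None,
        }
        for kind, value in values.items():
            if value is None:
                continue
            stats = table.get((cls, atom, kind))
            if stats is None:
                continue
            mean, sigma = stats
            if kind.startswith("dis"):
                delta = value - mean
            else:
                delta = wrap_diff(value, mean)
            total += math.exp(-(delta ** 2) / (2.0 * sigma ** 2))
            n_terms += 1
    if n_terms == 0:
        return None
    return total / n_terms, n_terms


def nts_from_chains(chains):
    """Flatten package chains into the primitive form score_pair wants."""
    out = []
    for tag, chain in enumerate(chains):
        for nt in chain.nucleotides:
            out.append((tag, nt.base,
                        {a: tuple(c) for a, c in nt.coords.items()}))
    return out


def table_from_params(params):
    return {key: (st.mean, st.sigma) for key, st in params.table.items()}


# --------------------------------------------------------- greedy filter

def greedy_filter(scored_pairs, cutoff=0.5):
    """Literal transcription of the ranked-exclusion rule: pairs with
    score >= cutoff are listed in descending order of score and a pair is
    excluded if one or both nucleotides overlap with any pair ranking
    higher on the (remaining) list."""
    listed = sorted([p for p in scored_pairs if p[2] >= cutoff],
                    key=lambda p: (-p[2], p[0], p[1]))
    kept = []
    for i, j, score in listed:
        overlap = any(i in (a, b) or j in (a, b) for a, b, _ in kept)
        if not overlap:
            kept.append((i, j, score))
    return {(i, j) for i, j, _ in kept}
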