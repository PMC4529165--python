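"""Secondary-structure reconstruction for ITS2 and 5.8S sequences.

The built-in engine is base-pair maximization (Nussinov dynamic programme)
with a minimum hairpin loop of 3 nt and Watson-Crick plus G·U wobble pairs;
among count-optimal structures the one with the most stacked pair
adjacencies is selected, which removes the degeneracy of plain pair
counting.
The paired structure is decomposed into helices — runs of stacked pairs, with
small interior loops and bulges bridged — and tested against the canonical
ITS2 topology: four helices radiating from the central loop, a
pyrimidine-pyrimidine mismatch in helix II, and the conserved TGGT on the
5' arm of helix III.  A 5.8S fold is scored by how many base pairs of a
reference fold it recovers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

__all__ = [
    "FoldResult",
    "Helix",
    "nussinov_pairs",
    "pairs_to_dotbracket",
    "find_helices",
    "fold_its2",
    "fold_58s",
]

_PAIRS = {
    ("A", "T"), ("T", "A"), ("A", "U"), ("U", "A"),
    ("G", "C"), ("C", "G"),
    ("G", "T"), ("T", "G"), ("G", "U"), ("U", "G"),
}


def _can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


@dataclass(frozen=True)
class FoldResult:
    """Outcome of folding one region."""

    structure: str  # dot-bracket
    n_helices: int
    helix2_pyrimidine_bulge: bool
    helix3_tggt: bool
    formed: bool
    n_pairs: int = 0


@dataclass
class Helix:
    """A chain of stacked pairs, possibly bridging small interior loops."""

    pairs: list[tuple[int, int]] = field(default_factory=list)
    top_level: bool = False

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def five_prime_span(self) -> tuple[int, int]:
        """0-based half-open span of the 5' arm."""
        starts = [p[0] for p in self.pairs]
        return min(starts), max(starts) + 1

    def interior_loops(self):
        """(left_gap_span, right_gap_span) between consecutive chain pairs."""
        loops = []
        for (i1, j1), (i2, j2) in zip(self.pairs, self.pairs[1:]):
            lg = (i1 + 1, i2)  # unpaired on 5' side
            rg = (j2 + 1, j1)  # unpaired on 3' side
            if lg[1] > lg[0] or rg[1] > rg[0]:
                loops.append((lg, rg))
        return loops


#: Score of one base pair; stacking contributes +1, so with PAIR_SCORE
#: large the DP maximizes pair count first and stacked adjacencies second.
_PAIR_SCORE = 4096


def nussinov_pairs(seq: str, min_loop: int = 3) -> list[tuple[int, int]]:
    """Maximum-base-pairing structure of ``seq`` (deterministic traceback).

    The dynamic programme maximizes the number of base pairs and, among
    count-optimal structures, the number of stacked pair adjacencies.  The
    stacking tie-break removes the massive degeneracy of plain pair
    maximization and makes long contiguous stems win over fragmented
    count-neutral alternatives.  Remaining ties prefer leaving the right
    end unpaired, then the leftmost partner.
    """
    s = seq.upper().replace("U", "T")
    n = len(s)
    if n < min_loop + 2:
        raise ValueError(f"sequence too short to fold (length {n})")
    pairable = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + min_loop + 1, n):
            pairable[i, j] = _can_pair(s[i], s[j])
    NEG = -1
    # P[i,j]: best score of [i..j] given (i,j) paired; U[i,j]: unconstrained
    P = np.full((n, n), NEG, dtype=np.int64)
    U = np.zeros((n, n), dtype=np.int64)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            if pairable[i, j]:
                inner = U[i + 1, j - 1]
                if P[i + 1, j - 1] + 1 > inner:
                    inner = P[i + 1, j - 1] + 1
                P[i, j] = _PAIR_SCORE + inner
            best = U[i, j - 1]
            for k in range(i, j - min_loop):
                if pairable[k, j]:
                    cand = P[k, j] + (U[i, k - 1] if k > i else 0)
                    if cand > best:
                        best = cand
            U[i, j] = best

    pairs: list[tuple[int, int]] = []
    stack: list[tuple[int, int, bool]] = [(0, n - 1, False)]
    while stack:
        i, j, must_pair = stack.pop()
        if j - i <= min_loop:
            continue
        if must_pair:
            pairs.append((i, j))
            inner_u = U[i + 1, j - 1]
            inner_p = P[i + 1, j - 1] + 1
            if inner_p > inner_u:
                stack.append((i + 1, j - 1, True))
            else:
                stack.append((i + 1, j - 1, False))
            continue
        target = U[i, j]
        if U[i, j - 1] == target:
            stack.append((i, j - 1, False))
            continue
        for k in range(i, j - min_loop):
            if pairable[k, j] and P[k, j] + (U[i, k - 1] if k > i else 0) == target:
                stack.append((k, j, True))
                if k > i:
                    stack.append((i, k - 1, False))
                break
    pairs.sort()
    return pairs


def pairs_to_dotbracket(pairs: list[tuple[int, int]], n: int) -> str:
    out = ["."] * n
    for i, j in pairs:
        out[i] = "("
        out[j] = ")"
    return "".join(out)


def find_helices(
    pairs: list[tuple[int, int]],
    merge_gap: int = 3,
    min_stack: int = 3,
) -> list[Helix]:
    """Decompose a nested pairing into helices.

    Consecutively nested pairs are chained into one helix as long as the
    interior loop between them leaves at most ``merge_gap`` unpaired
    nucleotides on each side.  Helices shorter than ``min_stack`` pairs are
    discarded.  A helix is top-level when its outermost pair is not nested
    inside any other pair.
    """
    if not pairs:
        return []
    pairs = sorted(pairs)
    # direct-nesting children of each pair (and of the root)
    children: dict[tuple[int, int] | None, list[tuple[int, int]]] = {None: []}
    stack: list[tuple[int, int]] = []
    for p in pairs:
        while stack and not (stack[-1][0] < p[0] and p[1] < stack[-1][1]):
            stack.pop()
        parent = stack[-1] if stack else None
        children.setdefault(parent, []).append(p)
        children.setdefault(p, [])
        stack.append(p)

    helices: list[Helix] = []
    in_helix: set[tuple[int, int]] = set()

    def grow(start: tuple[int, int], top: bool) -> None:
        helix = Helix(top_level=top)
        cur = start
        while True:
            helix.pairs.append(cur)
            in_helix.add(cur)
            kids = children[cur]
            if len(kids) == 1:
                (nxt,) = kids
                if nxt[0] - cur[0] - 1 <= merge_gap and cur[1] - nxt[1] - 1 <= merge_gap:
                    cur = nxt
                    continue
            break
        if helix.n_pairs >= min_stack:
            helices.append(helix)
        # descend into whatever follows the chain
        for kid in children[helix.pairs[-1]]:
            grow(kid, top=False)

    for root in children[None]:
        grow(root, top=True)
    helices.sort(key=lambda h: h.pairs[0][0])
    return helices


def _is_pyrimidine(b: str) -> bool:
    return b in "CTU"


def fold_its2(
    seq: str,
    min_loop: int = 3,
    merge_gap: int = 3,
    min_stack: int = 3,
) -> FoldResult:
    """Fold an ITS2 span and test the canonical four-helix topology.

    ``formed`` requires exactly four top-level helices radiating from the
    central (exterior) loop.  The pyrimidine-pyrimidine bulge is looked for
    in helix II (an interior loop whose unpaired bases on both strands are
    all pyrimidines) and the TGGT motif on the 5' arm of helix III.
    """
    seq = seq.upper()
    pairs = nussinov_pairs(seq, min_loop=min_loop)
    helices = find_helices(pairs, merge_gap=merge_gap, min_stack=min_stack)
    top = [h for h in helices if h.top_level]
    formed = len(top) == 4
    py_bulge = False
    tggt = False
    if len(top) >= 2:
        h2 = top[1]
        for (lg, rg) in h2.interior_loops():
            left = seq[lg[0]: lg[1]]
            right = seq[rg[0]: rg[1]]
            if (left or right) and all(_is_pyrimidine(b) for b in left + right) and left + right:
                py_bulge = True
                break
    if len(top) >= 3:
        a, b = top[2].five_prime_span
        tggt = "TGGT" in seq[a:b]
    return FoldResult(
        structure=pairs_to_dotbracket(pairs, len(seq)),
        n_helices=len(top),
        helix2_pyrimidine_bulge=py_bulge,
        helix3_tggt=tggt,
        formed=formed,
        n_pairs=len(pairs),
    )


def _map_positions(query: str, reference: str) -> dict[int, int]:
    """Map reference coordinates onto query coordinates via global alignment."""
    res = edlib.align(reference, query, mode="NW", task="path")
    mapping: dict[int, int] = {}
    qi = ri = 0
    for n_, op in _cigar_ops(res["cigar"]):
        for _ in range(n_):
            if op in ("=", "X", "M"):
                mapping[ri] = qi
                ri += 1
                qi += 1
            elif op == "I":  # present in reference only
                ri += 1
            elif op == "D":  # present in query only
                qi += 1
    return mapping


def _cigar_ops(cigar: str):
    num = ""
    for c in cigar:
        if c.isdigit():
            num += c
        else:
            yield int(num), c
            num = ""


def fold_58s(
    seq: str,
    reference: str,
    min_fraction: float = 0.5,
    min_loop: int = 3,
    merge_gap: int = 3,
    min_stack: int = 3,
) -> FoldResult:
    """Fold a 5.8S span and compare it to the fold of a reference 5.8S.

    ``formed`` is true when at least ``min_fraction`` of the reference
    fold's base pairs (mapped through a global alignment of the two
    sequences) are recovered in the observed fold.
    """
    seq = seq.upper()
    reference = reference.upper()
    obs_pairs = set(nussinov_pairs(seq, min_loop=min_loop))
    ref_pairs = nussinov_pairs(reference, min_loop=min_loop)
    if seq == reference:
        mapped = set(ref_pairs)
    else:
        m = _map_positions(seq, reference)
        mapped = {
            (m[i], m[j]) for i, j in ref_pairs if i in m and j in m
        }
    frac = len(mapped & obs_pairs) / len(ref_pairs) if ref_pairs else 1.0
    helices = find_helices(sorted(obs_pairs), merge_gap=merge_gap, min_stack=min_stack)
    top = [h for h in helices if h.top_level]
    return FoldResult(
        structure=pairs_to_dotbracket(sorted(obs_pairs), len(seq)),
        n_helices=len(top),
        helix2_pyrimidine_bulge=False,
        helix3_tggt=False,
        formed=frac >= min_fraction,
        n_pairs=len(obs_pairs),
    )
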