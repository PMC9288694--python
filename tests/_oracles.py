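"""Independent brute-force oracles for scan/containment operations.

These deliberately use the most naive correct algorithm (full enumeration)
so they share no code path with the package implementation.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGTN",
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq.upper()))


def match_at(seq: str, site: str, offset: int) -> bool:
    if offset + len(site) > len(seq):
        return False
    return all(seq[offset + j] in IUPAC[site[j]] for j in range(len(site)))


def cut_positions(seq: str, site: str) -> List[int]:
    """Every offset where the site matches (overlap-tolerant)."""
    seq = seq.upper()
    return [o for o in range(len(seq)) if match_at(seq, site, o)]


def digest_fragments(seq: str, site: str) -> List[Tuple[int, int]]:
    cuts = [c for c in cut_positions(seq, site) if c > 0]
    bounds = [0] + sorted(set(cuts)) + [len(seq)]
    bounds = sorted(set(bounds))
    return list(zip(bounds[:-1], bounds[1:]))


def containing_fragment(fragments: List[Tuple[int, int]], position: int) -> int:
    """Linear scan over (start, end) fragments for half-open containment."""
    for i, (s, e) in enumerate(fragments):
        if s <= position < e:
            return i
    raise ValueError("position outside all fragments")


def ebox_hits(seq: str) -> List[int]:
    """CANNTG occurrences on both strands, deduplicated to forward offsets."""
    seq = seq.upper()
    hits = set()
    for strand_seq in (seq, revcomp(seq)):
        for o in range(len(strand_seq) - 5):
            w = strand_seq[o : o + 6]
            if w[0] == "C" and w[1] == "A" and w[4] == "T" and w[5] == "G":
                if strand_seq is seq:
                    hits.add(o)
                else:
                    hits.add(len(seq) - 6 - o)
    return sorted(hits)


def pwm_score_all(seq: str, matrix, pseudocount: float, background) -> Dict[Tuple[int, str], float]:
    """Log-odds score at every (offset, strand), scored base by base."""
    import math

    seq = seq.upper()
    L = len(matrix[0])
    base_row = {"A": 0, "C": 1, "G": 2, "T": 3}

    def col_score(base: str, j: int) -> float:
        if base not in base_row:
            return 0.0
        b = base_row[base]
        p = matrix[b][j]
        bg = background[b]
        return math.log2((p + pseudocount * bg) / ((1 + pseudocount) * bg))

    out: Dict[Tuple[int, str], float] = {}
    rc = revcomp(seq)
    for o in range(len(seq) - L + 1):
        out[(o, "+")] = sum(col_score(seq[o + j], j) for j in range(L))
    for o in range(len(rc) - L + 1):
        orig = len(seq) - L - o
        out[(orig, "-")] = sum(col_score(rc[o + j], j) for j in range(L))
    return out


def max_window_scan(runs: List[Tuple[int, int, float]], start: int, end: int, width_cap: int):
    """Exhaustive scan over every integer window start for the max integrated signal."""
    width = min(width_cap, end - start)

    def integral(a: int, b: int) -> float:
        tot = 0.0
        for s, e, v in runs:
            lo, hi = max(s, a), min(e, b)
            if hi > lo:
                tot += v * (hi - lo)
        return tot

    best_s, best_v = start, -1.0
    for s in range(start, end - width + 1):
        v = integral(s, s + width)
        if v > best_v + 1e-9:
            best_s, best_v = s, v
    return best_s, best_s + width, best_v
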