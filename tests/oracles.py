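"""Independent brute-force oracles used only by the test suite.

Each oracle deliberately uses a different computational route from the
package implementation it checks (exact integer arithmetic, explicit
loops, per-position scans, recursive path counting).
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

from triomap.datamodel import Pedigree


def hwe_exact_enumeration(n_AA: int, n_Aa: int, n_aa: int) -> Fraction:
    """Exact HWE test p-value by full enumeration with integer weights.

    Conditional on allele counts, P(het = h) is proportional to the
    integer weight C(n, hom_rare) * C(n - hom_rare, h) * 2^h; the
    p-value is the exact rational sum of weights <= the observed one.
    """
    n = n_AA + n_Aa + n_aa
    n_rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if n_rare == 0:
        return Fraction(1)

    def weight(h: int) -> int:
        hom_rare = (n_rare - h) // 2
        return comb(n, hom_rare) * comb(n - hom_rare, h) * 2**h

    hets = range(n_rare % 2, n_rare + 1, 2)
    weights = {h: weight(h) for h in hets}
    w_obs = weights[n_Aa]
    return Fraction(sum(w for w in weights.values() if w <= w_obs),
                    sum(weights.values()))


def roh_bruteforce(calls, positions, params) -> list[tuple[int, int, int]]:
    """Window-rule ROH by explicit loops; returns (start, end, n_snv)."""
    g = list(map(int, calls))
    pos = list(map(int, positions))
    n = len(g)
    W = params.window_snv
    if n < W:
        return []
    window_pass = []
    for i in range(n - W + 1):
        win = g[i:i + W]
        het = sum(1 for x in win if x == 1)
        mis = sum(1 for x in win if x == -1)
        window_pass.append(het <= params.max_het_per_window
                           and mis <= params.max_miss_per_window)
    qualifies = []
    for j in range(n):
        covering = [i for i in range(max(0, j - W + 1), min(j, n - W) + 1)]
        frac = sum(window_pass[i] for i in covering) / len(covering)
        qualifies.append(frac > params.window_hit_fraction and g[j] != 1)
    segments = []
    j = 0
    while j < n:
        if not qualifies[j]:
            j += 1
            continue
        k = j
        while k + 1 < n and qualifies[k + 1]:
            k += 1
        length = pos[k] - pos[j] + 1
        count = k - j + 1
        if (length >= params.min_length_bp and count >= params.min_snv
                and length / count <= params.max_bp_per_snv):
            segments.append((pos[j], pos[k], count))
        j = k + 1
    return segments


def shared_intervals_perbp(segment_lists: list[list[tuple[int, int]]],
                           max_pos: int) -> list[tuple[int, int]]:
    """Per-position intersection of interval sets (toy coordinates only)."""
    covered = []
    for pos in range(1, max_pos + 1):
        covered.append(all(any(s <= pos <= e for s, e in segs)
                           for segs in segment_lists))
    out = []
    start = None
    for pos, c in enumerate(covered, start=1):
        if c and start is None:
            start = pos
        elif not c and start is not None:
            out.append((start, pos - 1))
            start = None
    if start is not None:
        out.append((start, max_pos))
    return out


def kinship(pedigree: Pedigree, a: str, b: str) -> Fraction:
    """Wright's kinship coefficient by recursive path counting."""
    depth_cache: dict[str, int] = {}

    def depth(i: str) -> int:
        if i not in pedigree:
            return 0
        if i in depth_cache:
            return depth_cache[i]
        rec = pedigree.get(i)
        d = 0 if rec.sire == "0" else 1 + max(depth(rec.sire), depth(rec.dam))
        depth_cache[i] = d
        return d

    cache: dict[tuple[str, str], Fraction] = {}

    def phi(x: str, y: str) -> Fraction:
        if x == "0" or y == "0":
            return Fraction(0)
        key = (min(x, y), max(x, y))
        if key in cache:
            return cache[key]
        if x == y:
            rec = pedigree.get(x)
            val = Fraction(1, 2) * (1 + phi(rec.sire, rec.dam))
        else:
            # recurse through the parents of the lower individual
            if depth(x) < depth(y):
                x, y = y, x
            rec = pedigree.get(x)
            if rec.sire == "0":
                val = Fraction(0)
            else:
                val = Fraction(1, 2) * (phi(rec.sire, y) + phi(rec.dam, y))
        cache[key] = val
        return val

    return phi(a, b)


def allele_frequency_exact(n_varvar: int, n_refvar: int, n_refref: int
                           ) -> Fraction:
    total = n_varvar + n_refvar + n_refref
    return Fraction(2 * n_varvar + n_refvar, 2 * total)
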