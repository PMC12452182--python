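"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive: exhaustive enumeration, literal
counting, exact rational arithmetic. These share at most the energy
parameter table with the package (so that energies are comparable), never
its algorithms.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from fractions import Fraction
from typing import Iterator

from riboarch.terminator import TerminatorParams, pairable, structure_energy


def dinucleotide_multiset(seq: str) -> Counter:
    """Multiset of overlapping dinucleotides."""
    return Counter(seq[i : i + 2] for i in range(len(seq) - 1))


def sequences_with_same_dinucs(seq: str) -> set[str]:
    """All strings over ACGT with the same length, first/last letter and
    overlapping-dinucleotide multiset as ``seq`` (exhaustive; use only for
    short sequences)."""
    target = dinucleotide_multiset(seq)
    n = len(seq)
    out = set()
    for middle in itertools.product("ACGT", repeat=max(0, n - 2)):
        cand = seq[0] + "".join(middle) + (seq[-1] if n > 1 else "")
        if dinucleotide_multiset(cand) == target:
            out.add(cand)
    return out


def enumerate_single_stems(
    seq: str, params: TerminatorParams = TerminatorParams()
) -> Iterator[list[tuple[int, int]]]:
    """Every legal single-stem structure of ``seq``: nested pairs with
    bulge/internal defects up to ``max_bulge`` per side, at least
    ``min_stem`` pairs and a closing loop of at least ``min_loop`` nt."""
    seq = seq.upper().replace("U", "T")
    n = len(seq)

    def extend(pairs: list[tuple[int, int]]):
        i, j = pairs[-1]
        if len(pairs) >= params.min_stem and j - i - 1 >= params.min_loop:
            yield list(pairs)
        for li in range(params.max_bulge + 1):
            i2 = i + 1 + li
            if i2 >= j:
                break
            for lj in range(params.max_bulge + 1):
                j2 = j - 1 - lj
                if j2 <= i2:
                    break
                if pairable(seq[i2], seq[j2]):
                    pairs.append((i2, j2))
                    yield from extend(pairs)
                    pairs.pop()

    for i in range(n):
        for j in range(i + 1, n):
            if pairable(seq[i], seq[j]):
                yield from extend([(i, j)])


def best_hairpin_by_enumeration(seq: str, params: TerminatorParams = TerminatorParams()):
    """(dg, pairs) of the minimum-energy enumerated structure, or None.

    Scores each enumerated structure with the package's parameter table via
    ``structure_energy`` (the table is shared; the search is not)."""
    best = None
    for pairs in enumerate_single_stems(seq, params):
        dg = structure_energy(seq, pairs)
        if best is None or dg < best[0]:
            best = (dg, pairs)
    return best


def hypergeom_tail_exact(N: int, K: int, n: int, k: int) -> Fraction:
    """P(X >= k) as an exact rational via direct pmf summation."""
    num = sum(math.comb(K, j) * math.comb(N - K, n - j) for j in range(k, min(n, K) + 1))
    return Fraction(num, math.comb(N, n))


def hypergeom_tails_all_k(N: int, K: int, n: int) -> list[Fraction]:
    """Exact upper-tail values for every k in 0..min(n,K) (suffix sums)."""
    kmax = min(n, K)
    terms = [math.comb(K, j) * math.comb(N - K, n - j) for j in range(kmax + 1)]
    denom = math.comb(N, n)
    suffix = 0
    tails = [Fraction(0)] * (kmax + 1)
    for k in range(kmax, -1, -1):
        suffix += terms[k]
        tails[k] = Fraction(suffix, denom)
    return tails


def t_runs_brute(seq: str, params: TerminatorParams = TerminatorParams()) -> list[tuple[int, int]]:
    """T-runs by literal enumeration of every window placement, interval
    union, then trimming each merged interval to its T extent."""
    seq = seq.upper().replace("U", "T")
    n, w = len(seq), params.t_run_window
    covered = set()
    for s in range(0, n - w + 1):
        if seq[s : s + w].count("T") >= params.t_run_min_t:
            covered.update(range(s, s + w))
    runs = []
    for pos in sorted(covered):
        if runs and pos == runs[-1][1]:
            runs[-1][1] = pos + 1
        elif not runs or pos > runs[-1][1]:
            runs.append([pos, pos + 1])
    trimmed = []
    for a, b in runs:
        while a < b and seq[a] != "T":
            a += 1
        while b > a and seq[b - 1] != "T":
            b -= 1
        if a < b:
            trimmed.append((a, b))
    return trimmed


def random_dna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
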