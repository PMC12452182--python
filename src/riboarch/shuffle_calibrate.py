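"""Dinucleotide-preserving shuffling and empirical bit-score cutoffs.

Curated per-model gathering thresholds can be too stringent for some
riboswitch classes (T-box being the classic case), so score cutoffs are
re-derived empirically: every intergenic region is shuffled preserving its
dinucleotide composition, the shuffles are scanned with the model, and the
highest bit score any shuffle achieves becomes the model's cutoff — by
construction the strongest score attainable by compositional noise alone.

Shuffling uses the Euler-path (Altschul–Erickson) construction, which
samples uniformly among sequences with exactly the input's multiset of
overlapping dinucleotides (hence identical length, mononucleotide counts,
and first/last letter).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from ._records import AptamerHit, IntergenicRegion

_ALPHABET = set("ACGT")

#: A scanner maps a sequence to a list of (bit_score, (start, end)) hits.
Scanner = Callable[[str], list[tuple[float, tuple[int, int]]]]


@dataclass(frozen=True)
class ShuffleParams:
    """Replicates per region and the root RNG seed."""

    n_shuffles: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")


@dataclass(frozen=True)
class ScoreCutoff:
    """Empirical per-model bit-score cutoff (max over random-sequence hits)."""

    model_name: str
    cutoff_bits: float
    n_random_hits: int


def dinucleotide_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Shuffle ``sequence`` preserving its overlapping-dinucleotide multiset.

    Euler-path construction: the sequence is a walk on the graph whose edges
    are its dinucleotides; a uniformly random Eulerian walk with the same
    start is returned. Rejects sequences shorter than 2 nt or containing
    characters outside ACGT (hard-mask or drop ambiguous regions upstream).
    """
    if len(sequence) < 2:
        raise ValueError("sequence must be at least 2 nt long")
    if not _ALPHABET.issuperset(sequence):
        bad = sorted(set(sequence) - _ALPHABET)
        raise ValueError(f"sequence contains non-ACGT characters: {bad}")

    edges: dict[str, list[str]] = {}
    for a, b in zip(sequence, sequence[1:]):
        edges.setdefault(a, []).append(b)
    first, last = sequence[0], sequence[-1]

    vertices = [v for v in edges if v != last]
    # Choose a random "last edge" per non-sink vertex until those edges form
    # a tree directed toward the sink (Altschul–Erickson); then permute the
    # remaining edges freely.
    last_edge: dict[str, str] = {}
    while True:
        for v in vertices:
            last_edge[v] = edges[v][rng.integers(len(edges[v]))]
        if _all_reach_sink(last_edge, vertices, last):
            break

    ordered: dict[str, list[str]] = {}
    for v, out in edges.items():
        out = out.copy()
        if v != last:
            out.remove(last_edge[v])
        perm = rng.permutation(len(out))
        shuffled = [out[i] for i in perm]
        if v != last:
            shuffled.append(last_edge[v])
        ordered[v] = shuffled

    walk = [first]
    counters = {v: 0 for v in ordered}
    cur = first
    for _ in range(len(sequence) - 1):
        nxt = ordered[cur][counters[cur]]
        counters[cur] += 1
        walk.append(nxt)
        cur = nxt
    return "".join(walk)


def _all_reach_sink(last_edge: Mapping[str, str], vertices: Sequence[str], sink: str) -> bool:
    for v in vertices:
        seen = set()
        cur = v
        while cur != sink:
            if cur in seen or cur not in last_edge:
                return False
            seen.add(cur)
            cur = last_edge[cur]
    return True


def _substream(seed: int, region_key: str, replicate: int) -> np.random.Generator:
    """Deterministic per-(region, replicate) stream, order-independent."""
    return np.random.default_rng([seed, zlib.crc32(region_key.encode()), replicate])


def region_shuffles(
    region: IntergenicRegion, params: ShuffleParams
) -> Iterable[str]:
    """The region's ``n_shuffles`` dinucleotide-preserving shuffles."""
    for rep in range(params.n_shuffles):
        rng = _substream(params.seed, region.region_id, rep)
        yield dinucleotide_shuffle(region.sequence.upper(), rng)


def calibrate_cutoff(
    model_name: str,
    regions: Sequence[IntergenicRegion],
    scanner: Scanner,
    params: ShuffleParams = ShuffleParams(),
    floor: float = 0.0,
) -> ScoreCutoff:
    """Empirical cutoff: the best score the scanner achieves on any shuffle.

    When no shuffle yields a hit, the configured ``floor`` (default 0.0 bits,
    permissive so that a curated gathering threshold supplied by the caller
    can dominate) is returned with ``n_random_hits = 0``.
    """
    if not regions:
        raise ValueError("calibrate_cutoff requires at least one region")
    best = None
    n_hits = 0
    for region in regions:
        for shuffled in region_shuffles(region, params):
            for score, _interval in scanner(shuffled):
                n_hits += 1
                if best is None or score > best:
                    best = score
    return ScoreCutoff(
        model_name=model_name,
        cutoff_bits=floor if best is None else float(best),
        n_random_hits=n_hits,
    )


def apply_cutoffs(
    hits: Iterable[AptamerHit], cutoffs: Mapping[str, ScoreCutoff | float]
) -> list[AptamerHit]:
    """Keep hits scoring strictly above their model's empirical cutoff.

    The cutoff is the maximum score noise achieved, so a score equal to it is
    attainable by noise and is removed. Hits of models without a cutoff are
    retained unchanged but flagged in ``note``.
    """
    kept: list[AptamerHit] = []
    for h in hits:
        if h.model_class not in cutoffs:
            note = f"{h.note};no-cutoff" if h.note else "no-cutoff"
            kept.append(AptamerHit(**{**h.__dict__, "note": note}))
            continue
        cut = cutoffs[h.model_class]
        cutoff_bits = cut.cutoff_bits if isinstance(cut, ScoreCutoff) else float(cut)
        if h.bit_score > cutoff_bits:
            kept.append(h)
    return kept


# ---------------------------------------------------------------------------
# built-in toy scanners (test/demo substitutes for a covariance-model search)
# ---------------------------------------------------------------------------


def motif_count_scanner(motif: str) -> Scanner:
    """Score = number of occurrences of ``motif`` (overlapping); one hit
    spanning the whole sequence when the count is positive."""

    def scan(seq: str) -> list[tuple[float, tuple[int, int]]]:
        count = 0
        start = 0
        while True:
            idx = seq.find(motif, start)
            if idx < 0:
                break
            count += 1
            start = idx + 1
        return [(float(count), (0, len(seq)))] if count else []

    return scan


def null_scanner(_seq: str) -> list[tuple[float, tuple[int, int]]]:
    """Scanner that never reports a hit."""
    return []


BUILTIN_SCANNERS: dict[str, Scanner] = {
    "null": null_scanner,
    "cccc-count": motif_count_scanner("CCCC"),
}
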