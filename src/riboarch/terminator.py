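"""Rho-independent (intrinsic) terminator detection downstream of aptamers.

An intrinsic terminator is a GC-rich stem-loop immediately followed by a
uridine-rich run that dissociates RNA polymerase without Rho factor. The
detector works on a 50-nt window downstream of an aptamer: find T-runs
(a 6-nt sliding window holding >= 5 T), then look for the most stable single
stem-loop whose 3' base lies at most 2 nt before the run, and call a
terminator when its free energy is below -10 kcal/mol.

Folding is done by an in-repo hairpin-only minimum-free-energy engine: a
dynamic program over a single stem (bulges/internal loops up to 3 nt per
side, no multiloops), scored with Turner-style nearest-neighbor stack free
energies and tabulated hairpin-loop initiation penalties at 37 degC. DNA
input is treated as the transcribed RNA (T == U). A different folding
backend can be plugged into :func:`call_terminator` via ``fold``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Optional

from ._records import ContiguousGroup, HairpinFold, IntergenicRegion, TerminatorCall


@dataclass(frozen=True)
class TerminatorParams:
    window_len: int = 50  # nt scanned downstream of the aptamer
    t_run_min_t: int = 5  # minimum T count inside the sliding window
    t_run_window: int = 6  # nt, sliding-window width for T-runs
    dg_threshold: float = -10.0  # kcal/mol, strict "<" comparison
    max_gap: int = 2  # nt between hairpin base and T-run start
    min_stem: int = 3  # base pairs
    min_loop: int = 3  # nt
    max_bulge: int = 3  # nt per side within the stem

    def __post_init__(self) -> None:
        if self.window_len <= 0:
            raise ValueError("window_len must be positive")
        if self.dg_threshold >= 0:
            raise ValueError("dg_threshold must be negative")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")


# ---------------------------------------------------------------------------
# nearest-neighbor energy model (kcal/mol, 37 degC)
# ---------------------------------------------------------------------------

PAIRABLE = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}

# Stack free energies: key = (outer pair, inner pair), each pair written
# 5'->3' on the top strand. Watson-Crick and G.U wobble stacks.
STACK = {
    ("AT", "AT"): -0.93, ("AT", "TA"): -1.10, ("AT", "GC"): -2.24,
    ("AT", "CG"): -2.08, ("AT", "GT"): -0.55, ("AT", "TG"): -1.36,
    ("TA", "AT"): -1.33, ("TA", "TA"): -0.93, ("TA", "GC"): -2.35,
    ("TA", "CG"): -2.11, ("TA", "GT"): -1.00, ("TA", "TG"): -1.27,
    ("CG", "AT"): -2.11, ("CG", "TA"): -2.08, ("CG", "GC"): -3.26,
    ("CG", "CG"): -2.36, ("CG", "GT"): -1.41, ("CG", "TG"): -2.11,
    ("GC", "AT"): -2.35, ("GC", "TA"): -2.24, ("GC", "GC"): -3.42,
    ("GC", "CG"): -3.26, ("GC", "GT"): -1.53, ("GC", "TG"): -2.51,
    ("GT", "AT"): -1.27, ("GT", "TA"): -1.36, ("GT", "GC"): -2.51,
    ("GT", "CG"): -2.11, ("GT", "GT"): -0.50, ("GT", "TG"): 1.29,
    ("TG", "AT"): -1.00, ("TG", "TA"): -0.55, ("TG", "GC"): -1.41,
    ("TG", "CG"): -1.53, ("TG", "GT"): 0.30, ("TG", "TG"): -0.50,
}

# Hairpin-loop initiation by loop length; Jacobson-Stockmayer extrapolation
# beyond 9 nt (RT = 0.6163 kcal/mol at 37 degC).
_HAIRPIN_INIT = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
_RT37 = 0.6163

# Bulge (one side unpaired) and internal-loop (both sides) initiation by
# total unpaired length; stacking across the defect is not scored.
_BULGE = {1: 3.8, 2: 2.8, 3: 3.2}
_INTERNAL = {2: 1.0, 3: 1.8, 4: 2.0, 5: 2.2, 6: 2.5}


def hairpin_loop_energy(loop_len: int) -> float:
    if loop_len <= 9:
        return _HAIRPIN_INIT[max(3, loop_len)]
    return _HAIRPIN_INIT[9] + 1.75 * _RT37 * math.log(loop_len / 9.0)


def _defect_energy(li: int, lj: int) -> float:
    if li == 0 and lj == 0:
        raise ValueError("not a defect")
    if li == 0 or lj == 0:
        return _BULGE[li + lj]
    return _INTERNAL[li + lj]


def _norm(seq: str) -> str:
    return seq.upper().replace("U", "T")


def pairable(a: str, b: str) -> bool:
    return (a, b) in PAIRABLE


def structure_energy(seq: str, pairs: list[tuple[int, int]]) -> float:
    """Free energy of an explicit single-stem structure (outermost pair
    first). Shared by the engine and by enumeration oracles: the sum of the
    stack/defect terms between consecutive pairs plus the hairpin-loop
    initiation for the closing loop."""
    seq = _norm(seq)
    if not pairs:
        raise ValueError("structure must contain at least one pair")
    dg = 0.0
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        li, lj = i2 - i1 - 1, j1 - j2 - 1
        if li == 0 and lj == 0:
            dg += STACK[(seq[i1] + seq[j1], seq[i2] + seq[j2])]
        else:
            dg += _defect_energy(li, lj)
    ik, jk = pairs[-1]
    dg += hairpin_loop_energy(jk - ik - 1)
    return dg


def _fold_engine(seq: str, params: TerminatorParams):
    """Memoized inward minimizer; returns f(i, j, need) -> (dg, trace)."""
    n = len(seq)

    @lru_cache(maxsize=None)
    def f(i: int, j: int, need: int):
        best: Optional[tuple[float, tuple]] = None
        loop_len = j - i - 1
        if need == 0 and loop_len >= params.min_loop:
            best = (hairpin_loop_energy(loop_len), ("loop",))
        for li in range(params.max_bulge + 1):
            i2 = i + 1 + li
            if i2 >= j:
                break
            for lj in range(params.max_bulge + 1):
                j2 = j - 1 - lj
                if j2 <= i2:
                    break
                if not pairable(seq[i2], seq[j2]):
                    continue
                sub = f(i2, j2, max(0, need - 1))
                if sub is None:
                    continue
                if li == 0 and lj == 0:
                    cost = STACK[(seq[i] + seq[j], seq[i2] + seq[j2])]
                else:
                    cost = _defect_energy(li, lj)
                total = cost + sub[0]
                if best is None or total < best[0]:
                    best = (total, ("pair", i2, j2))
        return best

    return f


def _traceback(f, i: int, j: int, need: int) -> list[tuple[int, int]]:
    pairs = [(i, j)]
    while True:
        _, trace = f(i, j, need)
        if trace[0] == "loop":
            return pairs
        _, i, j = trace
        need = max(0, need - 1)
        pairs.append((i, j))


def _make_fold(seq: str, pairs: list[tuple[int, int]], dg: float) -> HairpinFold:
    ik, jk = pairs[-1]
    i1, j1 = pairs[0]
    return HairpinFold(
        stem_pairs=tuple(pairs),
        loop=(ik + 1, jk),
        dg=dg,
        span=(i1, j1 + 1),
    )


def best_hairpin(
    sequence: str, params: TerminatorParams = TerminatorParams(), end_at: Optional[int] = None
) -> Optional[HairpinFold]:
    """Minimum-free-energy single stem-loop of ``sequence``, or None.

    Requires at least ``min_stem`` pairs. With ``end_at`` set, only
    structures whose outermost pair closes exactly at that index (the
    hairpin 3' base) are considered — used to anchor the hairpin at a fixed
    distance from a T-run. Ties are resolved toward the 5'-most span.
    """
    seq = _norm(sequence)
    n = len(seq)
    if n < 2 * params.min_stem + params.min_loop:
        return None
    f = _fold_engine(seq, params)
    need = params.min_stem - 1
    best: Optional[tuple[float, int, int]] = None
    ends = [end_at] if end_at is not None else range(n)
    for j in ends:
        if j is None or j >= n:
            continue
        for i in range(j):
            if not pairable(seq[i], seq[j]):
                continue
            sub = f(i, j, need)
            if sub is None:
                continue
            key = (sub[0], i, j)
            if best is None or key < best:
                best = key
    if best is None:
        return None
    dg, i, j = best
    pairs = _traceback(f, i, j, need)
    return _make_fold(seq, pairs, dg)


# ---------------------------------------------------------------------------
# T-runs
# ---------------------------------------------------------------------------


def find_t_runs(sequence: str, params: TerminatorParams = TerminatorParams()) -> list[tuple[int, int]]:
    """Maximal T-run intervals, 5'->3'.

    Every placement of a ``t_run_window``-nt sliding window containing at
    least ``t_run_min_t`` T residues is marked; overlapping placements are
    merged and each merged interval trimmed to its outermost T residues.
    """
    seq = _norm(sequence)
    n, w = len(seq), params.t_run_window
    if n < w:
        return []
    is_t = [c == "T" for c in seq]
    count = sum(is_t[:w])
    covered = [False] * n
    for start in range(n - w + 1):
        if start > 0:
            count += is_t[start + w - 1] - is_t[start - 1]
        if count >= params.t_run_min_t:
            for k in range(start, start + w):
                covered[k] = True
    runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if covered[i]:
            j = i
            while j < n and covered[j]:
                j += 1
            # trim to the T extent
            a, b = i, j
            while a < b and not is_t[a]:
                a += 1
            while b > a and not is_t[b - 1]:
                b -= 1
            if a < b:
                runs.append((a, b))
            i = j
        else:
            i += 1
    return runs


# ---------------------------------------------------------------------------
# terminator calling
# ---------------------------------------------------------------------------

FoldBackend = Callable[[str, TerminatorParams, Optional[int]], Optional[HairpinFold]]


def _default_fold(window: str, params: TerminatorParams, end_at: Optional[int]) -> Optional[HairpinFold]:
    return best_hairpin(window, params, end_at=end_at)


def call_terminator(
    region: IntergenicRegion | str,
    aptamer_end: int,
    params: TerminatorParams = TerminatorParams(),
    limit: Optional[int] = None,
    aptamer_ref: str = "",
    fold: FoldBackend = _default_fold,
) -> Optional[TerminatorCall]:
    """Call an intrinsic terminator in the window downstream of an aptamer.

    The window is ``[aptamer_end, aptamer_end + window_len)`` clipped to the
    region (and to ``limit``, e.g. the next aptamer's start). T-runs are
    tried 5'->3'; for each, hairpins whose 3' base ends 0..max_gap nt before
    the run start are folded, and among those below the energy threshold the
    one nearest the run wins (ties: lower dg, then 5'-most span). The first
    T-run with a qualifying hairpin yields the call. Coordinates are in the
    region's transcript-orientation system.
    """
    seq = _norm(region.sequence if isinstance(region, IntergenicRegion) else region)
    if not 0 <= aptamer_end <= len(seq):
        raise ValueError(f"aptamer_end {aptamer_end} outside region of length {len(seq)}")
    wend = min(len(seq), aptamer_end + params.window_len)
    if limit is not None:
        wend = min(wend, limit)
    window = seq[aptamer_end:wend]
    for run_start, run_end in find_t_runs(window, params):
        best: Optional[tuple[tuple, int, HairpinFold]] = None
        for gap in range(params.max_gap + 1):
            hp_end = run_start - gap - 1  # index of hairpin 3' base
            if hp_end < 0:
                break
            hp = fold(window, params, hp_end)
            if hp is None or not hp.dg < params.dg_threshold:
                continue
            key = (gap, hp.dg, hp.span[0])
            if best is None or key < best[0]:
                best = (key, gap, hp)
        if best is not None:
            _, gap, hp = best
            off = aptamer_end
            shifted = HairpinFold(
                stem_pairs=tuple((i + off, j + off) for i, j in hp.stem_pairs),
                loop=(hp.loop[0] + off, hp.loop[1] + off),
                dg=hp.dg,
                span=(hp.span[0] + off, hp.span[1] + off),
            )
            call = TerminatorCall(
                aptamer_ref=aptamer_ref,
                t_run=(run_start + off, run_end + off),
                hairpin=shifted,
                gap=gap,
            )
            _check_call(call, params)
            return call
    return None


def _check_call(call: TerminatorCall, params: TerminatorParams) -> None:
    gap = call.t_run[0] - call.hairpin.span[1]
    assert call.gap == gap, "gap inconsistent with hairpin span"
    assert 0 <= call.gap <= params.max_gap, "gap outside configured bound"
    assert call.hairpin.dg < params.dg_threshold, "hairpin above energy threshold"


def scan_interaptamer(
    group: ContiguousGroup,
    region: IntergenicRegion | str,
    params: TerminatorParams = TerminatorParams(),
    fold: FoldBackend = _default_fold,
) -> list[TerminatorCall]:
    """Terminator calls after each non-final aptamer of a contiguous group,
    restricted to the sequence before the next aptamer's start."""
    if group.n_aptamers < 2:
        raise ValueError("scan_interaptamer requires a group with >= 2 aptamers")
    calls: list[TerminatorCall] = []
    for upstream, downstream in zip(group.aptamers, group.aptamers[1:]):
        call = call_terminator(
            region,
            upstream.end,
            params,
            limit=downstream.start,
            aptamer_ref=upstream.hit_id,
            fold=fold,
        )
        if call is not None:
            calls.append(call)
    return calls
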