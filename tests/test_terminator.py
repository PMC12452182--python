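"""T-run detection, hairpin MFE engine and terminator calling."""

import numpy as np
import pytest

import riboarch as ra
from riboarch.terminator import TerminatorParams, structure_energy
from riboarch.synthetic_data import CANONICAL_TERMINATOR

from oracles import best_hairpin_by_enumeration, random_dna, t_runs_brute

P = TerminatorParams()


class TestTRuns:
    def test_no_t_no_run(self):
        assert ra.find_t_runs("AAAAAAAA") == []

    def test_simple_run_covers_the_ts(self):
        runs = ra.find_t_runs("AATTTTTAA")
        assert runs == [(2, 7)]

    def test_merged_run_spans_both_blocks(self):
        # brute-force: all 6-nt windows with >=5 T, union, trim
        seq = "TTTTTATTTTT"
        assert ra.find_t_runs(seq) == t_runs_brute(seq) == [(0, 11)]

    def test_matches_bruteforce_on_random_sequences(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            seq = "".join(rng.choice(list("AT"), size=int(rng.integers(6, 60))))
            assert ra.find_t_runs(seq) == t_runs_brute(seq)


class TestBestHairpin:
    def test_unpairable_sequence_returns_none(self):
        assert ra.best_hairpin("AAAAAAAAAAAA") is None

    def test_gc_stem_matches_enumeration_oracle(self):
        seq = "GGGGGAAAACCCCC"
        fold = ra.best_hairpin(seq)
        dg, pairs = best_hairpin_by_enumeration(seq)
        assert fold.dg == pytest.approx(dg, abs=1e-9)
        assert list(fold.stem_pairs) == pairs

    def test_fold_energy_consistent_with_scorer(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            seq = random_dna(rng, int(rng.integers(15, 26)))
            fold = ra.best_hairpin(seq)
            if fold is not None:
                assert fold.dg == pytest.approx(
                    structure_energy(seq, list(fold.stem_pairs)), abs=1e-9
                )

    def test_dominates_enumeration_on_random_sequences(self):
        """Engine dg is minimal over every enumerated single-stem structure
        (100 random 15-25-mers here; the full 1,000 run in acceptance)."""
        rng = np.random.default_rng(2)
        for _ in range(100):
            seq = random_dna(rng, int(rng.integers(15, 26)))
            fold = ra.best_hairpin(seq)
            oracle = best_hairpin_by_enumeration(seq)
            if oracle is None:
                assert fold is None
            else:
                assert fold is not None
                assert fold.dg == pytest.approx(oracle[0], abs=1e-9)


class TestAgainstRNAfold:
    @pytest.mark.parametrize(
        "seq",
        ["GGCGCGCCGAAAGGCGCGCC", "GGGGGGGGAAAACCCCCCCC", "GCGCGCGAAAACGCGCGC"],
    )
    def test_structure_and_energy_scale_match_rnafold(self, seq):
        """Independent cross-check: on clean stem-loops the packaged engine
        reproduces RNAfold's structure and lands on the same kcal/mol scale
        (the engine's reduced loop tables allow a small offset)."""
        import re
        import subprocess

        out = subprocess.run(
            ["RNAfold", "--noPS"], input=seq + "\n", capture_output=True, text=True,
            check=True,
        ).stdout.splitlines()
        db, dg_txt = out[1].rsplit(" ", 1)
        rnafold_dg = float(re.sub(r"[()\s]", "", dg_txt))
        fold = ra.best_hairpin(seq)
        assert fold is not None
        assert fold.dot_bracket(len(seq)) == db.strip()
        assert fold.dg == pytest.approx(rnafold_dg, abs=3.0)
        assert fold.dg < -10.0


class TestCallTerminator:
    def test_all_a_window_none(self):
        assert ra.call_terminator("A" * 50, 0) is None

    def test_canonical_construct_called_with_zero_gap(self):
        window = "GGGGGGGG" + "AAAA" + "CCCCCCCC" + "TTTTTTTT"
        call = ra.call_terminator(window, 0)
        assert call is not None
        assert call.gap == 0
        assert call.hairpin.dg < -10.0
        # dg equals the exhaustive-oracle optimum for a hairpin ending there
        hp_end = call.hairpin.span[1] - 1
        oracle_dg = min(
            structure_energy(window, pairs)
            for pairs in _stems_ending_at(window, hp_end)
        )
        assert call.hairpin.dg == pytest.approx(oracle_dg, abs=1e-9)

    def test_hairpin_without_t_run_is_not_called(self):
        window = "GGGGGGGG" + "AAAA" + "CCCCCCCC" + "AAAAAAAA"
        assert ra.call_terminator(window, 0) is None

    def test_translation_invariance(self):
        body = CANONICAL_TERMINATOR
        for k in (0, 7, 23):
            seq = "A" * k + body + "A" * 10
            call = ra.call_terminator(seq, k)
            assert call is not None
            base = ra.call_terminator(body + "A" * 10, 0)
            assert call.t_run == (base.t_run[0] + k, base.t_run[1] + k)
            assert call.hairpin.span == (
                base.hairpin.span[0] + k,
                base.hairpin.span[1] + k,
            )
            assert call.gap == base.gap and call.hairpin.dg == pytest.approx(base.hairpin.dg)

    def test_all_calls_satisfy_invariants(self):
        rng = np.random.default_rng(3)
        n_calls = 0
        for _ in range(300):
            seq = random_dna(rng, 60)
            call = ra.call_terminator(seq, 0)
            if call is None:
                continue
            n_calls += 1
            assert call.t_run[0] - call.hairpin.span[1] == call.gap
            assert 0 <= call.gap <= P.max_gap
            assert call.hairpin.dg < P.dg_threshold
        # random GC-balanced 60-mers should only rarely contain a terminator
        assert n_calls < 30


def _stems_ending_at(seq, end_idx):
    from oracles import enumerate_single_stems

    for pairs in enumerate_single_stems(seq):
        if pairs[0][1] == end_idx:
            yield pairs


class TestScanInteraptamer:
    def _group(self, seq, intervals):
        hits = [
            ra.AptamerHit(
                hit_id=f"h{i}", model_class="T-box", start=s, end=e, strand="+",
                bit_score=50.0, evalue=1e-10, region_ref="G1|g1",
            )
            for i, (s, e) in enumerate(intervals)
        ]
        region = ra.IntergenicRegion(
            genome_id="G1", contig="c1", start=0, end=len(seq),
            downstream_gene_id="g1", orientation="+", sequence=seq,
        )
        group = ra.ContiguousGroup(
            region_ref="G1|g1", regulated_gene_ids=["g1"], aptamers=hits,
            junction_gaps=[b[0] - a[1] for a, b in zip(intervals, intervals[1:])],
        )
        return group, region

    def test_tiny_gap_geometrically_impossible(self):
        seq = "A" * 40 + "ACGTACGT" + "A" * 40
        group, region = self._group(seq, [(0, 40), (48, 88)])
        assert ra.scan_interaptamer(group, region) == []

    def test_planted_terminator_found_in_pair(self):
        rng = np.random.default_rng(4)
        a1 = random_dna(rng, 40)
        junction = ra.plant_terminator(random_dna(rng, 45), 1)
        a2 = random_dna(rng, 40)
        seq = a1 + junction + a2
        group, region = self._group(seq, [(0, 40), (85, 125)])
        calls = ra.scan_interaptamer(group, region)
        assert len(calls) == 1
        assert calls[0].aptamer_ref == "h0"
        assert calls[0].hairpin.dg < -10.0

    def test_triple_with_two_planted_terminators(self):
        rng = np.random.default_rng(5)
        a = [random_dna(rng, 30) for _ in range(3)]
        j1 = ra.plant_terminator(random_dna(rng, 40), 1)
        j2 = ra.plant_terminator(random_dna(rng, 40), 1)
        seq = a[0] + j1 + a[1] + j2 + a[2]
        group, region = self._group(seq, [(0, 30), (70, 100), (140, 170)])
        calls = ra.scan_interaptamer(group, region)
        assert len(calls) == 2
        assert [c.aptamer_ref for c in calls] == ["h0", "h1"]

    def test_requires_two_aptamers(self):
        group, region = self._group("A" * 100, [(0, 40)])
        with pytest.raises(ValueError, match=">= 2"):
            ra.scan_interaptamer(group, region)
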