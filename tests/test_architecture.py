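"""Hit deduplication, contiguity grouping and architecture classification."""

import itertools

import numpy as np
import pytest

import riboarch as ra
from riboarch.architecture import ArchParams


def _hit(hid, start, end, score=40.0, model="SAM", evalue=1e-10, region="G1|g1"):
    return ra.AptamerHit(
        hit_id=hid, model_class=model, start=start, end=end, strand="+",
        bit_score=score, evalue=evalue, region_ref=region,
    )


def _region(seq_len=400, gene="g1", genome="G1"):
    return ra.IntergenicRegion(
        genome_id=genome, contig="c1", start=0, end=seq_len,
        downstream_gene_id=gene, orientation="+", sequence="A" * seq_len,
    )


def _dedupe_oracle(hits, params):
    """Independent transitive-closure dedup: build the pairwise-overlap graph
    by literal comparison, take connected components, keep each component's
    best hit."""
    survivors = []
    hits = list(hits)
    comp = {h.hit_id: {h.hit_id} for h in hits}
    by_id = {h.hit_id: h for h in hits}
    for a, b in itertools.combinations(hits, 2):
        if a.region_ref != b.region_ref:
            continue
        ov = max(0, min(a.end, b.end) - max(a.start, b.start))
        if ov > params.overlap_frac * min(len(a), len(b)):
            merged = comp[a.hit_id] | comp[b.hit_id]
            for hid in merged:
                comp[hid] = merged
    seen = set()
    for h in hits:
        key = frozenset(comp[h.hit_id])
        if key in seen:
            continue
        seen.add(key)
        members = [by_id[hid] for hid in key]
        survivors.append(min(members, key=lambda x: (-x.bit_score, x.evalue, x.model_class)))
    return sorted(survivors, key=lambda h: (h.region_ref, h.start, h.end))


class TestDedupeHits:
    def test_overlapping_pair_keeps_best_score(self):
        hits = [_hit("a", 10, 110, score=40), _hit("b", 12, 108, score=35)]
        kept = ra.dedupe_hits(hits)
        assert [h.hit_id for h in kept] == ["a"]

    def test_non_overlapping_both_kept(self):
        hits = [_hit("a", 0, 100), _hit("b", 150, 250)]
        assert len(ra.dedupe_hits(hits)) == 2

    def test_transitive_cluster_matches_closure_oracle(self):
        hits = [
            _hit("a", 0, 100, score=10),
            _hit("b", 40, 140, score=20),
            _hit("c", 80, 180, score=30),
        ]
        kept = ra.dedupe_hits(hits)
        params = ArchParams()
        assert kept == _dedupe_oracle(hits, params)
        assert [h.hit_id for h in kept] == ["c"]

    def test_random_collections_match_oracle(self):
        rng = np.random.default_rng(0)
        params = ArchParams()
        for _ in range(30):
            hits = []
            for i in range(int(rng.integers(2, 10))):
                s = int(rng.integers(0, 200))
                hits.append(
                    _hit(f"h{i}", s, s + int(rng.integers(50, 120)),
                         score=float(rng.integers(10, 60)),
                         model=str(rng.choice(["SAM", "TPP", "T-box"])))
                )
            assert ra.dedupe_hits(hits, params) == _dedupe_oracle(hits, params)


class TestGroupContiguous:
    def test_single_hit_group(self):
        groups = ra.group_contiguous([_hit("a", 0, 100)], [_region()])
        assert len(groups) == 1
        assert groups[0].group_class == "single"
        assert groups[0].regulated_gene_ids == ["g1"]

    def test_junction_gap_arithmetic(self):
        groups = ra.group_contiguous(
            [_hit("a", 0, 100), _hit("b", 135, 235)], [_region()]
        )
        assert groups[0].junction_gaps == [35]

    def test_order_invariance(self):
        hits = [_hit("a", 0, 100), _hit("b", 135, 235)]
        g1 = ra.group_contiguous(hits, [_region()])
        g2 = ra.group_contiguous(hits[::-1], [_region()])
        assert [h.hit_id for h in g1[0].aptamers] == [h.hit_id for h in g2[0].aptamers]
        assert g1[0].junction_gaps == g2[0].junction_gaps

    def test_negative_gap_signals_dedup_failure(self):
        with pytest.raises(ValueError, match="negative junction gap"):
            ra.group_contiguous([_hit("a", 0, 100), _hit("b", 90, 190)], [_region()])

    def test_partition_property(self, default_collection):
        deduped = ra.dedupe_hits(default_collection.hits)
        regions = {r.region_id: r for r in default_collection.regions}
        groups = ra.group_contiguous(deduped, regions)
        assert sum(g.n_aptamers for g in groups) == len(deduped)
        seen = [h.hit_id for g in groups for h in g.aptamers]
        assert len(seen) == len(set(seen))


class TestClassifyGroup:
    def _group(self, gaps):
        starts = [0]
        for gap in gaps:
            starts.append(starts[-1] + 100 + gap)
        hits = [_hit(f"h{i}", s, s + 100) for i, s in enumerate(starts)]
        return ra.ContiguousGroup(
            region_ref="G1|g1", regulated_gene_ids=["g1"], aptamers=hits,
            junction_gaps=list(gaps),
        )

    def test_tandem_with_terminator_evidence(self):
        group = self._group([35])
        term = ra.call_terminator(
            ra.plant_terminator("A" * 35, 1), 0, aptamer_ref="h0"
        )
        assert term is not None
        out = ra.classify_group(group, [term])
        assert out.group_class == "tandem"
        assert out.terminator_evidence == [True]

    def test_small_gap_is_adjacent(self):
        assert ra.classify_group(self._group([5])).group_class == "adjacent"

    def test_boundary_gap_exactly_threshold_is_tandem(self):
        assert ra.classify_group(self._group([20])).group_class == "tandem"

    def test_disagreeing_junctions_are_mixed(self):
        out = ra.classify_group(self._group([5, 35]))
        assert out.group_class == "mixed"
        assert out.junction_classes == ["adjacent", "tandem"]

    def test_terminator_does_not_override_distance(self):
        group = self._group([5])
        fake = ra.call_terminator(ra.plant_terminator("A" * 40, 1), 0, aptamer_ref="h0")
        out = ra.classify_group(group, [fake])
        assert out.group_class == "adjacent"

    def test_order_invariance_of_inputs(self):
        g1 = ra.classify_group(self._group([35, 40]))
        g2 = ra.classify_group(self._group([35, 40]), terminators=[])
        assert g1.group_class == g2.group_class == "tandem"


class TestHomogeneity:
    def _group(self, models):
        hits = [
            _hit(f"h{i}", i * 150, i * 150 + 100, model=m) for i, m in enumerate(models)
        ]
        return ra.ContiguousGroup(region_ref="G1|g1", regulated_gene_ids=["g1"], aptamers=hits)

    def test_same_family_homogeneous(self, fam_map):
        out = ra.label_homogeneity(self._group(["T-box", "T-box"]), fam_map)
        assert out.homogeneity == "homogeneous"
        assert out.architecture_string == "T-box T-box"

    def test_different_families_heterogeneous(self, fam_map):
        out = ra.label_homogeneity(self._group(["T-box", "Guanidine-I"]), fam_map)
        assert out.homogeneity == "heterogeneous"
        assert out.architecture_string == "T-box Guanidine"

    def test_same_family_different_classes_homogeneous(self, fam_map):
        # two SAM-family classes: homogeneity is about the sensed ligand
        out = ra.label_homogeneity(self._group(["SAM", "SAM-IV"]), fam_map)
        assert out.homogeneity == "homogeneous"
        assert out.architecture_string == "SAM SAM"

    def test_single_aptamer_na(self, fam_map):
        assert ra.label_homogeneity(self._group(["TPP"]), fam_map).homogeneity == "n/a"


class TestPlantedRecovery:
    def test_architecture_and_homogeneity_match_ground_truth(
        self, default_collection, classified
    ):
        groups, _calls = classified
        truth = {g["region_ref"]: g for g in default_collection.truth.groups}
        assert len(groups) == len(truth)
        for g in groups:
            t = truth[g.region_ref]
            assert g.group_class == t["expected_class"], g.region_ref
            assert g.homogeneity == t["homogeneity"], g.region_ref
            assert g.junction_gaps == t["junction_gaps"]
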