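"""Grouping of aptamer hits and architecture classification.

A set of riboswitches is *contiguous* when the aptamers share one intergenic
region and regulate the same gene(s). Each junction between consecutive
aptamers is labeled by the gap between them: gaps below the adjacency
threshold (20 nt — the minimum space an intrinsic terminator needs) mean
*adjacent aptamers* sharing one expression platform; gaps of at least the
threshold mean *tandemly arranged* riboswitches, each a complete
aptamer + platform unit. Terminator calls are recorded as supporting
evidence per tandem junction but never override the distance rule.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from ._records import AptamerHit, ContiguousGroup, IntergenicRegion, TerminatorCall

GROUP_SINGLE = "single"
GROUP_TANDEM = "tandem"
GROUP_ADJACENT = "adjacent"
GROUP_MIXED = "mixed"


@dataclass(frozen=True)
class ArchParams:
    adjacency_threshold: int = 20  # nt; gap < threshold -> adjacent
    overlap_frac: float = 0.5  # of the shorter hit, for deduplication

    def __post_init__(self) -> None:
        if self.adjacency_threshold < 0:
            raise ValueError("adjacency_threshold must be >= 0")
        if not 0 < self.overlap_frac <= 1:
            raise ValueError("overlap_frac must be in (0, 1]")


def _overlap(a: AptamerHit, b: AptamerHit) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def dedupe_hits(hits: Iterable[AptamerHit], params: ArchParams = ArchParams()) -> list[AptamerHit]:
    """Collapse overlapping model matches on the same region.

    Hits whose intervals overlap by more than ``overlap_frac`` of the shorter
    hit compete; within each transitive-overlap cluster only the best hit
    survives (highest bit score, then lower E-value, then lexicographically
    smallest model name). Prevents one aptamer matched by several related
    models from being counted as a contiguous pair.
    """
    out: list[AptamerHit] = []
    by_region: dict[str, list[AptamerHit]] = collections.defaultdict(list)
    for h in hits:
        by_region[h.region_ref].append(h)
    for region_ref in sorted(by_region):
        rhits = sorted(by_region[region_ref], key=lambda h: (h.start, h.end, h.model_class))
        n = len(rhits)
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(n):
            for j in range(i + 1, n):
                if rhits[j].start >= rhits[i].end:
                    break
                shorter = min(len(rhits[i]), len(rhits[j]))
                if _overlap(rhits[i], rhits[j]) > params.overlap_frac * shorter:
                    parent[find(i)] = find(j)
        clusters: dict[int, list[AptamerHit]] = collections.defaultdict(list)
        for i, h in enumerate(rhits):
            clusters[find(i)].append(h)
        for members in clusters.values():
            best = min(members, key=lambda h: (-h.bit_score, h.evalue, h.model_class))
            out.append(best)
    return sorted(out, key=lambda h: (h.region_ref, h.start, h.end))


def group_contiguous(
    hits: Iterable[AptamerHit],
    regions: Iterable[IntergenicRegion] | Mapping[str, IntergenicRegion],
) -> list[ContiguousGroup]:
    """One ContiguousGroup per region holding at least one hit.

    Aptamers are sorted 5'->3' in transcript orientation; junction gaps are
    end-of-upstream to start-of-downstream distances. A negative gap after
    deduplication signals a dedup failure and raises.
    """
    if not isinstance(regions, Mapping):
        regions = {r.region_id: r for r in regions}
    by_region: dict[str, list[AptamerHit]] = collections.defaultdict(list)
    for h in hits:
        if not h.region_ref:
            raise ValueError(f"hit {h.hit_id} carries no region_ref")
        by_region[h.region_ref].append(h)
    groups: list[ContiguousGroup] = []
    for region_ref in sorted(by_region):
        rhits = sorted(by_region[region_ref], key=lambda h: (h.start, h.end))
        gaps = []
        for a, b in zip(rhits, rhits[1:]):
            gap = b.start - a.end
            if gap < 0:
                raise ValueError(
                    f"negative junction gap ({gap} nt) between {a.hit_id} and {b.hit_id}; "
                    "deduplicate hits before grouping"
                )
            gaps.append(gap)
        region = regions.get(region_ref)
        regulated = [region.downstream_gene_id] if region is not None else []
        groups.append(
            ContiguousGroup(
                region_ref=region_ref,
                regulated_gene_ids=regulated,
                aptamers=rhits,
                junction_gaps=gaps,
                group_class=GROUP_SINGLE if len(rhits) == 1 else "",
            )
        )
    return groups


def classify_group(
    group: ContiguousGroup,
    terminators: Sequence[TerminatorCall] = (),
    params: ArchParams = ArchParams(),
) -> ContiguousGroup:
    """Label each junction and derive the group class from the gaps.

    A junction is *adjacent* when its gap is strictly below the adjacency
    threshold, *tandem* otherwise (a gap of exactly the threshold is tandem).
    The group class is the common junction label, ``mixed`` when junctions
    disagree, or ``single``. Terminator calls matching the upstream aptamer
    of a junction are recorded as evidence, without overriding the distance
    rule.
    """
    with_term = {t.aptamer_ref for t in terminators}
    junction_classes = [
        GROUP_ADJACENT if gap < params.adjacency_threshold else GROUP_TANDEM
        for gap in group.junction_gaps
    ]
    evidence = [a.hit_id in with_term for a in group.aptamers[:-1]]
    if group.n_aptamers == 1:
        group_class = GROUP_SINGLE
    elif all(c == GROUP_TANDEM for c in junction_classes):
        group_class = GROUP_TANDEM
    elif all(c == GROUP_ADJACENT for c in junction_classes):
        group_class = GROUP_ADJACENT
    else:
        group_class = GROUP_MIXED
    group.junction_classes = junction_classes
    group.group_class = group_class
    group.terminator_evidence = evidence
    return group


def label_homogeneity(group: ContiguousGroup, fam: Mapping[str, str]) -> ContiguousGroup:
    """Homogeneous iff all aptamers sense the same ligand family.

    The architecture string is the 5'->3' space-joined family names (class
    name as fallback for unmapped models). Single-aptamer groups are 'n/a'.
    """
    families = [h.family or fam.get(h.model_class, h.model_class) for h in group.aptamers]
    group.architecture_string = " ".join(families)
    if group.n_aptamers < 2:
        group.homogeneity = "n/a"
    else:
        group.homogeneity = "homogeneous" if len(set(families)) == 1 else "heterogeneous"
    return group


def classify_collection(
    hits: Iterable[AptamerHit],
    regions: Iterable[IntergenicRegion] | Mapping[str, IntergenicRegion],
    fam: Mapping[str, str],
    params: ArchParams = ArchParams(),
    terminator_params=None,
) -> tuple[list[ContiguousGroup], dict[str, list[TerminatorCall]]]:
    """Full grouping + terminator scan + classification for a hit collection.

    Returns the classified groups and, per region, the inter-aptamer
    terminator calls used as evidence.
    """
    from .terminator import TerminatorParams, scan_interaptamer

    tparams = terminator_params or TerminatorParams()
    if not isinstance(regions, Mapping):
        regions = {r.region_id: r for r in regions}
    deduped = dedupe_hits(hits, params)
    groups = group_contiguous(deduped, regions)
    calls_by_region: dict[str, list[TerminatorCall]] = {}
    for group in groups:
        calls: list[TerminatorCall] = []
        if group.n_aptamers >= 2 and group.region_ref in regions:
            calls = scan_interaptamer(group, regions[group.region_ref], tparams)
        calls_by_region[group.region_ref] = calls
        classify_group(group, calls, params)
        label_homogeneity(group, fam)
    return groups, calls_by_region


def groups_to_table(groups: Iterable[ContiguousGroup]):
    """Flat pandas DataFrame view of classified groups (one row per group)."""
    import pandas as pd

    rows = []
    for g in groups:
        rows.append(
            {
                "region_ref": g.region_ref,
                "regulated_genes": ",".join(g.regulated_gene_ids),
                "n_aptamers": g.n_aptamers,
                "architecture_string": g.architecture_string,
                "group_class": g.group_class,
                "homogeneity": g.homogeneity,
                "junction_gaps": ",".join(map(str, g.junction_gaps)),
                "terminator_evidence": ",".join("yes" if e else "no" for e in g.terminator_evidence),
            }
        )
    return pd.DataFrame(rows)
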