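"""Synthetic genome collections with planted, fully known ground truth.

The generator emulates the statistical structure the enrichment analyses
assume: a multi-phylum collection of annotated genomes, per-gene riboswitch
regulation with per-phylum and per-COG rate multipliers, planted aptamer
hits with bit scores, planted contiguous architectures (tandem / adjacent,
homogeneous / heterogeneous) with controlled junction gaps, and canonical
intrinsic terminators spliced into tandem junctions. Background intergenic
sequence comes from a first-order Markov chain with configurable GC.

Every piece of randomness flows from one root seed through named substreams
(per genome, per purpose), so outputs are byte-identical across runs and
independent of iteration order.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._records import AptamerHit, GeneRecord, IntergenicRegion
from . import io_formats

ARCH_SINGLE = "single"
ARCH_TANDEM_PAIR = "tandem-pair"
ARCH_ADJACENT_PAIR = "adjacent-pair"
ARCH_TANDEM_TRIPLE = "tandem-triple"
_ARCH_SIZES = {
    ARCH_SINGLE: 1,
    ARCH_TANDEM_PAIR: 2,
    ARCH_ADJACENT_PAIR: 2,
    ARCH_TANDEM_TRIPLE: 3,
}
_ARCH_CLASS = {  # architecture -> expected recovered group_class
    ARCH_SINGLE: "single",
    ARCH_TANDEM_PAIR: "tandem",
    ARCH_ADJACENT_PAIR: "adjacent",
    ARCH_TANDEM_TRIPLE: "tandem",
}

# Canonical intrinsic terminator: 8-bp G:C stem, 4-nt loop, 8-nt T tail.
TERMINATOR_STEM5 = "GGCGCGCC"
TERMINATOR_LOOP = "GAAA"
TERMINATOR_STEM3 = "GGCGCGCC"  # reverse complement of the 5' arm
TERMINATOR_TAIL = "TTTTTTTT"
CANONICAL_TERMINATOR = TERMINATOR_STEM5 + TERMINATOR_LOOP + TERMINATOR_STEM3 + TERMINATOR_TAIL


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated collection.

    The default per-gene riboswitch rate (0.0036) matches the prevalence of
    riboswitch-regulated genes observed across large non-redundant
    prokaryotic genome surveys (~0.36% of genes); phylum and COG multipliers
    scale it. Tandem junction gaps (30-45 nt) leave room for the 28-nt
    canonical terminator and sit well above the 20-nt adjacency threshold;
    adjacent gaps (3-15 nt) sit well below it.
    """

    n_phyla: int = 5
    genomes_per_phylum: int = 4
    genes_per_genome: int = 500
    mean_intergenic_len: int = 150
    base_riboswitch_rate: float = 0.0036
    phylum_rate_multipliers: dict = field(default_factory=dict)
    architecture_mix: dict = field(
        default_factory=lambda: {
            ARCH_SINGLE: 0.50,
            ARCH_TANDEM_PAIR: 0.25,
            ARCH_ADJACENT_PAIR: 0.20,
            ARCH_TANDEM_TRIPLE: 0.05,
        }
    )
    family_weights: dict = field(
        default_factory=lambda: {
            "T-box": 0.30,
            "TPP": 0.15,
            "SAM": 0.15,
            "Cobalamin": 0.10,
            "FMN": 0.10,
            "Glycine": 0.10,
            "c-di-GMP-I": 0.05,
            "Lysine": 0.05,
        }
    )
    cog_pool: tuple = (
        "COG0147", "COG0512", "COG0547", "COG0134", "COG0135", "COG0133",
        "COG0159", "COG0509", "COG0404", "COG0403", "COG1003", "COG0112",
        "COG0119", "COG0473", "COG0065", "COG0066", "COG0441", "COG0352",
        "COG0422", "COG0307",
    )
    cog_enrichment: dict = field(default_factory=dict)
    cog_missing_rate: float = 0.10
    terminator_plant_prob: float = 1.0
    tandem_gap_range: tuple = (30, 45)
    adjacent_gap_range: tuple = (3, 15)
    adjacency_threshold: int = 20
    aptamer_len_range: tuple = (70, 130)
    nominal_cutoff_bits: float = 20.0
    decoy_hit_rate: float = 0.0
    gc_content: float = 0.50
    markov_persistence: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        mix_total = sum(self.architecture_mix.values())
        if abs(mix_total - 1.0) > 1e-9:
            raise ValueError(f"architecture_mix must sum to 1, got {mix_total}")
        if abs(sum(self.family_weights.values()) - 1.0) > 1e-9:
            raise ValueError("family_weights must sum to 1")
        for prob in (self.terminator_plant_prob, self.base_riboswitch_rate, self.decoy_hit_rate):
            if not 0.0 <= prob <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.tandem_gap_range[0] <= self.adjacency_threshold:
            raise ValueError(
                "tandem gap lower bound must exceed the adjacency threshold "
                f"({self.tandem_gap_range[0]} <= {self.adjacency_threshold})"
            )
        if self.adjacent_gap_range[1] >= self.adjacency_threshold:
            raise ValueError(
                "adjacent gap upper bound must stay below the adjacency threshold "
                f"({self.adjacent_gap_range[1]} >= {self.adjacency_threshold})"
            )
        if self.tandem_gap_range[0] < len(CANONICAL_TERMINATOR) + 1:
            raise ValueError("tandem gaps leave no room for the canonical terminator")


@dataclass
class GroundTruth:
    """Planted truth for one simulated collection, consistent with the files."""

    regulated_genes: list  # of (genome_id, gene_id)
    groups: list  # of dicts, see simulate_collection
    decoy_hit_ids: list

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            regulated_genes=[tuple(x) for x in d["regulated_genes"]],
            groups=d["groups"],
            decoy_hit_ids=d["decoy_hit_ids"],
        )


@dataclass
class SimulatedCollection:
    genes: list
    regions: list
    hits: list
    truth: GroundTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genes": outdir / "genes.tsv",
            "regions": outdir / "regions.fasta",
            "hits": outdir / "hits.tbl",
            "truth": outdir / "truth.json",
        }
        io_formats.write_gene_table(self.genes, paths["genes"])
        io_formats.regions_to_fasta(self.regions, paths["regions"])
        io_formats.write_tblout(self.hits, paths["hits"])
        self.truth.to_json(paths["truth"])
        return paths


def plant_terminator(sequence: str, position: int) -> str:
    """Splice the canonical terminator element into ``sequence`` at
    ``position`` (overwriting in place, length preserved). The element is
    detected by the default terminator detector by construction."""
    if position < 0 or position + len(CANONICAL_TERMINATOR) > len(sequence):
        raise ValueError(
            f"no room for a {len(CANONICAL_TERMINATOR)}-nt terminator at position "
            f"{position} in a {len(sequence)}-nt sequence"
        )
    return (
        sequence[:position]
        + CANONICAL_TERMINATOR
        + sequence[position + len(CANONICAL_TERMINATOR):]
    )


def markov_background(length: int, rng: np.random.Generator, gc: float = 0.5,
                      persistence: float = 0.2) -> str:
    """First-order Markov background: stationary base composition set by
    ``gc``, with probability ``persistence`` of repeating the previous base
    (locally correlated composition, as in real intergenic DNA)."""
    if length <= 0:
        return ""
    bases = np.array(list("ACGT"))
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = np.empty(length, dtype=np.int64)
    idx[0] = rng.choice(4, p=probs)
    repeat = rng.random(length) < persistence
    draws = rng.choice(4, size=length, p=probs)
    for i in range(1, length):
        idx[i] = idx[i - 1] if repeat[i] else draws[i]
    return "".join(bases[idx])


def _genome_rng(cfg: SimConfig, p: int, g: int, purpose: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, p, g, purpose])


def simulate_collection(cfg: SimConfig = SimConfig()) -> SimulatedCollection:
    """Generate one collection: gene table, intergenic FASTA, tblout hits and
    the planted ground truth.

    Genes are laid out head-to-tail on one plus-strand contig per genome,
    each preceded by its intergenic region. Regulated genes receive planted
    aptamers (architecture drawn from ``architecture_mix``, classes from
    ``family_weights``) written as tblout rows scoring above the nominal
    cutoff; tandem junctions receive the canonical terminator with
    probability ``terminator_plant_prob``. Decoy sub-cutoff hits are planted
    in unregulated regions at ``decoy_hit_rate``.
    """
    fam_map = io_formats.packaged_family_map()
    arch_names = sorted(cfg.architecture_mix)
    arch_probs = np.array([cfg.architecture_mix[a] for a in arch_names])
    class_names = sorted(cfg.family_weights)
    class_probs = np.array([cfg.family_weights[c] for c in class_names])

    genes: list[GeneRecord] = []
    regions: list[IntergenicRegion] = []
    hits: list[AptamerHit] = []
    regulated: list[tuple[str, str]] = []
    truth_groups: list[dict] = []
    decoy_ids: list[str] = []

    for p in range(cfg.n_phyla):
        phylum = f"Phylum{p:02d}"
        mult = cfg.phylum_rate_multipliers.get(phylum, 1.0)
        for g in range(cfg.genomes_per_phylum):
            genome_id = f"G{p:02d}_{g:02d}"
            species = f"Species_{p:02d}_{g:02d}"
            contig = f"{genome_id}_c1"
            rng = _genome_rng(cfg, p, g, 0)
            cursor = 0
            for i in range(cfg.genes_per_genome):
                gene_id = f"{genome_id}_g{i:04d}"
                has_cog = rng.random() >= cfg.cog_missing_rate
                cog = str(rng.choice(np.array(cfg.cog_pool))) if has_cog else None
                cog_mult = cfg.cog_enrichment.get(cog, 1.0) if cog else 1.0
                p_reg = min(0.95, cfg.base_riboswitch_rate * mult * cog_mult)
                is_reg = rng.random() < p_reg

                if is_reg:
                    arch = arch_names[rng.choice(len(arch_names), p=arch_probs)]
                    seq, gene_hits, group = _build_regulated_region(
                        cfg, rng, arch, class_names, class_probs, fam_map
                    )
                else:
                    length = max(1, int(rng.geometric(1.0 / cfg.mean_intergenic_len)))
                    seq = markov_background(length, rng, cfg.gc_content, cfg.markov_persistence)
                    gene_hits, group = [], None

                region_start = cursor
                region_end = cursor + len(seq)
                gene_len = int(rng.integers(300, 1501))
                gene_start, gene_end = region_end, region_end + gene_len
                cursor = gene_end

                region = IntergenicRegion(
                    genome_id=genome_id,
                    contig=contig,
                    start=region_start,
                    end=region_end,
                    downstream_gene_id=gene_id,
                    orientation="+",
                    sequence=seq,
                )
                genes.append(
                    GeneRecord(
                        genome_id=genome_id,
                        species=species,
                        phylum=phylum,
                        contig=contig,
                        start=gene_start,
                        end=gene_end,
                        strand="+",
                        gene_id=gene_id,
                        cog_id=cog,
                    )
                )
                regions.append(region)

                if is_reg:
                    regulated.append((genome_id, gene_id))
                    for h in gene_hits:
                        hits.append(
                            AptamerHit(
                                **{
                                    **h.__dict__,
                                    "region_ref": region.region_id,
                                    "genome_id": genome_id,
                                    "contig": contig,
                                    "hit_id": f"{region.region_id}:{h.start}-{h.end}:{h.model_class}",
                                }
                            )
                        )
                    group.update(
                        region_ref=region.region_id,
                        genome_id=genome_id,
                        gene_id=gene_id,
                        phylum=phylum,
                        cog_id=cog,
                    )
                    truth_groups.append(group)
                elif cfg.decoy_hit_rate > 0 and rng.random() < cfg.decoy_hit_rate:
                    decoy = _plant_decoy(cfg, rng, region, class_names, class_probs)
                    if decoy is not None:
                        hits.append(decoy)
                        decoy_ids.append(decoy.hit_id)

    truth = GroundTruth(regulated_genes=regulated, groups=truth_groups, decoy_hit_ids=decoy_ids)
    return SimulatedCollection(genes=genes, regions=regions, hits=hits, truth=truth)


def _build_regulated_region(cfg, rng, arch, class_names, class_probs, fam_map):
    """Region sequence + local-coordinate hits + truth record for one
    regulated gene."""
    n_apt = _ARCH_SIZES[arch]
    classes = [class_names[rng.choice(len(class_names), p=class_probs)] for _ in range(n_apt)]
    apt_lens = [int(rng.integers(cfg.aptamer_len_range[0], cfg.aptamer_len_range[1] + 1)) for _ in range(n_apt)]
    junction_kind = {
        ARCH_SINGLE: [],
        ARCH_TANDEM_PAIR: ["tandem"],
        ARCH_ADJACENT_PAIR: ["adjacent"],
        ARCH_TANDEM_TRIPLE: ["tandem", "tandem"],
    }[arch]
    gaps = []
    for kind in junction_kind:
        lo, hi = cfg.tandem_gap_range if kind == "tandem" else cfg.adjacent_gap_range
        gaps.append(int(rng.integers(lo, hi + 1)))

    lead = 15
    tail = 35
    parts = [markov_background(lead, rng, cfg.gc_content, cfg.markov_persistence)]
    pos = lead
    hits = []
    terminators = []
    for idx in range(n_apt):
        start, end = pos, pos + apt_lens[idx]
        score = float(rng.uniform(cfg.nominal_cutoff_bits + 5, cfg.nominal_cutoff_bits + 40))
        evalue = float(10.0 ** -rng.uniform(5, 20))
        hits.append(
            AptamerHit(
                hit_id=f"local:{start}-{end}:{classes[idx]}",
                model_class=classes[idx],
                start=start,
                end=end,
                strand="+",
                bit_score=round(score, 1),
                evalue=evalue,
                family=fam_map.get(classes[idx], ""),
            )
        )
        parts.append(markov_background(apt_lens[idx], rng, cfg.gc_content, cfg.markov_persistence))
        pos = end
        if idx < n_apt - 1:
            gap = gaps[idx]
            junction = markov_background(gap, rng, cfg.gc_content, cfg.markov_persistence)
            planted = None
            if junction_kind[idx] == "tandem" and rng.random() < cfg.terminator_plant_prob:
                junction = plant_terminator(junction, 1)
                planted = {"start": pos + 1, "end": pos + 1 + len(CANONICAL_TERMINATOR)}
            terminators.append(planted)
            parts.append(junction)
            pos += gap
    parts.append(markov_background(tail, rng, cfg.gc_content, cfg.markov_persistence))
    seq = "".join(parts)

    families = [fam_map.get(c, c) for c in classes]
    group = {
        "architecture": arch,
        "expected_class": _ARCH_CLASS[arch],
        "n_aptamers": n_apt,
        "classes": classes,
        "families": families,
        "homogeneity": "n/a" if n_apt == 1 else (
            "homogeneous" if len(set(families)) == 1 else "heterogeneous"
        ),
        "junction_gaps": gaps,
        "terminators": terminators,
        "aptamer_intervals": [[h.start, h.end] for h in hits],
    }
    return seq, hits, group


def _plant_decoy(cfg, rng, region, class_names, class_probs):
    min_len = cfg.aptamer_len_range[0]
    if len(region) < min_len + 2:
        return None
    length = min(len(region) - 1, int(rng.integers(min_len, cfg.aptamer_len_range[1] + 1)))
    start = int(rng.integers(0, len(region) - length))
    cls = class_names[rng.choice(len(class_names), p=class_probs)]
    score = round(float(rng.uniform(cfg.nominal_cutoff_bits - 15, cfg.nominal_cutoff_bits)), 1)
    return AptamerHit(
        hit_id=f"{region.region_id}:{start}-{start + length}:{cls}",
        model_class=cls,
        start=start,
        end=start + length,
        strand="+",
        bit_score=score,
        evalue=float(10.0 ** -rng.uniform(0, 3)),
        region_ref=region.region_id,
        genome_id=region.genome_id,
        contig=region.contig,
    )


def simulate_phylum_counts(cfg: SimConfig, replicate: int = 0) -> pd.DataFrame:
    """Counts-level fast path: per-phylum gene / regulated-gene / riboswitch-
    instance totals without materializing sequences.

    Statistically identical to aggregating :func:`simulate_collection` over
    genomes (per-gene Bernoulli regulation, architecture sizes from the
    mix), drawn as binomial/multinomial totals per genome. Used for power
    and type-I calibration studies at survey scale. COG effects are not
    applied (counts are marginal over COGs when ``cog_enrichment`` is empty).
    """
    if cfg.cog_enrichment:
        raise ValueError("counts-level simulation does not support cog_enrichment")
    arch_names = sorted(cfg.architecture_mix)
    arch_probs = np.array([cfg.architecture_mix[a] for a in arch_names])
    sizes = np.array([_ARCH_SIZES[a] for a in arch_names])
    rows = []
    for p in range(cfg.n_phyla):
        phylum = f"Phylum{p:02d}"
        mult = cfg.phylum_rate_multipliers.get(phylum, 1.0)
        rate = min(0.95, cfg.base_riboswitch_rate * mult)
        n_genes = cfg.genomes_per_phylum * cfg.genes_per_genome
        n_reg = 0
        n_inst = 0
        for g in range(cfg.genomes_per_phylum):
            rng = np.random.default_rng([cfg.seed, replicate, p, g, 1])
            reg = int(rng.binomial(cfg.genes_per_genome, rate))
            counts = rng.multinomial(reg, arch_probs)
            n_reg += reg
            n_inst += int((counts * sizes).sum())
        rows.append(
            {"phylum": phylum, "n_genes": n_genes, "n_regulated": n_reg, "n_riboswitches": n_inst}
        )
    return pd.DataFrame(rows)
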