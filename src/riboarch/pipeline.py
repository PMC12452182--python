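"""End-to-end composition of the pipeline stages.

Order: (optional) empirical cutoff filtering → family assignment →
deduplication → contiguity grouping → inter-aptamer terminator scan →
architecture classification → homogeneity labeling → enrichment analyses.
Outputs are pure functions of (inputs, parameters, seed); a run manifest
records parameter values, input digests and the tool version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io_formats
from .architecture import ArchParams, classify_collection, groups_to_table
from .enrichment import ANALYSES, riboswitch_table, run_analyses
from .shuffle_calibrate import ShuffleParams, apply_cutoffs
from .terminator import TerminatorParams

logger = logging.getLogger("riboarch")

EXIT_OK = 0
EXIT_BAD_INPUT = 2
EXIT_STAGE_FAILURE = 3


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    genes_path: Path
    regions_path: Path
    hits_path: Path
    family_map_path: Optional[Path] = None  # None -> packaged map
    cutoffs_path: Optional[Path] = None  # model\tcutoff_bits TSV
    out_dir: Path = Path("riboarch_out")
    analyses: list = field(default_factory=lambda: sorted(ANALYSES))
    arch_params: ArchParams = field(default_factory=ArchParams)
    terminator_params: TerminatorParams = field(default_factory=TerminatorParams)
    shuffle_params: ShuffleParams = field(default_factory=ShuffleParams)
    seed: int = 0
    bh: bool = False

    def validate(self) -> None:
        for label, p in [
            ("genes", self.genes_path),
            ("regions", self.regions_path),
            ("hits", self.hits_path),
            ("family-map", self.family_map_path),
            ("cutoffs", self.cutoffs_path),
        ]:
            if p is not None and not Path(p).exists():
                raise StageError("config", f"{label} file not found: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    """Context manager: per-stage timing and stage-named error wrapping."""

    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                logger.info("stage %s: done in %.2fs", name, dt)
                return False
            if isinstance(exc, StageError):
                return False
            raise StageError(name, str(exc)) from exc

    return _Ctx()


def read_cutoffs_tsv(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    if "model" not in df.columns or "cutoff_bits" not in df.columns:
        raise ValueError(f"{path}: cutoffs TSV needs columns model, cutoff_bits")
    return dict(zip(df["model"], df["cutoff_bits"].astype(float)))


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run all stages; returns the paths of the result files."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _stage("load"):
        genes = io_formats.read_gene_table(config.genes_path, dialect="tsv")
        sequences = io_formats.read_fasta(config.regions_path)
        hits = io_formats.read_tblout(config.hits_path)
        fam = (
            io_formats.read_family_map(config.family_map_path)
            if config.family_map_path
            else io_formats.packaged_family_map()
        )
        genes_df = pd.DataFrame([dataclasses.asdict(g) for g in genes])

    with _stage("regions"):
        # regions.fasta ids are region ids "<genome>|<gene>"
        by_gene = {(g.genome_id, g.gene_id): g for g in genes}
        regions = {}
        for rid, seq in sequences.items():
            genome_id, gene_id = rid.split("|", 1)
            gene = by_gene.get((genome_id, gene_id))
            if gene is None:
                raise ValueError(f"region {rid}: downstream gene not in gene table")
            regions[rid] = io_formats.IntergenicRegion(
                genome_id=genome_id,
                contig=gene.contig,
                start=0,
                end=len(seq),
                downstream_gene_id=gene_id,
                orientation=gene.strand,
                sequence=seq,
            )

    with _stage("cutoffs"):
        if config.cutoffs_path:
            cutoffs = read_cutoffs_tsv(config.cutoffs_path)
            hits = apply_cutoffs(hits, cutoffs)
        hits = io_formats.assign_families(hits, fam)
        hits = io_formats.assign_regions(hits, regions.values())

    with _stage("classify"):
        groups, calls_by_region = classify_collection(
            hits,
            regions,
            fam,
            params=config.arch_params,
            terminator_params=config.terminator_params,
        )
        groups_df = groups_to_table(groups)

    with _stage("terminators"):
        trows = []
        for region_ref, calls in sorted(calls_by_region.items()):
            region = regions[region_ref]
            for c in calls:
                trows.append(
                    {
                        "region_ref": region_ref,
                        "aptamer_ref": c.aptamer_ref,
                        "t_run_start": c.t_run[0],
                        "t_run_end": c.t_run[1],
                        "hairpin_start": c.hairpin.span[0],
                        "hairpin_end": c.hairpin.span[1],
                        "dot_bracket": c.hairpin.dot_bracket(len(region))[
                            c.hairpin.span[0]: c.hairpin.span[1]
                        ],
                        "dg_kcal_mol": round(c.hairpin.dg, 2),
                        "gap": c.gap,
                    }
                )
        terminators_df = pd.DataFrame(
            trows,
            columns=[
                "region_ref", "aptamer_ref", "t_run_start", "t_run_end",
                "hairpin_start", "hairpin_end", "dot_bracket", "dg_kcal_mol", "gap",
            ],
        )

    with _stage("enrich"):
        rs = riboswitch_table(groups, genes_df)
        enrichment_df = run_analyses(config.analyses, genes_df, rs, bh=config.bh)

    with _stage("write"):
        paths = {
            "groups": out / "groups.tsv",
            "terminators": out / "terminators.tsv",
            "enrichment": out / "enrichment.tsv",
            "manifest": out / "manifest.json",
        }
        groups_df.to_csv(paths["groups"], sep="\t", index=False)
        terminators_df.to_csv(paths["terminators"], sep="\t", index=False)
        enrichment_df.to_csv(paths["enrichment"], sep="\t", index=False)
        manifest = {
            "tool": "riboarch",
            "version": _version(),
            "seed": config.seed,
            "analyses": list(config.analyses),
            "params": {
                "arch": dataclasses.asdict(config.arch_params),
                "terminator": dataclasses.asdict(config.terminator_params),
                "shuffle": dataclasses.asdict(config.shuffle_params),
            },
            "inputs": {
                str(p): _sha256(Path(p))
                for p in [config.genes_path, config.regions_path, config.hits_path]
                if p is not None
            },
        }
        with open(paths["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    return paths


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("riboarch")
    except Exception:
        return "unknown"
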