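"""Hypergeometric enrichment analyses over a classified riboswitch collection.

Each analysis id (S6, S7, S9..S19) names one stratified family of one-sided
upper-tail hypergeometric tests: given a population of N elements of which K
are "successes", and a stratum (a phylum, riboswitch family, COG, or a
composite) holding n elements with k successes, the reported p-value is
P(X >= k) for X ~ Hypergeometric(N, K, n) — the probability of observing the
same or a greater number of occurrences by drawing the stratum at random.

Counting units follow the analysis: gene-denominated rows count distinct
regulated genes (a gene under two aptamers counts once); riboswitch-
denominated rows count aptamer instances after deduplication. Raw p-values
are primary; a Benjamini-Hochberg column is an opt-in convenience.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from ._records import ContiguousGroup

ANALYSES = {
    "S6": "phylum enriched in riboswitches (genes / riboswitches)",
    "S7": "phylum enriched in contiguous riboswitches",
    "S9": "phylum enriched in tandemly arranged riboswitches",
    "S10": "phylum enriched in adjacent aptamers",
    "S11": "family enriched among contiguous riboswitches",
    "S12": "family enriched among tandemly arranged riboswitches",
    "S13": "family enriched among adjacent-aptamer riboswitches",
    "S14": "family enrichment within a phylum (all riboswitches)",
    "S15": "contiguous-family enrichment within a phylum",
    "S16": "COG enriched for riboswitch regulation",
    "S17": "COG enriched for riboswitch regulation within a phylum",
    "S18": "COG enriched for contiguous-riboswitch regulation",
    "S19": "COG enriched for contiguous-riboswitch regulation within a phylum",
}


@dataclass(frozen=True)
class EnrichmentTask:
    analysis_id: str
    stratum: str
    N: int  # population elements
    K: int  # population successes
    n: int  # stratum elements
    k: int  # stratum successes

    def __post_init__(self) -> None:
        if not (0 <= self.K <= self.N and 0 <= self.n <= self.N):
            raise ValueError(f"invalid task counts N={self.N} K={self.K} n={self.n}")
        if not 0 <= self.k <= min(self.n, self.K):
            raise ValueError(
                f"invalid success count k={self.k} for N={self.N} K={self.K} n={self.n} "
                f"({self.analysis_id}/{self.stratum})"
            )


@dataclass(frozen=True)
class EnrichmentResult:
    task: EnrichmentTask
    p_value: float
    fold: float


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), computed in log space.

    The tail is accumulated as logsumexp over the log-pmf
    log C(K,j) + log C(N-K,n-j) - log C(N,n); k = 0 (and any k at or below
    the support minimum) is the certain event.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid counts N={N} K={K} n={n}")
    if not 0 <= k <= min(n, K):
        raise ValueError(f"invalid success count k={k} for N={N} K={K} n={n}")
    kmin = max(0, n + K - N)
    if k <= kmin:
        return 1.0
    kmax = min(n, K)
    if kmax - k > 200_000:
        return float(np.exp(stats.hypergeom.logsf(k - 1, N, K, n)))
    j = np.arange(k, kmax + 1, dtype=np.float64)
    # log C(K,j) + log C(N-K,n-j) - log C(N,n), one batched gammaln call
    g = gammaln([[K + 1], [N - K + 1], [N + 1], [n + 1], [N - n + 1]])
    gj = gammaln(np.stack([j + 1, K - j + 1, n - j + 1, N - K - n + j + 1]))
    logpmf = g[0, 0] + g[1, 0] - g[2, 0] + g[3, 0] + g[4, 0] - gj.sum(axis=0)
    m = logpmf.max()
    return float(min(1.0, np.exp(m) * np.exp(logpmf - m).sum()))


# ---------------------------------------------------------------------------
# instance table assembly
# ---------------------------------------------------------------------------


def riboswitch_table(
    groups: Iterable[ContiguousGroup], genes: pd.DataFrame
) -> pd.DataFrame:
    """One row per aptamer instance with phylum / COG / architecture context.

    ``genes`` must carry genome_id, gene_id, phylum, cog_id. Genome ids are
    taken from the hits (filled by assign_regions or the simulator).
    """
    rows = []
    for g in groups:
        gene_id = g.regulated_gene_ids[0] if g.regulated_gene_ids else ""
        for h in g.aptamers:
            genome = h.genome_id or g.region_ref.split("|", 1)[0]
            rows.append(
                {
                    "region_ref": g.region_ref,
                    "genome_id": genome,
                    "gene_id": gene_id,
                    "model_class": h.model_class,
                    "family": h.family or h.model_class,
                    "group_class": g.group_class,
                    "group_size": g.n_aptamers,
                }
            )
    rs = pd.DataFrame(
        rows,
        columns=[
            "region_ref", "genome_id", "gene_id", "model_class",
            "family", "group_class", "group_size",
        ],
    )
    rs["contiguous"] = rs["group_size"] >= 2
    context = genes[["genome_id", "gene_id", "phylum", "cog_id"]]
    rs = rs.merge(context, on=["genome_id", "gene_id"], how="left")
    rs["phylum"] = rs["phylum"].fillna("")
    return rs


def _count_by(df: pd.DataFrame, cols: list[str]) -> pd.Series:
    return df.groupby(cols, dropna=True).size()


def _distinct_genes(rs: pd.DataFrame) -> pd.DataFrame:
    return rs.drop_duplicates(subset=["genome_id", "gene_id"])


def build_tasks(
    analysis_id: str, genes: pd.DataFrame, rs: pd.DataFrame
) -> list[EnrichmentTask]:
    """Assemble the per-stratum contingency counts for one analysis id.

    ``genes``: one row per gene. ``rs``: one row per deduplicated aptamer
    instance (see :func:`riboswitch_table`). Strata with zero elements are
    not emitted.
    """
    aid = analysis_id.upper()
    if aid not in ANALYSES:
        raise ValueError(f"unknown analysis id {analysis_id!r}; known: {sorted(ANALYSES)}")

    contiguous = rs[rs["contiguous"]]
    tandem = rs[rs["group_class"] == "tandem"]
    adjacent = rs[rs["group_class"] == "adjacent"]
    tasks: list[EnrichmentTask] = []

    if aid in ("S6", "S7", "S9", "S10"):
        success = {"S6": rs, "S7": contiguous, "S9": tandem, "S10": adjacent}[aid]
        N, K = len(genes), len(success)
        n_by = _count_by(genes, ["phylum"])
        k_by = _count_by(success, ["phylum"])
        for phylum, n in n_by.items():
            tasks.append(EnrichmentTask(aid, str(phylum), N, K, int(n), int(k_by.get(phylum, 0))))

    elif aid in ("S11", "S12", "S13"):
        success = {"S11": contiguous, "S12": tandem, "S13": adjacent}[aid]
        N, K = len(rs), len(success)
        n_by = _count_by(rs, ["family"])
        k_by = _count_by(success, ["family"])
        for family, n in n_by.items():
            tasks.append(EnrichmentTask(aid, str(family), N, K, int(n), int(k_by.get(family, 0))))

    elif aid in ("S14", "S15"):
        success = rs if aid == "S14" else contiguous
        N = len(rs)
        K_by = _count_by(rs, ["family"])  # population successes: riboswitches by family
        n_by = _count_by(rs, ["phylum"])  # stratum elements: riboswitches in the phylum
        k_by = _count_by(success, ["family", "phylum"])
        for family in K_by.index:
            for phylum in n_by.index:
                k = int(k_by.get((family, phylum), 0))
                tasks.append(
                    EnrichmentTask(
                        aid, f"{family}|{phylum}", N, int(K_by[family]), int(n_by[phylum]), k
                    )
                )

    elif aid in ("S16", "S18"):
        regulated = _distinct_genes(rs if aid == "S16" else contiguous)
        N, K = len(genes), len(regulated)
        gene_cog = genes.dropna(subset=["cog_id"])
        reg_ctx = regulated.dropna(subset=["cog_id"])
        n_by = _count_by(gene_cog, ["cog_id"])
        k_by = _count_by(reg_ctx, ["cog_id"])
        for cog, n in n_by.items():
            tasks.append(EnrichmentTask(aid, str(cog), N, K, int(n), int(k_by.get(cog, 0))))

    elif aid in ("S17", "S19"):
        regulated = _distinct_genes(rs if aid == "S17" else contiguous)
        gene_cog = genes.dropna(subset=["cog_id"])
        reg_ctx = regulated.dropna(subset=["cog_id"])
        N_by = _count_by(gene_cog, ["cog_id"])
        K_by = _count_by(reg_ctx, ["cog_id"])
        n_by = _count_by(gene_cog, ["cog_id", "phylum"])
        k_by = _count_by(reg_ctx, ["cog_id", "phylum"])
        for (cog, phylum), n in n_by.items():
            tasks.append(
                EnrichmentTask(
                    aid,
                    f"{cog}|{phylum}",
                    int(N_by[cog]),
                    int(K_by.get(cog, 0)),
                    int(n),
                    int(k_by.get((cog, phylum), 0)),
                )
            )
    return tasks


def tasks_from_phylum_counts(counts: pd.DataFrame, analysis_id: str = "S6") -> list[EnrichmentTask]:
    """S6-style tasks straight from a per-phylum counts table.

    ``counts`` columns: phylum, n_genes, n_riboswitches. Used with the
    counts-level simulator for power and type-I calibration studies.
    """
    N = int(counts["n_genes"].sum())
    K = int(counts["n_riboswitches"].sum())
    return [
        EnrichmentTask(analysis_id, str(row.phylum), N, K, int(row.n_genes), int(row.n_riboswitches))
        for row in counts.itertuples()
        if row.n_genes > 0
    ]


def evaluate_tasks(tasks: Sequence[EnrichmentTask]) -> list[EnrichmentResult]:
    results = []
    for t in tasks:
        p = hypergeom_upper_tail(t.N, t.K, t.n, t.k)
        fold = (t.k / t.n) / (t.K / t.N) if t.n > 0 and t.K > 0 else float("nan")
        results.append(EnrichmentResult(task=t, p_value=p, fold=fold))
    return results


def _check_success_budget(aid: str, tasks: Sequence[EnrichmentTask]) -> None:
    """Stratum successes must never exceed the population successes.

    For the simple rows the strata partition one population (sum k <= K);
    for the composite rows the budget holds within each family (S14/S15) or
    COG (S17/S19), whose phylum strata partition that sub-population.
    """
    if aid in ("S14", "S15", "S17", "S19"):
        budgets: dict[str, list[int]] = {}
        for t in tasks:
            unit = t.stratum.split("|", 1)[0]
            budgets.setdefault(unit, [t.K, 0])[1] += t.k
        for unit, (K, ksum) in budgets.items():
            if ksum > K:
                raise AssertionError(
                    f"{aid}/{unit}: stratum successes {ksum} exceed population successes {K}"
                )
    else:
        ksum = sum(t.k for t in tasks)
        if ksum > tasks[0].K:
            raise AssertionError(
                f"{aid}: stratum successes {ksum} exceed population successes {tasks[0].K}"
            )


def run_analyses(
    ids: Iterable[str],
    genes: pd.DataFrame,
    rs: pd.DataFrame,
    bh: bool = False,
) -> pd.DataFrame:
    """Run the requested analyses; rows sorted by (analysis_id, p_value).

    Raw p-values are the primary output; with ``bh=True`` a Benjamini-
    Hochberg adjusted column is appended per analysis (never used for the
    ordering). Per analysis, stratum successes are checked to never exceed
    the population successes.
    """
    frames = []
    for aid in ids:
        tasks = build_tasks(aid, genes, rs)
        if not tasks:
            continue
        _check_success_budget(aid.upper(), tasks)
        results = evaluate_tasks(tasks)
        df = pd.DataFrame(
            {
                "analysis_id": [r.task.analysis_id for r in results],
                "stratum": [r.task.stratum for r in results],
                "N": [r.task.N for r in results],
                "K": [r.task.K for r in results],
                "n": [r.task.n for r in results],
                "k": [r.task.k for r in results],
                "fold": [r.fold for r in results],
                "p_value": [r.p_value for r in results],
            }
        )
        if bh and len(df):
            df["p_bh"] = stats.false_discovery_control(df["p_value"], method="bh")
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=["analysis_id", "stratum", "N", "K", "n", "k", "fold", "p_value"]
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["analysis_id", "p_value", "stratum"], kind="mergesort").reset_index(
        drop=True
    )
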