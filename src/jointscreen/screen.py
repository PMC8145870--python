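"""Depletion statistics and toxicity calling.

The screen compares a gene's share of joint-reads in the pooled ligation
mixture with its share in the plasmid DNA of pooled transformants.  A gene
whose product kills or inhibits the host cannot establish itself as a
plasmid, so its share collapses in the transformant pool:

    ratio(g) = plasmid_pct(g) / ligation_pct(g)

Ratios well below 1 indicate toxicity; because ligation efficiencies vary
strongly between genes, the screen calls candidates at ratio <= 0.5 rather
than at 1.  A gene with zero joint-reads in the ligation mixture was never
in the pool (a dropout) and gets no ratio at all.

The parallel plating assay transforms each gene separately and normalizes
its colony count to a non-toxic control gene (g178) processed in the same
batch.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .counting import JointCountTable
from .errors import EmptySampleError, JointScreenError

DEFAULT_THRESHOLD = 0.5
DEFAULT_CONTROL_GENE = "g178"

CALL_TOXIC = "toxic-candidate"
CALL_NON = "non-candidate"
CALL_DROPOUT = "dropout"


@dataclass
class ScreenResult:
    """Per-gene outcome of the joint-read depletion screen."""

    gene_id: str
    ligation_pct: float
    plasmid_pct: float
    ratio: float | None  # None for dropouts
    ratio_sd: float
    dropout: bool
    call: str


@dataclass
class PlatingResult:
    """Per-gene outcome of the plating-efficiency assay."""

    gene_id: str
    batch_id: str
    fraction: float
    fraction_sd: float
    control_gene_id: str


def joint_read_percentages(table: JointCountTable) -> pd.Series:
    """Each gene's joint-reads as a percentage of the sample's total.

    Percentages over all genes sum to exactly 100 (up to float rounding).
    """
    totals = table.gene_totals.astype(float)
    grand = totals.sum()
    if grand <= 0:
        raise EmptySampleError(
            f"sample {table.sample_id!r} has no joint-reads (empty sample)"
        )
    return 100.0 * totals / grand


def toxicity_ratio(ligation_pct: float, plasmid_pct: float) -> float | None:
    """Depletion ratio plasmid% / ligation%, or ``None`` for a dropout.

    A zero ligation percentage means the gene never entered the pool and no
    ratio is defined.  A zero plasmid percentage with a positive ligation
    percentage is strong depletion: ratio 0.0, not a dropout.
    """
    if ligation_pct < 0 or plasmid_pct < 0:
        raise JointScreenError("percentages must be non-negative")
    if ligation_pct == 0:
        return None
    return plasmid_pct / ligation_pct


def call_toxicity(ratio: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """Call a gene from its depletion ratio; the threshold is inclusive."""
    if ratio is None or math.isnan(ratio) or ratio < 0:
        raise JointScreenError("ratio must be a defined non-negative number")
    return CALL_TOXIC if ratio <= threshold else CALL_NON


def aggregate_replicates(ratios: Sequence[float]) -> tuple[float, float]:
    """Mean and sample SD (n-1) of per-replicate ratios.

    With a single replicate the SD is reported as 0 with a warning.
    """
    vals = np.asarray(list(ratios), dtype=float)
    if vals.size == 0:
        raise JointScreenError("no replicate ratios to aggregate")
    if vals.size == 1:
        warnings.warn("single replicate: SD reported as 0", stacklevel=2)
        return float(vals[0]), 0.0
    return float(vals.mean()), float(vals.std(ddof=1))


def screen_counts(
    replicate_pairs: Sequence[tuple[JointCountTable, JointCountTable]],
    threshold: float = DEFAULT_THRESHOLD,
    pool_counts: bool = False,
) -> list[ScreenResult]:
    """Run the depletion screen over matched (ligation, plasmid) samples.

    Each pair is one replicate transformation together with the ligation
    mixture it came from.  By default ratios are computed per replicate and
    then aggregated (mean, sample SD); ``pool_counts`` instead sums counts
    across replicates per arm first and computes a single ratio (SD 0).

    A gene is a dropout only when it has zero ligation joint-reads in every
    replicate; replicates where it is present still contribute ratios.
    """
    if not replicate_pairs:
        raise JointScreenError("no replicate pairs supplied")
    gene_ids = list(replicate_pairs[0][0].gene_ids)
    for lig, plas in replicate_pairs:
        if list(lig.gene_ids) != gene_ids or list(plas.gene_ids) != gene_ids:
            raise JointScreenError("all count tables must cover the same genes")

    if pool_counts:
        lig_sum = replicate_pairs[0][0].counts.copy()
        plas_sum = replicate_pairs[0][1].counts.copy()
        for lig, plas in replicate_pairs[1:]:
            lig_sum += lig.counts
            plas_sum += plas.counts
        pooled = [
            (
                JointCountTable("ligation-pooled", gene_ids, lig_sum),
                JointCountTable("plasmid-pooled", gene_ids, plas_sum),
            )
        ]
        return screen_counts(pooled, threshold=threshold, pool_counts=False)

    lig_pcts = []
    plas_pcts = []
    for lig, plas in replicate_pairs:
        lig_pcts.append(joint_read_percentages(lig))
        plas_pcts.append(joint_read_percentages(plas))

    results: list[ScreenResult] = []
    for gene in gene_ids:
        ratios = []
        for lp, pp in zip(lig_pcts, plas_pcts):
            r = toxicity_ratio(lp[gene], pp[gene])
            if r is not None:
                ratios.append(r)
        mean_lig = float(np.mean([lp[gene] for lp in lig_pcts]))
        mean_plas = float(np.mean([pp[gene] for pp in plas_pcts]))
        if not ratios:
            results.append(
                ScreenResult(gene, mean_lig, mean_plas, None, 0.0, True, CALL_DROPOUT)
            )
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mean_r, sd_r = aggregate_replicates(ratios)
        results.append(
            ScreenResult(
                gene_id=gene,
                ligation_pct=mean_lig,
                plasmid_pct=mean_plas,
                ratio=mean_r,
                ratio_sd=sd_r,
                dropout=False,
                call=call_toxicity(mean_r, threshold),
            )
        )
    return results


def screen_summary(
    results: Iterable[ScreenResult], threshold: float = DEFAULT_THRESHOLD
) -> dict:
    """Summary over a screen: candidate count and ratio distribution.

    Dropouts are excluded from the ratio statistics; a screen consisting
    only of dropouts has no summary.
    """
    results = list(results)
    ratios = np.asarray([r.ratio for r in results if r.ratio is not None], dtype=float)
    if ratios.size == 0:
        raise JointScreenError("all genes are dropouts: no ratios to summarize")
    n_cand = sum(
        1
        for r in results
        if r.ratio is not None and call_toxicity(r.ratio, threshold) == CALL_TOXIC
    )
    return {
        "n_genes": len(results),
        "n_candidates": int(n_cand),
        "min_ratio": float(ratios.min()),
        "max_ratio": float(ratios.max()),
        "mean_ratio": float(ratios.mean()),
        "sd_ratio": float(ratios.std(ddof=1)) if ratios.size > 1 else 0.0,
        "dropouts": sum(1 for r in results if r.dropout),
    }


def plating_fractions(
    cfu_by_gene: Mapping[str, Sequence[float]],
    control_gene: str = DEFAULT_CONTROL_GENE,
    batch_id: str = "1",
) -> list[PlatingResult]:
    """Plating-efficiency fractions for one transformation batch.

    ``fraction(g)`` is mean CFU of the gene over its replicate platings
    divided by the mean CFU of the batch's non-toxic control gene; the SD is
    the sample SD of per-replicate fractions (each replicate CFU divided by
    the control mean).  The control's own fraction is 1 by construction.
    """
    if control_gene not in cfu_by_gene:
        raise JointScreenError(
            f"control gene {control_gene!r} missing from batch {batch_id!r}"
        )
    control_mean = float(np.mean(cfu_by_gene[control_gene]))
    if control_mean <= 0:
        raise JointScreenError(
            f"control gene {control_gene!r} has zero mean CFU in batch {batch_id!r}"
        )
    out = []
    for gene, cfus in cfu_by_gene.items():
        vals = np.asarray(list(cfus), dtype=float)
        if vals.size == 0:
            raise JointScreenError(f"gene {gene!r}: no CFU replicates")
        if (vals < 0).any():
            raise JointScreenError(f"gene {gene!r}: negative CFU count")
        per_rep = vals / control_mean
        out.append(
            PlatingResult(
                gene_id=gene,
                batch_id=batch_id,
                fraction=float(per_rep.mean()),
                fraction_sd=float(per_rep.std(ddof=1)) if vals.size > 1 else 0.0,
                control_gene_id=control_gene,
            )
        )
    return out


def plating_fractions_batched(
    cfu: pd.DataFrame, control_gene: str = DEFAULT_CONTROL_GENE
) -> list[PlatingResult]:
    """Plating fractions for a long-format CFU table.

    ``cfu`` has columns batch, gene_id, cfu (one row per replicate plating);
    every batch must contain the control gene.
    """
    required = {"batch", "gene_id", "cfu"}
    if not required.issubset(cfu.columns):
        raise JointScreenError(f"CFU table needs columns {sorted(required)}")
    results: list[PlatingResult] = []
    for batch, grp in cfu.groupby("batch", sort=False):
        by_gene = {g: sub["cfu"].tolist() for g, sub in grp.groupby("gene_id", sort=False)}
        results.extend(plating_fractions(by_gene, control_gene, batch_id=str(batch)))
    return results


def format_ratio(ratio: float | None) -> str:
    """Render a ratio at report precision: 2 decimals, 3 below 0.01;
    dropouts as 'NA'."""
    if ratio is None:
        return "NA"
    if ratio < 0.01:
        return f"{ratio:.3f}"
    return f"{ratio:.2f}"


def results_to_frame(results: Iterable[ScreenResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "gene_id": r.gene_id,
                "ligation_pct": round(r.ligation_pct, 2),
                "plasmid_pct": round(r.plasmid_pct, 2),
                "ratio": "NA" if r.ratio is None else float(format_ratio(r.ratio)),
                "ratio_sd": round(r.ratio_sd, 3),
                "dropout": r.dropout,
                "call": r.call,
            }
        )
    return pd.DataFrame(rows)


def plating_to_frame(results: Iterable[PlatingResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "gene_id": r.gene_id,
                "batch": r.batch_id,
                "fraction": round(r.fraction, 3),
                "fraction_sd": round(r.fraction_sd, 3),
                "control_gene": r.control_gene_id,
            }
        )
    return pd.DataFrame(rows)
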