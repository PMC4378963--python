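"""Expression calling against an empirical false-positive-rate null.

An annotation is called expressed when the number of overlapping RNA-seq
reads reaches a count threshold.  The threshold is calibrated empirically:
read counts are computed over randomly sampled, un-annotated genomic regions
whose lengths are drawn from the annotation length distribution, and the
smallest count is chosen whose exceedance fraction on that null sample is at
most the target false-positive rate (default 10%).  Length-matching the null
absorbs the length bias of raw counts, so no per-annotation normalization is
applied.
"""
from __future__ import annotations

import math
from collections import defaultdict
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .conservation import fisher_exact_2x2
from .model import (
    Annotation,
    CountVector,
    EnrichmentTable,
    ExpressionThreshold,
    GenomeIndex,
    NullSample,
    ReadInterval,
    Region,
)

Interval = Union[Annotation, Region, ReadInterval]


def _interval_id(iv: Interval) -> str:
    if isinstance(iv, Annotation):
        return iv.locus_id
    return f"{iv.scaffold_id}:{iv.start}-{iv.end}({iv.strand})"


def _read_trees(reads: Sequence[ReadInterval]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = defaultdict(IntervalTree)
    # the payload carries a unique index: identical Interval objects would
    # otherwise be deduplicated by IntervalTree, silently dropping duplicate reads
    for i, r in enumerate(reads):
        trees[r.scaffold_id].addi(r.start, r.end, (r.strand, i))
    return trees


def count_reads(
    reads: Sequence[ReadInterval],
    intervals: Sequence[Interval],
    strand_aware: bool = True,
) -> CountVector:
    """Count reads overlapping each interval by >= 1 bp.

    With ``strand_aware`` only same-strand reads count.  A read overlapping
    several intervals contributes to each of them (no deduplication).
    """
    trees = _read_trees(reads)
    counts = np.zeros(len(intervals), dtype=int)
    for i, iv in enumerate(intervals):
        tree = trees.get(iv.scaffold_id)
        if tree is None:
            continue
        overlapping = tree.overlap(iv.start, iv.end)
        if strand_aware:
            counts[i] = sum(1 for o in overlapping if o.data[0] == iv.strand)
        else:
            counts[i] = len(overlapping)
    return CountVector(
        ids=[_interval_id(iv) for iv in intervals],
        counts=counts,
        strand_aware=strand_aware,
    )


def sample_null_regions(
    genome_index: GenomeIndex,
    annotations: Sequence[Annotation],
    n_regions: int,
    seed: int,
    lengths: Optional[Sequence[int]] = None,
    max_attempts: int = 1000,
) -> NullSample:
    """Sample random un-annotated regions, length-matched to the annotations.

    Region lengths are drawn with replacement from the annotation length
    distribution (or an explicit ``lengths`` pool); positions are uniform over
    scaffolds weighted by scaffold length; candidates overlapping any
    annotation by >= 1 bp are rejected.  Strand is assigned uniformly.
    Deterministic given ``seed``.

    Raises RuntimeError when a region cannot be placed within
    ``max_attempts`` tries, reporting the un-annotated genome fraction.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    pool = list(lengths) if lengths is not None else [a.length for a in annotations]
    if not pool:
        raise ValueError("no lengths available: supply annotations or a lengths pool")

    ann_trees: Dict[str, IntervalTree] = defaultdict(IntervalTree)
    for a in annotations:
        ann_trees[a.scaffold_id].addi(a.start, a.end)

    rng = np.random.default_rng(seed)
    scaffold_ids = [sid for sid, _ in genome_index.scaffolds]
    scaffold_lens = np.array([ln for _, ln in genome_index.scaffolds], dtype=float)
    weights = scaffold_lens / scaffold_lens.sum()
    pool_arr = np.asarray(pool, dtype=int)

    regions: List[Region] = []
    for _ in range(n_regions):
        placed = False
        for _attempt in range(max_attempts):
            length = int(pool_arr[rng.integers(0, len(pool_arr))])
            si = int(rng.choice(len(scaffold_ids), p=weights))
            slen = int(scaffold_lens[si])
            if slen < length:
                continue
            start = int(rng.integers(0, slen - length + 1))
            end = start + length
            tree = ann_trees.get(scaffold_ids[si])
            if tree is not None and tree.overlaps(start, end):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            regions.append(Region(scaffold_ids[si], start, end, strand))
            placed = True
            break
        if not placed:
            covered = sum(
                iv.end - iv.begin for t in ann_trees.values() for iv in t
            )
            frac_free = 1.0 - covered / genome_index.total_length
            raise RuntimeError(
                f"failed to place a null region after {max_attempts} attempts; "
                f"un-annotated genome fraction ~ {frac_free:.3f}"
            )
    return NullSample(regions=regions, seed=seed)


def select_threshold(
    null_counts: Union[np.ndarray, Sequence[int], CountVector],
    target_fpr: float = 0.10,
) -> ExpressionThreshold:
    """Smallest count c >= 1 whose null exceedance fraction is <= target_fpr.

    The exceedance fraction P(count >= c) is non-increasing in c and reaches
    0 at max(null) + 1, so the minimum always exists.
    """
    if isinstance(null_counts, CountVector):
        null_counts = null_counts.counts
    counts = np.asarray(null_counts, dtype=int)
    if counts.size == 0:
        raise ValueError("empty null counts")
    if not (0 < target_fpr < 1):
        raise ValueError("target_fpr must be in (0, 1)")
    n = counts.size
    for c in range(1, int(counts.max()) + 2):
        frac = float((counts >= c).sum()) / n
        if frac <= target_fpr:
            return ExpressionThreshold(
                min_count=c, target_fpr=target_fpr, achieved_fpr=frac
            )
    raise RuntimeError("no feasible threshold found")  # pragma: no cover


def call_expression(
    counts: Union[np.ndarray, Sequence[int], CountVector],
    threshold: ExpressionThreshold,
) -> np.ndarray:
    """Boolean calls: expressed iff count >= threshold.min_count (inclusive)."""
    if isinstance(counts, CountVector):
        counts = counts.counts
    return np.asarray(counts, dtype=int) >= threshold.min_count


def _pct(expressed: int, annotated: int) -> float:
    """Percentage rounded half-up to one decimal (table formatting rule)."""
    if annotated == 0:
        return 0.0
    frac = Decimal(expressed * 100) / Decimal(annotated)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


class ExpressionSummary:
    """Per-class expression table with totals, fold enrichment and Fisher test."""

    def __init__(
        self,
        table: pd.DataFrame,
        total_annotated: int,
        total_expressed: int,
        total_pct: float,
        threshold: Optional[ExpressionThreshold] = None,
        fold_enrichment: Optional[float] = None,
        fisher: Optional[EnrichmentTable] = None,
    ):
        self.table = table
        self.total_annotated = total_annotated
        self.total_expressed = total_expressed
        self.total_pct = total_pct
        self.threshold = threshold
        self.fold_enrichment = fold_enrichment
        self.fisher = fisher

    def to_tsv(self) -> str:
        lines = ["rna_class\tn_annotated\tn_expressed\tpct_expressed"]
        for _, row in self.table.iterrows():
            lines.append(
                f"{row['rna_class']}\t{row['n_annotated']}\t"
                f"{row['n_expressed']}\t{row['pct_expressed']:.1f}"
            )
        lines.append(
            f"Total\t{self.total_annotated}\t{self.total_expressed}\t{self.total_pct:.1f}"
        )
        if self.threshold is not None:
            lines.append(f"# min_count\t{self.threshold.min_count}")
            lines.append(f"# target_fpr\t{self.threshold.target_fpr}")
            lines.append(f"# achieved_fpr\t{self.threshold.achieved_fpr:.4f}")
        if self.fold_enrichment is not None:
            lines.append(f"# fold_enrichment\t{self.fold_enrichment:.2f}")
        if self.fisher is not None:
            lines.append(f"# fisher_p\t{self.fisher.p_value_str}")
        return "\n".join(lines) + "\n"


def summarize_counts(
    class_counts: Mapping[str, Tuple[int, int]],
) -> ExpressionSummary:
    """Build the per-class summary from (n_annotated, n_expressed) pairs.

    Percentages are rounded half-up to one decimal; the totals row is the
    column sums.
    """
    rows = []
    for rna_class, (annotated, expressed) in class_counts.items():
        rows.append(
            {
                "rna_class": rna_class,
                "n_annotated": int(annotated),
                "n_expressed": int(expressed),
                "pct_expressed": _pct(expressed, annotated),
            }
        )
    table = pd.DataFrame(rows, columns=["rna_class", "n_annotated", "n_expressed", "pct_expressed"])
    total_annotated = int(table["n_annotated"].sum()) if rows else 0
    total_expressed = int(table["n_expressed"].sum()) if rows else 0
    return ExpressionSummary(
        table=table,
        total_annotated=total_annotated,
        total_expressed=total_expressed,
        total_pct=_pct(total_expressed, total_annotated),
    )


def summarize(
    calls: np.ndarray,
    annotations: Sequence[Annotation],
    class_map: Optional[Mapping[str, str]] = None,
    null_counts: Optional[Union[np.ndarray, CountVector]] = None,
    threshold: Optional[ExpressionThreshold] = None,
) -> ExpressionSummary:
    """Per-class expression summary plus overall enrichment over the null.

    fold_enrichment = (fraction of annotations called expressed) /
    (fraction of null regions at or above the threshold); infinity with a
    warning when the null exceedance is zero.  The Fisher 2x2 is
    {expressed, not} x {annotation, null region}, one-sided greater.
    """
    if len(calls) != len(annotations):
        raise ValueError("calls and annotations differ in length")
    per_class: Dict[str, List[int]] = {}
    for called, a in zip(calls, annotations):
        rna_class = a.rna_class or (class_map or {}).get(a.family_id, "")
        if not rna_class:
            rna_class = "unclassified"
        pair = per_class.setdefault(rna_class, [0, 0])
        pair[0] += 1
        pair[1] += int(bool(called))
    summary = summarize_counts({k: (v[0], v[1]) for k, v in sorted(per_class.items())})
    summary.threshold = threshold

    if null_counts is not None and threshold is not None:
        if isinstance(null_counts, CountVector):
            null_counts = null_counts.counts
        null_counts = np.asarray(null_counts, dtype=int)
        n_null = null_counts.size
        null_exceed = int((null_counts >= threshold.min_count).sum())
        expressed_frac = summary.total_expressed / max(summary.total_annotated, 1)
        null_frac = null_exceed / n_null if n_null else 0.0
        if null_frac == 0.0:
            import warnings

            warnings.warn("zero null exceedance: fold enrichment is infinite")
            summary.fold_enrichment = math.inf
        else:
            summary.fold_enrichment = expressed_frac / null_frac
        summary.fisher = fisher_exact_2x2(
            summary.total_expressed,
            null_exceed,
            summary.total_annotated - summary.total_expressed,
            n_null - null_exceed,
            sidedness="greater",
        )
    return summary
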