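"""GA/E-value filtering, clan competition and overlap collapsing of hits.

The three stages turn raw per-genome homology hits into a non-redundant
annotation set:

1. ``filter_hits``      — keep hits with bit score >= the family's curated GA
                          threshold and E-value <= 5e-4 (defaults).
2. ``compete_clans``    — within each clan (group of homologous families that
                          cannot be aligned into one model), only the best
                          hit survives in any overlapping genomic region.
3. ``collapse_overlaps``— overlapping same-family, same-strand hits are
                          merged into single loci.

Competition ranks hits by (E-value asc, bit score desc, family_id asc,
start asc) and resolves greedily: accept the best-ranked hit, discard any
clan-mate overlapping it by >= 1 bp (strand-agnostic), recurse.  Families
without a clan compete only with themselves.
"""
from __future__ import annotations

from collections import defaultdict
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .model import Annotation, FamilyMeta, FilterConfig, Hit, sort_annotations


class UnknownFamilyError(KeyError):
    """A hit references a family absent from the metadata table."""

    def __init__(self, family_ids: Sequence[str]):
        self.family_ids = sorted(set(family_ids))
        super().__init__(f"unknown family ids: {', '.join(self.family_ids)}")


def filter_hits(
    hits: Sequence[Hit],
    family_meta: Dict[str, FamilyMeta],
    config: FilterConfig = FilterConfig(),
) -> List[Hit]:
    """Retain hits passing both the GA bit-score and the E-value cutoff.

    Order-preserving.  With ``config.apply_ga`` False only the E-value rule
    applies and unknown families are tolerated.
    """
    if config.apply_ga:
        unknown = [h.family_id for h in hits if h.family_id not in family_meta]
        if unknown:
            raise UnknownFamilyError(unknown)
    kept = []
    for h in hits:
        if h.evalue > config.evalue_max:
            continue
        if config.apply_ga and h.bit_score < family_meta[h.family_id].ga_threshold:
            continue
        kept.append(h)
    return kept


def _rank_key(h: Hit) -> Tuple[float, float, str, int, int]:
    return (h.evalue, -h.bit_score, h.family_id, h.start, h.end)


def _clan_key(h: Hit, family_meta: Dict[str, FamilyMeta]):
    meta = family_meta.get(h.family_id)
    if meta is not None and meta.clan_id:
        return ("clan", meta.clan_id)
    return ("family", h.family_id)


def compete_clans(
    hits: Sequence[Hit], family_meta: Dict[str, FamilyMeta]
) -> List[Hit]:
    """Keep only the best hit in each overlapping same-clan region.

    Overlap is >= 1 bp on the same scaffold, strand-agnostic (clan members
    may match either strand of one locus).  Hits in different clans never
    compete.  Returns survivors in input order.
    """
    groups: Dict[tuple, List[int]] = defaultdict(list)
    for i, h in enumerate(hits):
        groups[(_clan_key(h, family_meta), h.scaffold_id)].append(i)

    survivors = set()
    for indices in groups.values():
        ordered = sorted(indices, key=lambda i: _rank_key(hits[i]))
        accepted: List[Hit] = []
        for i in ordered:
            h = hits[i]
            if any(h.start < a.end and a.start < h.end for a in accepted):
                continue
            accepted.append(h)
            survivors.add(i)
    return [h for i, h in enumerate(hits) if i in survivors]


def collapse_overlaps(
    hits: Sequence[Hit],
    family_meta: Optional[Dict[str, FamilyMeta]] = None,
) -> List[Annotation]:
    """Merge overlapping same-family, same-strand hits into single loci.

    Merged annotations span the union interval and carry the members'
    minimum E-value, maximum bit score and the member count.  Pseudogene and
    non-pseudogene hits never merge; pseudogene tRNA loci are reported under
    the class "<base class> pseudogene".  Output in canonical sorted order.
    """
    family_meta = family_meta or {}
    groups: Dict[tuple, List[Hit]] = defaultdict(list)
    for h in hits:
        groups[(h.genome_id, h.scaffold_id, h.strand, h.family_id, h.pseudogene)].append(h)

    annotations: List[Annotation] = []
    for (genome, scaffold, strand, family, pseudo), members in groups.items():
        meta = family_meta.get(family)
        base_class = meta.rna_class if meta else ""
        rna_class = f"{base_class} pseudogene" if pseudo and base_class else base_class
        members.sort(key=lambda h: (h.start, h.end))
        cluster: List[Hit] = []
        cluster_end = -1
        for h in members:
            if cluster and h.start < cluster_end:  # >= 1 bp overlap with cluster span
                cluster.append(h)
                cluster_end = max(cluster_end, h.end)
            else:
                if cluster:
                    annotations.append(
                        _merge(cluster, genome, scaffold, strand, family, rna_class)
                    )
                cluster = [h]
                cluster_end = h.end
        if cluster:
            annotations.append(_merge(cluster, genome, scaffold, strand, family, rna_class))
    return sort_annotations(annotations)


def _merge(
    cluster: List[Hit], genome: str, scaffold: str, strand: str, family: str, rna_class: str
) -> Annotation:
    return Annotation(
        genome_id=genome,
        scaffold_id=scaffold,
        family_id=family,
        start=min(h.start for h in cluster),
        end=max(h.end for h in cluster),
        strand=strand,
        best_bit_score=max(h.bit_score for h in cluster),
        best_evalue=min(h.evalue for h in cluster),
        rna_class=rna_class,
        n_merged=len(cluster),
    )


def consolidate_genome(
    raw_hits: Sequence[Hit],
    trna_hits: Sequence[Hit],
    family_meta: Dict[str, FamilyMeta],
    config: FilterConfig = FilterConfig(),
) -> List[Annotation]:
    """filter -> compete -> collapse, over the union of general and tRNA hits."""
    combined = list(raw_hits) + list(trna_hits)
    filtered = filter_hits(combined, family_meta, config)
    competed = compete_clans(filtered, family_meta)
    return collapse_overlaps(competed, family_meta)


def covered_bases(intervals: Iterable[Tuple[str, int, int]]) -> int:
    """Total bases covered by the union of (scaffold, start, end) intervals."""
    by_scaffold: Dict[str, List[Tuple[int, int]]] = defaultdict(list)
    for scaffold, start, end in intervals:
        by_scaffold[scaffold].append((start, end))
    total = 0
    for spans in by_scaffold.values():
        spans.sort()
        cur_start, cur_end = spans[0]
        for s, e in spans[1:]:
            if s <= cur_end:
                cur_end = max(cur_end, e)
            else:
                total += cur_end - cur_start
                cur_start, cur_end = s, e
        total += cur_end - cur_start
    return total
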