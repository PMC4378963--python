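"""Order conservation of lncRNA RNA-domains along scaffolds.

Long non-coding RNAs are modelled as sets of locally conserved "RNA-domains",
each its own family.  When several domains of one lncRNA land on the same
scaffold, their genomic order should match the reference (human) domain
order.  The check uses subsequence semantics — missing domains do not break
consistency — and accepts whole-locus reversal, since assembly scaffolds have
arbitrary orientation.
"""
from __future__ import annotations

from collections import defaultdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .model import Annotation, DomainOrderSpec, ParseError, SyntenyCheck


def _orderable(observed: Sequence[Tuple[int, str]], reference: Sequence[str]) -> bool:
    """True iff one occurrence of each observed domain id can be chosen so the
    chosen occurrences, in genomic order, follow the reference order.

    ``observed`` is (position, domain_id) sorted by position.  Reference ids
    are unique, so a distinct-id sequence is a subsequence of the reference
    iff its ids appear in reference-index order; greedily matching the
    leftmost usable occurrence per reference id is optimal.
    """
    ids = {d for _, d in observed}
    ref_set = set(reference)
    if not ids <= ref_set:
        return False
    last = -1
    for rid in reference:
        if rid not in ids:
            continue
        candidates = [pos for pos, d in observed if d == rid and pos > last]
        if not candidates:
            return False
        last = min(candidates)
    return True


def check_order(
    annotations: Sequence[Annotation],
    spec: DomainOrderSpec,
    max_span: int = 1_000_000,
) -> List[SyntenyCheck]:
    """Classify each domain cluster as forward/reverse-consistent or not.

    Annotations are restricted to the spec's domain families, grouped per
    (genome, scaffold), and split into clusters whose extent does not exceed
    ``max_span`` bp (chance hits far away on a large scaffold are separate
    loci).  A cluster is consistent when its observed domain sequence is a
    subsequence of the reference order (orientation "forward") or of its
    reversal ("reverse"); clusters with fewer than two domains are vacuous
    (consistent None, orientation "n/a").
    """
    domains = set(spec.reference_order)
    by_scaffold: Dict[Tuple[str, str], List[Annotation]] = defaultdict(list)
    for a in annotations:
        if a.family_id in domains:
            by_scaffold[(a.genome_id, a.scaffold_id)].append(a)

    checks: List[SyntenyCheck] = []
    for (genome, scaffold), anns in sorted(by_scaffold.items()):
        anns.sort(key=lambda a: (a.start, a.end, a.family_id))
        clusters: List[List[Annotation]] = []
        for a in anns:
            if clusters and a.end - clusters[-1][0].start <= max_span:
                clusters[-1].append(a)
            else:
                clusters.append([a])
        for cluster in clusters:
            observed = [(a.start, a.family_id) for a in cluster]
            order = tuple(d for _, d in observed)
            if len(cluster) < 2:
                checks.append(
                    SyntenyCheck(spec.lncrna_id, genome, scaffold, order,
                                 len(cluster), None, "n/a")
                )
                continue
            forward = _orderable(observed, spec.reference_order)
            reverse = _orderable(observed, tuple(reversed(spec.reference_order)))
            if forward:
                orientation = "forward"
            elif reverse:
                orientation = "reverse"
            else:
                orientation = "n/a"
            checks.append(
                SyntenyCheck(spec.lncrna_id, genome, scaffold, order,
                             len(cluster), forward or reverse, orientation)
            )
    return checks


def synteny_report(
    annotations_by_genome: Mapping[str, Sequence[Annotation]],
    specs: Sequence[DomainOrderSpec],
    max_span: int = 1_000_000,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """One row per (lncRNA, genome, scaffold cluster) with >= 1 domain.

    Returns the table and summary counts of consistent / inconsistent /
    single-domain cases.
    """
    rows = []
    summary = {"consistent": 0, "inconsistent": 0, "single_domain": 0}
    for spec in specs:
        for genome, anns in annotations_by_genome.items():
            genome_anns = [a for a in anns if a.genome_id == genome or not a.genome_id]
            for chk in check_order(genome_anns, spec, max_span=max_span):
                rows.append(
                    {
                        "lncrna_id": chk.lncrna_id,
                        "genome_id": genome,
                        "scaffold_id": chk.scaffold_id,
                        "n_domains": chk.n_domains,
                        "observed_order": ",".join(chk.observed_order),
                        "consistent": "n/a" if chk.consistent is None else str(chk.consistent),
                        "orientation": chk.orientation,
                    }
                )
                if chk.consistent is None:
                    summary["single_domain"] += 1
                elif chk.consistent:
                    summary["consistent"] += 1
                else:
                    summary["inconsistent"] += 1
    columns = ["lncrna_id", "genome_id", "scaffold_id", "n_domains",
               "observed_order", "consistent", "orientation"]
    return pd.DataFrame(rows, columns=columns), summary


def read_domain_specs(source) -> List[DomainOrderSpec]:
    """TSV (lncrna_id, comma-separated ordered domain family ids)."""
    from .formats_io import _lines

    specs: List[DomainOrderSpec] = []
    for n, line in _lines(source):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"expected 2 columns, got {len(fields)}", n)
        order = tuple(d.strip() for d in fields[1].split(",") if d.strip())
        specs.append(DomainOrderSpec(fields[0].strip(), order))
    return specs


def write_domain_specs(specs: Sequence[DomainOrderSpec]) -> str:
    return "".join(
        f"{s.lncrna_id}\t{','.join(s.reference_order)}\n" for s in specs
    )
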