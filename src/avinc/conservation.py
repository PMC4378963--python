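"""Family x genome copy-number matrices, conservation filtering and
chromosome-class enrichment testing.

The copy-number matrix underlies presence/absence heatmaps across genomes.
Families detected in fewer than a minimum fraction of genomes (default 10%)
are discarded as likely contamination or fast-turnover, clade-specific
families.  Families missing from fragmented assemblies can be tested for
enrichment on microchromosomes — the small, hard-to-assemble chromosomes of
avian karyotypes — with Fisher's exact test.
"""
from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, TextIO, Tuple

import pandas as pd
from scipy import stats

from .model import Annotation, ConservationConfig, EnrichmentTable


@dataclass
class CopyNumberMatrix:
    """Copy counts of each family in each genome.

    ``counts`` is a families x genomes integer DataFrame; ``classes`` maps
    family_id -> RNA class (empty string when unknown).
    """

    counts: pd.DataFrame
    classes: Dict[str, str] = field(default_factory=dict)

    @property
    def families(self) -> List[str]:
        return list(self.counts.index)

    @property
    def genomes(self) -> List[str]:
        return list(self.counts.columns)

    def presence_count(self) -> pd.Series:
        """Number of genomes in which each family has >= 1 copy."""
        return (self.counts > 0).sum(axis=1)


def build_matrix(
    annotations_by_genome: Mapping[str, Sequence[Annotation]],
    families: Optional[Mapping[str, str]] = None,
) -> CopyNumberMatrix:
    """Count annotations per (family, genome).

    ``families`` optionally declares the full family roster (family_id ->
    rna_class); declared families absent everywhere get all-zero rows.
    Column sums equal per-genome annotation counts.
    """
    genomes = list(annotations_by_genome)
    classes: Dict[str, str] = dict(families) if families else {}
    fam_order: List[str] = list(classes)
    for anns in annotations_by_genome.values():
        for a in anns:
            if a.family_id not in classes:
                classes[a.family_id] = a.rna_class
                fam_order.append(a.family_id)
            elif not classes[a.family_id] and a.rna_class:
                classes[a.family_id] = a.rna_class
    counts = pd.DataFrame(0, index=fam_order, columns=genomes, dtype=int)
    for genome, anns in annotations_by_genome.items():
        for a in anns:
            counts.at[a.family_id, genome] += 1
    return CopyNumberMatrix(counts=counts, classes=classes)


def conservation_cutoff(n_genomes: int, min_genome_fraction: float) -> int:
    """Smallest genome count satisfying the conservation fraction.

    ceil(fraction * N), computed with a small tolerance so float artefacts
    (e.g. 0.1 * 30 = 3.0000000000000004) do not inflate the cutoff.
    """
    return max(1, math.ceil(min_genome_fraction * n_genomes - 1e-9))


def filter_conserved(
    matrix: CopyNumberMatrix,
    config: ConservationConfig = ConservationConfig(),
) -> Tuple[CopyNumberMatrix, List[str]]:
    """Drop families present in fewer than ceil(fraction x N) genomes.

    Returns (filtered matrix, removed family ids).
    """
    cutoff = conservation_cutoff(len(matrix.genomes), config.min_genome_fraction)
    present = matrix.presence_count()
    keep = [f for f in matrix.families if present[f] >= cutoff]
    removed = [f for f in matrix.families if present[f] < cutoff]
    filtered = CopyNumberMatrix(
        counts=matrix.counts.loc[keep].copy(),
        classes={f: matrix.classes.get(f, "") for f in keep},
    )
    return filtered, removed


def absence_report(
    matrix: CopyNumberMatrix,
    outgroup_presence: Optional[Mapping[str, Set[str]]] = None,
) -> pd.DataFrame:
    """Summarise per-family absences across the focal genomes.

    Flags are descriptive labels, not causal inferences:

    * ``avian_absent`` — zero copies in every focal genome but present in at
      least one outgroup (candidate genuine loss).
    * ``patchy`` — present in some but not all focal genomes (candidate
      missing data or divergence).
    """
    outgroup_presence = outgroup_presence or {}
    n = len(matrix.genomes)
    rows = []
    for fam in matrix.families:
        row = matrix.counts.loc[fam]
        absent = [g for g in matrix.genomes if row[g] == 0]
        n_present = n - len(absent)
        in_outgroup = bool(outgroup_presence.get(fam))
        rows.append(
            {
                "family_id": fam,
                "rna_class": matrix.classes.get(fam, ""),
                "n_present": n_present,
                "absent_genomes": ",".join(absent),
                "avian_absent": n_present == 0 and in_outgroup,
                "patchy": 0 < n_present < n,
            }
        )
    return pd.DataFrame(rows).set_index("family_id")


def flag_missing(matrix: CopyNumberMatrix, absent_fraction: float = 0.5) -> List[str]:
    """Families absent from more than ``absent_fraction`` of the genomes."""
    n = len(matrix.genomes)
    present = matrix.presence_count()
    return [f for f in matrix.families if (n - present[f]) > absent_fraction * n]


def fisher_exact_2x2(
    a: int, b: int, c: int, d: int, sidedness: str = "greater"
) -> EnrichmentTable:
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    One-sided "greater" is the exact hypergeometric upper tail on cell a;
    "two-sided" sums tables with probability <= the observed one.  The odds
    ratio is the sample estimate (a*d)/(b*c), infinity when b*c == 0.
    """
    cells = (a, b, c, d)
    if any(x < 0 or int(x) != x for x in cells):
        raise ValueError(f"cells must be non-negative integers, got {cells}")
    if sum(cells) == 0:
        raise ValueError("all-zero contingency table")
    alternative = {"greater": "greater", "less": "less", "two-sided": "two-sided"}.get(
        sidedness
    )
    if alternative is None:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    odds = (a * d) / (b * c) if b * c > 0 else math.inf
    return EnrichmentTable(
        a=int(a), b=int(b), c=int(c), d=int(d),
        p_value=float(p), odds_ratio=odds, sidedness=sidedness,
    )


def microchromosome_enrichment(
    missing_family_loci: Mapping[str, str],
    all_family_loci: Mapping[str, str],
    chrom_class_map: Mapping[str, str],
    sidedness: str = "greater",
) -> EnrichmentTable:
    """Test whether missing families are enriched on microchromosomes.

    Each family is mapped to a chromosome class via the scaffold of its
    reference-genome locus (family_id -> scaffold_id mappings); scaffolds
    without a macro/micro assignment are excluded.  Builds the 2x2 table
    {missing, not-missing} x {micro, macro} and runs a one-sided (greater on
    the missing/micro cell) Fisher exact test by default.
    """
    def classify(loci: Mapping[str, str]) -> Dict[str, str]:
        out = {}
        for fam, scaffold in loci.items():
            label = chrom_class_map.get(scaffold, "unassigned")
            if label in ("macro", "micro"):
                out[fam] = label
        return out

    missing = classify(missing_family_loci)
    everything = classify(all_family_loci)
    if not everything and not missing:
        raise ValueError("no family has a macro/micro chromosome-class assignment")
    not_missing = {f: c for f, c in everything.items() if f not in missing_family_loci}
    a = sum(1 for c in missing.values() if c == "micro")
    b = sum(1 for c in missing.values() if c == "macro")
    c_ = sum(1 for c in not_missing.values() if c == "micro")
    d = sum(1 for c in not_missing.values() if c == "macro")
    return fisher_exact_2x2(a, b, c_, d, sidedness=sidedness)


def export_heatmap(
    matrix: CopyNumberMatrix,
    stream: Optional[TextIO] = None,
    group_by_class: bool = True,
    plot_path: Optional[str] = None,
) -> str:
    """Write the matrix as TSV (family_id, rna_class, one column per genome).

    Rows are grouped by RNA class (stable within-class order) when
    ``group_by_class``.  With ``plot_path`` a heatmap on a log10(count + 1)
    colour scale is also rendered.
    """
    out = stream or io.StringIO()
    families = list(matrix.families)
    if group_by_class:
        # stable sort: classes in first-appearance order, families untouched within
        class_order: Dict[str, int] = {}
        for f in families:
            class_order.setdefault(matrix.classes.get(f, ""), len(class_order))
        families.sort(key=lambda f: class_order[matrix.classes.get(f, "")])
    out.write("family_id\trna_class\t" + "\t".join(matrix.genomes) + "\n")
    for fam in families:
        row = matrix.counts.loc[fam]
        out.write(
            fam + "\t" + matrix.classes.get(fam, "") + "\t"
            + "\t".join(str(int(row[g])) for g in matrix.genomes) + "\n"
        )
    if plot_path is not None:
        _plot_heatmap(matrix, families, plot_path)
    return out.getvalue() if stream is None else ""


def _plot_heatmap(matrix: CopyNumberMatrix, families: List[str], path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    data = np.log10(matrix.counts.loc[families].to_numpy(dtype=float) + 1.0)
    fig, ax = plt.subplots(
        figsize=(max(4, 0.25 * len(matrix.genomes)), max(3, 0.2 * len(families)))
    )
    im = ax.imshow(data, aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(matrix.genomes)))
    ax.set_xticklabels(matrix.genomes, rotation=90, fontsize=6)
    ax.set_yticks(range(len(families)))
    ax.set_yticklabels(families, fontsize=6)
    fig.colorbar(im, ax=ax, label="log10(copies + 1)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def read_heatmap_tsv(source) -> CopyNumberMatrix:
    """Read back the TSV written by :func:`export_heatmap`."""
    from .formats_io import _lines  # shared line iterator

    header: Optional[List[str]] = None
    fams: List[str] = []
    classes: Dict[str, str] = {}
    rows: List[List[int]] = []
    for n, line in _lines(source):
        if not line.strip():
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            continue
        fams.append(fields[0])
        classes[fields[0]] = fields[1]
        rows.append([int(x) for x in fields[2:]])
    if header is None:
        raise ValueError("empty matrix TSV")
    counts = pd.DataFrame(rows, index=fams, columns=header[2:], dtype=int)
    return CopyNumberMatrix(counts=counts, classes=classes)
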