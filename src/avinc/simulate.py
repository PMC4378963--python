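"""Synthetic multi-genome fixtures with known ground truth.

The generator emulates the statistical structure of a multi-genome ncRNA
homology screen: scaffolds, planted family loci with controlled conservation
fractions, decoy hits straddling the E-value/GA filters, clan-mate hits
overlapping true loci with worse E-values, tRNA loci emitted through the
specialist-tool channel (with pseudogene copies), lncRNA domain clusters in
reference order, microchromosome placement bias for poorly conserved
families, and strand-specific read coverage with a two-component
(expressed ~ Poisson(lambda_hi), background ~ Poisson(lambda_lo)) count
mixture.  No sequence content is generated — hits are coordinates plus
scores, since no downstream stage reads sequence.

All outputs are rendered in exactly the dialects ``formats_io`` reads and
round-trip through those readers.  Everything is deterministic given the
seed.
"""
from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from intervaltree import IntervalTree

from . import formats_io
from .model import AvincError, FamilyMeta, GenomeIndex, Hit, ReadInterval


class SimulationError(AvincError):
    """Raised when a configuration cannot be realised (e.g. infeasible packing)."""


@dataclass(frozen=True)
class FamilySpec:
    """One planted family and its conservation / copy-number behaviour."""

    family_id: str
    rna_class: str
    clan_id: Optional[str] = None
    ga_threshold: float = 30.0
    conservation_fraction: float = 1.0
    mean_copies: float = 1.0        # copies/genome ~ 1 + Poisson(mean_copies - 1)
    exact_copies: Optional[int] = None
    length_range: Tuple[int, int] = (70, 300)
    via_trnascan: bool = False
    pseudogene_fraction: float = 0.0
    on_micro: Optional[bool] = None  # reference-genome chromosome-class bias
    domain_group: Optional[str] = None  # lncRNA whose ordered domain this is


def default_families() -> Tuple[FamilySpec, ...]:
    """A roster emulating the major ncRNA classes of an avian screen.

    Includes a specialist-tool tRNA channel sharing a clan with a general
    tRNA model, clanned microRNA pairs (competition targets), ordered lncRNA
    domain groups (synteny targets), and seven sparsely conserved "core"
    families placed on microchromosomes (all but one) in the reference
    genome.
    """
    fams: List[FamilySpec] = [
        FamilySpec("tRNA", "Transfer RNA", clan_id="CL00001", ga_threshold=20.0,
                   conservation_fraction=1.0, mean_copies=6.0,
                   length_range=(70, 90), via_trnascan=True, pseudogene_fraction=0.15),
        FamilySpec("RF00005", "Transfer RNA", clan_id="CL00001", ga_threshold=29.0,
                   conservation_fraction=0.8, mean_copies=2.0, length_range=(70, 90)),
    ]
    for i in range(1, 6):
        fams.append(FamilySpec(f"RFCD{i:03d}", "C/D box snoRNA",
                               conservation_fraction=0.9, mean_copies=1.5,
                               length_range=(70, 110)))
    for i in range(1, 4):
        fams.append(FamilySpec(f"RFHA{i:03d}", "H/ACA box snoRNA",
                               conservation_fraction=0.85, mean_copies=1.5,
                               length_range=(120, 160)))
    for i in range(1, 7):
        clan = "CLMIR1" if i <= 2 else ("CLMIR2" if i <= 4 else None)
        fams.append(FamilySpec(f"RFMIR{i:02d}", "microRNA", clan_id=clan,
                               conservation_fraction=0.9, mean_copies=2.0,
                               length_range=(60, 90)))
    for name in ("U1", "U2", "U4", "U5", "U6"):
        fams.append(FamilySpec(name, "Major spliceosomal RNA",
                               conservation_fraction=1.0, mean_copies=1.5,
                               length_range=(100, 190)))
    for name in ("U12", "U6atac"):
        fams.append(FamilySpec(name, "Minor spliceosomal RNA",
                               conservation_fraction=0.7, length_range=(100, 150)))
    # lncRNA RNA-domain groups, planted in reference order on one scaffold
    for i in range(6, 10):
        fams.append(FamilySpec(f"RMST_d{i}", "Long non-coding RNA",
                               conservation_fraction=0.8, length_range=(80, 160),
                               domain_group="RMST"))
    for i in range(1, 6):
        fams.append(FamilySpec(f"HOTAIRM1_d{i}", "Long non-coding RNA",
                               conservation_fraction=0.8, length_range=(80, 160),
                               domain_group="HOTAIRM1"))
    # sparsely conserved "core" families; all but RNase MRP sit on
    # microchromosomes in the reference genome
    missing = [
        ("RF00009", "RNase P/MRP RNA", True),     # RNase P
        ("RF00030", "RNase P/MRP RNA", False),    # RNase MRP (macro)
        ("RF00004v", "Vault RNA", True),
        ("RF00024", "Telomerase RNA", True),
        ("U4atac", "Minor spliceosomal RNA", True),
        ("U11", "Minor spliceosomal RNA", True),
        ("tRNA-Sec", "Transfer RNA", True),
    ]
    for fam_id, rna_class, on_micro in missing:
        fams.append(FamilySpec(fam_id, rna_class, conservation_fraction=0.3,
                               length_range=(90, 300), on_micro=on_micro))
    return tuple(fams)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the simulation (defaults mirror a 48-genome screen)."""

    n_genomes: int = 48
    scaffolds_per_genome: int = 4
    scaffold_length_range: Tuple[int, int] = (300_000, 800_000)
    families: Tuple[FamilySpec, ...] = field(default_factory=default_families)
    decoy_rate: float = 20.0          # expected filter-failing decoys per genome
    overlap_decoy_rate: float = 0.3   # P(clan-mate decoy overlapping a true locus)
    expressed_fraction: float = 0.7
    lambda_hi: float = 50.0
    lambda_lo: float = 0.5
    read_length: int = 25
    micro_fraction: float = 0.5       # fraction of reference scaffolds labelled micro
    missing_micro_prob: float = 1.0   # effect size of the micro placement bias
    missing_conservation_max: float = 0.5  # cf <= this marks a family "missing"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        if self.scaffolds_per_genome < 1:
            raise ValueError("scaffolds_per_genome must be >= 1")
        for name in ("decoy_rate",):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("overlap_decoy_rate", "expressed_fraction", "micro_fraction",
                     "missing_micro_prob"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (self.lambda_hi > self.lambda_lo > 0):
            raise ValueError("need lambda_hi > lambda_lo > 0")


@dataclass(frozen=True)
class TrueLocus:
    genome_id: str
    scaffold_id: str
    family_id: str
    start: int
    end: int
    strand: str
    pseudogene: bool = False
    expressed: Optional[bool] = None  # set for reference-genome loci only
    channel: str = "tblout"           # "tblout" | "trnascan"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GroundTruth:
    loci: List[TrueLocus]
    planted_genomes: Dict[str, Set[str]]
    missing_families: List[str]
    reference_scaffold: Dict[str, str]  # family -> scaffold of its reference locus

    def loci_of(self, genome_id: str) -> List[TrueLocus]:
        return [t for t in self.loci if t.genome_id == genome_id]


@dataclass
class SimResult:
    """Simulated inputs plus their ground truth."""

    config: SimConfig
    genome_indexes: Dict[str, GenomeIndex]
    chrom_classes: Dict[str, str]
    family_meta: Dict[str, FamilyMeta]
    hits_by_genome: Dict[str, List[Hit]]
    trna_hits_by_genome: Dict[str, List[Hit]]
    reads: List[ReadInterval]
    truth: GroundTruth

    @property
    def genomes(self) -> List[str]:
        return list(self.genome_indexes)

    @property
    def reference_genome(self) -> str:
        return self.genomes[0]

    # -- rendered file contents (byte-stable given the seed) -----------------
    def tblout_text(self, genome_id: str) -> str:
        return formats_io.write_cmsearch_tblout(self.hits_by_genome[genome_id])

    def trnascan_text(self, genome_id: str) -> str:
        return formats_io.write_trnascan(self.trna_hits_by_genome[genome_id])

    def family_metadata_text(self) -> str:
        return formats_io.write_family_metadata(self.family_meta)

    def scaffold_lengths_text(self, genome_id: str) -> str:
        return formats_io.write_scaffold_lengths(self.genome_indexes[genome_id])

    def chrom_class_text(self) -> str:
        return formats_io.write_chromosome_classes(self.chrom_classes)

    def reads_bed_text(self) -> str:
        return formats_io.write_bed_reads(self.reads)

    def write(self, out_dir: str) -> Dict[str, str]:
        """Write every fixture file; returns a name -> path manifest."""
        os.makedirs(out_dir, exist_ok=True)
        paths: Dict[str, str] = {}

        def _put(name: str, text: str) -> None:
            path = os.path.join(out_dir, name)
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
            paths[name] = path

        for gid in self.genomes:
            _put(f"{gid}.tblout", self.tblout_text(gid))
            _put(f"{gid}.trnascan", self.trnascan_text(gid))
            _put(f"{gid}.lengths.tsv", self.scaffold_lengths_text(gid))
        _put("families.tsv", self.family_metadata_text())
        _put("chrom_classes.tsv", self.chrom_class_text())
        _put("reads.bed", self.reads_bed_text())
        return paths


def _round_evalue(x: float) -> float:
    return float(f"{x:.3g}")


class _Packer:
    """Non-overlapping placement of loci on a genome's scaffolds."""

    def __init__(self, index: GenomeIndex, rng: np.random.Generator):
        self.index = index
        self.rng = rng
        self.trees: Dict[str, IntervalTree] = {
            sid: IntervalTree() for sid, _ in index.scaffolds
        }
        self.lens = {sid: ln for sid, ln in index.scaffolds}

    def place(self, length: int, scaffolds: Optional[Sequence[str]] = None,
              tries: int = 200) -> Tuple[str, int]:
        candidates = list(scaffolds) if scaffolds else [s for s, _ in self.index.scaffolds]
        candidates = [s for s in candidates if self.lens[s] >= length]
        if not candidates:
            raise SimulationError(
                f"infeasible packing: no scaffold can hold a {length} bp locus"
            )
        weights = np.array([self.lens[s] for s in candidates], dtype=float)
        weights /= weights.sum()
        for _ in range(tries):
            sid = candidates[int(self.rng.choice(len(candidates), p=weights))]
            start = int(self.rng.integers(0, self.lens[sid] - length + 1))
            if not self.trees[sid].overlaps(start, start + length):
                self.trees[sid].addi(start, start + length)
                return sid, start
        raise SimulationError(
            f"infeasible packing: could not place a {length} bp locus in "
            f"{tries} attempts (loci may exceed scaffold space)"
        )


def simulate(config: SimConfig) -> SimResult:
    """Generate the full multi-genome fixture described by ``config``."""
    rng = np.random.default_rng(config.seed)
    genomes = [f"g{i:02d}" for i in range(config.n_genomes)]
    if not genomes:
        raise ValueError("n_genomes must be >= 1")
    reference = genomes[0]

    # chromosome classes for the reference genome (ensure both classes exist);
    # micro scaffolds are an order of magnitude shorter, as in avian karyotypes
    labels = ["micro" if rng.random() < config.micro_fraction else "macro"
              for _ in range(config.scaffolds_per_genome)]
    if len(labels) >= 2:
        if all(l == "micro" for l in labels):
            labels[-1] = "macro"
        elif all(l == "macro" for l in labels):
            labels[-1] = "micro"

    lo, hi = config.scaffold_length_range
    micro_lo, micro_hi = max(lo // 10, 1000), max(hi // 10, 2000)
    genome_indexes: Dict[str, GenomeIndex] = {}
    for gid in genomes:
        scaffolds = []
        for j in range(config.scaffolds_per_genome):
            if gid == reference and labels[j] == "micro" and len(labels) >= 2:
                length = int(rng.integers(micro_lo, micro_hi + 1))
            else:
                length = int(rng.integers(lo, hi + 1))
            scaffolds.append((f"{gid}_s{j}", length))
        genome_indexes[gid] = GenomeIndex(gid, scaffolds)

    ref_scaffolds = [sid for sid, _ in genome_indexes[reference].scaffolds]
    chrom_classes = dict(zip(ref_scaffolds, labels))
    ref_micro = [s for s, l in chrom_classes.items() if l == "micro"]
    ref_macro = [s for s, l in chrom_classes.items() if l == "macro"]

    family_meta = {
        f.family_id: FamilyMeta(f.family_id, f.clan_id, f.rna_class, f.ga_threshold)
        for f in config.families
    }
    packers = {gid: _Packer(genome_indexes[gid], rng) for gid in genomes}

    hits_by_genome: Dict[str, List[Hit]] = {gid: [] for gid in genomes}
    trna_hits_by_genome: Dict[str, List[Hit]] = {gid: [] for gid in genomes}
    loci: List[TrueLocus] = []
    planted_genomes: Dict[str, Set[str]] = {}
    reference_scaffold: Dict[str, str] = {}

    def choose_genomes(fraction: float) -> List[str]:
        k = int(round(fraction * config.n_genomes))
        if k <= 0:
            return []
        others = genomes[1:]
        if k >= config.n_genomes:
            return list(genomes)
        extra = list(rng.choice(len(others), size=k - 1, replace=False)) if k > 1 else []
        return [reference] + [others[int(i)] for i in sorted(extra)]

    def ref_scaffold_choice(fam: FamilySpec) -> Optional[List[str]]:
        if fam.on_micro is None:
            return None
        preferred = ref_micro if fam.on_micro else ref_macro
        fallback = ref_macro if fam.on_micro else ref_micro
        if preferred and rng.random() < config.missing_micro_prob:
            return preferred
        return fallback or preferred

    def n_copies(fam: FamilySpec) -> int:
        if fam.exact_copies is not None:
            return fam.exact_copies
        if fam.mean_copies <= 1.0:
            return 1
        return 1 + int(rng.poisson(fam.mean_copies - 1.0))

    def emit_locus(fam: FamilySpec, gid: str, sid: str, start: int, length: int,
                   strand: str) -> None:
        end = start + length
        pseudo = fam.via_trnascan and rng.random() < fam.pseudogene_fraction
        if fam.via_trnascan:
            trna_hits_by_genome[gid].append(
                Hit(gid, sid, "tRNA", start, end, strand,
                    bit_score=round(float(rng.uniform(30, 80)), 2), evalue=0.0,
                    pseudogene=pseudo,
                    attributes={
                        "isotype": "Pseudo" if pseudo else "Ala",
                        "anticodon": "AGC",
                        "intron_begin": "0",
                        "intron_end": "0",
                    })
            )
        else:
            evalue = _round_evalue(10 ** float(rng.uniform(-10, -5)))
            score = round(fam.ga_threshold + float(rng.uniform(1, 20)), 1)
            hits_by_genome[gid].append(
                Hit(gid, sid, fam.family_id, start, end, strand,
                    bit_score=score, evalue=evalue)
            )
        loci.append(TrueLocus(gid, sid, fam.family_id, start, end, strand,
                              pseudogene=pseudo, channel=fam.via_trnascan and
                              "trnascan" or "tblout"))
        if gid == reference and fam.family_id not in reference_scaffold:
            reference_scaffold[fam.family_id] = sid

    # --- plant independent families ----------------------------------------
    singles = [f for f in config.families if f.domain_group is None]
    groups: Dict[str, List[FamilySpec]] = {}
    for f in config.families:
        if f.domain_group is not None:
            groups.setdefault(f.domain_group, []).append(f)

    for fam in singles:
        chosen = choose_genomes(fam.conservation_fraction)
        planted_genomes[fam.family_id] = set(chosen)
        for gid in chosen:
            allowed = ref_scaffold_choice(fam) if gid == reference else None
            for _ in range(n_copies(fam)):
                length = int(rng.integers(fam.length_range[0], fam.length_range[1] + 1))
                sid, start = packers[gid].place(length, scaffolds=allowed)
                strand = "+" if rng.random() < 0.5 else "-"
                emit_locus(fam, gid, sid, start, length, strand)

    # --- plant lncRNA domain groups in reference order ---------------------
    for group_name, members in groups.items():
        chosen = choose_genomes(members[0].conservation_fraction)
        for fam in members:
            planted_genomes[fam.family_id] = set(chosen)
        for gid in chosen:
            lengths = [int(rng.integers(f.length_range[0], f.length_range[1] + 1))
                       for f in members]
            gaps = [int(rng.integers(200, 2000)) for _ in members[:-1]]
            span = sum(lengths) + sum(gaps)
            sid, base = packers[gid].place(span)
            inverted = rng.random() < 0.5  # scaffold orientation is arbitrary
            strand = "+" if rng.random() < 0.5 else "-"
            ordered = list(zip(members, lengths))
            if inverted:
                ordered = ordered[::-1]
            pos = base
            for i, (fam, length) in enumerate(ordered):
                emit_locus(fam, gid, sid, pos, length, strand)
                pos += length + (gaps[i] if i < len(gaps) else 0)

    # --- clan-mate decoys overlapping true loci ----------------------------
    clan_members: Dict[str, List[FamilySpec]] = {}
    for f in config.families:
        if f.clan_id:
            clan_members.setdefault(f.clan_id, []).append(f)
    for locus in list(loci):
        fam = next(f for f in config.families if f.family_id == locus.family_id)
        if not fam.clan_id:
            continue
        mates = [m for m in clan_members[fam.clan_id] if m.family_id != fam.family_id
                 and not m.via_trnascan]
        if not mates or rng.random() >= config.overlap_decoy_rate:
            continue
        mate = mates[int(rng.integers(0, len(mates)))]
        shift = (locus.length // 4) * (1 if rng.random() < 0.5 else -1)
        start = max(0, locus.start + shift)
        end = start + locus.length
        slen = genome_indexes[locus.genome_id].lengths[locus.scaffold_id]
        if end > slen:
            end = slen
            start = max(0, end - locus.length)
        base_e = max(locus.channel == "trnascan" and 1e-8 or 0.0, 1e-12)
        true_e = next(
            (h.evalue for h in hits_by_genome[locus.genome_id]
             if h.scaffold_id == locus.scaffold_id and h.start == locus.start
             and h.family_id == locus.family_id),
            base_e,
        )
        worse = min(_round_evalue(max(true_e, 1e-10) * 10 ** float(rng.uniform(1, 3))),
                    4.9e-4)
        hits_by_genome[locus.genome_id].append(
            Hit(locus.genome_id, locus.scaffold_id, mate.family_id, start, end,
                locus.strand, bit_score=round(mate.ga_threshold + float(rng.uniform(1, 10)), 1),
                evalue=worse)
        )

    # --- filter-failing random decoys --------------------------------------
    decoy_pool = [f for f in config.families if not f.via_trnascan]
    for gid in genomes:
        if not decoy_pool or config.decoy_rate == 0:
            break
        for _ in range(int(rng.poisson(config.decoy_rate))):
            fam = decoy_pool[int(rng.integers(0, len(decoy_pool)))]
            length = int(rng.integers(fam.length_range[0], fam.length_range[1] + 1))
            sid, slen = genome_indexes[gid].scaffolds[
                int(rng.integers(0, config.scaffolds_per_genome))
            ]
            start = int(rng.integers(0, max(1, slen - length)))
            strand = "+" if rng.random() < 0.5 else "-"
            if rng.random() < 0.5:  # fails the E-value cutoff
                evalue = _round_evalue(10 ** float(rng.uniform(math.log10(6e-4), 0)))
                score = round(fam.ga_threshold + float(rng.uniform(1, 10)), 1)
            else:                   # fails the GA threshold
                evalue = _round_evalue(10 ** float(rng.uniform(-8, -5)))
                score = round(fam.ga_threshold - float(rng.uniform(1, 10)), 1)
            hits_by_genome[gid].append(
                Hit(gid, sid, fam.family_id, start, start + length, strand,
                    bit_score=score, evalue=evalue)
            )

    # --- strand-specific reads over the reference genome --------------------
    ref_loci_idx = [i for i, t in enumerate(loci) if t.genome_id == reference]
    n_ref = len(ref_loci_idx)
    reads: List[ReadInterval] = []
    rid = 0
    if n_ref:
        n_expressed = int(round(config.expressed_fraction * n_ref))
        expressed_set = set(
            int(i) for i in rng.choice(n_ref, size=n_expressed, replace=False)
        )
        mean_len = sum(loci[i].length for i in ref_loci_idx) / n_ref
        ref_index = genome_indexes[reference]
        occupancy = packers[reference].trees
        for j, i in enumerate(ref_loci_idx):
            locus = loci[i]
            expressed = j in expressed_set
            loci[i] = replace(locus, expressed=expressed)
            lam = config.lambda_hi if expressed else config.lambda_lo
            slen = ref_index.lengths[locus.scaffold_id]
            for _ in range(int(rng.poisson(lam))):
                hi_start = max(locus.start + 1, locus.end - config.read_length + 1)
                start = int(rng.integers(locus.start, hi_start))
                end = min(start + config.read_length, slen)
                rid += 1
                reads.append(ReadInterval(locus.scaffold_id, start, end,
                                          locus.strand, f"r{rid:07d}"))
        # background noise over un-annotated space: same-strand expected count
        # of a mean-length null region ~ lambda_lo
        rate = 2.0 * config.lambda_lo / (mean_len + config.read_length - 1)
        total_len = ref_index.total_length
        scaffold_ids = [s for s, _ in ref_index.scaffolds]
        scaffold_lens = np.array([l for _, l in ref_index.scaffolds], dtype=float)
        weights = scaffold_lens / scaffold_lens.sum()
        for _ in range(int(rng.poisson(rate * total_len))):
            for _try in range(20):
                si = int(rng.choice(len(scaffold_ids), p=weights))
                slen = int(scaffold_lens[si])
                start = int(rng.integers(0, max(1, slen - config.read_length)))
                end = start + config.read_length
                if occupancy[scaffold_ids[si]].overlaps(start, end):
                    continue
                rid += 1
                strand = "+" if rng.random() < 0.5 else "-"
                reads.append(ReadInterval(scaffold_ids[si], start, end, strand,
                                          f"r{rid:07d}"))
                break

    missing_families = [
        f.family_id for f in config.families
        if f.conservation_fraction <= config.missing_conservation_max
        and planted_genomes.get(f.family_id)
    ]
    truth = GroundTruth(
        loci=loci,
        planted_genomes=planted_genomes,
        missing_families=missing_families,
        reference_scaffold=reference_scaffold,
    )
    return SimResult(
        config=config,
        genome_indexes=genome_indexes,
        chrom_classes=chrom_classes,
        family_meta=family_meta,
        hits_by_genome=hits_by_genome,
        trna_hits_by_genome=trna_hits_by_genome,
        reads=reads,
        truth=truth,
    )


def expression_benchmark_config(
    n_annotations: int = 2000,
    expressed_fraction: float = 0.7,
    lambda_hi: float = 50.0,
    lambda_lo: float = 0.5,
    seed: int = 0,
    n_families: int = 40,
) -> SimConfig:
    """Single-genome configuration for expression-threshold calibration studies.

    Plants exactly ``n_annotations`` loci (n_families families with fixed copy
    numbers) on a 10 Mb genome, with no decoys, so the expression caller can
    be evaluated against a clean planted truth.
    """
    per_family, remainder = divmod(n_annotations, n_families)
    fams = tuple(
        FamilySpec(
            f"EXPR{i:03d}", "microRNA", conservation_fraction=1.0,
            exact_copies=per_family + (1 if i < remainder else 0),
            length_range=(70, 300),
        )
        for i in range(n_families)
    )
    return SimConfig(
        n_genomes=1,
        scaffolds_per_genome=5,
        scaffold_length_range=(2_000_000, 2_000_001),
        families=fams,
        decoy_rate=0.0,
        overlap_decoy_rate=0.0,
        expressed_fraction=expressed_fraction,
        lambda_hi=lambda_hi,
        lambda_lo=lambda_lo,
        seed=seed,
    )


#: Chicken per-class (annotated, expressed) counts of the published summary
#: table, for end-to-end testing of the expression summariser.
_TABLE1_CHICKEN: Tuple[Tuple[str, int, int], ...] = (
    ("Long non-coding RNA", 34, 12),
    ("microRNA", 427, 280),
    ("C/D box snoRNA", 106, 90),
    ("H/ACA box snoRNA", 68, 48),
    ("Small cajal body RNA", 12, 12),
    ("Major spliceosomal RNA", 71, 32),
    ("Minor spliceosomal RNA", 6, 3),
    ("Cis-regulatory element", 122, 88),
    ("7SK RNA", 9, 3),
    ("Telomerase RNA", 2, 0),
    ("Vault RNA", 2, 1),
    ("Y RNA", 3, 2),
    ("Transfer RNA", 300, 278),
    ("Transfer RNA pseudogene", 4, 2),
    ("SRP RNA", 4, 2),
    ("Ribosomal RNA", 22, 10),
    ("RNase P/MRP RNA", 2, 2),
)


def table1_fixture() -> Dict[str, Tuple[int, int]]:
    """Per-class chicken (annotated, expressed) pairs of the published table."""
    return {name: (a, e) for name, a, e in _TABLE1_CHICKEN}
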