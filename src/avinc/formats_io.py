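"""Readers and writers for the external formats the pipeline touches.

Supported dialects
------------------
* INFERNAL 1.1 ``cmsearch --tblout`` (18 whitespace-delimited columns,
  1-based inclusive coordinates, minus strand implied by seq-from > seq-to)
* tRNAscan-SE 1.3.1 tabular output
* family-metadata TSV (family_id, clan_id, rna_class, ga_threshold)
* two-column scaffold-length TSV (FASTA-index style)
* chromosome-class TSV (scaffold_id, macro|micro|unassigned)
* BED6 and GFF3 for annotations, BED6 for aligned reads

Every reader normalizes into the internal convention (0-based half-open,
explicit strand); every writer converts back, so reader/writer pairs
round-trip.  Sources may be paths, file-like objects, or raw text.
"""
from __future__ import annotations

import io
import os
from typing import Dict, Iterable, List, Optional, Sequence, TextIO, Tuple, Union

from .model import (
    CHROM_CLASSES,
    Annotation,
    FamilyMeta,
    GenomeIndex,
    Hit,
    ParseError,
    ReadInterval,
    sort_annotations,
)

Source = Union[str, os.PathLike, TextIO]

TBLOUT_COLUMNS = 18

_TRNASCAN_HEADER = (
    "Sequence\t\ttRNA\tBounds\ttRNA\tAnti\tIntron Bounds\tCove\n"
    "Name    \ttRNA #\tBegin\tEnd\tType\tCodon\tBegin\tEnd\tScore\n"
    "--------\t------\t----\t------\t----\t-----\t-----\t----\t------\n"
)


def _open_text(source: Source) -> Tuple[TextIO, bool]:
    """Return (handle, should_close). Strings containing newlines are raw text."""
    if hasattr(source, "read"):
        return source, False  # type: ignore[return-value]
    if isinstance(source, str) and ("\n" in source or not os.path.exists(source)):
        # Raw text, or a path that doesn't exist; raw text wins when it has
        # newlines, otherwise let open() raise the natural error.
        if "\n" in source:
            return io.StringIO(source), True
    return open(os.fspath(source), "r", encoding="utf-8"), True  # type: ignore[arg-type]


def _lines(source: Source):
    handle, close = _open_text(source)
    try:
        for i, line in enumerate(handle, start=1):
            yield i, line.rstrip("\n")
    finally:
        if close:
            handle.close()


def _normalize_coords(a: int, b: int) -> Tuple[int, int]:
    """1-based inclusive (possibly reversed) -> 0-based half-open."""
    lo, hi = (a, b) if a <= b else (b, a)
    return lo - 1, hi


# ---------------------------------------------------------------------------
# cmsearch --tblout
# ---------------------------------------------------------------------------

def read_cmsearch_tblout(source: Source, genome_id: str) -> List[Hit]:
    """Parse INFERNAL 1.1 ``cmsearch --tblout`` output into hits.

    The family identifier is taken from the query accession column when
    present (Rfam puts the RFxxxxx accession there), falling back to the
    query name.
    """
    hits: List[Hit] = []
    for n, line in _lines(source):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split(None, TBLOUT_COLUMNS - 1)
        if len(fields) < TBLOUT_COLUMNS:
            raise ParseError(
                f"expected {TBLOUT_COLUMNS} tblout columns, got {len(fields)}", n
            )
        (target, _tacc, qname, qacc, _mdl, _mfrom, _mto,
         seq_from_s, seq_to_s, strand, _trunc, _pass, _gc, _bias,
         score_s, evalue_s, _inc, _desc) = fields
        try:
            seq_from, seq_to = int(seq_from_s), int(seq_to_s)
        except ValueError:
            raise ParseError(f"non-integer coordinates {seq_from_s!r}/{seq_to_s!r}", n)
        try:
            score = float(score_s)
            evalue = float(evalue_s)
        except ValueError:
            raise ParseError(f"non-numeric score/E-value {score_s!r}/{evalue_s!r}", n)
        if strand not in ("+", "-"):
            raise ParseError(f"unknown strand token {strand!r}", n)
        if seq_from != seq_to and (strand == "-") != (seq_from > seq_to):
            raise ParseError(
                f"strand {strand!r} inconsistent with coordinates {seq_from}..{seq_to}", n
            )
        start, end = _normalize_coords(seq_from, seq_to)
        family = qacc if qacc not in ("-", "") else qname
        hits.append(
            Hit(
                genome_id=genome_id,
                scaffold_id=target,
                family_id=family,
                start=start,
                end=end,
                strand=strand,
                bit_score=score,
                evalue=evalue,
            )
        )
    return hits


def write_cmsearch_tblout(hits: Sequence[Hit], stream: Optional[TextIO] = None) -> str:
    """Render hits back into the tblout dialect (inverse of the reader)."""
    out = stream or io.StringIO()
    out.write("#target name\taccession\tquery name\taccession\tmdl\tmdl from\t"
              "mdl to\tseq from\tseq to\tstrand\ttrunc\tpass\tgc\tbias\tscore\t"
              "E-value\tinc\tdescription of target\n")
    for h in hits:
        if h.strand == "+":
            seq_from, seq_to = h.start + 1, h.end
        else:
            seq_from, seq_to = h.end, h.start + 1
        mdl_to = h.end - h.start
        out.write(
            f"{h.scaffold_id} - {h.family_id} - cm 1 {mdl_to} "
            f"{seq_from} {seq_to} {h.strand} no 1 0.50 0.0 "
            f"{h.bit_score:.1f} {h.evalue:.3g} ! -\n"
        )
    return out.getvalue() if stream is None else ""


# ---------------------------------------------------------------------------
# tRNAscan-SE
# ---------------------------------------------------------------------------

def read_trnascan(source: Source, genome_id: str) -> List[Hit]:
    """Parse tRNAscan-SE 1.3.1 tabular output.

    All hits are assigned family_id "tRNA" with a pseudo E-value of 0, so the
    specialist tool outranks general homology hits in clan competition.  Rows
    whose isotype is "Pseudo" are flagged as pseudogenes.  Intron bounds are
    recorded in attributes but the locus spans the full begin..end interval.
    """
    hits: List[Hit] = []
    in_body = False
    saw_header = False
    for n, line in _lines(source):
        if not in_body:
            if line.startswith("--------"):
                in_body = True
                saw_header = True
            elif line.strip():
                saw_header = True
            continue
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            fields = line.split()
        if len(fields) < 9:
            raise ParseError(f"expected >= 9 tRNAscan columns, got {len(fields)}", n)
        scaffold = fields[0].strip()
        try:
            begin, end_ = int(fields[2]), int(fields[3])
            intron_begin, intron_end = int(fields[6]), int(fields[7])
            cove = float(fields[8])
        except ValueError:
            raise ParseError(f"non-numeric field in tRNAscan row {fields!r}", n)
        if begin == end_:
            raise ParseError(f"degenerate tRNA bounds {begin}=={end_}", n)
        strand = "+" if begin < end_ else "-"
        start, end = _normalize_coords(begin, end_)
        isotype = fields[4].strip()
        hits.append(
            Hit(
                genome_id=genome_id,
                scaffold_id=scaffold,
                family_id="tRNA",
                start=start,
                end=end,
                strand=strand,
                bit_score=cove,
                evalue=0.0,
                pseudogene=isotype.lower() == "pseudo",
                attributes={
                    "isotype": isotype,
                    "anticodon": fields[5].strip(),
                    "intron_begin": str(intron_begin),
                    "intron_end": str(intron_end),
                },
            )
        )
    if not in_body or not saw_header:
        raise ParseError("missing tRNAscan header (no dashed separator line found)")
    return hits


def write_trnascan(hits: Sequence[Hit], stream: Optional[TextIO] = None) -> str:
    out = stream or io.StringIO()
    out.write(_TRNASCAN_HEADER)
    for i, h in enumerate(hits, start=1):
        if h.strand == "+":
            begin, end = h.start + 1, h.end
        else:
            begin, end = h.end, h.start + 1
        isotype = h.attributes.get("isotype", "Pseudo" if h.pseudogene else "Xxx")
        anticodon = h.attributes.get("anticodon", "NNN")
        ib = h.attributes.get("intron_begin", "0")
        ie = h.attributes.get("intron_end", "0")
        out.write(
            f"{h.scaffold_id}\t{i}\t{begin}\t{end}\t{isotype}\t{anticodon}\t"
            f"{ib}\t{ie}\t{h.bit_score:.2f}\n"
        )
    return out.getvalue() if stream is None else ""


# ---------------------------------------------------------------------------
# Family metadata
# ---------------------------------------------------------------------------

def read_family_metadata(source: Source) -> Dict[str, FamilyMeta]:
    """Parse the family-metadata TSV into an ordered family_id -> FamilyMeta map.

    Columns: family_id, clan_id (may be empty -> singleton clan), rna_class,
    ga_threshold.  An optional header line starting with "family_id" is
    skipped.  Duplicate family ids are an error.
    """
    meta: Dict[str, FamilyMeta] = {}
    for n, line in _lines(source):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0].strip() == "family_id":
            continue
        if len(fields) < 4:
            raise ParseError(f"expected 4 tab-separated columns, got {len(fields)}", n)
        family_id = fields[0].strip()
        clan = fields[1].strip() or None
        rna_class = fields[2].strip()
        try:
            ga = float(fields[3])
        except ValueError:
            raise ParseError(f"non-numeric GA threshold {fields[3]!r}", n)
        if family_id in meta:
            raise ParseError(f"duplicate family_id {family_id!r}", n)
        meta[family_id] = FamilyMeta(family_id, clan, rna_class, ga)
    return meta


def write_family_metadata(
    meta: Dict[str, FamilyMeta], stream: Optional[TextIO] = None
) -> str:
    out = stream or io.StringIO()
    out.write("family_id\tclan_id\trna_class\tga_threshold\n")
    for fam in meta.values():
        out.write(
            f"{fam.family_id}\t{fam.clan_id or ''}\t{fam.rna_class}\t"
            f"{fam.ga_threshold:g}\n"
        )
    return out.getvalue() if stream is None else ""


# ---------------------------------------------------------------------------
# Scaffold lengths / chromosome classes
# ---------------------------------------------------------------------------

def read_scaffold_lengths(source: Source, genome_id: str) -> GenomeIndex:
    """Two-column TSV (scaffold_id, length in bp) -> GenomeIndex."""
    scaffolds: List[Tuple[str, int]] = []
    for n, line in _lines(source):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"expected 2 columns, got {len(fields)}", n)
        try:
            length = int(fields[1])
        except ValueError:
            raise ParseError(f"non-integer length {fields[1]!r}", n)
        if length <= 0:
            raise ParseError(f"non-positive scaffold length {length}", n)
        scaffolds.append((fields[0].strip(), length))
    return GenomeIndex(genome_id=genome_id, scaffolds=scaffolds)


def write_scaffold_lengths(index: GenomeIndex, stream: Optional[TextIO] = None) -> str:
    out = stream or io.StringIO()
    for sid, length in index.scaffolds:
        out.write(f"{sid}\t{length}\n")
    return out.getvalue() if stream is None else ""


def read_chromosome_classes(source: Source) -> Dict[str, str]:
    """TSV (scaffold_id, macro|micro|unassigned) -> scaffold -> class label."""
    classes: Dict[str, str] = {}
    for n, line in _lines(source):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"expected 2 columns, got {len(fields)}", n)
        label = fields[1].strip()
        if label not in CHROM_CLASSES:
            raise ParseError(f"unknown chromosome class {label!r}", n)
        classes[fields[0].strip()] = label
    return classes


def write_chromosome_classes(
    classes: Dict[str, str], stream: Optional[TextIO] = None
) -> str:
    out = stream or io.StringIO()
    for sid, label in classes.items():
        out.write(f"{sid}\t{label}\n")
    return out.getvalue() if stream is None else ""


# ---------------------------------------------------------------------------
# Reads (BED6)
# ---------------------------------------------------------------------------

def read_bed_reads(source: Source) -> List[ReadInterval]:
    """BED6 -> aligned-read intervals (0-based half-open, explicit strand)."""
    reads: List[ReadInterval] = []
    for n, line in _lines(source):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            fields = line.split()
        if len(fields) < 6:
            raise ParseError(f"expected 6 BED columns, got {len(fields)}", n)
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise ParseError(f"non-integer BED coordinates {fields[1:3]!r}", n)
        if end <= start or start < 0:
            raise ParseError(f"invalid BED interval [{start}, {end})", n)
        strand = fields[5].strip()
        if strand not in ("+", "-"):
            raise ParseError(f"unknown strand token {strand!r}", n)
        reads.append(ReadInterval(fields[0], start, end, strand, fields[3]))
    return reads


def write_bed_reads(reads: Iterable[ReadInterval], stream: Optional[TextIO] = None) -> str:
    out = stream or io.StringIO()
    for r in reads:
        out.write(f"{r.scaffold_id}\t{r.start}\t{r.end}\t{r.read_id}\t0\t{r.strand}\n")
    return out.getvalue() if stream is None else ""


# ---------------------------------------------------------------------------
# Annotations (BED6 / GFF3)
# ---------------------------------------------------------------------------

def write_annotations(
    annotations: Sequence[Annotation],
    fmt: str = "GFF3",
    stream: Optional[TextIO] = None,
    family_meta: Optional[Dict[str, FamilyMeta]] = None,
) -> str:
    """Serialise annotations as BED6 or GFF3, sorted by scaffold then start.

    BED6 score is the bit score capped at 1000 (BED validity); the raw score
    is preserved in GFF3 attributes.  GFF3 coordinates are 1-based inclusive.
    """
    fmt = fmt.upper()
    if fmt not in ("BED6", "GFF3"):
        raise ValueError(f"unsupported format {fmt!r}")
    out = stream or io.StringIO()
    anns = sort_annotations(annotations)
    if fmt == "BED6":
        out.write('track name="avinc_annotations"\n')
        for a in anns:
            score = min(int(round(a.best_bit_score)), 1000)
            out.write(
                f"{a.scaffold_id}\t{a.start}\t{a.end}\t{a.family_id}\t"
                f"{max(score, 0)}\t{a.strand}\n"
            )
    else:
        out.write("##gff-version 3\n")
        for i, a in enumerate(anns, start=1):
            attrs = [
                f"ID=ncRNA{i}",
                f"genome={a.genome_id}",
                f"family={a.family_id}",
                f"class={a.rna_class}",
                f"evalue={a.best_evalue:.6g}",
                f"bit_score={a.best_bit_score:g}",
                f"n_merged={a.n_merged}",
            ]
            if family_meta and a.family_id in family_meta:
                clan = family_meta[a.family_id].clan_id
                if clan:
                    attrs.insert(3, f"clan={clan}")
            out.write(
                f"{a.scaffold_id}\tavinc\tncRNA\t{a.start + 1}\t{a.end}\t"
                f"{a.best_bit_score:g}\t{a.strand}\t.\t{';'.join(attrs)}\n"
            )
    return out.getvalue() if stream is None else ""


def read_annotations_gff3(source: Source, genome_id: Optional[str] = None) -> List[Annotation]:
    """Read back the GFF3 dialect produced by :func:`write_annotations`."""
    anns: List[Annotation] = []
    for n, line in _lines(source):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            raise ParseError(f"expected 9 GFF3 columns, got {len(fields)}", n)
        attrs = {}
        for item in fields[8].split(";"):
            if "=" in item:
                k, v = item.split("=", 1)
                attrs[k.strip()] = v.strip()
        try:
            start = int(fields[3]) - 1
            end = int(fields[4])
        except ValueError:
            raise ParseError(f"non-integer GFF3 coordinates {fields[3:5]!r}", n)
        strand = fields[6]
        if strand not in ("+", "-"):
            raise ParseError(f"unknown strand token {strand!r}", n)
        anns.append(
            Annotation(
                genome_id=genome_id or attrs.get("genome", ""),
                scaffold_id=fields[0],
                family_id=attrs.get("family", fields[2]),
                start=start,
                end=end,
                strand=strand,
                best_bit_score=float(attrs.get("bit_score", fields[5])),
                best_evalue=float(attrs.get("evalue", "0")),
                rna_class=attrs.get("class", ""),
                n_merged=int(attrs.get("n_merged", "1")),
            )
        )
    return anns
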