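"""Reading and writing the standard formats the pipeline touches.

FASTA and FASTQ go through Bio.SeqIO, SAM through pysam; GFF3 uses a small
two-level (parent + LTR/INT children) reader/writer. All coordinates are
converted to a single internal convention at the I/O boundary: 0-based,
half-open intervals. GFF3 on disk is 1-based inclusive, SAM positions are
handled by pysam (already 0-based in its API).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam
from Bio import SeqIO

from .mapping import Hit, revcomp

logger = logging.getLogger(__name__)

SubLocus = tuple[str, tuple[int, int]]  # (role in {LTR5, INT, LTR3}, (start, end))


@dataclass(frozen=True)
class SpeciesRecord:
    """A distinct read sequence ("species") and its read count ("expression")."""

    sequence: str
    expression: int

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("species sequence must be non-empty")
        if self.expression < 1:
            raise ValueError("expression must be >= 1")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class AnnotationRecord:
    """An annotated element: genomic interval plus LTR/INT sub-loci.

    Intervals are 0-based half-open on `reference_id`. Sub-loci must nest
    within the element interval and must not overlap one another.
    """

    element_id: str
    family: str
    reference_id: str
    interval: tuple[int, int]
    strand: str = "+"
    sub_loci: list[SubLocus] = field(default_factory=list)

    def __post_init__(self) -> None:
        s, e = self.interval
        if not (0 <= s < e):
            raise ValueError(f"{self.element_id}: bad interval {self.interval}")
        spans = sorted(iv for _, iv in self.sub_loci)
        for cs, ce in spans:
            if cs < s or ce > e or cs >= ce:
                raise ValueError(
                    f"{self.element_id}: sub-locus ({cs},{ce}) outside parent {self.interval}"
                )
        for (_s1, e1), (s2, _e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(f"{self.element_id}: overlapping sub-loci")

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]

    def sub_locus(self, role: str) -> tuple[int, int]:
        for r, iv in self.sub_loci:
            if r == role:
                return iv
        raise KeyError(role)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-)FASTA into {id: uppercase sequence}.

    Identifiers are kept up to the first whitespace. Duplicate identifiers
    and empty files are hard errors.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA identifier: {rec.id}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def dereplicate_reads(fastq_path: str | Path) -> list[SpeciesRecord]:
    """Collapse a FASTQ into species records (one per distinct sequence).

    The expression of a species is the number of reads carrying exactly that
    sequence, so expressions sum to the library's read count. Qualities are
    ignored. Records are returned sorted by (-expression, sequence) for
    determinism.
    """
    counts: Counter[str] = Counter()
    for rec in SeqIO.parse(str(path_str := str(fastq_path)), "fastq"):
        counts[str(rec.seq).upper()] += 1
    logger.info("dereplicated %s: %d reads, %d species", path_str, sum(counts.values()), len(counts))
    return [
        SpeciesRecord(seq, n)
        for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


# ---------------------------------------------------------------------------
# GFF3

_ROLE_TO_SO = {"LTR5": "long_terminal_repeat", "LTR3": "long_terminal_repeat", "INT": "internal_region"}


def read_annotations(gff_path: str | Path) -> list[AnnotationRecord]:
    """Read a GFF3 TE annotation into AnnotationRecords.

    Disk coordinates (1-based inclusive) are converted to internal 0-based
    half-open intervals. Child features are attached to parents via their
    Parent attribute; a `role` attribute (LTR5/INT/LTR3) labels sub-loci.
    A child interval escaping its parent is a hard error.
    """
    parents: dict[str, AnnotationRecord] = {}
    children: list[tuple[str, str, str, tuple[int, int]]] = []
    with open(gff_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            ref, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            iv = (int(start) - 1, int(end))
            adict = dict(
                kv.split("=", 1) for kv in attrs.split(";") if kv and "=" in kv
            )
            if "Parent" in adict:
                role = adict.get("role", ftype)
                children.append((adict["Parent"], adict.get("ID", ""), role, iv))
            else:
                eid = adict["ID"]
                parents[eid] = AnnotationRecord(
                    element_id=eid,
                    family=adict.get("family", "unknown"),
                    reference_id=ref,
                    interval=iv,
                    strand=strand,
                )
    for parent_id, _cid, role, iv in children:
        if parent_id not in parents:
            raise ValueError(f"GFF3 child references unknown parent {parent_id}")
        rec = parents[parent_id]
        ps, pe = rec.interval
        if iv[0] < ps or iv[1] > pe:
            raise ValueError(
                f"child {role} interval {iv} outside parent {parent_id} {rec.interval}"
            )
        rec.sub_loci.append((role, iv))
    out = sorted(parents.values(), key=lambda r: (r.reference_id, r.interval, r.element_id))
    for rec in out:
        rec.sub_loci.sort(key=lambda ri: ri[1])
        # re-validate nesting/overlap after attachment
        AnnotationRecord(rec.element_id, rec.family, rec.reference_id, rec.interval,
                         rec.strand, rec.sub_loci)
    return out


def write_annotations(records: Iterable[AnnotationRecord], gff_path: str | Path,
                      source: str = "tesrna") -> None:
    """Write AnnotationRecords as GFF3 (1-based inclusive on disk)."""
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in sorted(records, key=lambda r: (r.reference_id, r.interval, r.element_id)):
            s, e = rec.interval
            fh.write(
                "\t".join([
                    rec.reference_id, source, "LTR_retrotransposon",
                    str(s + 1), str(e), ".", rec.strand, ".",
                    f"ID={rec.element_id};family={rec.family}",
                ]) + "\n"
            )
            for i, (role, (cs, ce)) in enumerate(sorted(rec.sub_loci, key=lambda ri: ri[1])):
                fh.write(
                    "\t".join([
                        rec.reference_id, source, _ROLE_TO_SO.get(role, role),
                        str(cs + 1), str(ce), ".", rec.strand, ".",
                        f"ID={rec.element_id}.{i};Parent={rec.element_id};role={role}",
                    ]) + "\n"
                )


# ---------------------------------------------------------------------------
# SAM


def import_sam_hits(sam_path: str | Path) -> dict[str, list[Hit]]:
    """Import an all-hits SAM into {species sequence: [Hit, ...]}.

    Only ungapped, full-length, edit-distance-0 alignments are accepted, both
    from alignment lines (primary/secondary) and from XA-style alternative-hit
    tags (``ref,±pos,CIGAR,NM`` with 1-based pos). Records with mismatches or
    indels are skipped and counted, not raised. Hits are deduplicated by
    (reference, position, strand).
    """
    hits: dict[str, set[Hit]] = {}
    skipped = 0
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.query_sequence is None:
                continue
            seq = aln.query_sequence.upper()
            if aln.is_reverse:
                seq = revcomp(seq)
            cig = aln.cigartuples or []
            if len(cig) == 1 and cig[0][0] == 0 and cig[0][1] == len(seq) and (
                not aln.has_tag("NM") or aln.get_tag("NM") == 0
            ):
                strand = "antisense" if aln.is_reverse else "sense"
                hits.setdefault(seq, set()).add(
                    Hit(aln.reference_name, aln.reference_start, strand)
                )
            else:
                skipped += 1
            if aln.has_tag("XA"):
                for alt in str(aln.get_tag("XA")).rstrip(";").split(";"):
                    ref, pos, cigar, nm = alt.split(",")
                    if int(nm) != 0 or cigar != f"{len(seq)}M":
                        skipped += 1
                        continue
                    strand = "antisense" if pos.startswith("-") else "sense"
                    hits.setdefault(seq, set()).add(
                        Hit(ref, abs(int(pos)) - 1, strand)
                    )
    if skipped:
        logger.info("import_sam_hits: skipped %d imperfect alignments", skipped)
    return {seq: sorted(hs) for seq, hs in hits.items()}


def write_sam_hits(
    hits_by_species: Mapping[str, Sequence[Hit]],
    reference_lengths: Mapping[str, int],
    sam_path: str | Path,
) -> None:
    """Write a hit list as an all-hits SAM (one line per hit, first = primary).

    Antisense hits store the reverse-complemented sequence with the reverse
    flag set, matching aligner conventions, so a round trip through
    import_sam_hits reproduces the input hit list.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": int(ln)} for name, ln in reference_lengths.items()],
    }
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as out:
        for i, (seq, hits) in enumerate(hits_by_species.items()):
            for j, hit in enumerate(hits):
                a = pysam.AlignedSegment(out.header)
                a.query_name = f"sp{i}"
                a.flag = (16 if hit.strand == "antisense" else 0) | (256 if j else 0)
                a.query_sequence = revcomp(seq) if hit.strand == "antisense" else seq
                a.reference_name = hit.reference_id
                a.reference_start = hit.position
                a.mapping_quality = 0
                a.cigarstring = f"{len(seq)}M"
                a.set_tag("NM", 0)
                out.write(a)


# ---------------------------------------------------------------------------
# TSV


def write_metrics_table(records: Sequence[Mapping[str, object]], path: str | Path,
                        float_precision: int = 6) -> None:
    """Write records as a deterministic TSV.

    Columns follow the first record's key order; rows are sorted by
    element_id when present, else by the first column. Floats are written at
    fixed precision so identical inputs give byte-identical files.
    """
    import pandas as pd

    df = pd.DataFrame.from_records(records)
    if len(df):
        key = "element_id" if "element_id" in df.columns else df.columns[0]
        df = df.sort_values(key, kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format=f"%.{float_precision}f")


def read_metrics_table(path: str | Path):
    import pandas as pd

    return pd.read_csv(path, sep="\t")
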