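"""Genome sequences, transcript annotations and strand-aware class lookup.

Coordinates are 0-based half-open internally; GFF3 I/O converts from/to the
1-based inclusive convention.  Overlapping annotations are resolved per
nucleotide by a fixed priority list (rRNA > tRNA > snRNA > snoRNA > intron >
CDS > UTR > SUT > CUT > NUT), matching how PAR-CLIP cross-link sites are
assigned to a single transcript class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

#: transcript classes understood by the pipeline
CLASSES = ("mRNA", "rRNA", "tRNA", "snoRNA", "snRNA", "SUT", "CUT", "NUT")

#: priority order for per-nucleotide class resolution (highest first);
#: the single "UTR" slot covers both utr5 and utr3 (they cannot overlap
#: within one gene's chosen isoform)
PRIORITY = ("rRNA", "tRNA", "snRNA", "snoRNA", "intron", "CDS", "UTR",
            "SUT", "CUT", "NUT")

#: detailed labels used for counting; CDS/UTR expand to mRNA segments
DETAILED_LABELS = ("rRNA", "tRNA", "snRNA", "snoRNA", "intron", "cds",
                   "utr5", "utr3", "SUT", "CUT", "NUT")

_PRIORITY_RANK = {lab: i for i, lab in enumerate(PRIORITY)}
# rank of a detailed label under the coarse priority list
_DETAILED_RANK = {
    "rRNA": 0, "tRNA": 1, "snRNA": 2, "snoRNA": 3, "intron": 4,
    "cds": 5, "utr5": 6, "utr3": 6, "SUT": 7, "CUT": 8, "NUT": 9,
}
_LABEL_CODE = {lab: i for i, lab in enumerate(DETAILED_LABELS)}
_CODE_LABEL = dict(enumerate(DETAILED_LABELS))
_NO_LABEL = 127

STRANDS = ("+", "-")

_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class AnnotationError(ValueError):
    """Raised for malformed annotation input or invalid coordinates."""


@dataclass
class GenomeSequence:
    """Per-chromosome base strings over the alphabet {A, C, G, T, N}."""

    chroms: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.chroms.items():
            if len(seq) == 0:
                raise AnnotationError(f"chromosome {name!r} has length 0")
            if set(seq) - set("ACGTN"):
                bad = sorted(set(seq) - set("ACGTN"))
                raise AnnotationError(
                    f"chromosome {name!r} contains non-ACGTN bases: {bad}")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chroms.items()}

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of [start, end) in reading orientation of `strand`."""
        seq = self.chroms[chrom][start:end]
        return seq if strand == "+" else reverse_complement(seq)

    @classmethod
    def from_fasta(cls, path) -> "GenomeSequence":
        chroms = {rec.id: str(rec.seq).upper()
                  for rec in SeqIO.parse(str(path), "fasta")}
        return cls(chroms)

    def to_fasta(self, path) -> None:
        records = [SeqRecord(Seq(seq), id=name, description="")
                   for name, seq in self.chroms.items()]
        SeqIO.write(records, str(path), "fasta")


@dataclass
class Segment:
    kind: str  # utr5 | cds | intron | utr3
    start: int
    end: int


@dataclass
class Transcript:
    id: str
    chrom: str
    strand: str
    start: int  # 0-based half-open genomic interval
    end: int
    class_label: str
    gene_id: str = ""
    abundance: float = 0.0
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise AnnotationError(
                f"transcript {self.id}: start {self.start} >= end {self.end}")
        if self.strand not in STRANDS:
            raise AnnotationError(f"transcript {self.id}: bad strand {self.strand!r}")
        if self.class_label not in CLASSES:
            raise AnnotationError(
                f"transcript {self.id}: unknown class {self.class_label!r}")
        if self.class_label != "mRNA" and self.segments:
            raise AnnotationError(
                f"transcript {self.id}: non-mRNA transcripts carry no segments")
        if not self.gene_id:
            self.gene_id = self.id

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Genomic coordinate of the transcription start site."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def pa_site(self) -> int:
        """Genomic coordinate of the poly-adenylation site (3' end)."""
        return self.end - 1 if self.strand == "+" else self.start

    def anchor(self, align_point: str) -> int:
        if align_point in ("TSS", "gene_start"):
            return self.tss
        if align_point in ("pA", "gene_end"):
            return self.pa_site
        if align_point == "stop_codon":
            cds = [s for s in self.segments if s.kind == "cds"]
            if not cds:
                raise AnnotationError(f"transcript {self.id} has no CDS segment")
            return (max(s.end for s in cds) - 1 if self.strand == "+"
                    else min(s.start for s in cds))
        raise AnnotationError(f"unknown align point {align_point!r}")

    def cds_interval(self) -> tuple[int, int] | None:
        """Genomic span of the CDS (introns included), or None."""
        spans = [s for s in self.segments if s.kind in ("cds", "intron")]
        if not spans:
            return None
        return min(s.start for s in spans), max(s.end for s in spans)


def segment_mrna(transcript: Transcript,
                 cds_interval: tuple[int, int],
                 introns: list[tuple[int, int]] | None = None) -> Transcript:
    """Attach utr5/cds/intron/utr3 segments to an mRNA.

    The UTRs are defined in transcript orientation: utr5 runs from the
    transcript 5' end to the CDS start, utr3 from the CDS end to the 3' end.
    Intron intervals must lie within the CDS span.  Zero-length segments are
    omitted.  Segments are returned ordered 5'->3' in transcript orientation.
    """
    cs, ce = cds_interval
    if not (transcript.start <= cs < ce <= transcript.end):
        raise AnnotationError(
            f"CDS [{cs},{ce}) outside transcript {transcript.id} "
            f"[{transcript.start},{transcript.end})")
    introns = sorted(introns or [])
    for istart, iend in introns:
        if not (cs <= istart < iend <= ce):
            raise AnnotationError(
                f"intron [{istart},{iend}) outside CDS span of {transcript.id}")
    segs: list[Segment] = []
    if transcript.start < cs:
        segs.append(Segment("utr5" if transcript.strand == "+" else "utr3",
                            transcript.start, cs))
    # split the CDS span at introns (genomic order)
    pos = cs
    for istart, iend in introns:
        if pos < istart:
            segs.append(Segment("cds", pos, istart))
        segs.append(Segment("intron", istart, iend))
        pos = iend
    if pos < ce:
        segs.append(Segment("cds", pos, ce))
    if ce < transcript.end:
        segs.append(Segment("utr3" if transcript.strand == "+" else "utr5",
                            ce, transcript.end))
    if transcript.strand == "-":
        segs = segs[::-1]  # order 5'->3' in transcript orientation
    return replace(transcript, segments=segs)


class AnnotationSet:
    """Class-labeled transcript intervals with strand-aware priority lookup.

    Lookups return at most one (detailed) class label per position by the
    fixed priority order.  A dense per-(chrom, strand) code array is built
    lazily for fast vectorized classification of many sites.
    """

    def __init__(self, transcripts: list[Transcript],
                 genome: GenomeSequence | None = None) -> None:
        self.transcripts = list(transcripts)
        self.genome = genome
        ids = [t.id for t in self.transcripts]
        if len(set(ids)) != len(ids):
            raise AnnotationError("duplicate transcript ids")
        if genome is not None:
            lengths = genome.lengths
            for t in self.transcripts:
                if t.chrom not in lengths:
                    raise AnnotationError(
                        f"transcript {t.id}: chromosome {t.chrom!r} not in genome")
                if t.end > lengths[t.chrom]:
                    raise AnnotationError(
                        f"transcript {t.id}: end {t.end} beyond chromosome "
                        f"{t.chrom} length {lengths[t.chrom]}")
        self._by_id = {t.id: t for t in self.transcripts}
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for t in self.transcripts:
            tree = self._trees.setdefault((t.chrom, t.strand), IntervalTree())
            tree.addi(t.start, t.end, t)
        self._class_arrays: dict[tuple[str, str], np.ndarray] | None = None

    def __len__(self) -> int:
        return len(self.transcripts)

    def __getitem__(self, tid: str) -> Transcript:
        return self._by_id[tid]

    def by_class(self, *labels: str) -> list[Transcript]:
        return [t for t in self.transcripts if t.class_label in labels]

    @property
    def mrnas(self) -> list[Transcript]:
        return self.by_class("mRNA")

    # -- interval queries ---------------------------------------------------

    def transcripts_at(self, chrom: str, pos: int, strand: str) -> list[Transcript]:
        tree = self._trees.get((chrom, strand))
        if tree is None:
            return []
        return [iv.data for iv in tree.at(pos)]

    def overlapping(self, chrom: str, start: int, end: int,
                    strand: str) -> list[Transcript]:
        tree = self._trees.get((chrom, strand))
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]

    # -- priority class assignment ------------------------------------------

    def _features(self):
        """Yield (chrom, strand, start, end, detailed_label) priority features."""
        for t in self.transcripts:
            if t.class_label == "mRNA":
                segs = t.segments or [Segment("cds", t.start, t.end)]
                for s in segs:
                    yield t.chrom, t.strand, s.start, s.end, s.kind
            else:
                yield t.chrom, t.strand, t.start, t.end, t.class_label

    def _build_class_arrays(self) -> dict[tuple[str, str], np.ndarray]:
        if self.genome is None:
            raise AnnotationError("dense class arrays require a genome")
        arrays = {
            (chrom, strand): np.full(length, _NO_LABEL, dtype=np.int8)
            for chrom, length in self.genome.lengths.items()
            for strand in STRANDS
        }
        feats = sorted(self._features(),
                       key=lambda f: _DETAILED_RANK[f[4]], reverse=True)
        # paint lowest priority first so higher priorities overwrite
        for chrom, strand, start, end, label in feats:
            arrays[(chrom, strand)][start:end] = _LABEL_CODE[label]
        return arrays

    @property
    def class_arrays(self) -> dict[tuple[str, str], np.ndarray]:
        if self._class_arrays is None:
            self._class_arrays = self._build_class_arrays()
        return self._class_arrays

    def assign_site_class(self, chrom: str, pos: int, strand: str,
                          detailed: bool = True) -> str | None:
        """Highest-priority class label at (chrom, pos, strand), or None.

        With ``detailed=False`` utr5/utr3 collapse to "UTR" and cds to "CDS".
        """
        if self.genome is not None:
            code = self.class_arrays[(chrom, strand)][pos]
            label = _CODE_LABEL.get(int(code))
        else:
            best = None
            for t in self.transcripts_at(chrom, pos, strand):
                if t.class_label == "mRNA":
                    segs = t.segments or [Segment("cds", t.start, t.end)]
                    for s in segs:
                        if s.start <= pos < s.end:
                            cand = s.kind
                            break
                    else:
                        continue
                else:
                    cand = t.class_label
                if best is None or _DETAILED_RANK[cand] < _DETAILED_RANK[best]:
                    best = cand
            label = best
        if label is None:
            return None
        if not detailed:
            return {"utr5": "UTR", "utr3": "UTR", "cds": "CDS"}.get(label, label)
        return label

    def assign_site_classes(self, chroms, positions, strands) -> np.ndarray:
        """Vectorized detailed class codes for many sites; -1 = unannotated.

        Returns int codes indexing :data:`DETAILED_LABELS`.
        """
        arrays = self.class_arrays
        out = np.full(len(positions), _NO_LABEL, dtype=np.int16)
        df = pd.DataFrame({"chrom": chroms, "pos": positions, "strand": strands})
        for (chrom, strand), grp in df.groupby(["chrom", "strand"], sort=False):
            arr = arrays.get((chrom, strand))
            if arr is None:
                continue
            out[grp.index.to_numpy()] = arr[grp["pos"].to_numpy()]
        out = out.astype(np.int16)
        out[out == _NO_LABEL] = -1
        return out


# ---------------------------------------------------------------------------
# isoform selection


def select_major_isoforms(isoform_records: list[Transcript],
                          genome: GenomeSequence | None = None) -> AnnotationSet:
    """Keep exactly one transcript per gene: the most abundant isoform.

    Ties are broken by longest transcript, then by lexicographically smallest
    id, so the selection is deterministic.  Genes whose isoforms all have
    zero abundance keep the longest isoform (with a warning).
    """
    by_gene: dict[str, list[Transcript]] = {}
    for t in isoform_records:
        by_gene.setdefault(t.gene_id, []).append(t)
    chosen = []
    for gene, isoforms in by_gene.items():
        if all(t.abundance == 0 for t in isoforms) and len(isoforms) > 1:
            log.warning("gene %s: all isoform abundances zero; keeping longest",
                        gene)
        best = max(isoforms, key=lambda t: (t.abundance, t.length, _NegStr(t.id)))
        chosen.append(best)
    chosen.sort(key=lambda t: (t.chrom, t.start, t.id))
    return AnnotationSet(chosen, genome=genome)


class _NegStr:
    """Reverses string comparison so max() picks the smallest id on ties."""

    __slots__ = ("s",)

    def __init__(self, s: str) -> None:
        self.s = s

    def __lt__(self, other: "_NegStr") -> bool:
        return self.s > other.s

    def __eq__(self, other) -> bool:
        return self.s == other.s


# ---------------------------------------------------------------------------
# GFF3 I/O (package dialect: class in `type`, segments as child features)

_SEG_TYPES = {"five_prime_UTR": "utr5", "CDS": "cds", "intron": "intron",
              "three_prime_UTR": "utr3"}
_SEG_TYPES_INV = {v: k for k, v in _SEG_TYPES.items()}


def _parse_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        if "=" not in part:
            raise ValueError(f"malformed attribute {part!r}")
        key, value = part.split("=", 1)
        out[key] = value
    return out


def load_annotations(annotation_file, genome: GenomeSequence | None = None
                     ) -> AnnotationSet:
    """Load the package's GFF3 dialect into an AnnotationSet.

    Transcript-level rows carry the class in the `type` column; mRNA segment
    rows (five_prime_UTR / CDS / intron / three_prime_UTR) reference their
    transcript via `Parent=`.  1-based inclusive coordinates are converted to
    0-based half-open.
    """
    transcripts: dict[str, dict] = {}
    order: list[str] = []
    n_lines = 0
    with open(annotation_file) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{annotation_file}:{lineno}: expected 9 tab-separated "
                    f"columns, got {len(fields)}")
            chrom, _, ftype, start_s, end_s, _, strand, _, attr_s = fields
            try:
                start1, end1 = int(start_s), int(end_s)
                attrs = _parse_attributes(attr_s)
            except ValueError as exc:
                raise AnnotationError(
                    f"{annotation_file}:{lineno}: {exc}") from exc
            start, end = start1 - 1, end1  # to 0-based half-open
            if start < 0 or start >= end:
                raise AnnotationError(
                    f"{annotation_file}:{lineno}: invalid interval "
                    f"{start1}..{end1}")
            if genome is not None:
                length = genome.lengths.get(chrom)
                if length is None:
                    raise AnnotationError(
                        f"{annotation_file}:{lineno}: unknown chromosome "
                        f"{chrom!r}")
                if end > length:
                    raise AnnotationError(
                        f"{annotation_file}:{lineno}: end {end1} beyond "
                        f"chromosome {chrom} length {length}")
            if ftype in CLASSES:
                tid = attrs.get("ID")
                if tid is None:
                    raise AnnotationError(
                        f"{annotation_file}:{lineno}: missing ID attribute")
                transcripts[tid] = {
                    "id": tid, "chrom": chrom, "strand": strand,
                    "start": start, "end": end, "class_label": ftype,
                    "gene_id": attrs.get("gene_id", tid),
                    "abundance": float(attrs.get("abundance", 0.0)),
                    "segments": [],
                }
                order.append(tid)
            elif ftype in _SEG_TYPES:
                parent = attrs.get("Parent")
                if parent is None or parent not in transcripts:
                    raise AnnotationError(
                        f"{annotation_file}:{lineno}: segment with missing or "
                        f"unknown Parent")
                transcripts[parent]["segments"].append(
                    Segment(_SEG_TYPES[ftype], start, end))
            else:
                raise AnnotationError(
                    f"{annotation_file}:{lineno}: unknown feature type "
                    f"{ftype!r}")
    if n_lines == 0:
        log.warning("annotation file %s is empty", annotation_file)
    out = []
    for tid in order:
        rec = transcripts[tid]
        segs = rec.pop("segments")
        t = Transcript(**rec)
        if segs:
            segs.sort(key=lambda s: s.start)
            if t.strand == "-":
                segs = segs[::-1]
            t = replace(t, segments=segs)
        out.append(t)
    return AnnotationSet(out, genome=genome)


def write_annotations(annotation_set: AnnotationSet, path) -> None:
    """Write the GFF3 dialect read by :func:`load_annotations`."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in annotation_set.transcripts:
            attrs = f"ID={t.id};gene_id={t.gene_id};abundance={t.abundance:g}"
            fh.write("\t".join([
                t.chrom, "clipmaps", t.class_label, str(t.start + 1),
                str(t.end), ".", t.strand, ".", attrs]) + "\n")
            for s in t.segments:
                fh.write("\t".join([
                    t.chrom, "clipmaps", _SEG_TYPES_INV[s.kind],
                    str(s.start + 1), str(s.end), ".", t.strand, ".",
                    f"Parent={t.id}"]) + "\n")


def load_isoform_abundances(path) -> pd.DataFrame:
    """TSV (gene_id, transcript_id, abundance) -> DataFrame."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "transcript_id": str})
    required = {"gene_id", "transcript_id", "abundance"}
    missing = required - set(df.columns)
    if missing:
        raise AnnotationError(f"abundance table missing columns {sorted(missing)}")
    return df
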