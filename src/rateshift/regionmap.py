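"""Alignment-block and annotation analysis around the locus.

Covers four comparative-genomics stages: calling genomic inversions from
strand-flipped runs in a chain of alignment blocks, tabulating which
reference features each species' homologous blocks cover, parsing
RepeatMasker annotation tables into grouped transposable-element (TE)
records, and scanning transcripts for open reading frames.

All genomic coordinates are 0-based half-open on the forward strand;
MAF's negative-strand source coordinates are converted on input.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.AlignIO.MafIO import MafWriter
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

REPEAT_CLASSES = ("SINE", "LINE", "DNA", "LTR", "Other")
#: RepeatMasker classes excluded when restricting to ancient mobile elements.
NON_TE_CLASSES = ("Simple_repeat", "Low_complexity")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class SpeciesAnchor:
    chrom: str
    start: int  # forward strand, 0-based half-open
    end: int
    strand: str  # '+' or '-'
    src_size: int
    text: str  # aligned sequence with gaps

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("anchor end must exceed start")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class AlignmentBlock:
    """One species-anchored aligned segment; the reference strand is '+'."""

    anchors: dict[str, SpeciesAnchor]
    reference: str

    def __post_init__(self) -> None:
        if self.reference not in self.anchors:
            raise ValueError(f"reference {self.reference!r} not among anchors")
        if self.anchors[self.reference].strand != "+":
            raise ValueError("reference anchor must be on the forward strand")

    @property
    def ref_anchor(self) -> SpeciesAnchor:
        return self.anchors[self.reference]


@dataclass(frozen=True)
class FeatureInterval:
    id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"feature {self.id}: end must exceed start")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TEAnnotation:
    """One repeat hit in one species."""

    name: str  # repeat name, e.g. MIR, L1MD3
    repeat_class: str  # collapsed: SINE/LINE/DNA/LTR/Other
    species: str
    chrom: str
    start: int
    end: int
    symbol: str | None = None  # A-K for the curated ancestral set
    raw_class: str = ""  # RepeatMasker class/family string as read

    def __post_init__(self) -> None:
        if self.repeat_class not in REPEAT_CLASSES:
            raise ValueError(f"unknown repeat class {self.repeat_class!r}")
        if self.end <= self.start:
            raise ValueError("TE end must exceed start")


@dataclass(frozen=True)
class TEGroup:
    """The same element observed across species (grouped by symbol/name+locus)."""

    key: str
    name: str
    repeat_class: str
    species: frozenset[str]
    members: tuple[TEAnnotation, ...]


@dataclass(frozen=True)
class ORFRecord:
    frame: int  # +1,+2,+3 sense; -1,-2,-3 antisense
    start: int  # forward-strand coordinates of the ORF span incl. stop
    end: int
    length_aa: int

    def __post_init__(self) -> None:
        if self.frame not in (1, 2, 3, -1, -2, -3):
            raise ValueError(f"bad frame {self.frame}")


# ---------------------------------------------------------------------------
# MAF I/O


def _collapse_class(raw: str) -> str:
    head = raw.split("/")[0]
    return head if head in ("SINE", "LINE", "DNA", "LTR") else "Other"


def read_maf(path: str | Path, reference: str | None = None) -> list[AlignmentBlock]:
    """Read MAF blocks; species labels are the part of ``src`` before '.'.

    Negative-strand source coordinates are converted to forward-strand
    0-based half-open intervals (start' = srcSize - start - size).  The
    first species of the first block is taken as the reference unless
    given explicitly.
    """
    blocks: list[AlignmentBlock] = []
    try:
        msas = list(AlignIO.parse(str(path), "maf"))
    except ValueError as exc:
        raise ValueError(f"malformed MAF file {path}: {exc}") from exc
    for msa in msas:
        anchors: dict[str, SpeciesAnchor] = {}
        for rec in msa:
            species, _, chrom = rec.id.partition(".")
            ann = rec.annotations
            start, size, src_size = ann["start"], ann["size"], ann["srcSize"]
            if ann["strand"] == 1:
                fstart, strand = start, "+"
            else:
                fstart, strand = src_size - start - size, "-"
            anchors[species] = SpeciesAnchor(
                chrom or species, fstart, fstart + size, strand, src_size, str(rec.seq)
            )
        if not anchors:
            continue
        ref = reference or next(iter(anchors))
        if reference is None:
            reference = ref
        blocks.append(AlignmentBlock(anchors, ref))
    return blocks


def write_maf(blocks: Sequence[AlignmentBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        writer = MafWriter(fh)
        writer.write_header()
        for b in blocks:
            recs = []
            for sp, a in b.anchors.items():
                rec = SeqRecord(Seq(a.text), id=f"{sp}.{a.chrom}", description="")
                if a.strand == "+":
                    start, strand = a.start, 1
                else:
                    start, strand = a.src_size - a.end, -1
                rec.annotations = {
                    "start": start,
                    "size": a.end - a.start,
                    "strand": strand,
                    "srcSize": a.src_size,
                }
                recs.append(rec)
            msa = MultipleSeqAlignment(recs)
            writer.write_alignment(msa)


# ---------------------------------------------------------------------------
# Inversions and feature coverage


def majority_strand(blocks: Sequence[AlignmentBlock], query: str) -> str:
    """Reference-length-weighted majority strand of a query's chained blocks."""
    weight = 0
    seen = False
    for b in blocks:
        a = b.anchors.get(query)
        if a is None:
            continue
        seen = True
        w = b.ref_anchor.end - b.ref_anchor.start
        weight += w if a.strand == "+" else -w
    if not seen:
        raise ValueError(f"query species {query!r} absent from all blocks")
    return "+" if weight >= 0 else "-"  # ties resolve to '+'


def detect_inversions(
    blocks: Sequence[AlignmentBlock],
    query: str,
    merge_dist: int = 1000,
) -> list[tuple[str, int, int]]:
    """Reference intervals where the query's strand opposes its majority.

    Consecutive minority-strand blocks are merged into one interval when
    their reference gap is at most ``merge_dist`` (alignment chains
    fragment single rearrangement events into adjacent blocks).
    """
    major = majority_strand(blocks, query)
    chain = sorted(
        (b for b in blocks if query in b.anchors),
        key=lambda b: (b.ref_anchor.chrom, b.ref_anchor.start),
    )
    flipped = [b for b in chain if b.anchors[query].strand != major]
    intervals: list[tuple[str, int, int]] = []
    for b in flipped:
        a = b.ref_anchor
        if (
            intervals
            and intervals[-1][0] == a.chrom
            and a.start - intervals[-1][2] <= merge_dist
        ):
            chrom, s, e = intervals[-1]
            intervals[-1] = (chrom, s, max(e, a.end))
        else:
            intervals.append((a.chrom, a.start, a.end))
    return intervals


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def feature_coverage(
    blocks: Sequence[AlignmentBlock],
    features: Sequence[FeatureInterval],
    species_list: Sequence[str],
    threshold: float = 0.5,
    merge_dist: int = 1000,
) -> pd.DataFrame:
    """Per (feature, species) coverage state from the block chain.

    ``state`` is ``covered`` when the aligned fraction of the feature is
    at least ``threshold``, ``partial`` when positive but below it, and
    ``absent`` otherwise; ``inverted`` flags features whose covering
    blocks are predominantly on the query's minority strand.
    """
    rows = []
    for sp in species_list:
        major = majority_strand(blocks, sp)
        for feat in features:
            total = flipped = 0
            for b in blocks:
                a = b.anchors.get(sp)
                ra = b.ref_anchor
                if a is None or ra.chrom != feat.chrom:
                    continue
                ov = _overlap(ra.start, ra.end, feat.start, feat.end)
                total += ov
                if a.strand != major:
                    flipped += ov
            frac = total / len(feat)
            state = "absent" if total == 0 else ("covered" if frac >= threshold else "partial")
            rows.append(
                {
                    "feature": feat.id,
                    "species": sp,
                    "state": state,
                    "fraction": frac,
                    "inverted": total > 0 and flipped * 2 > total,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# RepeatMasker tables and TE filtering


def read_repeatmasker_out(
    path: str | Path,
    species: str = "mouse",
    ancient_only: bool = False,
) -> list[TEAnnotation]:
    """Parse a RepeatMasker ``.out`` table (3 header lines, then records).

    Repeat classes are collapsed to SINE/LINE/DNA/LTR/Other; with
    ``ancient_only`` simple repeats and low-complexity records are
    dropped (they are not mobile elements).
    """
    annotations: list[TEAnnotation] = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines[3:], start=4):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) < 11:
            raise ValueError(f"{path}:{lineno}: malformed RepeatMasker record")
        try:
            qstart, qend = int(fields[5]), int(fields[6])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
        raw_class = fields[10]
        if ancient_only and raw_class.split("/")[0] in NON_TE_CLASSES:
            continue
        annotations.append(
            TEAnnotation(
                name=fields[9],
                repeat_class=_collapse_class(raw_class),
                species=species,
                chrom=fields[4],
                start=qstart - 1,  # .out coordinates are 1-based inclusive
                end=qend,
                raw_class=raw_class,
            )
        )
    return annotations


def shared_te_filter(
    annotations: Iterable[TEAnnotation],
    min_species: int = 2,
    required_species: str = "mouse",
) -> list[TEGroup]:
    """Group per-species TE records and keep widely shared elements.

    Records sharing a curated symbol (or, lacking one, the same repeat
    name at the same locus) form one group; groups are kept when they
    occur in at least ``min_species`` species including
    ``required_species``.
    """
    groups: dict[str, list[TEAnnotation]] = {}
    for ann in annotations:
        key = ann.symbol or f"{ann.name}@{ann.chrom}:{ann.start}-{ann.end}"
        groups.setdefault(key, []).append(ann)
    kept = []
    for key, members in groups.items():
        species = frozenset(m.species for m in members)
        if len(species) >= min_species and required_species in species:
            kept.append(
                TEGroup(
                    key=key,
                    name=members[0].name,
                    repeat_class=members[0].repeat_class,
                    species=species,
                    members=tuple(members),
                )
            )
    kept.sort(key=lambda g: g.key)
    return kept


def te_feature_overlap(
    tes: Iterable[TEAnnotation],
    features: Sequence[FeatureInterval],
) -> pd.DataFrame:
    """Which TEs intersect each feature (half-open intervals, >= 1 bp).

    Returns one row per feature with the comma-joined labels of the
    overlapping elements (curated symbol when present, else name).
    """
    tes = list(tes)
    rows = []
    for feat in features:
        hits = [
            te
            for te in tes
            if te.chrom == feat.chrom and _overlap(te.start, te.end, feat.start, feat.end) > 0
        ]
        hits.sort(key=lambda t: (t.start, t.symbol or t.name))
        rows.append(
            {
                "feature": feat.id,
                "n_te": len(hits),
                "elements": ", ".join(t.symbol or t.name for t in hits),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ORF scanning


@dataclass
class ORFScan:
    orfs: list[ORFRecord]
    upstream_atg_count: int  # sense-strand AUGs preceding the longest ORF

    @property
    def longest(self) -> ORFRecord | None:
        return self.orfs[0] if self.orfs else None


def _scan_strand(seq: str, sense: bool, min_aa: int) -> list[ORFRecord]:
    n = len(seq)
    work = seq if sense else str(Seq(seq).reverse_complement())
    orfs = []
    for offset in range(3):
        i = offset
        while i + 3 <= n:
            if work[i : i + 3] == "ATG":
                # walk to the first in-frame stop
                j = i + 3
                while j + 3 <= n:
                    if work[j : j + 3] in STOP_CODONS:
                        aa = (j + 3 - i) // 3 - 1
                        if aa >= min_aa:
                            if sense:
                                start, end, frame = i, j + 3, offset + 1
                            else:
                                start, end, frame = n - (j + 3), n - i, -(offset + 1)
                            orfs.append(ORFRecord(frame, start, end, aa))
                        break
                    j += 3
            i += 3
    return orfs


def find_orfs(
    transcript: str,
    min_aa: int = 30,
    frames: Literal["sense", "six"] = "sense",
) -> ORFScan:
    """All AUG-initiated, stop-terminated ORFs of at least ``min_aa`` aa.

    ORFs are returned sorted by amino-acid length, longest first (ties
    by position).  ``upstream_atg_count`` counts sense-strand ATG codons
    strictly upstream of the longest ORF's start — a standard argument
    against coding capacity, since upstream AUGs suppress translation of
    the long frame.
    """
    seq = transcript.upper()
    if set(seq) - set("ACGT"):
        bad = sorted(set(seq) - set("ACGT"))
        raise ValueError(f"non-DNA characters in transcript: {bad}")
    orfs = _scan_strand(seq, True, min_aa)
    if frames == "six":
        orfs += _scan_strand(seq, False, min_aa)
    elif frames != "sense":
        raise ValueError("frames must be 'sense' or 'six'")
    orfs.sort(key=lambda o: (-o.length_aa, o.start, o.frame))
    upstream = 0
    if orfs:
        head = orfs[0].start
        upstream = sum(1 for i in range(head) if seq[i : i + 3] == "ATG")
    return ORFScan(orfs=orfs, upstream_atg_count=upstream)
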