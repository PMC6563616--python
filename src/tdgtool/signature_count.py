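"""Classify aligned DREAM reads into digestion signatures and count per site.

A read is evidence for a site's methylation state only if its 5'-most
aligned base lands exactly on one of the site's four anchors and its first
bases, in read orientation, literally equal the anchor's expected prefix
(GGG for the SmaI blunt end at unmethylated sites, CCGGG for the filled-in
XmaI end at methylated sites).  Matching is exact: a single mismatch can
flip the GGG/CCGGG identity, so no mismatch allowance is given, and any
5'-clipping destroys the signature evidence and unassigns the read.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pysam

from .site_index import SiteIndex

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# unassignment reason codes
R_OK = "ok"
R_NO_ANCHOR = "no_anchor"
R_PREFIX_MISMATCH = "prefix_mismatch"
R_CLIPPED = "clipped_5prime"
R_UNKNOWN_CONTIG = "unknown_contig"


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignedRead:
    """Minimal alignment record (sequence stored in forward-genome orientation)."""

    contig: str
    start: int  # 0-based leftmost aligned reference position
    strand: str  # '+' or '-'
    seq: str
    mapq: int
    clipped5: int = 0  # clip length at the *read's* 5' end
    aligned_length: int | None = None  # reference span; defaults to len(seq)

    @property
    def fiveprime_pos(self) -> int:
        length = self.aligned_length if self.aligned_length is not None else len(self.seq)
        return self.start if self.strand == "+" else self.start + length - 1


@dataclass(frozen=True)
class Classification:
    site_id: str | None
    meth_state: str | None
    reason: str

    @property
    def assigned(self) -> bool:
        return self.reason == R_OK


@dataclass
class SiteCounts:
    site_id: str
    n_meth: int = 0
    n_unmeth: int = 0

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth


@dataclass
class SampleCounts:
    """Per-site signature counts for one sample, with reconciliation totals.

    Invariant: n_classified + n_unassigned + n_lowmapq == n_examined, where
    examined reads are primary, mapped, non-duplicate alignments.
    """

    sample_id: str
    index_genome_id: str
    counts: dict[str, SiteCounts]
    n_unassigned: int = 0
    n_lowmapq: int = 0
    n_examined: int = 0
    unassigned_reasons: Counter = field(default_factory=Counter)
    merged_from: list[str] = field(default_factory=list)

    @property
    def n_classified(self) -> int:
        return sum(c.coverage for c in self.counts.values())

    def reconciles(self) -> bool:
        return self.n_classified + self.n_unassigned + self.n_lowmapq == self.n_examined

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("site_id\tn_meth\tn_unmeth\n")
            for sid in sorted(self.counts):
                c = self.counts[sid]
                fh.write(f"{sid}\t{c.n_meth}\t{c.n_unmeth}\n")

    def qc_to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            fh.write(f"sample_id\t{self.sample_id}\n")
            fh.write(f"n_examined\t{self.n_examined}\n")
            fh.write(f"n_classified\t{self.n_classified}\n")
            fh.write(f"n_unassigned\t{self.n_unassigned}\n")
            fh.write(f"n_lowmapq\t{self.n_lowmapq}\n")
            for reason, n in sorted(self.unassigned_reasons.items()):
                fh.write(f"unassigned_{reason}\t{n}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, sample_id: str | None = None,
                 index_genome_id: str = "") -> "SampleCounts":
        counts: dict[str, SiteCounts] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("site_id"):
                raise ValueError(f"{path}: expected 'site_id\\tn_meth\\tn_unmeth' header")
            for line in fh:
                sid, nm, nu = line.rstrip("\n").split("\t")
                counts[sid] = SiteCounts(sid, int(nm), int(nu))
        sid_ = sample_id or Path(path).stem
        sc = cls(sample_id=sid_, index_genome_id=index_genome_id, counts=counts)
        sc.n_examined = sc.n_classified
        return sc


def classify_read(read: AlignedRead, index: SiteIndex) -> Classification:
    """Assign a read to (site, methylation state) or explain why not.

    Assignment requires: contig known to the index; zero 5'-clipping; the
    read's 5' end on an anchor; and an exact prefix match in read
    orientation (for minus-strand reads the stored forward-orientation
    sequence is reverse-complemented before comparison).
    """
    if read.contig not in index.contig_lengths:
        return Classification(None, None, R_UNKNOWN_CONTIG)
    anchor = index.anchors.get((read.contig, read.fiveprime_pos, read.strand))
    if anchor is None:
        return Classification(None, None, R_NO_ANCHOR)
    if read.clipped5 != 0:
        return Classification(None, None, R_CLIPPED)
    k = len(anchor.expected_prefix)
    if read.strand == "+":
        prefix = read.seq[:k].upper()
    else:
        prefix = revcomp(read.seq[-k:]) if len(read.seq) >= k else ""
    if prefix != anchor.expected_prefix:
        return Classification(None, None, R_PREFIX_MISMATCH)
    return Classification(anchor.site_id, anchor.meth_state, R_OK)


def _from_pysam(aln: pysam.AlignedSegment) -> AlignedRead:
    cigar = aln.cigartuples or []
    # CIGAR ops 4 (S) and 5 (H) clip read ends; the read's 5' end is the
    # left end of the CIGAR for forward reads, the right end for reverse.
    left = cigar[0][1] if cigar and cigar[0][0] in (4, 5) else 0
    right = cigar[-1][1] if cigar and cigar[-1][0] in (4, 5) else 0
    return AlignedRead(
        contig=aln.reference_name,
        start=aln.reference_start,
        strand="-" if aln.is_reverse else "+",
        seq=(aln.query_sequence or "").upper(),
        mapq=aln.mapping_quality,
        clipped5=right if aln.is_reverse else left,
        aligned_length=aln.reference_length,
    )


def count_signatures(
    alignments: str | Path | pysam.AlignmentFile,
    index: SiteIndex,
    mapq_min: int = 20,
    sample_id: str | None = None,
) -> SampleCounts:
    """Count methylated/unmethylated signatures per site over a SAM/BAM file.

    Only primary, mapped, non-duplicate alignments are examined; those below
    ``mapq_min`` (the operational proxy for unique mapping) are tallied as
    low-mapq.  Header contigs absent from the index raise a hard error.
    """
    own = not isinstance(alignments, pysam.AlignmentFile)
    af = (
        pysam.AlignmentFile(str(alignments), check_sq=False)
        if own
        else alignments
    )
    try:
        header_contigs = list(af.references or [])
        unknown = [c for c in header_contigs if c not in index.contig_lengths]
        if unknown:
            raise ValueError(
                "alignment header contigs absent from the site index: "
                + ", ".join(unknown)
            )
        sc = SampleCounts(
            sample_id=sample_id or Path(str(getattr(af, "filename", b"sample"),
                                             "utf-8", "ignore")).stem or "sample",
            index_genome_id=index.genome_id,
            counts={s.site_id: SiteCounts(s.site_id) for s in index.sites},
        )
        for aln in af.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary or aln.is_duplicate:
                continue
            sc.n_examined += 1
            if aln.mapping_quality < mapq_min:
                sc.n_lowmapq += 1
                continue
            cls = classify_read(_from_pysam(aln), index)
            if cls.assigned:
                c = sc.counts[cls.site_id]
                if cls.meth_state == "methylated":
                    c.n_meth += 1
                else:
                    c.n_unmeth += 1
            else:
                sc.n_unassigned += 1
                sc.unassigned_reasons[cls.reason] += 1
        return sc
    finally:
        if own:
            af.close()


def merge_replicates(samples: list[SampleCounts], mode: str = "pool") -> SampleCounts:
    """Pool replicate counts site-wise (the only supported mode)."""
    if mode != "pool":
        raise ValueError(f"unsupported merge mode {mode!r}")
    if not samples:
        raise ValueError("cannot merge an empty list of samples")
    gids = {s.index_genome_id for s in samples}
    if len(gids) > 1:
        raise ValueError(f"samples counted against different genomes: {sorted(gids)}")
    merged = SampleCounts(
        sample_id="+".join(s.sample_id for s in samples),
        index_genome_id=samples[0].index_genome_id,
        counts={},
        merged_from=[s.sample_id for s in samples],
    )
    for s in samples:
        merged.n_unassigned += s.n_unassigned
        merged.n_lowmapq += s.n_lowmapq
        merged.n_examined += s.n_examined
        merged.unassigned_reasons.update(s.unassigned_reasons)
        for sid, c in s.counts.items():
            m = merged.counts.setdefault(sid, SiteCounts(sid))
            m.n_meth += c.n_meth
            m.n_unmeth += c.n_unmeth
    return merged
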