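"""Restriction-site indexing for DREAM methylome sequencing.

DREAM (Digital Restriction Enzyme Analysis of Methylation) digests genomic
DNA sequentially with the isoschizomers SmaI and XmaI, which both recognize
the palindromic hexamer CCCGGG.  SmaI cuts blunt (CCC^GGG) but only at
unmethylated sites; XmaI cuts C^CCGGG regardless of CpG methylation, leaving
a 4-nt 5' overhang that is filled in before adapter ligation.  The result is
that sequenced fragment ends carry a methylation-state *signature*: reads
from unmethylated sites start with 5'-GGG, reads from methylated sites start
with 5'-CCGGG.

This module enumerates CCCGGG recognition sites in a reference genome and
derives, for each site, the four (strand, 5'-end coordinate, expected
prefix) anchors at which an aligned read unambiguously reports the site's
methylation state.  All coordinates are 0-based; a site's ``pos`` is the
first C of the hexamer on the forward strand.  The motif is palindromic, so
one entry per forward-strand match covers both strands.
"""

from __future__ import annotations

import gzip
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

MOTIF = "CCCGGG"
UNMETH_PREFIX = "GGG"
METH_PREFIX = "CCGGG"

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class ReferenceSite:
    """A CCCGGG recognition site on the forward strand of a contig."""

    contig: str
    pos: int  # 0-based coordinate of the first C of the hexamer
    neighbor_distance: int | None = None  # bp to nearest other site, same contig
    short_fragment: bool = False  # neighbor closer than min_fragment

    @property
    def site_id(self) -> str:
        return f"{self.contig}:{self.pos}"


@dataclass(frozen=True)
class SignatureAnchor:
    """One of the four read anchors of a recognition site.

    A read reports a site's methylation state iff its mapped 5'-most base
    sits exactly at ``fiveprime_pos`` on ``strand`` and its first bases in
    read orientation equal ``expected_prefix``.

    Geometry, worked from the cut chemistry: SmaI's blunt cut CCC^GGG puts
    the downstream (+) fragment end at pos+3 reading GGG, and the upstream
    fragment's bottom-strand 5' end at pos+2, also reading GGG.  XmaI's
    C^CCGGG cut leaves CCGG 5' overhangs; after fill-in the (+) fragment
    starts at pos+1 reading CCGGG and the (-) fragment's 5' end sits at
    pos+4, likewise reading CCGGG.
    """

    site_id: str
    strand: str  # '+' or '-'
    fiveprime_pos: int
    expected_prefix: str  # "GGG" or "CCGGG"
    meth_state: str  # "methylated" or "unmethylated"


@dataclass
class SiteIndex:
    """Index of all recognition sites of a genome plus their anchors.

    ``anchors`` maps (contig, fiveprime_pos, strand) to a SignatureAnchor;
    the mapping is injective by construction (colliding keys, only possible
    for sites < 6 bp apart which the motif geometry forbids, are dropped
    and recorded in ``collisions``).
    """

    genome_id: str
    sites: list[ReferenceSite]
    anchors: dict[tuple[str, int, str], SignatureAnchor]
    contig_lengths: dict[str, int]
    collisions: list[tuple[str, int, str]] = field(default_factory=list)

    @property
    def contigs(self) -> list[str]:
        return list(self.contig_lengths)

    def sites_on(self, contig: str) -> list[ReferenceSite]:
        return [s for s in self.sites if s.contig == contig]

    def to_bed(self, path: str | Path) -> None:
        """Write sites as BED6 (name = site_id, score = 0, strand = '+')."""
        with open(path, "w") as fh:
            for s in self.sites:
                fh.write(f"{s.contig}\t{s.pos}\t{s.pos + 6}\t{s.site_id}\t0\t+\n")

    def anchors_to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("contig\tfiveprime_pos\tstrand\tsite_id\texpected_prefix\tmeth_state\n")
            for (contig, fp, strand), a in sorted(self.anchors.items()):
                fh.write(
                    f"{contig}\t{fp}\t{strand}\t{a.site_id}\t{a.expected_prefix}\t{a.meth_state}\n"
                )


def find_sites(sequence: str, contig: str, min_fragment: int = 40) -> list[ReferenceSite]:
    """Enumerate CCCGGG sites in ``sequence`` (case-insensitive).

    N never matches (an ambiguous base cannot confirm a recognition site).
    Characters outside {A,C,G,T,N} raise ValueError.  Sites whose nearest
    neighbour on the contig is closer than ``min_fragment`` bp are flagged
    ``short_fragment`` (counted normally, surfaced in QC).
    """
    seq = sequence.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(
            f"contig {contig!r} contains non-IUPAC characters {sorted(bad)!r} "
            "(only A/C/G/T/N are accepted)"
        )
    positions: list[int] = []
    start = 0
    while True:
        hit = seq.find(MOTIF, start)
        if hit == -1:
            break
        positions.append(hit)
        start = hit + 1  # allow any shift; CCCGGG cannot overlap itself anyway
    sites = []
    for i, pos in enumerate(positions):
        dist: int | None = None
        if len(positions) > 1:
            cand = []
            if i > 0:
                cand.append(pos - positions[i - 1])
            if i < len(positions) - 1:
                cand.append(positions[i + 1] - pos)
            dist = min(cand)
        sites.append(
            ReferenceSite(
                contig=contig,
                pos=pos,
                neighbor_distance=dist,
                short_fragment=dist is not None and dist < min_fragment,
            )
        )
    return sites


def anchors_for_site(site: ReferenceSite) -> list[SignatureAnchor]:
    """The four signature anchors of a site, per the digestion geometry."""
    p = site.pos
    sid = site.site_id
    return [
        SignatureAnchor(sid, "+", p + 3, UNMETH_PREFIX, "unmethylated"),
        SignatureAnchor(sid, "-", p + 2, UNMETH_PREFIX, "unmethylated"),
        SignatureAnchor(sid, "+", p + 1, METH_PREFIX, "methylated"),
        SignatureAnchor(sid, "-", p + 4, METH_PREFIX, "methylated"),
    ]


def _read_fasta(path: str | Path) -> dict[str, str]:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    contigs: dict[str, str] = {}
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in contigs:
                raise ValueError(f"duplicate contig name in FASTA: {rec.id!r}")
            contigs[rec.id] = str(rec.seq)
    return contigs


def genome_digest(contigs: Mapping[str, str]) -> str:
    """Stable content hash identifying a genome (order- and case-normalised)."""
    h = hashlib.sha256()
    for name in sorted(contigs):
        h.update(name.encode())
        h.update(b"\0")
        h.update(contigs[name].upper().encode())
        h.update(b"\0")
    return h.hexdigest()[:16]


def build_index(
    genome: str | Path | Mapping[str, str], min_fragment: int = 40
) -> SiteIndex:
    """Scan a genome (FASTA path or contig→sequence mapping) into a SiteIndex.

    Raises on an empty genome or duplicate contig names.  Anchor collisions
    between adjacent sites are excluded from the mapping and recorded —
    geometrically impossible for this motif, guarded defensively.
    """
    contigs = genome if isinstance(genome, Mapping) else _read_fasta(genome)
    if not contigs:
        raise ValueError("empty genome: no contigs found")
    all_sites: list[ReferenceSite] = []
    anchors: dict[tuple[str, int, str], SignatureAnchor] = {}
    collisions: list[tuple[str, int, str]] = []
    for contig, seq in contigs.items():
        sites = find_sites(seq, contig, min_fragment=min_fragment)
        all_sites.extend(sites)
        for site in sites:
            for a in anchors_for_site(site):
                key = (contig, a.fiveprime_pos, a.strand)
                if key in anchors:
                    collisions.append(key)
                    del anchors[key]
                elif key not in collisions:
                    anchors[key] = a
    return SiteIndex(
        genome_id=genome_digest(contigs),
        sites=all_sites,
        anchors=anchors,
        contig_lengths={c: len(s) for c, s in contigs.items()},
        collisions=collisions,
    )
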