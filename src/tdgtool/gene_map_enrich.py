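"""Assign differential sites to adjacent genes; gene-set enrichment.

"Adjacent" is operationalised as: distance 0 if the site falls inside a
gene's span, otherwise distance from the site position to the gene's TSS,
with a configurable cap (default 10 kb).  Enrichment is a background-
corrected one-sided hypergeometric test per user-supplied gene set (GMT),
where the universe is the background gene list (genes with at least one
covered site) and every set is intersected with it first.  No pathway
database is bundled: term-level results depend entirely on the GMT given.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from scipy.stats import hypergeom

from .diff_meth import bh_adjust
from .site_index import ReferenceSite


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    contig: str
    strand: str
    start: int  # span, 0-based half-open
    end: int

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class SiteGeneAssignment:
    site_id: str
    gene_id: str
    distance: int  # 0 if the site overlaps the gene span


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    k: int  # foreground genes in set
    K: int  # background genes in set
    n: int  # foreground size
    N: int  # background size
    p_value: float
    q_value: float


def load_genes(annotation: str | Path) -> list[GeneModel]:
    """Load gene models from BED6 (.bed) or GFF3 (.gff/.gff3).

    For GFF3 only ``gene``-type records are used (an annotation without any
    is rejected); the gene id is taken from ID, gene_id or Name attributes.
    """
    path = Path(annotation)
    genes: list[GeneModel] = []
    if path.suffix.lower() == ".bed":
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 6:
                    raise ValueError(f"{path}:{ln}: BED6 requires 6 columns")
                contig, start, end, name, _score, strand = fields[:6]
                if strand not in "+-":
                    raise ValueError(f"{path}:{ln}: unknown strand {strand!r} for {name!r}")
                genes.append(GeneModel(name, contig, strand, int(start), int(end)))
    elif path.suffix.lower() in (".gff", ".gff3"):
        from gffutils.iterators import DataIterator

        for feat in DataIterator(str(path)):
            if feat.featuretype != "gene":
                continue
            gid = (feat.attributes.get("ID") or feat.attributes.get("gene_id")
                   or feat.attributes.get("Name"))
            if not gid:
                raise ValueError(f"{path}: gene record without ID/gene_id/Name")
            if feat.strand not in "+-":
                raise ValueError(f"{path}: unknown strand {feat.strand!r} for {gid[0]!r}")
            # GFF3 is 1-based closed; convert to 0-based half-open
            genes.append(GeneModel(gid[0], feat.seqid, feat.strand, feat.start - 1, feat.end))
        if not genes:
            raise ValueError(f"{path}: no 'gene' features found in GFF3")
    else:
        raise ValueError(f"unrecognised annotation format: {path.suffix!r}")
    return genes


def nearest_gene(
    site: ReferenceSite | tuple[str, int],
    genes: Sequence[GeneModel],
    max_dist: int = 10_000,
) -> SiteGeneAssignment | None:
    """Closest gene by TSS distance (0 if inside the span); None beyond max_dist.

    Ties break to the lexicographically smallest gene_id for determinism.
    """
    if isinstance(site, tuple):
        contig, pos = site
        site_id = f"{contig}:{pos}"
    else:
        contig, pos, site_id = site.contig, site.pos, site.site_id
    best: tuple[int, str] | None = None
    for g in genes:
        if g.contig != contig:
            continue
        if g.start <= pos < g.end:
            d = 0
        else:
            d = abs(pos - g.tss)
        if best is None or (d, g.gene_id) < best:
            best = (d, g.gene_id)
    if best is None or best[0] > max_dist:
        return None
    return SiteGeneAssignment(site_id, best[1], best[0])


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: one set per line, 'name <tab> description <tab> gene1 <tab> ...'."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


def hypergeom_enrich(
    foreground_genes: Iterable[str],
    background_genes: Iterable[str],
    gene_sets: str | Path | Mapping[str, set[str]],
) -> list[EnrichmentResult]:
    """One-sided hypergeometric enrichment of foreground within background.

    Background correction: the universe is the background gene list and each
    set is intersected with it before testing; sets that vanish under the
    intersection are skipped.  BH adjustment across the tested sets.
    """
    fg = set(foreground_genes)
    bg = set(background_genes)
    if not fg or not bg:
        raise ValueError("foreground and background must be non-empty")
    if not fg <= bg:
        raise ValueError("foreground must be a subset of the background universe")
    sets = read_gmt(gene_sets) if not isinstance(gene_sets, Mapping) else gene_sets
    N, n = len(bg), len(fg)
    tested: list[tuple[str, int, int, float]] = []
    for name, members in sets.items():
        in_bg = members & bg
        K = len(in_bg)
        if K == 0:
            continue  # disjoint from the universe; reported by omission
        k = len(in_bg & fg)
        p = float(hypergeom.sf(k - 1, N, K, n))
        tested.append((name, k, K, min(p, 1.0)))
    if not tested:
        return []
    qs = bh_adjust([t[3] for t in tested])
    results = [
        EnrichmentResult(name, k, K, n, N, p, q)
        for (name, k, K, p), q in zip(tested, qs)
    ]
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results
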