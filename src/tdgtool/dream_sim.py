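"""Synthetic DREAM experiment generator with ground truth.

Emulates the inputs of a restriction-signature methylome experiment:

* a random genome with CCCGGG sites planted at jittered regular spacing
  (incidental motif occurrences are allowed and picked up by the scan — the
  truth table is keyed to the post-scan site index, not the planting list);
* per-site methylation levels drawn from a Beta baseline (condition A),
  with a knockdown-like condition B in which a chosen fraction of sites
  gains a fixed methylation delta (clipped to [0, 1]) — modelling the
  hypermethylation gain expected when active DNA demethylation is lost;
* spike-in contigs of fixed, known methylation for calibration QC;
* digestion-anchored reads: per site and replicate a Poisson number of
  classifiable reads, each methylated with probability equal to the site's
  true level, placed at a methylated or unmethylated anchor (strand chosen
  fairly), sequence copied from the reference with i.i.d. substitution
  errors, emitted as coordinate-sorted SAM.

Everything derives from one seed; identical configs give identical bundles.
The generator emits pre-aligned SAM because alignment is upstream of the
bespoke computation; fragment-end pairing, PCR duplicates, GC bias and
size selection are deliberately not modelled.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pysam

from .meth_call import SpikeInStandard
from .site_index import MOTIF, ReferenceSite, SiteIndex, anchors_for_site, build_index

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimConfig:
    """All generation parameters; ``seed`` is mandatory.

    Defaults describe a small but realistic two-condition experiment:
    beta(2, 2) baseline methylome, 5% of sites gaining +0.3 methylation in
    condition B, ~100 classified reads per site and replicate, biological
    duplicates, 50-bp reads with a 0.1% per-base substitution error.
    """

    seed: int
    n_contigs: int = 2
    contig_length: int = 50_000
    target_sites_per_contig: int = 40
    spikein_levels: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    spikein_length: int = 3_000
    spikein_sites: int = 6
    beta_a: float = 2.0
    beta_b: float = 2.0
    effect_fraction: float = 0.05
    effect_delta: float = 0.3
    coverage_mean: float = 100.0
    read_length: int = 50
    error_rate: float = 0.001
    n_replicates: int = 2

    def __post_init__(self) -> None:
        for name in ("effect_fraction", "error_rate", "beta_a", "beta_b"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.effect_fraction <= 1:
            raise ValueError("effect_fraction must be in [0, 1]")
        for lv in self.spikein_levels:
            if not 0 <= lv <= 1:
                raise ValueError("spike-in levels must be in [0, 1]")
        if min(self.contig_length, self.spikein_length, self.read_length) <= 0:
            raise ValueError("lengths must be positive")
        if self.read_length < 5:
            raise ValueError("read_length must cover the 5-base CCGGG signature")


@dataclass
class TruthTable:
    """Ground truth per indexed site plus per-replicate drawn counts."""

    site_ids: list[str]
    true_level_a: dict[str, float]
    true_level_b: dict[str, float]
    affected: dict[str, bool]
    # (condition, replicate) -> site_id -> (n_meth, n_unmeth)
    counts: dict[tuple[str, int], dict[str, tuple[int, int]]] = field(default_factory=dict)

    def level(self, site_id: str, condition: str) -> float:
        return (self.true_level_a if condition == "A" else self.true_level_b)[site_id]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("site_id\ttrue_level_A\ttrue_level_B\taffected\n")
            for sid in self.site_ids:
                fh.write(
                    f"{sid}\t{self.true_level_a[sid]:.6g}\t{self.true_level_b[sid]:.6g}"
                    f"\t{int(self.affected[sid])}\n"
                )


@dataclass
class SimBundle:
    """Paths of everything a full pipeline run needs, plus in-memory truth."""

    config: SimConfig
    fasta: Path
    sams: dict[tuple[str, int], Path]
    spikein_tsv: Path
    truth_tsv: Path
    config_json: Path
    index: SiteIndex
    truth: TruthTable
    standards: list[SpikeInStandard]


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _plant_sites(
    seq: np.ndarray, n_sites: int, read_length: int, rng: np.random.Generator
) -> list[int]:
    """Overwrite hexamers at jittered regular spacing >= 2*read_length apart."""
    length = len(seq)
    margin = read_length
    usable = length - 2 * margin - 6
    if n_sites < 1:
        return []
    step = usable / n_sites
    min_gap = 2 * read_length
    if step < min_gap + 6:
        raise ValueError(
            f"infeasible spacing: {n_sites} sites need "
            f"{(min_gap + 6) * n_sites + 2 * margin} bp, contig has {length}"
        )
    jitter_max = max(1, int(min((step - min_gap - 6) / 2, step / 8)))
    positions = []
    for j in range(n_sites):
        base = margin + int(j * step + step / 2)
        pos = base + int(rng.integers(-jitter_max, jitter_max + 1))
        positions.append(pos)
    motif = np.frombuffer(MOTIF.encode(), dtype="S1")
    for pos in positions:
        seq[pos : pos + 6] = motif
    return positions


def spike_contig_name(level: float) -> str:
    return f"SPIKE_{level:g}"


def simulate_genome(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], dict[str, list[int]]]:
    """Random genome with planted sites; spike-in contigs appended.

    Returns (contig -> sequence, contig -> planted positions).  Incidental
    CCCGGG occurrences may add sites beyond the planted list; downstream
    truth is keyed to the scanned index so this is harmless.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    contigs: dict[str, str] = {}
    planted: dict[str, list[int]] = {}
    for i in range(config.n_contigs):
        name = f"chrSim{i + 1}"
        seq = _random_sequence(rng, config.contig_length)
        planted[name] = _plant_sites(
            seq, config.target_sites_per_contig, config.read_length, rng
        )
        contigs[name] = seq.tobytes().decode()
    for level in config.spikein_levels:
        name = spike_contig_name(level)
        seq = _random_sequence(rng, config.spikein_length)
        planted[name] = _plant_sites(seq, config.spikein_sites, config.read_length, rng)
        contigs[name] = seq.tobytes().decode()
    return contigs, planted


def simulate_methylome(
    index: SiteIndex, config: SimConfig, rng: np.random.Generator
) -> TruthTable:
    """Draw true per-site levels for both conditions, keyed to the index.

    Biological sites: A ~ Beta(beta_a, beta_b); B copies A, then an exact
    round(effect_fraction * n) subset gains effect_delta, clipped to [0,1].
    Spike-in sites carry their contig's fixed known level in both
    conditions.  ``affected`` is true iff the clipped levels actually differ.
    """
    spike_levels = {spike_contig_name(lv): lv for lv in config.spikein_levels}
    bio_sites = [s for s in index.sites if s.contig not in spike_levels]
    level_a: dict[str, float] = {}
    level_b: dict[str, float] = {}
    for s in bio_sites:
        level_a[s.site_id] = float(rng.beta(config.beta_a, config.beta_b))
        level_b[s.site_id] = level_a[s.site_id]
    n_affected = int(round(config.effect_fraction * len(bio_sites)))
    if n_affected > 0:
        chosen = rng.choice(len(bio_sites), size=n_affected, replace=False)
        for idx in chosen:
            sid = bio_sites[idx].site_id
            level_b[sid] = min(1.0, max(0.0, level_a[sid] + config.effect_delta))
    for s in index.sites:
        if s.contig in spike_levels:
            level_a[s.site_id] = spike_levels[s.contig]
            level_b[s.site_id] = spike_levels[s.contig]
    site_ids = [s.site_id for s in index.sites]
    affected = {sid: level_a[sid] != level_b[sid] for sid in site_ids}
    return TruthTable(site_ids, level_a, level_b, affected)


def draw_truth_counts(
    truth: TruthTable,
    config: SimConfig,
    condition: str,
    rng: np.random.Generator,
) -> dict[str, tuple[int, int]]:
    """Per-site (n_meth, n_unmeth): n ~ Poisson(coverage_mean), binomial split."""
    counts: dict[str, tuple[int, int]] = {}
    for sid in truth.site_ids:
        n = int(rng.poisson(config.coverage_mean))
        n_meth = int(rng.binomial(n, truth.level(sid, condition))) if n else 0
        counts[sid] = (n_meth, n - n_meth)
    return counts


def _emit_site_reads(
    site: ReferenceSite,
    seq: str,
    n_meth: int,
    n_unmeth: int,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[tuple[int, str, str]]:
    """Reads for one site as (start, strand, forward-orientation sequence)."""
    anchors = anchors_for_site(site)
    meth_anchors = [a for a in anchors if a.meth_state == "methylated"]
    unmeth_anchors = [a for a in anchors if a.meth_state == "unmethylated"]
    out: list[tuple[int, str, str]] = []
    rl, length = config.read_length, len(seq)
    for group, n in ((meth_anchors, n_meth), (unmeth_anchors, n_unmeth)):
        if n == 0:
            continue
        picks = rng.integers(0, 2, size=n)
        for pick in picks:
            a = group[pick]
            f = a.fiveprime_pos
            if a.strand == "+":
                start, stop = f, min(f + rl, length)
            else:
                start, stop = max(0, f - rl + 1), f + 1
            read = seq[start:stop]
            if config.error_rate > 0:
                arr = np.frombuffer(read.encode(), dtype="S1").copy()
                hits = np.nonzero(rng.random(len(arr)) < config.error_rate)[0]
                for h in hits:
                    orig = arr[h]
                    choices = _BASES[_BASES != orig]
                    arr[h] = choices[rng.integers(0, len(choices))]
                read = arr.tobytes().decode()
            out.append((start, a.strand, read))
    return out


def simulate_reads(
    contigs: Mapping[str, str],
    index: SiteIndex,
    truth_counts: Mapping[str, tuple[int, int]],
    config: SimConfig,
    rng: np.random.Generator,
    path: str | Path,
    sample_id: str = "sim",
) -> None:
    """Write one replicate's reads as coordinate-sorted SAM (mapq 60)."""
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": index.contig_lengths[c]} for c in index.contigs],
            "RG": [{"ID": sample_id, "SM": sample_id}],
        }
    )
    contig_order = {c: i for i, c in enumerate(index.contigs)}
    records: list[tuple[int, int, str, int, str, str]] = []
    serial = 0
    for site in index.sites:
        n_meth, n_unmeth = truth_counts.get(site.site_id, (0, 0))
        for start, strand, read in _emit_site_reads(
            site, contigs[site.contig], n_meth, n_unmeth, config, rng
        ):
            records.append(
                (contig_order[site.contig], start, site.contig, serial, strand, read)
            )
            serial += 1
    records.sort(key=lambda r: (r[0], r[1], r[3]))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for _, start, contig, serial_, strand, read in records:
            a = pysam.AlignedSegment(header)
            a.query_name = f"{sample_id}.{serial_}"
            a.query_sequence = read
            a.flag = 16 if strand == "-" else 0
            a.reference_id = contig_order[contig]
            a.reference_start = start
            a.mapping_quality = 60
            a.cigartuples = [(0, len(read))]
            a.set_tag("RG", sample_id)
            out.write(a)


def simulate_experiment(config: SimConfig, outdir: str | Path) -> SimBundle:
    """Generate the full bundle: FASTA, per-replicate SAMs, truth, spike spec.

    Deterministic under ``config.seed``: genome, methylome and each
    (condition, replicate) read draw get independent child generators
    spawned from one seed sequence.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(config.seed)
    n_streams = 2 + 2 * config.n_replicates
    children = master.spawn(n_streams)
    genome_rng = np.random.default_rng(children[0])
    meth_rng = np.random.default_rng(children[1])

    contigs, _planted = simulate_genome(config, genome_rng)
    fasta = outdir / "genome.fa"
    with open(fasta, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")

    index = build_index(contigs)
    truth = simulate_methylome(index, config, meth_rng)

    sams: dict[tuple[str, int], Path] = {}
    stream = 2
    for condition in ("A", "B"):
        for rep in range(1, config.n_replicates + 1):
            rng = np.random.default_rng(children[stream])
            stream += 1
            counts = draw_truth_counts(truth, config, condition, rng)
            truth.counts[(condition, rep)] = counts
            sam = outdir / f"{condition}_rep{rep}.sam"
            simulate_reads(
                contigs, index, counts, config, rng, sam,
                sample_id=f"{condition}_rep{rep}",
            )
            sams[(condition, rep)] = sam

    standards = [
        SpikeInStandard(spike_contig_name(lv), lv) for lv in config.spikein_levels
    ]
    spikein_tsv = outdir / "spikeins.tsv"
    with open(spikein_tsv, "w") as fh:
        fh.write("contig\tknown_level\n")
        for std in standards:
            fh.write(f"{std.contig}\t{std.known_level:g}\n")

    truth_tsv = outdir / "truth.tsv"
    truth.to_tsv(truth_tsv)

    config_json = outdir / "sim_config.json"
    with open(config_json, "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, sort_keys=True)
        fh.write("\n")

    return SimBundle(
        config=config, fasta=fasta, sams=sams, spikein_tsv=spikein_tsv,
        truth_tsv=truth_tsv, config_json=config_json, index=index,
        truth=truth, standards=standards,
    )
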