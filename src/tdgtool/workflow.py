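"""End-to-end orchestration of the DREAM and screening tracks.

One RunConfig drives either track (or both) from a single seed: in
simulation mode the generators produce the inputs, otherwise user paths are
consumed.  Each stage's artifacts are written under the output directory and
listed, with sha256 checksums, in a JSON manifest that also echoes the full
config — re-running an identical config and seed reproduces identical
checksums.  Child seeds for each stage are derived deterministically from
the master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import beacon_screen as bs
from . import diff_meth, dream_sim, gene_map_enrich, meth_call, signature_count
from .site_index import build_index

log = logging.getLogger("tdgtool")


@dataclass
class RunConfig:
    track: str = "both"  # dream | screen | both
    seed: int = 1
    outdir: str = "tdgtool_out"
    # DREAM stage parameters
    sim: dict = field(default_factory=dict)  # overrides for dream_sim.SimConfig
    mapq_min: int = 20
    min_coverage: int = 20
    alpha: float = 0.05
    min_delta: float = 0.10
    max_dist: int = 10_000
    annotation: str | None = None  # BED6/GFF3; enables gene mapping
    gmt: str | None = None  # gene sets; enables enrichment
    genome: str | None = None  # non-sim mode inputs
    bams_a: list = field(default_factory=list)
    bams_b: list = field(default_factory=list)
    spikeins: str | None = None
    # screen stage parameters
    n_compounds: int = 300
    n_planted: int = 3
    screening_conc: float = 1.0e-5  # M
    planted_ki: float = 1.0e-7  # M
    hit_threshold: float = 50.0
    qc_min_zprime: float = 0.5
    metric: str = "endpoint"
    plate_tsv: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _child_seed(seed: int, label: str) -> int:
    h = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _write_manifest(outdir: Path, config: RunConfig, artifacts: dict[str, Path],
                    name: str) -> Path:
    manifest = {
        "config": dataclasses.asdict(config),
        "artifacts": {
            stage: {"path": str(p.relative_to(outdir)), "sha256": _sha256(p)}
            for stage, p in artifacts.items()
        },
    }
    path = outdir / name
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def run_dream(config: RunConfig) -> Path:
    """index -> count -> call -> differential -> (optional) gene map/enrich.

    Returns the manifest path.  In simulation mode (no ``genome`` given) a
    synthetic bundle is generated first and analysed exactly like real data.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    if config.genome is None:
        sim_cfg = dream_sim.SimConfig(seed=_child_seed(config.seed, "dream_sim"),
                                      **config.sim)
        bundle = dream_sim.simulate_experiment(sim_cfg, outdir / "sim")
        genome_path = bundle.fasta
        bams = {"A": [bundle.sams[("A", r)] for r in range(1, sim_cfg.n_replicates + 1)],
                "B": [bundle.sams[("B", r)] for r in range(1, sim_cfg.n_replicates + 1)]}
        spikein_path = bundle.spikein_tsv
        artifacts["sim_truth"] = bundle.truth_tsv
    else:
        genome_path = Path(config.genome)
        if not genome_path.exists():
            raise FileNotFoundError(f"genome FASTA not found: {genome_path}")
        for p in [*config.bams_a, *config.bams_b]:
            if not Path(p).exists():
                raise FileNotFoundError(f"alignment file not found: {p}")
        bams = {"A": [Path(p) for p in config.bams_a],
                "B": [Path(p) for p in config.bams_b]}
        spikein_path = Path(config.spikeins) if config.spikeins else None

    log.info("stage index: scanning %s", genome_path)
    index = build_index(genome_path)
    sites_bed = outdir / "sites.bed"
    index.to_bed(sites_bed)
    artifacts["index"] = sites_bed

    merged = {}
    for cond in ("A", "B"):
        log.info("stage count: condition %s (%d replicates)", cond, len(bams[cond]))
        reps = [
            signature_count.count_signatures(p, index, mapq_min=config.mapq_min,
                                             sample_id=Path(p).stem)
            for p in bams[cond]
        ]
        merged[cond] = signature_count.merge_replicates(reps)
        counts_tsv = outdir / f"counts_{cond}.tsv"
        merged[cond].to_tsv(counts_tsv)
        merged[cond].qc_to_tsv(outdir / f"counts_{cond}.qc.tsv")
        artifacts[f"counts_{cond}"] = counts_tsv

    log.info("stage call: min_coverage=%d", config.min_coverage)
    calls = {c: meth_call.call_methylation(merged[c], config.min_coverage)
             for c in ("A", "B")}
    for cond in ("A", "B"):
        calls_tsv = outdir / f"calls_{cond}.tsv"
        meth_call.calls_to_tsv(calls[cond], calls_tsv)
        artifacts[f"calls_{cond}"] = calls_tsv

    if spikein_path is not None:
        standards = meth_call.read_spikein_spec(spikein_path)
        try:
            report = meth_call.calibrate_spikeins(calls["A"], standards)
            calib_tsv = outdir / "calibration_A.tsv"
            meth_call.calibration_to_tsv(report, calib_tsv)
            artifacts["calibration"] = calib_tsv
        except ValueError as exc:
            log.warning("spike-in calibration skipped: %s", exc)

    log.info("stage differential: alpha=%g min_delta=%g", config.alpha, config.min_delta)
    sites, summary = diff_meth.classify_sites(
        calls["A"], calls["B"], merged["A"], merged["B"],
        alpha=config.alpha, min_delta=config.min_delta,
    )
    volcano = diff_meth.volcano_table(sites)
    volcano_tsv = outdir / "volcano.tsv"
    volcano.to_csv(volcano_tsv, sep="\t", index=False)
    artifacts["volcano"] = volcano_tsv
    summary_json = outdir / "diff_summary.json"
    with open(summary_json, "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    artifacts["diff_summary"] = summary_json

    if config.annotation:
        genes = gene_map_enrich.load_genes(config.annotation)
        assignments = []
        covered = []
        pos_by_id = {s.site_id: s for s in index.sites}
        for ds in sites:
            asg = gene_map_enrich.nearest_gene(pos_by_id[ds.site_id], genes,
                                               max_dist=config.max_dist)
            if asg is not None:
                covered.append((ds, asg))
                assignments.append(asg)
        asg_tsv = outdir / "site_gene.tsv"
        with open(asg_tsv, "w") as fh:
            fh.write("site_id\tgene_id\tdistance\n")
            for a in assignments:
                fh.write(f"{a.site_id}\t{a.gene_id}\t{a.distance}\n")
        artifacts["site_gene"] = asg_tsv
        if config.gmt:
            background = {a.gene_id for _, a in covered}
            foreground = {a.gene_id for ds, a in covered if ds.klass != "unchanged"}
            if foreground and background:
                results = gene_map_enrich.hypergeom_enrich(foreground, background,
                                                           config.gmt)
                enr_tsv = outdir / "enrichment.tsv"
                with open(enr_tsv, "w") as fh:
                    fh.write("set_name\tk\tK\tn\tN\tp_value\tq_value\n")
                    for r in results:
                        fh.write(f"{r.set_name}\t{r.k}\t{r.K}\t{r.n}\t{r.N}"
                                 f"\t{r.p_value:.6g}\t{r.q_value:.6g}\n")
                artifacts["enrichment"] = enr_tsv

    return _write_manifest(outdir, config, artifacts, "dream_manifest.json")


def run_screen(config: RunConfig) -> Path:
    """QC -> inhibition -> hits; gated on a minimum Z'.

    Simulation mode plants ``n_planted`` genuine inhibitors (Ki far below
    the screening concentration) among inactive compounds.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    if config.plate_tsv is None:
        seed = _child_seed(config.seed, "screen_sim")
        rng = np.random.default_rng(seed)
        planted = set(rng.choice(config.n_compounds, config.n_planted, replace=False))
        compounds = [
            (f"CMPD{i:04d}", config.screening_conc,
             config.planted_ki if i in planted else float("inf"))
            for i in range(config.n_compounds)
        ]
        layout = bs.default_layout_384(compounds)
        traces = bs.simulate_plate(layout, bs.KineticParams(), seed=seed + 1)
        plate_tsv = outdir / "plate.tsv"
        bs.traces_to_tsv(traces, plate_tsv)
        artifacts["plate"] = plate_tsv
    else:
        traces = bs.traces_from_tsv(config.plate_tsv)

    qc, inhibition = bs.analyze_plate(traces, metric=config.metric)
    qc_json = outdir / "plate_qc.json"
    with open(qc_json, "w") as fh:
        json.dump(dataclasses.asdict(qc), fh, indent=2, sort_keys=True)
        fh.write("\n")
    artifacts["qc"] = qc_json

    if qc.z_prime < config.qc_min_zprime:
        log.warning("plate %s fails QC (Z'=%.3f < %.2f); hit calling skipped",
                    qc.plate_id, qc.z_prime, config.qc_min_zprime)
        flag = outdir / "qc_failed.flag"
        flag.write_text(f"z_prime={qc.z_prime:.4f}\n")
        artifacts["qc_failed"] = flag
        return _write_manifest(outdir, config, artifacts, "screen_manifest.json")

    inh_tsv = outdir / "inhibition.tsv"
    inhibition.to_csv(inh_tsv, sep="\t", index=False)
    artifacts["inhibition"] = inh_tsv

    hits = bs.call_hits(inhibition, threshold=config.hit_threshold)
    hits_tsv = outdir / "hits.tsv"
    with open(hits_tsv, "w") as fh:
        fh.write("compound_id\tpct_inhibition\tis_hit\n")
        for h in hits:
            fh.write(f"{h.compound_id}\t{h.pct_inhibition:.4f}\t{int(h.is_hit)}\n")
    artifacts["hits"] = hits_tsv

    return _write_manifest(outdir, config, artifacts, "screen_manifest.json")


def run(config: RunConfig) -> list[Path]:
    manifests = []
    if config.track in ("dream", "both"):
        manifests.append(run_dream(config))
    if config.track in ("screen", "both"):
        manifests.append(run_screen(config))
    if config.track not in ("dream", "screen", "both"):
        raise ValueError(f"unknown track {config.track!r}")
    return manifests
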