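"""Per-site methylation levels from signature counts, with spike-in QC.

The methylation level of a SmaI/XmaI site is the fraction of its classified
signatures that are methylated (CCGGG-type), computed only at sites whose
classified coverage reaches ``min_coverage``; under-covered sites are
dropped, not zeroed.  Spike-in standards — control contigs of known
methylation added before digestion — provide an accuracy check via a
coverage-weighted least-squares line of observed on known level.  The
calibration is reported by default and applied to calls only on request.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .signature_count import SampleCounts


@dataclass(frozen=True)
class MethylationCall:
    site_id: str
    coverage: int
    level: float  # exact n_meth / coverage, in [0, 1]
    calibrated_level: float | None = None


@dataclass(frozen=True)
class SpikeInStandard:
    contig: str
    known_level: float


@dataclass(frozen=True)
class CalibrationReport:
    """Weighted regression of observed spike-in level on known level."""

    standards: tuple[tuple[float, float, int], ...]  # (known, observed, coverage)
    slope: float
    intercept: float
    r_squared: float


def call_methylation(
    counts: SampleCounts, min_coverage: int = 20
) -> dict[str, MethylationCall]:
    """One call per site with classified coverage >= min_coverage."""
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    calls: dict[str, MethylationCall] = {}
    for sid, c in counts.counts.items():
        cov = c.coverage
        if cov >= min_coverage:
            calls[sid] = MethylationCall(sid, cov, c.n_meth / cov)
    return calls


def _standard_observation(
    calls: Mapping[str, MethylationCall], contig: str
) -> tuple[float, int] | None:
    """Coverage-weighted mean level over a standard contig's called sites."""
    prefix = contig + ":"
    levels, weights = [], []
    for sid, call in calls.items():
        if sid.startswith(prefix):
            levels.append(call.level)
            weights.append(call.coverage)
    if not levels:
        return None
    w = np.asarray(weights, dtype=float)
    return float(np.average(levels, weights=w)), int(w.sum())


def calibrate_spikeins(
    calls: Mapping[str, MethylationCall], standards: Iterable[SpikeInStandard]
) -> CalibrationReport:
    """Fit observed ~ known over spike-in standards, weighted by coverage."""
    rows = []
    for std in standards:
        obs = _standard_observation(calls, std.contig)
        if obs is not None:
            rows.append((std.known_level, obs[0], obs[1]))
    if len(rows) < 2:
        raise ValueError(
            f"need >= 2 spike-in standards with called sites, got {len(rows)}"
        )
    known = np.array([r[0] for r in rows])
    observed = np.array([r[1] for r in rows])
    w = np.array([r[2] for r in rows], dtype=float)
    # weighted least squares; polyfit weights multiply residuals, hence sqrt
    slope, intercept = np.polyfit(known, observed, 1, w=np.sqrt(w))
    fitted = slope * known + intercept
    ss_res = float(np.sum(w * (observed - fitted) ** 2))
    mean_obs = float(np.average(observed, weights=w))
    ss_tot = float(np.sum(w * (observed - mean_obs) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return CalibrationReport(
        standards=tuple(rows), slope=float(slope), intercept=float(intercept),
        r_squared=float(r2),
    )


def apply_calibration(
    calls: Mapping[str, MethylationCall],
    report: CalibrationReport,
    clip: bool = True,
) -> dict[str, MethylationCall]:
    """Invert the calibration line: calibrated = (level - intercept) / slope."""
    if report.slope == 0:
        raise ValueError("calibration slope is zero; cannot invert")
    out: dict[str, MethylationCall] = {}
    for sid, call in calls.items():
        raw = (call.level - report.intercept) / report.slope
        if clip:
            raw = min(1.0, max(0.0, raw))
        out[sid] = replace(call, calibrated_level=raw)
    return out


def calls_to_tsv(calls: Mapping[str, MethylationCall], path: str | Path) -> None:
    calibrated = any(c.calibrated_level is not None for c in calls.values())
    with open(path, "w") as fh:
        cols = "site_id\tcoverage\tlevel"
        fh.write(cols + ("\tcalibrated_level\n" if calibrated else "\n"))
        for sid in sorted(calls):
            c = calls[sid]
            row = f"{sid}\t{c.coverage}\t{c.level:.6g}"
            if calibrated:
                row += f"\t{'' if c.calibrated_level is None else format(c.calibrated_level, '.6g')}"
            fh.write(row + "\n")


def calibration_to_tsv(report: CalibrationReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("known_level\tobserved_level\tcoverage\n")
        for known, obs, cov in report.standards:
            fh.write(f"{known:.6g}\t{obs:.6g}\t{cov}\n")
        fh.write(f"# slope={report.slope:.6g} intercept={report.intercept:.6g} "
                 f"r_squared={report.r_squared:.6g}\n")


def read_spikein_spec(path: str | Path) -> list[SpikeInStandard]:
    """Read a two-column TSV (contig, known_level) of spike-in standards."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["contig", "known_level"]:
            raise ValueError(f"{path}: expected 'contig\\tknown_level' header")
        for line in fh:
            contig, level = line.rstrip("\n").split("\t")[:2]
            out.append(SpikeInStandard(contig, float(level)))
    return out
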