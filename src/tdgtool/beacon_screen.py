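"""Molecular-beacon glycosylase/AP-endonuclease screening analysis.

The assay: a hairpin oligonucleotide with a 5' fluorophore quenched by a 3'
dark quencher carries a G:U mismatch.  Uracil excision by the glycosylase
(TDG) leaves an abasic site that the coupling enzyme APE1 incises, releasing
the fluorophore-bearing fragment; repair activity therefore reads out as
fluorescence gain over time.  Kinetically this is sequential first-order
conversion, substrate -> AP-site -> fluorescent product:

    F(t) = F_bg + drift*t
           + F_scale*S0*[1 - (kap*exp(-kg*t) - kg*exp(-kap*t)) / (kap - kg)]

with kg the excision rate (proportional to glycosylase activity), kap the
incision rate, S0 the substrate concentration; the kg -> kap limit is
handled continuously.  Inhibitors are modelled as scaling kg by
1/(1 + conc/Ki) — a simple activity-scaling model, adequate for generating
testable plates, not a mechanistic binding model.

Analysis side: endpoint or slope activity metrics, Z'-factor plate QC
(Z' = 1 - 3*(sd_pos + sd_neg)/|mean_pos - mean_neg|), percent inhibition
against uninhibited (pos) and no-enzyme (neg) controls, threshold hit
calling, and 4-parameter-logistic IC50 fitting in log-concentration space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

ROLES = ("pos_control", "neg_control", "compound")


@dataclass
class TimeCourse:
    plate_id: str
    well: str
    role: str
    times: np.ndarray  # seconds, strictly increasing
    rfu: np.ndarray
    compound_id: str | None = None
    concentration: float | None = None  # molar

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rfu = np.asarray(self.rfu, dtype=float)
        if self.role not in ROLES:
            raise ValueError(f"unknown well role {self.role!r}")
        if self.times.size < 2 or self.times.size != self.rfu.size:
            raise ValueError("a time course needs >= 2 matched (time, rfu) points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class PlateQC:
    plate_id: str
    mean_pos: float
    sd_pos: float
    mean_neg: float
    sd_neg: float
    z_prime: float


@dataclass(frozen=True)
class HitCall:
    compound_id: str
    pct_inhibition: float
    is_hit: bool


@dataclass(frozen=True)
class FourPLFit:
    bottom: float
    top: float
    hill: float
    ic50: float
    converged: bool
    rss: float
    reason: str = ""


@dataclass(frozen=True)
class KineticParams:
    """Defaults reflect the 384-well assay regime: 280 nM beacon substrate,
    nanomolar enzyme, ~70% substrate conversion over the 2-h read."""

    S0: float = 280.0  # nM substrate
    kg: float = 2.0e-4  # /s, glycosylase excision (scales with TDG activity)
    kap: float = 1.0e-3  # /s, AP-site incision (scales with APE1 activity)
    F_bg: float = 50.0  # RFU, quenched background
    F_scale: float = 1.0  # RFU per nM converted substrate
    drift: float = 1.0e-3  # RFU/s, linear instrument drift
    noise_sd: float = 5.0  # RFU, additive Gaussian noise per sample

    def __post_init__(self) -> None:
        if self.kg < 0 or self.kap < 0:
            raise ValueError("rates must be non-negative")


def beacon_kinetics(params: KineticParams, t: float | np.ndarray) -> np.ndarray | float:
    """Closed-form expected fluorescence of the two-step repair kinetics.

    Written in an expm1-stable form that is exact in the kg -> kap limit:
    with d = kap - kg, the unconverted fraction is
    exp(-kg*t) * (1 + kg * (1 - exp(-d*t))/d), and (1 - exp(-d*t))/d -> t
    as d -> 0.
    """
    t = np.asarray(t, dtype=float)
    kg, kap = params.kg, params.kap
    d = kap - kg
    with np.errstate(invalid="ignore"):
        ratio = np.where(d == 0, t, -np.expm1(-d * t) / np.where(d == 0, 1.0, d))
    unconverted = np.exp(-kg * t) * (1.0 + kg * ratio)
    f = params.F_bg + params.drift * t + params.F_scale * params.S0 * (1.0 - unconverted)
    return f if f.shape else float(f)


def activity_endpoint(trace: TimeCourse, t0: float, t1: float) -> float:
    """Delta-RFU between linearly interpolated readings at t1 and t0."""
    if not t0 < t1:
        raise ValueError("t0 must precede t1")
    if t0 < trace.times[0] or t1 > trace.times[-1]:
        raise ValueError(
            f"[{t0}, {t1}] outside trace span [{trace.times[0]}, {trace.times[-1]}]"
        )
    f0, f1 = np.interp([t0, t1], trace.times, trace.rfu)
    return float(f1 - f0)


def activity_slope(trace: TimeCourse, window: tuple[float, float]) -> float:
    """Least-squares slope (RFU/s) over samples inside the window."""
    lo, hi = window
    mask = (trace.times >= lo) & (trace.times <= hi)
    if mask.sum() < 3:
        raise ValueError(f"need >= 3 samples in window [{lo}, {hi}], have {int(mask.sum())}")
    slope, _ = np.polyfit(trace.times[mask], trace.rfu[mask], 1)
    return float(slope)


def z_prime(
    pos_activities: Sequence[float],
    neg_activities: Sequence[float],
    plate_id: str = "plate",
) -> PlateQC:
    """Z'-factor plate QC from control activities (sample sd, n-1)."""
    pos = np.asarray(pos_activities, dtype=float)
    neg = np.asarray(neg_activities, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("need >= 2 activities per control group")
    mp, mn = float(pos.mean()), float(neg.mean())
    if mp == mn:
        raise ValueError("control means are equal; Z' separation undefined")
    sp, sn = float(pos.std(ddof=1)), float(neg.std(ddof=1))
    z = 1.0 - 3.0 * (sp + sn) / abs(mp - mn)
    return PlateQC(plate_id, mp, sp, mn, sn, z)


def percent_inhibition(activity: float, qc: PlateQC) -> float:
    """100 * (1 - (activity - mean_neg)/(mean_pos - mean_neg)); raw, unclipped."""
    return 100.0 * (1.0 - (activity - qc.mean_neg) / (qc.mean_pos - qc.mean_neg))


def call_hits(
    inhibitions: Mapping[str, float] | pd.DataFrame, threshold: float = 50.0
) -> list[HitCall]:
    """Threshold hit calling on one inhibition value per compound.

    A DataFrame with ``compound_id``/``pct_inhibition`` columns is collapsed
    to the median across replicate wells first.
    """
    if isinstance(inhibitions, pd.DataFrame):
        collapsed = (
            inhibitions.groupby("compound_id")["pct_inhibition"].median().to_dict()
        )
    else:
        collapsed = dict(inhibitions)
    return [
        HitCall(cid, float(v), bool(v >= threshold))
        for cid, v in sorted(collapsed.items())
    ]


def _fourpl(logc: np.ndarray, bottom: float, top: float, hill: float,
            log_ic50: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + np.exp(hill * (logc - log_ic50)))


def fit_4pl(
    concentrations: Sequence[float],
    responses: Sequence[float],
    noise_floor: float | None = None,
) -> FourPLFit:
    """Fit R(c) = bottom + (top-bottom)/(1 + (c/ic50)^hill), hill > 0.

    Least squares in log-concentration space, multi-started from quartiles
    of the tested span; honest ``converged`` flag — a flat response (range
    below the noise floor), a negative fitted Hill slope (response rising
    with dose in an inhibition fit), or an IC50 outside 100x the tested
    span all report non-convergence with a reason.
    """
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if conc.size != resp.size:
        raise ValueError("concentrations and responses differ in length")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if np.unique(conc).size < 5:
        raise ValueError("need >= 5 distinct concentrations")
    logc = np.log(conc)
    span = resp.max() - resp.min()
    floor = noise_floor if noise_floor is not None else 0.0
    if span <= floor:
        return FourPLFit(float(resp.mean()), float(resp.mean()), 1.0, float(np.nan),
                         False, float(np.sum((resp - resp.mean()) ** 2)),
                         reason="flat_response")
    best = None
    for q in (0.25, 0.5, 0.75):
        x0 = np.array([resp.min(), resp.max(), 1.0, np.quantile(logc, q)])
        sol = least_squares(
            lambda p: _fourpl(logc, *p) - resp, x0,
            bounds=([-np.inf, -np.inf, -10.0, logc.min() - np.log(1e4)],
                    [np.inf, np.inf, 10.0, logc.max() + np.log(1e4)]),
        )
        if best is None or sol.cost < best.cost:
            best = sol
    bottom, top, hill, log_ic50 = best.x
    if top < bottom:  # canonical form: top >= bottom, sign carried by hill
        bottom, top, hill = top, bottom, -hill
    ic50 = float(np.exp(log_ic50))
    rss = float(2 * best.cost)
    if hill <= 0:
        return FourPLFit(float(bottom), float(top), float(hill), ic50, False, rss,
                         reason="nonpositive_hill")
    span_lo, span_hi = conc.min() / 100.0, conc.max() * 100.0
    if not (span_lo <= ic50 <= span_hi):
        return FourPLFit(float(bottom), float(top), float(hill), ic50, False, rss,
                         reason="ic50_outside_span")
    return FourPLFit(float(bottom), float(top), float(hill), ic50, bool(best.success),
                     rss)


# ---------------------------------------------------------------------------
# plate simulation


@dataclass(frozen=True)
class WellSpec:
    well: str
    role: str
    compound_id: str | None = None
    concentration: float | None = None  # molar
    ki: float = float("inf")  # molar; inf = inactive


def default_layout_384(
    compounds: Sequence[tuple[str, float, float]],
    n_controls: int = 16,
) -> list[WellSpec]:
    """Simple layout: n_controls pos + n_controls neg wells, then compounds.

    ``compounds`` are (id, screening concentration in M, Ki in M).
    """
    wells: list[WellSpec] = []
    serial = 0

    def next_well() -> str:
        nonlocal serial
        row, col = divmod(serial, 24)
        serial += 1
        return f"{chr(ord('A') + row)}{col + 1:02d}"

    for _ in range(n_controls):
        wells.append(WellSpec(next_well(), "pos_control"))
    for _ in range(n_controls):
        wells.append(WellSpec(next_well(), "neg_control"))
    for cid, conc, ki in compounds:
        wells.append(WellSpec(next_well(), "compound", cid, conc, ki))
    return wells


def simulate_plate(
    layout: Sequence[WellSpec],
    params: KineticParams,
    seed: int,
    times: np.ndarray | None = None,
    plate_id: str = "plate1",
) -> list[TimeCourse]:
    """Simulate fluorescence traces for every well on one plate.

    Compound wells scale the excision rate kg by 1/(1 + conc/Ki)
    (Ki = inf leaves kg untouched); no-enzyme negative controls have
    kg = 0, i.e. background + drift + noise only.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, 7200.0 + 1, 60.0) if times is None else np.asarray(times, float)
    traces: list[TimeCourse] = []
    for spec in layout:
        if spec.role == "neg_control":
            kg = 0.0
        elif spec.role == "pos_control":
            kg = params.kg
        elif spec.role == "compound":
            scale = 1.0
            if spec.concentration and np.isfinite(spec.ki):
                scale = 1.0 / (1.0 + spec.concentration / spec.ki)
            kg = params.kg * scale
        else:
            raise ValueError(f"unknown well role {spec.role!r}")
        well_params = KineticParams(
            S0=params.S0, kg=kg, kap=params.kap, F_bg=params.F_bg,
            F_scale=params.F_scale, drift=params.drift, noise_sd=params.noise_sd,
        )
        rfu = np.asarray(beacon_kinetics(well_params, t), dtype=float)
        if params.noise_sd > 0:
            rfu = rfu + rng.normal(0.0, params.noise_sd, size=t.size)
        traces.append(
            TimeCourse(plate_id, spec.well, spec.role, t, rfu,
                       compound_id=spec.compound_id,
                       concentration=spec.concentration)
        )
    return traces


def analyze_plate(
    traces: Iterable[TimeCourse],
    metric: str = "endpoint",
    t0: float = 0.0,
    t1: float = 7200.0,
    slope_window: tuple[float, float] = (0.0, 1800.0),
) -> tuple[PlateQC, pd.DataFrame]:
    """Plate QC plus a per-well inhibition table.

    ``metric`` is 'endpoint' (fluorescence change between t0 and t1, the
    0-and-3-h readout of the miniaturised assay) or 'slope' (initial-rate
    readout of the kinetic mode).
    """
    traces = list(traces)
    if metric == "endpoint":
        act = {id(tr): activity_endpoint(tr, t0, t1) for tr in traces}
    elif metric == "slope":
        act = {id(tr): activity_slope(tr, slope_window) for tr in traces}
    else:
        raise ValueError(f"unknown metric {metric!r}")
    pos = [act[id(tr)] for tr in traces if tr.role == "pos_control"]
    neg = [act[id(tr)] for tr in traces if tr.role == "neg_control"]
    plate_id = traces[0].plate_id if traces else "plate"
    qc = z_prime(pos, neg, plate_id=plate_id)
    rows = [
        {
            "well": tr.well,
            "compound_id": tr.compound_id,
            "concentration": tr.concentration,
            "activity": act[id(tr)],
            "pct_inhibition": percent_inhibition(act[id(tr)], qc),
        }
        for tr in traces
        if tr.role == "compound"
    ]
    return qc, pd.DataFrame(rows, columns=["well", "compound_id", "concentration",
                                           "activity", "pct_inhibition"])


def traces_to_tsv(traces: Iterable[TimeCourse], path) -> None:
    """Long-format TSV: plate, well, role, compound, conc, time, rfu."""
    rows = []
    for tr in traces:
        for t, f in zip(tr.times, tr.rfu):
            rows.append((tr.plate_id, tr.well, tr.role, tr.compound_id or "",
                         "" if tr.concentration is None else tr.concentration, t, f))
    pd.DataFrame(rows, columns=["plate", "well", "role", "compound", "conc",
                                "time", "rfu"]).to_csv(path, sep="\t", index=False)


def traces_from_tsv(path) -> list[TimeCourse]:
    df = pd.read_csv(path, sep="\t", dtype={"compound": str})
    traces = []
    for (plate, well), grp in df.groupby(["plate", "well"], sort=True):
        grp = grp.sort_values("time")
        role = grp["role"].iloc[0]
        compound = grp["compound"].iloc[0]
        conc = grp["conc"].iloc[0]
        traces.append(
            TimeCourse(
                str(plate), str(well), str(role),
                grp["time"].to_numpy(), grp["rfu"].to_numpy(),
                compound_id=None if pd.isna(compound) or compound == "" else str(compound),
                concentration=None if pd.isna(conc) or conc == "" else float(conc),
            )
        )
    return traces
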