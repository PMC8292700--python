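"""Linac delivery simulation and RT-log-file-plan reconstruction.

The treatment control system evolves the machine at 25 Hz; the interface
that external QA software can read republishes the same state at 4 Hz,
one record per 0.25 s.  This module simulates that delivery for any
:class:`~vmatqa.plan.VmatPlan` and reconstructs a deliverable plan from
any log ("RT log file plan", one control point per log record).

Delivery model
--------------
MU accrues linearly in time within each arc.  At every internal tick the
axes track their MU-interpolated planned targets plus a truncated-Gaussian
deviation; leaf deviations are additionally low-pass filtered with a
first-order lag to mimic servo acceleration limits.  All deviations are
truncated at the configured bound (the machine's dynamic tolerance); an
emitted deviation beyond the machine tolerance raises
:class:`~vmatqa.exceptions.DeliveryFaultError`, modelling an interlock.
Emitted values are quantized to 1e-9 (mm / deg / MU), the precision of
the plain-text log dialect; quantization is far below machine tolerances
so reconstruction fidelity is limited only by sampling, not by encoding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .exceptions import DeliveryFaultError, ValidationError
from .plan import ArcBeam, ControlPoint, VmatPlan, sample_beam_state

__all__ = [
    "JitterSpec", "LogRecord", "DeliveryLog",
    "simulate_delivery", "log_to_plan", "downsample_equivalence",
    "DownsampleReport",
]


@dataclass(frozen=True)
class JitterSpec:
    """Stochastic delivery-deviation model, truncated at the machine bounds."""

    leaf_sd_mm: float = 0.3
    leaf_bound_mm: float = 0.8
    gantry_sd_deg: float = 0.05
    gantry_bound_deg: float = 0.3
    leaf_lag_s: float = 0.08
    mu_sd: float = 0.02
    mu_bound: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("leaf_sd_mm", "leaf_bound_mm", "gantry_sd_deg",
                     "gantry_bound_deg", "leaf_lag_s", "mu_sd", "mu_bound"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    @classmethod
    def zero(cls) -> "JitterSpec":
        """Noise-free delivery: every record equals the interpolated plan."""
        return cls(leaf_sd_mm=0.0, leaf_bound_mm=0.0, gantry_sd_deg=0.0,
                   gantry_bound_deg=0.0, leaf_lag_s=0.0, mu_sd=0.0,
                   mu_bound=0.0, seed=0)


@dataclass
class LogRecord:
    """One time-stamped machine-state sample."""

    time_s: float
    gantry_deg: float
    collimator_deg: float
    leaves_a_mm: np.ndarray
    leaves_b_mm: np.ndarray
    jaws_mm: np.ndarray
    mu: float


@dataclass
class DeliveryLog:
    """Ordered machine-state samples at a fixed rate, column-major storage."""

    time_s: np.ndarray
    gantry_deg: np.ndarray
    collimator_deg: np.ndarray
    leaves_a_mm: np.ndarray   # (n, 80)
    leaves_b_mm: np.ndarray   # (n, 80)
    jaws_mm: np.ndarray       # (n, 4)
    mu: np.ndarray
    rate_hz: float = 4.0
    leaf_tolerance_mm: float = 1.0
    gantry_tolerance_deg: float = 1.0

    def __post_init__(self) -> None:
        for name in ("time_s", "gantry_deg", "collimator_deg", "mu"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.leaves_a_mm = np.asarray(self.leaves_a_mm, dtype=float)
        self.leaves_b_mm = np.asarray(self.leaves_b_mm, dtype=float)
        self.jaws_mm = np.asarray(self.jaws_mm, dtype=float)
        self.validate()

    def __len__(self) -> int:
        return self.time_s.size

    def __getitem__(self, i: int) -> LogRecord:
        return LogRecord(
            time_s=float(self.time_s[i]),
            gantry_deg=float(self.gantry_deg[i]),
            collimator_deg=float(self.collimator_deg[i]),
            leaves_a_mm=self.leaves_a_mm[i],
            leaves_b_mm=self.leaves_b_mm[i],
            jaws_mm=self.jaws_mm[i],
            mu=float(self.mu[i]),
        )

    def validate(self) -> None:
        n = len(self)
        if n == 0:
            raise ValidationError("log contains no records")
        if self.rate_hz <= 0:
            raise ValidationError("sampling rate must be positive")
        if n > 1:
            dt = np.diff(self.time_s)
            if np.any(np.abs(dt) < 1e-9):
                raise ValidationError("duplicated timestamps in log")
            if np.any(dt <= 0):
                raise ValidationError("timestamps must strictly increase")
            if np.any(np.abs(dt - 1.0 / self.rate_hz) > 1e-6):
                raise ValidationError(
                    "record interval must equal 1/rate everywhere")
        if np.any(np.diff(self.mu) < 0):
            raise ValidationError("cumulative MU must be non-decreasing")
        if self.leaves_a_mm.shape != (n, 80) or self.leaves_b_mm.shape != (n, 80):
            raise ValidationError("leaf columns must be (n, 80) per bank")
        if self.jaws_mm.shape != (n, 4):
            raise ValidationError("jaw columns must be (n, 4)")


# ---------------------------------------------------------------------------
# planned trajectory


def _plan_targets(plan: VmatPlan, times: np.ndarray, duration_s: float,
                  gap_s: float) -> dict[str, np.ndarray]:
    """Planned machine state (MU-interpolated) at arbitrary global times.

    Arcs are delivered back to back with a beam-hold of ``gap_s`` between
    them during which MU is constant and the MLC morphs linearly to the
    next arc's starting aperture.
    """
    n = times.size
    out = {
        "mu": np.zeros(n),
        "gantry_deg": np.zeros(n),
        "collimator_deg": np.zeros(n),
        "leaves_a_mm": np.zeros((n, 80)),
        "leaves_b_mm": np.zeros((n, 80)),
        "jaws_mm": np.zeros((n, 4)),
    }
    mu_offset = 0.0
    for b, beam in enumerate(plan.beams):
        start = b * (duration_s + gap_s)
        end = start + duration_s
        in_beam = (times >= start - 1e-9) & (times <= end + 1e-9)
        if in_beam.any():
            w = np.clip((times[in_beam] - start) / duration_s, 0.0, 1.0)
            state = sample_beam_state(beam, w)
            out["mu"][in_beam] = mu_offset + w * beam.meterset_mu
            for key in ("gantry_deg", "collimator_deg", "leaves_a_mm",
                        "leaves_b_mm", "jaws_mm"):
                out[key][in_beam] = state[key]
        mu_offset += beam.meterset_mu
        if b + 1 < len(plan.beams):
            gap_lo, gap_hi = end, end + gap_s
            in_gap = (times > end + 1e-9) & (times < gap_hi - 1e-9)
            if in_gap.any():
                f = (times[in_gap] - gap_lo) / gap_s
                s0 = sample_beam_state(beam, 1.0)
                s1 = sample_beam_state(plan.beams[b + 1], 0.0)
                out["mu"][in_gap] = mu_offset
                for key in ("gantry_deg", "collimator_deg"):
                    out[key][in_gap] = (s0[key][0]
                                        + (s1[key][0] - s0[key][0]) * f)
                for key in ("leaves_a_mm", "leaves_b_mm", "jaws_mm"):
                    out[key][in_gap] = (s0[key][0]
                                        + (s1[key][0] - s0[key][0]) * f[:, None])
    return out


def _truncated_noise(rng: np.random.Generator, n: int, cols: int,
                     sd: float, bound: float,
                     lag_alpha: float | None = None) -> np.ndarray:
    shape = (n, cols) if cols else (n,)
    if sd == 0.0 or bound == 0.0:
        return np.zeros(shape)
    raw = rng.normal(0.0, sd, size=shape)
    if lag_alpha is not None and lag_alpha > 0.0:
        # first-order servo lag: e_k = a e_{k-1} + (1-a) n_k
        raw = signal.lfilter([1.0 - lag_alpha], [1.0, -lag_alpha], raw, axis=0)
    return np.clip(raw, -bound, bound)


def _lerp_rows(t_query: np.ndarray, t_grid: np.ndarray,
               values: np.ndarray) -> np.ndarray:
    """Linear interpolation along axis 0 for 1D or 2D ``values``."""
    j = np.clip(np.searchsorted(t_grid, t_query, side="right"),
                1, len(t_grid) - 1)
    t0, t1 = t_grid[j - 1], t_grid[j]
    f = np.clip((t_query - t0) / (t1 - t0), 0.0, 1.0)
    v0, v1 = values[j - 1], values[j]
    if values.ndim == 2:
        f = f[:, None]
    return v0 + (v1 - v0) * f


def simulate_delivery(
    plan: VmatPlan,
    jitter: JitterSpec | None = None,
    duration_per_arc_s: float = 90.0,
    *,
    gap_s: float = 1.0,
    tcs_rate_hz: float = 25.0,
    log_rate_hz: float = 4.0,
    leaf_tolerance_mm: float = 1.0,
    gantry_tolerance_deg: float = 1.0,
    return_internal: bool = False,
):
    """Deliver a plan and return its 4-Hz log (optionally also the 25-Hz trace).

    With ``jitter=JitterSpec.zero()`` every emitted record equals the
    MU-interpolated plan state exactly (up to the 1e-6 log quantization).
    """
    plan.validate()
    jitter = jitter if jitter is not None else JitterSpec()
    if duration_per_arc_s <= 0:
        raise ValidationError("arc duration must be positive")
    emit_dt = 1.0 / log_rate_hz
    if abs(duration_per_arc_s / emit_dt - round(duration_per_arc_s / emit_dt)) > 1e-9:
        raise ValidationError(
            "arc duration must be a multiple of the emission interval")
    if abs(gap_s / emit_dt - round(gap_s / emit_dt)) > 1e-9:
        raise ValidationError(
            "inter-arc gap must be a multiple of the emission interval")

    n_beams = len(plan.beams)
    total_s = n_beams * duration_per_arc_s + (n_beams - 1) * gap_s
    t_emit = np.round(np.arange(round(total_s / emit_dt) + 1) * emit_dt, 6)
    int_dt = 1.0 / tcs_rate_hz
    t_int = np.arange(math.floor(total_s / int_dt) + 1) * int_dt

    targets_emit = _plan_targets(plan, t_emit, duration_per_arc_s, gap_s)
    targets_int = _plan_targets(plan, t_int, duration_per_arc_s, gap_s)

    # deviation processes on the internal (TCS) tick grid
    rng = np.random.default_rng(jitter.seed)
    n_int = t_int.size
    lag_alpha = (math.exp(-int_dt / jitter.leaf_lag_s)
                 if jitter.leaf_lag_s > 0 else None)
    dev_leaf = _truncated_noise(rng, n_int, 160, jitter.leaf_sd_mm,
                                jitter.leaf_bound_mm, lag_alpha)
    dev_gantry = _truncated_noise(rng, n_int, 0, jitter.gantry_sd_deg,
                                  jitter.gantry_bound_deg)
    dev_mu = _truncated_noise(rng, n_int, 0, jitter.mu_sd, jitter.mu_bound)

    if np.any(np.abs(dev_leaf) > leaf_tolerance_mm + 1e-12):
        raise DeliveryFaultError(
            "leaf position left its dynamic tolerance; delivery interlocked")
    if np.any(np.abs(dev_gantry) > gantry_tolerance_deg + 1e-12):
        raise DeliveryFaultError(
            "gantry angle left its dynamic tolerance; delivery interlocked")

    def _emit(times, targets, dleaf, dgantry, dmu, rate):
        leaves = targets["leaves_a_mm"], targets["leaves_b_mm"]
        la = np.round(leaves[0] + dleaf[:, :80], 9)
        lb = np.round(leaves[1] + dleaf[:, 80:], 9)
        mu = np.round(np.maximum(targets["mu"] + dmu, 0.0), 9)
        mu = np.maximum.accumulate(mu)
        return DeliveryLog(
            time_s=np.round(times, 9),
            gantry_deg=np.round(targets["gantry_deg"] + dgantry, 9),
            collimator_deg=np.round(targets["collimator_deg"], 9),
            leaves_a_mm=la, leaves_b_mm=lb,
            jaws_mm=np.round(targets["jaws_mm"], 9),
            mu=mu,
            rate_hz=rate,
            leaf_tolerance_mm=leaf_tolerance_mm,
            gantry_tolerance_deg=gantry_tolerance_deg,
        )

    log4 = _emit(
        t_emit, targets_emit,
        _lerp_rows(t_emit, t_int, dev_leaf),
        _lerp_rows(t_emit, t_int, dev_gantry),
        _lerp_rows(t_emit, t_int, dev_mu),
        log_rate_hz,
    )
    if not return_internal:
        return log4
    log25 = _emit(t_int, targets_int, dev_leaf, dev_gantry, dev_mu,
                  tcs_rate_hz)
    return log4, log25


# ---------------------------------------------------------------------------
# reconstruction


def _split_beams(mu: np.ndarray, min_run: int = 3) -> list[tuple[int, int]]:
    """Split a log into per-arc record ranges at cumulative-MU plateaus.

    A plateau is a run of >= ``min_run`` consecutive increments below a
    quarter of the median increment (beam-hold between arcs; the margin
    absorbs MU-counter noise).  Each plateau is cut at its middle so every
    record lands in exactly one beam.
    """
    n = mu.size
    dmu = np.diff(mu)
    if dmu.size == 0:
        return [(0, n)]
    positive = dmu[dmu > 0]
    thresh = 0.25 * np.median(positive) if positive.size else 1e-9
    small = dmu <= max(thresh, 1e-9)
    splits = []
    i = 0
    while i < dmu.size:
        if small[i]:
            j = i
            while j < dmu.size and small[j]:
                j += 1
            if j - i >= min_run and i > 0 and j < dmu.size:
                splits.append((i + j + 1) // 2)  # middle record of the hold
            i = j
        else:
            i += 1
    bounds = [0] + splits + [n]
    return [(bounds[k], bounds[k + 1]) for k in range(len(bounds) - 1)]


def log_to_plan(log: DeliveryLog, template: VmatPlan) -> VmatPlan:
    """Reconstruct an RT log file plan: one control point per log record.

    Dynamic fields are copied from the records verbatim; static fields
    (isocenter, SAD, leaf geometry, energy) come from the template plan.
    Cumulative meterset weights are the records' cumulative MU normalized
    per reconstructed arc, so the final weight of each arc is exactly 1.
    """
    log.validate()
    delivered = float(log.mu[-1] - log.mu[0])
    if delivered <= 0:
        raise ValidationError("log delivered no MU; cannot reconstruct a plan")

    beams = []
    for k, (s, e) in enumerate(_split_beams(log.mu)):
        mu0 = float(log.mu[s])
        cum = np.round(log.mu[s:e] - mu0, 9)
        meterset = float(cum[-1])
        if meterset <= 0:
            raise ValidationError(
                "reconstructed arc has zero meterset; malformed log")
        cps = [
            ControlPoint(
                gantry_deg=float(log.gantry_deg[i]),
                collimator_deg=float(log.collimator_deg[i]),
                leaves_a_mm=log.leaves_a_mm[i].copy(),
                leaves_b_mm=log.leaves_b_mm[i].copy(),
                jaws_mm=log.jaws_mm[i].copy(),
                cumulative_mu=float(cum[i - s]),
            )
            for i in range(s, e)
        ]
        beams.append(ArcBeam(control_points=cps, meterset_mu=meterset,
                             name=f"log_arc_{k + 1}"))

    out = template.copy()
    out.beams = beams
    out.name = f"{template.name}_logfile"
    out.validate()
    return out


# ---------------------------------------------------------------------------
# 25 Hz vs 4 Hz equivalence


@dataclass
class DownsampleReport:
    """Dose agreement between the 25-Hz trace and the 4-Hz emission."""

    gpr_pct: float
    ptv_dmean_diff_pct: float
    ptv_dmean_25hz_gy: float
    ptv_dmean_4hz_gy: float
    n_records_25hz: int = 0
    n_records_4hz: int = 0


def downsample_equivalence(plan, phantom, structures, jitter=None, cfg=None,
                           duration_per_arc_s: float = 90.0,
                           criteria=None) -> DownsampleReport:
    """Quantify how much is lost by logging at 4 Hz instead of 25 Hz.

    Both traces come from one simulated delivery; each is reconstructed
    into a plan and recomputed with the same engine configuration (same
    noise seed, so statistical noise cancels), then compared by gamma
    analysis and PTV Dmean.
    """
    from .compare import GammaCriteria, gamma_index, passing_rate
    from .dose_engine import EngineConfig, compute_dose

    cfg = cfg if cfg is not None else EngineConfig()
    criteria = criteria if criteria is not None else GammaCriteria()
    log4, log25 = simulate_delivery(
        plan, jitter, duration_per_arc_s, return_internal=True)
    dose25 = compute_dose(log_to_plan(log25, plan), phantom, cfg)
    dose4 = compute_dose(log_to_plan(log4, plan), phantom, cfg)

    ptv = structures.mask_on(dose25.geometry, dose25.dose.shape)["PTV"]
    dmean25 = float(dose25.dose[ptv].mean())
    dmean4 = float(dose4.dose[ptv].mean())
    gmap = gamma_index(dose25, dose4, criteria)
    return DownsampleReport(
        gpr_pct=passing_rate(gmap),
        ptv_dmean_diff_pct=100.0 * (dmean25 - dmean4) / dmean25,
        ptv_dmean_25hz_gy=dmean25,
        ptv_dmean_4hz_gy=dmean4,
        n_records_25hz=len(log25),
        n_records_4hz=len(log4),
    )
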