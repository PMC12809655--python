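"""From block ratios to drift-corrected, calibrated delta values.

Implements the reference-bracketing workflow of isotope-ratio MS by
standard-sample bracketing: a valve alternates the ion source between
the sample and a continuously infused reference, the run is cut into
alternating segments, each segment into fixed-length processing blocks,
and every sample block is referenced against the linear interpolation
of the two bracketing reference blocks (cancelling slow instrument
drift). Deltas are reported in the conventional per-mil notation

    delta = 1000 * (R_sample - R_reference) / R_reference   [permil]

and differences between two deltas as Delta-delta. One- and two-point
calibrations map measured deltas onto an assigned scale (VPDB, VCDT,
air) through anchor standards. Uncertainties combine the block-to-block
scatter of sample and reference with a Welch-Satterthwaite t interval.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import nuclides
from .ion_stats import BlockResult, DegenerateBlockError, aggregate_block
from .scan_model import (
    IsotopologueSpec,
    ProcessingConstants,
    ScanRecord,
)

__all__ = [
    "BracketSchedule",
    "CalibrationModel",
    "DeltaResult",
    "allan_deviation",
    "build_schedule",
    "calibrate",
    "combined_ci",
    "delta_diff",
    "delta_value",
    "drift_correct",
    "exact_mass",
    "fit_one_point",
    "fit_two_point",
    "mass_dependent_delta33",
    "process_records",
    "reference_residuals",
    "segment_blocks",
    "substituted_nuclide",
]

RESULT_COLUMNS = (
    "fragment_id",
    "element",
    "block_start_min",
    "block_end_min",
    "channel",
    "ratio",
    "delta_permil",
    "ci95_permil",
    "calibration",
)


# ---------------------------------------------------------------------------
# schedule

@dataclass(frozen=True)
class BracketSchedule:
    """Alternating sample/reference segments partitioning a run.

    ``segments`` are (start_min, end_min, channel) triples; the leading
    ``guard_min`` of each segment is discarded before block formation to
    let the source settle after the valve switch.
    """

    segments: tuple[tuple[float, float, str], ...]
    switch_period_min: float
    guard_min: float

    def usable_window(self, segment: tuple[float, float, str]) -> tuple[float, float]:
        start, end, _ = segment
        return (start + self.guard_min, end)


def build_schedule(
    duration_min: float,
    switch_period_min: float = 20.0,
    first_channel: str = "reference",
    guard_min: float = 2.0,
) -> BracketSchedule:
    """Alternating segments of one valve period each, first_channel first.

    A 180-min run at a 20-min period, reference first, yields 5 reference
    and 4 sample segments. The final segment is truncated at the run end.
    """
    if duration_min <= 0 or switch_period_min <= 0:
        raise ValueError("duration and switch period must be > 0")
    if not 0 <= guard_min < switch_period_min:
        raise ValueError("guard_min must satisfy 0 <= guard < switch_period")
    if first_channel not in ("sample", "reference"):
        raise ValueError(f"unknown channel {first_channel!r}")
    if duration_min < switch_period_min:
        warnings.warn(
            "run shorter than one switch period; single-segment schedule",
            stacklevel=2,
        )
    other = "sample" if first_channel == "reference" else "reference"
    segments = []
    start = 0.0
    k = 0
    while start < duration_min:
        end = min(start + switch_period_min, duration_min)
        segments.append((start, end, first_channel if k % 2 == 0 else other))
        start = end
        k += 1
    return BracketSchedule(
        segments=tuple(segments),
        switch_period_min=switch_period_min,
        guard_min=guard_min,
    )


def segment_blocks(
    records: Sequence[ScanRecord],
    schedule: BracketSchedule,
    specs: Sequence[IsotopologueSpec],
    constants: ProcessingConstants | None = None,
    block_min: float = 15.0,
) -> list[BlockResult]:
    """Cut each schedule segment into consecutive fixed-length blocks.

    Blocks start at the segment's usable start (after the guard) and any
    trailing remainder shorter than ``block_min`` is dropped. Records of
    several fragments are aggregated separately.
    """
    if block_min <= 0:
        raise ValueError("block_min must be > 0")
    constants = constants or ProcessingConstants()
    fragments = sorted({r.fragment_id for r in records})
    blocks: list[BlockResult] = []
    for start, end, channel in schedule.segments:
        u_start, u_end = schedule.usable_window((start, end, channel))
        if u_end - u_start < block_min:
            warnings.warn(
                f"segment [{start}, {end}) shorter than one block after guard "
                "trimming; skipped",
                stacklevel=2,
            )
            continue
        w = u_start
        while w + block_min <= u_end + 1e-9:
            for fragment_id in fragments:
                frag_records = [
                    r
                    for r in records
                    if r.fragment_id == fragment_id and r.channel == channel
                ]
                try:
                    blocks.append(
                        aggregate_block(
                            frag_records, (w, w + block_min), specs, constants
                        )
                    )
                except DegenerateBlockError:
                    warnings.warn(
                        f"no usable {fragment_id} spectra in block "
                        f"[{w}, {w + block_min}) ({channel}); skipped",
                        stacklevel=2,
                    )
            w += block_min
    return blocks


# ---------------------------------------------------------------------------
# delta calculus

def delta_value(r_sample: float, r_reference: float) -> float:
    """delta in permil: 1000 * (R_sample - R_reference) / R_reference."""
    if r_reference <= 0:
        raise ValueError(f"reference ratio must be > 0, got {r_reference}")
    return 1000.0 * (r_sample - r_reference) / r_reference


def delta_diff(delta_sample: float, delta_reference: float) -> float:
    """Delta-delta in permil: sample delta minus reference delta."""
    return delta_sample - delta_reference


def drift_correct(
    sample_blocks: Sequence[BlockResult],
    reference_blocks: Sequence[BlockResult],
    isotopologue: str,
) -> np.ndarray:
    """Per-sample-block Delta-delta (permil) against the drift-interpolated
    reference.

    The reference ratio at each sample block's mid-time is the linear
    interpolation between the ratios of the nearest earlier and later
    reference blocks; any drift that is linear in time between
    consecutive reference blocks therefore cancels exactly.
    """
    if len(reference_blocks) < 2:
        raise ValueError("drift correction needs >= 2 reference blocks")
    ref = sorted(reference_blocks, key=lambda b: b.mid_time)
    ref_t = np.array([b.mid_time for b in ref])
    ref_r = np.array([b.ratios[isotopologue] for b in ref])
    out = np.empty(len(sample_blocks))
    for i, blk in enumerate(sorted(sample_blocks, key=lambda b: b.mid_time)):
        t = blk.mid_time
        if not ref_t[0] <= t <= ref_t[-1]:
            raise ValueError(
                f"sample block [{blk.window[0]}, {blk.window[1]}) at t={t} min "
                "is not bracketed by reference blocks (run must start and end "
                "on the reference channel)"
            )
        r_ref = float(np.interp(t, ref_t, ref_r))
        out[i] = delta_value(blk.ratios[isotopologue], r_ref)
    return out


def reference_residuals(
    reference_blocks: Sequence[BlockResult], isotopologue: str
) -> np.ndarray:
    """Reference block deltas (permil, vs the reference mean ratio) after
    removing their linear time trend.

    The bracketing correction removes drift that is linear between
    reference blocks from the sample side; the reference scatter entering
    the combined uncertainty must therefore also exclude the drift trend,
    leaving counting noise plus nonlinear drift residuals.
    """
    ref = sorted(reference_blocks, key=lambda b: b.mid_time)
    if len(ref) < 2:
        raise ValueError("need >= 2 reference blocks")
    r = np.array([b.ratios[isotopologue] for b in ref])
    t = np.array([b.mid_time for b in ref])
    deltas = 1000.0 * (r - r.mean()) / r.mean()
    coeffs = np.polyfit(t, deltas, 1)
    return deltas - np.polyval(coeffs, t)


# ---------------------------------------------------------------------------
# calibration

@dataclass(frozen=True)
class CalibrationModel:
    """Affine map from measured delta to an assigned reference scale."""

    mode: str  # "one_point" | "two_point"
    slope: float
    intercept_permil: float
    anchors: tuple[tuple[float, float], ...]  # (measured, assigned) permil

    def __post_init__(self) -> None:
        if self.mode not in ("one_point", "two_point"):
            raise ValueError(f"unknown calibration mode {self.mode!r}")
        if not math.isfinite(self.slope):
            raise ValueError("calibration slope must be finite")


def fit_one_point(anchor_measured: float, anchor_assigned: float) -> CalibrationModel:
    """Offset-only calibration: slope 1 through the single anchor."""
    return CalibrationModel(
        mode="one_point",
        slope=1.0,
        intercept_permil=anchor_assigned - anchor_measured,
        anchors=((anchor_measured, anchor_assigned),),
    )


def fit_two_point(
    anchor1: tuple[float, float], anchor2: tuple[float, float]
) -> CalibrationModel:
    """Affine calibration through two anchors; inverts any affine scale
    distortion (e.g. a scale expansion) exactly at and between anchors."""
    (m1, a1), (m2, a2) = anchor1, anchor2
    if m1 == m2:
        raise ValueError(
            "two-point calibration requires anchors with distinct measured values"
        )
    slope = (a2 - a1) / (m2 - m1)
    return CalibrationModel(
        mode="two_point",
        slope=slope,
        intercept_permil=a1 - slope * m1,
        anchors=(anchor1, anchor2),
    )


def calibrate(model: CalibrationModel, measured_delta):
    """Map measured delta(s) in permil onto the assigned scale."""
    measured = np.asarray(measured_delta, dtype=float)
    out = model.slope * measured + model.intercept_permil
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# uncertainty

def combined_ci(
    sample_block_values: Sequence[float],
    reference_block_values: Sequence[float],
    level: float = 0.95,
) -> float:
    """Half-width of the combined confidence interval in permil.

    SE = sqrt(s_s^2/n_s + s_r^2/n_r) with Welch-Satterthwaite degrees of
    freedom and the corresponding two-sided t quantile.
    """
    s = np.asarray(sample_block_values, dtype=float)
    r = np.asarray(reference_block_values, dtype=float)
    if len(s) < 2 or len(r) < 2:
        raise ValueError("combined_ci needs >= 2 blocks on each side")
    vs = s.var(ddof=1) / len(s)
    vr = r.var(ddof=1) / len(r)
    se = math.sqrt(vs + vr)
    if se == 0.0:
        return 0.0
    denom = 0.0
    if vs > 0:
        denom += vs**2 / (len(s) - 1)
    if vr > 0:
        denom += vr**2 / (len(r) - 1)
    df = (vs + vr) ** 2 / denom
    t = stats.t.ppf(0.5 + level / 2.0, df)
    return float(t * se)


def allan_deviation(
    block_series: Sequence[float],
    taus: Sequence[float],
    spacing_min: float = 1.0,
) -> pd.DataFrame:
    """Non-overlapping Allan deviation versus averaging time.

    ``block_series`` are equally spaced values (spacing ``spacing_min``);
    each tau is rounded to a whole number of points, consecutive
    non-overlapping tau-averages y_k are formed, and

        sigma_A(tau) = sqrt( 0.5 * mean( (y_{k+1} - y_k)^2 ) ).

    Taus leaving fewer than two averages are skipped with a warning.
    Locates the optimal integration time: under pure white (counting)
    noise sigma_A falls as tau^(-1/2), until instrument drift takes over.
    """
    y = np.asarray(block_series, dtype=float)
    rows = []
    for tau in taus:
        m = max(1, int(round(tau / spacing_min)))
        n_avg = len(y) // m
        if n_avg < 2:
            warnings.warn(
                f"tau={tau} min needs >= 2 non-overlapping averages; skipped",
                stacklevel=2,
            )
            continue
        means = y[: n_avg * m].reshape(n_avg, m).mean(axis=1)
        sigma = math.sqrt(0.5 * np.mean(np.diff(means) ** 2))
        rows.append({"tau_min": m * spacing_min, "allan_dev": sigma, "n_averages": n_avg})
    return pd.DataFrame(rows, columns=["tau_min", "allan_dev", "n_averages"])


# ---------------------------------------------------------------------------
# small utilities

def mass_dependent_delta33(delta34_permil: float, exponent: float = 0.515) -> float:
    """delta33S expected from delta34S under mass-dependent fractionation:
    1000*((1 + d34/1000)^exponent - 1), conventional exponent 0.515."""
    if delta34_permil <= -1000:
        raise ValueError("delta34 must be > -1000 permil")
    return 1000.0 * ((1.0 + delta34_permil / 1000.0) ** exponent - 1.0)


def exact_mass(spec: IsotopologueSpec) -> float:
    """Theoretical m/z of the isotopologue ion (singly charged).

    Sum of nuclide masses, minus one electron mass for positive ions and
    plus one for negative ions. When the spec carries a nominal mz that
    deviates by more than 0.001, a warning flags the discrepancy (it is
    not forced into agreement).
    """
    mz = nuclides.ion_mz(spec.isotopic_formula, spec.polarity)
    if spec.mz > 0 and abs(mz - spec.mz) > 0.001:
        warnings.warn(
            f"{spec.fragment_id}/{spec.isotopologue}: computed m/z {mz:.4f} "
            f"deviates from nominal {spec.mz:.4f} by more than 0.001",
            stacklevel=2,
        )
    return mz


def substituted_nuclide(
    spec: IsotopologueSpec, base: IsotopologueSpec
) -> str | None:
    """Label of the rare nuclide substituted relative to the basepeak
    (e.g. '13C'), or None for the basepeak itself."""
    base_counts = dict(base.isotopic_formula)
    extra = [
        nuclide
        for nuclide, count in spec.isotopic_formula
        if count > base_counts.get(nuclide, 0)
    ]
    if not extra:
        return None
    return extra[0]


# ---------------------------------------------------------------------------
# results

@dataclass(frozen=True)
class DeltaResult:
    """A delta or Delta-delta value in permil with its uncertainty."""

    element: str
    fragment_id: str
    value_permil: float
    ci95_permil: float
    n_sample_blocks: int
    n_reference_blocks: int
    calibration: str  # raw | drift_corrected | one_point | two_point

    def __post_init__(self) -> None:
        if self.ci95_permil < 0:
            raise ValueError("ci95_permil must be >= 0")
        if self.n_sample_blocks < 1 or self.n_reference_blocks < 1:
            raise ValueError("block counts must be >= 1")


def process_records(
    records: Sequence[ScanRecord],
    specs: Sequence[IsotopologueSpec],
    schedule: BracketSchedule,
    block_min: float = 15.0,
    constants: ProcessingConstants | None = None,
    calibration: CalibrationModel | None = None,
) -> tuple[pd.DataFrame, list[DeltaResult]]:
    """Full bracketed processing of one run.

    Returns a per-block results table (one row per block x rare
    isotopologue) and one drift-corrected :class:`DeltaResult` per
    (fragment, rare isotopologue), optionally mapped through an anchor
    calibration.
    """
    constants = constants or ProcessingConstants()
    blocks = segment_blocks(records, schedule, specs, constants, block_min)
    by_fragment: dict[str, list[BlockResult]] = {}
    for b in blocks:
        by_fragment.setdefault(b.fragment_id, []).append(b)

    rows: list[dict] = []
    results: list[DeltaResult] = []
    cal_state = calibration.mode if calibration is not None else "drift_corrected"
    for fragment_id, frag_blocks in sorted(by_fragment.items()):
        frag_specs = [s for s in specs if s.fragment_id == fragment_id]
        base = next(s for s in frag_specs if s.is_basepeak)
        sample_blocks = [b for b in frag_blocks if b.channel == "sample"]
        reference_blocks = [b for b in frag_blocks if b.channel == "reference"]
        for spec in frag_specs:
            element = substituted_nuclide(spec, base)
            if element is None:
                continue
            iso = spec.isotopologue
            ref_with_iso = [b for b in reference_blocks if iso in b.ratios]
            ref_mean = (
                float(np.mean([b.ratios[iso] for b in ref_with_iso]))
                if ref_with_iso
                else float("nan")
            )
            for b in sorted(frag_blocks, key=lambda b: b.mid_time):
                if iso not in b.ratios:
                    continue
                delta = delta_value(b.ratios[iso], ref_mean) if ref_with_iso else float("nan")
                rse = b.shot_noise_rse.get(iso, float("nan"))
                rows.append(
                    {
                        "fragment_id": fragment_id,
                        "element": element,
                        "block_start_min": b.window[0],
                        "block_end_min": b.window[1],
                        "channel": b.channel,
                        "ratio": b.ratios[iso],
                        "delta_permil": delta,
                        "ci95_permil": 1000.0 * 1.96 * rse,
                        "calibration": "raw",
                    }
                )
            if len(sample_blocks) >= 1 and len(reference_blocks) >= 2:
                dd = drift_correct(sample_blocks, reference_blocks, iso)
                value = float(np.mean(dd))
                ref_deltas = reference_residuals(ref_with_iso, iso)
                if len(dd) >= 2 and len(ref_deltas) >= 2:
                    ci = combined_ci(dd, ref_deltas)
                else:
                    ci = float("nan")
                if calibration is not None:
                    value = calibrate(calibration, value)
                    ci = abs(calibration.slope) * ci
                results.append(
                    DeltaResult(
                        element=element,
                        fragment_id=fragment_id,
                        value_permil=value,
                        ci95_permil=ci if math.isfinite(ci) else 0.0,
                        n_sample_blocks=len(sample_blocks),
                        n_reference_blocks=len(reference_blocks),
                        calibration=cal_state,
                    )
                )
    frame = pd.DataFrame(rows, columns=list(RESULT_COLUMNS))
    return frame, results
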