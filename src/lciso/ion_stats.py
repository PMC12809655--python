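"""Ion counting and isotopologue-ratio aggregation.

The Orbitrap reports a signal intensity S and peak noise N per mass peak
per averaged spectrum. The number of ions observed per scan follows from
the S/N ratio via the empirical proportionality

    N_IO = (S/N) * (C_N / z) * sqrt(R_N / R) * sqrt(mu)

with C_N the empirical S/N-to-ion-count constant, z the charge, R the
nominal resolving power relative to the reference R_N, and mu the number
of microscans averaged into the spectrum. Isotopologue ratios over a
time window are ratios of summed ion counts (rare over basepeak), whose
precision floor is set by Poisson counting statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .scan_model import (
    IsotopologueSpec,
    ProcessingConstants,
    ScanRecord,
    ScanTableError,
)

__all__ = [
    "BlockResult",
    "DegenerateBlockError",
    "aggregate_block",
    "ions_observed",
    "ions_observed_array",
    "shot_noise_limit",
    "sn_from_ions",
]


class DegenerateBlockError(ValueError):
    """A time window without usable basepeak signal (or mixed channels)."""


def ions_observed(record: ScanRecord, constants: ProcessingConstants | None = None) -> float:
    """Number of ions observed in one spectrum for one isotopologue.

    Deterministic conversion of the record's S/N to an (in general
    non-integer) ion count; Poisson statistics enter only through the
    measurement itself, never through this conversion.
    """
    constants = constants or ProcessingConstants()
    if record.peak_noise <= 0:
        raise ScanTableError(f"peak_noise must be > 0, got {record.peak_noise}")
    return float(
        ions_observed_array(
            record.intensity,
            record.peak_noise,
            record.resolution,
            record.microscans,
            record.charge,
            constants,
        )
    )


def ions_observed_array(
    intensity,
    peak_noise,
    resolution,
    microscans,
    charge,
    constants: ProcessingConstants | None = None,
):
    """Vectorized ion-count conversion (see :func:`ions_observed`)."""
    constants = constants or ProcessingConstants()
    intensity = np.asarray(intensity, dtype=float)
    peak_noise = np.asarray(peak_noise, dtype=float)
    resolution = np.asarray(resolution, dtype=float)
    if np.any(peak_noise <= 0):
        raise ScanTableError("peak_noise must be > 0")
    if np.any(resolution <= 0):
        raise ScanTableError("resolution must be > 0")
    microscans = np.asarray(microscans, dtype=float)
    charge = np.asarray(charge, dtype=float)
    sn = intensity / peak_noise
    return sn * (constants.cn / charge) * np.sqrt(constants.rn / resolution) * np.sqrt(microscans)


def sn_from_ions(
    n_io,
    resolution,
    microscans,
    charge=1,
    constants: ProcessingConstants | None = None,
):
    """Signal-to-noise ratio that encodes a given ion count.

    Exact inverse of :func:`ions_observed` (used by the simulator to emit
    scan tables the pipeline decodes); strictly monotone in ``n_io``.
    """
    constants = constants or ProcessingConstants()
    n_io = np.asarray(n_io, dtype=float)
    resolution = np.asarray(resolution, dtype=float)
    microscans = np.asarray(microscans, dtype=float)
    if np.any(n_io < 0):
        raise ValueError("n_io must be >= 0")
    if np.any(resolution <= 0) or np.any(microscans <= 0):
        raise ScanTableError("resolution and microscans must be > 0")
    charge = np.asarray(charge, dtype=float)
    out = n_io * charge / (constants.cn * np.sqrt(constants.rn / resolution) * np.sqrt(microscans))
    return out if out.ndim else float(out)


def shot_noise_limit(summed_rare: float, summed_base: float) -> float:
    """Relative standard error of a ratio of two independent Poisson sums.

    sqrt(1/N_rare + 1/N_base); halves when both counts quadruple.
    Covariance between the two mass peaks is neglected (separate peaks).
    """
    if summed_rare <= 0 or summed_base <= 0:
        raise ValueError("shot_noise_limit requires both summed counts > 0")
    return math.sqrt(1.0 / summed_rare + 1.0 / summed_base)


@dataclass(frozen=True)
class BlockResult:
    """Summed ion counts and isotopologue ratios over one time window."""

    fragment_id: str
    window: tuple[float, float]
    channel: str
    n_spectra: int
    summed_ions: Mapping[str, float]
    ratios: Mapping[str, float]
    shot_noise_rse: Mapping[str, float]

    @property
    def mid_time(self) -> float:
        return 0.5 * (self.window[0] + self.window[1])


def aggregate_block(
    records: Sequence[ScanRecord],
    window: tuple[float, float],
    specs: Sequence[IsotopologueSpec],
    constants: ProcessingConstants | None = None,
) -> BlockResult:
    """Aggregate spectra with time in the half-open window [start, end)
    into summed ion counts and rare/basepeak ratios.

    All in-window records must share one channel and one fragment;
    a straddled channel switch is a schedule error, not silently trimmed.
    """
    constants = constants or ProcessingConstants()
    start, end = window
    if not end > start:
        raise ValueError(f"empty window {window}")
    in_win = [r for r in records if start <= r.time_min < end]
    if not in_win:
        raise DegenerateBlockError(f"no spectra in window [{start}, {end})")
    channels = {r.channel for r in in_win}
    if len(channels) > 1:
        raise DegenerateBlockError(
            f"window [{start}, {end}) mixes channels {sorted(channels)}"
        )
    fragments = {r.fragment_id for r in in_win}
    if len(fragments) > 1:
        raise DegenerateBlockError(
            f"window [{start}, {end}) mixes fragments {sorted(fragments)}"
        )
    fragment_id = in_win[0].fragment_id
    frag_specs = [s for s in specs if s.fragment_id == fragment_id]
    basepeaks = [s.isotopologue for s in frag_specs if s.is_basepeak]
    if len(basepeaks) != 1:
        raise ScanTableError(f"fragment {fragment_id}: need exactly one basepeak spec")
    basepeak = basepeaks[0]

    summed: dict[str, float] = {s.isotopologue: 0.0 for s in frag_specs}
    for r in in_win:
        if r.isotopologue not in summed:
            raise ScanTableError(
                f"record isotopologue {r.isotopologue!r} not defined for {fragment_id}"
            )
        summed[r.isotopologue] += ions_observed(r, constants)
    base_sum = summed[basepeak]
    if base_sum <= 0:
        raise DegenerateBlockError(
            f"window [{start}, {end}): basepeak ion sum is zero"
        )
    ratios = {iso: (1.0 if iso == basepeak else total / base_sum) for iso, total in summed.items()}
    rse = {
        iso: shot_noise_limit(total, base_sum)
        for iso, total in summed.items()
        if total > 0 and iso != basepeak
    }
    n_spectra = len({(r.scan_no, r.channel) for r in in_win})
    return BlockResult(
        fragment_id=fragment_id,
        window=(float(start), float(end)),
        channel=in_win[0].channel,
        n_spectra=n_spectra,
        summed_ions=summed,
        ratios=ratios,
        shot_noise_rse=rse,
    )
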