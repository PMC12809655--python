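"""Forward simulator of the LC -> peak capture -> ESI -> Orbitrap chain.

Generates scan tables (plus a truth log) emulating isotopologue-ratio
measurements of sulfamethoxazole (SMX) fragments, so that every stage of
the processing pipeline can be exercised without instrument data:

* chromatographic isotope fractionation: each isotopologue elutes as a
  Gaussian of common width, the heavier species offset by a signed
  retention shift (positive = more retained, the "normal" effect);
* peak capture in a plug-flow capillary (shape retained, elution order
  reversed at the low flow) or a stirred mixing chamber (instantaneous
  homogenization, washout front by plug displacement + axial dispersion);
* ESI amount-dependency as a concentration-dependent delta bias;
* slow instrument drift (linear + random walk) on the measured ratio;
* AGC-regulated trap fills with Poisson ion-counting noise, encoded back
  to intensity/noise so the pipeline's ion-count conversion decodes them.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .delta_pipeline import build_schedule
from .ion_stats import sn_from_ions
from .nuclides import ion_mz
from .scan_model import (
    IsotopologueSpec,
    ScanRecord,
    write_scan_table,
    write_spec_table,
)

__all__ = [
    "FRAGMENTS",
    "NATURAL_RATIO",
    "Chromatogram",
    "EsiBiasParams",
    "OutletProfile",
    "SimConfig",
    "TruthLog",
    "capture_capillary",
    "capture_chamber",
    "chamber_front",
    "chamber_stability_time_min",
    "default_esi_bias",
    "direct_infusion_profile",
    "esi_bias",
    "fragment_specs",
    "instrument_drift",
    "isotopologue_ratio",
    "linearity_experiment",
    "preset_config",
    "run_experiment",
    "sample_scans",
    "simulate_chromatogram",
]

#: natural rare/abundant atom ratios (IUPAC representative abundances)
NATURAL_RATIO: dict[str, float] = {
    "13C": 0.0107 / 0.9893,
    "15N": 0.00364 / 0.99636,
    "34S": 0.0425 / 0.9499,
    "33S": 0.0075 / 0.9499,
}

# per-fragment definitions: formulas of the tracked isotopologues (singly
# substituted species + basepeak), substitutable atom counts, polarity and
# instrument defaults (resolution per Table-style settings, spectrum period
# from transient-length scaling at 10 microscans)
_FRAGMENT_DEFS: dict[str, dict] = {
    "F99": {
        "polarity": "positive",
        "resolution": 90_000.0,
        "spectrum_period_s": 2.0,
        "formulas": {
            "M0": (("12C", 4), ("1H", 7), ("14N", 2), ("16O", 1)),
            "13C": (("13C", 1), ("12C", 3), ("1H", 7), ("14N", 2), ("16O", 1)),
            "15N": (("12C", 4), ("1H", 7), ("14N", 1), ("15N", 1), ("16O", 1)),
        },
        "n_atoms": {"13C": 4, "15N": 2},
    },
    "F92": {
        "polarity": "negative",
        "resolution": 90_000.0,
        "spectrum_period_s": 2.0,
        "formulas": {
            "M0": (("12C", 6), ("1H", 6), ("14N", 1)),
            "13C": (("13C", 1), ("12C", 5), ("1H", 6), ("14N", 1)),
            "15N": (("12C", 6), ("1H", 6), ("15N", 1)),
        },
        "n_atoms": {"13C": 6, "15N": 1},
    },
    "F64": {
        "polarity": "negative",
        "resolution": 30_000.0,
        "spectrum_period_s": 0.75,
        "formulas": {
            "M0": (("32S", 1), ("16O", 2)),
            "33S": (("33S", 1), ("16O", 2)),
            "34S": (("34S", 1), ("16O", 2)),
        },
        "n_atoms": {"33S": 1, "34S": 1},
    },
}

FRAGMENTS = tuple(_FRAGMENT_DEFS)


def fragment_specs(fragment_id: str) -> list[IsotopologueSpec]:
    """Isotopologue specs (with theoretical m/z) for one SMX fragment."""
    try:
        d = _FRAGMENT_DEFS[fragment_id]
    except KeyError:
        raise ValueError(f"unknown fragment {fragment_id!r}") from None
    specs = []
    for label, formula in d["formulas"].items():
        specs.append(
            IsotopologueSpec(
                fragment_id=fragment_id,
                isotopologue=label,
                isotopic_formula=formula,
                polarity=d["polarity"],
                is_basepeak=(label == "M0"),
                mz=round(ion_mz(formula, d["polarity"]), 4),
            )
        )
    return specs


def isotopologue_ratio(fragment_id: str, isotopologue: str, delta_permil: float = 0.0) -> float:
    """Expected rare/basepeak isotopologue abundance ratio.

    Assumes a stochastic (binomial) isotope distribution, under which the
    singly substituted over unsubstituted ratio equals n_atoms times the
    atom ratio; a sample enrichment delta scales the atom ratio.
    """
    d = _FRAGMENT_DEFS[fragment_id]
    n = d["n_atoms"][isotopologue]
    return n * NATURAL_RATIO[isotopologue] * (1.0 + delta_permil / 1000.0)


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class EsiBiasParams:
    """Concentration-dependent delta bias of one element's ratio."""

    beta_permil: float
    c_lin_uM: float
    c_ref_uM: float = 4.0


_LN8 = math.log(8.0)


def default_esi_bias() -> dict[str, EsiBiasParams]:
    """Default amount-dependency: 13C nonlinear up to 10 uM and ~-65 permil
    at 0.5 uM; 34S linear above 4 uM with at most -9 permil below; 33S mass-
    dependently scaled from 34S; 15N intermediate."""
    return {
        "13C": EsiBiasParams(beta_permil=65.0 / _LN8, c_lin_uM=10.0),
        "15N": EsiBiasParams(beta_permil=30.0 / _LN8, c_lin_uM=10.0),
        "34S": EsiBiasParams(beta_permil=9.0 / _LN8, c_lin_uM=4.0),
        "33S": EsiBiasParams(beta_permil=0.515 * 9.0 / _LN8, c_lin_uM=4.0),
    }


@dataclass
class SimConfig:
    """Full parameterization of one simulated experiment.

    Volumes in uL, flows in uL/min, times as indicated; the capture
    geometry, AGC settings and bracketing cadence default to the values
    of the hyphenated SMX setup (capillary 540 uL at 0.7 mm i.d., mixing
    chamber 1140 uL, high flow 0.5 mL/min, low flow 4 uL/min, AGC target
    1.5e5 charges per fill, 10 microscans, 1000 ms maximum injection,
    20-min valve switching with the run starting and ending on the
    reference).
    """

    fragment_id: str = "F99"
    # injection & chromatography
    injection_volume_uL: float = 40.0
    injection_conc_uM: float = 100.0
    hplc_flow_uL_min: float = 500.0
    low_flow_uL_min: float = 4.0
    peak_center_min: float = 8.0
    peak_sigma_s: float = 15.0
    retention_offset_s: dict[str, float] = field(default_factory=dict)
    # capture device
    capture_mode: str = "chamber"  # capillary | chamber | none
    capillary_volume_uL: float = 540.0
    chamber_volume_uL: float = 1140.0
    chamber_peclet: float = 40.0
    capture_window_s: float = 80.0
    # source & instrument response
    esi_bias_params: dict[str, EsiBiasParams] = field(default_factory=default_esi_bias)
    drift_permil_per_hour: float = 1.0
    drift_walk_permil_sqrt_hour: float = 0.2
    scale_distortion: float = 1.0
    reference_conc_uM: float = 4.0
    agc_target: float = 1.5e5
    max_injection_ms: float = 1000.0
    esi_ions_per_uM_ms: float = 300.0
    spectrum_period_s: float | None = None
    resolution: float | None = None
    microscans: int = 10
    charge: int = 1
    # run structure
    sample_start_min: float = 0.0
    duration_min: float = 180.0
    switch_period_min: float = 20.0
    guard_min: float = 2.0
    bracketing: bool = True
    poisson_noise: bool = True
    seed: int = 0
    # sample material
    true_delta_permil: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "injection_volume_uL",
            "injection_conc_uM",
            "hplc_flow_uL_min",
            "low_flow_uL_min",
            "peak_sigma_s",
            "capillary_volume_uL",
            "chamber_volume_uL",
            "chamber_peclet",
            "capture_window_s",
            "reference_conc_uM",
            "agc_target",
            "max_injection_ms",
            "esi_ions_per_uM_ms",
            "duration_min",
            "switch_period_min",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.capture_mode not in ("capillary", "chamber", "none"):
            raise ValueError(f"unknown capture_mode {self.capture_mode!r}")
        if self.fragment_id not in _FRAGMENT_DEFS:
            raise ValueError(f"unknown fragment {self.fragment_id!r}")

    @property
    def effective_resolution(self) -> float:
        return self.resolution if self.resolution is not None else _FRAGMENT_DEFS[self.fragment_id]["resolution"]

    @property
    def effective_period_s(self) -> float:
        return (
            self.spectrum_period_s
            if self.spectrum_period_s is not None
            else _FRAGMENT_DEFS[self.fragment_id]["spectrum_period_s"]
        )

    @property
    def injected_nmol(self) -> float:
        # uL * uM = pmol; /1000 -> nmol
        return self.injection_volume_uL * self.injection_conc_uM / 1000.0

    def specs(self) -> list[IsotopologueSpec]:
        return fragment_specs(self.fragment_id)

    def rare_isotopologues(self) -> list[str]:
        return list(_FRAGMENT_DEFS[self.fragment_id]["n_atoms"])


class CaptureOverflowError(ValueError):
    """Captured volume exceeds the capture device capacity."""


# ---------------------------------------------------------------------------
# chromatography

@dataclass
class Chromatogram:
    """Per-isotopologue analyte flux (nmol/s) vs time (s) at column outlet."""

    t_s: np.ndarray
    flux_nmol_s: dict[str, np.ndarray]

    def total_flux(self) -> np.ndarray:
        return np.sum(list(self.flux_nmol_s.values()), axis=0)


def simulate_chromatogram(config: SimConfig) -> Chromatogram:
    """Gaussian elution of each isotopologue with a common peak width.

    Isotopologue i is centered at t_center + retention_offset(i) (positive
    offset = heavier species more retained), with area equal to injected
    moles times its abundance fraction (natural abundance adjusted by the
    sample's true enrichment). The instantaneous heavy/light log-ratio is
    then linear in time with slope offset/sigma^2.
    """
    if config.peak_sigma_s <= 0:
        raise ValueError("peak_sigma_s must be > 0")
    sigma = config.peak_sigma_s
    tc = config.peak_center_min * 60.0
    offsets = {iso: config.retention_offset_s.get(iso, 0.0) for iso in config.rare_isotopologues()}
    offsets["M0"] = config.retention_offset_s.get("M0", 0.0)
    max_off = max(abs(v) for v in offsets.values())
    dt = sigma / 200.0
    t = np.arange(tc - 6.0 * sigma - max_off, tc + 6.0 * sigma + max_off + dt, dt)

    ratios = {
        iso: isotopologue_ratio(
            config.fragment_id, iso, config.true_delta_permil.get(iso, 0.0)
        )
        for iso in config.rare_isotopologues()
    }
    denom = 1.0 + sum(ratios.values())
    fractions = {"M0": 1.0 / denom}
    fractions.update({iso: r / denom for iso, r in ratios.items()})

    flux = {}
    for iso, frac in fractions.items():
        area = config.injected_nmol * frac
        center = tc + offsets[iso]
        flux[iso] = area * np.exp(-0.5 * ((t - center) / sigma) ** 2) / (sigma * math.sqrt(2.0 * math.pi))
    return Chromatogram(t_s=t, flux_nmol_s=flux)


# ---------------------------------------------------------------------------
# capture devices

@dataclass
class OutletProfile:
    """Per-isotopologue concentration (uM) vs time (min) at the low-flow
    inlet of the ion source, measured from the start of low-flow elution."""

    t_min: np.ndarray
    conc_uM: dict[str, np.ndarray]

    def conc_at(self, t_min) -> dict[str, np.ndarray]:
        t = np.asarray(t_min, dtype=float)
        return {
            iso: np.interp(t, self.t_min, c, left=0.0, right=0.0)
            for iso, c in self.conc_uM.items()
        }

    def captured_nmol(self, low_flow_uL_min: float) -> dict[str, float]:
        return {
            iso: float(np.trapezoid(c, self.t_min)) * low_flow_uL_min / 1000.0
            for iso, c in self.conc_uM.items()
        }


def _capture_window(config: SimConfig) -> tuple[float, float]:
    tc = config.peak_center_min * 60.0
    half = config.capture_window_s / 2.0
    return (tc - half, tc + half)


def capture_capillary(chrom: Chromatogram, config: SimConfig) -> OutletProfile:
    """Plug-flow capture: the slug loaded at the high flow is eluted
    time-reversed at the low flow (last-captured fluid reaches the source
    first), with times stretched by the flow ratio. Peak shape and
    intra-peak isotope gradients are retained; total moles are conserved.
    """
    t0, t1 = _capture_window(config)
    slug_uL = (t1 - t0) / 60.0 * config.hplc_flow_uL_min
    if slug_uL > config.capillary_volume_uL:
        raise CaptureOverflowError(
            f"capture window loads {slug_uL:.0f} uL but the capillary holds "
            f"{config.capillary_volume_uL:.0f} uL"
        )
    stretch = config.hplc_flow_uL_min / config.low_flow_uL_min
    duration_min = (t1 - t0) / 60.0 * stretch
    # dense grid over the elution; map outlet time back to column time
    # (fine enough that trapezoid quadrature conserves moles to < 1e-6)
    n = max(int((t1 - t0) / (config.peak_sigma_s / 200.0)), 500)
    t_out = np.linspace(0.0, duration_min, n)
    t_col = t1 - t_out * 60.0 / stretch  # reversed order
    conc = {}
    q_uL_s = config.hplc_flow_uL_min / 60.0
    for iso, f in chrom.flux_nmol_s.items():
        flux_at = np.interp(t_col, chrom.t_s, f, left=0.0, right=0.0)
        conc[iso] = 1000.0 * flux_at / q_uL_s  # nmol/s / (uL/s) -> mM -> uM
    return OutletProfile(t_min=t_out, conc_uM=conc)


def chamber_front(t_min, config: SimConfig) -> np.ndarray:
    """Chamber washout front C(t)/C0 = Phi((tau - t)/sigma_t), the plug-
    displacement + axial-dispersion model with tau = V/Q and
    sigma_t = tau*sqrt(2/Pe)."""
    tau = config.chamber_volume_uL / config.low_flow_uL_min
    sigma_t = tau * math.sqrt(2.0 / config.chamber_peclet)
    return stats.norm.cdf((tau - np.asarray(t_min, dtype=float)) / sigma_t)


def chamber_stability_time_min(config: SimConfig, threshold: float = 0.95) -> float:
    """First elution time (min) at which the chamber outlet TIC falls
    below ``threshold`` of its plateau."""
    tau = config.chamber_volume_uL / config.low_flow_uL_min
    sigma_t = tau * math.sqrt(2.0 / config.chamber_peclet)
    f = lambda t: float(chamber_front(t, config)) - threshold
    return float(optimize.brentq(f, 0.0, tau + 10.0 * sigma_t))


def capture_chamber(chrom: Chromatogram, config: SimConfig) -> OutletProfile:
    """Stirred-chamber capture: all analyte entering during the capture
    window is homogenized instantaneously (1-min stir) at capture end, so
    outlet isotopologue ratios are constant for the whole elution; the
    total concentration follows the dispersed plug-displacement front."""
    t0, t1 = _capture_window(config)
    mask_t = chrom.t_s
    captured = {}
    for iso, f in chrom.flux_nmol_s.items():
        sel = (mask_t >= t0) & (mask_t <= t1)
        captured[iso] = float(np.trapezoid(np.where(sel, f, 0.0), mask_t))
    c0 = {iso: 1000.0 * m / config.chamber_volume_uL for iso, m in captured.items()}
    tau = config.chamber_volume_uL / config.low_flow_uL_min
    sigma_t = tau * math.sqrt(2.0 / config.chamber_peclet)
    t_end = tau + 5.0 * sigma_t
    t = np.linspace(0.0, t_end, max(int(t_end), 200))
    front = chamber_front(t, config)
    conc = {iso: c * front for iso, c in c0.items()}
    return OutletProfile(t_min=t, conc_uM=conc)


def direct_infusion_profile(config: SimConfig) -> OutletProfile:
    """No column, no capture: the injected plug is delivered at constant
    concentration for injection_volume/low_flow minutes (e.g. 80 uL at
    4 uL/min -> 20 min of usable data)."""
    usable_min = config.injection_volume_uL / config.low_flow_uL_min
    ratios = {
        iso: isotopologue_ratio(
            config.fragment_id, iso, config.true_delta_permil.get(iso, 0.0)
        )
        for iso in config.rare_isotopologues()
    }
    denom = 1.0 + sum(ratios.values())
    t = np.linspace(0.0, usable_min, max(int(usable_min * 10), 20))
    conc = {"M0": np.full_like(t, config.injection_conc_uM / denom)}
    for iso, r in ratios.items():
        conc[iso] = np.full_like(t, config.injection_conc_uM * r / denom)
    return OutletProfile(t_min=t, conc_uM=conc)


# ---------------------------------------------------------------------------
# source & instrument response

def esi_bias(concentration_uM: float, element: str, params: Mapping[str, EsiBiasParams]) -> float:
    """Concentration-dependent delta bias (permil) of an element's ratio.

    bias(c) = beta * ln(min(c, c_lin)/c_ref): logarithmic amount-
    dependency below the linear threshold, constant above it, zero at the
    reference concentration. Elements without parameters get no bias.
    """
    if concentration_uM <= 0:
        raise ValueError("concentration must be > 0")
    p = params.get(element)
    if p is None:
        return 0.0
    return p.beta_permil * math.log(min(concentration_uM, p.c_lin_uM) / p.c_ref_uM)


def _esi_bias_array(conc: np.ndarray, element: str, params: Mapping[str, EsiBiasParams]) -> np.ndarray:
    p = params.get(element)
    if p is None:
        return np.zeros_like(conc)
    out = np.zeros_like(conc)
    pos = conc > 0
    out[pos] = p.beta_permil * np.log(np.minimum(conc[pos], p.c_lin_uM) / p.c_ref_uM)
    return out


def instrument_drift(
    t_min: np.ndarray,
    linear_permil_per_hour: float,
    walk_permil_sqrt_hour: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Multiplicative drift factor on the measured ratio at times t_min.

    factor = 1 + (d_lin * t_h + random_walk(t_h)) / 1000, the walk being a
    Brownian path with standard deviation walk*sqrt(t_h); reproducible
    under a seeded generator.
    """
    t = np.asarray(t_min, dtype=float)
    t_h = t / 60.0
    drift_permil = linear_permil_per_hour * t_h
    if walk_permil_sqrt_hour > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        dt = np.diff(t_h, prepend=0.0)
        steps = rng.standard_normal(len(t)) * walk_permil_sqrt_hour * np.sqrt(np.maximum(dt, 0.0))
        drift_permil = drift_permil + np.cumsum(steps)
    return 1.0 + drift_permil / 1000.0


# ---------------------------------------------------------------------------
# scan generation

def sample_scans(
    outlet_profile: OutletProfile,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[ScanRecord]:
    """Generate the scan records of one (optionally bracketed) run.

    Per spectrum the expected trap content is min(AGC target, source-rate
    x maximum injection time) ions per microscan fill, times the number of
    microscans, split across isotopologues by the instantaneous source
    composition modified by ESI bias, scale distortion and drift; counts
    are drawn Poisson (unless noise is disabled) and encoded to intensity
    at fixed peak noise 1.0 so that the ion-count conversion decodes them
    exactly. The reference channel measures the constant syringe solution
    at natural abundance through the same drift trace.
    """
    if config.effective_period_s <= 0:
        raise ValueError("spectrum period must be > 0")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    period_min = config.effective_period_s / 60.0
    duration = config.duration_min
    if not config.bracketing:
        duration = min(
            duration, float(outlet_profile.t_min[-1]) + config.sample_start_min
        )
    times = np.arange(period_min / 2.0, duration, period_min)
    n_spec = len(times)

    if config.bracketing:
        schedule = build_schedule(
            config.duration_min, config.switch_period_min, "reference", config.guard_min
        )
        channel = np.empty(n_spec, dtype=object)
        for start, end, ch in schedule.segments:
            channel[(times >= start) & (times < end)] = ch
    else:
        channel = np.full(n_spec, "sample", dtype=object)

    rare = config.rare_isotopologues()
    # elution clock of the sample profile may be offset from the run clock
    # (e.g. an injection timed to reach the source at a valve switch)
    sample_conc = outlet_profile.conc_at(times - config.sample_start_min)
    nat = {iso: isotopologue_ratio(config.fragment_id, iso, 0.0) for iso in rare}
    ref_denom = 1.0 + sum(nat.values())

    conc = {}
    is_sample = channel == "sample"
    for iso in ["M0", *rare]:
        if iso == "M0":
            ref_c = config.reference_conc_uM / ref_denom
        else:
            ref_c = config.reference_conc_uM * nat[iso] / ref_denom
        conc[iso] = np.where(is_sample, sample_conc[iso], ref_c)
    c_tot = np.sum([conc[i] for i in conc], axis=0)

    drift = instrument_drift(
        times, config.drift_permil_per_hour, config.drift_walk_permil_sqrt_hour, rng
    )

    # expected total ions per spectrum: AGC-capped fill x microscans
    rate_per_ms = config.esi_ions_per_uM_ms * c_tot
    with np.errstate(divide="ignore"):
        fill_ms = np.where(
            rate_per_ms > 0,
            np.minimum(config.max_injection_ms, config.agc_target / np.where(rate_per_ms > 0, rate_per_ms, 1.0)),
            0.0,
        )
    n_total = rate_per_ms * fill_ms * config.microscans

    # measured ratios: composition x (1 + bias/1000), distorted about the
    # natural ratio, then multiplied by the drift factor
    ratio = {}
    for iso in rare:
        with np.errstate(divide="ignore", invalid="ignore"):
            r0 = np.where(conc["M0"] > 0, conc[iso] / np.where(conc["M0"] > 0, conc["M0"], 1.0), 0.0)
        bias = _esi_bias_array(c_tot, iso, config.esi_bias_params)
        r1 = r0 * (1.0 + bias / 1000.0)
        if config.scale_distortion != 1.0:
            r1 = nat[iso] + config.scale_distortion * (r1 - nat[iso])
        ratio[iso] = r1 * drift

    denom = 1.0 + np.sum([ratio[i] for i in rare], axis=0)
    expected = {"M0": n_total / denom}
    for iso in rare:
        expected[iso] = expected["M0"] * ratio[iso]

    counts = {}
    for iso, mu in expected.items():
        if config.poisson_noise:
            counts[iso] = rng.poisson(mu).astype(float)
        else:
            counts[iso] = mu

    resolution = config.effective_resolution
    records: list[ScanRecord] = []
    for iso in ["M0", *rare]:
        intensity = sn_from_ions(
            counts[iso], resolution, config.microscans, config.charge
        )
        for k in range(n_spec):
            records.append(
                ScanRecord(
                    time_min=float(times[k]),
                    scan_no=k + 1,
                    fragment_id=config.fragment_id,
                    isotopologue=iso,
                    intensity=float(np.atleast_1d(intensity)[k]),
                    peak_noise=1.0,
                    resolution=resolution,
                    microscans=config.microscans,
                    charge=config.charge,
                    channel=str(channel[k]),
                )
            )
    records.sort(key=lambda r: (r.scan_no, r.isotopologue))
    return records


# ---------------------------------------------------------------------------
# experiment assembly

@dataclass
class TruthLog:
    """Ground truth of one simulated experiment, sufficient to compute the
    expected pipeline output analytically."""

    seed: int
    fragment_id: str
    injected_nmol: float
    captured_nmol: dict[str, float]
    true_delta_permil: dict[str, float]
    natural_ratio: dict[str, float]
    c0_uM: float | None
    config: dict

    def to_file(self, path: str | os.PathLike) -> None:
        lines = []
        for key, value in (
            ("seed", self.seed),
            ("fragment_id", self.fragment_id),
            ("injected_nmol", self.injected_nmol),
            ("captured_nmol", self.captured_nmol),
            ("true_delta_permil", self.true_delta_permil),
            ("natural_ratio", self.natural_ratio),
            ("c0_uM", self.c0_uM),
            ("config", self.config),
        ):
            lines.append(f"{key} = {json.dumps(value, sort_keys=True)}")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "TruthLog":
        values = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                key, _, raw = line.partition(" = ")
                values[key] = json.loads(raw)
        return cls(**values)


def _outlet_profile(config: SimConfig) -> tuple[OutletProfile, float | None]:
    if config.capture_mode == "none":
        return direct_infusion_profile(config), None
    chrom = simulate_chromatogram(config)
    if config.capture_mode == "capillary":
        return capture_capillary(chrom, config), None
    profile = capture_chamber(chrom, config)
    c0 = float(sum(c[0] for c in profile.conc_uM.values()))
    return profile, c0


def _config_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["esi_bias_params"] = {
        el: asdict(p) for el, p in config.esi_bias_params.items()
    }
    return d


def run_experiment(
    config: SimConfig, out_dir: str | os.PathLike | None = None
) -> tuple[list[ScanRecord], TruthLog]:
    """Compose chromatography, capture, source response and scan
    generation into one simulated run; optionally write the scan table,
    sidecar spec table and truth log to ``out_dir``."""
    rng = np.random.default_rng(config.seed)
    profile, c0 = _outlet_profile(config)
    records = sample_scans(profile, config, rng)
    truth = TruthLog(
        seed=config.seed,
        fragment_id=config.fragment_id,
        injected_nmol=config.injected_nmol,
        captured_nmol=profile.captured_nmol(config.low_flow_uL_min),
        true_delta_permil=dict(config.true_delta_permil),
        natural_ratio={
            iso: isotopologue_ratio(config.fragment_id, iso, 0.0)
            for iso in config.rare_isotopologues()
        },
        c0_uM=c0,
        config=_config_dict(config),
    )
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        write_scan_table(records, os.path.join(out_dir, "scans.tsv"))
        write_spec_table(config.specs(), os.path.join(out_dir, "isotopologues.tsv"))
        truth.to_file(os.path.join(out_dir, "truth.txt"))
    return records, truth


def linearity_experiment(
    concentrations_uM: Sequence[float],
    reps: int,
    config: SimConfig,
) -> "pd.DataFrame":
    """Direct-infusion amount-dependency experiment.

    Each concentration is infused ``reps`` times (no column, no capture),
    bracketed by the reference concentration, and the drift-corrected
    Delta-delta per element is recorded; returns a tidy table plus can be
    summarized per concentration per element (mean, sd, n).
    """
    import pandas as pd

    from .delta_pipeline import drift_correct, segment_blocks

    if reps < 2:
        raise ValueError("reps must be >= 2")
    rows = []
    specs = config.specs()
    base_seed = np.random.SeedSequence(config.seed)
    children = base_seed.spawn(len(concentrations_uM) * reps)
    for ci, conc in enumerate(concentrations_uM):
        for rep in range(reps):
            seed = int(children[ci * reps + rep].generate_state(1)[0] % (2**31))
            run_cfg = SimConfig(
                **{
                    **_config_dict(config),
                    "capture_mode": "none",
                    "injection_conc_uM": conc,
                    "injection_volume_uL": 80.0,
                    "duration_min": 60.0,
                    "sample_start_min": 20.0,
                    "bracketing": True,
                    "seed": seed,
                    "esi_bias_params": config.esi_bias_params,
                }
            )
            records, _ = run_experiment(run_cfg)
            schedule = build_schedule(
                run_cfg.duration_min, run_cfg.switch_period_min, "reference", run_cfg.guard_min
            )
            blocks = segment_blocks(records, schedule, specs, block_min=15.0)
            sample_blocks = [b for b in blocks if b.channel == "sample"]
            reference_blocks = [b for b in blocks if b.channel == "reference"]
            for iso in run_cfg.rare_isotopologues():
                dd = drift_correct(sample_blocks, reference_blocks, iso)
                rows.append(
                    {
                        "element": iso,
                        "concentration_uM": conc,
                        "rep": rep + 1,
                        "ddelta_permil": float(np.mean(dd)),
                    }
                )
    frame = pd.DataFrame(rows)
    return frame


def summarize_linearity(frame: "pd.DataFrame") -> "pd.DataFrame":
    """Mean, standard deviation and n of Delta-delta per concentration
    per element."""
    return (
        frame.groupby(["element", "concentration_uM"])["ddelta_permil"]
        .agg(mean_ddelta_permil="mean", sd_permil="std", n="count")
        .reset_index()
    )


# ---------------------------------------------------------------------------
# scenario presets

def preset_config(name: str, fragment_id: str | None = None, seed: int = 0, **overrides) -> SimConfig:
    """Named scenario configurations.

    linearity - direct infusion, amount-dependency defaults (F99);
    capillary - captured peak with a normal 34S retention offset (F64),
                +-2 sigma capture window, bias/drift off, unbracketed;
    chamber   - homogenized 40 uL x 100 uM injection, bracketed (F99);
    accuracy  - chamber scenario with a 13C-enriched sample (F99).
    """
    if name == "linearity":
        cfg = dict(
            fragment_id=fragment_id or "F99",
            capture_mode="none",
            injection_volume_uL=80.0,
            duration_min=60.0,
        )
    elif name == "capillary":
        cfg = dict(
            fragment_id=fragment_id or "F64",
            capture_mode="capillary",
            injection_volume_uL=20.0,
            injection_conc_uM=100.0,
            capture_window_s=60.0,
            retention_offset_s={"34S": 0.075},
            esi_bias_params={},
            drift_permil_per_hour=0.0,
            drift_walk_permil_sqrt_hour=0.0,
            bracketing=False,
        )
    elif name == "chamber":
        cfg = dict(
            fragment_id=fragment_id or "F99",
            capture_mode="chamber",
            injection_volume_uL=40.0,
            injection_conc_uM=100.0,
            duration_min=180.0,
        )
    elif name == "accuracy":
        cfg = dict(
            fragment_id=fragment_id or "F99",
            capture_mode="chamber",
            injection_volume_uL=40.0,
            injection_conc_uM=100.0,
            duration_min=180.0,
            true_delta_permil={"13C": 18.2},
        )
    else:
        raise ValueError(f"unknown preset {name!r}")
    cfg.update(overrides)
    cfg["seed"] = seed
    return SimConfig(**cfg)
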