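"""Domain types for scan-level Orbitrap isotopologue data and the
tab-separated scan-table dialect shared by the processing pipeline and
the simulator.

A scan table holds one row per (averaged spectrum x isotopologue) with
the intensity, peak noise, resolution, microscan and charge metadata
needed for ion counting, plus a ``channel`` column recording whether the
spectrum measured the sample or the bracketing reference (the position
of the reference-bracketing valve, which is not recoverable from the
spectra themselves). An optional sidecar table defines the isotopologue
species of each fragment.
"""

from __future__ import annotations

import io
import math
import os
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CHANNELS",
    "POLARITIES",
    "SCAN_COLUMNS",
    "SPEC_COLUMNS",
    "IsotopologueSpec",
    "ProcessingConstants",
    "ScanRecord",
    "ScanTableError",
    "ValidationReport",
    "read_scan_table",
    "read_spec_table",
    "records_to_frame",
    "frame_to_records",
    "validate_records",
    "validate_specs",
    "write_scan_table",
    "write_spec_table",
    "parse_isotopic_formula",
    "format_isotopic_formula",
]

CHANNELS = ("sample", "reference")
POLARITIES = ("positive", "negative")

SCAN_COLUMNS = (
    "time_min",
    "scan_no",
    "fragment_id",
    "isotopologue",
    "intensity",
    "peak_noise",
    "resolution",
    "microscans",
    "charge",
    "channel",
)

SPEC_COLUMNS = (
    "fragment_id",
    "isotopologue",
    "isotopic_formula",
    "polarity",
    "is_basepeak",
    "mz",
)


class ScanTableError(ValueError):
    """Raised for malformed scan tables or records violating invariants."""


@dataclass(frozen=True)
class IsotopologueSpec:
    """One isotopic species of a fragment ion.

    ``isotopic_formula`` is a tuple of (nuclide, count) pairs, e.g.
    ``(("13C", 1), ("12C", 3), ("1H", 7), ("14N", 2), ("16O", 1))``.
    The species containing only the most abundant isotopes is the
    basepeak and serves as the ratio denominator.
    """

    fragment_id: str
    isotopologue: str
    isotopic_formula: tuple[tuple[str, int], ...]
    polarity: str
    is_basepeak: bool
    mz: float

    def __post_init__(self) -> None:
        if self.polarity not in POLARITIES:
            raise ScanTableError(
                f"polarity must be one of {POLARITIES}, got {self.polarity!r}"
            )
        if self.mz <= 0:
            raise ScanTableError(f"mz must be > 0, got {self.mz}")
        for nuclide, count in self.isotopic_formula:
            if count < 1:
                raise ScanTableError(
                    f"nuclide count must be >= 1, got {nuclide}{count}"
                )


@dataclass(frozen=True)
class ScanRecord:
    """One averaged spectrum's measurement of one isotopologue."""

    time_min: float
    scan_no: int
    fragment_id: str
    isotopologue: str
    intensity: float
    peak_noise: float
    resolution: float
    microscans: int
    charge: int
    channel: str

    def __post_init__(self) -> None:
        problems = _record_problems(self)
        if problems:
            raise ScanTableError("; ".join(problems))


@dataclass(frozen=True)
class ProcessingConstants:
    """Constants of the signal-to-noise -> ion-count conversion.

    ``cn`` is the empirical constant relating S/N to the number of ions
    (default 3), ``rn`` the reference resolving power (default 240,000)
    at which that constant was determined.
    """

    cn: float = 3.0
    rn: float = 240_000.0

    def __post_init__(self) -> None:
        if self.cn <= 0 or self.rn <= 0:
            raise ScanTableError("cn and rn must both be > 0")


def _record_problems(rec: ScanRecord) -> list[str]:
    problems = []
    if not math.isfinite(rec.time_min):
        problems.append(f"time_min not finite ({rec.time_min})")
    if rec.intensity < 0 or not math.isfinite(rec.intensity):
        problems.append(f"intensity must be >= 0, got {rec.intensity}")
    if rec.peak_noise <= 0 or not math.isfinite(rec.peak_noise):
        problems.append(f"peak_noise must be > 0, got {rec.peak_noise}")
    if rec.resolution <= 0:
        problems.append(f"resolution must be > 0, got {rec.resolution}")
    if rec.microscans < 1:
        problems.append(f"microscans must be >= 1, got {rec.microscans}")
    if rec.charge < 1:
        problems.append(f"charge must be >= 1, got {rec.charge}")
    if rec.channel not in CHANNELS:
        problems.append(f"channel must be one of {CHANNELS}, got {rec.channel!r}")
    return problems


# ---------------------------------------------------------------------------
# isotopic formula serialization ("13C1 12C3 1H7 14N2 16O1")

def parse_isotopic_formula(text: str) -> tuple[tuple[str, int], ...]:
    """Parse a whitespace-separated nuclide-count formula string."""
    parts = []
    for token in text.split():
        i = len(token)
        while i > 0 and token[i - 1].isdigit():
            i -= 1
        # nuclide itself starts with digits (mass number), so split at the
        # last run of digits that follows a letter
        j = i
        if j == len(token) or j == 0 or not token[j - 1].isalpha():
            raise ScanTableError(f"cannot parse formula token {token!r}")
        parts.append((token[:j], int(token[j:])))
    if not parts:
        raise ScanTableError("empty isotopic formula")
    return tuple(parts)


def format_isotopic_formula(formula: Sequence[tuple[str, int]]) -> str:
    return " ".join(f"{nuclide}{count}" for nuclide, count in formula)


# ---------------------------------------------------------------------------
# scan table I/O

def records_to_frame(records: Iterable[ScanRecord]) -> pd.DataFrame:
    """Pack records into a DataFrame with the canonical column order."""
    records = list(records)
    return pd.DataFrame(
        {
            "time_min": [r.time_min for r in records],
            "scan_no": pd.array([r.scan_no for r in records], dtype="int64"),
            "fragment_id": [r.fragment_id for r in records],
            "isotopologue": [r.isotopologue for r in records],
            "intensity": [r.intensity for r in records],
            "peak_noise": [r.peak_noise for r in records],
            "resolution": [r.resolution for r in records],
            "microscans": pd.array([r.microscans for r in records], dtype="int64"),
            "charge": pd.array([r.charge for r in records], dtype="int64"),
            "channel": [r.channel for r in records],
        }
    )


def frame_to_records(frame: pd.DataFrame) -> list[ScanRecord]:
    """Unpack a DataFrame (canonical columns) into validated records.

    Rows violating record invariants are collected and reported together
    with their 1-based data-row numbers.
    """
    missing = [c for c in SCAN_COLUMNS if c not in frame.columns]
    if missing:
        raise ScanTableError(f"missing mandatory column(s): {', '.join(missing)}")
    records: list[ScanRecord] = []
    bad: list[str] = []
    for row_no, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            records.append(
                ScanRecord(
                    time_min=float(row.time_min),
                    scan_no=int(row.scan_no),
                    fragment_id=str(row.fragment_id),
                    isotopologue=str(row.isotopologue),
                    intensity=float(row.intensity),
                    peak_noise=float(row.peak_noise),
                    resolution=float(row.resolution),
                    microscans=int(row.microscans),
                    charge=int(row.charge),
                    channel=str(row.channel),
                )
            )
        except (ScanTableError, ValueError, TypeError) as exc:
            bad.append(f"row {row_no}: {exc}")
    if bad:
        raise ScanTableError("invalid scan-table rows:\n" + "\n".join(bad))
    return records


def read_scan_table(path: str | os.PathLike | io.IOBase) -> list[ScanRecord]:
    """Read a tab-separated scan table into validated ScanRecords.

    File ordering is preserved. Raises :class:`ScanTableError` naming the
    offending column for missing columns, or the offending row(s) for
    non-numeric cells and invariant violations.
    """
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ScanTableError("scan table is empty (no header row)") from None
    return frame_to_records(frame)


_FLOAT_COLS = ("time_min", "intensity", "peak_noise", "resolution")


def write_scan_table(records: Sequence[ScanRecord], path: str | os.PathLike) -> None:
    """Write records as a tab-separated scan table (UTF-8, '.' decimals).

    Reals are serialized with repr round-trip precision so that
    ``read_scan_table(write_scan_table(x)) == x``.
    """
    records = list(records)
    if not records:
        raise ScanTableError("refusing to write an empty scan table")
    lines = ["\t".join(SCAN_COLUMNS)]
    for r in records:
        lines.append(
            "\t".join(
                (
                    repr(float(r.time_min)),
                    str(int(r.scan_no)),
                    r.fragment_id,
                    r.isotopologue,
                    repr(float(r.intensity)),
                    repr(float(r.peak_noise)),
                    repr(float(r.resolution)),
                    str(int(r.microscans)),
                    str(int(r.charge)),
                    r.channel,
                )
            )
        )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def write_spec_table(specs: Sequence[IsotopologueSpec], path: str | os.PathLike) -> None:
    """Write the sidecar isotopologue-definition table."""
    if not specs:
        raise ScanTableError("refusing to write an empty spec table")
    lines = ["\t".join(SPEC_COLUMNS)]
    for s in specs:
        lines.append(
            "\t".join(
                (
                    s.fragment_id,
                    s.isotopologue,
                    format_isotopic_formula(s.isotopic_formula),
                    s.polarity,
                    "true" if s.is_basepeak else "false",
                    repr(float(s.mz)),
                )
            )
        )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_spec_table(path: str | os.PathLike | io.IOBase) -> list[IsotopologueSpec]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SPEC_COLUMNS if c not in frame.columns]
    if missing:
        raise ScanTableError(f"missing mandatory column(s): {', '.join(missing)}")
    specs = [
        IsotopologueSpec(
            fragment_id=row.fragment_id,
            isotopologue=row.isotopologue,
            isotopic_formula=parse_isotopic_formula(row.isotopic_formula),
            polarity=row.polarity,
            is_basepeak=row.is_basepeak.lower() in ("true", "1", "yes"),
            mz=float(row.mz),
        )
        for row in frame.itertuples(index=False)
    ]
    validate_specs(specs)
    return specs


def validate_specs(specs: Sequence[IsotopologueSpec]) -> None:
    """Check cross-spec invariants: exactly one basepeak per fragment and
    a single polarity per fragment."""
    by_fragment: dict[str, list[IsotopologueSpec]] = defaultdict(list)
    for s in specs:
        by_fragment[s.fragment_id].append(s)
    for fragment_id, group in by_fragment.items():
        n_base = sum(s.is_basepeak for s in group)
        if n_base != 1:
            raise ScanTableError(
                f"fragment {fragment_id}: expected exactly one basepeak spec, "
                f"found {n_base}"
            )
        if len({s.polarity for s in group}) != 1:
            raise ScanTableError(f"fragment {fragment_id}: mixed polarities")
        labels = [s.isotopologue for s in group]
        if len(set(labels)) != len(labels):
            raise ScanTableError(f"fragment {fragment_id}: duplicate isotopologue labels")


# ---------------------------------------------------------------------------
# diagnostics

@dataclass
class ValidationReport:
    """Diagnostics over a record collection; always produced, never raises."""

    n_records: int
    coverage: dict[str, dict[str, int]]  # fragment -> isotopologue -> n rows
    channel_counts: dict[str, int]
    monotonicity_violations: list[tuple[str, int]] = field(default_factory=list)
    coverage_gaps: list[str] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not self.monotonicity_violations and not self.coverage_gaps

    def summary(self) -> str:
        verdict = "clean" if self.clean else "dirty"
        lines = [f"{self.n_records} records, verdict: {verdict}"]
        for frag, cov in sorted(self.coverage.items()):
            cov_txt = ", ".join(f"{iso}: {n}" for iso, n in sorted(cov.items()))
            lines.append(f"  {frag}: {cov_txt}")
        lines.append(
            "  channels: "
            + ", ".join(f"{ch}: {n}" for ch, n in sorted(self.channel_counts.items()))
        )
        for ch, scan_no in self.monotonicity_violations:
            lines.append(f"  time reversal in channel {ch} at scan_no {scan_no}")
        for gap in self.coverage_gaps:
            lines.append(f"  coverage gap: {gap}")
        return "\n".join(lines)


def validate_records(
    records: Sequence[ScanRecord],
    specs: Sequence[IsotopologueSpec] | None = None,
) -> ValidationReport:
    """Diagnose per-fragment isotopologue coverage, channel balance and
    time monotonicity. When ``specs`` is given, isotopologues defined there
    but absent from the records are flagged as coverage gaps."""
    coverage: dict[str, dict[str, int]] = defaultdict(Counter)
    channel_counts: Counter = Counter()
    last_time: dict[tuple[str, str], tuple[float, int]] = {}
    violations: list[tuple[str, int]] = []
    for r in records:
        coverage[r.fragment_id][r.isotopologue] += 1
        channel_counts[r.channel] += 1
        key = (r.channel, r.isotopologue)
        if key in last_time:
            prev_t, _prev_no = last_time[key]
            if r.time_min <= prev_t:
                violations.append((r.channel, r.scan_no))
        last_time[key] = (r.time_min, r.scan_no)
    gaps: list[str] = []
    if specs is not None:
        for s in specs:
            if coverage.get(s.fragment_id, {}).get(s.isotopologue, 0) == 0:
                gaps.append(f"{s.fragment_id}/{s.isotopologue} has no records")
    return ValidationReport(
        n_records=len(records),
        coverage={f: dict(c) for f, c in coverage.items()},
        channel_counts=dict(channel_counts),
        monotonicity_violations=violations,
        coverage_gaps=gaps,
    )
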