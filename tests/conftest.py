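import numpy as np
import pytest

from lciso.lcsim import fragment_specs
from lciso.scan_model import ScanRecord


@pytest.fixture
def f99_specs():
    return fragment_specs("F99")


@pytest.fixture
def f64_specs():
    return fragment_specs("F64")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_record(
    time_min=0.0,
    scan_no=1,
    fragment_id="F99",
    isotopologue="M0",
    intensity=100.0,
    peak_noise=1.0,
    resolution=90_000.0,
    microscans=10,
    charge=1,
    channel="sample",
):
    return ScanRecord(
        time_min=time_min,
        scan_no=scan_no,
        fragment_id=fragment_id,
        isotopologue=isotopologue,
        intensity=intensity,
        peak_noise=peak_noise,
        resolution=resolution,
        microscans=microscans,
        charge=charge,
        channel=channel,
    )


@pytest.fixture
def record_factory():
    return make_record


def constant_block_records(
    counts: dict[str, float],
    n_spectra: int = 10,
    t0: float = 0.0,
    spacing_min: float = 0.5,
    channel: str = "sample",
    fragment_id: str = "F99",
    resolution: float = 240_000.0,
):
    """Records encoding a fixed ion count per spectrum per isotopologue
    (peak_noise 1, reference resolution, 1 microscan, so intensity*3 = ions)."""
    records = []
    for k in range(n_spectra):
        for iso, ions in counts.items():
            records.append(
                ScanRecord(
                    time_min=t0 + k * spacing_min,
                    scan_no=k + 1,
                    fragment_id=fragment_id,
                    isotopologue=iso,
                    intensity=ions / 3.0,
                    peak_noise=1.0,
                    resolution=resolution,
                    microscans=1,
                    charge=1,
                    channel=channel,
                )
            )
    return records


@pytest.fixture
def block_record_factory():
    return constant_block_records
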