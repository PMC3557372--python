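import numpy as np
import pytest

from tickniche import (
    RasterStack,
    RecordSet,
    OccurrenceRecord,
    default_field_spec,
    simulate_raster_stack,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20120728)


@pytest.fixture(scope="session")
def small_stack() -> RasterStack:
    """A 20x20 noiseless seasonal LST/NDVI stack (24 layers)."""
    spec = default_field_spec(seed=3, nrows=20, ncols=20)
    noiseless = spec.variables
    from tickniche.simulate import SeasonalFieldSpec, VariableField

    quiet = {
        name: VariableField(
            base=f.base, lon_gradient=f.lon_gradient, lat_gradient=f.lat_gradient,
            amplitude=f.amplitude, phase_month=f.phase_month, noise_sd=0.0,
        )
        for name, f in noiseless.items()
    }
    return simulate_raster_stack(
        SeasonalFieldSpec(variables=quiet, nrows=20, ncols=20, seed=3)
    )


def make_record(
    species="Ixodes ricinus", lon=10.0, lat=50.0, quality="coordinates", **kw
) -> OccurrenceRecord:
    return OccurrenceRecord(
        species_raw=species, lon=lon, lat=lat, locality_quality=quality, **kw
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def recordset_factory():
    def build(specs) -> RecordSet:
        rs = RecordSet(provenance="test")
        for s in specs:
            rs.records.append(make_record(**s))
        return rs

    return build


@pytest.fixture
def records_csv(tmp_path):
    """Write rows (list of dicts keyed by CSV columns) to a records file."""
    import csv

    from tickniche.records import CSV_COLUMNS

    def write(rows, name="records.csv", columns=CSV_COLUMNS):
        path = tmp_path / name
        with path.open("w", newline="", encoding="utf-8") as fh:
            w = csv.DictWriter(fh, fieldnames=columns)
            w.writeheader()
            for row in rows:
                w.writerow(row)
        return path

    return write
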