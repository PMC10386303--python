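import dataclasses

import pytest

from depthdiv.synthetic import default_config, scaled_config


@pytest.fixture
def tiny_config():
    """A 2-station dataset at fixed shallow read depth: fast to generate and
    to push through the whole pipeline."""
    return dataclasses.replace(
        scaled_config(default_config(seed=11), 2_000),
        n_stations=2,
        samples_per_station_layer={"SRF": 2, "DCM": 2, "MES": 2},
    )


@pytest.fixture
def kaiju_lines():
    """Hand-written classification rows in the kaiju-addTaxonNames dialect."""
    return [
        "C\tread1\t1280\tBacteria; Bacillota; Bacilli; Caryophanales; "
        "Staphylococcaceae; Staphylococcus; Staphylococcus aureus;",
        "U\tread2\t0",
        "C\tread3\t1279\tBacteria; Bacillota; Bacilli; Caryophanales; "
        "Staphylococcaceae; Staphylococcus;",
        "C\tread4\t2\tBacteria;",
    ]


@pytest.fixture
def kaiju_file(tmp_path, kaiju_lines):
    path = tmp_path / "sample.tsv"
    path.write_text("\n".join(kaiju_lines) + "\n", encoding="utf-8")
    return path
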