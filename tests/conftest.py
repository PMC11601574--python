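import numpy as np
import pandas as pd
import pytest

from nkgraft.cytometry import EventTable
from nkgraft import simulate
from nkgraft.immunogenetics import (HlaGenotype, KirGenotype,
                                    load_epitope_table)


@pytest.fixture(scope="session")
def epitope_table():
    return load_epitope_table()


@pytest.fixture(scope="session")
def fast_config():
    """Small event tables for unit tests; study-condition parameters kept."""
    return simulate.SimulationConfig(events_per_sample=400)


def make_genotype(sid="R1", a=("A*01:01", "A*02:01"),
                  b=("B*07:02", "B*08:01"), c=("C*07:01", "C*07:02")):
    return HlaGenotype(subject_id=sid, alleles={"A": a, "B": b, "C": c})


def make_kir(sid="R1", **flags):
    defaults = dict(kir3dl1=True, kir3dl2=True, kir2dl1=True,
                    kir2dl2=True, kir2dl3=True)
    defaults.update(flags)
    return KirGenotype(subject_id=sid, **defaults)


def make_event_table(channel_values: dict, sample_id="S1",
                     condition="baseline", timepoint="pre",
                     transformed=True) -> EventTable:
    """Event table from explicit per-channel value arrays."""
    n = len(next(iter(channel_values.values())))
    data = pd.DataFrame({
        "sample_id": sample_id if np.isscalar(sample_id) else sample_id,
        "condition": condition,
        "timepoint": timepoint,
        **{ch: np.asarray(v, dtype=float) for ch, v in channel_values.items()},
    })
    return EventTable(data=data, channels=tuple(channel_values),
                      transformed=transformed)
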