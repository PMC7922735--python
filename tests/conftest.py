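from datetime import datetime, timedelta

import pytest

from pofkit import (OvaryRecord, PofObservation, PofStage, SimulationConfig,
                    OocyteStage, simulate_population)

BASE = datetime(2014, 7, 15)


def make_record(fish_id, clock_hour, stages_areas=(), gonad=2.0,
                oocyte=OocyteStage.VIT2):
    """Hand-built ovary record at a given clock hour with (stage, area) POFs."""
    rec = OvaryRecord(
        fish_id=fish_id,
        capture_time=BASE + timedelta(hours=clock_hour),
        most_advanced_oocyte=oocyte,
        gonad_section_area=gonad)
    for k, (stage, area) in enumerate(stages_areas):
        rec.pofs.append(PofObservation(
            pof_id=f"F{fish_id}-{k}", area=area, stage=PofStage(stage)))
    return rec


@pytest.fixture(scope="session")
def default_records():
    """One default simulated collection, shared across read-only tests."""
    return simulate_population(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=11)
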