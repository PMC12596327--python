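import pytest

from solvselect import (
    AbrahamDescriptors,
    Catalog,
    CatalogSimSpec,
    HansenParameters,
    HazardClass,
    SolventFlags,
    SolventRecord,
    simulate_catalog,
)


@pytest.fixture(scope="session")
def sim_catalog():
    """Default synthetic catalog (272 solvents, 29 descriptors) with truth."""
    return simulate_catalog(CatalogSimSpec(seed=7))


@pytest.fixture()
def toy_catalog():
    """Five solvents with hand-set Hansen/Abraham values and flags."""
    records = [
        SolventRecord(
            name="refsolv",
            hazard_class=HazardClass.HAZARDOUS,
            boiling_point=61.0,
            hansen=HansenParameters(17.8, 3.1, 5.7),
            abraham=AbrahamDescriptors({"E": 0.4, "S": 0.5, "A": 0.1, "B": 0.0, "V": 0.6}),
            flags=SolventFlags(chlorinated=True),
        ),
        SolventRecord(
            name="ether-a",
            hazard_class=HazardClass.RECOMMENDED,
            boiling_point=106.0,
            hansen=HansenParameters(16.7, 4.3, 4.3),
            abraham=AbrahamDescriptors({"E": 0.2, "S": 0.4, "A": 0.0, "B": 0.5, "V": 0.9}),
        ),
        SolventRecord(
            name="arene-b",
            hazard_class=HazardClass.PROBLEMATIC,
            boiling_point=111.0,
            hansen=HansenParameters(18.0, 1.4, 2.0),
            abraham=AbrahamDescriptors({"E": 0.6, "S": 0.5, "A": 0.0, "B": 0.1, "V": 0.8}),
            flags=SolventFlags(aromatic=True),
        ),
        SolventRecord(
            name="chloro-c",
            hazard_class=HazardClass.HAZARDOUS,
            boiling_point=40.0,
            hansen=HansenParameters(18.2, 6.3, 6.1),
            abraham=AbrahamDescriptors({"E": 0.4, "S": 0.6, "A": 0.1, "B": 0.1, "V": 0.5}),
            flags=SolventFlags(chlorinated=True),
        ),
        SolventRecord(
            name="ester-d",
            hazard_class=HazardClass.RECOMMENDED,
            boiling_point=117.0,
            hansen=HansenParameters(15.6, 3.7, 6.3),
            abraham=AbrahamDescriptors({"E": 0.1, "S": 0.6, "A": 0.0, "B": 0.5, "V": 1.0}),
        ),
    ]
    return Catalog(records)
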