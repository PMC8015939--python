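import csv
import json
from pathlib import Path

import pytest

from pgxscribe import fixture_kb, parse_patient_input

DATA_DIR = Path(__file__).parent / "data"

#: A fully-typed demonstration patient: every supported gene gets a mapped
#: genotype; paroxetine (strong CYP2D6 inhibitor) and omeprazole (moderate
#: CYP2C19 inhibitor, also a CYP2C19 substrate) are current medications.
DEMO_PATIENT_DOC = {
    "genotypes": [
        {"gene": "CYP2B6", "value": "*1/*6"},
        {"gene": "CYP2C19", "value": "*1/*2"},
        {"gene": "CYP2C9", "value": "*1/*1"},
        {"gene": "CYP2D6", "value": "*2/*1", "note": "array panel"},
        {"gene": "CYP3A5", "value": "*3/*3"},
        {"gene": "HLA-A", "value": "*31:01 negative"},
        {"gene": "HLA-B", "value": "57:01 pos"},
        {"gene": "NUDT15", "value": "*1/*1"},
        {"gene": "SLCO1B1", "value": "*1/*5"},
        {"gene": "TPMT", "value": "*1/*3A"},
        {"gene": "VKORC1", "value": "G/A"},
    ],
    "current": ["paroxetine", "omeprazole"],
    "considered": ["codeine", "warfarin", "notadrug"],
    "metadata": {"specimen": "S-001"},
}


@pytest.fixture(scope="session")
def kb():
    return fixture_kb()


@pytest.fixture(scope="session")
def demo_patient():
    return parse_patient_input(json.dumps(DEMO_PATIENT_DOC))


@pytest.fixture(scope="session")
def transcribed_registry():
    """Independently transcribed registry of supported gene-drug pairs."""
    with (DATA_DIR / "gene_drug_registry.tsv").open(newline="", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    pairs = {(r["gene"], r["drug"]) for r in rows}
    qualifiers = {(r["gene"], r["drug"]): r["qualifier"] for r in rows if r.get("qualifier")}
    assert len(pairs) == len(rows), "transcription contains duplicate pairs"
    return pairs, qualifiers
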