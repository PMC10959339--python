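import pytest

from qtykit.topology import ProteinRecord, topology_from_rows


@pytest.fixture
def two_tm_protein():
    """60-residue protein: cytoplasmic 1-9, TM 10-30, extracellular 31-40,
    TM 41-60."""
    seq = (
        "MKKDERSAG"  # 1-9 cytoplasmic
        + "LIVFLIVFLIVFLIVFLIVFL"  # 10-30 TM1 (21 aa)
        + "NDSGERKHST"  # 31-40 ECL1
        + "QTYQTYQTYQTYQTYQTYQT"  # 41-60 TM2 (20 aa)
    )
    prot = ProteinRecord(accession="TOY2TM", name="two-helix toy", sequence=seq)
    topo = topology_from_rows(
        [
            ("CYTOPLASMIC", 1, 9),
            ("TM_HELIX", 10, 30),
            ("EXTRACELLULAR", 31, 40),
            ("TM_HELIX", 41, 60),
        ],
        prot.length,
    )
    return prot, topo
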