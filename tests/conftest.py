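import numpy as np
import pytest

from pentamut.structure_io import ONE_TO_THREE


def format_atom(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resseq: int,
    x: float,
    y: float,
    z: float,
    altloc: str = " ",
    icode: str = " ",
) -> str:
    return (
        f"ATOM  {serial:>5d}  {name:<3s}{altloc}{resname:>3s} {chain}"
        f"{resseq:>4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
    )


def pdb_from_sequence(sequence, spacing=3.8, n_offset=-1.235, c_offset=1.232,
                      chain="A", start=1):
    """Minimal extended-geometry PDB text: N, CA, C per residue.

    C(i)-N(i+1) distance is spacing - c_offset + n_offset = 1.333 A by
    default, i.e. no chain breaks.
    """
    lines = []
    serial = 1
    for i, aa in enumerate(sequence):
        resname = ONE_TO_THREE.get(aa, aa if len(aa) == 3 else "UNK")
        x = i * spacing
        for atom, off in (("N", n_offset), ("CA", 0.0), ("C", c_offset)):
            lines.append(format_atom(serial, atom, resname, chain, start + i,
                                     x + off, 0.0, 0.0))
            serial += 1
    lines.append("TER")
    return "\n".join(lines) + "\n"


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def clean_pdb_10():
    return pdb_from_sequence("ALKVGWYFDE")
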