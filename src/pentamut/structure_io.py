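"""Read PDB-format coordinate files into protein chains.

Only the backbone atoms used downstream (N, CA, C) are retained.  Residue
filtering follows three rules applied at parse time or immediately after:

* residues with alternative locations keep only the first-encountered set of
  coordinates per atom (``had_altloc`` is flagged),
* non-standard residues get ``one_letter = None`` and an ``'X'`` in the
  chain sequence,
* a peptide bond longer than 2.5 Angstrom between consecutive residues (or a
  missing C/N atom at either end) marks a chain break.

Only the first MODEL of multi-model entries is read.  HETATM records, waters
and chains without any C-alpha atom are ignored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "Residue",
    "ProteinChain",
    "ChainBreakSet",
    "PDBParseError",
    "parse_pdb",
    "detect_chain_breaks",
    "write_pdb",
    "chain_to_fasta",
    "chain_table",
    "THREE_TO_ONE",
    "ONE_TO_THREE",
    "STANDARD_RESIDUES",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_RESIDUES = frozenset(THREE_TO_ONE)

_BACKBONE_ATOMS = ("N", "CA", "C")


class PDBParseError(ValueError):
    """Raised for a malformed ATOM record; the message names the line."""


@dataclass
class Residue:
    """One residue with its backbone atom coordinates (Angstrom) or None."""

    name: str
    one_letter: Optional[str]
    seq_id: str
    ca: Optional[np.ndarray] = None
    n: Optional[np.ndarray] = None
    c: Optional[np.ndarray] = None
    had_altloc: bool = False

    def __post_init__(self) -> None:
        for atom in (self.ca, self.n, self.c):
            if atom is not None and not np.all(np.isfinite(atom)):
                raise ValueError(f"non-finite coordinates in residue {self.seq_id}")


@dataclass
class ProteinChain:
    """An ordered polypeptide chain parsed from one coordinate file."""

    source_id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        """One-letter sequence with 'X' at non-standard positions."""
        return "".join(r.one_letter or "X" for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ChainBreakSet:
    """0-based indices i with a broken peptide bond between i and i+1."""

    break_after: frozenset[int]

    def __contains__(self, idx: int) -> bool:
        return idx in self.break_after

    def __len__(self) -> int:
        return len(self.break_after)


def _parse_float(line: str, lo: int, hi: int, lineno: int, what: str) -> float:
    raw = line[lo:hi]
    try:
        value = float(raw)
    except ValueError as exc:
        raise PDBParseError(
            f"line {lineno}: malformed ATOM record ({what} field {raw!r})"
        ) from exc
    if not math.isfinite(value):
        raise PDBParseError(f"line {lineno}: non-finite {what} coordinate")
    return value


def parse_pdb(text: str, structure_id: str = "struct") -> list[ProteinChain]:
    """Parse PDB-format text into protein chains.

    Fixed-column ATOM parsing (PDB v3.3 layout).  Chains appear in file
    order; residues in record order.  For residues with altloc codes only
    the first-encountered coordinates per atom are kept.

    Parameters
    ----------
    text:
        Contents of a PDB file.
    structure_id:
        Prefix used to build each chain's ``source_id`` as
        ``"<structure_id>_<chain letter>"``.
    """
    # chain id -> list of residue dicts; residue keyed by (resSeq, iCode, name)
    chains: dict[str, list[dict]] = {}
    index: dict[tuple[str, str], dict] = {}  # (chain, seq_id) -> residue dict
    past_first_model = False

    for lineno, line in enumerate(text.splitlines(), start=1):
        record = line[:6].strip()
        if record == "ENDMDL":
            past_first_model = True
            continue
        if past_first_model or record != "ATOM":
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: ATOM record shorter than 54 columns")

        atom_name = line[12:16].strip()
        altloc = line[16]
        res_name = line[17:20].strip()
        chain_id = line[21]
        seq_id = line[22:26].strip() + line[26].strip()

        key = (chain_id, seq_id)
        res = index.get(key)
        if res is None:
            res = {
                "name": res_name,
                "seq_id": seq_id,
                "atoms": {},
                "altlocs": {},
                "had_altloc": False,
            }
            index[key] = res
            chains.setdefault(chain_id, []).append(res)

        if altloc != " ":
            res["had_altloc"] = True
        if res_name != res["name"]:
            # microheterogeneity: keep the first residue name seen
            continue

        if atom_name not in _BACKBONE_ATOMS:
            continue

        chosen = res["altlocs"].get(atom_name)
        if chosen is None:
            res["altlocs"][atom_name] = altloc
        elif altloc != chosen:
            continue  # later alternative location: drop
        if atom_name in res["atoms"]:
            continue  # duplicate record for the same atom

        coords = np.array(
            [
                _parse_float(line, 30, 38, lineno, "x"),
                _parse_float(line, 38, 46, lineno, "y"),
                _parse_float(line, 46, 54, lineno, "z"),
            ]
        )
        res["atoms"][atom_name] = coords

    result = []
    for chain_id, residues in chains.items():
        if not any("CA" in r["atoms"] for r in residues):
            continue  # not a protein chain
        chain = ProteinChain(source_id=f"{structure_id}_{chain_id.strip() or '_'}")
        for r in residues:
            chain.residues.append(
                Residue(
                    name=r["name"],
                    one_letter=THREE_TO_ONE.get(r["name"]),
                    seq_id=r["seq_id"],
                    ca=r["atoms"].get("CA"),
                    n=r["atoms"].get("N"),
                    c=r["atoms"].get("C"),
                    had_altloc=r["had_altloc"],
                )
            )
        result.append(chain)
    return result


def detect_chain_breaks(chain: ProteinChain, max_bond: float = 2.5) -> ChainBreakSet:
    """Find broken peptide bonds: C(i)-N(i+1) distance > ``max_bond`` Angstrom.

    A missing C or N atom at either end of the bond counts as a break, so
    that superposition downstream never sees absent coordinates.  The
    comparison is strict: a bond of exactly ``max_bond`` is intact.
    """
    breaks = set()
    for i in range(len(chain.residues) - 1):
        c_i = chain.residues[i].c
        n_next = chain.residues[i + 1].n
        if c_i is None or n_next is None:
            breaks.add(i)
            continue
        if float(np.linalg.norm(c_i - n_next)) > max_bond:
            breaks.add(i)
    return ChainBreakSet(frozenset(breaks))


def write_pdb(chain: ProteinChain) -> str:
    """Serialize a chain's backbone atoms back to PDB format."""
    chain_id = chain.source_id.rsplit("_", 1)[-1][:1] or "A"
    lines = []
    serial = 1
    for idx, res in enumerate(chain.residues):
        seq = res.seq_id or str(idx + 1)
        icode = " "
        if seq and seq[-1].isalpha():
            seq, icode = seq[:-1], seq[-1]
        resseq = int(seq) if seq else idx + 1
        for atom_name, coords in (("N", res.n), ("CA", res.ca), ("C", res.c)):
            if coords is None:
                continue
            name_field = f" {atom_name:<3s}"
            lines.append(
                f"ATOM  {serial:>5d} {name_field}"
                f" {res.name:>3s} {chain_id}{resseq:>4d}{icode}   "
                f"{coords[0]:8.3f}{coords[1]:8.3f}{coords[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def chain_to_fasta(chain: ProteinChain, line_width: int = 60) -> str:
    """FASTA record for one chain; header is the source_id."""
    seq = chain.sequence
    body = "\n".join(seq[i : i + line_width] for i in range(0, len(seq), line_width))
    return f">{chain.source_id}\n{body}\n"


def chain_table(chains: Iterable[ProteinChain]) -> str:
    """TSV summary table: source_id, length, n_breaks."""
    rows = ["source_id\tlength\tn_breaks"]
    for chain in chains:
        breaks = detect_chain_breaks(chain)
        rows.append(f"{chain.source_id}\t{len(chain)}\t{len(breaks)}")
    return "\n".join(rows) + "\n"
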