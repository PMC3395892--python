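"""Pentamer extraction and pairing.

Chains are chopped into all overlapping five-residue fragments; windows
containing a chain break, a non-standard residue or a missing C-alpha are
dropped.  Pairs are formed across two fragment collections when the two
pentamers agree everywhere except at the central residue and their source
chains share more than a minimum global sequence identity.  Pairs embedded
in a much larger identical-except-center region are filtered out, and one
fragment per pair is randomly designated as the wild type.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .structure_io import ChainBreakSet, ProteinChain

__all__ = [
    "Pentamer",
    "PentamerPair",
    "extract_pentamers",
    "global_identity",
    "pair_pentamers",
    "maximal_fragment_filter",
    "designate_roles",
    "greedy_redundancy_reduction",
    "pairs_to_tsv",
    "pairs_from_tsv",
]


@dataclass(frozen=True, eq=False)
class Pentamer:
    """Five consecutive residues with complete C-alpha coordinates."""

    chain_ref: str
    start: int
    sequence: str
    ca_coords: np.ndarray  # (5, 3), Angstrom

    def __post_init__(self) -> None:
        if len(self.sequence) != 5 or "X" in self.sequence:
            raise ValueError(f"invalid pentamer sequence {self.sequence!r}")
        if self.ca_coords.shape != (5, 3):
            raise ValueError("pentamer requires a 5x3 C-alpha coordinate matrix")
        if not np.all(np.isfinite(self.ca_coords)):
            raise ValueError("pentamer coordinates must be finite")


@dataclass
class PentamerPair:
    """Two pentamers identical except at the central position."""

    frag_a: Pentamer
    frag_b: Pentamer
    source_identity: float
    wt_is_a: Optional[bool] = None

    def __post_init__(self) -> None:
        sa, sb = self.frag_a.sequence, self.frag_b.sequence
        if sa[:2] != sb[:2] or sa[3:] != sb[3:] or sa[2] == sb[2]:
            raise ValueError(
                f"pentamers {sa!r}/{sb!r} must differ exactly at the center"
            )

    @property
    def center_a(self) -> str:
        return self.frag_a.sequence[2]

    @property
    def center_b(self) -> str:
        return self.frag_b.sequence[2]

    @property
    def wt_frag(self) -> Pentamer:
        if self.wt_is_a is None:
            raise ValueError("roles not designated yet")
        return self.frag_a if self.wt_is_a else self.frag_b

    @property
    def mut_frag(self) -> Pentamer:
        if self.wt_is_a is None:
            raise ValueError("roles not designated yet")
        return self.frag_b if self.wt_is_a else self.frag_a


def extract_pentamers(chain: ProteinChain, breaks: ChainBreakSet) -> list[Pentamer]:
    """All 5-residue windows without breaks, 'X' residues or missing CA."""
    pentamers = []
    residues = chain.residues
    seq = chain.sequence
    for start in range(len(residues) - 4):
        window = residues[start : start + 5]
        if any(r.one_letter is None for r in window):
            continue
        if any(r.ca is None for r in window):
            continue
        if any(i in breaks for i in range(start, start + 4)):
            continue
        pentamers.append(
            Pentamer(
                chain_ref=chain.source_id,
                start=start,
                sequence=seq[start : start + 5],
                ca_coords=np.vstack([r.ca for r in window]),
            )
        )
    return pentamers


_aligner: Optional[Align.PairwiseAligner] = None


def _get_aligner() -> Align.PairwiseAligner:
    global _aligner
    if _aligner is None:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -0.5
        _aligner = aligner
    return _aligner


def global_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity from a Needleman-Wunsch global alignment.

    BLOSUM62 scoring, gap open 10, gap extend 0.5.  Identity is
    100 * identical aligned columns / alignment length, with gap columns
    counted in the length.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    alignment = _get_aligner().align(seq_a, seq_b)[0]
    counts = alignment.counts()
    length = counts.gaps + counts.identities + counts.mismatches
    return 100.0 * counts.identities / length


def pair_pentamers(
    set_a: Iterable[Pentamer],
    set_b: Iterable[Pentamer],
    sequences: Mapping[str, str],
    min_identity: float = 30.0,
) -> list[PentamerPair]:
    """Cross-set pentamer pairs with a single central mismatch.

    ``sequences`` maps each chain_ref to its full sequence so chain-pair
    identity can be computed (cached per chain pair; strict ``>``
    comparison against ``min_identity``).  Duplicate
    (chain_a, start_a, chain_b, start_b) combinations are emitted once.
    """
    by_context: dict[tuple[str, str], list[Pentamer]] = {}
    for p in set_b:
        by_context.setdefault((p.sequence[:2], p.sequence[3:]), []).append(p)

    identity_cache: dict[tuple[str, str], float] = {}

    def chain_identity(ref_a: str, ref_b: str) -> float:
        key = (ref_a, ref_b)
        if key not in identity_cache:
            identity_cache[key] = global_identity(sequences[ref_a], sequences[ref_b])
        return identity_cache[key]

    pairs = []
    seen = set()
    for pa in set_a:
        for pb in by_context.get((pa.sequence[:2], pa.sequence[3:]), ()):
            if pa.sequence[2] == pb.sequence[2]:
                continue
            dedup = (pa.chain_ref, pa.start, pb.chain_ref, pb.start)
            if dedup in seen:
                continue
            identity = chain_identity(pa.chain_ref, pb.chain_ref)
            if identity <= min_identity:
                continue
            seen.add(dedup)
            pairs.append(PentamerPair(frag_a=pa, frag_b=pb, source_identity=identity))
    return pairs


def maximal_fragment_filter(
    pairs: Iterable[PentamerPair],
    sequences: Mapping[str, str],
    max_extension: int = 4,
) -> list[PentamerPair]:
    """Drop pairs embedded in a much larger identical-except-center region.

    The matched region is extended outward residue by residue while the
    flanking residues of both source chains are equal (and standard); a
    pair survives only if the total extension (left + right) does not
    exceed ``max_extension``.
    """
    kept = []
    for pair in pairs:
        seq_a = sequences[pair.frag_a.chain_ref]
        seq_b = sequences[pair.frag_b.chain_ref]
        sa, sb = pair.frag_a.start, pair.frag_b.start
        ext = 0
        i = 1
        while sa - i >= 0 and sb - i >= 0 and seq_a[sa - i] == seq_b[sb - i] != "X":
            ext += 1
            i += 1
        i = 0
        while (
            sa + 5 + i < len(seq_a)
            and sb + 5 + i < len(seq_b)
            and seq_a[sa + 5 + i] == seq_b[sb + 5 + i] != "X"
        ):
            ext += 1
            i += 1
        if ext <= max_extension:
            kept.append(pair)
    return kept


def designate_roles(pairs: Iterable[PentamerPair], seed: int) -> list[PentamerPair]:
    """Randomly designate one fragment per pair as the wild type (seeded)."""
    rng = np.random.default_rng(seed)
    return [replace(p, wt_is_a=bool(rng.random() < 0.5)) for p in pairs]


def greedy_redundancy_reduction(
    sequences: Mapping[str, str], max_identity: float = 98.0
) -> list[str]:
    """Greedy identity-threshold redundancy reduction (fallback).

    Chains are visited in sorted-key order; a chain is retained if its
    global identity to every already retained chain is <= ``max_identity``.
    Intended only as a small-scale stand-in for external clustering tools;
    precomputed representative lists should be preferred.
    """
    kept: list[str] = []
    for ref in sorted(sequences):
        if all(global_identity(sequences[ref], sequences[k]) <= max_identity for k in kept):
            kept.append(ref)
    return kept


_TSV_COLUMNS = [
    "chain_a", "start_a", "seq_a", "chain_b", "start_b", "seq_b",
    "center_a", "center_b", "identity", "wt_is_a",
]


def pairs_to_tsv(pairs: Iterable[PentamerPair]) -> str:
    """Serialize pairs to TSV (coordinates are not stored)."""
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    writer.writerow(_TSV_COLUMNS)
    for p in pairs:
        writer.writerow(
            [
                p.frag_a.chain_ref, p.frag_a.start, p.frag_a.sequence,
                p.frag_b.chain_ref, p.frag_b.start, p.frag_b.sequence,
                p.center_a, p.center_b,
                f"{p.source_identity:.3f}",
                "" if p.wt_is_a is None else int(p.wt_is_a),
            ]
        )
    return buf.getvalue()


def pairs_from_tsv(text: str, chains: Mapping[str, ProteinChain]) -> list[PentamerPair]:
    """Rebuild pairs from TSV, pulling coordinates from parsed chains."""
    reader = csv.DictReader(io.StringIO(text), delimiter="\t")
    pairs = []
    for row in reader:
        frags = []
        for side in ("a", "b"):
            chain = chains[row[f"chain_{side}"]]
            start = int(row[f"start_{side}"])
            window = chain.residues[start : start + 5]
            frags.append(
                Pentamer(
                    chain_ref=chain.source_id,
                    start=start,
                    sequence=row[f"seq_{side}"],
                    ca_coords=np.vstack([r.ca for r in window]),
                )
            )
        wt_raw = row.get("wt_is_a", "")
        pairs.append(
            PentamerPair(
                frag_a=frags[0],
                frag_b=frags[1],
                source_identity=float(row["identity"]),
                wt_is_a=None if wt_raw in ("", None) else bool(int(wt_raw)),
            )
        )
    return pairs
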