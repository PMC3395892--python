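"""Synthetic fixtures: toy structures, tracks and planted-signal datasets.

Everything the pipeline consumes can be generated here at desk scale with
explicit seeds: idealized backbones written as PDB text (optionally with
Gaussian coordinate noise), per-residue feature tracks for every provider
slot, mutant pair fixtures with controlled perturbation, and Gaussian
class-conditional feature matrices with a known analytic AUC
(``Phi(d / sqrt(2))`` for class separation ``d``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .features import AA_ORDER, FeatureTrack
from .structure_io import ONE_TO_THREE, ProteinChain, parse_pdb, write_pdb
from .superposition import superpose

__all__ = [
    "ToyChainSpec",
    "PlantedDatasetSpec",
    "make_toy_chain",
    "make_pair_fixture",
    "make_planted_dataset",
    "make_synthetic_tracks",
    "planted_auc",
]

# extended-strand geometry: colinear C-alpha trace, N/C on-axis offsets
# tuned so the C(i)-N(i+1) bond is ~1.33 A at zero noise
_CA_SPACING = 3.8
_N_OFFSET = -1.235
_C_OFFSET = 1.232

# idealized helix: 100 degrees twist and 1.5 A rise per residue, 2.3 A
# C-alpha radius; N/C placed on the same curve at +/-0.3425 residue units
_HELIX_TWIST = math.radians(100.0)
_HELIX_RISE = 1.5
_HELIX_RADIUS = 2.3
_HELIX_ATOM_SHIFT = 0.3425


@dataclass(frozen=True)
class ToyChainSpec:
    length: int
    geometry: str = "extended"  # or "helix"
    seed: int = 0
    perturbation_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.length < 5:
            raise ValueError("toy chains must have at least 5 residues")
        if self.geometry not in ("extended", "helix"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.perturbation_sd < 0:
            raise ValueError("perturbation_sd must be >= 0")


@dataclass(frozen=True)
class PlantedDatasetSpec:
    n: int
    n_features: int
    signal_feature: int = 0
    effect_size: float = 1.0
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must be in (0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 <= self.signal_feature < self.n_features:
            raise ValueError("signal_feature out of range")


def _backbone_coords(length: int, geometry: str) -> np.ndarray:
    """(length, 3 atoms, 3) coordinates for N, CA, C of each residue."""
    coords = np.zeros((length, 3, 3))
    if geometry == "extended":
        for i in range(length):
            x = i * _CA_SPACING
            coords[i, 0] = (x + _N_OFFSET, 0.0, 0.0)
            coords[i, 1] = (x, 0.0, 0.0)
            coords[i, 2] = (x + _C_OFFSET, 0.0, 0.0)
    else:
        for i in range(length):
            for j, shift in enumerate((-_HELIX_ATOM_SHIFT, 0.0, _HELIX_ATOM_SHIFT)):
                t = i + shift
                angle = t * _HELIX_TWIST
                coords[i, j] = (
                    _HELIX_RADIUS * math.cos(angle),
                    _HELIX_RADIUS * math.sin(angle),
                    t * _HELIX_RISE,
                )
    return coords


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AA_ORDER), size=length))


def _chain_from_arrays(sequence: str, coords: np.ndarray, source_id: str) -> ProteinChain:
    from .structure_io import Residue

    chain = ProteinChain(source_id=source_id)
    for i, aa in enumerate(sequence):
        chain.residues.append(
            Residue(
                name=ONE_TO_THREE[aa],
                one_letter=aa,
                seq_id=str(i + 1),
                n=coords[i, 0].copy(),
                ca=coords[i, 1].copy(),
                c=coords[i, 2].copy(),
            )
        )
    return chain


def make_toy_chain(
    spec: ToyChainSpec, sequence: str | None = None, source_id: str = "toy_A"
) -> str:
    """PDB-format text for one idealized chain (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    if sequence is None:
        sequence = _random_sequence(spec.length, rng)
    elif len(sequence) != spec.length:
        raise ValueError("sequence length does not match spec")
    coords = _backbone_coords(spec.length, spec.geometry)
    if spec.perturbation_sd > 0:
        coords = coords + rng.normal(0.0, spec.perturbation_sd, coords.shape)
    return write_pdb(_chain_from_arrays(sequence, coords, source_id))


def make_pair_fixture(
    base_spec: ToyChainSpec,
    mutate_center: str,
    perturb: float,
    seed: int,
    flank_shuffle: float = 0.0,
) -> tuple[str, str, float]:
    """Wild-type/mutant PDB pair with a planted structural perturbation.

    The second chain copies the first, renames the central residue to
    ``mutate_center`` and jitters every C-alpha by seeded Gaussian noise
    of scale ``perturb`` (Angstrom).  With ``flank_shuffle > 0``, sequence
    positions more than two residues away from the center are re-drawn
    with that probability (keeps the central pentamer context intact while
    lowering full-chain identity).  Returns both PDB texts and the true
    post-superposition C-alpha RMSD of the central pentamer.
    """
    if perturb < 0:
        raise ValueError("perturb must be >= 0")
    rng = np.random.default_rng(seed)
    text_a = make_toy_chain(base_spec, source_id="wt_A")
    chain_a = parse_pdb(text_a, structure_id="wt")[0]

    center = base_spec.length // 2
    seq_b = list(chain_a.sequence)
    if seq_b[center] == mutate_center:
        raise ValueError("mutate_center must differ from the wild-type residue")
    seq_b[center] = mutate_center
    if flank_shuffle > 0:
        for i in range(len(seq_b)):
            if abs(i - center) > 2 and rng.random() < flank_shuffle:
                seq_b[i] = str(rng.choice(list(AA_ORDER)))

    coords = np.zeros((len(chain_a), 3, 3))
    for i, res in enumerate(chain_a.residues):
        coords[i] = (res.n, res.ca, res.c)
    if perturb > 0:
        coords[:, 1, :] += rng.normal(0.0, perturb, (len(chain_a), 3))
    chain_b = _chain_from_arrays("".join(seq_b), coords, "mut_A")
    text_b = write_pdb(chain_b)

    # true label signal: central pentamer RMSD after optimal superposition
    lo = center - 2
    ca_a = np.vstack([r.ca for r in chain_a.residues[lo : lo + 5]])
    ca_b = coords[lo : lo + 5, 1, :]
    rmsd = superpose(ca_a, ca_b).rmsd
    return text_a, text_b, rmsd


def planted_auc(effect_size: float) -> float:
    """Analytic single-feature AUC for unit-variance Gaussians ``d`` apart."""
    return 0.5 * (1.0 + math.erf(effect_size / 2.0))


def make_planted_dataset(spec: PlantedDatasetSpec) -> tuple[np.ndarray, np.ndarray]:
    """Class-conditional Gaussian feature matrix with one signal feature.

    The signal column is N(0, 1) for class 0 and N(d, 1) for class 1; all
    other columns are standard normal noise.  Returns (X, y).
    """
    rng = np.random.default_rng(spec.seed)
    y = (rng.random(spec.n) < spec.class_balance).astype(int)
    X = rng.normal(0.0, 1.0, (spec.n, spec.n_features))
    X[:, spec.signal_feature] += spec.effect_size * y
    return X, y


_SIMPLEX_TRACKS = {"ss": 3, "acc": 3, "ss_single": 3, "acc_single": 3, "freq": 20}
_ONEHOT_TRACKS = {"disorder": 2, "hotspot": 2, "dna": 2}
_SCALAR_TRACKS = ("flexibility", "pfam_fit", "psic", "info")


def make_synthetic_tracks(chain: ProteinChain, seed: int) -> dict[str, FeatureTrack]:
    """Range-respecting random tracks for every provider slot.

    Three-state (and frequency) tracks are Dirichlet rows summing to 1,
    two-state tracks are mutually exclusive one-hot rows, scalar tracks
    are uniform in [0, 1], and the "pssm" matrix is uniform in [0, 1].
    """
    rng = np.random.default_rng(seed)
    n = len(chain)
    tracks: dict[str, FeatureTrack] = {}
    for name, width in _SIMPLEX_TRACKS.items():
        values = rng.dirichlet(np.ones(width), size=n)
        tracks[name] = FeatureTrack(chain.source_id, name, values)
    for name, width in _ONEHOT_TRACKS.items():
        values = np.eye(width)[rng.integers(0, width, size=n)]
        tracks[name] = FeatureTrack(chain.source_id, name, values)
    for name in _SCALAR_TRACKS:
        tracks[name] = FeatureTrack(chain.source_id, name, rng.random((n, 1)))
    tracks["pssm"] = FeatureTrack(chain.source_id, "pssm", rng.random((n, 20)))
    return tracks
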