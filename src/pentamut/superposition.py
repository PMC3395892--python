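"""Optimal rigid-body superposition of pentamer C-alpha traces.

The least-squares optimum is computed with the Kabsch SVD construction,
including the determinant-sign correction that excludes improper rotations
(reflections).  RMSD is taken over exactly the five C-alpha atoms,
unweighted.  Labels partition the RMSD line three ways with strict
inequalities at both thresholds: below ``t_neutral`` is neutral, above
``t_change`` is change, everything in between (including the exact
threshold values) is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fragments import PentamerPair

__all__ = [
    "SuperpositionResult",
    "LABELS",
    "superpose",
    "label_pair",
    "pair_rmsd",
]

LABELS = ("change", "neutral", "excluded")


@dataclass(frozen=True)
class SuperpositionResult:
    """Proper rotation + translation mapping y onto x, and the RMSD (A)."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def superpose(x: np.ndarray, y: np.ndarray) -> SuperpositionResult:
    """Superpose point set ``y`` onto ``x`` minimizing the sum of squares.

    Parameters
    ----------
    x, y:
        (n, 3) coordinate matrices in Angstrom; rows correspond.

    Returns
    -------
    SuperpositionResult with a proper rotation (reflections excluded even
    for degenerate, e.g. planar or collinear, inputs).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("inputs must be matching (n, 3) coordinate matrices")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("coordinates must be finite")

    cx = x.mean(axis=0)
    cy = y.mean(axis=0)
    xc = x - cx
    yc = y - cy

    h = yc.T @ xc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if d == 0:  # fully degenerate covariance; any proper rotation is optimal
        d = 1.0
    correction = np.diag([1.0, 1.0, d])
    rotation = vt.T @ correction @ u.T
    translation = cx - rotation @ cy

    residual = yc @ rotation.T - xc
    rmsd = float(np.sqrt(np.mean(np.sum(residual**2, axis=1))))
    return SuperpositionResult(rotation=rotation, translation=translation, rmsd=rmsd)


def label_pair(rmsd: float, t_neutral: float = 0.2, t_change: float = 0.4) -> str:
    """Three-way structural label for an RMSD value.

    ``rmsd < t_neutral`` is "neutral", ``rmsd > t_change`` is "change",
    anything else -- including values exactly at a threshold -- is
    "excluded".
    """
    if t_neutral >= t_change:
        raise ValueError(
            f"t_neutral ({t_neutral}) must be below t_change ({t_change})"
        )
    if rmsd < 0 or not np.isfinite(rmsd):
        raise ValueError(f"invalid RMSD {rmsd}")
    if rmsd < t_neutral:
        return "neutral"
    if rmsd > t_change:
        return "change"
    return "excluded"


def pair_rmsd(pair: PentamerPair) -> float:
    """C-alpha RMSD of a pentamer pair after optimal superposition."""
    return superpose(pair.frag_a.ca_coords, pair.frag_b.ca_coords).rmsd
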