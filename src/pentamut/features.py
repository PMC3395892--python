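"""Numeric feature encoding for pentamer pairs.

Three kinds of channels feed the classifier:

* **global** -- whole-chain descriptors of the wild-type protein (length
  bins, amino acid composition, predicted secondary-structure and
  accessibility content),
* **local** -- per-residue tracks sliced in odd windows (1, 5, 9, 13, 17,
  21) centered on the position of change, zero-padded at chain ends,
* **difference** -- properties of the two central residues encoded as the
  absolute difference plus a sign bit (0 negative, 1 non-negative), with
  the delta taken as mutant minus wild type.

All values are normalized to [0, 1].  Per-position channel widths are
pinned: three-state predictions contribute 3 values per window position,
two-state predictions 2 mutually exclusive values, scalar tracks 1.  A
difference feature contributes (magnitude, sign) per underlying score
channel.  External predictors are never executed here; their outputs are
consumed as per-residue tracks from a provider (TSV files, parsed PSSMs or
synthetic stand-ins).
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .fragments import Pentamer, PentamerPair

__all__ = [
    "AA_ORDER",
    "ALLOWED_WINDOWS",
    "PROPENSITY_NAMES",
    "PropensityScale",
    "FeatureTrack",
    "FeatureDescriptor",
    "FeatureVector",
    "TrackStore",
    "propensity_scale",
    "propensity_track",
    "encode_length_bins",
    "encode_composition",
    "encode_window",
    "encode_difference",
    "parse_pssm",
    "write_pssm",
    "track_to_tsv",
    "track_from_tsv",
    "assemble_vector",
    "selected_model_descriptors",
    "candidate_descriptors",
]

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
ALLOWED_WINDOWS = (1, 5, 9, 13, 17, 21)

# Raw residue-level propensities, min-max normalized on construction.
# Masses are monoisotopic residue masses (Da); volumes in cubic Angstrom;
# hydrophobicity is the Kyte-Doolittle index; C-beta branching and the
# helix breaker (proline) are indicators; charge is three-level.
_RESIDUE_MASS = {
    "A": 71.08, "C": 103.14, "D": 115.09, "E": 129.12, "F": 147.18,
    "G": 57.05, "H": 137.14, "I": 113.16, "K": 128.17, "L": 113.16,
    "M": 131.19, "N": 114.10, "P": 97.12, "Q": 128.13, "R": 156.19,
    "S": 87.08, "T": 101.10, "V": 99.13, "W": 186.21, "Y": 163.18,
}
_RESIDUE_VOLUME = {
    "A": 88.6, "C": 108.5, "D": 111.1, "E": 138.4, "F": 189.9,
    "G": 60.1, "H": 153.2, "I": 166.7, "K": 168.6, "L": 166.7,
    "M": 162.9, "N": 114.1, "P": 112.7, "Q": 143.8, "R": 173.4,
    "S": 89.0, "T": 116.1, "V": 140.0, "W": 227.8, "Y": 193.6,
}
_HYDROPHOBICITY = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}
_CBETA_BRANCHING = {aa: (1.0 if aa in "IVT" else 0.0) for aa in AA_ORDER}
_HELIX_BREAKER = {aa: (1.0 if aa == "P" else 0.0) for aa in AA_ORDER}
_CHARGE = {
    aa: (0.0 if aa in "DE" else 1.0 if aa in "KRH" else 0.5) for aa in AA_ORDER
}

_RAW_SCALES = {
    "mass": _RESIDUE_MASS,
    "volume": _RESIDUE_VOLUME,
    "hydrophobicity": _HYDROPHOBICITY,
    "cbeta_branching": _CBETA_BRANCHING,
    "helix_breaker": _HELIX_BREAKER,
    "charge": _CHARGE,
}
PROPENSITY_NAMES = tuple(_RAW_SCALES)

# PSSM scores are affinely mapped from [-16, 16] onto [0, 1]; per-position
# information content is capped at 2 bits.  Documented constants, not
# claimed to match any external convention.
PSSM_SCORE_RANGE = (-16.0, 16.0)
INFO_CAP = 2.0


@dataclass(frozen=True)
class PropensityScale:
    """A named residue propensity, min-max normalized to [0, 1]."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(AA_ORDER) - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name} missing residues {sorted(missing)}")
        vals = np.array([self.values[aa] for aa in AA_ORDER])
        if vals.min() < 0 or vals.max() > 1:
            raise ValueError(f"scale {self.name} not normalized to [0, 1]")

    def __getitem__(self, aa: str) -> float:
        return self.values[aa]


def propensity_scale(name: str) -> PropensityScale:
    """Look up one of the six built-in propensity scales (normalized)."""
    raw = _RAW_SCALES[name]
    lo, hi = min(raw.values()), max(raw.values())
    span = (hi - lo) or 1.0
    return PropensityScale(
        name=name, values={aa: (v - lo) / span for aa, v in raw.items()}
    )


@dataclass
class FeatureTrack:
    """Per-residue numeric values of fixed width for one chain."""

    chain_ref: str
    name: str
    values: np.ndarray  # (chain length, width)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.ndim != 2:
            raise ValueError("track values must be a 2-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"track {self.name} contains non-finite values")

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def __len__(self) -> int:
        return self.values.shape[0]


_GLOBAL_WIDTHS = {
    "length_bins": 4,
    "composition": 20,
    "ss_content": 3,
    "acc_content": 3,
}


@dataclass(frozen=True)
class FeatureDescriptor:
    """One encodable channel: what to read and how wide it is.

    ``kind`` is "global", "local" or "difference".  Local descriptors name
    a per-residue track and an odd window; propensity tracks are addressed
    as ``"prop:<scale>"`` and computed from sequence on demand.  Difference
    descriptors use one of three sources:

    * ``"track"``  -- delta of per-chain track values at the center,
    * ``"column"`` -- delta between the mutant and wild-type amino acid
      columns of a 20-wide matrix track on the wild-type chain,
    * ``"scale"``  -- delta of a propensity scale between the two central
      residues.
    """

    name: str
    kind: str
    track: Optional[str] = None
    window: Optional[int] = None
    channels: int = 1
    diff_source: str = "track"

    def __post_init__(self) -> None:
        if self.kind not in ("global", "local", "difference"):
            raise ValueError(f"unknown descriptor kind {self.kind!r}")
        if self.kind == "local":
            if self.window not in ALLOWED_WINDOWS:
                raise ValueError(
                    f"window must be one of {ALLOWED_WINDOWS}, got {self.window}"
                )
        elif self.window is not None:
            raise ValueError("window applies to local descriptors only")
        if self.kind == "difference" and self.diff_source not in (
            "track", "column", "scale",
        ):
            raise ValueError(f"unknown diff_source {self.diff_source!r}")

    @property
    def width(self) -> int:
        if self.kind == "global":
            return _GLOBAL_WIDTHS[self.name]
        if self.kind == "local":
            return self.channels * self.window
        if self.diff_source == "track":
            return 2 * self.channels
        return 2  # column / scale differences are single-channel


@dataclass
class FeatureVector:
    """Assembled numeric vector plus its descriptor layout."""

    values: np.ndarray
    layout: list[tuple[str, int, int]]  # (descriptor name, offset, width)

    def __post_init__(self) -> None:
        if sum(w for _, _, w in self.layout) != len(self.values):
            raise ValueError("layout widths do not sum to vector length")

    def __len__(self) -> int:
        return len(self.values)


def encode_length_bins(length: int) -> np.ndarray:
    """Four-bin sequence-length encoding.

    Bins cover 1-60, 61-120, 121-180 and 181-240 residues; the containing
    bin is set to 0.5, bins below to 1 and bins above to 0.  Lengths over
    240 leave every bin "below", i.e. all four values are 1.
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    edges = (60, 120, 180, 240)
    out = np.zeros(4)
    for i, hi in enumerate(edges):
        lo = hi - 59
        if length > hi:
            out[i] = 1.0
        elif length >= lo:
            out[i] = 0.5
    return out


def encode_composition(sequence: str) -> np.ndarray:
    """Relative frequencies of the 20 standard residues (AA_ORDER).

    'X' positions are excluded from both numerator and denominator; an
    all-'X' sequence yields all zeros.
    """
    if not sequence:
        raise ValueError("empty sequence")
    counts = np.array([sequence.count(aa) for aa in AA_ORDER], dtype=float)
    total = counts.sum()
    return counts / total if total > 0 else counts


def encode_window(track: FeatureTrack, center: int, window: int) -> np.ndarray:
    """Concatenate track rows for a window centered on ``center``.

    Positions outside the chain are zero-padded.  Output length is
    ``track.width * window``.
    """
    if window not in ALLOWED_WINDOWS:
        raise ValueError(f"window must be one of {ALLOWED_WINDOWS}, got {window}")
    if not 0 <= center < len(track):
        raise ValueError(f"center {center} outside chain of length {len(track)}")
    half = (window - 1) // 2
    out = np.zeros((window, track.width))
    lo = max(0, center - half)
    hi = min(len(track), center + half + 1)
    out[lo - (center - half) : hi - (center - half)] = track.values[lo:hi]
    return out.ravel()


def encode_difference(wt_score: float, mut_score: float) -> np.ndarray:
    """(magnitude, sign) encoding of mutant minus wild-type score.

    The sign bit is 1 for a non-negative delta (ties count as positive)
    and 0 for a negative one.
    """
    delta = mut_score - wt_score
    return np.array([abs(delta), 1.0 if delta >= 0 else 0.0])


def propensity_track(sequence: str, scale: PropensityScale) -> FeatureTrack:
    """Per-position propensity values; 'X' positions get 0."""
    values = np.array([[scale[aa] if aa in scale.values else 0.0] for aa in sequence])
    return FeatureTrack(chain_ref="", name=f"prop:{scale.name}", values=values)


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM (-Q output)

def parse_pssm(
    text: str, expected_length: Optional[int] = None
) -> dict[str, FeatureTrack]:
    """Parse a PSI-BLAST ASCII PSSM into three aligned tracks.

    Returns ``"pssm"`` (20 scores affinely scaled from [-16, 16] to
    [0, 1]), ``"freq"`` (20 relative frequencies in [0, 1]) and ``"info"``
    (per-position information content divided by a 2-bit cap, clipped).
    Column order follows the file header, re-ordered to AA_ORDER.
    """
    scores, freqs, infos = [], [], []
    header_order: Optional[list[str]] = None
    for line in text.splitlines():
        tokens = line.split()
        if not tokens:
            continue
        if header_order is None and len(tokens) >= 40 and all(
            t in AA_ORDER for t in tokens[:40]
        ):
            header_order = tokens[:20]
            continue
        if not tokens[0].lstrip("-").isdigit() or len(tokens) < 44:
            continue
        scores.append([float(v) for v in tokens[2:22]])
        freqs.append([float(v) / 100.0 for v in tokens[22:42]])
        infos.append([float(tokens[42])])
    if header_order is None or not scores:
        raise ValueError("not a recognizable ASCII PSSM")
    if expected_length is not None and len(scores) != expected_length:
        raise ValueError(
            f"PSSM has {len(scores)} rows but chain has {expected_length} residues"
        )

    order = [header_order.index(aa) for aa in AA_ORDER]
    lo, hi = PSSM_SCORE_RANGE
    score_arr = np.clip((np.array(scores)[:, order] - lo) / (hi - lo), 0.0, 1.0)
    freq_arr = np.clip(np.array(freqs)[:, order], 0.0, 1.0)
    info_arr = np.clip(np.array(infos) / INFO_CAP, 0.0, 1.0)
    return {
        "pssm": FeatureTrack(chain_ref="", name="pssm", values=score_arr),
        "freq": FeatureTrack(chain_ref="", name="freq", values=freq_arr),
        "info": FeatureTrack(chain_ref="", name="info", values=info_arr),
    }


def write_pssm(
    sequence: str,
    scores: np.ndarray,
    freqs: np.ndarray,
    info: np.ndarray,
) -> str:
    """Serialize raw (unscaled) PSSM data in PSI-BLAST ASCII layout."""
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "            " + "   ".join(AA_ORDER) + "   " + "   ".join(AA_ORDER),
    ]
    for i, aa in enumerate(sequence):
        row = f"{i + 1:5d} {aa} "
        row += " ".join(f"{int(round(v)):3d}" for v in scores[i])
        row += "  " + " ".join(f"{int(round(v * 100)):3d}" for v in freqs[i])
        row += f"  {float(info[i]):5.2f} {1.00:5.2f}"
        lines.append(row)
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Track TSV round trip

def track_to_tsv(track: FeatureTrack) -> str:
    """TSV with a 0-based position column plus one column per channel."""
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    writer.writerow(["position"] + [f"v{i}" for i in range(track.width)])
    for pos, row in enumerate(track.values):
        writer.writerow([pos] + [f"{v:.6g}" for v in row])
    return buf.getvalue()


def track_from_tsv(text: str, chain_ref: str, name: str) -> FeatureTrack:
    reader = csv.reader(io.StringIO(text), delimiter="\t")
    header = next(reader)
    if not header or header[0] != "position":
        raise ValueError("track TSV must start with a 'position' column")
    rows = sorted((int(r[0]), [float(v) for v in r[1:]]) for r in reader if r)
    return FeatureTrack(
        chain_ref=chain_ref, name=name, values=np.array([r[1] for r in rows])
    )


# ---------------------------------------------------------------------------
# Providers and assembly

class TrackStore:
    """In-memory track provider: sequences plus named per-chain tracks.

    Propensity tracks (``"prop:<scale>"``) are derived from the stored
    sequence on demand and cached.
    """

    def __init__(self) -> None:
        self._sequences: dict[str, str] = {}
        self._tracks: dict[tuple[str, str], FeatureTrack] = {}

    def add_sequence(self, chain_ref: str, sequence: str) -> None:
        self._sequences[chain_ref] = sequence

    def add_track(self, chain_ref: str, track: FeatureTrack) -> None:
        if chain_ref in self._sequences and len(track) != len(
            self._sequences[chain_ref]
        ):
            raise ValueError(
                f"track {track.name} length {len(track)} != chain length "
                f"{len(self._sequences[chain_ref])}"
            )
        self._tracks[(chain_ref, track.name)] = track

    def sequence(self, chain_ref: str) -> str:
        return self._sequences[chain_ref]

    def track(self, chain_ref: str, name: str) -> Optional[FeatureTrack]:
        key = (chain_ref, name)
        if key not in self._tracks and name.startswith("prop:"):
            scale = propensity_scale(name.split(":", 1)[1])
            self._tracks[key] = propensity_track(self._sequences[chain_ref], scale)
        return self._tracks.get(key)


def _global_values(name: str, store: TrackStore, chain_ref: str) -> np.ndarray:
    sequence = store.sequence(chain_ref)
    if name == "length_bins":
        return encode_length_bins(len(sequence))
    if name == "composition":
        return encode_composition(sequence)
    if name in ("ss_content", "acc_content"):
        track = store.track(chain_ref, "ss" if name == "ss_content" else "acc")
        if track is None:
            raise KeyError(name)
        states = np.argmax(track.values, axis=1)
        return np.array([(states == k).mean() for k in range(track.width)])
    raise ValueError(f"unknown global feature {name!r}")


def _descriptor_values(
    desc: FeatureDescriptor, pair: PentamerPair, store: TrackStore
) -> np.ndarray:
    wt, mut = pair.wt_frag, pair.mut_frag
    wt_center = wt.start + 2
    mut_center = mut.start + 2

    if desc.kind == "global":
        return _global_values(desc.name, store, wt.chain_ref)

    if desc.kind == "local":
        track = store.track(wt.chain_ref, desc.track)
        if track is None:
            raise KeyError(desc.track)
        if track.width != desc.channels:
            raise ValueError(
                f"descriptor {desc.name} expects {desc.channels} channels, "
                f"track {desc.track} has {track.width}"
            )
        return encode_window(track, wt_center, desc.window)

    # difference features
    if desc.diff_source == "scale":
        scale = propensity_scale(desc.track)
        return encode_difference(scale[wt.sequence[2]], scale[mut.sequence[2]])
    if desc.diff_source == "column":
        track = store.track(wt.chain_ref, desc.track)
        if track is None:
            raise KeyError(desc.track)
        if track.width != 20:
            raise ValueError(f"column difference needs a 20-wide track, got {track.width}")
        row = track.values[wt_center]
        return encode_difference(
            row[AA_ORDER.index(wt.sequence[2])], row[AA_ORDER.index(mut.sequence[2])]
        )
    # per-chain track difference at the center position
    wt_track = store.track(wt.chain_ref, desc.track)
    mut_track = store.track(mut.chain_ref, desc.track)
    if wt_track is None or mut_track is None:
        raise KeyError(desc.track)
    if wt_track.width != desc.channels or mut_track.width != desc.channels:
        raise ValueError(f"descriptor {desc.name}: channel width mismatch")
    parts = [
        encode_difference(wt_track.values[wt_center][c], mut_track.values[mut_center][c])
        for c in range(desc.channels)
    ]
    return np.concatenate(parts)


def assemble_vector(
    pair: PentamerPair,
    descriptors: list[FeatureDescriptor],
    store: TrackStore,
    strict: bool = False,
) -> FeatureVector:
    """Concatenate descriptor values for one pair in configured order.

    A missing track yields zeros with a warning unless ``strict`` is set,
    in which case a ``KeyError`` propagates.
    """
    chunks = []
    layout = []
    offset = 0
    for desc in descriptors:
        try:
            values = _descriptor_values(desc, pair, store)
        except KeyError as exc:
            if strict:
                raise
            warnings.warn(
                f"track {exc.args[0]!r} unavailable for descriptor "
                f"{desc.name}; filling zeros",
                stacklevel=2,
            )
            values = np.zeros(desc.width)
        if len(values) != desc.width:
            raise ValueError(
                f"descriptor {desc.name} produced {len(values)} values, "
                f"declared width {desc.width}"
            )
        chunks.append(values)
        layout.append((desc.name, offset, desc.width))
        offset += desc.width
    values = np.concatenate(chunks) if chunks else np.zeros(0)
    return FeatureVector(values=values, layout=layout)


def selected_model_descriptors() -> list[FeatureDescriptor]:
    """The nine descriptors of the reference model, in acceptance order.

    Under the pinned per-channel widths these contribute
    2 + 51 + 21 + 21 + 2 + 6 + 13 + 26 + 5 = 147 feature values.
    """
    return [
        FeatureDescriptor("psic_diff", "difference", track="psic", channels=1),
        FeatureDescriptor("ss_w17", "local", track="ss", window=17, channels=3),
        FeatureDescriptor("info_w21", "local", track="info", window=21, channels=1),
        FeatureDescriptor("flexibility_w21", "local", track="flexibility", window=21, channels=1),
        FeatureDescriptor("pssm_diff", "difference", track="pssm", diff_source="column"),
        FeatureDescriptor("ss_single_diff", "difference", track="ss_single", channels=3),
        FeatureDescriptor("pfam_fit_w13", "local", track="pfam_fit", window=13, channels=1),
        FeatureDescriptor("hotspot_w13", "local", track="hotspot", window=13, channels=2),
        FeatureDescriptor("volume_w5", "local", track="prop:volume", window=5, channels=1),
    ]


_LOCAL_TRACK_CHANNELS = {
    "pssm": 20, "freq": 20, "info": 1, "psic": 1,
    "ss": 3, "acc": 3, "disorder": 2, "hotspot": 2, "dna": 2,
    "flexibility": 1, "pfam_fit": 1,
}


def candidate_descriptors() -> list[FeatureDescriptor]:
    """The full candidate pool for forward selection.

    Every global and difference feature plus every combination of local
    track (including the six propensity tracks) and allowed window.
    """
    out = [FeatureDescriptor(name, "global") for name in _GLOBAL_WIDTHS]
    for track, channels in _LOCAL_TRACK_CHANNELS.items():
        for w in ALLOWED_WINDOWS:
            out.append(
                FeatureDescriptor(
                    f"{track}_w{w}", "local", track=track, window=w, channels=channels
                )
            )
    for scale in PROPENSITY_NAMES:
        for w in ALLOWED_WINDOWS:
            out.append(
                FeatureDescriptor(
                    f"prop_{scale}_w{w}", "local", track=f"prop:{scale}",
                    window=w, channels=1,
                )
            )
        out.append(
            FeatureDescriptor(f"prop_{scale}_diff", "difference", track=scale,
                              diff_source="scale")
        )
    out.append(FeatureDescriptor("psic_diff", "difference", track="psic", channels=1))
    out.append(FeatureDescriptor("pssm_diff", "difference", track="pssm", diff_source="column"))
    out.append(FeatureDescriptor("freq_diff", "difference", track="freq", diff_source="column"))
    out.append(FeatureDescriptor("ss_single_diff", "difference", track="ss_single", channels=3))
    out.append(FeatureDescriptor("acc_single_diff", "difference", track="acc_single", channels=3))
    out.append(FeatureDescriptor("disorder_diff", "difference", track="disorder", channels=2))
    return out
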