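"""Bimodal per-residue embeddings: encoder contract, fusion, window framing.

Two frozen encoders produce per-residue representations of the same
protein: an amino-acid-aware track of width 1024 computed from the protein
sequence, and a codon-aware track of width 768 computed from its verified
coding sequence.  Special-token rows are already stripped, so both tracks
have exactly N rows for a protein of length N.  Early fusion concatenates
them horizontally (amino-acid columns first) into an N x 1792 matrix, from
which a window of W rows (default 9: four flanking residues each side)
centered on a candidate S/T/Y site forms one classification sample.
Because each row was computed by a full-sequence encoder, the window
retains global context even though it is spatially local.

The package ships a deterministic synthetic encoder that honours the same
contract.  It assigns every residue a pseudo-random base vector hashed
from its local sequence context and can plant a class signal: whenever a
specified amino-acid motif occurs, a fixed offset is added on designated
embedding coordinates of the residues it covers (optionally extended
``reach`` residues to each side).  This makes datasets separable by
construction, with the signal placed at a known window row, so that the
window/convolution machinery is the component under test.  Adapters to
real pretrained encoders can be plugged in behind the same contract.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from phoskan.errors import ContractError, PhosKANError
from phoskan.genetic_code import translate_cds

AA_DIM = 1024  #: amino-acid track width
CODON_DIM = 768  #: codon track width
FUSED_DIM = AA_DIM + CODON_DIM  #: 1792

_MODALITY_DIMS = {"aa": AA_DIM, "codon": CODON_DIM}


@dataclass(frozen=True)
class EmbeddingMatrix:
    """An N x L per-residue embedding for one modality, specials stripped."""

    values: np.ndarray
    modality: str  # "aa" or "codon"
    protein_id: str = ""

    def __post_init__(self):
        if self.modality not in _MODALITY_DIMS:
            raise ContractError(f"unknown modality {self.modality!r}")
        expect = _MODALITY_DIMS[self.modality]
        if self.values.ndim != 2 or self.values.shape[1] != expect:
            raise ContractError(
                f"{self.modality} embedding must be N x {expect}, got "
                f"shape {self.values.shape}"
            )

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class FusedEmbedding:
    """N x 1792 early-fusion matrix: columns 0-1023 amino-acid track,
    1024-1791 codon track."""

    values: np.ndarray
    protein_id: str = ""

    def __post_init__(self):
        if self.values.ndim != 2 or self.values.shape[1] != FUSED_DIM:
            raise ContractError(
                f"fused embedding must be N x {FUSED_DIM}, got shape "
                f"{self.values.shape}"
            )

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]

    def split_tracks(self) -> Tuple[np.ndarray, np.ndarray]:
        """De-concatenate into (amino-acid track, codon track)."""
        return self.values[:, :AA_DIM], self.values[:, AA_DIM:]


@dataclass(frozen=True)
class WindowSample:
    """One W x 1792 window centered on a candidate site.

    Rows that fall outside the protein are zero-filled and flagged in
    ``pad_mask`` (True = padded).  The site row sits at index W // 2.
    """

    window: np.ndarray
    pad_mask: np.ndarray
    protein_id: str = ""
    position: int = 0  # 1-based site position
    label: Optional[str] = None

    @property
    def width(self) -> int:
        return self.window.shape[0]


def check_embedding(
    matrix: np.ndarray, sequence: str, modality: str
) -> np.ndarray:
    """Validate an encoder's output against the shape contract.

    ``sequence`` is the protein (aa modality) or the verified 3N CDS
    (codon modality); a conforming encoder returns exactly N rows of the
    modality's width, special-token rows already removed.
    """
    if modality not in _MODALITY_DIMS:
        raise ContractError(f"unknown modality {modality!r}")
    n = len(sequence) if modality == "aa" else len(sequence) // 3
    if n == 0:
        raise ContractError("empty sequence has no embedding")
    expect = (n, _MODALITY_DIMS[modality])
    got = np.asarray(matrix)
    if got.shape != expect:
        raise ContractError(
            f"encoder contract violation: expected shape {expect}, "
            f"received {got.shape}"
        )
    return got


@dataclass(frozen=True)
class SignalSpec:
    """Describes the planted class signal understood by the synthetic encoder.

    When ``motif`` occurs in a sequence, coordinates ``coords`` of every
    residue the occurrence covers (extended by ``reach`` residues each
    side) are shifted by ``effect``.  ``effect = 0`` yields a null signal.
    """

    motif: str = "WC"
    coords: Tuple[int, ...] = tuple(range(16))
    effect: float = 3.0
    reach: int = 0
    modality: str = "aa"


class SyntheticEncoder:
    """Deterministic pseudo-embedding encoder for both modalities.

    Each residue's base vector is drawn from a generator seeded by a CRC
    hash of (modality, residue/codon identity, position, seed), so a
    point mutation perturbs exactly its own row and the base vectors
    carry no information about neighbouring residues — the only
    class-relevant structure is the planted signal of a
    :class:`SignalSpec`, added on designated coordinates wherever its
    motif occurs.  Frozen by construction: the same (sequence, modality,
    seed) always yields the same matrix.
    """

    def __init__(self, seed: int = 0, signal: Optional[SignalSpec] = None,
                 scale: float = 1.0):
        self.seed = int(seed)
        self.signal = signal
        self.scale = float(scale)

    def encode(self, sequence: str, modality: str,
               protein_id: str = "") -> EmbeddingMatrix:
        if modality not in _MODALITY_DIMS:
            raise ContractError(f"unknown modality {modality!r}")
        if not sequence:
            raise ContractError("cannot encode an empty sequence")
        dim = _MODALITY_DIMS[modality]
        if modality == "aa":
            units = list(sequence.upper())
            protein = sequence.upper()
        else:
            if len(sequence) % 3 != 0:
                raise ContractError("codon-track input must have length 3N")
            seq = sequence.upper().replace("U", "T")
            units = [seq[i:i + 3] for i in range(0, len(seq), 3)]
            protein = translate_cds(seq).rstrip("*")
        n = len(units)
        out = np.empty((n, dim), dtype=np.float64)
        for i in range(n):
            key = f"{modality}:{units[i]}:{i}:{self.seed}"
            h = zlib.crc32(key.encode())
            rng = np.random.default_rng(h)
            out[i] = rng.standard_normal(dim) * self.scale
        sig = self.signal
        if sig is not None and sig.effect != 0.0 and sig.modality == modality:
            for start in _find_occurrences(protein, sig.motif):
                lo = max(0, start - sig.reach)
                hi = min(n, start + len(sig.motif) + sig.reach)
                for coord in sig.coords:
                    out[lo:hi, coord] += sig.effect
        return EmbeddingMatrix(values=out, modality=modality,
                               protein_id=protein_id)


def _find_occurrences(haystack: str, needle: str):
    start = 0
    while True:
        k = haystack.find(needle, start)
        if k < 0:
            return
        yield k
        start = k + 1


def fuse(aa_track: EmbeddingMatrix, codon_track: EmbeddingMatrix,
         protein_id: str = "") -> FusedEmbedding:
    """Early fusion: horizontal concatenation, amino-acid columns first."""
    if aa_track.modality != "aa" or codon_track.modality != "codon":
        raise ContractError(
            f"fuse expects (aa, codon) tracks, got "
            f"({aa_track.modality}, {codon_track.modality})"
        )
    if aa_track.n_residues != codon_track.n_residues:
        raise ContractError(
            f"row-count mismatch: aa track N={aa_track.n_residues}, "
            f"codon track N={codon_track.n_residues}"
        )
    values = np.concatenate([aa_track.values, codon_track.values], axis=1)
    return FusedEmbedding(values=values,
                          protein_id=protein_id or aa_track.protein_id)


def frame_window(fused: FusedEmbedding, position: int, W: int = 9,
                 label: Optional[str] = None) -> WindowSample:
    """Extract the W-row window centered on the 1-based ``position``.

    W must be odd (W = 2*theta + 1); rows beyond the sequence ends are
    zero-filled and flagged in the pad mask.
    """
    if W % 2 != 1 or W < 1:
        raise PhosKANError(f"window size must be odd and positive, got {W}")
    n = fused.n_residues
    if not 1 <= position <= n:
        raise PhosKANError(f"position {position} outside 1..{n}")
    theta = W // 2
    center = position - 1
    window = np.zeros((W, FUSED_DIM), dtype=fused.values.dtype)
    pad_mask = np.ones(W, dtype=bool)
    lo = max(0, center - theta)
    hi = min(n, center + theta + 1)
    w_lo = lo - (center - theta)
    window[w_lo : w_lo + (hi - lo)] = fused.values[lo:hi]
    pad_mask[w_lo : w_lo + (hi - lo)] = False
    return WindowSample(window=window, pad_mask=pad_mask,
                        protein_id=fused.protein_id, position=position,
                        label=label)


def embed_protein(
    protein_seq: str, cds_seq: str, encoder: SyntheticEncoder,
    protein_id: str = "",
) -> FusedEmbedding:
    """Run both tracks of an encoder on a verified pair and fuse them."""
    aa = encoder.encode(protein_seq, "aa", protein_id)
    check_embedding(aa.values, protein_seq, "aa")
    codon = encoder.encode(cds_seq, "codon", protein_id)
    check_embedding(codon.values, cds_seq, "codon")
    return fuse(aa, codon, protein_id=protein_id)
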