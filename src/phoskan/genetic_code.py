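"""Standard genetic code tables, vocabularies and tokenization conventions.

The genetic code maps 64 codons onto 20 amino acids plus three stop codons
(TAA, TAG, TGA) — a surjective, non-injective ("degenerate") mapping in
which an amino acid is encoded by between one (Met, Trp) and six (Leu, Ser,
Arg) synonymous codons.  Both DNA (T) and RNA (U) spellings are accepted
and canonicalized to DNA internally.

Two tokenization conventions are provided, one per embedding modality:

* codon track — a coding sequence of 3N nucleotides becomes N codon tokens
  bracketed by a start and an end marker (N + 2 tokens total);
* amino-acid track — a protein of N residues becomes N residue tokens
  followed by a single end marker (N + 1 tokens total), with the rare
  letters U, Z, O and B collapsed onto a pseudo-residue token X.

Token ids are assigned deterministically: the 64 codons sorted
lexicographically over {A, C, G, T} receive ids 0-63, specials follow.
Only row counts of downstream embedding matrices are contractual; the id
layout is fixed here purely for reproducibility.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Tuple

from Bio.Data import CodonTable as _bio_codon_table

from phoskan.errors import FrameError, InvalidCodonError, InvalidResidueError

#: Marker returned by :func:`translate_codon` for the three stop codons.
STOP = "*"

#: The 20 canonical amino-acid letters, alphabetical.
CANONICAL_AA: str = "ACDEFGHIKLMNPQRSTVWY"

#: Rare/ambiguous residue letters collapsed onto the pseudo-residue X.
RARE_AA_TO_X: FrozenSet[str] = frozenset("UZOB")

_NUCLEOTIDES = frozenset("ACGT")


@dataclass(frozen=True)
class CodonTable:
    """The standard genetic code.

    Parameters
    ----------
    sense_map
        Codon string (DNA alphabet) to single-letter amino acid, for the
        61 sense codons.
    stop_set
        The stop codons, canonically {TAA, TAG, TGA}.
    accepts_rna
        Whether U is accepted on input and canonicalized to T.
    """

    sense_map: Dict[str, str]
    stop_set: FrozenSet[str]
    accepts_rna: bool = True
    _inverse: Dict[str, Tuple[str, ...]] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        n_codons = len(self.sense_map) + len(self.stop_set)
        if n_codons != 64:
            raise InvalidCodonError(f"codon table must cover 64 codons, got {n_codons}")
        inverse: Dict[str, List[str]] = {}
        for codon, aa in self.sense_map.items():
            inverse.setdefault(aa, []).append(codon)
        object.__setattr__(
            self, "_inverse", {aa: tuple(sorted(cs)) for aa, cs in inverse.items()}
        )

    def codons_for(self, aa: str) -> Tuple[str, ...]:
        """All synonymous codons encoding ``aa``, lexicographically sorted."""
        aa = aa.upper()
        if aa not in self._inverse:
            raise InvalidResidueError(f"unknown amino acid {aa!r}")
        return self._inverse[aa]

    def checksum(self) -> str:
        """Stable hex digest of the code, recorded in run logs for provenance."""
        payload = ";".join(
            f"{c}:{a}" for c, a in sorted(self.sense_map.items())
        ) + "|" + ",".join(sorted(self.stop_set))
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def standard_table() -> CodonTable:
    """The standard (NCBI translation table 1) genetic code."""
    bio = _bio_codon_table.unambiguous_dna_by_id[1]
    return CodonTable(
        sense_map=dict(bio.forward_table), stop_set=frozenset(bio.stop_codons)
    )


_STANDARD = standard_table()


def canonicalize_codon(codon: str, table: CodonTable | None = None) -> str:
    """Uppercase, map U to T, and validate a single codon string."""
    table = table or _STANDARD
    if not isinstance(codon, str) or len(codon) != 3:
        raise InvalidCodonError(f"codon must be a 3-letter string, got {codon!r}")
    out = codon.upper()
    if table.accepts_rna:
        out = out.replace("U", "T")
    if not set(out) <= _NUCLEOTIDES:
        raise InvalidCodonError(f"codon {codon!r} contains non-ACGTU characters")
    return out


def translate_codon(codon: str, table: CodonTable | None = None) -> str:
    """Translate one codon under the standard code.

    Returns the amino-acid letter, or :data:`STOP` for TAA/TAG/TGA.
    """
    table = table or _STANDARD
    canon = canonicalize_codon(codon, table)
    if canon in table.stop_set:
        return STOP
    return table.sense_map[canon]


def degeneracy(aa: str, table: CodonTable | None = None) -> int:
    """Number of synonymous codons encoding amino acid ``aa`` (1-6)."""
    table = table or _STANDARD
    return len(table.codons_for(aa))


def translate_cds(cds: str, table: CodonTable | None = None) -> str:
    """Translate a coding sequence codon-by-codon; stops appear as ``*``."""
    if len(cds) % 3 != 0:
        raise FrameError(f"CDS length {len(cds)} is not a multiple of 3")
    return "".join(
        translate_codon(cds[i : i + 3], table) for i in range(0, len(cds), 3)
    )


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------

#: Codon vocabulary: 64 codons sorted lexicographically, ids 0-63.
CODON_VOCAB: Dict[str, int] = {
    a + b + c: i
    for i, (a, b, c) in enumerate(
        (a, b, c) for a in "ACGT" for b in "ACGT" for c in "ACGT"
    )
}
CODON_START_ID = 64  #: start-of-sequence marker on the codon track
CODON_END_ID = 65  #: end-of-sequence marker on the codon track

#: Protein vocabulary: 20 canonical residues + X, then the end marker.
PROTEIN_VOCAB: Dict[str, int] = {aa: i for i, aa in enumerate(CANONICAL_AA + "X")}
PROTEIN_END_ID = len(PROTEIN_VOCAB)  # 21


@dataclass(frozen=True)
class TokenSequence:
    """An integer token sequence for one modality.

    ``special_positions`` marks the indices of start/end markers inside
    ``tokens``; the remaining positions map 1:1 onto residues.
    """

    tokens: Tuple[int, ...]
    special_positions: Tuple[int, ...]
    modality: str  # "codon" or "aa"

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def n_residues(self) -> int:
        return len(self.tokens) - len(self.special_positions)


def tokenize_cds(cds: str, table: CodonTable | None = None) -> TokenSequence:
    """Tokenize a coding sequence: start marker, N codon tokens, end marker."""
    table = table or _STANDARD
    if len(cds) % 3 != 0:
        raise FrameError(f"CDS length {len(cds)} is not a multiple of 3")
    body = [
        CODON_VOCAB[canonicalize_codon(cds[i : i + 3], table)]
        for i in range(0, len(cds), 3)
    ]
    tokens = (CODON_START_ID, *body, CODON_END_ID)
    return TokenSequence(
        tokens=tokens, special_positions=(0, len(tokens) - 1), modality="codon"
    )


def tokenize_protein(seq: str) -> TokenSequence:
    """Tokenize a protein: N residue tokens plus a single end marker.

    U, Z, O and B map to the pseudo-residue X; any other letter outside the
    canonical alphabet is rejected.
    """
    if not seq:
        raise InvalidResidueError("empty protein sequence")
    body = []
    for ch in seq:
        up = ch.upper()
        if not up.isalpha():
            raise InvalidResidueError(f"non-alphabetic residue {ch!r}")
        if up in RARE_AA_TO_X:
            up = "X"
        if up not in PROTEIN_VOCAB:
            raise InvalidResidueError(f"unknown residue letter {ch!r}")
        body.append(PROTEIN_VOCAB[up])
    tokens = (*body, PROTEIN_END_ID)
    return TokenSequence(
        tokens=tokens, special_positions=(len(tokens) - 1,), modality="aa"
    )
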