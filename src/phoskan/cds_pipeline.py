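"""Reverse-translation verification and labeled-site dataset construction.

Recovering the true coding sequence (CDS) of a protein is non-trivial
because the genetic code is degenerate: naive reverse translation would
have to guess among synonymous codons.  Instead, candidate CDS features are
read from curated GenBank records, each candidate is translated under the
standard code and globally aligned (Needleman-Wunsch) against the target
protein, and only pairs at 100% identity are kept.  A single terminal stop
codon, if present, is stripped, after which the CDS is exactly three times
the protein length.

Site datasets are then built on the verified proteins: every S/T/Y residue
becomes one record, labeled P (phosphorylated) when experimentally
annotated and NP otherwise; splits are made at protein granularity and the
negative class may be randomly undersampled to balance.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO

from phoskan.errors import FrameError, PhosKANError, VerificationFailure
from phoskan.genetic_code import STOP, CodonTable, standard_table, translate_cds

SITE_RESIDUES = frozenset("STY")


# ---------------------------------------------------------------------------
# Needleman-Wunsch global alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoringScheme:
    """Linear-gap global alignment scoring.

    Defaults (+1 match, -1 mismatch, -2 gap) are chosen for easy hand
    verification; the downstream accept/reject decision only depends on
    whether identity reaches 100%, which any sensible scheme agrees on.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0


@dataclass(frozen=True)
class AlignmentResult:
    """One optimal global alignment plus its score and identity.

    ``identity_percent`` uses the full alignment length as denominator, so
    gapped columns count against identity and 100% identity is equivalent
    to exact sequence equality.
    """

    aligned_a: str
    aligned_b: str
    score: float
    identity_percent: float

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise PhosKANError("aligned strings must have equal length")


def needleman_wunsch(
    a: str, b: str, scoring: ScoringScheme | None = None
) -> AlignmentResult:
    """Optimal global alignment of ``a`` and ``b`` by dynamic programming.

    Traceback ties break deterministically diagonal > up > left, where
    "up" consumes a character of ``a`` against a gap.  Empty vs empty
    aligns with score 0 and identity 100 by convention.
    """
    scoring = scoring or ScoringScheme()
    n, m = len(a), len(b)
    if n == 0 and m == 0:
        return AlignmentResult("", "", 0.0, 100.0)

    F = np.empty((n + 1, m + 1), dtype=float)
    F[0, :] = scoring.gap * np.arange(m + 1)
    F[:, 0] = scoring.gap * np.arange(n + 1)
    a_arr = np.frombuffer(a.encode("latin-1"), dtype=np.uint8)
    b_arr = np.frombuffer(b.encode("latin-1"), dtype=np.uint8)
    for i in range(1, n + 1):
        sub = np.where(b_arr == a_arr[i - 1], scoring.match, scoring.mismatch)
        row = F[i - 1]
        cur = F[i]
        for j in range(1, m + 1):
            cur[j] = max(row[j - 1] + sub[j - 1], row[j] + scoring.gap,
                         cur[j - 1] + scoring.gap)

    # Traceback, diagonal > up > left.
    out_a: List[str] = []
    out_b: List[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            s = scoring.match if a[i - 1] == b[j - 1] else scoring.mismatch
            if F[i, j] == F[i - 1, j - 1] + s:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i -= 1
                j -= 1
                continue
        if i > 0 and F[i, j] == F[i - 1, j] + scoring.gap:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
            continue
        out_a.append("-")
        out_b.append(b[j - 1])
        j -= 1

    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    matches = sum(x == y and x != "-" for x, y in zip(aligned_a, aligned_b))
    identity = 100.0 * matches / len(aligned_a)
    return AlignmentResult(aligned_a, aligned_b, float(F[n, m]), identity)


# ---------------------------------------------------------------------------
# CDS extraction and verification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodingRecord:
    """A verified protein/CDS pair: stop-stripped CDS of length exactly 3N
    whose codon-by-codon translation reproduces the protein."""

    protein_id: str
    protein_seq: str
    cds_seq: str
    source: str = ""
    identity_percent: float = 100.0

    def __post_init__(self):
        if len(self.cds_seq) != 3 * len(self.protein_seq):
            raise PhosKANError(
                f"{self.protein_id}: CDS length {len(self.cds_seq)} != "
                f"3 x {len(self.protein_seq)}"
            )
        if self.identity_percent != 100.0:
            raise PhosKANError("CodingRecord requires 100% identity")


def extract_cds_from_genbank(record) -> List[Tuple[str, str | None]]:
    """CDS features of one GenBank record as (cds_seq, declared_translation).

    ``record`` may be GenBank-format text, a file path, or a parsed
    ``SeqRecord``.  Nucleotide subsequences are assembled from each CDS
    feature's location spec (join(...) locations are spliced); the
    /translation qualifier is returned alongside when present.  A record
    with no CDS feature yields an empty list with a warning.
    """
    if isinstance(record, str):
        if "\n" in record or record.lstrip().startswith("LOCUS"):
            handle = io.StringIO(record)
        else:
            handle = open(record)
        with handle:
            parsed = list(SeqIO.parse(handle, "genbank"))
        out: List[Tuple[str, str | None]] = []
        for rec in parsed:
            out.extend(extract_cds_from_genbank(rec))
        return out

    results: List[Tuple[str, str | None]] = []
    for feat in record.features:
        if feat.type != "CDS":
            continue
        try:
            sub = str(feat.location.extract(record.seq))
        except Exception as exc:  # unparsable/out-of-range location
            raise PhosKANError(
                f"record {record.id}: cannot extract CDS location "
                f"{feat.location}: {exc}"
            ) from exc
        translation = feat.qualifiers.get("translation", [None])[0]
        results.append((sub, translation))
    if not results:
        warnings.warn(f"record {getattr(record, 'id', '?')} has no CDS feature")
    return results


def verify_and_strip(
    cds: str,
    protein: str,
    table: CodonTable | None = None,
    protein_id: str = "",
    source: str = "",
    scoring: ScoringScheme | None = None,
) -> CodingRecord:
    """Verify a candidate CDS against its protein and strip the stop codon.

    The CDS is translated under the standard code, a single terminal stop
    codon is removed if present, and the product is globally aligned to the
    protein.  Acceptance requires 100% identity; an internal stop codon or
    any mismatch raises :class:`VerificationFailure`.
    """
    table = table or standard_table()
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise FrameError(
            f"{protein_id}: CDS length {len(cds)} is not a multiple of 3"
        )
    translated = translate_cds(cds, table)
    if translated.endswith(STOP):
        translated = translated[:-1]
        cds = cds[:-3]
    if STOP in translated:
        raise VerificationFailure(
            f"{protein_id}: internal stop codon at residue "
            f"{translated.index(STOP) + 1}",
            reason="internal_stop",
        )
    aln = needleman_wunsch(translated, protein, scoring)
    if aln.identity_percent != 100.0:
        raise VerificationFailure(
            f"{protein_id}: translated CDS does not match protein "
            f"(identity {aln.identity_percent:.2f}%)",
            reason="identity_below_100",
            identity_percent=aln.identity_percent,
        )
    return CodingRecord(
        protein_id=protein_id,
        protein_seq=protein,
        cds_seq=cds,
        source=source,
        identity_percent=100.0,
    )


def reverse_translate(
    proteins: Dict[str, str],
    genbank_records: Dict[str, object],
    table: CodonTable | None = None,
    scoring: ScoringScheme | None = None,
) -> Tuple[List[CodingRecord], pd.DataFrame]:
    """Verify every protein against its GenBank record's CDS candidates.

    ``genbank_records`` maps protein id to GenBank text/path/SeqRecord.
    For records with several CDS features the first candidate passing the
    100%-identity filter is accepted and alternates are noted.  Returns the
    accepted records and a rejection report (protein_id, reason,
    identity_percent).
    """
    accepted: List[CodingRecord] = []
    rows = []
    for pid, pseq in proteins.items():
        if pid not in genbank_records:
            rows.append({"protein_id": pid, "reason": "no_genbank_record",
                         "identity_percent": np.nan})
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            candidates = extract_cds_from_genbank(genbank_records[pid])
        if not candidates:
            rows.append({"protein_id": pid, "reason": "no_cds_feature",
                         "identity_percent": np.nan})
            continue
        best_failure = None
        for k, (cds, _decl) in enumerate(candidates):
            try:
                rec = verify_and_strip(
                    cds, pseq, table, protein_id=pid,
                    source=f"genbank:cds[{k}]", scoring=scoring,
                )
            except PhosKANError as exc:
                best_failure = exc
                continue
            accepted.append(rec)
            break
        else:
            identity = getattr(best_failure, "identity_percent", None)
            rows.append({
                "protein_id": pid,
                "reason": getattr(best_failure, "reason", "frame_error"),
                "identity_percent": np.nan if identity is None else identity,
            })
    report = pd.DataFrame(rows, columns=["protein_id", "reason",
                                         "identity_percent"])
    return accepted, report


# ---------------------------------------------------------------------------
# Site labeling, splits, balancing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteRecord:
    """One candidate phosphosite: a S/T/Y residue with a binary label."""

    protein_id: str
    position: int  # 1-based
    residue: str  # S, T or Y
    label: str  # "P" or "NP"

    def __post_init__(self):
        if self.residue not in SITE_RESIDUES:
            raise PhosKANError(f"residue {self.residue!r} is not S/T/Y")
        if self.label not in ("P", "NP"):
            raise PhosKANError(f"label {self.label!r} must be P or NP")
        if self.position < 1:
            raise PhosKANError("positions are 1-based")


def label_sites(
    protein_id: str, protein_seq: str, annotated_positions: Set[int]
) -> List[SiteRecord]:
    """Every S/T/Y residue becomes one record; annotated positions are P,
    all remaining S/T/Y are NP.  Annotating a non-S/T/Y residue is an error."""
    for pos in annotated_positions:
        if pos < 1 or pos > len(protein_seq):
            raise PhosKANError(
                f"{protein_id}: annotated position {pos} outside 1..{len(protein_seq)}"
            )
        if protein_seq[pos - 1] not in SITE_RESIDUES:
            raise PhosKANError(
                f"{protein_id}: annotation at position {pos} targets "
                f"{protein_seq[pos - 1]!r}, not S/T/Y"
            )
    return [
        SiteRecord(
            protein_id=protein_id,
            position=i + 1,
            residue=ch,
            label="P" if (i + 1) in annotated_positions else "NP",
        )
        for i, ch in enumerate(protein_seq)
        if ch in SITE_RESIDUES
    ]


@dataclass(frozen=True)
class DatasetSplit:
    """A protein-level train/test partition (no id overlap by construction)."""

    train_ids: frozenset
    test_ids: frozenset
    seed: int

    def __post_init__(self):
        if self.train_ids & self.test_ids:
            raise PhosKANError("train/test protein sets overlap")


def split_by_protein(
    ids: Sequence[str], ratio: float = 0.9, seed: int = 0
) -> DatasetSplit:
    """Random train/test partition at protein granularity (default 9:1)."""
    ids = list(dict.fromkeys(ids))
    if len(ids) < 2:
        raise PhosKANError("need at least 2 protein ids to split")
    if not 0.0 < ratio < 1.0:
        raise PhosKANError("ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(round(ratio * len(ids)))
    n_train = min(max(n_train, 1), len(ids) - 1)
    train = frozenset(ids[k] for k in order[:n_train])
    test = frozenset(ids[k] for k in order[n_train:])
    return DatasetSplit(train_ids=train, test_ids=test, seed=seed)


def balance_undersample(
    sites: Sequence[SiteRecord], seed: int = 0
) -> List[SiteRecord]:
    """Random undersampling of the negative (NP) class to a 1:1 ratio.

    All P sites are retained; NP sites are subsampled without replacement.
    Output order follows the input order.
    """
    pos = [s for s in sites if s.label == "P"]
    neg = [s for s in sites if s.label == "NP"]
    if not pos or not neg:
        raise PhosKANError("both classes must be present to balance")
    if len(neg) <= len(pos):
        return list(sites)
    rng = np.random.default_rng(seed)
    keep = set(rng.choice(len(neg), size=len(pos), replace=False).tolist())
    kept_neg = {id(neg[k]) for k in keep}
    return [s for s in sites if s.label == "P" or id(s) in kept_neg]


# ---------------------------------------------------------------------------
# Tabular I/O for annotations and site tables
# ---------------------------------------------------------------------------

def sites_to_frame(sites: Iterable[SiteRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"protein_id": s.protein_id, "position": s.position,
             "residue": s.residue, "label": s.label}
            for s in sites
        ],
        columns=["protein_id", "position", "residue", "label"],
    )


def frame_to_sites(df: pd.DataFrame) -> List[SiteRecord]:
    return [
        SiteRecord(str(r.protein_id), int(r.position), str(r.residue),
                   str(r.label))
        for r in df.itertuples(index=False)
    ]


def read_site_table(path) -> List[SiteRecord]:
    """Read a tab-delimited site table (protein_id, position, residue, label)."""
    return frame_to_sites(pd.read_csv(path, sep="\t"))


def write_site_table(sites: Iterable[SiteRecord], path) -> None:
    sites_to_frame(sites).to_csv(path, sep="\t", index=False)
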