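"""Sequence-similarity baseline predictor.

A query is called family-positive when any sequence in the family's
reference database aligns to it with E-value <= 0.001 and percent
identity >= 40 — the classic "safe transfer" zone for function annotation.

Two interchangeable backends satisfy the same contract:

* the default internal backend: optimal local (Smith-Waterman) alignment
  under BLOSUM62 with affine gaps (open 11, extend 1, BLAST convention),
  via Biopython's C aligner, with E-values from the Karlin-Altschul form

      E = K * m * n * exp(-lambda * S)

  using the published gapped BLOSUM62/11-1 parameters
  (lambda = 0.267, K = 0.041; Altschul et al. 1997, Table 2).
  Effective-length edge corrections are deliberately omitted — at the
  small database sizes used per family they change E by a modest constant
  factor and no decision near the cutoff depends on them.
* an optional external backend shelling out to NCBI blastp, used as an
  independent cross-check of the internal calls.

Percent identity uses the external tool's convention: identical aligned
pairs divided by alignment length *including gap columns*.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

from Bio import Align
from Bio.Align import substitution_matrices

from .datasets import deduplicate
from .records import ProteinRecord

# Gapped Karlin-Altschul parameters for BLOSUM62, gap open 11 / extend 1.
GAPPED_LAMBDA = 0.267
GAPPED_K = 0.041

DEFAULT_E_CUTOFF = 1e-3
DEFAULT_ID_CUTOFF = 40.0


@dataclass(frozen=True)
class AlignmentResult:
    query_id: str
    subject_id: str
    raw_score: float
    bit_score: float
    e_value: float
    identity_percent: float
    alignment_length: int


@dataclass
class ReferenceDB:
    """Deduplicated positive reference sequences for one family."""

    family_id: str
    sequences: list[ProteinRecord]
    total_residues: int
    n_sequences: int

    def digest(self) -> tuple:
        return tuple((r.id, r.sequence) for r in self.sequences)


def build_reference(family_id: str, records: list[ProteinRecord]) -> ReferenceDB:
    if not records:
        raise ValueError("cannot build a reference database from no records")
    records = deduplicate(records)
    return ReferenceDB(
        family_id=family_id,
        sequences=records,
        total_residues=sum(len(r.sequence) for r in records),
        n_sequences=len(records),
    )


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # Biopython charges open for the first gap residue; BLAST's 11/1 makes
    # a length-k gap cost 11 + k, i.e. 12 for the first residue.
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER: Align.PairwiseAligner | None = None


def _aligner() -> Align.PairwiseAligner:
    global _ALIGNER
    if _ALIGNER is None:
        _ALIGNER = _make_aligner()
    return _ALIGNER


def _sanitize(seq: str) -> str:
    # the BLOSUM62 table lacks J/O/U; map them to X (scored as ambiguity)
    return seq.upper().replace("J", "X").replace("O", "X").replace("U", "X")


def evalue_from_score(score: float, query_len: int, db_residues: int) -> float:
    return GAPPED_K * query_len * db_residues * math.exp(-GAPPED_LAMBDA * score)


def bit_score_from_raw(score: float) -> float:
    return (GAPPED_LAMBDA * score - math.log(GAPPED_K)) / math.log(2.0)


def raw_score(query: str, subject: str) -> float:
    """Optimal local alignment score (no traceback; fast path)."""
    return float(_aligner().score(_sanitize(query), _sanitize(subject)))


def align(
    query: str,
    subject: str,
    db_residues: int,
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentResult:
    """Best local alignment of two sequences with search statistics.

    ``db_residues`` is the total residue count of the database being
    searched (the n of the Karlin-Altschul formula).
    """
    q, s = _sanitize(query), _sanitize(subject)
    aln = _aligner().align(q, s)[0]
    counts = aln.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    score = float(aln.score)
    return AlignmentResult(
        query_id=query_id,
        subject_id=subject_id,
        raw_score=score,
        bit_score=bit_score_from_raw(score),
        e_value=evalue_from_score(score, len(q), db_residues),
        identity_percent=100.0 * counts.identities / length if length else 0.0,
        alignment_length=length,
    )


def classify_by_similarity(
    query: str,
    db: ReferenceDB,
    e_cutoff: float = DEFAULT_E_CUTOFF,
    id_cutoff: float = DEFAULT_ID_CUTOFF,
    query_id: str = "query",
) -> tuple[bool, AlignmentResult | None]:
    """Positive iff some subject passes both cutoffs; returns the best hit.

    Scores every subject first (cheap, no traceback) and only reconstructs
    alignments for subjects whose E-value alone passes the cutoff — the
    identity filter needs the traceback, the E-value does not. The best
    hit is the lowest E-value, ties broken by higher identity then by
    subject id.
    """
    if not db.sequences:
        raise ValueError("empty reference database")
    scores = [(raw_score(query, rec.sequence), rec) for rec in db.sequences]
    candidates = [
        (s, rec)
        for s, rec in scores
        if evalue_from_score(s, len(query), db.total_residues) <= e_cutoff
    ]
    if not candidates:
        best_s, best_rec = max(scores, key=lambda t: t[0])
        return False, align(
            query, best_rec.sequence, db.total_residues, query_id, best_rec.id
        )
    hits = [
        align(query, rec.sequence, db.total_residues, query_id, rec.id)
        for _, rec in candidates
    ]
    hits.sort(key=lambda h: (h.e_value, -h.identity_percent, h.subject_id))
    passing = [h for h in hits if h.identity_percent >= id_cutoff]
    if passing:
        return True, passing[0]
    return False, hits[0]


# ---------------------------------------------------------------------------
# External NCBI BLAST+ backend


def blastp_available() -> bool:
    return shutil.which("blastp") is not None and shutil.which("makeblastdb") is not None


def classify_with_blastp(
    queries: list[ProteinRecord],
    db: ReferenceDB,
    e_cutoff: float = DEFAULT_E_CUTOFF,
    id_cutoff: float = DEFAULT_ID_CUTOFF,
) -> dict[str, bool]:
    """Batch classification through NCBI blastp (outfmt 6).

    Runs blastp with ``-evalue e_cutoff`` and post-filters hits at
    ``pident >= id_cutoff``; returns query id -> call. Composition-based
    score adjustment is disabled to match the internal statistics.
    """
    if not blastp_available():
        raise RuntimeError("blastp / makeblastdb not found on PATH")
    from .io import write_fasta

    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        db_fa, q_fa = tmp / "db.fasta", tmp / "q.fasta"
        write_fasta(db.sequences, db_fa)
        write_fasta(queries, q_fa)
        subprocess.run(
            ["makeblastdb", "-in", str(db_fa), "-dbtype", "prot"],
            check=True,
            capture_output=True,
        )
        out = subprocess.run(
            [
                "blastp",
                "-query", str(q_fa),
                "-db", str(db_fa),
                "-evalue", str(e_cutoff),
                "-comp_based_stats", "0",
                "-seg", "no",
                "-outfmt", "6 qseqid sseqid pident length evalue bitscore",
            ],
            check=True,
            capture_output=True,
            text=True,
        ).stdout
    calls = {rec.id: False for rec in queries}
    for line in out.splitlines():
        qid, _sid, pident, _length, _evalue, _bits = line.split("\t")
        if float(pident) >= id_cutoff:
            calls[qid] = True
    return calls


def hits_table(
    queries: list[ProteinRecord], db: ReferenceDB, e_cutoff: float = DEFAULT_E_CUTOFF
) -> list[AlignmentResult]:
    """Best internal-backend hit per query, outfmt-6-shaped."""
    out = []
    for rec in queries:
        _, best = classify_by_similarity(
            rec.sequence, db, e_cutoff=e_cutoff, id_cutoff=0.0, query_id=rec.id
        )
        if best is not None:
            out.append(best)
    return out
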