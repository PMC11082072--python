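"""Dataset-hygiene audit: flag homologous sequences between peptide sets.

A query is redundant if some database sequence (other than itself, for
within-set comparisons) aligns with e-value ≤ 1e-5. Training sets with
high within-set redundancy inflate apparent sample size; test sequences
homologous to training sequences inflate measured generalization. The
audit reports four directional ratios: train-to-train, train-to-test,
test-to-train, and test-to-test.

The default backend is exact Smith–Waterman local alignment (affine
gaps, BLOSUM62) with Karlin–Altschul e-values E = K·m·n·exp(−λS), so the
audit needs no external binary; an external BLAST backend with the same
interface is available when `makeblastdb`/`blastp` are installed.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Protocol

from Bio import Align
from Bio.Align import substitution_matrices

from .records import PeptideDataset, write_fasta


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme and Karlin–Altschul statistics.

    λ and K default to customary gapped-BLOSUM62 values. gap_open is the
    score of the first residue of a gap and gap_extend of each further
    residue, so a length-g gap scores gap_open + (g−1)·gap_extend.
    """

    substitution_matrix: str = "BLOSUM62"
    gap_open: int = -11
    gap_extend: int = -1
    lambda_: float = 0.267
    k_: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_open > 0 or self.gap_extend > 0:
            raise AlignmentError("gap penalties must be non-positive scores")
        if self.lambda_ <= 0 or self.k_ <= 0:
            raise AlignmentError("lambda and K must be positive")


def _make_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    matrix = substitution_matrices.load(params.substitution_matrix)
    aligner = Align.PairwiseAligner(
        mode="local",
        substitution_matrix=matrix,
        open_gap_score=params.gap_open,
        extend_gap_score=params.gap_extend,
    )
    return aligner


def smith_waterman_score(query: str, subject: str,
                         params: Optional[AlignmentParams] = None) -> int:
    """Optimal local-alignment score (affine gaps); 0 if nothing positive."""
    if not query or not subject:
        raise AlignmentError("cannot align an empty sequence")
    params = params or AlignmentParams()
    aligner = _make_aligner(params)
    return int(aligner.score(query, subject))


def karlin_altschul_evalue(score: float, query_len: int, db_len: int,
                           params: Optional[AlignmentParams] = None) -> float:
    """E = K·m·n·exp(−λ·S): expected chance alignments at score ≥ S."""
    if query_len <= 0 or db_len <= 0:
        raise AlignmentError("query_len and db_len must be positive")
    params = params or AlignmentParams()
    return params.k_ * query_len * db_len * math.exp(-params.lambda_ * score)


@dataclass
class Hit:
    query_id: str
    subject_id: str
    score: float
    evalue: float


class HomologyBackend(Protocol):
    def best_hits(self, queries: PeptideDataset, database: PeptideDataset,
                  exclude_self: bool) -> dict[str, Hit]:
        """Best (lowest e-value) database hit per query id."""


class BuiltinBackend:
    """Exact Smith–Waterman + Karlin–Altschul e-values, no external binary.

    The e-value search space uses m = query length and n = total residue
    count of the database, the closest analog of BLAST's convention at
    this scale.
    """

    def __init__(self, params: Optional[AlignmentParams] = None):
        self.params = params or AlignmentParams()

    def best_hits(self, queries: PeptideDataset, database: PeptideDataset,
                  exclude_self: bool) -> dict[str, Hit]:
        aligner = _make_aligner(self.params)
        db_len = sum(len(r.sequence) for r in database)
        hits: dict[str, Hit] = {}
        for q in queries:
            best: Optional[Hit] = None
            for s in database:
                if exclude_self and s.id == q.id:
                    continue
                score = float(aligner.score(q.sequence, s.sequence))
                evalue = karlin_altschul_evalue(score, len(q.sequence), db_len,
                                                self.params)
                if best is None or evalue < best.evalue or (
                        evalue == best.evalue and s.id < best.subject_id):
                    best = Hit(query_id=q.id, subject_id=s.id, score=score,
                               evalue=evalue)
            if best is not None:
                hits[q.id] = best
        return hits


class BlastBackend:
    """External BLAST (makeblastdb + blastp) behind the same interface."""

    def __init__(self, task: str = "blastp-short"):
        for exe in ("makeblastdb", "blastp"):
            if shutil.which(exe) is None:
                raise AlignmentError(f"external BLAST backend needs {exe!r} on PATH")
        self.task = task

    def best_hits(self, queries: PeptideDataset, database: PeptideDataset,
                  exclude_self: bool) -> dict[str, Hit]:
        with tempfile.TemporaryDirectory() as tmp:
            tmp_path = Path(tmp)
            q_fa = tmp_path / "queries.fasta"
            db_fa = tmp_path / "db.fasta"
            write_fasta(queries, q_fa)
            write_fasta(database, db_fa)
            subprocess.run(
                ["makeblastdb", "-in", str(db_fa), "-dbtype", "prot"],
                check=True, capture_output=True,
            )
            result = subprocess.run(
                ["blastp", "-task", self.task, "-query", str(q_fa),
                 "-db", str(db_fa), "-outfmt", "6 qseqid sseqid bitscore evalue",
                 "-evalue", "1000", "-max_target_seqs", "500"],
                check=True, capture_output=True, text=True,
            )
        hits: dict[str, Hit] = {}
        for line in result.stdout.splitlines():
            qid, sid, bitscore, evalue = line.split("\t")
            if exclude_self and qid == sid:
                continue
            hit = Hit(query_id=qid, subject_id=sid, score=float(bitscore),
                      evalue=float(evalue))
            prev = hits.get(qid)
            if prev is None or hit.evalue < prev.evalue:
                hits[qid] = hit
        return hits


@dataclass
class RedundancyReport:
    train_to_train: float
    train_to_test: float
    test_to_train: float
    test_to_test: float
    hits: dict[str, list[Hit]] = field(default_factory=dict)

    def report_fields(self) -> dict:
        return {
            "train_to_train": self.train_to_train,
            "train_to_test": self.train_to_test,
            "test_to_train": self.test_to_train,
            "test_to_test": self.test_to_test,
        }


def redundancy_ratio(queries: PeptideDataset, database: PeptideDataset,
                     threshold: float = 1e-5, exclude_self: bool = False,
                     backend: Optional[HomologyBackend] = None,
                     ) -> tuple[float, list[Hit]]:
    """Fraction of queries with a database homolog at e-value ≤ threshold.

    Returns the ratio and the flagged queries' best hits. With
    ``exclude_self``, a subject with the same record id as the query is
    skipped (within-set comparisons).
    """
    if len(queries) == 0:
        raise AlignmentError("empty query set")
    if len(database) == 0:
        raise AlignmentError("empty database set")
    if threshold <= 0:
        raise AlignmentError("threshold must be positive")
    backend = backend or BuiltinBackend()
    best = backend.best_hits(queries, database, exclude_self)
    flagged = [hit for hit in best.values() if hit.evalue <= threshold]
    flagged.sort(key=lambda h: h.query_id)
    return len(flagged) / len(queries), flagged


def audit_datasets(train: PeptideDataset, test: PeptideDataset,
                   params: Optional[AlignmentParams] = None,
                   threshold: float = 1e-5,
                   backend: Optional[HomologyBackend] = None) -> RedundancyReport:
    """All four directional redundancy ratios (within-set directions
    exclude the query itself)."""
    backend = backend or BuiltinBackend(params)
    directions = {
        "train_to_train": (train, train, True),
        "train_to_test": (train, test, False),
        "test_to_train": (test, train, False),
        "test_to_test": (test, test, True),
    }
    ratios = {}
    hits = {}
    for name, (q, db, excl) in directions.items():
        ratio, flagged = redundancy_ratio(q, db, threshold=threshold,
                                          exclude_self=excl, backend=backend)
        ratios[name] = ratio
        hits[name] = flagged
    return RedundancyReport(**ratios, hits=hits)
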