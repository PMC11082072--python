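"""Local-alignment scoring, e-values, and the directional redundancy audit."""

import math

import numpy as np
import pytest

from pepclr import (
    AlignmentParams,
    audit_datasets,
    karlin_altschul_evalue,
    redundancy_ratio,
    smith_waterman_score,
)
from pepclr.records import PeptideDataset, PeptideRecord
from pepclr.redundancy import AlignmentError, BlastBackend, BuiltinBackend
from pepclr.simulate import SignalSpec, generate_labeled_peptides

RNG = np.random.default_rng(61)
AAS = "ACDEFGHIKLMNPQRSTVWY"


def random_set(n, length, seed, prefix="q"):
    rng = np.random.default_rng(seed)
    return PeptideDataset([
        PeptideRecord(id=f"{prefix}{i}",
                      sequence="".join(rng.choice(list(AAS), size=length)))
        for i in range(n)
    ])


def test_smith_waterman_hand_values():
    # BLOSUM62 diagonal: A=4, C=9, D=6, E=5
    assert smith_waterman_score("ACDE", "ACDE") == 24
    assert smith_waterman_score("AAAA", "WWWW") == 0  # nothing positive


def test_smith_waterman_symmetry_and_validation():
    for _ in range(10):
        a = "".join(RNG.choice(list(AAS), size=12))
        b = "".join(RNG.choice(list(AAS), size=15))
        assert smith_waterman_score(a, b) == smith_waterman_score(b, a)
    with pytest.raises(AlignmentError):
        smith_waterman_score("", "ACDE")


def test_smith_waterman_handles_unknown_residue():
    assert smith_waterman_score("KWXKL", "KWXKL") > 0


def test_evalue_formula():
    p = AlignmentParams()
    assert karlin_altschul_evalue(0, 10, 20, p) == pytest.approx(p.k_ * 200)
    assert karlin_altschul_evalue(30, 10, 40, p) == \
        pytest.approx(2 * karlin_altschul_evalue(30, 10, 20, p))
    # direct formula oracle
    expected = 0.041 * 30 * 30 * math.exp(-0.267 * 50)
    assert karlin_altschul_evalue(50, 30, 30, p) == pytest.approx(expected, abs=1e-12)
    # strictly decreasing in score
    assert karlin_altschul_evalue(51, 30, 30, p) < karlin_altschul_evalue(50, 30, 30, p)
    with pytest.raises(AlignmentError):
        karlin_altschul_evalue(10, 0, 5, p)


def test_exact_copy_is_always_flagged():
    ds = PeptideDataset([PeptideRecord(id="q0", sequence="KWKLFKKIEKVGQNIRDGIIKAGPAVAVVGQATQIAK")])
    db = PeptideDataset([PeptideRecord(id="d0", sequence=ds[0].sequence),
                         PeptideRecord(id="d1", sequence="MNPQRSTVYACD")])
    ratio, hits = redundancy_ratio(ds, db, threshold=1e-5, exclude_self=False)
    assert ratio == 1.0
    assert hits[0].subject_id == "d0"


def test_random_set_self_audit_is_clean_against_brute_force():
    """exclude_self leaves random length-10 peptides unflagged at 1e-5."""
    ds = random_set(12, 10, seed=7)
    params = AlignmentParams()
    ratio, _ = redundancy_ratio(ds, ds, threshold=1e-5, exclude_self=True)
    # brute-force oracle: all-pairs scores and e-values via the formulas
    db_len = sum(len(r.sequence) for r in ds)
    flagged = 0
    for q in ds:
        evals = [
            karlin_altschul_evalue(
                smith_waterman_score(q.sequence, s.sequence, params),
                len(q.sequence), db_len, params)
            for s in ds if s.id != q.id
        ]
        flagged += min(evals) <= 1e-5
    assert ratio == pytest.approx(flagged / len(ds))
    assert ratio == 0.0


def test_threshold_monotonicity():
    ds = random_set(8, 20, seed=8)
    db = random_set(8, 20, seed=9, prefix="d")
    loose, _ = redundancy_ratio(ds, db, threshold=1e-3)
    strict, _ = redundancy_ratio(ds, db, threshold=1e-5)
    assert loose >= strict


def test_database_order_invariance():
    ds = random_set(6, 15, seed=10)
    db = random_set(10, 15, seed=11, prefix="d")
    shuffled = PeptideDataset(list(reversed(db.records)))
    r1, h1 = redundancy_ratio(ds, db, threshold=1e-2)
    r2, h2 = redundancy_ratio(ds, shuffled, threshold=1e-2)
    assert r1 == r2
    assert [(h.query_id, h.subject_id) for h in h1] == \
           [(h.query_id, h.subject_id) for h in h2]


def test_audit_directions():
    train = random_set(8, 12, seed=12, prefix="t")
    test = random_set(4, 12, seed=13, prefix="s")
    report = audit_datasets(train, test, threshold=1e-5)
    # disjoint random sets: no direction should flag anything
    assert report.train_to_test == 0.0
    assert report.test_to_train == 0.0
    for v in report.report_fields().values():
        assert 0.0 <= v <= 1.0

    # test subset of train: every test query has an exact hit in train
    subset = PeptideDataset(
        [PeptideRecord(id=f"c{i}", sequence=train[i].sequence) for i in range(3)]
    )
    report = audit_datasets(train, subset, threshold=1e-5)
    assert report.test_to_train == 1.0
    assert report.train_to_train == report.test_to_test == 0.0


def test_empty_inputs_error():
    ds = random_set(2, 10, seed=14)
    with pytest.raises(AlignmentError):
        redundancy_ratio(PeptideDataset([]), ds)
    with pytest.raises(AlignmentError):
        redundancy_ratio(ds, ds, threshold=0.0)


def test_blast_backend_agrees_on_exact_duplicates():
    """Smoke-level cross-check: both backends flag an exact-copy pair."""
    seqs, _ = generate_labeled_peptides(6, SignalSpec(length_range=(30, 40)),
                                        seed=15)
    db = PeptideDataset(
        [PeptideRecord(id=f"d{i}", sequence=r.sequence) for i, r in enumerate(seqs)]
    )
    queries = PeptideDataset([PeptideRecord(id="q0", sequence=db[0].sequence)])
    builtin_ratio, _ = redundancy_ratio(queries, db, backend=BuiltinBackend())
    blast_ratio, _ = redundancy_ratio(queries, db, backend=BlastBackend())
    assert builtin_ratio == blast_ratio == 1.0
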