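"""Integrated-gradients attribution and attention extraction."""

import numpy as np
import pytest

from pepclr import (
    build_dual_model,
    extract_attention,
    integrated_gradients,
    summarize_attributions,
)
from pepclr.attribution import AttributionError, AttributionResult
from pepclr.records import PeptideDataset, PeptideRecord

from conftest import small_config

REC = PeptideRecord(id="p0", sequence="KWKLFKKIEK", label=1)


def test_identical_input_and_baseline_attribute_zero():
    model = build_dual_model(small_config("cnn"), seed=2)
    # collapse the embedding table: every token embeds like the pad token,
    # so x == baseline along the whole path
    table = model.tower_1.embedding.weight
    table.data[:] = table.data[0]
    res = integrated_gradients(model, REC, tower=1, n_steps=8)
    assert np.allclose(res.per_position_scores, 0.0, atol=1e-12)
    assert res.completeness_gap < 1e-12


@pytest.mark.parametrize("tower", [1, 2])
@pytest.mark.parametrize("baseline", ["pad", "zero"])
def test_completeness_axiom_on_trained_model(trained_cnn, tower, baseline):
    model, _ = trained_cnn
    res = integrated_gradients(model, REC, tower=tower, n_steps=128,
                               baseline=baseline)
    delta = abs(res.predicted_prob - res.baseline_prob)
    assert res.completeness_gap <= 0.05 * delta + 1e-3
    assert len(res.per_position_scores) == len(res.tokens)


def test_completeness_improves_with_more_steps(trained_cnn):
    model, _ = trained_cnn
    gaps = [integrated_gradients(model, REC, tower=1, n_steps=m).completeness_gap
            for m in (16, 32, 64, 128)]
    # convergence: doubling steps never increases the gap materially
    for coarse, fine in zip(gaps, gaps[1:]):
        assert fine <= coarse + 1e-6


def test_lstm_and_transformer_towers_support_attribution(trained_transformer):
    model, _ = trained_transformer
    res = integrated_gradients(model, REC, tower=1, n_steps=32)
    assert np.isfinite(res.per_position_scores).all()
    assert 0.0 <= res.predicted_prob <= 1.0


def test_zeroed_head_attributes_zero(trained_cnn):
    model, _ = trained_cnn
    frozen = model.copy()
    frozen.tower_1.head.weight.data[:] = 0.0
    frozen.tower_1.head.bias.data[:] = 0.0
    res = integrated_gradients(frozen, REC, tower=1, n_steps=16)
    assert np.allclose(res.per_position_scores, 0.0, atol=1e-12)


def test_attribution_input_validation(trained_cnn):
    model, _ = trained_cnn
    with pytest.raises(AttributionError):
        integrated_gradients(model, REC, n_steps=1)
    with pytest.raises(AttributionError):
        integrated_gradients(model, REC, tower=3)
    with pytest.raises(AttributionError):
        integrated_gradients(model, REC, baseline="mean")


# -- summaries ---------------------------------------------------------------------

def _result(record_id, tokens, scores, classifier_id=1):
    specials = np.array([t == "[CLS]" for t in tokens])
    return AttributionResult(
        record_id=record_id, tokens=tokens,
        per_position_scores=np.asarray(scores, dtype=float),
        is_special=specials, predicted_prob=0.9, classifier_id=classifier_id,
        n_steps=8, completeness_gap=0.0, baseline_prob=0.1,
    )


def test_summary_arithmetic_and_unseen_residues():
    ds = PeptideDataset([PeptideRecord(id="a", sequence="KK", label=1)])
    res = _result("a", ["[CLS]", "K", "K"], [5.0, 0.2, 0.4])
    summary = summarize_attributions([res], ds)
    assert summary.mean["K"] == pytest.approx(0.3)
    assert summary.count["K"] == 2
    assert summary.mean["W"] is None and summary.count["W"] == 0
    # [CLS] excluded: its large score must not leak into any residue
    assert all(m is None or abs(m) < 1.0 for m in summary.mean.values())


def test_pair_tokens_split_scores_between_residues():
    ds = PeptideDataset([PeptideRecord(id="a", sequence="KWKL", label=1)])
    res = _result("a", ["[CLS]", "KW", "KL"], [9.0, 0.4, 0.8], classifier_id=2)
    summary = summarize_attributions([res], ds)
    assert summary.mean["K"] == pytest.approx((0.2 + 0.4) / 2)
    assert summary.mean["W"] == pytest.approx(0.2)
    assert summary.count["K"] == 2


def test_summary_order_invariance_and_merging():
    ds = PeptideDataset([PeptideRecord(id="a", sequence="KK", label=1),
                         PeptideRecord(id="b", sequence="KW", label=0)])
    r1 = _result("a", ["[CLS]", "K", "K"], [0.0, 0.2, 0.4])
    r2 = _result("b", ["[CLS]", "K", "W"], [0.0, 0.6, 1.0])
    fwd = summarize_attributions([r1, r2], ds)
    rev = summarize_attributions([r2, r1], ds)
    assert fwd.mean == rev.mean and fwd.count == rev.count
    # counts-weighted merge of disjoint halves equals the full summary
    half_a = summarize_attributions([r1], ds)
    half_b = summarize_attributions([r2], ds)
    merged_k = (half_a.mean["K"] * half_a.count["K"]
                + half_b.mean["K"] * half_b.count["K"]) / 3
    assert fwd.mean["K"] == pytest.approx(merged_k, abs=1e-9)


def test_summary_requires_results():
    ds = PeptideDataset([PeptideRecord(id="a", sequence="KK", label=1)])
    with pytest.raises(AttributionError):
        summarize_attributions([], ds)


# -- attention ---------------------------------------------------------------------

def test_attention_extraction_contract(trained_transformer):
    model, _ = trained_transformer
    matrices, labels = extract_attention(model, REC, tower=1, layer=0)
    assert len(matrices) == model.config.n_heads
    T = len(REC.sequence) + 1
    for mat in matrices:
        assert mat.shape == (T, T)
        assert np.allclose(mat.sum(axis=1), 1.0, atol=1e-5)
    assert labels[0] == "[CLS]"
    assert labels[1:] == list(REC.sequence)


def test_attention_requires_transformer(trained_cnn):
    model, _ = trained_cnn
    with pytest.raises(AttributionError, match="transformer"):
        extract_attention(model, REC)


def test_attention_layer_bounds(trained_transformer):
    model, _ = trained_transformer
    with pytest.raises(AttributionError, match="layer"):
        extract_attention(model, REC, layer=5)
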