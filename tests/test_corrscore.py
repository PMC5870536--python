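"""Additive smoothing, correlation models and the correlation score."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_alignment_rows
from ppap.alignment_areas import Alignment, filter_columns
from ppap.cma import PairSelection
from ppap.corrscore import (
    CORR_ALPHABET,
    CorrelationModel,
    build_correlation_model,
    correlation_score,
    smoothed_frequencies,
    smoothing_params,
)


def make_selection(pairs):
    return PairSelection(pairs=tuple(pairs), threshold_z=3.0, mu=0.0, sd=1.0)


def make_model(rows, pairs):
    aln = Alignment(ids=tuple(f"s{i}" for i in range(len(rows))),
                    rows=tuple(rows))
    filtered = filter_columns(aln, max_gap_fraction=1.0, trim_terminal=False)
    return build_correlation_model(filtered, make_selection(pairs))


# ---------------------------------------------------------------------------
# Smoothing parameters
# ---------------------------------------------------------------------------

def test_smoothing_params_printed_formula():
    p = smoothing_params(1)
    assert p.alpha == pytest.approx(1 / 21)
    # beta = alpha^2 / (N + 2 alpha d_s) = (1/441) / (1 + 2) = 1/1323
    assert p.beta == pytest.approx(1 / 1323, abs=1e-18)
    assert (p.d_s, p.d_p) == (21, 441)


def test_smoothing_params_requires_positive_n():
    with pytest.raises(ValueError):
        smoothing_params(0)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(n=st.integers(1, 200))
def test_beta_identity_unseen_pair_ratio_is_one(n):
    """An unseen pair of unseen residues has p_ij/(p_i p_j) = 1 exactly."""
    p = smoothing_params(n)
    ratio = (p.beta / (n + p.beta * p.d_p)) / (
        (p.alpha / (n + p.alpha * p.d_s)) ** 2
    )
    assert ratio == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# Smoothed frequencies
# ---------------------------------------------------------------------------

def test_single_frequencies_n1():
    model = make_model(["TG"], [(0, 1)])
    # N=1, T observed once at 0: p = (1 + 1/21) / (1 + 1) = 11/21
    assert model.p_single(0, "T") == pytest.approx(11 / 21)
    # unobserved residue: p = (1/21) / 2 = 1/42
    assert model.p_single(0, "A") == pytest.approx(1 / 42)


def test_smoothed_distributions_normalize():
    model = make_model(["TG", "AG", "T-"], [(0, 1)])
    assert sum(model.p_single(0, s) for s in CORR_ALPHABET) == pytest.approx(1.0)
    total = sum(model.p_pair((0, 1), x, y)
                for x in CORR_ALPHABET for y in CORR_ALPHABET)
    assert total == pytest.approx(1.0)


def test_unknown_symbol_errors():
    model = make_model(["TG"], [(0, 1)])
    with pytest.raises(ValueError, match="alphabet"):
        model.p_single(0, "1")


def test_smoothed_frequencies_dispatch():
    model = make_model(["TG", "TG"], [(0, 1)])
    assert smoothed_frequencies(model, 0, "T") == model.p_single(0, "T")
    assert smoothed_frequencies(model, (0, 1), ("T", "G")) == \
        model.p_pair((0, 1), "T", "G")


# ---------------------------------------------------------------------------
# Model building
# ---------------------------------------------------------------------------

def test_toy_counts_match_manual_tally():
    model = make_model(["TG", "TA"], [(0, 1)])
    i_t = CORR_ALPHABET.index("T")
    i_g = CORR_ALPHABET.index("G")
    i_a = CORR_ALPHABET.index("A")
    assert model.single_counts[0][i_t] == 2
    assert model.single_counts[1][i_g] == 1
    assert model.single_counts[1][i_a] == 1
    assert model.pair_counts[(0, 1)][i_t, i_g] == 1
    assert model.pair_counts[(0, 1)][i_t, i_a] == 1
    assert model.N == 2


def test_counts_marginalize_over_random_fixtures():
    rng = np.random.default_rng(17)
    rows = random_alignment_rows(rng, 12, 8, with_gaps=True)
    model = make_model(rows, [(0, 3), (2, 7), (4, 5)])
    for (i, j), mat in model.pair_counts.items():
        assert np.allclose(mat.sum(axis=1), model.single_counts[i])
        assert np.allclose(mat.sum(axis=0), model.single_counts[j])
        assert mat.sum() == model.N
    for p, vec in model.single_counts.items():
        assert vec.sum() == model.N


def test_mismatched_column_space_errors():
    aln = Alignment(ids=("a", "b"), rows=("ACD", "ACD"))
    filtered = filter_columns(aln)
    with pytest.raises(ValueError, match="column space"):
        build_correlation_model(filtered, make_selection([(0, 9)]))


def test_model_serialization_roundtrip_scores_identically():
    rng = np.random.default_rng(23)
    rows = random_alignment_rows(rng, 10, 9, with_gaps=True)
    model = make_model(rows, [(0, 2), (3, 8)])
    clone = CorrelationModel.from_dict(model.to_dict())
    for _ in range(5):
        q = "".join(rng.choice(list(CORR_ALPHABET), size=9))
        assert clone.score(q) == pytest.approx(model.score(q), abs=1e-15)


# ---------------------------------------------------------------------------
# Correlation score
# ---------------------------------------------------------------------------

def test_score_of_fully_unseen_query_is_exactly_zero():
    model = make_model(["TG", "TG", "CA"], [(0, 1)])
    # W/W never observed at either position: every term is log 1
    assert model.score("WW") == pytest.approx(0.0, abs=1e-12)


def test_score_single_pair_hand_computed():
    # training: two sequences, both (T, G) at the single selected pair; N=2
    model = make_model(["TG", "TG"], [(0, 1)])
    p = model.smoothing
    p_tg = (2 + p.beta) / (2 + p.beta * 441)
    p_t = (2 + p.alpha) / (2 + p.alpha * 21)
    expected = math.log(p_tg / (p_t * p_t))
    assert model.score("TG") == pytest.approx(expected, abs=1e-15)


def test_score_matches_independent_bruteforce():
    rng = np.random.default_rng(29)
    rows = random_alignment_rows(rng, 15, 10, with_gaps=True)
    pairs = [(0, 4), (1, 9), (2, 3), (5, 8)]
    model = make_model(rows, pairs)
    for _ in range(10):
        q = "".join(rng.choice(list(CORR_ALPHABET), size=10))
        # independent recomputation from raw rows
        n = len(rows)
        sp = smoothing_params(n)
        total = 0.0
        for i, j in pairs:
            x, y = q[i], q[j]
            n_ij = sum(r[i] == x and r[j] == y for r in rows)
            n_i = sum(r[i] == x for r in rows)
            n_j = sum(r[j] == y for r in rows)
            p_ij = (n_ij + sp.beta) / (n + sp.beta * 441)
            p_i = (n_i + sp.alpha) / (n + sp.alpha * 21)
            p_j = (n_j + sp.alpha) / (n + sp.alpha * 21)
            total += math.log(p_ij / (p_i * p_j))
        assert model.score(q) == pytest.approx(total / len(pairs), abs=1e-12)


def test_score_short_row_errors_with_diagnostics():
    model = make_model(["ACDEF", "ACDEF"], [(0, 4)])
    with pytest.raises(ValueError, match="missing selected"):
        model.score("ACD")


def test_adding_identity_ratio_pair_rescales_by_c():
    """A pair contributing log 1 leaves S_cor * C unchanged."""
    rows = ["TGAA", "TGAA", "CAAA"]
    m1 = make_model(rows, [(0, 1)])
    m2 = make_model(rows, [(0, 1), (2, 3)])
    q = "TGWW"  # (W, W) unseen at (2, 3): that term is exactly 0
    assert m2.score(q) * m2.C == pytest.approx(m1.score(q) * m1.C, abs=1e-15)


def test_query_sampled_from_model_outscores_permuted_self(small_benchmark):
    """Queries drawn from the joint pair distribution score higher on
    average than residue-permuted versions (sign test over 10 seeds)."""
    dataset = small_benchmark.dataset
    from ppap.classify import PipelineConfig, build_type_resources
    from ppap.alignment_areas import map_reference_positions

    cols = map_reference_positions(dataset.master, dataset.area_map)
    res = build_type_resources(dataset.type_alignment("R-4-C"), cols,
                               "R-4-C", PipelineConfig())
    model = res.corr
    wins = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        base = dataset.master.row(dataset.type_ids("R-4-C")[seed % 8])
        row = res.filtered.project_row(base)
        perm = np.array(list(row))
        rng.shuffle(perm)
        wins += model.score(row) > model.score("".join(perm))
    # one-sided sign test: P(wins >= 9 | p = 0.5) < 0.01
    assert wins >= 9


def test_correlation_score_accepts_full_coordinates():
    rng = np.random.default_rng(31)
    rows = ["".join(rng.choice(list("ACDEF"), size=6)) for _ in range(6)]
    rows = [r + "-" for r in rows]  # a trailing gap column to filter away
    aln = Alignment(ids=tuple(f"s{i}" for i in range(6)), rows=tuple(rows))
    filtered = filter_columns(aln)
    assert filtered.kept_columns == (0, 1, 2, 3, 4, 5)
    model = build_correlation_model(filtered, make_selection([(0, 5)]))
    full = rows[0]
    assert correlation_score(model, full) == pytest.approx(
        model.score(filtered.project_row(full))
    )
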