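"""Shared fixtures: small synthetic benchmarks and random-alignment makers."""

from __future__ import annotations

import math
import random
from collections import Counter

import numpy as np
import pytest

from ppap.alignment_areas import AA20, GAP, UNKNOWN
from ppap.classify import PipelineConfig
from ppap.evaluate import loocv
from ppap.synthgen import generate_benchmark


@pytest.fixture(scope="session")
def small_benchmark():
    """Three target families + two "other" families, 8 sequences each."""
    return generate_benchmark(seed=7, n_seqs=8)


@pytest.fixture(scope="session")
def small_loocv_report(small_benchmark):
    return loocv(small_benchmark.dataset, PipelineConfig())


@pytest.fixture(scope="session")
def full_benchmark():
    """The default-sized benchmark (20 sequences per family)."""
    return generate_benchmark(seed=42)


def random_alignment_rows(
    rng: np.random.Generator,
    n_seqs: int,
    n_cols: int,
    with_gaps: bool = False,
    with_unknown: bool = False,
) -> list[str]:
    symbols = AA20 + (GAP if with_gaps else "") + (UNKNOWN if with_unknown else "")
    return [
        "".join(rng.choice(list(symbols), size=n_cols)) for _ in range(n_seqs)
    ]


def mi_bruteforce(col_i, col_j) -> float:
    """Independent MI oracle: explicit double loop over observed symbols."""
    n = len(col_i)
    pi, pj = Counter(col_i), Counter(col_j)
    pij = Counter(zip(col_i, col_j))
    total = 0.0
    for x in pi:
        for y in pj:
            c = pij.get((x, y), 0)
            if c:
                p_xy = c / n
                total += p_xy * math.log(p_xy / ((pi[x] / n) * (pj[y] / n)))
    return total
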