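"""Reference per-subject score tables of the eight-subject feedback study.

The raw recordings behind these tables are not distributed, but every
derived statistic — the run-to-run signed-rank p-values, the per-subject
QCM regression coefficients, the run averages — can be recomputed from the
printed scores with the :mod:`riembci.metrics` module.  This module loads
the packaged tables and provides those recomputations.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

import numpy as np

from .metrics import linreg_runs, wilcoxon_left

__all__ = [
    "load_tables",
    "score_matrix",
    "run_comparison_pvalues",
    "qcm_regressions",
    "separability_pvalues",
]


@lru_cache(maxsize=1)
def load_tables() -> dict:
    with resources.files("riembci.data").joinpath("study_tables.json").open() as f:
        return json.load(f)


def score_matrix(metric: str) -> np.ndarray:
    """(8 subjects, 6 runs) matrix of 'accuracy' or 'qcm' scores."""
    t = load_tables()
    return np.array([t[metric][s] for s in t["subjects"]])


def run_comparison_pvalues(metric: str) -> tuple[list[float], list[float]]:
    """Exact left-tail signed-rank p-values across subjects, runs 2..6.

    Returns (vs-previous-run, vs-first-run) lists; each tests whether the
    eight subjects' scores improved relative to the earlier run.
    """
    M = score_matrix(metric)
    vs_prev = [wilcoxon_left(M[:, i - 1], M[:, i]) for i in range(1, 6)]
    vs_first = [wilcoxon_left(M[:, 0], M[:, i]) for i in range(1, 6)]
    return vs_prev, vs_first


def qcm_regressions() -> tuple[np.ndarray, np.ndarray]:
    """Per-subject OLS (slope, intercept) of QCM over the constrained runs 1-4."""
    M = score_matrix("qcm")
    coeffs = [linreg_runs(M[i, :4]) for i in range(M.shape[0])]
    return (
        np.array([c[0] for c in coeffs]),
        np.array([c[1] for c in coeffs]),
    )


def separability_pvalues(subject: str) -> tuple[list[float], list[float]]:
    """Signed-rank p-values over the six class pairs, runs 2..6, one subject."""
    t = load_tables()
    S = np.array(t["separability"][subject]["scores"])  # (6 pairs, 6 runs)
    vs_prev = [wilcoxon_left(S[:, i - 1], S[:, i]) for i in range(1, 6)]
    vs_first = [wilcoxon_left(S[:, 0], S[:, i]) for i in range(1, 6)]
    return vs_prev, vs_first
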