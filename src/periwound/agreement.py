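"""Chance-corrected agreement statistics shared by both experiments.

Cohen's kappa corrects raw two-rater agreement for the agreement expected
from the raters' marginal label frequencies; the Adjusted Rand Index does the
analogous correction for two partitions.  Cluster labels carry no category
names, so before kappa can compare clusters with clinical labels the cluster
ids are mapped one-to-one onto categories by maximizing the contingency-table
diagonal (an exact assignment problem, not a greedy match).
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import ttest_ind

from .io_config import AnnotationTable
from .synthetic import KappaUndefinedError


@dataclasses.dataclass(frozen=True)
class AgreementReport:
    """Pairwise kappa matrix over raters with its off-diagonal summary."""

    raters: list[str]
    kappa_matrix: np.ndarray  # symmetric, diagonal 1
    mean: float
    sd: float  # sample SD (ddof=1) over the C(R,2) pairs; 0 for one pair

    def pair(self, a: str, b: str) -> float:
        i, j = self.raters.index(a), self.raters.index(b)
        return float(self.kappa_matrix[i, j])


def _contingency(a: np.ndarray, b: np.ndarray):
    cats_a, ia = np.unique(a, return_inverse=True)
    cats_b, ib = np.unique(b, return_inverse=True)
    table = np.zeros((len(cats_a), len(cats_b)), dtype=np.int64)
    np.add.at(table, (ia, ib), 1)
    return cats_a, cats_b, table


def cohen_kappa(a, b) -> float:
    """kappa = (p_o - p_e) / (1 - p_e) for two label vectors."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"label vectors differ in shape: {a.shape} vs {b.shape}")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 rated items")
    cats = np.union1d(a, b)
    p_o = float(np.mean(a == b))
    marg_a = np.array([np.mean(a == c) for c in cats])
    marg_b = np.array([np.mean(b == c) for c in cats])
    p_e = float(marg_a @ marg_b)
    if np.isclose(p_e, 1.0):
        raise KappaUndefinedError(
            "both raters are constant with the same label: kappa undefined"
        )
    return (p_o - p_e) / (1.0 - p_e)


def pairwise_kappa(table: AnnotationTable) -> AgreementReport:
    """kappa for every rater pair; mean +/- sample SD over the pairs."""
    raters = table.raters
    if len(raters) < 2:
        raise ValueError("pairwise agreement needs >= 2 raters")
    r = len(raters)
    mat = np.eye(r)
    vals = []
    for i, j in itertools.combinations(range(r), 2):
        k = cohen_kappa(table.labels(raters[i]), table.labels(raters[j]))
        mat[i, j] = mat[j, i] = k
        vals.append(k)
    vals = np.array(vals)
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return AgreementReport(raters=raters, kappa_matrix=mat, mean=float(vals.mean()), sd=sd)


def adjusted_rand(a, b) -> float:
    """ARI between two partitions of the same items."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("partitions differ in length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 items")
    _, _, table = _contingency(a, b)

    def comb2(x):
        x = np.asarray(x, dtype=float)
        return x * (x - 1) / 2.0

    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if np.isclose(max_index, expected):  # both partitions trivial
        return 1.0 if np.isclose(sum_ij, expected) else 0.0
    return float((sum_ij - expected) / (max_index - expected))


def align_labels(pred, ref) -> tuple[dict, np.ndarray]:
    """Optimally map predicted group ids onto reference categories.

    Solves the assignment problem maximizing the contingency diagonal.
    Returns the mapping and the relabeled prediction vector; predicted groups
    left unmatched (more groups than categories) keep their own id.
    """
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    cats_p, cats_r, table = _contingency(pred, ref)
    rows, cols = linear_sum_assignment(table, maximize=True)
    mapping = {cats_p[i]: cats_r[j] for i, j in zip(rows, cols)}
    relabeled = np.array([mapping.get(p, p) for p in pred], dtype=ref.dtype)
    return mapping, relabeled


def two_sample_t(x, y) -> tuple[float, float]:
    """Classical pooled-variance two-sample Student's t; two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs >= 2 values")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        raise ValueError("zero variance in both samples with unequal means")
    with warnings.catch_warnings():
        # near-identical samples trip scipy's precision-loss warning; the
        # degenerate equal case is already handled above
        warnings.simplefilter("ignore", RuntimeWarning)
        res = ttest_ind(x, y, equal_var=True)
    return float(res.statistic), float(res.pvalue)
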