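"""Between-arrangement differentiation: Hudson's F_ST, the nearest-neighbour
statistic Snn with a label-permutation test, and the breakpoint-distance
correlation used to ask whether differentiation decays away from inversion
breakpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .diversity import pairwise_difference_matrix
from .errors import InsufficientSampleError, UndefinedValueError
from .io import HaplotypeAlignment, complete_deletion_mask


@dataclass
class DifferentiationResult:
    fst: float
    snn: float
    snn_p: float
    n_perm: int
    seed: int


def _stack(
    alnA: HaplotypeAlignment, alnB: HaplotypeAlignment, mask: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled ingroup matrix over jointly retained columns + class labels."""
    if alnA.n < 2 or alnB.n < 2:
        raise InsufficientSampleError("need >= 2 sequences per class")
    if alnA.length != alnB.length:
        raise InsufficientSampleError("class alignments have different lengths")
    if mask is None:
        mask = complete_deletion_mask(alnA) & complete_deletion_mask(alnB)
    ma = alnA.ingroup_matrix()[:, mask]
    mb = alnB.ingroup_matrix()[:, mask]
    labels = np.r_[np.zeros(ma.shape[0], int), np.ones(mb.shape[0], int)]
    return np.vstack([ma, mb]), labels


def hudson_fst(
    alnA: HaplotypeAlignment,
    alnB: HaplotypeAlignment,
    mask: np.ndarray | None = None,
) -> float:
    """F_ST = 1 − H_w/H_b (Hudson et al. 1992).

    H_w averages the two within-class mean pairwise difference rates with
    equal weight; H_b is the mean rate over all between-class pairs.
    Slightly negative values are reported as computed.
    """
    pooled, labels = _stack(alnA, alnB, mask)
    d = pairwise_difference_matrix(pooled)
    a = labels == 0
    b = labels == 1
    iu_a = np.triu_indices(a.sum(), 1)
    iu_b = np.triu_indices(b.sum(), 1)
    hw = 0.5 * (d[np.ix_(a, a)][iu_a].mean() + d[np.ix_(b, b)][iu_b].mean())
    hb = d[np.ix_(a, b)].mean()
    if hb == 0:
        raise UndefinedValueError("between-class diversity is zero")
    return float(1.0 - hw / hb)


def _snn_from_distances(d: np.ndarray, labels: np.ndarray) -> float:
    """Snn (Hudson 2000): mean fraction of each sequence's nearest
    neighbours (minimal distance, ties split fractionally) in its class."""
    n = d.shape[0]
    big = d.max() + 1
    frac = np.empty(n)
    for i in range(n):
        row = d[i].copy()
        row[i] = big
        mn = row.min()
        nn = np.nonzero(row == mn)[0]
        frac[i] = (labels[nn] == labels[i]).mean()
    return float(frac.mean())


def snn_test(
    alnA: HaplotypeAlignment,
    alnB: HaplotypeAlignment,
    mask: np.ndarray | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> DifferentiationResult:
    """Snn plus a permutation P-value (labels shuffled, +1 correction).

    Also computes Hudson's F_ST on the same pooled data so the Table-2 style
    report (F_ST with Snn significance stars) comes from one call.
    """
    pooled, labels = _stack(alnA, alnB, mask)
    d = pairwise_difference_matrix(pooled)
    if d.max() == 0:
        raise UndefinedValueError("all sequences identical; Snn undefined")
    obs = _snn_from_distances(d, labels)
    rng = np.random.default_rng(seed)
    ge = 0
    perm = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        if _snn_from_distances(d, perm) >= obs - 1e-12:
            ge += 1
    p = (1 + ge) / (n_perm + 1)
    try:
        fst = hudson_fst(alnA, alnB, mask)
    except UndefinedValueError:
        fst = float("nan")
    return DifferentiationResult(fst=fst, snn=obs, snn_p=p, n_perm=n_perm, seed=seed)


def pearson_distance_correlation(
    values: "list[float] | np.ndarray", distances: "list[float] | np.ndarray"
) -> tuple[float, float]:
    """Pearson r (two-sided t-test P) between a per-gene statistic and the
    gene's distance to the nearest inversion breakpoint."""
    x = np.asarray(values, float)
    y = np.asarray(distances, float)
    if len(x) != len(y) or len(x) < 3:
        raise InsufficientSampleError("need >= 3 paired points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedValueError("zero variance in one of the vectors")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def significance_stars(p: float) -> str:
    """Table-2 convention: * P<0.05, ** P<0.01, *** P<0.001, else ns."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
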