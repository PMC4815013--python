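"""Per-arrangement diversity and divergence summaries.

Implements the standard within-class estimators: haplotype count h,
segregating sites S and singletons, nucleotide diversity π (mean pairwise
difference per retained site), silent diversity π_sil and Watterson's θ_sil
per silent site, Jukes–Cantor corrected silent divergence K_sil to a single
outgroup, and a sliding-window π profile.

"Silent" means noncoding positions plus the synonymous fraction of coding
positions; pairwise silent differences at coding sites are counted by
averaging over minimal mutational pathways between the two codons
(synonymous steps only), so multi-hit codons contribute fractional counts.
π and θ are reported on the raw (uncorrected) scale; only K_sil receives the
Jukes–Cantor multiple-hit correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .codons import pathway_counts
from .errors import InsufficientSampleError, UndefinedValueError
from .io import (
    CODING,
    NONCODING,
    HaplotypeAlignment,
    SiteClassification,
    complete_deletion_mask,
)


@dataclass
class DiversitySummary:
    """One row of a per-gene × per-arrangement diversity table."""

    n: int
    h: int
    S: int
    singletons: int
    pi: float
    pi_sil: float
    theta_sil: float
    K_sil: float | None = None


def harmonic(n: int) -> float:
    """a1 = sum_{i=1}^{n-1} 1/i."""
    return sum(1.0 / i for i in range(1, n))


def jukes_cantor(p: float) -> float:
    """JC69 distance from a raw difference proportion."""
    if p >= 0.75:
        raise UndefinedValueError(f"JC correction saturates at p={p:.3f} >= 0.75")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _retained(aln: HaplotypeAlignment, mask: np.ndarray | None) -> np.ndarray:
    return complete_deletion_mask(aln) if mask is None else np.asarray(mask, bool)


def segregating_sites(
    aln: HaplotypeAlignment, mask: np.ndarray | None = None
) -> tuple[int, int]:
    """(S, singletons) over retained columns of the ingroup."""
    if aln.n < 2:
        raise InsufficientSampleError("need >= 2 ingroup sequences")
    m = aln.ingroup_matrix()[:, _retained(aln, mask)]
    S = singletons = 0
    for col in m.T:
        vals, counts = np.unique(col, return_counts=True)
        if len(vals) >= 2:
            S += 1
            # a singleton column: minor variants together occur in one sequence
            if counts.sum() - counts.max() == 1:
                singletons += 1
    return S, singletons


def pairwise_difference_matrix(matrix: np.ndarray) -> np.ndarray:
    """(n, n) matrix of Hamming difference counts between rows."""
    n = matrix.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        diff = (matrix[i] != matrix[i + 1 :]).sum(axis=1)
        d[i, i + 1 :] = diff
        d[i + 1 :, i] = diff
    return d


def mean_pairwise_differences(matrix: np.ndarray) -> float:
    """Mean Hamming difference count over all unordered row pairs."""
    n = matrix.shape[0]
    if n < 2:
        raise InsufficientSampleError("need >= 2 sequences")
    d = pairwise_difference_matrix(matrix)
    return float(d[np.triu_indices(n, 1)].mean())


def nucleotide_diversity(
    aln: HaplotypeAlignment, mask: np.ndarray | None = None
) -> float:
    """π: mean pairwise difference proportion per retained site."""
    keep = _retained(aln, mask)
    L = int(keep.sum())
    if L == 0:
        raise UndefinedValueError("no retained sites")
    return mean_pairwise_differences(aln.ingroup_matrix()[:, keep]) / L


def haplotype_count(aln: HaplotypeAlignment, mask: np.ndarray | None = None) -> int:
    m = aln.ingroup_matrix()[:, _retained(aln, mask)]
    return len({row.tobytes() for row in m})


# ---------------------------------------------------------------------------
# silent statistics


def _pair_silent_diffs(
    a: np.ndarray, b: np.ndarray, mask: np.ndarray, sc: SiteClassification
) -> float:
    """Silent differences between two sequences: retained noncoding
    mismatches plus pathway-averaged synonymous changes per shared codon."""
    nc = mask & (sc.status == NONCODING)
    diffs = float(((a != b) & nc).sum())
    for cols in sc.codon_columns.values():
        ca = bytes(a[list(cols)]).decode()
        cb = bytes(b[list(cols)]).decode()
        if ca != cb:
            diffs += pathway_counts(ca, cb)[0]
    return diffs


def silent_diversity(
    aln: HaplotypeAlignment,
    mask: np.ndarray | None,
    sc: SiteClassification,
) -> float:
    """π_sil: mean pairwise silent differences per silent site."""
    total = sc.silent_sites_total
    if total <= 0:
        raise UndefinedValueError("zero silent sites")
    keep = _retained(aln, mask)
    rows = aln.ingroup_matrix()
    n = rows.shape[0]
    if n < 2:
        raise InsufficientSampleError("need >= 2 ingroup sequences")
    acc = 0.0
    npairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            acc += _pair_silent_diffs(rows[i], rows[j], keep, sc)
            npairs += 1
    return acc / npairs / total


def silent_segregating_sites(
    aln: HaplotypeAlignment,
    mask: np.ndarray | None,
    sc: SiteClassification,
) -> int:
    """Count retained polymorphic columns whose variation is silent.

    A noncoding polymorphic column is silent. A coding polymorphic column is
    silent when every observed base, substituted into the consensus codon at
    that position, yields the same amino acid.
    """
    keep = _retained(aln, mask)
    rows = aln.ingroup_matrix()
    col_to_codon: dict[int, tuple[int, str, int]] = {}
    for ci, cols in sc.codon_columns.items():
        for k, c in enumerate(cols):
            col_to_codon[c] = (ci, sc.consensus_codons[ci], k)
    from .codons import translate

    S_sil = 0
    for c in np.nonzero(keep)[0]:
        col = rows[:, int(c)]
        vals = np.unique(col)
        if len(vals) < 2:
            continue
        if sc.status[c] == NONCODING:
            S_sil += 1
        elif sc.status[c] == CODING:
            _, codon, k = col_to_codon[int(c)]
            aas = {
                translate(codon[:k] + chr(v) + codon[k + 1 :]) for v in vals
            }
            if len(aas) == 1:
                S_sil += 1
    return S_sil


def watterson_theta_silent(
    aln: HaplotypeAlignment,
    mask: np.ndarray | None,
    sc: SiteClassification,
) -> float:
    """θ_sil = S_silent / (a1 · silent sites)."""
    n = aln.n
    if n < 2:
        raise InsufficientSampleError("need >= 2 ingroup sequences")
    total = sc.silent_sites_total
    if total <= 0:
        raise UndefinedValueError("zero silent sites")
    S = silent_segregating_sites(aln, mask, sc)
    return S / (harmonic(n) * total)


def divergence_silent(
    aln: HaplotypeAlignment,
    mask: np.ndarray | None,
    sc: SiteClassification,
    jc_correct: bool = True,
) -> float:
    """K_sil: mean silent difference proportion to the outgroup,
    Jukes–Cantor corrected by default."""
    total = sc.silent_sites_total
    if total <= 0:
        raise UndefinedValueError("zero silent sites")
    keep = _retained(aln, mask)
    out = aln.outgroup_row()
    rows = aln.ingroup_matrix()
    p = float(
        np.mean([_pair_silent_diffs(r, out, keep, sc) for r in rows]) / total
    )
    return jukes_cantor(p) if jc_correct else p


# ---------------------------------------------------------------------------
# windows and summaries


def sliding_window_pi(
    aln: HaplotypeAlignment,
    mask: np.ndarray | None = None,
    window: int = 100,
    step: int = 25,
) -> list[tuple[float, float]]:
    """Sliding-window π over alignment columns.

    Windows span ``window`` columns and advance by ``step`` while they fit
    inside the alignment; each yields (window midpoint, π over the retained
    columns inside; NaN when a window retains no column). Returns an empty
    list when the alignment is shorter than one window.
    """
    keep = _retained(aln, mask)
    L = aln.length
    if L < window:
        import warnings

        warnings.warn("alignment shorter than one window; empty π profile")
        return []
    rows = aln.ingroup_matrix()
    n = rows.shape[0]
    iu = np.triu_indices(n, 1)
    out = []
    for start in range(0, L - window + 1, step):
        cols = np.arange(start, start + window)
        cols = cols[keep[cols]]
        mid = start + window / 2.0
        if len(cols) == 0:
            out.append((mid, float("nan")))
            continue
        d = pairwise_difference_matrix(rows[:, cols])
        out.append((mid, float(d[iu].mean() / len(cols))))
    return out


def diversity_summary(
    aln: HaplotypeAlignment,
    sc: SiteClassification,
    mask: np.ndarray | None = None,
    jc_correct: bool = True,
) -> DiversitySummary:
    mask = _retained(aln, mask)
    S, sing = segregating_sites(aln, mask)
    k_sil = None
    if aln.outgroup_id is not None:
        k_sil = divergence_silent(aln, mask, sc, jc_correct=jc_correct)
    return DiversitySummary(
        n=aln.n,
        h=haplotype_count(aln, mask),
        S=S,
        singletons=sing,
        pi=nucleotide_diversity(aln, mask),
        pi_sil=silent_diversity(aln, mask, sc),
        theta_sil=watterson_theta_silent(aln, mask, sc),
        K_sil=k_sil,
    )
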