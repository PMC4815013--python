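"""Linkage disequilibrium, minimum recombination, and gene-conversion-tract
detection between chromosomal arrangements.

LD between biallelic informative sites is summarised by r² with a two-sided
Fisher exact test per pair, Benjamini–Hochberg adjusted within the
comparison set, and globally by Kelly's ZnS (mean pairwise r²). The
Hudson–Kaplan four-gamete bound R_m is the in-repo recombination signal.

Gene conversion tracts are detected Betrán-style: for a focal recipient
sequence, a site is informative when (excluding the recipient) its own class
is fixed — or above a configurable frequency threshold — for one base, the
donor class likewise for a different base, and the recipient carries the
donor base. A tract is a maximal run of informative sites for one recipient
uninterrupted by a diagnostic site at which the recipient carries its own
class's base. ψ is the per-site probability that a site would be informative
for a random recipient lineage under the class allele frequencies alone
(i.e. with no conversion), averaged over retained sites — the expected
false-informative rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientSampleError, UndefinedValueError
from .io import HaplotypeAlignment, complete_deletion_mask


@dataclass
class LDPair:
    site_i: int
    site_j: int
    r2: float
    fisher_p: float
    q: float | None = None


@dataclass
class ConversionTract:
    recipient_id: str
    donor_class: str
    first_site: int
    last_site: int
    n_informative: int
    psi: float

    @property
    def length_bp(self) -> int:
        return self.last_site - self.first_site + 1


# ---------------------------------------------------------------------------
# pairwise LD


def biallelic_informative_sites(
    aln: HaplotypeAlignment,
    mask: np.ndarray | None = None,
    min_minor: int = 2,
) -> list[int]:
    """Retained columns with exactly two bases and minor count >= min_minor."""
    if aln.n < 4:
        raise InsufficientSampleError("need >= 4 ingroup sequences")
    keep = complete_deletion_mask(aln) if mask is None else np.asarray(mask, bool)
    m = aln.ingroup_matrix()
    sites = []
    for c in np.nonzero(keep)[0]:
        vals, counts = np.unique(m[:, c], return_counts=True)
        if len(vals) == 2 and counts.min() >= min_minor:
            sites.append(int(c))
    return sites


def _r2_and_fisher(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """r² of two binary vectors and the two-sided Fisher P on their 2x2
    haplotype count table."""
    n = len(x)
    table = np.array(
        [
            [np.sum((x == 0) & (y == 0)), np.sum((x == 0) & (y == 1))],
            [np.sum((x == 1) & (y == 0)), np.sum((x == 1) & (y == 1))],
        ]
    )
    pA = x.mean()
    pB = y.mean()
    pAB = np.mean((x == 1) & (y == 1))
    denom = pA * (1 - pA) * pB * (1 - pB)
    r2 = float((pAB - pA * pB) ** 2 / denom) if denom > 0 else float("nan")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return r2, float(p)


def ld_matrix(aln: HaplotypeAlignment, sites: list[int]) -> list[LDPair]:
    """All unordered informative-site pairs with r², Fisher P and BH q."""
    if len(sites) < 2:
        raise UndefinedValueError("need >= 2 informative sites")
    m = aln.ingroup_matrix()
    coded = {}
    for s in sites:
        col = m[:, s]
        minor = np.unique(col)[1]  # arbitrary but fixed allele coding
        coded[s] = (col == minor).astype(int)
    pairs = []
    for a in range(len(sites)):
        for b in range(a + 1, len(sites)):
            i, j = sites[a], sites[b]
            r2, p = _r2_and_fisher(coded[i], coded[j])
            pairs.append(LDPair(i, j, r2, p))
    qs = bh_adjust([p.fisher_p for p in pairs])
    for pair, q in zip(pairs, qs):
        pair.q = q
    return pairs


def bh_adjust(pvalues: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up q-values, order preserved."""
    if len(pvalues) == 0:
        return []
    _, q, _, _ = multipletests(pvalues, method="fdr_bh")
    return [float(v) for v in q]


def zns(aln: HaplotypeAlignment, sites: list[int]) -> float:
    """Kelly's ZnS: mean r² over all unordered informative-site pairs."""
    if len(sites) < 2:
        raise UndefinedValueError("ZnS needs >= 2 informative sites")
    m = aln.ingroup_matrix()
    coded = []
    for s in sites:
        col = m[:, s]
        minor = np.unique(col)[1]
        coded.append((col == minor).astype(int))
    acc = 0.0
    k = 0
    for a in range(len(sites)):
        for b in range(a + 1, len(sites)):
            r2, _ = _r2_and_fisher(coded[a], coded[b])
            acc += r2
            k += 1
    return acc / k


# ---------------------------------------------------------------------------
# four-gamete minimum recombination


def _four_gametes(x: np.ndarray, y: np.ndarray) -> bool:
    return len({(a, b) for a, b in zip(x, y)}) == 4


def min_recombination_events(aln: HaplotypeAlignment, sites: list[int]) -> int:
    """Hudson–Kaplan R_m: minimum recombination events from the four-gamete
    test, via the greedy disjoint-interval scan."""
    if len(sites) < 2:
        return 0
    m = aln.ingroup_matrix()
    order = sorted(sites)
    coded = {}
    for s in order:
        col = m[:, s]
        minor = np.unique(col)[1]
        coded[s] = (col == minor).astype(int)
    intervals = []
    for a in range(len(order)):
        for b in range(a + 1, len(order)):
            if _four_gametes(coded[order[a]], coded[order[b]]):
                intervals.append((order[a], order[b]))
    # stab every open interval (i, j) with the fewest points
    intervals.sort(key=lambda iv: iv[1])
    events = 0
    last = -np.inf
    for i, j in intervals:
        if not (i < last < j):
            events += 1
            last = j - 0.5
    return events


# ---------------------------------------------------------------------------
# gene conversion tracts


def _class_matrix(aln: HaplotypeAlignment, label: str) -> tuple[list[str], np.ndarray]:
    ids = [
        s
        for s, a in zip(aln.seq_ids, aln.arrangement)
        if s != aln.outgroup_id and a == label
    ]
    idx = [aln.seq_ids.index(s) for s in ids]
    return ids, aln.matrix[idx]


def _freqs(col: np.ndarray) -> dict[int, float]:
    vals, counts = np.unique(col, return_counts=True)
    return {int(v): c / col.size for v, c in zip(vals, counts)}


@dataclass
class InformativeSiteMap:
    """Per-recipient informative/breaker sites for one donor→recipient
    class pair, plus the site/lineage trial counts behind ψ."""

    recipient_ids: list[str]
    informative: dict[str, list[int]]
    breakers: dict[str, list[int]]
    n_retained_sites: int

    @property
    def n_events(self) -> int:
        return sum(len(v) for v in self.informative.values())

    @property
    def n_trials(self) -> int:
        return len(self.recipient_ids) * self.n_retained_sites

    @property
    def psi(self) -> float:
        """Mean per-site, per-lineage probability that a site is informative.

        Ingroup lineages within a class are exchangeable under the null
        coalescent, so the exact conditional probability that a random focal
        lineage makes a given site informative is the leave-one-out
        enumeration over focal lineages; ψ averages it over retained sites.
        """
        if self.n_trials == 0:
            raise UndefinedValueError("no retained sites")
        return self.n_events / self.n_trials


def informative_site_map(
    aln: HaplotypeAlignment,
    recipient_class: str,
    donor_class: str,
    mask: np.ndarray | None = None,
    freq_threshold: float = 1.0,
) -> InformativeSiteMap:
    """Enumerate Betrán-informative sites for every recipient sequence.

    For focal recipient r at a retained site: excluding r, the recipient
    class must show one base X at frequency >= ``freq_threshold``, the donor
    class a different base Y at frequency >= threshold, and r must carry Y
    (informative) or X (a run breaker: the site is diagnostic and r carries
    its own class's base).
    """
    keep = complete_deletion_mask(aln) if mask is None else np.asarray(mask, bool)
    ids_a, ma = _class_matrix(aln, recipient_class)
    _, mb = _class_matrix(aln, donor_class)
    nA = ma.shape[0]
    if nA < 2 or mb.shape[0] < 2:
        raise InsufficientSampleError("need >= 2 sequences per class")
    cols = np.nonzero(keep)[0]
    informative: dict[str, list[int]] = {rid: [] for rid in ids_a}
    breakers: dict[str, list[int]] = {rid: [] for rid in ids_a}
    donor_major: dict[int, int | None] = {}
    for c in cols:
        fb = _freqs(mb[:, c])
        dm = [b for b, f in fb.items() if f >= freq_threshold]
        donor_major[int(c)] = dm[0] if dm else None
    for r, rid in enumerate(ids_a):
        rest = np.delete(ma, r, axis=0)
        for c in cols:
            dY = donor_major[int(c)]
            if dY is None:
                continue
            fa = _freqs(rest[:, c])
            own = [b for b, f in fa.items() if f >= freq_threshold]
            if not own or own[0] == dY:
                continue
            base = int(ma[r, c])
            if base == dY:
                informative[rid].append(int(c))
            elif base == own[0]:
                breakers[rid].append(int(c))
    return InformativeSiteMap(ids_a, informative, breakers, len(cols))


def conversion_psi(
    aln: HaplotypeAlignment,
    recipient_class: str,
    donor_class: str,
    mask: np.ndarray | None = None,
    freq_threshold: float = 1.0,
) -> float:
    """ψ for one donor→recipient pair (see InformativeSiteMap.psi)."""
    return informative_site_map(
        aln, recipient_class, donor_class, mask, freq_threshold
    ).psi


def detect_conversion_tracts(
    aln: HaplotypeAlignment,
    recipient_class: str,
    donor_class: str,
    mask: np.ndarray | None = None,
    freq_threshold: float = 1.0,
) -> list[ConversionTract]:
    """Betrán-style tract detection from donor-diagnostic alleles.

    Returns one tract per maximal run of informative sites per recipient
    sequence (no intervening diagnostic site carrying the recipient-class
    base); tract extent is the span of the outermost informative sites, a
    conservative lower bound on the true converted segment.
    """
    smap = informative_site_map(
        aln, recipient_class, donor_class, mask, freq_threshold
    )
    psi = smap.psi if smap.n_retained_sites else float("nan")
    tracts: list[ConversionTract] = []
    for rid in smap.recipient_ids:
        breakers = smap.breakers[rid]
        run: list[int] = []
        for c in smap.informative[rid]:
            if run and any(run[-1] < b < c for b in breakers):
                tracts.append(
                    ConversionTract(rid, donor_class, run[0], run[-1], len(run), psi)
                )
                run = []
            run.append(c)
        if run:
            tracts.append(
                ConversionTract(rid, donor_class, run[0], run[-1], len(run), psi)
            )
    return tracts
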