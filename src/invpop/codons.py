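"""Codon-level bookkeeping shared by the silent-site classifier, the silent
diversity/divergence estimators and the McDonald–Kreitman counter.

All functions use the standard nuclear genetic code. Synonymous site
fractions follow the Nei–Gojobori counting scheme: at each codon position the
synonymous fraction is the proportion of the three possible single-base
changes that leave the amino acid unchanged. Differences between codons that
differ at several positions are resolved by averaging over all minimal
mutational pathways; pathways passing through a stop codon are discarded
unless every pathway does.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"

CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TO_AA[_stop] = "*"


def translate(codon: str) -> str:
    """Amino acid for a codon; '*' for stop, 'X' if the codon is ambiguous."""
    return CODON_TO_AA.get(codon, "X")


def is_stop(codon: str) -> bool:
    return CODON_TO_AA.get(codon) == "*"


@lru_cache(maxsize=None)
def syn_fraction(codon: str, pos: int) -> float:
    """Nei–Gojobori synonymous site fraction of position ``pos`` (0..2).

    Changes producing a stop codon count as nonsynonymous.
    """
    aa = translate(codon)
    if aa in "*X":
        raise ValueError(f"cannot count degeneracy of codon {codon!r}")
    syn = 0
    for b in BASES:
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1 :]
        if translate(alt) == aa:
            syn += 1
    return syn / 3.0


@lru_cache(maxsize=None)
def pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) change counts between two codons.

    Averaged over all minimal mutational pathways (orderings of the differing
    positions). Pathways traversing a stop codon are excluded when at least
    one stop-free pathway exists.
    """
    if translate(c1) == "X" or translate(c2) == "X":
        return (0.0, 0.0)
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return (0.0, 0.0)
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        syn = nsyn = 0
        through_stop = False
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            if is_stop(nxt) and nxt != c2:
                through_stop = True
            if translate(cur) == translate(nxt):
                syn += 1
            else:
                nsyn += 1
            cur = nxt
        paths.append((through_stop, syn, nsyn))
    clean = [p for p in paths if not p[0]]
    use = clean if clean else paths
    s = sum(p[1] for p in use) / len(use)
    n = sum(p[2] for p in use) / len(use)
    return (s, n)


def synonymous_changes(c1: str, c2: str) -> float:
    return pathway_counts(c1, c2)[0]


def nonsynonymous_changes(c1: str, c2: str) -> float:
    return pathway_counts(c1, c2)[1]
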