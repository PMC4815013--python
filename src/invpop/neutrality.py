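"""Neutrality tests: Tajima's D, Fu & Li's D (outgroup form), the
McDonald–Kreitman 2×2 framework with Fisher exact P, the Direction of
Selection statistic DoS = Dn/(Dn+Ds) − Pn/(Pn+Ps), and the per-position
amino-acid replacement profile.

Site-frequency-spectrum tests can be restricted to a site subset (e.g.
silent-only columns) and run after removing named sequences (e.g. detected
recombinants); both choices are recorded in the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .codons import pathway_counts, translate
from .diversity import harmonic, mean_pairwise_differences
from .errors import ConfigError, InsufficientSampleError, UndefinedValueError
from .io import (
    GeneAnnotation,
    HaplotypeAlignment,
    SiteClassification,
    classify_sites,
    complete_deletion_mask,
)


@dataclass
class MKTable:
    """Polymorphism/divergence × nonsynonymous/synonymous counts."""

    Pn: int
    Ps: int
    Dn: int
    Ds: int

    def __post_init__(self) -> None:
        if min(self.Pn, self.Ps, self.Dn, self.Ds) < 0:
            raise ConfigError("MK counts must be non-negative")

    def as_2x2(self) -> np.ndarray:
        return np.array([[self.Pn, self.Dn], [self.Ps, self.Ds]])


@dataclass
class SFSTestResult:
    statistic: float
    n_used: int
    S_used: int
    variant: str = "all_sites"
    exclusions: list[str] = field(default_factory=list)


def _prepare(
    aln: HaplotypeAlignment,
    mask: np.ndarray | None,
    site_subset: np.ndarray | None,
    exclusions: list[str] | None,
) -> tuple[HaplotypeAlignment, np.ndarray]:
    if exclusions:
        keep_ids = [s for s in aln.seq_ids if s not in set(exclusions)]
        aln = aln.subset(keep_ids, keep_outgroup=True)
    keep = complete_deletion_mask(aln) if mask is None else np.asarray(mask, bool).copy()
    if site_subset is not None:
        sub = np.zeros(aln.length, bool)
        sub[np.asarray(site_subset, int)] = True
        keep = keep & sub
    return aln, keep


# ---------------------------------------------------------------------------
# Tajima's D


def tajimas_d(
    aln: HaplotypeAlignment,
    mask: np.ndarray | None = None,
    site_subset: np.ndarray | None = None,
    exclusions: list[str] | None = None,
    variant: str = "all_sites",
) -> SFSTestResult:
    """Tajima (1989): D = (π̂ − S/a1) / sqrt(e1·S + e2·S·(S−1))."""
    aln, keep = _prepare(aln, mask, site_subset, exclusions)
    n = aln.n
    if n < 4:
        raise InsufficientSampleError("Tajima's D needs n >= 4")
    m = aln.ingroup_matrix()[:, keep]
    S = int(sum(len(np.unique(m[:, c])) > 1 for c in range(m.shape[1])))
    if S == 0:
        raise UndefinedValueError("no segregating sites")
    pi_hat = mean_pairwise_differences(m)

    a1 = harmonic(n)
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    d = (pi_hat - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))
    return SFSTestResult(float(d), n, S, variant, list(exclusions or []))


# ---------------------------------------------------------------------------
# Fu & Li's D (outgroup form)


def fu_li_d(
    aln: HaplotypeAlignment,
    mask: np.ndarray | None = None,
    site_subset: np.ndarray | None = None,
    exclusions: list[str] | None = None,
    variant: str = "all_sites",
) -> SFSTestResult:
    """Fu & Li (1993) D from total mutations η and external mutations ηe.

    External mutations are derived singletons: a base carried by exactly one
    ingroup sequence and differing from the outgroup base at that column.
    Columns where the outgroup is gapped or ambiguous are excluded.
    """
    if aln.outgroup_id is None:
        raise ConfigError("Fu & Li's D requires an outgroup sequence")
    aln, keep = _prepare(aln, mask, site_subset, exclusions)
    n = aln.n
    if n < 4:
        raise InsufficientSampleError("Fu & Li's D needs n >= 4")
    out = aln.outgroup_row()
    valid = np.isin(out, np.frombuffer(b"ACGT", np.uint8))
    keep = keep & valid
    m = aln.ingroup_matrix()[:, keep]
    outb = out[keep]

    eta = eta_e = 0
    for c in range(m.shape[1]):
        vals, counts = np.unique(m[:, c], return_counts=True)
        if len(vals) < 2:
            continue
        eta += len(vals) - 1
        for v, k in zip(vals, counts):
            if k == 1 and v != outb[c]:
                eta_e += 1
    if eta == 0:
        raise UndefinedValueError("no segregating sites")

    an = harmonic(n)
    bn = sum(1.0 / i**2 for i in range(1, n))
    cn = 2.0 * (n * an - 2 * (n - 1)) / ((n - 1) * (n - 2))
    vd = 1.0 + (an**2 / (bn + an**2)) * (cn - (n + 1) / (n - 1))
    ud = an - 1.0 - vd
    d = (eta - an * eta_e) / np.sqrt(ud * eta + vd * eta**2)
    return SFSTestResult(float(d), n, eta, variant, list(exclusions or []))


# ---------------------------------------------------------------------------
# McDonald–Kreitman


def mk_table(
    aln: HaplotypeAlignment,
    annot: GeneAnnotation,
    mask: np.ndarray | None = None,
    sc: SiteClassification | None = None,
) -> MKTable:
    """Count synonymous/nonsynonymous polymorphisms and fixed differences.

    Per codon: within-ingroup changes are classified by minimal mutational
    pathways between the observed codons (minor codons vs the most common
    one). Fixed differences are counted only at codon positions monomorphic
    in the ingroup and different from the outgroup; a codon that is both
    polymorphic and divergent contributes polymorphism at its varying
    positions and divergence at its monomorphic divergent positions.
    Pathway-averaged fractions are rounded to integers at the end.
    """
    if aln.outgroup_id is None:
        raise ConfigError("MK table requires an outgroup sequence")
    if mask is None:
        mask = complete_deletion_mask(aln)
    if sc is None:
        sc = classify_sites(aln, annot, mask)
    ing = aln.ingroup_matrix()
    out = aln.outgroup_row()

    Pn = Ps = Dn = Ds = 0.0
    skipped = 0
    for ci, cols in sc.codon_columns.items():
        cl = list(cols)
        codons = [bytes(row[cl]).decode() for row in ing]
        out_codon = bytes(out[cl]).decode()
        if any(translate(c) == "X" for c in codons) or translate(out_codon) == "X":
            skipped += 1
            continue
        uniq, counts = np.unique(codons, return_counts=True)
        major = uniq[np.argmax(counts)]
        # polymorphism: every minor codon against the major codon
        for u in uniq:
            if u == major:
                continue
            s, ns = pathway_counts(major, u)
            Ps += s
            Pn += ns
        # divergence at ingroup-monomorphic positions
        mono = [
            k
            for k in range(3)
            if len({c[k] for c in codons}) == 1 and codons[0][k] != out_codon[k]
        ]
        if mono:
            # swap only the monomorphic divergent positions into the major codon
            target = list(major)
            for k in mono:
                target[k] = out_codon[k]
            s, ns = pathway_counts(major, "".join(target))
            Ds += s
            Dn += ns
    if skipped:
        warnings.warn(f"{skipped} untranslatable codons excluded from MK counts")
    return MKTable(round(Pn), round(Ps), round(Dn), round(Ds))


def mk_fisher(t: MKTable) -> float:
    """Two-sided Fisher exact P on [[Pn, Dn], [Ps, Ds]]."""
    tab = t.as_2x2()
    if tab.sum() == 0:
        raise UndefinedValueError("empty MK table")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        warnings.warn("degenerate MK table margin; Fisher P = 1")
        return 1.0
    _, p = stats.fisher_exact(tab, alternative="two-sided")
    return float(p)


def dos(t: MKTable) -> float:
    """Direction of Selection: Dn/(Dn+Ds) − Pn/(Pn+Ps)."""
    if t.Dn + t.Ds == 0 or t.Pn + t.Ps == 0:
        raise UndefinedValueError("DoS undefined for an empty margin")
    return t.Dn / (t.Dn + t.Ds) - t.Pn / (t.Pn + t.Ps)


def neutrality_index(t: MKTable) -> float:
    """NI = (Pn/Ps) / (Dn/Ds)."""
    if t.Ps == 0 or t.Dn == 0:
        raise UndefinedValueError("NI undefined with Ps = 0 or Dn = 0")
    return (t.Pn / t.Ps) / (t.Dn / t.Ds)


# ---------------------------------------------------------------------------
# amino-acid replacement profile


def replacement_profile(
    alignments: "dict[str, HaplotypeAlignment]",
    annot: GeneAnnotation,
    low_freq_cutoff: float = 0.3,
    reference_offset: int = 0,
) -> "dict[str, dict[int, list[tuple[str, str]]]]":
    """Per-class, per-codon amino acids with frequency tags.

    Returns {class: {position: [(aa, tag), ...]}} with residues sorted by
    descending frequency; tag 'a' marks low-frequency residues
    (freq < cutoff), 'b' marks an exact 50/50 split, '' the major residue.
    Positions are codon indices (1-based) plus ``reference_offset`` so they
    can be numbered against an external reference protein.
    """
    profile: dict[str, dict[int, list[tuple[str, str]]]] = {}
    for label, aln in alignments.items():
        mask = complete_deletion_mask(aln)
        sc = classify_sites(aln, annot, mask)
        ing = aln.ingroup_matrix()
        per_pos: dict[int, list[tuple[str, str]]] = {}
        for ci, cols in sc.codon_columns.items():
            cl = list(cols)
            aas = [translate(bytes(row[cl]).decode()) for row in ing]
            aas = [a for a in aas if a not in "X*"]
            if not aas:
                continue
            uniq, counts = np.unique(aas, return_counts=True)
            freqs = counts / counts.sum()
            order = np.argsort(-freqs, kind="stable")
            entries = []
            for k in order:
                f = freqs[k]
                if abs(f - 0.5) < 1e-9 and len(uniq) == 2:
                    tag = "b"
                elif f < low_freq_cutoff:
                    tag = "a"
                else:
                    tag = ""
                entries.append((str(uniq[k]), tag))
            per_pos[ci + 1 + reference_offset] = entries
        profile[label] = per_pos
    return profile
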