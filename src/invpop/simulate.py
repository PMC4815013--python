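"""Synthetic haplotype alignments with the structure the analysis assumes.

The generator emulates a set of isochromosomal lines sampled from one
ancestral arrangement plus one or more derived arrangements, each founded by
a single chromosome entering the ancestral class ``age_gen`` generations ago
(a hard founding bottleneck — the same star-like onset the diversity-based
age estimator assumes). Ongoing gene flux between arrangements is modelled
as symmetric migration; crossover and gene conversion act within the locus.
Mutation is finite-sites Jukes–Cantor, so multiple hits and the divergence
correction are exercised. A single outgroup sequence is produced by evolving
the ancestral root sequence to a configured expected divergence rather than
by coalescent sampling.

All scaled rates are per site per 2N_e generations (the haploid coalescent
unit: one isochromosomal line carries one chromosome): ``theta_per_site`` is
2N_e·μ, ``rho_per_site`` 2N_e·r, ``flux_rate`` 2N_e·m, ``conversion_rate``
2N_e·g. Everything is deterministic given ``seed``.

The coalescent machinery is msprime; this module adds the arrangement
demography, FASTA/TSV emission, tract implanting, fixed-difference injection
and ground-truth records.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field

import msprime
import numpy as np

from .codons import translate
from .errors import ConfigError
from .io import (
    GeneAnnotation,
    HaplotypeAlignment,
    classify_sites,
    complete_deletion_mask,
    consensus_sequence,
    write_annotation,
    write_fasta_alignment,
)

_BASES = np.frombuffer(b"ACGT", np.uint8)


@dataclass
class ClassSample:
    """One sampled group: an arrangement label in one population.

    ``age_gen`` is the founding time of the arrangement in generations;
    0 marks the ancestral arrangement. Groups sharing a label share the
    same arrangement (and founding event)."""

    label: str
    population: str
    n: int
    age_gen: float = 0.0


@dataclass
class CoalescentConfig:
    classes: list[ClassSample]
    locus_length: int = 2000
    exon_intervals: list[tuple[int, int]] = field(default_factory=list)
    frame: int = 0
    theta_per_site: float = 0.01
    rho_per_site: float = 0.0
    flux_rate: float = 0.0
    conversion_rate: float = 0.0
    mean_tract_bp: float = 100.0
    outgroup_divergence: float = 0.0
    ne: int = 1000
    #: post-founding size of derived arrangements; large values give the
    #: star-like onset the diversity-based age estimator assumes
    derived_ne: int | None = None
    seed: int = 1

    def validate(self) -> None:
        if not self.classes:
            raise ConfigError("no sample classes configured")
        for c in self.classes:
            if c.n <= 0:
                raise ConfigError(f"class {c.label}/{c.population}: zero samples")
            if c.age_gen < 0:
                raise ConfigError("founding age must be >= 0")
        ages = {}
        for c in self.classes:
            if c.label in ages and ages[c.label] != c.age_gen:
                raise ConfigError(f"class {c.label}: inconsistent founding ages")
            ages[c.label] = c.age_gen
        for r in (self.theta_per_site, self.rho_per_site, self.flux_rate,
                  self.conversion_rate):
            if r < 0:
                raise ConfigError("rates must be >= 0")
        if self.mean_tract_bp < 1:
            raise ConfigError("mean tract length must be >= 1 bp")
        for s, e in self.exon_intervals:
            if not (0 <= s < e <= self.locus_length):
                raise ConfigError(f"exon ({s},{e}) outside locus")


@dataclass
class SimTruth:
    """Ground truth of one simulated alignment."""

    ages_gen: dict[str, float]
    implanted_tracts: list[dict] = field(default_factory=list)
    injected_sites: list[dict] = field(default_factory=list)
    n_mutations: int = 0
    seed: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)


def _popname(label: str) -> str:
    return "p_" + re.sub(r"\W", "_", label)


_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if translate(a + b + c) != "*"
]


def _reference_sequence(cfg: CoalescentConfig, rng: np.random.Generator) -> np.ndarray:
    """Random root sequence whose in-frame exon codons are stop-free."""
    ref = rng.choice(_BASES, size=cfg.locus_length)
    annot = annotation_from_config(cfg)
    spliced = annot.spliced_positions()
    usable = spliced[cfg.frame :]
    for k in range(len(usable) // 3):
        codon = _NONSTOP_CODONS[rng.integers(len(_NONSTOP_CODONS))]
        ref[usable[3 * k : 3 * k + 3]] = np.frombuffer(codon.encode(), np.uint8)
    return ref


def annotation_from_config(cfg: CoalescentConfig, gene_name: str = "locus") -> GeneAnnotation:
    return GeneAnnotation(gene_name, sorted(cfg.exon_intervals), cfg.frame)


def _purge_stop_codons(matrix: np.ndarray, ref: np.ndarray, cfg: CoalescentConfig) -> None:
    """Revert changes that create premature stop codons (in place).

    Nonsense mutations are taken as lethal: any sequence whose in-frame
    codon translates to a stop has its deviating bases reverted to the
    (stop-free) root codon.
    """
    annot = annotation_from_config(cfg)
    usable = annot.spliced_positions()[cfg.frame :]
    for k in range(len(usable) // 3):
        cols = usable[3 * k : 3 * k + 3]
        for r in range(matrix.shape[0]):
            codon = bytes(matrix[r, cols]).decode()
            if translate(codon) == "*":
                matrix[r, cols] = ref[cols]


def simulate_arrangements(
    cfg: CoalescentConfig,
) -> tuple[HaplotypeAlignment, SimTruth]:
    """Simulate one locus under the arrangement demography.

    Returns the alignment (ingroup lines labelled by arrangement and
    population, plus an outgroup when ``outgroup_divergence > 0``) and the
    ground-truth record.
    """
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    anc_seed, mut_seed = (int(s) for s in ss.generate_state(2) % (2**31 - 1) + 1)
    rng = np.random.default_rng(ss.spawn(1)[0])
    ne = cfg.ne
    mu = cfg.theta_per_site / (2 * ne)

    ages = {}
    for c in cfg.classes:
        ages[c.label] = c.age_gen
    derived = sorted({lab for lab, a in ages.items() if a > 0})
    ancestral = sorted({lab for lab, a in ages.items() if a == 0})
    if not ancestral:
        raise ConfigError("at least one class must be ancestral (age_gen == 0)")

    demography = msprime.Demography()
    # anc is both sampled at time 0 and the split target, so it must be
    # active from the start (split-ancestral populations default inactive)
    demography.add_population(name="anc", initial_size=ne, initially_active=True)
    dne = cfg.derived_ne if cfg.derived_ne is not None else ne
    for lab in derived:
        demography.add_population(name=_popname(lab), initial_size=dne)
    if cfg.flux_rate > 0:
        m = cfg.flux_rate / (2 * ne)
        pops = ["anc"] + [_popname(x) for x in derived]
        for a in pops:
            for b in pops:
                if a != b:
                    demography.set_migration_rate(source=a, dest=b, rate=m)
    for lab in derived:
        t = ages[lab]
        demography.add_instantaneous_bottleneck(
            time=max(t - 0.5, t * 0.999), strength=1000 * dne, population=_popname(lab)
        )
        demography.add_population_split(
            time=t, derived=[_popname(lab)], ancestral="anc"
        )
    demography.sort_events()

    samples = []
    for c in cfg.classes:
        pop = _popname(c.label) if ages[c.label] > 0 else "anc"
        samples.append(msprime.SampleSet(c.n, population=pop, ploidy=1))

    ts = msprime.sim_ancestry(
        samples=samples,
        demography=demography,
        sequence_length=cfg.locus_length,
        recombination_rate=cfg.rho_per_site / (2 * ne),
        gene_conversion_rate=cfg.conversion_rate / (2 * ne),
        gene_conversion_tract_length=cfg.mean_tract_bp,
        ploidy=1,
        random_seed=anc_seed,
    )
    mts = msprime.sim_mutations(
        ts, rate=mu, model=msprime.JC69(), random_seed=mut_seed
    )

    n_samp = mts.num_samples
    L = cfg.locus_length
    ref = _reference_sequence(cfg, rng)
    matrix = np.tile(ref, (n_samp, 1))
    root = ref.copy()
    for var in mts.variants():
        pos = int(var.site.position)
        # JC69 is symmetric under nucleotide relabelling: swap the drawn
        # ancestral state with the reference base so the root sequence is
        # exactly ref (keeps exon codons stop-free at the root)
        anc = var.site.ancestral_state
        refb = chr(ref[pos])
        swap = {anc: refb, refb: anc}
        alleles = np.array(
            [ord(swap.get(a, a)) for a in var.alleles if a is not None], np.uint8
        )
        matrix[:, pos] = alleles[var.genotypes]

    _purge_stop_codons(matrix, ref, cfg)

    ids, arrs, pops = [], [], []
    i = 0
    for c in cfg.classes:
        for k in range(c.n):
            ids.append(f"{c.population}{k + 1:02d}_{c.label}")
            arrs.append(c.label)
            pops.append(c.population)
            i += 1
    assert i == n_samp

    outgroup_id = None
    if cfg.outgroup_divergence > 0:
        d = cfg.outgroup_divergence
        p_sub = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
        og = root.copy()
        hit = rng.random(L) < p_sub
        for pos in np.nonzero(hit)[0]:
            others = _BASES[_BASES != og[pos]]
            og[pos] = rng.choice(others)
        og2 = og.reshape(1, -1)
        _purge_stop_codons(og2, root, cfg)
        og = og2[0]
        outgroup_id = "OUTGROUP"
        matrix = np.vstack([matrix, og])
        ids.append(outgroup_id)
        arrs.append(None)
        pops.append(None)

    aln = HaplotypeAlignment(ids, matrix, arrs, pops, outgroup_id)
    truth = SimTruth(ages_gen=ages, n_mutations=mts.num_mutations, seed=cfg.seed)
    return aln, truth


# ---------------------------------------------------------------------------
# fixture edits with ground truth


def implant_conversion_tract(
    aln: HaplotypeAlignment,
    recipient_id: str,
    donor_class: str,
    interval: tuple[int, int],
    truth: SimTruth | None = None,
) -> HaplotypeAlignment:
    """Overwrite the recipient's bases on ``interval`` (half-open) with the
    donor-class consensus, recording the exact interval in the truth."""
    start, end = interval
    if not (0 <= start < end <= aln.length):
        raise ConfigError(f"tract interval {interval} outside locus")
    r = aln.seq_ids.index(recipient_id)
    if aln.arrangement[r] == donor_class:
        raise ConfigError("recipient already belongs to the donor class")
    donor_ids = [
        s
        for s, a in zip(aln.seq_ids, aln.arrangement)
        if s != aln.outgroup_id and a == donor_class
    ]
    if not donor_ids:
        raise ConfigError(f"donor class {donor_class!r} is empty")
    didx = [aln.seq_ids.index(s) for s in donor_ids]
    cons = consensus_sequence(aln.matrix[didx])
    matrix = aln.matrix.copy()
    seg = cons[start:end]
    ok = np.isin(seg, _BASES)
    matrix[r, start:end][ok] = seg[ok]
    if truth is not None:
        truth.implanted_tracts.append(
            {
                "recipient_id": recipient_id,
                "donor_class": donor_class,
                "start": int(start),
                "end": int(end),
            }
        )
    return HaplotypeAlignment(
        list(aln.seq_ids), matrix, list(aln.arrangement), list(aln.population), aln.outgroup_id
    )


def inject_fixed_differences(
    aln: HaplotypeAlignment,
    annot: GeneAnnotation,
    class_label: str,
    n_nonsyn: int,
    seed: int = 0,
    truth: SimTruth | None = None,
) -> HaplotypeAlignment:
    """Force ``n_nonsyn`` diagnostic nonsynonymous differences onto a class.

    Candidate columns are coding positions monomorphic across the whole
    ingroup where some base change is nonsynonymous on every observed codon
    background; the change is applied to every member of ``class_label``.
    """
    if n_nonsyn == 0:
        return aln
    mask = complete_deletion_mask(aln)
    sc = classify_sites(aln, annot, mask)
    ing = aln.ingroup_matrix()
    rng = np.random.default_rng(seed)

    candidates = []
    for ci, cols in sc.codon_columns.items():
        cl = list(cols)
        codons = {bytes(row[cl]).decode() for row in ing}
        for k, c in enumerate(cl):
            column = ing[:, c]
            if len(np.unique(column)) != 1:
                continue
            x = chr(column[0])
            for y in "ACGT":
                if y == x:
                    continue
                alts = {cd[:k] + y + cd[k + 1 :] for cd in codons}
                if any(translate(a) in "*X" for a in alts):
                    continue
                if all(
                    translate(cd) != translate(cd[:k] + y + cd[k + 1 :])
                    for cd in codons
                ):
                    candidates.append((c, x, y))
                    break
    if len(candidates) < n_nonsyn:
        raise ConfigError(
            f"only {len(candidates)} eligible positions for {n_nonsyn} injections"
        )
    # one injection per codon, spread across the locus
    chosen_idx = rng.choice(len(candidates), size=n_nonsyn, replace=False)
    matrix = aln.matrix.copy()
    members = [
        i
        for i, (s, a) in enumerate(zip(aln.seq_ids, aln.arrangement))
        if s != aln.outgroup_id and a == class_label
    ]
    if not members:
        raise ConfigError(f"class {class_label!r} is empty")
    for idx in chosen_idx:
        c, x, y = candidates[idx]
        matrix[members, c] = ord(y)
        if truth is not None:
            truth.injected_sites.append(
                {"column": int(c), "from": x, "to": y, "class": class_label}
            )
    return HaplotypeAlignment(
        list(aln.seq_ids), matrix, list(aln.arrangement), list(aln.population), aln.outgroup_id
    )


def apply_coding_constraint(
    aln: HaplotypeAlignment, annot: GeneAnnotation
) -> HaplotypeAlignment:
    """Emulate strong purifying selection on the protein.

    Every nonsynonymous deviation from the ingroup consensus codon — in
    ingroup sequences and in the outgroup — is reverted to the consensus
    base; synonymous deviations are kept. The neutral coalescent places
    mutations without regard to codon impact, so a conserved protein
    (the Na,K-ATPase regime) needs this post-process.
    """
    mask = complete_deletion_mask(aln)
    sc = classify_sites(aln, annot, mask)
    matrix = aln.matrix.copy()
    for ci, cols in sc.codon_columns.items():
        cl = list(cols)
        cons = sc.consensus_codons[ci]
        aa_cons = translate(cons)
        for r in range(matrix.shape[0]):
            codon = bytes(matrix[r, cl]).decode()
            if codon == cons or "N" in codon or "-" in codon:
                continue
            fixed = list(codon)
            for k in range(3):
                if codon[k] == cons[k]:
                    continue
                single = cons[:k] + codon[k] + cons[k + 1 :]
                if translate(single) != aa_cons:
                    fixed[k] = cons[k]
            if translate("".join(fixed)) != aa_cons:
                fixed = list(cons)
            matrix[r, cl] = np.frombuffer("".join(fixed).encode(), np.uint8)
    return HaplotypeAlignment(
        list(aln.seq_ids), matrix, list(aln.arrangement), list(aln.population), aln.outgroup_id
    )


# ---------------------------------------------------------------------------
# study-shaped emission


def study_layout(seed: int = 1, **overrides) -> CoalescentConfig:
    """Config mirroring the sampled study design: 11 derived + 12 ancestral
    lines in one population, 10 derived + 12 ancestral in the other."""
    kw = dict(
        classes=[
            ClassSample("O3+4+1", "MP", 11, age_gen=1000.0),
            ClassSample("O3+4", "MP", 12, 0.0),
            ClassSample("O3+4+7", "BC", 10, age_gen=1000.0),
            ClassSample("O3+4", "BC", 12, 0.0),
        ],
        locus_length=1500,
        exon_intervals=[(0, 600), (1100, 1500)],
        theta_per_site=0.01,
        rho_per_site=0.01,
        flux_rate=0.5,
        outgroup_divergence=0.17,
        seed=seed,
    )
    kw.update(overrides)
    return CoalescentConfig(**kw)


def write_simulation(
    aln: HaplotypeAlignment,
    truth: SimTruth,
    annot: GeneAnnotation,
    prefix,
) -> None:
    """Emit the alignment_io dialect: FASTA + metadata TSV + annotation TSV
    + truth JSON under ``prefix``."""
    prefix = str(prefix)
    write_fasta_alignment(aln, prefix + ".fasta", prefix + ".meta.tsv")
    write_annotation([annot], prefix + ".annot.tsv")
    truth.to_json(prefix + ".truth.json")
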