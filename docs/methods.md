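# Methods

`invpop` analyses haplotype alignments from isochromosomal lines of a
species segregating for chromosomal inversions. Sequences are stratified by
*arrangement* (a combination of inversions on one chromosome, e.g. O3+4,
O3+4+1, O3+4+7) and by sampling population, with a single diverged outgroup
sequence per gene. This note documents the statistical models, the numerical
conventions, the synthetic-data generator, and the design choices made where
the published software conventions (DnaSP-era pipelines) leave the details
open.

## Alignment handling and site classification

**Gap/ambiguity policy.** All statistics run on a *complete-deletion* mask:
any column containing `-` or `N` in any sequence of the alignment under
consideration is excluded from numerators and denominators alike. One fixed
policy keeps per-arrangement tables reproducible; it is exposed as the
`mask` argument everywhere, so a different policy can be substituted.

**Silent sites.** A silent site is a noncoding position or the synonymous
fraction of a coding position. Coding positions receive fractional
synonymous/nonsynonymous site counts by Nei–Gojobori degeneracy counting on
the *ingroup consensus codon* (column-wise majority base, ties resolved to
the alphabetically first base): the synonymous fraction of a codon position
is the proportion of the three possible single-base changes that preserve
the amino acid, with changes to stop codons counted as nonsynonymous.
Consensus counting is deterministic, which matters more here than the minor
differences among counting variants. Codons containing any masked column,
and partial codons at exon edges, are excluded whole. An internal stop codon
in the consensus is treated as an annotation error (a terminal stop is
ignored).

**Pathway resolution.** Differences between two codons observed at the same
position set are decomposed by averaging over all minimal mutational
pathways (orderings of the differing positions); pathways through stop
codons are discarded when a stop-free pathway exists. Synonymous steps count
toward silent differences, nonsynonymous steps toward replacement
differences. Multi-hit codons therefore contribute fractional counts.

## Diversity and divergence

Per arrangement (optionally per population) the package reports sample size
n, haplotype count h, segregating sites S and singletons, nucleotide
diversity π (mean pairwise difference proportion over retained sites),
silent diversity π_sil and Watterson's θ_sil per silent site, and silent
divergence K_sil to the outgroup. Following the conventions of the standard
polymorphism tables, π and θ are reported on the raw scale; only K_sil is
corrected for multiple hits, with the Jukes–Cantor transform
K = −(3/4)·ln(1 − 4p/3) applied to the mean silent difference proportion p
(a raw-scale switch, `jc_correct=False`, is available for matching outputs
that skipped the correction — whether the original tables corrected K_sil is
not stated, and JC is the default here). θ_sil counts a polymorphic coding
column as silent when every observed base, substituted into the consensus
codon at that column, yields the same amino acid.

Sliding-window π uses windows of 100 alignment columns advancing by 25;
masked columns inside a window are dropped from both numerator and
denominator while the window span stays fixed on alignment coordinates.

## Differentiation

F_ST uses the Hudson-style pairwise estimator 1 − H_w/H_b, with H_w the
equal-weight mean of the two within-class mean pairwise difference rates and
H_b the mean between-class rate. Negative values are reported as computed.
Note a finite-sample property: for two multiset-identical classes of k
copies each of two haplotypes the estimator equals exactly −1/(2k−1), not 0,
because within-class means exclude self-pairs; the offset vanishes with
sample size.

Snn (the nearest-neighbour statistic) is the mean over sequences of the
fraction of its nearest neighbours (minimal Hamming distance on retained
sites, ties split fractionally) belonging to its own class. Significance is
by label permutation with the +1-corrected P-value
(1 + #{Snn* ≥ Snn})/(n_perm + 1); 10 000 permutations by default.
Between-arrangement comparisons are computed within one population whenever
the design allows it (the two derived arrangements, sampled in different
populations, are compared across populations and labelled as such).

## Linkage disequilibrium and recombination

Informative sites are retained biallelic columns with minor-allele count
≥ 2. Each unordered pair gets r² from the two-locus haplotype counts and a
two-sided Fisher exact P (summing tables with probability ≤ observed);
P-values are Benjamini–Hochberg adjusted within one comparison panel. ZnS is
the mean r² over all pairs. The in-repo recombination signal is the
Hudson–Kaplan four-gamete lower bound R_m, computed by the greedy
disjoint-interval scan over all incompatible site pairs; composite-likelihood
ρ estimation is out of scope.

## Gene conversion tracts and ψ

For a focal recipient sequence, a site is *informative* for conversion from
a donor arrangement when, excluding the recipient, the recipient class shows
one base at frequency ≥ `freq_threshold` (default 1.0 — strictly fixed;
the threshold is configurable because the original settings are unstated),
the donor class shows a different base at the same threshold, and the
recipient carries the donor base. A tract is a maximal run of informative
sites for one recipient uninterrupted by a diagnostic site at which the
recipient carries its own class's base; its extent is the span of the
outermost informative sites — a conservative lower bound on the true
converted segment, matching the semantics of published tract-length ranges.
Large "tracts" at loci outside inversions may in truth be single or double
crossovers; the detector reports them and leaves interpretation to the
report layer.

ψ is the per-site probability that a site is informative for one randomly
chosen recipient lineage. Within a class, lineages are exchangeable under
the null (no conversion), so the exact conditional probability given the
observed alleles is the leave-one-out enumeration over focal lineages; ψ
averages this over retained sites, i.e. ψ = informative events /
(recipients × retained sites). Plug-in frequency formulas of the form
p^(n−1) systematically underestimate this rate at coalescent-realistic
frequency spectra, which is why the enumeration form is used. On study-like
data ψ falls in the 10⁻³–10⁻⁵ range, so false tracts are rare and dominated
by single-site runs.

## Neutrality tests

**Tajima's D** is (π̂ − S/a₁)/√(e₁S + e₂S(S−1)) with the 1989 constants;
π̂ is the mean pairwise difference count on the chosen site subset (all
retained sites or silent-only), and sequences can be excluded (detected
recombinants) with the exclusion list recorded in the result.

**Fu & Li's D** is implemented in its outgroup form from total mutations η
and external mutations ηe (derived singletons: a base carried by exactly one
ingroup sequence and different from the outgroup base), with the 1993
variance constants; columns where the outgroup is gapped or ambiguous are
excluded. The within-sample D* variant is deliberately not used, since the
analysis design names an outgroup.

**McDonald–Kreitman.** Per fully retained codon, within-ingroup changes
(each minor codon against the most common codon) are pathway-classified into
Pn/Ps; fixed differences are counted only at codon positions monomorphic in
the ingroup and different from the outgroup, substituted jointly into the
major codon and pathway-classified into Dn/Ds. A codon that is both
polymorphic and divergent contributes polymorphism at its varying positions
and divergence at its monomorphic divergent positions. Pathway averaging can
produce fractional counts; the final table rounds to nearest integers
(almost all codons differ at a single position, where rounding is a no-op).
Significance is the two-sided Fisher exact P on [[Pn, Dn], [Ps, Ds]]; a
degenerate margin returns P = 1 with a warning. DoS = Dn/(Dn+Ds) −
Pn/(Pn+Ps). Note that the published counts for the classic Atpα example
(Pn=7, Ps=2, Dn=9, Ds=51) give DoS = −0.628 by this formula, not the −0.442
printed alongside them; the package reports the formula value and flags the
discrepancy rather than forcing agreement.

The amino-acid replacement profile translates each arrangement's codons and
tags residues by frequency class: untagged major residue, `a` for
low-frequency (< 0.3 by default), `b` for an exact 50/50 split; positions
can be renumbered against an external reference protein via a configurable
offset.

## Inversion dating

The age of an arrangement is estimated from within-arrangement silent
diversity calibrated by interspecific silent divergence:

    rate = K_sil / (2·t_div)          age = π_sil / (2·rate) = π_sil·t_div / K_sil

with t_div = 17.7 ± 4.4 Myr for the D. subobscura–D. pseudoobscura split.
The estimator form was fixed by the observation that the published age SEs
are exactly the calibration's relative SE (4.4/17.7 ≈ 0.249) times the
point estimates, so only calibration uncertainty is propagated:
se(age) = age·(t_div_se/t_div), asserted to 1e-12 in the tests. Sequences
carrying conversion tracts or crossover signals inflate π_sil and hence the
age; exclusion lists are explicit inputs produced by the tract detector,
never hard-coded. π_sil entering the estimator is pooled by arrangement
across populations by default (configurable), since the published choice is
not stated. The estimator assumes a star-like onset (all coalescence at the
founding event); with ongoing flux it overestimates the age, a directional
property reproduced on simulations.

## The synthetic-data generator

`simulate_arrangements` emulates the sampled study design: isochromosomal
lines from one ancestral arrangement plus derived arrangements, each founded
by a single chromosome entering the ancestral class `age_gen` generations
ago. The machinery is msprime's structured coalescent:

- each derived arrangement is a population joined to the ancestral one by a
  population split at its founding time, preceded by an instantaneous
  bottleneck strong enough to force coalescence to a single founder lineage
  (the same star-like onset the age estimator assumes);
- gene flux between arrangements is symmetric migration at scaled rate
  `flux_rate`; crossover and gene conversion act along the locus at
  `rho_per_site` and `conversion_rate` with geometric tract length
  `mean_tract_bp`;
- all scaled rates are per site per 2N_e generations (haploid coalescent
  unit — an isochromosomal line carries one chromosome): θ = 2N_e·μ,
  ρ = 2N_e·r, flux = 2N_e·m. N_e defaults to 1000; `derived_ne` sets the
  post-founding size of derived arrangements (large values keep the
  genealogy star-like, the regime of the dating recovery study);
- mutation is finite-sites Jukes–Cantor, so multiple hits and the divergence
  correction are genuinely exercised. JC69 draws random ancestral states, so
  alleles are relabelled per site (a symmetry of the model) to make the root
  sequence equal the generated reference, whose in-frame exon codons are
  stop-free. Changes creating premature stop codons are treated as lethal
  and reverted;
- the outgroup evolves from the root sequence to an expected divergence of
  `outgroup_divergence` substitutions per site (not by coalescent sampling),
  so the configured value is on the corrected scale and the observed raw
  difference is the JC-saturated transform of it plus the within-ingroup
  depth.

Fixture edits with recorded ground truth: `implant_conversion_tract`
replaces a recipient's segment by the donor-class consensus;
`inject_fixed_differences` forces diagnostic nonsynonymous changes onto
every member of one class at ingroup-monomorphic coding positions where the
change is nonsynonymous on every codon background; and
`apply_coding_constraint` emulates strong purifying selection on the protein
by reverting every nonsynonymous deviation from the consensus codon
(conserved-gene regime — the neutral coalescent otherwise produces
unconstrained replacement variation, with Dn/Ds near the nonsynonymous/
synonymous site ratio).

**What the generator does and does not emulate.** It reproduces the
statistical structure the analysis assumes — class founding times, flux,
recombination, mixed intron/exon composition, a diverged outgroup, realistic
θ (≈0.004–0.01/site) and divergence (≈0.17) — but not selection dynamics
(no fitness-based forward simulation), not an explicit suppression map
around breakpoints (class membership alone carries the flux reduction), and
not sequencing artefacts (no alignment error, no missing data unless
masked in). Passing recovery tests therefore demonstrates correctness of the
estimators under the model's own assumptions, not robustness to demographic
misspecification on real data.

**Simulated six-gene ecosystem.** `write_simulated_study` emits six loci
under the sampled layout (11 + 12 lines in one population, 10 + 12 in the
other; derived classes founded 1000 generations ago; flux 0.3; 1.5 kb loci
with a 600 bp and a 400 bp exon). All coding regions evolve under the
purifying constraint; one gene receives four injected diagnostic
replacements fixed in one derived arrangement. In pooled two-arrangement
samples these segregate as nonsynonymous polymorphism against constrained
divergence — exactly the signature of nearly-fixed adaptive replacements in
a conserved gene — making the McDonald–Kreitman test significant for that
gene's pooled samples and degenerate (P = 1) elsewhere. Per-arrangement MK
tables are reported alongside the pooled ones.

## Problem sizes and numerical conventions

Simulation studies use deliberately modest problem sizes chosen to give
stable Monte-Carlo answers: 200 replicates at n = 10+10 and 2 kb for the
dating recovery (≈30 segregating silent sites; mean recovered age within a
few percent of truth, well inside the 25% acceptance band), 200 replicates
for tract recovery, 100–150 seeds for the neutral-expectation checks. The
dating recovery maps simulation truth to calendar time through the
calibration itself: with per-generation rate μ and configured outgroup
divergence d, the founding age T generations corresponds to
T·2μ·t_div/d Myr.

Tolerances: closed-form identities are asserted to 1e-10–1e-12; Monte-Carlo
expectations to four standard errors; permutation P-values are exactly
reproducible given a seed. All pipeline randomness derives from the master
seed and the stage name (CRC-mixed, kept below 2³¹), so a re-run with the
same config is byte-identical, which the manifest's report checksums make
checkable.

## Known limitations

- Reproducing the published per-gene tables requires the GenBank dataset
  (the KT and JN accession ranges), which must be fetched and curated with
  `scripts/fetch_accessions.py`; the repository ships no sequence data.
  Where the original software's conventions are unstated (gap policy,
  synonymous-site counting variant, K_sil correction, tract frequency
  threshold), the choices above are pinned defaults exposed as configuration
  so accession-level reproduction can be tuned.
- The MK counter resolves multi-hit codons by pathway averaging then
  rounding; under extreme divergence this can differ from codon-model-based
  counting.
- The dating estimator inherits the star-like assumption; its SE reflects
  calibration uncertainty only, not coalescent variance in π_sil.
- R_m is a lower bound and is not comparable across loci with different
  numbers of informative sites.
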