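"""End-to-end study orchestration.

A study is described by one YAML config: per-gene alignment/metadata/
annotation paths, the arrangement comparisons to run (within-population by
default), a cytological map for breakpoint distances, the divergence
calibration, thresholds, and a master seed. ``run_study`` produces a bundle
of TSV reports — per-arrangement diversity, F_ST/Snn differentiation,
LD/ZnS/R_m, gene conversion tracts, neutrality tests with MK/DoS, inversion
dating, breakpoint-distance correlations — plus a JSON run manifest that
fully determines the bundle. All randomness derives from the master seed and
the stage name, so a re-run with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .dating import tmrca_silent
from .differentiation import (
    pearson_distance_correlation,
    significance_stars,
    snn_test,
)
from .diversity import diversity_summary
from .errors import ConfigError, DataError, UndefinedValueError
from .io import (
    GeneAnnotation,
    HaplotypeAlignment,
    classify_sites,
    complete_deletion_mask,
    read_annotation,
    read_fasta_alignment,
)
from .linkage import (
    biallelic_informative_sites,
    detect_conversion_tracts,
    ld_matrix,
    min_recombination_events,
    zns,
)
from .neutrality import dos, fu_li_d, mk_fisher, mk_table, tajimas_d


@dataclass
class GeneEntry:
    name: str
    alignment: str
    metadata: str
    annotation: str


@dataclass
class Comparison:
    a: str
    b: str
    population: str | None = None  # None -> cross-population, labelled as such

    @property
    def label(self) -> str:
        where = self.population or "cross"
        return f"{self.a}-{self.b}({where})"


@dataclass
class StudyConfig:
    genes: list[GeneEntry]
    comparisons: list[Comparison]
    seed: int = 1
    t_div_myr: float = 17.7
    t_div_se_myr: float = 4.4
    min_minor: int = 2
    freq_threshold: float = 1.0
    low_freq_cutoff: float = 0.3
    n_perm: int = 10_000
    fdr_q: float = 0.05
    band_scale_bp: float = 0.0
    gene_bands: dict[str, float] = field(default_factory=dict)
    inversions: dict[str, tuple[float, float]] = field(default_factory=dict)
    dating: list[dict] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict) or "genes" not in raw:
            raise ConfigError(f"{path}: study config must define 'genes'")
        base = Path(path).parent

        def _p(rel: str) -> str:
            return str((base / rel) if not Path(rel).is_absolute() else Path(rel))

        genes = [
            GeneEntry(
                g["name"], _p(g["alignment"]), _p(g["metadata"]), _p(g["annotation"])
            )
            for g in raw["genes"]
        ]
        comps = [
            Comparison(c["a"], c["b"], c.get("population"))
            for c in raw.get("comparisons", [])
        ]
        cal = raw.get("calibration", {})
        thr = raw.get("thresholds", {})
        cmap = raw.get("map", {})
        cfg = cls(
            genes=genes,
            comparisons=comps,
            seed=int(raw.get("seed", 1)),
            t_div_myr=float(cal.get("t_div_myr", 17.7)),
            t_div_se_myr=float(cal.get("t_div_se_myr", 4.4)),
            min_minor=int(thr.get("min_minor", 2)),
            freq_threshold=float(thr.get("freq_threshold", 1.0)),
            low_freq_cutoff=float(thr.get("low_freq_cutoff", 0.3)),
            n_perm=int(thr.get("n_perm", 10_000)),
            fdr_q=float(thr.get("fdr_q", 0.05)),
            band_scale_bp=float(cmap.get("band_scale_bp", 0.0)),
            gene_bands={k: float(v) for k, v in cmap.get("gene_bands", {}).items()},
            inversions={
                k: (float(v[0]), float(v[1]))
                for k, v in cmap.get("inversions", {}).items()
            },
            dating=list(raw.get("dating", [])),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.genes:
            raise ConfigError("study config lists no genes")
        if not (0 < self.freq_threshold <= 1.0):
            raise ConfigError("freq_threshold must be in (0, 1]")
        if not (0 < self.low_freq_cutoff < 1.0):
            raise ConfigError("low_freq_cutoff must be in (0, 1)")
        if self.n_perm < 1 or self.min_minor < 1:
            raise ConfigError("n_perm and min_minor must be >= 1")
        if not (0 < self.fdr_q < 1):
            raise ConfigError("fdr_q must be in (0, 1)")


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage RNG seed below 2**31."""
    return (int(master) ^ zlib.crc32(stage.encode())) % (2**31 - 1)


def breakpoint_distance(
    gene_band: float,
    inversions: "dict[str, tuple[float, float]] | list[tuple[float, float]]",
    band_scale_bp: float,
) -> tuple[float, bool]:
    """Distance (bp) from a gene's band to the nearest inversion breakpoint,
    assuming equal genetic content per cytological band, plus an
    inside-any-inversion flag."""
    if band_scale_bp <= 0:
        raise ConfigError("band_scale_bp must be positive")
    ivs = list(inversions.values()) if isinstance(inversions, dict) else list(inversions)
    if not ivs:
        raise ConfigError("no inversion breakpoints configured")
    bps = [b for iv in ivs for b in iv]
    dist = min(abs(gene_band - b) for b in bps) * band_scale_bp
    inside = any(s <= gene_band <= e for s, e in ivs)
    return dist, inside


# ---------------------------------------------------------------------------
# the orchestrator


def _fmt(x, nd=3):
    if x is None:
        return "NA"
    if isinstance(x, float):
        if np.isnan(x):
            return "NA"
        return f"{x:.{nd}f}"
    return str(x)


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def _arrangement_groups(aln: HaplotypeAlignment) -> list[tuple[str, str]]:
    """(population, arrangement) groups with >= 2 sequences, stable order."""
    seen: dict[tuple[str, str], int] = {}
    for s, a, p in zip(aln.seq_ids, aln.arrangement, aln.population):
        if s == aln.outgroup_id:
            continue
        seen[(p, a)] = seen.get((p, a), 0) + 1
    return [k for k, n in seen.items() if n >= 2]


def _pooled_pair(
    aln: HaplotypeAlignment, comp: Comparison
) -> tuple[HaplotypeAlignment, HaplotypeAlignment]:
    popA = popB = comp.population
    a = aln.by_arrangement(comp.a, popA)
    b = aln.by_arrangement(comp.b, popB)
    return a, b


def run_study(cfg: StudyConfig, out_dir) -> dict:
    """Run every stage; independent stage failures are recorded in the
    manifest and do not abort the rest. Returns the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "invpop_version": __version__,
        "seed": cfg.seed,
        "thresholds": {
            "min_minor": cfg.min_minor,
            "freq_threshold": cfg.freq_threshold,
            "low_freq_cutoff": cfg.low_freq_cutoff,
            "n_perm": cfg.n_perm,
            "fdr_q": cfg.fdr_q,
        },
        "calibration": {"t_div_myr": cfg.t_div_myr, "t_div_se_myr": cfg.t_div_se_myr},
        "stages": {},
        "reports": {},
    }

    genes: dict[str, tuple[HaplotypeAlignment, GeneAnnotation]] = {}
    for g in cfg.genes:
        aln = read_fasta_alignment(g.alignment, g.metadata)
        annots = read_annotation(g.annotation)
        named = [a for a in annots if a.gene_name == g.name]
        annot = named[0] if named else annots[0]
        genes[g.name] = (aln, annot)

    def stage(name):
        def deco(fn):
            try:
                fn()
                manifest["stages"][name] = "ok"
            except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
                manifest["stages"][name] = f"failed: {type(exc).__name__}: {exc}"
            return fn

        return deco

    pi_by_gene_arr: dict[tuple[str, str], float] = {}
    fst_by_gene_pair: dict[tuple[str, str], float] = {}

    @stage("diversity")
    def _diversity():
        rows = []
        for name, (aln, annot) in genes.items():
            for pop, arr in _arrangement_groups(aln):
                sub = aln.by_arrangement(arr, pop, keep_outgroup=True)
                mask = complete_deletion_mask(sub)
                sc = classify_sites(sub, annot, mask)
                s = diversity_summary(sub, sc, mask)
                rows.append(
                    [name, pop, arr, s.n, s.h, s.S, s.singletons,
                     _fmt(s.pi), _fmt(s.pi_sil), _fmt(s.theta_sil), _fmt(s.K_sil)]
                )
                pi_by_gene_arr[(name, arr)] = s.pi
        _write_tsv(
            out / "diversity.tsv",
            ["gene", "population", "arrangement", "n", "h", "S", "singletons",
             "pi", "pi_sil", "theta_sil", "K_sil"],
            rows,
        )

    @stage("differentiation")
    def _differentiation():
        rows = []
        for name, (aln, _) in genes.items():
            for comp in cfg.comparisons:
                a, b = _pooled_pair(aln, comp)
                if a.n < 2 or b.n < 2:
                    rows.append([name, comp.label, "NA", "NA", "NA", "NA"])
                    continue
                seed = stage_seed(cfg.seed, f"snn:{name}:{comp.label}")
                try:
                    r = snn_test(a, b, n_perm=cfg.n_perm, seed=seed)
                except (DataError, UndefinedValueError) as exc:
                    rows.append([name, comp.label, "NA", "NA", "NA", f"({exc})"])
                    continue
                rows.append(
                    [name, comp.label, _fmt(r.fst), _fmt(r.snn),
                     _fmt(r.snn_p, 4), significance_stars(r.snn_p)]
                )
                fst_by_gene_pair[(name, comp.label)] = r.fst
        _write_tsv(
            out / "differentiation.tsv",
            ["gene", "comparison", "fst", "snn", "snn_p", "stars"],
            rows,
        )

    @stage("linkage")
    def _linkage():
        rows = []
        pair_rows = []
        for name, (aln, _) in genes.items():
            for comp in cfg.comparisons:
                a, b = _pooled_pair(aln, comp)
                if a.n + b.n < 4:
                    continue
                pooled = aln.subset(a.seq_ids + b.seq_ids)
                mask = complete_deletion_mask(pooled)
                sites = biallelic_informative_sites(pooled, mask, cfg.min_minor)
                if len(sites) < 2:
                    rows.append([name, comp.label, len(sites), "NA", 0, 0, "NA"])
                    continue
                pairs = ld_matrix(pooled, sites)
                nsig = sum(1 for p in pairs if p.q is not None and p.q < cfg.fdr_q)
                rows.append(
                    [name, comp.label, len(sites), _fmt(zns(pooled, sites)),
                     len(pairs), nsig,
                     min_recombination_events(pooled, sites)]
                )
                for p in pairs:
                    pair_rows.append(
                        [name, comp.label, p.site_i + 1, p.site_j + 1,
                         _fmt(p.r2), _fmt(p.fisher_p, 5), _fmt(p.q, 5),
                         int(p.q is not None and p.q < cfg.fdr_q)]
                    )
        _write_tsv(
            out / "linkage.tsv",
            ["gene", "comparison", "informative_sites", "zns", "n_pairs",
             "n_significant", "Rm"],
            rows,
        )
        _write_tsv(
            out / "ld_pairs.tsv",
            ["gene", "comparison", "site_i", "site_j", "r2", "p", "q", "significant"],
            pair_rows,
        )

    @stage("gene_conversion")
    def _gct():
        rows = []
        for name, (aln, _) in genes.items():
            for comp in cfg.comparisons:
                a, b = _pooled_pair(aln, comp)
                if a.n < 2 or b.n < 2:
                    continue
                pooled = aln.subset(a.seq_ids + b.seq_ids)
                for recip, donor in ((comp.a, comp.b), (comp.b, comp.a)):
                    tracts = detect_conversion_tracts(
                        pooled, recip, donor, freq_threshold=cfg.freq_threshold
                    )
                    for t in tracts:
                        rows.append(
                            [name, comp.label, t.recipient_id, t.donor_class,
                             t.first_site + 1, t.last_site + 1, t.length_bp,
                             t.n_informative, f"{t.psi:.2e}"]
                        )
        _write_tsv(
            out / "conversion_tracts.tsv",
            ["gene", "comparison", "recipient", "donor_class", "first", "last",
             "length_bp", "n_informative", "psi"],
            rows,
        )

    @stage("neutrality")
    def _neutrality():
        rows = []
        for name, (aln, annot) in genes.items():
            units: list[tuple[str, HaplotypeAlignment]] = []
            for pop, arr in _arrangement_groups(aln):
                units.append(
                    (f"{arr}({pop})", aln.by_arrangement(arr, pop, keep_outgroup=True))
                )
            for comp in cfg.comparisons:
                a, b = _pooled_pair(aln, comp)
                if a.n >= 2 and b.n >= 2:
                    units.append(
                        (f"pooled:{comp.label}",
                         aln.subset(a.seq_ids + b.seq_ids, keep_outgroup=True))
                    )
            for label, sub in units:
                if sub.n < 4:
                    continue
                mask = complete_deletion_mask(sub)
                sc = classify_sites(sub, annot, mask)
                silent_cols = np.nonzero(
                    (sc.status == 0) | ((sc.status == 1) & (sc.syn_sites > 0.5))
                )[0]
                row = [name, label, sub.n]
                try:
                    row.append(_fmt(tajimas_d(sub, mask).statistic))
                except DataError:
                    row.append("NA")
                try:
                    row.append(
                        _fmt(tajimas_d(sub, mask, site_subset=silent_cols,
                                       variant="silent_only").statistic)
                    )
                except DataError:
                    row.append("NA")
                try:
                    row.append(_fmt(fu_li_d(sub, mask).statistic))
                except (DataError, ConfigError):
                    row.append("NA")
                try:
                    t = mk_table(sub, annot, mask, sc)
                    p = mk_fisher(t)
                    try:
                        d = _fmt(dos(t))
                    except UndefinedValueError:
                        d = "NA"
                    row += [t.Pn, t.Ps, t.Dn, t.Ds, _fmt(p, 5), d]
                except (DataError, ConfigError):
                    row += ["NA"] * 6
                rows.append(row)
        _write_tsv(
            out / "neutrality.tsv",
            ["gene", "sample", "n", "tajima_d", "tajima_d_silent", "fu_li_d",
             "Pn", "Ps", "Dn", "Ds", "mk_p", "dos"],
            rows,
        )

    @stage("dating")
    def _dating():
        rows = []
        for spec in cfg.dating:
            gene = spec["gene"]
            arr = spec["arrangement"]
            excl = list(spec.get("exclusions", []))
            aln, annot = genes[gene]
            est = tmrca_silent(
                aln, annot, arr, exclusions=excl,
                t_div_myr=cfg.t_div_myr, t_div_se_myr=cfg.t_div_se_myr,
            )
            rows.append(
                [gene, arr, _fmt(est.pi_sil_used, 4), _fmt(est.k_sil_used, 4),
                 _fmt(est.age_myr), _fmt(est.se_myr),
                 ";".join(est.excluded) or "-"]
            )
        _write_tsv(
            out / "dating.tsv",
            ["gene", "arrangement", "pi_sil", "K_sil", "age_myr", "se_myr",
             "excluded"],
            rows,
        )

    @stage("correlation")
    def _correlation():
        rows = []
        if cfg.band_scale_bp > 0 and cfg.gene_bands and cfg.inversions:
            dist = {
                g: breakpoint_distance(b, cfg.inversions, cfg.band_scale_bp)
                for g, b in cfg.gene_bands.items()
            }
            for g, (d, inside) in sorted(dist.items()):
                rows.append(["distance", g, "-", _fmt(d, 1),
                             "inside" if inside else "outside"])
            arrs = sorted({a for (_, a) in pi_by_gene_arr})
            for arr in arrs:
                pts = [
                    (pi_by_gene_arr[(g, arr)], dist[g][0])
                    for g in cfg.gene_bands
                    if (g, arr) in pi_by_gene_arr
                ]
                if len(pts) >= 3:
                    try:
                        r, p = pearson_distance_correlation(
                            [x for x, _ in pts], [y for _, y in pts]
                        )
                        rows.append(["pi_vs_distance", arr, len(pts), _fmt(r), _fmt(p, 4)])
                    except (DataError, UndefinedValueError):
                        rows.append(["pi_vs_distance", arr, len(pts), "NA", "NA"])
            pairs = sorted({p for (_, p) in fst_by_gene_pair})
            for pair in pairs:
                pts = [
                    (fst_by_gene_pair[(g, pair)], dist[g][0])
                    for g in cfg.gene_bands
                    if (g, pair) in fst_by_gene_pair
                ]
                if len(pts) >= 3:
                    try:
                        r, p = pearson_distance_correlation(
                            [x for x, _ in pts], [y for _, y in pts]
                        )
                        rows.append(["fst_vs_distance", pair, len(pts), _fmt(r), _fmt(p, 4)])
                    except (DataError, UndefinedValueError):
                        rows.append(["fst_vs_distance", pair, len(pts), "NA", "NA"])
        _write_tsv(
            out / "correlation.tsv",
            ["analysis", "unit", "n", "value", "detail"],
            rows,
        )

    for f in sorted(out.glob("*.tsv")):
        manifest["reports"][f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# simulated study emission (the desk-scale ecosystem)


def write_simulated_study(
    out_dir,
    seed: int = 1,
    n_genes: int = 6,
    inject_gene: str | None = "gene5",
    inject_class: str = "O3+4+7",
    n_inject: int = 4,
    constrain_coding: bool = True,
    theta_per_site: float = 0.005,
    flux_rate: float = 0.3,
    n_perm: int = 2000,
) -> Path:
    """Generate a study-shaped multi-gene dataset plus its YAML config.

    Mirrors the sampled design (two populations, one ancestral and two
    derived arrangements) across ``n_genes`` loci. Coding regions evolve
    under strong purifying constraint when ``constrain_coding``; one gene
    optionally receives ``n_inject`` diagnostic nonsynonymous differences
    fixed in one derived class — the qualitative Atpα signature.
    """
    from .simulate import (
        annotation_from_config,
        apply_coding_constraint,
        inject_fixed_differences,
        simulate_arrangements,
        study_layout,
        write_simulation,
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gene_names = [f"gene{i + 1}" for i in range(n_genes)]
    entries = []
    for i, name in enumerate(gene_names):
        cfg = study_layout(
            seed=stage_seed(seed, f"sim:{name}"),
            theta_per_site=theta_per_site,
            flux_rate=flux_rate,
        )
        aln, truth = simulate_arrangements(cfg)
        annot = annotation_from_config(cfg, name)
        if constrain_coding:
            aln = apply_coding_constraint(aln, annot)
        if inject_gene == name:
            aln = inject_fixed_differences(
                aln, annot, inject_class, n_inject,
                seed=stage_seed(seed, f"inject:{name}"), truth=truth,
            )
        write_simulation(aln, truth, annot, out / name)
        entries.append(
            {
                "name": name,
                "alignment": f"{name}.fasta",
                "metadata": f"{name}.meta.tsv",
                "annotation": f"{name}.annot.tsv",
            }
        )
    study = {
        "seed": seed,
        "genes": entries,
        "comparisons": [
            {"a": "O3+4", "b": "O3+4+1", "population": "MP"},
            {"a": "O3+4", "b": "O3+4+7", "population": "BC"},
            {"a": "O3+4+1", "b": "O3+4+7"},
        ],
        "calibration": {"t_div_myr": 17.7, "t_div_se_myr": 4.4},
        "thresholds": {"n_perm": n_perm},
        "map": {
            "band_scale_bp": 120000.0,
            "gene_bands": {name: 75.0 + 5 * i for i, name in enumerate(gene_names)},
            "inversions": {"O1": [91.0, 97.0], "O7": [75.0, 91.0]},
        },
        "dating": [
            {"gene": "gene2", "arrangement": "O3+4+1"},
            {"gene": "gene2", "arrangement": "O3+4+7"},
        ],
    }
    cfg_path = out / "study.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(study, fh, sort_keys=False)
    return cfg_path
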