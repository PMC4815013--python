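"""Alignment input/output, validation, masking, site classification and
gene concatenation.

The universal input is a :class:`HaplotypeAlignment`: equal-length haploid
sequences (one per isochromosomal line) labelled with a chromosomal
arrangement and a population, plus at most one outgroup sequence from a
diverged species. Sequences are stored uppercase over the alphabet
``{A,C,G,T,N,-}`` in coding orientation; coordinates are 0-based half-open
internally and 1-based closed in human-readable reports.

Gap policy: every per-site statistic in this package runs on the
complete-deletion mask — any column carrying ``-`` or ``N`` in any sequence
of the alignment under consideration is excluded everywhere. One fixed,
explicit policy keeps per-arrangement tables reproducible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codons import is_stop, syn_fraction, translate
from .errors import (
    AlignmentError,
    AnnotationError,
    ConfigError,
    MetadataError,
)

ALPHABET = set(b"ACGTN-")

#: per-position status codes used by SiteClassification
NONCODING, CODING, EXCLUDED = 0, 1, 2


@dataclass
class HaplotypeAlignment:
    """Equal-length haploid sequences with arrangement/population labels.

    ``matrix`` holds the alignment as an (n, L) uint8 array of ASCII codes;
    ``sequences`` reconstructs plain strings on demand. At most one row may
    be the outgroup (``outgroup_id``); every other row must carry an
    arrangement and a population label.
    """

    seq_ids: list[str]
    matrix: np.ndarray
    arrangement: list[str | None]
    population: list[str | None]
    outgroup_id: str | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.seq_ids):
            raise AlignmentError("matrix shape inconsistent with seq_ids")
        if len(set(self.seq_ids)) != len(self.seq_ids):
            raise AlignmentError("duplicate sequence ids")
        bad = set(np.unique(self.matrix).tobytes()) - ALPHABET
        if bad:
            raise AlignmentError(
                f"illegal characters in alignment: {sorted(chr(b) for b in bad)}"
            )
        if self.outgroup_id is not None and self.outgroup_id not in self.seq_ids:
            raise MetadataError(f"outgroup id {self.outgroup_id!r} not in alignment")
        for sid, arr, pop in zip(self.seq_ids, self.arrangement, self.population):
            if sid == self.outgroup_id:
                continue
            if arr is None or pop is None:
                raise MetadataError(f"ingroup sequence {sid!r} lacks arrangement/population")

    # -- basic properties -------------------------------------------------

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_total(self) -> int:
        return self.matrix.shape[0]

    @property
    def n(self) -> int:
        """Number of ingroup sequences."""
        return self.n_total - (1 if self.outgroup_id is not None else 0)

    @property
    def sequences(self) -> list[str]:
        return [row.tobytes().decode("ascii") for row in self.matrix]

    def row(self, seq_id: str) -> np.ndarray:
        return self.matrix[self.seq_ids.index(seq_id)]

    def ingroup_indices(self) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.seq_ids) if s != self.outgroup_id], dtype=int
        )

    def ingroup_matrix(self) -> np.ndarray:
        return self.matrix[self.ingroup_indices()]

    def outgroup_row(self) -> np.ndarray:
        if self.outgroup_id is None:
            raise ConfigError("alignment has no outgroup sequence")
        return self.matrix[self.seq_ids.index(self.outgroup_id)]

    # -- subsetting -------------------------------------------------------

    def subset(self, seq_ids: list[str], keep_outgroup: bool = False) -> "HaplotypeAlignment":
        """New alignment restricted to ``seq_ids`` (order preserved)."""
        ids = list(seq_ids)
        if keep_outgroup and self.outgroup_id is not None and self.outgroup_id not in ids:
            ids.append(self.outgroup_id)
        idx = [self.seq_ids.index(s) for s in ids]
        return HaplotypeAlignment(
            seq_ids=ids,
            matrix=self.matrix[idx].copy(),
            arrangement=[self.arrangement[i] for i in idx],
            population=[self.population[i] for i in idx],
            outgroup_id=self.outgroup_id if self.outgroup_id in ids else None,
        )

    def by_arrangement(
        self,
        label: str,
        population: str | None = None,
        keep_outgroup: bool = False,
    ) -> "HaplotypeAlignment":
        ids = [
            s
            for s, a, p in zip(self.seq_ids, self.arrangement, self.population)
            if s != self.outgroup_id
            and a == label
            and (population is None or p == population)
        ]
        return self.subset(ids, keep_outgroup=keep_outgroup)

    def arrangement_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s, a in zip(self.seq_ids, self.arrangement):
            if s == self.outgroup_id:
                continue
            counts[a] = counts.get(a, 0) + 1
        return counts


@dataclass
class GeneAnnotation:
    """Exon layout of one gene on alignment coordinates.

    ``exons`` are 0-based half-open intervals, sorted and non-overlapping;
    ``frame`` is the offset (0–2) of the first complete codon within the
    spliced exon sequence. The alignment is stored in coding orientation, so
    ``strand`` is metadata only.
    """

    gene_name: str
    exons: list[tuple[int, int]]
    frame: int = 0
    strand: str = "+"

    def validate(self, length: int) -> None:
        prev_end = -1
        for s, e in self.exons:
            if not (0 <= s < e <= length):
                raise AnnotationError(f"{self.gene_name}: exon ({s},{e}) out of bounds")
            if s < prev_end:
                raise AnnotationError(f"{self.gene_name}: exons overlap or unsorted")
            prev_end = e
        if self.frame not in (0, 1, 2):
            raise AnnotationError(f"{self.gene_name}: frame must be 0..2")
        if self.strand not in "+-":
            raise AnnotationError(f"{self.gene_name}: strand must be + or -")

    def spliced_positions(self) -> np.ndarray:
        """Alignment columns of the spliced exon sequence, 5'→3'."""
        if not self.exons:
            return np.array([], dtype=int)
        return np.concatenate([np.arange(s, e) for s, e in self.exons])


@dataclass
class SiteClassification:
    """Per-column coding status and fractional synonymous site counts.

    For each retained coding column ``syn_sites + nonsyn_sites == 1``;
    retained noncoding columns contribute 1 to ``silent_sites_total``;
    excluded columns contribute 0 everywhere. ``codon_columns`` maps codon
    index -> the three alignment columns of every fully retained codon, and
    ``consensus_codons`` the ingroup consensus codon string for each.
    """

    status: np.ndarray
    syn_sites: np.ndarray
    nonsyn_sites: np.ndarray
    codon_columns: dict[int, tuple[int, int, int]] = field(default_factory=dict)
    consensus_codons: dict[int, str] = field(default_factory=dict)

    @property
    def silent_sites_total(self) -> float:
        return float(np.sum(self.status == NONCODING) + self.syn_sites.sum())

    @property
    def nonsyn_sites_total(self) -> float:
        return float(self.nonsyn_sites.sum())


# ---------------------------------------------------------------------------
# readers / writers


def read_fasta_alignment(path, metadata_path) -> HaplotypeAlignment:
    """Read a FASTA alignment plus its sidecar metadata TSV.

    The TSV needs columns ``seq_id``, ``arrangement``, ``population``,
    ``role`` (``ingroup``/``outgroup``). Characters are uppercased and U is
    mapped to T.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"{path}: no FASTA records")
    meta: dict[str, dict[str, str]] = {}
    with open(metadata_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"seq_id", "arrangement", "population", "role"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise MetadataError(
                f"{metadata_path}: metadata TSV must have columns {sorted(required)}"
            )
        for row in reader:
            meta[row["seq_id"]] = row

    length = len(records[0].seq)
    ids, rows, arrs, pops = [], [], [], []
    outgroup_id = None
    for rec in records:
        seq = str(rec.seq).upper().replace("U", "T")
        if len(seq) != length:
            raise AlignmentError(
                f"record {rec.id!r}: length {len(seq)} != expected {length}"
            )
        for i, ch in enumerate(seq):
            if ord(ch) not in ALPHABET:
                raise AlignmentError(f"record {rec.id!r}: illegal character {ch!r} at column {i + 1}")
        if rec.id not in meta:
            raise MetadataError(f"record {rec.id!r} missing from metadata TSV")
        m = meta[rec.id]
        ids.append(rec.id)
        rows.append(np.frombuffer(seq.encode(), dtype=np.uint8))
        if m["role"].strip().lower() == "outgroup":
            if outgroup_id is not None:
                raise MetadataError("more than one outgroup sequence")
            outgroup_id = rec.id
            arrs.append(m["arrangement"].strip() or None)
            pops.append(m["population"].strip() or None)
        else:
            arrs.append(m["arrangement"].strip())
            pops.append(m["population"].strip())
    return HaplotypeAlignment(ids, np.vstack(rows), arrs, pops, outgroup_id)


def write_fasta_alignment(aln: HaplotypeAlignment, path, metadata_path=None) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in zip(aln.seq_ids, aln.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")
    if metadata_path is not None:
        with open(metadata_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["seq_id", "arrangement", "population", "role"])
            for sid, arr, pop in zip(aln.seq_ids, aln.arrangement, aln.population):
                role = "outgroup" if sid == aln.outgroup_id else "ingroup"
                w.writerow([sid, arr or "", pop or "", role])


def read_annotation(path) -> list[GeneAnnotation]:
    """Read a BED-like annotation TSV: gene, start, end, frame, strand."""
    by_gene: dict[str, GeneAnnotation] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            g = row["gene"]
            if g not in by_gene:
                by_gene[g] = GeneAnnotation(
                    g, [], int(row.get("frame", 0) or 0), row.get("strand", "+") or "+"
                )
            by_gene[g].exons.append((int(row["start"]), int(row["end"])))
    for ann in by_gene.values():
        ann.exons.sort()
    return list(by_gene.values())


def write_annotation(annots: list[GeneAnnotation], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene", "start", "end", "frame", "strand"])
        for ann in annots:
            for s, e in ann.exons:
                w.writerow([ann.gene_name, s, e, ann.frame, ann.strand])


# ---------------------------------------------------------------------------
# masking and site classification


def complete_deletion_mask(aln: HaplotypeAlignment) -> np.ndarray:
    """Boolean mask of columns free of '-' and 'N' in every sequence."""
    m = aln.matrix
    bad = (m == ord("-")) | (m == ord("N"))
    return ~bad.any(axis=0)


def consensus_sequence(matrix: np.ndarray) -> np.ndarray:
    """Column-wise majority base among A/C/G/T, ties to the alphabetically
    first base. Columns with no unambiguous base yield ``N``."""
    n, L = matrix.shape
    out = np.full(L, ord("N"), dtype=np.uint8)
    bases = [ord(b) for b in "ACGT"]
    counts = np.stack([(matrix == b).sum(axis=0) for b in bases])  # (4, L)
    best = counts.argmax(axis=0)  # argmax breaks ties to first (alphabetical)
    has_base = counts.max(axis=0) > 0
    out[has_base] = np.array(bases, dtype=np.uint8)[best[has_base]]
    return out


def classify_sites(
    aln: HaplotypeAlignment,
    annot: GeneAnnotation,
    mask: np.ndarray | None = None,
) -> SiteClassification:
    """Classify every alignment column for silent-site accounting.

    Coding columns get Nei–Gojobori fractional synonymous/nonsynonymous site
    counts from the degeneracy of the ingroup consensus codon. Codons with
    any masked column, and partial codons at exon edges, are excluded whole.
    Retained non-exonic columns are noncoding (fully silent).
    """
    annot.validate(aln.length)
    if mask is None:
        mask = complete_deletion_mask(aln)
    L = aln.length
    status = np.full(L, NONCODING, dtype=np.int8)
    syn = np.zeros(L)
    nonsyn = np.zeros(L)
    status[~mask] = EXCLUDED

    spliced = annot.spliced_positions()
    # every exonic column is provisionally excluded until its codon qualifies
    if len(spliced):
        status[spliced] = EXCLUDED
    cons = consensus_sequence(aln.ingroup_matrix())

    codon_cols: dict[int, tuple[int, int, int]] = {}
    consensus_codons: dict[int, str] = {}
    usable = spliced[annot.frame :]
    n_codons = len(usable) // 3
    for ci in range(n_codons):
        cols = tuple(int(c) for c in usable[3 * ci : 3 * ci + 3])
        if not all(mask[c] for c in cols):
            continue
        codon = bytes(cons[list(cols)]).decode()
        if "N" in codon:
            continue
        if is_stop(codon):
            if ci == n_codons - 1:
                continue  # terminal stop is legitimate, not a site
            raise AnnotationError(
                f"{annot.gene_name}: internal stop codon in consensus at codon {ci}"
            )
        if translate(codon) == "X":
            continue
        for k, c in enumerate(cols):
            f = syn_fraction(codon, k)
            status[c] = CODING
            syn[c] = f
            nonsyn[c] = 1.0 - f
        codon_cols[ci] = cols
        consensus_codons[ci] = codon
    return SiteClassification(status, syn, nonsyn, codon_cols, consensus_codons)


# ---------------------------------------------------------------------------
# concatenation


def concatenate_alignments(
    alns: list[HaplotypeAlignment],
    gene_names: list[str] | None = None,
) -> tuple[HaplotypeAlignment, dict[str, tuple[int, int]], list[str]]:
    """Join gene alignments line-by-line.

    Only lines present in every input are retained; dropped lines are
    returned for the run log. Returns (concatenated alignment, offset table
    mapping gene -> half-open interval, dropped ids).
    """
    if not alns:
        raise ConfigError("no alignments to concatenate")
    if gene_names is None:
        gene_names = [f"gene{i + 1}" for i in range(len(alns))]
    common = set(alns[0].seq_ids)
    for a in alns[1:]:
        common &= set(a.seq_ids)
    kept = [s for s in alns[0].seq_ids if s in common]
    if not kept:
        raise AlignmentError("concatenation: no line is present in every gene")
    dropped = sorted({s for a in alns for s in a.seq_ids} - common)

    offsets: dict[str, tuple[int, int]] = {}
    pieces = []
    pos = 0
    for name, a in zip(gene_names, alns):
        idx = [a.seq_ids.index(s) for s in kept]
        pieces.append(a.matrix[idx])
        offsets[name] = (pos, pos + a.length)
        pos += a.length
    first = alns[0]
    idx0 = [first.seq_ids.index(s) for s in kept]
    out = HaplotypeAlignment(
        seq_ids=kept,
        matrix=np.hstack(pieces),
        arrangement=[first.arrangement[i] for i in idx0],
        population=[first.population[i] for i in idx0],
        outgroup_id=first.outgroup_id if first.outgroup_id in kept else None,
    )
    return out, offsets, dropped
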