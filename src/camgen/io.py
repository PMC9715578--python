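"""Readers, writers and domain containers for the on-disk formats.

All genomic coordinates are stored 0-based half-open internally; GFF3
input/output converts at the boundary (GFF3 is 1-based inclusive).
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("camgen")


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class GeneCountMatrix:
    """Orthogroup x species matrix of non-negative gene counts."""

    orthogroup_ids: list[str]
    species_ids: list[str]
    counts: np.ndarray  # shape (n_orthogroups, n_species), integer

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.orthogroup_ids), len(self.species_ids)):
            raise ValueError("counts shape does not match identifier lists")
        if (self.counts < 0).any():
            raise ValueError("gene counts must be non-negative")
        if len(set(self.orthogroup_ids)) != len(self.orthogroup_ids):
            raise ValueError("duplicate orthogroup identifiers")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise ValueError("duplicate species identifiers")
        if len(self.species_ids) < 2:
            raise ValueError("a count matrix needs at least 2 species")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.orthogroup_ids,
                            columns=self.species_ids)

    def species_index(self, species: Iterable[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.species_ids)}
        missing = [s for s in species if s not in pos]
        if missing:
            raise KeyError(f"species not in matrix: {', '.join(missing)}")
        return np.array([pos[s] for s in species], dtype=int)


@dataclass(frozen=True)
class GeneLocus:
    """A gene interval with its start-order rank along its chromosome."""

    gene_id: str
    chromosome_id: str
    start: int  # 0-based
    end: int    # half-open
    strand: str = "+"
    rank: int = -1

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")


class GenomeAnnotation:
    """Ordered gene loci, ranks recomputed from start order per chromosome."""

    def __init__(self, loci: Iterable[GeneLocus]):
        by_chrom: dict[str, list[GeneLocus]] = {}
        for loc in loci:
            by_chrom.setdefault(loc.chromosome_id, []).append(loc)
        self.loci: list[GeneLocus] = []
        for chrom in sorted(by_chrom):
            ordered = sorted(by_chrom[chrom], key=lambda l: (l.start, l.gene_id))
            for rank, loc in enumerate(ordered):
                self.loci.append(GeneLocus(loc.gene_id, loc.chromosome_id,
                                           loc.start, loc.end, loc.strand, rank))
        self._by_id = {l.gene_id: l for l in self.loci}
        if len(self._by_id) != len(self.loci):
            raise ValueError("duplicate gene identifiers in annotation")

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __getitem__(self, gene_id: str) -> GeneLocus:
        return self._by_id[gene_id]

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for l in self.loci:
            seen.setdefault(l.chromosome_id, None)
        return list(seen)

    def genes_on(self, chromosome_id: str) -> list[GeneLocus]:
        return [l for l in self.loci if l.chromosome_id == chromosome_id]


@dataclass(frozen=True)
class HomologyHit:
    """One row of a 12-column tabular homology hit."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bitscore: float
    extra: tuple = ()  # remaining columns, kept opaquely

    def __post_init__(self) -> None:
        if self.alignment_length < 0:
            raise ValueError("alignment_length must be >= 0")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@dataclass
class ExpressionMatrix:
    """Gene x (timepoint, replicate) FPKM matrix.

    ``timepoints`` are clock hours; every timepoint carries the same number
    of replicates. ``values`` has one column per (timepoint, replicate)
    pair, timepoint-major.
    """

    gene_ids: list[str]
    timepoints: list[float]
    n_replicates: int
    values: np.ndarray  # (n_genes, n_timepoints * n_replicates)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n_cols = len(self.timepoints) * self.n_replicates
        if self.values.shape != (len(self.gene_ids), n_cols):
            raise ValueError("values shape inconsistent with design")
        if (self.values < 0).any():
            raise ValueError("FPKM values must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")

    @property
    def sample_labels(self) -> list[str]:
        return [f"t{tp:g}_r{r + 1}"
                for tp in self.timepoints for r in range(self.n_replicates)]

    def replicate_means(self) -> np.ndarray:
        """Per-timepoint mean over replicates, shape (n_genes, n_timepoints)."""
        nt, nr = len(self.timepoints), self.n_replicates
        return self.values.reshape(len(self.gene_ids), nt, nr).mean(axis=2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids,
                            columns=self.sample_labels)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def parse_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an order-preserving id -> sequence mapping.

    Sequences are uppercased and RNA U is normalized to T. Duplicate
    identifiers are a hard error; an empty file yields an empty mapping
    with a warning.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA identifier: {rec.id}")
        out[rec.id] = str(rec.seq).upper().replace("U", "T")
    if not out:
        log.warning("FASTA file %s contains no records", path)
    return out


def write_fasta(path, sequences: Mapping[str, str], width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=k, description="") for k, s in sequences.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    del width  # Biopython wraps at 60; width kept for signature stability


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _gff3_attributes(field9: str) -> dict[str, str]:
    out = {}
    for part in field9.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def parse_gff3(path, feature_type: str = "gene") -> GenomeAnnotation:
    """Read GFF3 features of one type into a :class:`GenomeAnnotation`.

    GFF3 coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention. Records with start > end are rejected
    with a logged warning. Ranks are recomputed from sorted starts.
    """
    loci = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                log.warning("%s:%d: fewer than 9 columns, skipped", path, lineno)
                continue
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = cols[:9]
            if ftype != feature_type:
                continue
            start_i, end_i = int(start), int(end)
            if start_i > end_i:
                log.warning("%s:%d: start > end, record rejected", path, lineno)
                continue
            attr = _gff3_attributes(attrs)
            gene_id = attr.get("ID") or attr.get("Name")
            if gene_id is None:
                log.warning("%s:%d: no ID attribute, record rejected", path, lineno)
                continue
            loci.append(GeneLocus(gene_id, seqid, start_i - 1, end_i,
                                  strand if strand in "+-" else "+"))
    return GenomeAnnotation(loci)


def write_gff3(path, annotation: GenomeAnnotation,
               feature_type: str = "gene", source: str = "camgen") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for loc in annotation:
            fh.write("\t".join([
                loc.chromosome_id, source, feature_type,
                str(loc.start + 1), str(loc.end), ".", loc.strand, ".",
                f"ID={loc.gene_id}",
            ]) + "\n")


# ---------------------------------------------------------------------------
# 12-column tabular homology hits
# ---------------------------------------------------------------------------

_HIT_NUMERIC = ((2, float), (3, int), (10, float), (11, float))


def parse_hit_table(path) -> list[HomologyHit]:
    """Parse a tab-separated 12-column hit table (BLAST outfmt-6 layout).

    Malformed numeric fields reject the row with a logged warning.
    Self-hits are retained; downstream stages decide their fate.
    """
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                log.warning("%s:%d: fewer than 12 columns, row rejected",
                            path, lineno)
                continue
            try:
                hit = HomologyHit(
                    query_id=cols[0], subject_id=cols[1],
                    percent_identity=float(cols[2]),
                    alignment_length=int(cols[3]),
                    evalue=float(cols[10]), bitscore=float(cols[11]),
                    extra=tuple(cols[4:10]) + tuple(cols[12:]),
                )
            except ValueError:
                log.warning("%s:%d: malformed numeric field, row rejected",
                            path, lineno)
                continue
            hits.append(hit)
    return hits


def write_hit_table(path, hits: Sequence[HomologyHit]) -> None:
    with open(path, "w") as fh:
        for h in hits:
            mid = list(h.extra[:6]) if len(h.extra) >= 6 else ["0"] * 6
            fh.write("\t".join([
                h.query_id, h.subject_id, repr(float(h.percent_identity)),
                str(int(h.alignment_length)), *mid[:6],
                repr(float(h.evalue)), repr(float(h.bitscore)),
            ]) + "\n")


def filter_homology_hits(hits: Iterable[HomologyHit],
                         min_align_len: float = 100,
                         max_evalue: float = 1e-5) -> set[str]:
    """Query ids with >=1 hit passing the length/e-value filter.

    Both inequalities are strict: alignment length > ``min_align_len`` and
    e-value < ``max_evalue`` — a hit exactly at either threshold fails.
    """
    if min_align_len <= 0 or max_evalue <= 0:
        raise ValueError("thresholds must be positive")
    return {h.query_id for h in hits
            if h.alignment_length > min_align_len and h.evalue < max_evalue}


# ---------------------------------------------------------------------------
# count matrices and OrthoMCL-style groups files
# ---------------------------------------------------------------------------

def read_count_matrix(path) -> GeneCountMatrix:
    """Read a TSV with orthogroups as rows and species as columns."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return GeneCountMatrix(list(df.index.astype(str)),
                           list(df.columns.astype(str)),
                           df.to_numpy())


def write_count_matrix(path, matrix: GeneCountMatrix,
                       header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        matrix.to_frame().to_csv(fh, sep="\t", index_label="orthogroup")


def read_groups_file(path, delimiter: str = "|") -> GeneCountMatrix:
    """Read an OrthoMCL-style groups text: ``OG1: spA|g1 spA|g2 spB|g3``.

    Every gene token must carry a ``species<delimiter>gene`` prefix; a token
    without one is a hard error naming the token. Empty group lines become
    rows of zeros with a warning.
    """
    group_ids: list[str] = []
    per_group: list[dict[str, int]] = []
    species_seen: dict[str, None] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise ValueError(f"{path}:{lineno}: missing ':' group separator")
            gid, rest = line.split(":", 1)
            counts: dict[str, int] = {}
            tokens = rest.split()
            if not tokens:
                log.warning("%s:%d: empty group %s", path, lineno, gid.strip())
            for tok in tokens:
                if delimiter not in tok:
                    raise ValueError(
                        f"gene token without species prefix: {tok!r}")
                sp = tok.split(delimiter, 1)[0]
                counts[sp] = counts.get(sp, 0) + 1
                species_seen.setdefault(sp, None)
            group_ids.append(gid.strip())
            per_group.append(counts)
    species = sorted(species_seen)
    mat = np.zeros((len(group_ids), len(species)), dtype=np.int64)
    for i, counts in enumerate(per_group):
        for j, sp in enumerate(species):
            mat[i, j] = counts.get(sp, 0)
    return GeneCountMatrix(group_ids, species, mat)


def write_groups_file(path, matrix: GeneCountMatrix,
                      delimiter: str = "|") -> None:
    """Write counts back as a groups text with synthetic member names."""
    with open(path, "w") as fh:
        for i, og in enumerate(matrix.orthogroup_ids):
            members = []
            for j, sp in enumerate(matrix.species_ids):
                members += [f"{sp}{delimiter}{og}.g{k + 1}"
                            for k in range(int(matrix.counts[i, j]))]
            fh.write(f"{og}: {' '.join(members)}\n")


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a gene x sample FPKM TSV with columns named ``t<hour>_r<k>``."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    tps: list[float] = []
    reps_per_tp: dict[float, int] = {}
    for col in df.columns:
        if not col.startswith("t") or "_r" not in col:
            raise ValueError(f"sample column {col!r} not in t<hour>_r<k> form")
        tp_s, rep_s = col[1:].split("_r", 1)
        tp = float(tp_s)
        if tp not in reps_per_tp:
            tps.append(tp)
        reps_per_tp[tp] = reps_per_tp.get(tp, 0) + 1
        int(rep_s)  # validate
    nreps = set(reps_per_tp.values())
    if len(nreps) != 1:
        raise ValueError("uneven replicate count across timepoints")
    n_rep = nreps.pop()
    order = [f"t{tp:g}_r{r + 1}" for tp in tps for r in range(n_rep)]
    df = df[order]
    return ExpressionMatrix(list(df.index.astype(str)), tps, n_rep,
                            df.to_numpy())


def write_expression_matrix(path, matrix: ExpressionMatrix,
                            header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        matrix.to_frame().to_csv(fh, sep="\t", index_label="gene")
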