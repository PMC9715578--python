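"""Collinear-block chaining, duplication classes, Ks peaks, fusion counts.

Blocks are chains of homologous anchor gene pairs whose ranks move
monotonically on both chromosomes (descending on the second for inverted
blocks), found by sparse dynamic programming that maximizes
sum(anchor scores) - gap_penalty * (total intervening genes). Anchors are
assigned to at most one reported block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as _st

from .io import GenomeAnnotation, HomologyHit

log = logging.getLogger("camgen")


@dataclass(frozen=True)
class AnchorPair:
    gene_a: str
    gene_b: str
    chrom_a: str
    chrom_b: str
    rank_a: int
    rank_b: int
    score: float = 1.0


@dataclass(frozen=True)
class CollinearBlock:
    anchors: tuple[AnchorPair, ...]
    orientation: str  # "same" | "inverted"

    @property
    def chrom_a(self) -> str:
        return self.anchors[0].chrom_a

    @property
    def chrom_b(self) -> str:
        return self.anchors[0].chrom_b

    @property
    def n_genes(self) -> int:
        return len(self.anchors)

    @property
    def score(self) -> float:
        return sum(a.score for a in self.anchors)


def anchors_from_hits(annot_a: GenomeAnnotation, annot_b: GenomeAnnotation,
                      hits: Iterable[HomologyHit]) -> list[AnchorPair]:
    """Build anchors from homology hits; unknown genes skipped with warning."""
    out = []
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        if h.query_id not in annot_a or h.subject_id not in annot_b:
            log.warning("hit %s-%s outside annotations, skipped",
                        h.query_id, h.subject_id)
            continue
        la, lb = annot_a[h.query_id], annot_b[h.subject_id]
        out.append(AnchorPair(h.query_id, h.subject_id,
                              la.chromosome_id, lb.chromosome_id,
                              la.rank, lb.rank, h.bitscore))
    return out


def _gap(a1: AnchorPair, a2: AnchorPair, direction: int) -> int | None:
    """Intervening gene count between consecutive anchors, None if invalid."""
    da = a2.rank_a - a1.rank_a
    db = (a2.rank_b - a1.rank_b) * direction
    if da <= 0 or db <= 0:
        return None
    return max(da, db) - 1


def best_chain(anchors: Sequence[AnchorPair], max_gap: int,
               gap_penalty: float = 1.0,
               direction: int = 1) -> tuple[float, list[AnchorPair]]:
    """Highest-scoring monotone chain by dynamic programming.

    ``direction`` +1 seeks rank_b ascending, -1 descending. Gaps between
    consecutive anchors must be <= max_gap on both sides. Ties break
    toward the chain with smaller total gap, then lexicographic gene ids.
    Returns (score, chain in rank_a order); empty input gives (0, []).
    """
    if not anchors:
        return 0.0, []
    order = sorted(range(len(anchors)),
                   key=lambda i: (anchors[i].rank_a, anchors[i].rank_b))
    a = [anchors[i] for i in order]
    n = len(a)
    # (score, -total_gap, ids) per chain end, maximized lexicographically
    best_score = [ai.score for ai in a]
    total_gap = [0] * n
    prev = [-1] * n
    for j in range(n):
        for i in range(j):
            g = _gap(a[i], a[j], direction)
            if g is None or g > max_gap:
                continue
            cand = best_score[i] + a[j].score - gap_penalty * g
            cand_gap = total_gap[i] + g
            cur = (best_score[j], -total_gap[j])
            if (cand, -cand_gap) > cur or (
                    (cand, -cand_gap) == cur and prev[j] >= 0
                    and a[i].gene_a < a[prev[j]].gene_a):
                best_score[j] = cand
                total_gap[j] = cand_gap
                prev[j] = i
    end = max(range(n),
              key=lambda j: (best_score[j], -total_gap[j], a[j].gene_a))
    chain = []
    j = end
    while j >= 0:
        chain.append(a[j])
        j = prev[j]
    chain.reverse()
    return best_score[end], chain


def chain_collinear_blocks(anchors: Sequence[AnchorPair],
                           min_block_genes: int = 11,
                           max_gap: int = 4,
                           gap_penalty: float = 1.0) -> list[CollinearBlock]:
    """All collinear blocks of >= min_block_genes anchors.

    Anchors are grouped by chromosome pair; within each group the best
    ascending or descending chain is extracted greedily, its anchors
    removed, and the search repeated until no qualifying chain remains.
    """
    groups: dict[tuple[str, str], list[AnchorPair]] = {}
    for anc in anchors:
        groups.setdefault((anc.chrom_a, anc.chrom_b), []).append(anc)
    blocks: list[CollinearBlock] = []
    for key in sorted(groups):
        pool = groups[key]
        while True:
            s_up, c_up = best_chain(pool, max_gap, gap_penalty, +1)
            s_dn, c_dn = best_chain(pool, max_gap, gap_penalty, -1)
            candidates = [(s, c, o) for s, c, o in
                          ((s_up, c_up, "same"), (s_dn, c_dn, "inverted"))
                          if len(c) >= min_block_genes]
            if not candidates:
                break
            score, chain, orient = max(candidates, key=lambda t: t[0])
            blocks.append(CollinearBlock(tuple(chain), orient))
            used = {(x.gene_a, x.gene_b) for x in chain}
            pool = [x for x in pool if (x.gene_a, x.gene_b) not in used]
    blocks.sort(key=lambda b: (b.chrom_a, b.chrom_b,
                               b.anchors[0].rank_a))
    return blocks


def classify_duplications(blocks: Sequence[CollinearBlock],
                          tandem_genes: set[str]) -> dict[tuple[str, str], str]:
    """Class per duplicated anchor pair from a self-comparison.

    Trivial self-diagonal pairs (gene paired with itself) are dropped.
    A pair on one chromosome is "tandem" when both genes are known tandem
    duplicates, otherwise "segmental"; pairs across chromosomes are
    "interchromosomal".
    """
    out: dict[tuple[str, str], str] = {}
    for b in blocks:
        for anc in b.anchors:
            if anc.gene_a == anc.gene_b:
                continue
            key = tuple(sorted((anc.gene_a, anc.gene_b)))
            if anc.chrom_a != anc.chrom_b:
                out[key] = "interchromosomal"
            elif anc.gene_a in tandem_genes and anc.gene_b in tandem_genes:
                out[key] = "tandem"
            else:
                out[key] = "segmental"
    return out


def ks_distribution(ks_values: Iterable[float], bin_width: float = 0.05,
                    ks_max: float = 3.0,
                    bandwidth: float | None = None) -> dict:
    """Histogram plus kernel-density modes of a Ks sample.

    Saturated (NaN) estimates and values outside (0, ks_max] are
    excluded. Modes are local maxima of a Gaussian KDE (Silverman
    bandwidth unless given), each reported with the share of observations
    nearest to it.
    """
    vals = np.asarray([k for k in ks_values if np.isfinite(k)], dtype=float)
    vals = vals[(vals > 0) & (vals <= ks_max)]
    edges = np.arange(0.0, ks_max + bin_width, bin_width)
    counts, _ = np.histogram(vals, bins=edges)
    result = {"bin_edges": edges, "counts": counts, "n": int(vals.size),
              "modes": [], "mode_masses": []}
    if vals.size < 2 or np.ptp(vals) == 0:
        if vals.size:
            result["modes"] = [float(vals[0])]
            result["mode_masses"] = [1.0]
        return result
    kde = _st.gaussian_kde(vals, bw_method=bandwidth)
    grid = np.linspace(0.0, ks_max, 1024)
    dens = kde(grid)
    interior = np.where((dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:]))[0] + 1
    modes = grid[interior]
    if modes.size:
        assign = np.argmin(np.abs(vals[:, None] - modes[None, :]), axis=1)
        masses = np.bincount(assign, minlength=modes.size) / vals.size
        order = np.argsort(-masses)
        result["modes"] = [float(m) for m in modes[order]]
        result["mode_masses"] = [float(m) for m in masses[order]]
    return result


@dataclass(frozen=True)
class PaintedBlock:
    """A stretch of a modern chromosome assigned to one ancestral group."""

    span: tuple[int, int]      # gene-rank span on the modern chromosome
    ancestral_label: str
    n_genes: int


def count_fusions(painting: Mapping[str, Sequence[PaintedBlock]],
                  min_block_genes: int = 1) -> int:
    """Minimal fusion count implied by an ancestral-karyotype painting.

    Blocks smaller than ``min_block_genes`` are discarded; each modern
    chromosome then contributes (number of distinct ancestral labels - 1)
    fusions, zero if no blocks survive.
    """
    total = 0
    for chrom, blocks in painting.items():
        labels = {b.ancestral_label for b in blocks
                  if b.n_genes >= min_block_genes}
        if not labels:
            log.warning("chromosome %s has no surviving painted blocks", chrom)
            continue
        total += len(labels) - 1
    return total
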