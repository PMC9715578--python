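"""Tandem-duplicate array detection and lineage-bias testing.

A tandem array is a maximal single-linkage cluster of mutually homologous
genes lying (nearly) consecutively on one chromosome: a gene joins an
array when it is homologous to at least one current member and lies within
``max_intervening`` non-member genes of the nearest member (0 means
strictly consecutive, the MCScanX convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import logging

import numpy as np
from scipy import stats

from .io import GenomeAnnotation, HomologyHit

log = logging.getLogger("camgen")


@dataclass(frozen=True)
class TandemArray:
    chromosome_id: str
    gene_ids: tuple[str, ...]   # in rank order
    rank_span: tuple[int, int]  # first, last rank (inclusive)

    def __post_init__(self) -> None:
        if len(self.gene_ids) < 2:
            raise ValueError("an array needs >= 2 members")


def _symmetric_pairs(homology: Iterable[HomologyHit]) -> set[frozenset]:
    pairs = set()
    for h in homology:
        if h.query_id != h.subject_id:
            pairs.add(frozenset((h.query_id, h.subject_id)))
    return pairs


def find_tandem_arrays(annotation: GenomeAnnotation,
                       homology: Iterable[HomologyHit],
                       max_intervening: int = 0) -> list[TandemArray]:
    """Maximal tandem arrays from gene order plus pairwise homology.

    Homology is symmetrized internally and self-hits are ignored; pairs
    naming genes absent from the annotation are skipped with a warning.
    Single-linkage growth within a chromosome; arrays are reported in
    chromosomal order and are disjoint in membership.
    """
    pairs = set()
    for pair in _symmetric_pairs(homology):
        a, b = tuple(pair)
        if a not in annotation or b not in annotation:
            log.warning("homology pair %s-%s references unknown gene, skipped",
                        a, b)
            continue
        pairs.add(pair)

    arrays: list[TandemArray] = []
    for chrom in annotation.chromosomes():
        genes = annotation.genes_on(chrom)  # already rank-ordered
        # union-find over genes on this chromosome, linking homologous
        # genes within the rank window
        parent = list(range(len(genes)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        window = max_intervening + 1
        for i in range(len(genes)):
            for j in range(i + 1, min(len(genes), i + window + 1)):
                if frozenset((genes[i].gene_id, genes[j].gene_id)) in pairs:
                    parent[find(i)] = find(j)
        clusters: dict[int, list[int]] = {}
        for i in range(len(genes)):
            clusters.setdefault(find(i), []).append(i)
        for members in clusters.values():
            if len(members) < 2:
                continue
            members.sort()
            arrays.append(TandemArray(
                chrom, tuple(genes[i].gene_id for i in members),
                (genes[members[0]].rank, genes[members[-1]].rank)))
    arrays.sort(key=lambda a: (a.chromosome_id, a.rank_span[0]))
    return arrays


def td_genes(arrays: Sequence[TandemArray]) -> set[str]:
    out: set[str] = set()
    for a in arrays:
        out.update(a.gene_ids)
    return out


def classify_td_lineage(arrays_by_species: Mapping[str, Sequence[TandemArray]],
                        orthogroup_of: Mapping[str, str]
                        ) -> tuple[set[str], dict[str, set[str]]]:
    """Split TD genes into shared vs species-specific sets.

    A TD gene is *shared* iff its orthogroup contains TD genes in at least
    two species; otherwise it is specific to its own species. A TD gene
    with no orthogroup assignment is species-specific (with a warning).
    Returns ``(shared_genes, {species: specific_genes})``.
    """
    og_species: dict[str, set[str]] = {}
    gene_sp: dict[str, str] = {}
    for sp, arrays in arrays_by_species.items():
        for g in td_genes(arrays):
            gene_sp[g] = sp
            og = orthogroup_of.get(g)
            if og is not None:
                og_species.setdefault(og, set()).add(sp)

    shared: set[str] = set()
    specific: dict[str, set[str]] = {sp: set() for sp in arrays_by_species}
    for g, sp in gene_sp.items():
        og = orthogroup_of.get(g)
        if og is None:
            log.warning("TD gene %s has no orthogroup; counted species-specific", g)
            specific[sp].add(g)
        elif len(og_species[og]) >= 2:
            shared.add(g)
        else:
            specific[sp].add(g)
    return shared, specific


def td_bias_test(percent_by_species: Mapping[str, float],
                 group_a: Sequence[str],
                 group_b: Sequence[str]) -> tuple[float, float]:
    """Welch two-sample t-test on per-species category percentages.

    ``percent_by_species`` maps species id to the percentage of its
    lineage-specific TD genes in one functional category. Returns
    ``(t, p)``; zero variance in both groups yields ``(nan, nan)``.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 species")
    xa = np.array([percent_by_species[s] for s in group_a], dtype=float)
    xb = np.array([percent_by_species[s] for s in group_b], dtype=float)
    if not (0 <= xa.min() and xa.max() <= 100 and
            0 <= xb.min() and xb.max() <= 100):
        raise ValueError("percentages must lie in [0, 100]")
    if xa.std() == 0 and xb.std() == 0:
        log.warning("zero variance in both groups; t-test undefined")
        return float("nan"), float("nan")
    t, p = stats.ttest_ind(xa, xb, equal_var=False)
    return float(t), float(p)
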