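"""Synthetic-data generators with planted, recorded ground truth.

Every downstream stage of the pipeline can be exercised end-to-end on
data from this module: an 18-species orthogroup count matrix with a
planted succulent-specific expansion signal, toy genome layouts with
planted tandem arrays and collinear blocks, codon pairs at controlled
synonymous/nonsynonymous divergence, replicated diel expression profiles
with planted circadian phases, and promoters with planted cis-element
instances. Each generator is a pure function of its spec and seed, and
returns a truth record sufficient to score sensitivity and FDR.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix, GeneCountMatrix, GeneLocus, GenomeAnnotation, \
    HomologyHit
from .kaks import translate_codon, _STOPS, _BASES
from .ltr import LtrPair

_GENE_LEN = 1000
_GENE_SPACING = 2500


def _truth(kind: str, spec, **payload) -> dict:
    rec = {"kind": kind, "spec": dataclasses.asdict(spec) if
           dataclasses.is_dataclass(spec) else dict(spec)}
    rec.update(payload)
    return rec


def write_truth(path, truth: dict) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, default=list)


# ---------------------------------------------------------------------------
# orthogroup count matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpansionSimSpec:
    """Two-group count matrix with a planted group-A expansion signal.

    Background counts are Poisson(lam) in every species; planted
    orthogroups draw their group-A counts at mean lam * fold_effect.
    Defaults mirror an 18-genome comparison of 5 succulents vs 13 others.
    """

    n_orthogroups: int = 2000
    n_species_group_a: int = 5
    n_species_group_b: int = 13
    lam: float = 2.0
    planted_fraction: float = 0.05
    fold_effect: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if self.fold_effect < 1:
            raise ValueError("fold_effect must be >= 1")
        if not 0 <= self.planted_fraction <= 1:
            raise ValueError("planted_fraction in [0, 1]")


def gen_count_matrix(spec: ExpansionSimSpec) -> tuple[GeneCountMatrix, dict]:
    rng = np.random.default_rng(spec.seed)
    na, nb = spec.n_species_group_a, spec.n_species_group_b
    n = spec.n_orthogroups
    species = [f"succ{i+1}" for i in range(na)] + \
              [f"other{i+1}" for i in range(nb)]
    counts = rng.poisson(spec.lam, size=(n, na + nb))
    n_planted = int(round(spec.planted_fraction * n))
    planted_idx = rng.choice(n, size=n_planted, replace=False)
    planted_idx.sort()
    if n_planted and spec.fold_effect > 1:
        counts[planted_idx, :na] = rng.poisson(
            spec.lam * spec.fold_effect, size=(n_planted, na))
    og_ids = [f"OG{i:06d}" for i in range(n)]
    matrix = GeneCountMatrix(og_ids, species, counts)
    truth = _truth("expansion", spec,
                   planted=[og_ids[i] for i in planted_idx],
                   group_a=species[:na], group_b=species[na:])
    return matrix, truth


# ---------------------------------------------------------------------------
# genome layouts: tandem arrays and collinear blocks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSimSpec:
    n_chromosomes: int = 3
    genes_per_chromosome: int = 100
    n_tandem_arrays: int = 4
    array_size_range: tuple[int, int] = (2, 4)
    max_intervening: int = 0
    n_collinear_blocks: int = 2
    block_length_range: tuple[int, int] = (12, 15)
    inversion_probability: float = 0.3
    hit_noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_chromosomes, self.genes_per_chromosome) < 1:
            raise ValueError("counts must be positive")
        if self.array_size_range[0] < 2:
            raise ValueError("array sizes must be >= 2")


def _toy_annotation(prefix: str, n_chrom: int, n_genes: int) -> GenomeAnnotation:
    loci = []
    for c in range(1, n_chrom + 1):
        for i in range(n_genes):
            start = i * _GENE_SPACING
            loci.append(GeneLocus(f"{prefix}_c{c}_{i:04d}", f"{prefix}_chr{c}",
                                  start, start + _GENE_LEN, "+"))
    return GenomeAnnotation(loci)


def _hit(q: str, s: str, rng) -> HomologyHit:
    return HomologyHit(q, s, 95.0, 300, 1e-50,
                       float(200 + int(rng.integers(0, 50))))


def gen_genome_layout(spec: GenomeSimSpec) -> dict:
    """Two toy genomes with planted tandem arrays and collinear blocks.

    Returns a dict with ``annot_a``/``annot_b`` (gene orders), ``self_hits``
    (within-genome homology covering exactly the planted tandem arrays),
    ``cross_hits`` (between-genome anchors covering the planted blocks,
    plus optional random noise pairs), and ``truth``.
    """
    rng = np.random.default_rng(spec.seed)
    annot_a = _toy_annotation("gA", spec.n_chromosomes,
                              spec.genes_per_chromosome)
    annot_b = _toy_annotation("gB", spec.n_chromosomes,
                              spec.genes_per_chromosome)

    # place tandem arrays on genome A without overlap
    lo, hi = spec.array_size_range
    arrays: list[list[str]] = []
    used_a: dict[int, set[int]] = {c: set() for c in range(spec.n_chromosomes)}
    capacity = spec.n_chromosomes * spec.genes_per_chromosome
    need = spec.n_tandem_arrays * (hi * (spec.max_intervening + 1) + 2)
    if need > capacity:
        raise ValueError("requested tandem arrays exceed chromosome capacity")
    self_hits: list[HomologyHit] = []
    for _ in range(spec.n_tandem_arrays):
        size = int(rng.integers(lo, hi + 1))
        for _try in range(200):
            c = int(rng.integers(spec.n_chromosomes))
            gaps = rng.integers(0, spec.max_intervening + 1,
                                size=size - 1) if size > 1 else []
            span = size + int(np.sum(gaps))
            start = int(rng.integers(0, spec.genes_per_chromosome - span + 1))
            ranks = [start]
            for g in gaps:
                ranks.append(ranks[-1] + 1 + int(g))
            # keep one rank of margin so planted arrays stay maximal/separate
            occupied = set(range(start - 1, ranks[-1] + 2))
            if occupied & used_a[c]:
                continue
            used_a[c].update(occupied)
            members = [f"gA_c{c+1}_{r:04d}" for r in ranks]
            arrays.append(members)
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    self_hits.append(_hit(members[i], members[j], rng))
            break
        else:
            raise ValueError("could not place tandem array; reduce request")

    # place collinear blocks between genome A and genome B
    blo, bhi = spec.block_length_range
    blocks = []
    used_b: dict[int, set[int]] = {c: set() for c in range(spec.n_chromosomes)}
    cross_hits: list[HomologyHit] = []
    for _ in range(spec.n_collinear_blocks):
        length = int(rng.integers(blo, bhi + 1))
        for _try in range(200):
            ca = int(rng.integers(spec.n_chromosomes))
            cb = int(rng.integers(spec.n_chromosomes))
            sa = int(rng.integers(0, spec.genes_per_chromosome - length + 1))
            sb = int(rng.integers(0, spec.genes_per_chromosome - length + 1))
            ra = set(range(sa, sa + length))
            rb = set(range(sb, sb + length))
            if ra & used_a[ca] or rb & used_b[cb]:
                continue
            used_a[ca].update(ra)
            used_b[cb].update(rb)
            inverted = bool(rng.random() < spec.inversion_probability)
            b_ranks = range(sb + length - 1, sb - 1, -1) if inverted \
                else range(sb, sb + length)
            pairs = []
            for i, rb_i in zip(range(sa, sa + length), b_ranks):
                ga = f"gA_c{ca+1}_{i:04d}"
                gb = f"gB_c{cb+1}_{rb_i:04d}"
                pairs.append((ga, gb))
                cross_hits.append(_hit(ga, gb, rng))
            blocks.append({"pairs": pairs,
                           "orientation": "inverted" if inverted else "same"})
            break
        else:
            raise ValueError("could not place collinear block; reduce request")

    n_noise = int(round(spec.hit_noise_rate * len(cross_hits)))
    for _ in range(n_noise):
        ca = int(rng.integers(spec.n_chromosomes))
        cb = int(rng.integers(spec.n_chromosomes))
        ia = int(rng.integers(spec.genes_per_chromosome))
        ib = int(rng.integers(spec.genes_per_chromosome))
        cross_hits.append(_hit(f"gA_c{ca+1}_{ia:04d}",
                               f"gB_c{cb+1}_{ib:04d}", rng))

    truth = _truth("genome_layout", spec, tandem_arrays=arrays, blocks=blocks)
    return {"annot_a": annot_a, "annot_b": annot_b,
            "self_hits": self_hits, "cross_hits": cross_hits, "truth": truth}


# ---------------------------------------------------------------------------
# codon pairs at controlled divergence
# ---------------------------------------------------------------------------

_SENSE_CODONS = sorted("".join(t) for t in itertools.product(_BASES, repeat=3)
                       if "".join(t) not in _STOPS)


def _single_base_changes(codon: str):
    for pos in range(3):
        for base in _BASES:
            if base != codon[pos]:
                alt = codon[:pos] + base + codon[pos + 1:]
                if alt not in _STOPS:
                    yield alt


def gen_codon_pairs(n_pairs: int, n_codons: int, syn_subs: int,
                    nonsyn_subs: int, seed: int = 0) -> tuple[list, dict]:
    """Codon-aligned pairs with exact planted substitution counts.

    Each pair starts from a random stop-free CDS; exactly ``syn_subs``
    synonymous and ``nonsyn_subs`` nonsynonymous single-base changes are
    applied to the copy, at most one change per codon, never creating a
    stop. Returns ``(pairs, truth)`` where pairs are (seq_a, seq_b)
    tuples.
    """
    if syn_subs + nonsyn_subs > n_codons:
        raise ValueError("more substitutions requested than codons")
    rng = np.random.default_rng(seed)
    pairs = []
    records = []
    for _ in range(n_pairs):
        codons = [ _SENSE_CODONS[i]
                   for i in rng.integers(len(_SENSE_CODONS), size=n_codons)]
        target_idx = rng.choice(n_codons, size=syn_subs + nonsyn_subs,
                                replace=False)
        syn_idx, nonsyn_idx = target_idx[:syn_subs], target_idx[syn_subs:]
        mutated = list(codons)
        for i in syn_idx:
            for _try in range(500):
                opts = [c for c in _single_base_changes(codons[i])
                        if translate_codon(c) == translate_codon(codons[i])]
                if opts:
                    mutated[i] = opts[int(rng.integers(len(opts)))]
                    break
                codons[i] = _SENSE_CODONS[int(rng.integers(len(_SENSE_CODONS)))]
                mutated[i] = codons[i]
            else:
                raise ValueError("could not place synonymous change")
        for i in nonsyn_idx:
            for _try in range(500):
                opts = [c for c in _single_base_changes(codons[i])
                        if translate_codon(c) != translate_codon(codons[i])]
                if opts:
                    mutated[i] = opts[int(rng.integers(len(opts)))]
                    break
                codons[i] = _SENSE_CODONS[int(rng.integers(len(_SENSE_CODONS)))]
                mutated[i] = codons[i]
            else:
                raise ValueError("could not place nonsynonymous change")
        seq_a, seq_b = "".join(codons), "".join(mutated)
        pairs.append((seq_a, seq_b))
        records.append({"syn_codons": [int(i) for i in syn_idx],
                        "nonsyn_codons": [int(i) for i in nonsyn_idx]})
    truth = _truth("codon_pairs", {"n_pairs": n_pairs, "n_codons": n_codons,
                                   "syn_subs": syn_subs,
                                   "nonsyn_subs": nonsyn_subs, "seed": seed},
                   pairs=records)
    return pairs, truth


# ---------------------------------------------------------------------------
# diel expression profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DielSimSpec:
    """Replicated 24-h time courses with a planted rhythmic fraction.

    Timepoints are hours elapsed from the first sampling (clock 18:00),
    3-h steps with the start repeated after one full cycle. Rhythmic
    genes follow FPKM = exp(b + a cos(2 pi (t - phase)/24) + eps) with
    lognormal noise; flat genes have a = 0.
    """

    n_genes: int = 1000
    timepoints: tuple[float, ...] = (0, 3, 6, 9, 12, 15, 18, 21, 24)
    replicates: int = 3
    rhythmic_fraction: float = 0.3
    amplitude: float = 1.0
    phase_set: tuple[float, ...] = (0.0, 6.0, 12.0, 18.0)
    noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates")
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitude and noise_sd must be >= 0")


def gen_diel_profiles(spec: DielSimSpec) -> tuple[ExpressionMatrix, dict]:
    rng = np.random.default_rng(spec.seed)
    n, nt, nr = spec.n_genes, len(spec.timepoints), spec.replicates
    genes = [f"cam{i:05d}" for i in range(n)]
    n_rhythmic = int(round(spec.rhythmic_fraction * n))
    rhythmic = np.zeros(n, dtype=bool)
    idx = rng.choice(n, size=n_rhythmic, replace=False)
    rhythmic[idx] = True
    phases = np.full(n, np.nan)
    phases[rhythmic] = rng.choice(spec.phase_set, size=n_rhythmic)
    baseline = rng.uniform(1.0, 3.0, size=n)
    t = np.asarray(spec.timepoints, dtype=float)
    mean_log = np.tile(baseline[:, None], (1, nt))
    mean_log[rhythmic] += spec.amplitude * np.cos(
        2 * np.pi * (t[None, :] - phases[rhythmic, None]) / 24.0)
    eps = rng.normal(0.0, spec.noise_sd, size=(n, nt, nr)) \
        if spec.noise_sd > 0 else np.zeros((n, nt, nr))
    fpkm = np.exp(mean_log[:, :, None] + eps)
    matrix = ExpressionMatrix(genes, list(t), nr, fpkm.reshape(n, nt * nr))
    truth = _truth("diel", spec,
                   rhythmic=[g for g, r in zip(genes, rhythmic) if r],
                   phases={g: float(p) for g, p, r in
                           zip(genes, phases, rhythmic) if r})
    return matrix, truth


# ---------------------------------------------------------------------------
# promoters with planted motifs
# ---------------------------------------------------------------------------

def gen_promoters(n_genes: int, length: int, motif: str,
                  planted_rate: float, seed: int = 0,
                  n_per_promoter: int = 1) -> tuple[dict, dict]:
    """Uniform-background promoters with planted motif instances.

    Each promoter independently receives ``n_per_promoter`` non-
    overlapping planted copies of ``motif`` with probability
    ``planted_rate``; insertion positions are recorded in the truth.
    """
    m = len(motif)
    if length < m:
        raise ValueError("promoter shorter than motif")
    if n_per_promoter * m > length:
        raise ValueError("requested insertions exceed promoter capacity")
    rng = np.random.default_rng(seed)
    promoters: dict[str, str] = {}
    planted: dict[str, list[int]] = {}
    for i in range(n_genes):
        seq = rng.integers(0, 4, size=length)
        seq = "".join("ACGT"[b] for b in seq)
        gene = f"prom{i:05d}"
        positions: list[int] = []
        if rng.random() < planted_rate:
            for _ in range(n_per_promoter):
                for _try in range(200):
                    p = int(rng.integers(0, length - m + 1))
                    if all(abs(p - q) >= m for q in positions):
                        positions.append(p)
                        seq = seq[:p] + motif + seq[p + m:]
                        break
                else:
                    raise ValueError("could not place motif without overlap")
        promoters[gene] = seq
        planted[gene] = sorted(positions)
    truth = _truth("promoters", {"n_genes": n_genes, "length": length,
                                 "motif": motif, "planted_rate": planted_rate,
                                 "seed": seed,
                                 "n_per_promoter": n_per_promoter},
                   planted_positions=planted)
    return promoters, truth


# ---------------------------------------------------------------------------
# LTR pairs at known insertion age
# ---------------------------------------------------------------------------

def gen_ltr_pairs(n_elements: int, ltr_length: int, mean_age_years: float,
                  age_sd_years: float, mu: float, seed: int = 0
                  ) -> tuple[list[LtrPair], dict]:
    """LTR 5'/3' pairs diverged to a planted age distribution.

    Ages are drawn N(mean, sd) truncated at 0; each site of the 3' LTR
    mutates with probability p(T) = (3/4)(1 - exp(-8 mu T / 3)), the
    JC69 expectation, so the estimator's JC correction is unbiased.
    """
    rng = np.random.default_rng(seed)
    pairs = []
    ages = []
    for i in range(n_elements):
        age = max(0.0, float(rng.normal(mean_age_years, age_sd_years)))
        p_expect = 0.75 * (1.0 - np.exp(-8.0 * mu * age / 3.0))
        seq5 = "".join("ACGT"[b] for b in rng.integers(0, 4, size=ltr_length))
        seq3 = list(seq5)
        for j in range(ltr_length):
            if rng.random() < p_expect:
                seq3[j] = "ACGT"[(("ACGT".index(seq3[j])) +
                                  int(rng.integers(1, 4))) % 4]
        pairs.append(LtrPair(f"LTR{i:05d}", seq5, "".join(seq3)))
        ages.append(age)
    truth = _truth("ltr", {"n_elements": n_elements, "ltr_length": ltr_length,
                           "mean_age_years": mean_age_years,
                           "age_sd_years": age_sd_years, "mu": mu,
                           "seed": seed},
                   ages=ages)
    return pairs, truth
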