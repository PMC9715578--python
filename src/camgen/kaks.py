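"""Nei–Gojobori (NG86) Ka/Ks estimation on gap-free codon alignments.

Synonymous and nonsynonymous *sites* are counted per codon from the
standard genetic code: at each codon position the synonymous fraction is
the number of synonymous single-base changes divided by 3 (changes to
stop codons count as nonsynonymous), summed over positions and averaged
over the two sequences. *Differences* between codons differing at d
positions are resolved by enumerating all d! single-substitution
pathways; pathways crossing a stop codon are excluded and the remaining
pathways weighted equally. The proportions pS = Sd/S and pN = Nd/N are
corrected for multiple hits with the Jukes–Cantor formula
K = -(3/4)·ln(1 - (4/3)p), undefined (saturated) when p >= 3/4.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = frozenset(_TABLE.stop_codons)
_BASES = "ACGT"


def translate_codon(codon: str) -> str | None:
    """Amino acid for a sense codon, None for a stop."""
    return None if codon in _STOPS else _TABLE.forward_table[codon]


@dataclass(frozen=True)
class CodonAlignmentPair:
    """Equal-length, gap-free, stop-free paired coding sequences."""

    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        a, b = self.seq_a.upper(), self.seq_b.upper()
        object.__setattr__(self, "seq_a", a)
        object.__setattr__(self, "seq_b", b)
        if len(a) != len(b):
            raise ValueError("aligned sequences differ in length")
        if len(a) % 3 != 0:
            raise ValueError("alignment length not divisible by 3")
        for seq in (a, b):
            if set(seq) - set(_BASES):
                raise ValueError("sequences must be gap-free ACGT")
            for i in range(0, len(seq), 3):
                if seq[i:i + 3] in _STOPS:
                    raise ValueError(f"stop codon at position {i}")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3


@dataclass(frozen=True)
class KsEstimate:
    S: float
    N: float
    Sd: float
    Nd: float

    @property
    def pS(self) -> float:
        return self.Sd / self.S if self.S > 0 else 0.0

    @property
    def pN(self) -> float:
        return self.Nd / self.N if self.N > 0 else 0.0

    @property
    def saturated(self) -> bool:
        return self.pS >= 0.75 or self.pN >= 0.75

    @property
    def Ks(self) -> float:
        return jukes_cantor(self.pS)

    @property
    def Ka(self) -> float:
        return jukes_cantor(self.pN)

    @property
    def omega(self) -> float:
        ks = self.Ks
        return self.Ka / ks if np.isfinite(ks) and ks > 0 else float("nan")


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction K = -(3/4)·ln(1 - (4/3)p)."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return float("nan")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


@lru_cache(maxsize=None)
def codon_syn_sites(codon: str) -> float:
    """Synonymous site count of one sense codon (0..3).

    Each position contributes (#synonymous single-base changes)/3; a
    change producing a stop counts as nonsynonymous.
    """
    aa = translate_codon(codon)
    if aa is None:
        raise ValueError(f"stop codon {codon} has no site count")
    s = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if alt not in _STOPS and translate_codon(alt) == aa:
                s += 1.0 / 3.0
    return s


@lru_cache(maxsize=None)
def codon_pair_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons.

    Averaged over all minimal substitution pathways with equal weights;
    pathways passing through a stop codon are dropped and the weights
    renormalized (if every pathway crosses a stop, all are kept).
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(diff_pos):
        cur = codon_a
        sd = nd = 0.0
        crosses_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if nxt in _STOPS:
                crosses_stop = True
            if translate_codon(cur) == translate_codon(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        pathways.append((sd, nd, crosses_stop))
    valid = [(sd, nd) for sd, nd, x in pathways if not x]
    if not valid:  # degenerate: every route crosses a stop
        valid = [(sd, nd) for sd, nd, _ in pathways]
    sd = sum(v[0] for v in valid) / len(valid)
    nd = sum(v[1] for v in valid) / len(valid)
    return sd, nd


def ng86_ka_ks(pair: CodonAlignmentPair) -> KsEstimate:
    """NG86 site and difference counts plus JC-corrected Ka and Ks.

    Symmetric in the two sequences; S + N equals the alignment length in
    nucleotides exactly.
    """
    s_total = 0.0
    sd = nd = 0.0
    for i in range(0, len(pair.seq_a), 3):
        ca, cb = pair.seq_a[i:i + 3], pair.seq_b[i:i + 3]
        s_total += 0.5 * (codon_syn_sites(ca) + codon_syn_sites(cb))
        d_s, d_n = codon_pair_differences(ca, cb)
        sd += d_s
        nd += d_n
    n_total = 3.0 * pair.n_codons - s_total
    return KsEstimate(S=s_total, N=n_total, Sd=sd, Nd=nd)
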