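"""IUPAC consensus motif scanning and circadian cis-element enrichment.

The five circadian clock-associated elements shipped as defaults are the
morning element (CCACAC), the evening element (AAAATATCT), the
CCA1-binding site (AAAAATCT), the TCP15 element (NGGNCCCAC) and the
G-box (CACGTG). Scanning is exact degenerate-consensus matching (with an
optional per-window mismatch allowance); enrichment between gene groups
is a per-motif Fisher exact test on motif presence/absence with BH
adjustment across motifs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expansion import bh_adjust

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

DEFAULT_MOTIFS = (
    ("morning_element", "CCACAC"),
    ("evening_element", "AAAATATCT"),
    ("CCA1_binding_site", "AAAAATCT"),
    ("TCP15_element", "NGGNCCCAC"),
    ("G_box", "CACGTG"),
)


@dataclass(frozen=True)
class MotifDef:
    name: str
    pattern: str
    strand: str = "both"  # "both" | "forward"

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty motif pattern")
        bad = set(self.pattern.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"illegal IUPAC code(s): {sorted(bad)}")
        object.__setattr__(self, "pattern", self.pattern.upper())
        if self.strand not in ("both", "forward"):
            raise ValueError("strand must be 'both' or 'forward'")

    @property
    def reverse_complement(self) -> str:
        return self.pattern.translate(_COMPLEMENT)[::-1]

    @property
    def is_palindromic(self) -> bool:
        return self.pattern == self.reverse_complement


def _matches_at(seq: str, pattern: str, i: int, max_mismatch: int) -> bool:
    mm = 0
    for j, code in enumerate(pattern):
        if seq[i + j] not in IUPAC[code]:
            mm += 1
            if mm > max_mismatch:
                return False
    return True


def scan_motif(sequence: str, motif: MotifDef,
               max_mismatch: int = 0) -> list[int]:
    """All (possibly overlapping) match start positions, forward coordinates.

    With strand "both", matches of the reverse complement on the forward
    sequence are included; palindromic patterns are counted once per
    position.
    """
    seq = sequence.upper()
    m = len(motif.pattern)
    patterns = [motif.pattern]
    if motif.strand == "both" and not motif.is_palindromic:
        patterns.append(motif.reverse_complement)
    hits: set[int] = set()
    for pat in patterns:
        if max_mismatch == 0 and all(len(IUPAC[c]) == 1 for c in pat):
            i = seq.find(pat)
            while i != -1:
                hits.add(i)
                i = seq.find(pat, i + 1)
            continue
        for i in range(len(seq) - m + 1):
            if _matches_at(seq, pat, i, max_mismatch):
                hits.add(i)
    return sorted(hits)


def promoter_motif_table(promoters: Mapping[str, str],
                         motifs: Sequence[MotifDef],
                         max_mismatch: int = 0
                         ) -> tuple[pd.DataFrame, dict]:
    """Gene x motif occurrence-count table plus per-cell match positions.

    Genes with zero occurrences are included; counts equal the number of
    recorded positions.
    """
    counts = pd.DataFrame(0, index=pd.Index(promoters.keys(), name="gene"),
                          columns=[m.name for m in motifs], dtype=int)
    positions: dict[tuple[str, str], list[int]] = {}
    for gene, seq in promoters.items():
        for m in motifs:
            pos = scan_motif(seq, m, max_mismatch)
            counts.loc[gene, m.name] = len(pos)
            positions[(gene, m.name)] = pos
    return counts, positions


def motif_enrichment(table: pd.DataFrame,
                     group_labels: Mapping[str, str]) -> pd.DataFrame:
    """Per-motif Fisher exact test of presence between two gene groups.

    ``group_labels`` maps every gene in the table to one of exactly two
    group names. For each motif a 2x2 table of (genes with >= 1
    occurrence vs without) x group is tested (two-sided); BH adjustment
    across motifs. Returns odds ratio, p, q per motif; an empty group is
    a hard error.
    """
    labels = pd.Series({g: group_labels[g] for g in table.index})
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    g1, g2 = groups
    n1, n2 = (labels == g1).sum(), (labels == g2).sum()
    if n1 == 0 or n2 == 0:
        raise ValueError("a group has zero genes")
    rows = []
    for motif in table.columns:
        present = table[motif] >= 1
        a = int((present & (labels == g1)).sum())
        b = n1 - a
        c = int((present & (labels == g2)).sum())
        d = n2 - c
        odds, p = stats.fisher_exact([[a, b], [c, d]])
        rows.append({"motif": motif, "group1": g1, "group2": g2,
                     "present_g1": a, "absent_g1": b,
                     "present_g2": c, "absent_g2": d,
                     "odds_ratio": float(odds), "p": float(p)})
    out = pd.DataFrame(rows).set_index("motif")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def extract_promoters(chromosomes: Mapping[str, str], annotation,
                      length: int = 2000) -> dict[str, str]:
    """Slice the upstream promoter of every gene, strand-aware.

    For a + gene the ``length`` bases before its start are returned; for
    a - gene the bases after its end, reverse-complemented. Truncated at
    chromosome edges.
    """
    out: dict[str, str] = {}
    for locus in annotation:
        chrom = chromosomes.get(locus.chromosome_id)
        if chrom is None:
            continue
        if locus.strand == "+":
            seq = chrom[max(0, locus.start - length):locus.start]
        else:
            seq = chrom[locus.end:locus.end + length]
            seq = seq.translate(_COMPLEMENT)[::-1]
        out[locus.gene_id] = seq.upper()
    return out


def read_motif_file(path) -> list[MotifDef]:
    """Read ``name<TAB>pattern[<TAB>strand]`` lines into motif definitions."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"bad motif line: {line!r}")
            strand = parts[2] if len(parts) > 2 else "both"
            out.append(MotifDef(parts[0], parts[1], strand))
    return out
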