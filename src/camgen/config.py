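"""Run configuration: every tunable threshold of the pipeline plus the seed.

A config can be loaded from a flat ``key = value`` text file; unknown keys
are an error so typos never silently fall back to defaults. Every output
the pipeline writes embeds the config and seed so runs are reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field


@dataclass
class RunConfig:
    seed: int = 0

    # expansion testing
    expansion_alpha: float = 0.05
    min_contrib_a: int = 3
    min_contrib_b: int = 7

    # homology-hit filter (strict inequalities)
    min_align_len: float = 100.0
    max_evalue: float = 1e-5

    # tandem arrays
    max_intervening: int = 0

    # collinear-block chaining
    min_block_genes: int = 11      # "blocks of >10 genes"
    max_gap: int = 4               # "gaps of <5 genes"
    min_block_genes_self: int = 5  # self-comparison segmental duplications
    gap_penalty: float = 1.0

    # Ks summarization
    ks_max: float = 3.0
    ks_bin_width: float = 0.05
    kde_bandwidth: float | None = None  # None => Silverman

    # LTR dating: substitutions/site/year; no default is assumed silently
    mu: float | None = None
    ltr_bin_width_years: float = 1e4

    # diel analysis
    min_mean_fpkm: float = 1.0
    rhythm_degree: int = 3
    rhythm_alpha: float = 0.05
    n_clusters: int = 9
    cluster_linkage: str = "average"
    corr_t_low: float = 0.5
    corr_t_high: float = 0.8
    corr_rule: str = "both"  # "both" coefficients, or "pearson"

    # motif scanning/enrichment
    motif_strand: str = "both"  # or "forward"
    motif_mismatches: int = 0

    _RANGES = {
        "expansion_alpha": (0.0, 1.0), "rhythm_alpha": (0.0, 1.0),
        "corr_t_low": (-1.0, 1.0), "corr_t_high": (-1.0, 1.0),
    }

    def __post_init__(self) -> None:
        for key, (lo, hi) in self._RANGES.items():
            v = getattr(self, key)
            if not lo < v < hi:
                raise ValueError(f"{key}={v} outside ({lo}, {hi})")
        for key in ("min_contrib_a", "min_contrib_b", "max_intervening",
                    "min_block_genes", "max_gap", "min_block_genes_self",
                    "n_clusters", "rhythm_degree", "motif_mismatches"):
            if getattr(self, key) < 0:
                raise ValueError(f"{key} must be non-negative")
        if self.corr_rule not in ("both", "pearson"):
            raise ValueError("corr_rule must be 'both' or 'pearson'")
        if self.motif_strand not in ("both", "forward"):
            raise ValueError("motif_strand must be 'both' or 'forward'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def header(self) -> str:
        """One-line JSON block embedded in output file headers."""
        return "camgen-config " + json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key = value")
                key, raw = (s.strip() for s in line.split("=", 1))
                if key not in fields:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                kwargs[key] = _coerce(raw, fields[key].type)
        return cls(**kwargs)


def _coerce(raw: str, annotation) -> object:
    ann = str(annotation)
    if raw.lower() in ("none", "null"):
        return None
    if "int" in ann and "float" not in ann:
        return int(raw)
    if "float" in ann:
        return float(raw)
    return raw
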