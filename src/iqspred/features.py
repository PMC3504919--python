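"""Per-SNP predictors of imputation quality.

Twelve features describe each imputed SNP, in this fixed order:

 1. chrom_code              chromosome as a numeric code 1-22
 2. pos_bp                  physical position, 1-based bp
 3. platform_maf            minor allele frequency from the platform annotation
 4. mean_baf                mean B-allele frequency in an ethnic-matched sample
                            (genotype-derived: mean b_count/2)
 5. panel_maf               minor allele frequency in the reference panel
 6. ratio_aa_ab             reference-panel genotype count ratio AA/AB
 7. ratio_bb_ab             reference-panel genotype count ratio BB/AB
 8. dist_nearest_typed_bp   distance to the nearest genotyped (typed) SNP
 9. dist_nearest_hotspot_bp distance to the nearest recombination hotspot
10. hotspot_rate_cM_per_Mb  that hotspot's recombination rate
11. mean_posterior          mean over individuals of the best-guess posterior
12. mean_b_dosage           mean B-allele dosage, 0*P(AA)+1*P(AB)+2*P(BB)

The order and length are frozen: fitted regression models are only reusable
against feature matrices built with the same layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .iqs import MISSING, normalize_posteriors

__all__ = [
    "FEATURE_NAMES",
    "SnpRecord",
    "HotspotMap",
    "ReferencePanelStats",
    "panel_ratios",
    "nearest_typed_distance",
    "nearest_hotspot",
    "mean_posterior",
    "mean_b_dosage",
    "mean_baf",
    "assemble_features",
]

FEATURE_NAMES: Tuple[str, ...] = (
    "chrom_code",
    "pos_bp",
    "platform_maf",
    "mean_baf",
    "panel_maf",
    "ratio_aa_ab",
    "ratio_bb_ab",
    "dist_nearest_typed_bp",
    "dist_nearest_hotspot_bp",
    "hotspot_rate_cM_per_Mb",
    "mean_posterior",
    "mean_b_dosage",
)

N_FEATURES = len(FEATURE_NAMES)


@dataclass(frozen=True)
class SnpRecord:
    """Platform annotation for one SNP."""

    snp_id: str
    chrom: int
    pos: int
    platform_maf: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: position must be >= 1")
        if not 0.0 <= self.platform_maf <= 0.5:
            raise ValueError(f"{self.snp_id}: MAF must be in [0, 0.5]")


@dataclass
class HotspotMap:
    """Recombination hotspots per chromosome: sorted (pos_bp, rate_cM_per_Mb)."""

    by_chrom: Dict[int, List[Tuple[int, float]]] = field(default_factory=dict)

    def add(self, chrom: int, pos: int, rate: float) -> None:
        if rate < 0:
            raise ValueError(f"negative recombination rate {rate} at {chrom}:{pos}")
        self.by_chrom.setdefault(int(chrom), []).append((int(pos), float(rate)))

    def finalize(self) -> "HotspotMap":
        """Sort by position and collapse duplicate positions keeping max rate."""
        for chrom, entries in self.by_chrom.items():
            best: Dict[int, float] = {}
            for pos, rate in entries:
                if pos not in best or rate > best[pos]:
                    best[pos] = rate
            self.by_chrom[chrom] = sorted(best.items())
        return self

    def positions(self, chrom: int) -> np.ndarray:
        return np.asarray([p for p, _ in self.by_chrom.get(chrom, [])], dtype=np.int64)

    def rates(self, chrom: int) -> np.ndarray:
        return np.asarray([r for _, r in self.by_chrom.get(chrom, [])], dtype=float)


@dataclass(frozen=True)
class ReferencePanelStats:
    """Genotype counts of one SNP in the reference panel."""

    count_aa: float
    count_ab: float
    count_bb: float

    @property
    def maf(self) -> float:
        tot = self.count_aa + self.count_ab + self.count_bb
        if tot <= 0:
            return 0.0
        b_freq = (self.count_ab + 2.0 * self.count_bb) / (2.0 * tot)
        return min(b_freq, 1.0 - b_freq)


def panel_ratios(stats: ReferencePanelStats, pseudocount: float = 1.0) -> Tuple[float, float]:
    """Genotype-count ratios AA/AB and BB/AB in the reference panel.

    An additive pseudocount on all three counts keeps the ratios finite when
    the panel has no heterozygotes.
    """
    s = pseudocount
    denom = stats.count_ab + s
    return ((stats.count_aa + s) / denom, (stats.count_bb + s) / denom)


def nearest_typed_distance(pos: int, typed_positions: np.ndarray | Sequence[int]) -> int:
    """Distance in bp from ``pos`` to the nearest typed SNP (same chromosome)."""
    typed = np.asarray(typed_positions, dtype=np.int64)
    if typed.size == 0:
        raise ValueError("typed_positions is empty")
    i = int(np.searchsorted(typed, pos))
    cands = typed[max(0, i - 1) : i + 1]
    return int(np.min(np.abs(cands - pos)))


def nearest_hotspot(pos: int, hotspot_map: HotspotMap, chrom: int) -> Tuple[int, float]:
    """Nearest hotspot to ``pos`` on ``chrom``: returns (distance_bp, rate).

    Equidistant hotspots resolve to the lower position.
    """
    positions = hotspot_map.positions(chrom)
    if positions.size == 0:
        raise ValueError(f"no recombination hotspot on chromosome {chrom}")
    rates = hotspot_map.rates(chrom)
    i = int(np.searchsorted(positions, pos))
    lo, hi = max(0, i - 1), min(i + 1, positions.size)
    cands = np.arange(lo, hi)
    dists = np.abs(positions[cands] - pos)
    best = cands[int(np.argmin(dists))]  # argmin takes first min: lower position wins ties
    return int(abs(positions[best] - pos)), float(rates[best])


def mean_posterior(posteriors: np.ndarray) -> float:
    """Mean over individuals of the maximum genotype posterior.

    The per-individual maximum posterior is the imputation program's
    confidence in its best-guess genotype; its mean lies in [1/3, 1].
    """
    p = normalize_posteriors(posteriors)
    if p.shape[0] == 0:
        raise ValueError("empty posterior sequence")
    return float(p.max(axis=1).mean())


def mean_b_dosage(posteriors: np.ndarray) -> float:
    """Mean estimated B-allele dosage 0*P(AA) + 1*P(AB) + 2*P(BB), in [0, 2]."""
    p = normalize_posteriors(posteriors)
    if p.shape[0] == 0:
        raise ValueError("empty posterior sequence")
    return float((p[:, 1] + 2.0 * p[:, 2]).mean())


def mean_baf(genotypes: np.ndarray | Sequence[int]) -> float:
    """Mean B-allele frequency of the sample: mean of b_count/2 over non-missing calls."""
    g = np.asarray(genotypes, dtype=np.int64)
    g = g[g != MISSING]
    if g.size == 0:
        raise ValueError("all genotype calls missing; cannot compute BAF")
    if np.any((g < 0) | (g > 2)):
        raise ValueError("genotype codes must be in {0, 1, 2} or -1 (missing)")
    return float(g.mean() / 2.0)


def assemble_features(
    snp: SnpRecord,
    panel: ReferencePanelStats,
    typed_positions: np.ndarray | Sequence[int],
    hotspot_map: HotspotMap,
    posteriors: np.ndarray,
    baf_genotypes: np.ndarray | Sequence[int],
    pseudocount: float = 1.0,
) -> np.ndarray:
    """Build the 12-feature vector for one imputed SNP (fixed documented order).

    ``baf_genotypes`` are genotype calls of an ethnic-matched sample used for
    the B-allele-frequency feature; in the synthetic scenarios they come from
    reference-panel haplotype pairs, never from the test truth.
    """
    try:
        r_aa, r_bb = panel_ratios(panel, pseudocount)
        d_typed = nearest_typed_distance(snp.pos, typed_positions)
        d_hot, rate = nearest_hotspot(snp.pos, hotspot_map, snp.chrom)
        vec = np.array(
            [
                float(snp.chrom),
                float(snp.pos),
                snp.platform_maf,
                mean_baf(baf_genotypes),
                panel.maf,
                r_aa,
                r_bb,
                float(d_typed),
                float(d_hot),
                rate,
                mean_posterior(posteriors),
                mean_b_dosage(posteriors),
            ]
        )
    except ValueError as exc:
        raise ValueError(f"feature assembly failed for SNP {snp.snp_id}: {exc}") from exc
    return vec


def feature_frame(rows: Dict[str, np.ndarray]) -> pd.DataFrame:
    """Assemble a snp_id-indexed DataFrame with the frozen feature columns."""
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(FEATURE_NAMES))
    df.index.name = "snp_id"
    return df
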