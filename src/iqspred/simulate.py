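"""Synthetic imputation scenarios with hotspot-structured recombination.

Real evaluations of imputation-quality regression need a genotyped cohort, a
haplotype reference panel and an imputation engine. This module emulates all
three so the full pipeline runs from a single seed:

* **Reference panel** — ``K`` founder haplotypes drawn site-wise from a
  U-shaped allele-frequency spectrum (Beta(0.5, 0.5) truncated to
  MAF >= 1%), expanded to ``H`` panel haplotypes as founder mosaics. The
  per-interval crossover probability is a small background value multiplied
  by a large odds factor in intervals containing a recombination hotspot,
  so linkage disequilibrium decays sharply across hotspots, as in real
  genomes.
* **Study sample** — ``N`` individuals, each the sum of two fresh mosaics of
  panel haplotypes.
* **Surrogate imputer** — for a masked SNP, panel haplotype pairs that match
  the individual's genotypes at the ``w`` nearest typed SNPs on each side
  vote on the missing genotype; the vote is shrunk toward the panel's
  Hardy-Weinberg
  genotype distribution by a fidelity weight ``alpha = exp(-D/lambda) *
  r_hot`` that decays with the distance ``D`` to the nearest typed SNP and is
  penalized when a hotspot lies between the masked SNP and that typed SNP.
  This reproduces the qualitative error structure of model-based imputation
  (worse far from typed SNPs, at low MAF, and near hotspots) without running
  an HMM engine.

Everything is deterministic given ``SimulationParams.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .features import HotspotMap
from .scenario import ImputationScenario, mask_training_snps

__all__ = [
    "SimulationParams",
    "REFERENCE_PARAMS",
    "HaplotypePanel",
    "generate_panel",
    "sample_study",
    "surrogate_impute",
    "build_fixture",
]


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic scenario generator (defaults = reference fixture)."""

    n_founders: int = 20            # K distinct ancestral haplotypes
    n_haplotypes: int = 200         # H panel haplotypes (H/2 panel individuals)
    n_individuals: int = 300        # N study individuals
    n_snps: int = 4000              # M biallelic SNPs on one chromosome
    chrom: int = 1
    chrom_length_bp: int = 10_000_000
    n_hotspots: int = 40
    hotspot_rate_shape: float = 2.0     # Gamma shape for rates (cM/Mb)
    hotspot_rate_scale: float = 10.0    # Gamma scale -> mean 20 cM/Mb
    p_switch_bg: float = 0.003          # background crossover prob per interval
    hotspot_odds: float = 100.0         # crossover odds multiplier in hotspot intervals
    old_platform_fraction: float = 0.5  # fraction of SNPs on the old array
    mask_fraction: float = 0.10         # typed SNPs erased for training truth
    flank_window: int = 4               # w typed SNPs consulted per side of the masked SNP
    decay_scale_bp: float = 10_000.0    # lambda of the fidelity decay
    hotspot_penalty_scale: float = 20.0 # cM/Mb scale of the hotspot penalty
    maf_min: float = 0.01
    n_annotation_sample: int = 100      # cohort used for the annotation MAF
    seed: int = 7

    def __post_init__(self) -> None:
        counts = (
            self.n_founders, self.n_haplotypes, self.n_individuals, self.n_snps,
            self.n_hotspots, self.flank_window, self.chrom_length_bp,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        for frac in (self.old_platform_fraction, self.mask_fraction):
            if not 0.0 < frac < 1.0:
                raise ValueError("fractions must be in (0, 1)")
        if self.decay_scale_bp <= 0:
            raise ValueError("decay scale lambda must be positive")
        if self.hotspot_odds <= 0 or self.p_switch_bg <= 0:
            raise ValueError("crossover parameters must be positive")


REFERENCE_PARAMS = SimulationParams()


@dataclass
class HaplotypePanel:
    """H x M binary haplotype matrix with positions and hotspot annotation."""

    haplotypes: np.ndarray          # (H, M) uint8 alleles in {0, 1}
    positions: np.ndarray           # (M,) sorted bp
    chrom: int
    hotspots: HotspotMap
    n_founders: int
    switch_events: np.ndarray       # (H, M-1) bool crossover indicator, for QC

    @property
    def allele_freq(self) -> np.ndarray:
        """Per-SNP B-allele frequency among panel haplotypes."""
        return self.haplotypes.mean(axis=0)

    @property
    def maf(self) -> np.ndarray:
        f = self.allele_freq
        return np.minimum(f, 1.0 - f)

    def paired_genotypes(self) -> np.ndarray:
        """(H/2, M) genotypes from pairing consecutive panel haplotypes."""
        h = self.haplotypes
        return (h[0::2] + h[1::2]).astype(np.int8)

    def genotype_counts(self) -> pd.DataFrame:
        """Per-SNP AA/AB/BB counts among panel individuals."""
        g = self.paired_genotypes()
        return pd.DataFrame(
            {
                "count_aa": (g == 0).sum(axis=0),
                "count_ab": (g == 1).sum(axis=0),
                "count_bb": (g == 2).sum(axis=0),
            }
        )

    def interval_has_hotspot(self) -> np.ndarray:
        """(M-1,) mask of inter-SNP intervals containing a hotspot."""
        hpos = self.hotspots.positions(self.chrom)
        left = self.positions[:-1]
        right = self.positions[1:]
        idx = np.searchsorted(hpos, left, side="right")
        return (idx < len(hpos)) & (hpos[np.minimum(idx, len(hpos) - 1)] <= right)


def _mosaic(
    rng: np.random.Generator,
    sources: np.ndarray,
    p_interval: np.ndarray,
    n_out: int,
) -> Tuple[np.ndarray, np.ndarray]:
    """Build ``n_out`` mosaic haplotypes over ``sources`` rows.

    A crossover fires in interval i with probability ``p_interval[i]``; on a
    crossover the source row is redrawn uniformly. Returns (mosaics,
    switch_events).
    """
    n_src, m = sources.shape
    switches = rng.random((n_out, m - 1)) < p_interval[None, :]
    draws = rng.integers(0, n_src, size=(n_out, m))
    # source index at SNP j = draw at the last crossover boundary <= j
    boundary = np.zeros((n_out, m), dtype=np.int64)
    boundary[:, 1:] = np.cumsum(switches, axis=1)
    # map each (row, segment) to the draw made at that segment start
    seg_start_draw = draws  # re-use draws: take the draw at each segment's first SNP
    src = np.empty((n_out, m), dtype=np.int64)
    for r in range(n_out):
        seg = boundary[r]
        starts = np.flatnonzero(np.diff(seg, prepend=-1))  # first SNP of each segment
        src[r] = seg_start_draw[r, starts][seg]
    out = sources[src, np.arange(m)[None, :]]
    return out.astype(np.uint8), switches


def generate_panel(params: SimulationParams) -> HaplotypePanel:
    """Simulate the haplotype reference panel (deterministic given the seed)."""
    rng = np.random.default_rng(params.seed)
    m = params.n_snps
    positions = np.sort(
        rng.choice(
            np.arange(1, params.chrom_length_bp + 1), size=m, replace=False
        )
    ).astype(np.int64)

    hpos = np.sort(
        rng.choice(np.arange(1, params.chrom_length_bp + 1),
                   size=params.n_hotspots, replace=False)
    )
    rates = rng.gamma(params.hotspot_rate_shape, params.hotspot_rate_scale,
                      size=params.n_hotspots)
    hmap = HotspotMap()
    for p, r in zip(hpos, rates):
        hmap.add(params.chrom, int(p), float(r))
    hmap.finalize()

    # U-shaped frequency spectrum, truncated below the pipeline's MAF filter
    freq = rng.beta(0.5, 0.5, size=m)
    while True:
        bad = np.minimum(freq, 1 - freq) < params.maf_min
        if not bad.any():
            break
        freq[bad] = rng.beta(0.5, 0.5, size=int(bad.sum()))

    founders = (rng.random((params.n_founders, m)) < freq[None, :]).astype(np.uint8)

    left, right = positions[:-1], positions[1:]
    idx = np.searchsorted(hpos, left, side="right")
    has_hot = (idx < len(hpos)) & (hpos[np.minimum(idx, len(hpos) - 1)] <= right)
    p_interval = np.where(
        has_hot,
        np.minimum(params.p_switch_bg * params.hotspot_odds, 0.5),
        params.p_switch_bg,
    )
    haplotypes, switches = _mosaic(rng, founders, p_interval, params.n_haplotypes)
    return HaplotypePanel(
        haplotypes=haplotypes,
        positions=positions,
        chrom=params.chrom,
        hotspots=hmap,
        n_founders=params.n_founders,
        switch_events=switches,
    )


def sample_study(
    panel: HaplotypePanel,
    n_individuals: int,
    seed: int,
    p_switch_bg: float = REFERENCE_PARAMS.p_switch_bg,
    hotspot_odds: float = REFERENCE_PARAMS.hotspot_odds,
) -> np.ndarray:
    """Draw study genotypes: each individual sums two panel-haplotype mosaics.

    Returns an (n_individuals, M) int8 matrix of B-allele counts (0/1/2).
    """
    if panel.haplotypes.shape[0] < 2:
        raise ValueError("panel needs at least 2 haplotypes")
    rng = np.random.default_rng(seed)
    has_hot = panel.interval_has_hotspot()
    p_interval = np.where(
        has_hot, np.minimum(p_switch_bg * hotspot_odds, 0.5), p_switch_bg
    )
    h1, _ = _mosaic(rng, panel.haplotypes, p_interval, n_individuals)
    h2, _ = _mosaic(rng, panel.haplotypes, p_interval, n_individuals)
    return (h1 + h2).astype(np.int8)


def _hotspot_between(panel: HaplotypePanel, a_bp: int, b_bp: int) -> float:
    """Max hotspot rate strictly between two positions, or 0 if none."""
    lo, hi = (a_bp, b_bp) if a_bp <= b_bp else (b_bp, a_bp)
    hpos = panel.hotspots.positions(panel.chrom)
    rates = panel.hotspots.rates(panel.chrom)
    sel = (hpos > lo) & (hpos < hi)
    return float(rates[sel].max()) if sel.any() else 0.0


def surrogate_impute(
    truth: np.ndarray,
    panel: HaplotypePanel,
    typed_idx: np.ndarray,
    masked_idx: np.ndarray,
    params: SimulationParams,
) -> np.ndarray:
    """Impute posteriors for masked SNPs from typed genotypes and the panel.

    For each masked SNP: panel haplotype pairs agreeing with an individual's
    genotypes at the ``w`` nearest typed SNPs on each flank define a genotype
    vote, mixed with the panel Hardy-Weinberg distribution by weight
    ``alpha = exp(-D/lambda) * r_hot``; with no matching pair the
    Hardy-Weinberg term is used alone. Returns (len(masked_idx), N, 3)
    posteriors.

    ``truth`` is the (N, M) study genotype matrix; only its typed columns are
    consulted, so nothing about a masked SNP's true genotype leaks in.
    """
    typed_idx = np.asarray(typed_idx, dtype=np.int64)
    masked_idx = np.asarray(masked_idx, dtype=np.int64)
    if typed_idx.size == 0:
        raise ValueError("typed set is empty")
    if np.intersect1d(typed_idx, masked_idx).size:
        raise ValueError("masked SNPs must not be typed")
    w_side = params.flank_window
    hap = panel.haplotypes
    n_hap = hap.shape[0]
    n_ind = truth.shape[0]
    typed_pos = panel.positions[typed_idx]
    order = np.argsort(typed_pos)
    typed_idx_sorted = typed_idx[order]
    typed_pos_sorted = typed_pos[order]

    pair_i, pair_j = np.triu_indices(n_hap)
    out = np.empty((masked_idx.size, n_ind, 3))

    freq = panel.allele_freq
    for k, mi in enumerate(masked_idx):
        pos = panel.positions[mi]
        ins = np.searchsorted(typed_pos_sorted, pos)
        lo = max(0, ins - w_side)
        hi = min(typed_pos_sorted.size, ins + w_side)
        window = np.arange(lo, hi)
        flank_cols = typed_idx_sorted[window]
        w = flank_cols.size
        pow3 = 3 ** np.arange(w)
        dists = np.abs(typed_pos_sorted[window] - pos)
        d_nearest = int(dists.min())
        nearest_pos = int(typed_pos_sorted[window[int(np.argmin(dists))]])

        rate_between = _hotspot_between(panel, int(pos), nearest_pos)
        r_hot = np.exp(-rate_between / params.hotspot_penalty_scale)
        alpha = float(np.exp(-d_nearest / params.decay_scale_bp) * r_hot)

        f = float(freq[mi])
        hw = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
        hw = hw / hw.sum()

        # genotype votes of all panel haplotype pairs, grouped by flank key
        flank_h = hap[:, flank_cols].astype(np.int64)       # (H, w)
        pair_geno = flank_h[pair_i] + flank_h[pair_j]       # (P, w) in {0,1,2}
        keys = pair_geno @ pow3
        g_masked = (hap[pair_i, mi] + hap[pair_j, mi]).astype(np.int64)
        votes = np.bincount(keys * 3 + g_masked, minlength=3**w * 3).reshape(-1, 3)

        ind_keys = truth[:, flank_cols].astype(np.int64) @ pow3
        v = votes[ind_keys].astype(float)                   # (N, 3)
        tot = v.sum(axis=1, keepdims=True)
        match = np.divide(v, tot, out=np.tile(hw, (n_ind, 1)), where=tot > 0)
        post = alpha * match + (1.0 - alpha) * hw[None, :]
        out[k] = post / post.sum(axis=1, keepdims=True)
    return out


def _annotation_maf(
    panel: HaplotypePanel, params: SimulationParams, seed: int
) -> np.ndarray:
    """Platform-annotation MAF, estimated from an independent mosaic cohort."""
    g = sample_study(
        panel, params.n_annotation_sample, seed,
        p_switch_bg=params.p_switch_bg, hotspot_odds=params.hotspot_odds,
    )
    f = g.mean(axis=0) / 2.0
    return np.minimum(f, 1.0 - f)


def build_fixture(
    params: SimulationParams = REFERENCE_PARAMS,
) -> Tuple[ImputationScenario, ImputationScenario]:
    """Build the (train, test) scenario pair of a platform-upgrade experiment.

    The old platform covers a random fraction of the SNPs; for **training**,
    10% of old-platform SNPs are masked and imputed from the remaining 90%,
    giving truth-labelled quality scores. For **testing**, the SNPs present
    only on the new platform are imputed from the full old platform. The two
    imputed SNP sets are disjoint by construction.
    """
    panel = generate_panel(params)
    seeds = np.random.SeedSequence(params.seed).spawn(4)
    rng_plat = np.random.default_rng(seeds[0])
    truth = sample_study(
        panel, params.n_individuals, seed=int(seeds[1].generate_state(1)[0] % 2**31),
        p_switch_bg=params.p_switch_bg, hotspot_odds=params.hotspot_odds,
    )

    m = params.n_snps
    n_old = int(round(params.old_platform_fraction * m))
    old_idx = np.sort(rng_plat.choice(m, size=n_old, replace=False))
    new_only_idx = np.setdiff1d(np.arange(m), old_idx)

    snp_names = np.array([f"snp{i:05d}" for i in range(m)])
    kept_names, masked_names = mask_training_snps(
        snp_names[old_idx], fraction=params.mask_fraction,
        seed=int(seeds[2].generate_state(1)[0] % 2**31),
    )
    name_to_idx = {n: i for i, n in enumerate(snp_names)}
    kept_idx = np.array(sorted(name_to_idx[n] for n in kept_names))
    masked_idx = np.array(sorted(name_to_idx[n] for n in masked_names))

    ann_maf = _annotation_maf(
        panel, params, int(seeds[3].generate_state(1)[0] % 2**31)
    )
    counts = panel.genotype_counts()
    counts.index = snp_names
    counts.index.name = "snp_id"
    baf_sample = panel.paired_genotypes()

    def make_scenario(imputed: np.ndarray, typed: np.ndarray) -> ImputationScenario:
        post = surrogate_impute(truth, panel, typed, imputed, params)
        ann = pd.DataFrame(
            {
                "chrom": params.chrom,
                "pos": panel.positions[imputed],
                "maf": ann_maf[imputed],
            },
            index=pd.Index(snp_names[imputed], name="snp_id"),
        )
        return ImputationScenario(
            snp_ids=list(snp_names[imputed]),
            annotation=ann,
            typed_positions={params.chrom: np.sort(panel.positions[typed])},
            hotspots=panel.hotspots,
            truth=truth[:, imputed].T.astype(np.int8),
            posteriors=np.transpose(post, (0, 1, 2)),
            panel_counts=counts.iloc[imputed],
            baf_genotypes=baf_sample[:, imputed].T.astype(np.int8),
        )

    train_scn = make_scenario(masked_idx, kept_idx)
    test_scn = make_scenario(new_only_idx, old_idx)
    return train_scn, test_scn


def scaled_params(scale: float, seed: Optional[int] = None) -> SimulationParams:
    """Reference parameters shrunk by ``scale`` (for quick tests/examples)."""
    p = REFERENCE_PARAMS
    kwargs: Dict[str, int] = dict(
        n_haplotypes=max(20, int(p.n_haplotypes * scale) // 2 * 2),
        n_individuals=max(20, int(p.n_individuals * scale)),
        n_snps=max(200, int(p.n_snps * scale)),
        chrom_length_bp=max(500_000, int(p.chrom_length_bp * scale)),
        n_hotspots=max(4, int(p.n_hotspots * scale)),
    )
    if seed is not None:
        kwargs["seed"] = seed
    return replace(p, **kwargs)
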