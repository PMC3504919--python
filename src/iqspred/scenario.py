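"""Scenario construction and evaluation of imputation-quality regression.

An :class:`ImputationScenario` bundles everything needed to score and predict
imputation quality for a set of imputed SNPs: their truth genotypes and
imputation posteriors, the typed-SNP positions they were imputed from, the
platform annotation, reference-panel genotype counts, a recombination hotspot
map, and an ethnic-matched genotype sample for the B-allele-frequency
feature. Training scenarios come from masking a fraction of typed SNPs so
truth is known; test scenarios are the SNPs absent from the old platform.

Evaluation mirrors the platform-upgrade study design: train nu-SVR models for
IQS, Po and Pc on the masked training SNPs, predict on the test scenario, and
report mean squared error, Pearson correlation, and ROC/AUC for the
false-positive filtering use case, where an imputed SNP whose true IQS falls
below a threshold (0.5 or 0.9) is a presumed false positive that should be
filtered out. Lower predicted quality must rank such SNPs higher, so ROC
scores are negated predictions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn import metrics as skm

from . import io as iqio
from .features import (
    FEATURE_NAMES,
    HotspotMap,
    ReferencePanelStats,
    SnpRecord,
    assemble_features,
)
from .iqs import build_contingency, iqs as compute_iqs
from .model import RegressionModel, combine_po_pc, fit_with_selection

logger = logging.getLogger("iqspred")

__all__ = [
    "ImputationScenario",
    "EvaluationReport",
    "apply_snp_filters",
    "mask_training_snps",
    "regression_metrics",
    "filtering_labels",
    "roc_auc",
    "run_scenario",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
FILTER_THRESHOLDS = (0.5, 0.9)


@dataclass
class ImputationScenario:
    """One unit of evaluation: imputed SNPs with truth, posteriors and context."""

    snp_ids: List[str]
    annotation: pd.DataFrame          # chrom, pos, maf — indexed by snp_id
    typed_positions: Dict[int, np.ndarray]  # per chromosome, sorted bp
    hotspots: HotspotMap
    truth: np.ndarray                 # (m, N) genotype codes
    posteriors: np.ndarray            # (m, N, 3)
    panel_counts: pd.DataFrame        # count_aa, count_ab, count_bb — indexed by snp_id
    baf_genotypes: np.ndarray         # (m, Nb) ethnic-matched sample genotypes
    sample_ids: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = len(self.snp_ids)
        if self.truth.shape[0] != m or self.posteriors.shape[0] != m:
            raise ValueError("truth/posteriors row count must match snp_ids")
        for sid in self.snp_ids:
            chrom = int(self.annotation.loc[sid, "chrom"])
            pos = int(self.annotation.loc[sid, "pos"])
            typed = self.typed_positions.get(chrom)
            if typed is not None and typed.size and np.any(typed == pos):
                raise ValueError(
                    f"imputed SNP {sid} at {chrom}:{pos} also appears typed; "
                    "typed and imputed sets must be disjoint"
                )
        if not self.sample_ids:
            self.sample_ids = [f"S{i + 1}" for i in range(self.truth.shape[1])]

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def scores(self, mode: str = "soft") -> pd.DataFrame:
        """True per-SNP agreement scores (po, pc, iqs) from truth + posteriors."""
        rows = []
        for k in range(self.n_snps):
            s = compute_iqs(build_contingency(self.truth[k], self.posteriors[k], mode))
            rows.append((s.po, s.pc, s.iqs))
        return pd.DataFrame(rows, index=self.snp_ids, columns=["po", "pc", "iqs"])

    def feature_matrix(self) -> pd.DataFrame:
        """The frozen 12-column feature table for all imputed SNPs."""
        rows = {}
        for k, sid in enumerate(self.snp_ids):
            ann = self.annotation.loc[sid]
            snp = SnpRecord(sid, int(ann["chrom"]), int(ann["pos"]), float(ann["maf"]))
            cnt = self.panel_counts.loc[sid]
            panel = ReferencePanelStats(
                float(cnt["count_aa"]), float(cnt["count_ab"]), float(cnt["count_bb"])
            )
            rows[sid] = assemble_features(
                snp,
                panel,
                self.typed_positions[snp.chrom],
                self.hotspots,
                self.posteriors[k],
                self.baf_genotypes[k],
            )
        df = pd.DataFrame.from_dict(rows, orient="index", columns=list(FEATURE_NAMES))
        df.index.name = "snp_id"
        return df

    # -- file round trip ------------------------------------------------------

    def write_files(self, outdir: str | Path, prefix: str) -> Dict[str, Path]:
        """Write the scenario in the pipeline's native text dialects."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "truth": outdir / f"{prefix}.truth.tsv",
            "gprobs": outdir / f"{prefix}.gprobs",
            "dose": outdir / f"{prefix}.dose",
            "annotation": outdir / f"{prefix}.annot.tsv",
            "typed": outdir / f"{prefix}.typed.tsv",
            "panel_counts": outdir / f"{prefix}.panel_counts.tsv",
            "baf_truth": outdir / f"{prefix}.baf.tsv",
            "hotspots": outdir / f"{prefix}.hotspots.tsv",
        }
        iqio.write_truth(paths["truth"], self.snp_ids, self.sample_ids, self.truth)
        grecs = [
            iqio.GprobsRecord(sid, "A", "B", self.posteriors[k])
            for k, sid in enumerate(self.snp_ids)
        ]
        iqio.write_gprobs(paths["gprobs"], self.sample_ids, grecs)
        drecs = [
            iqio.DoseRecord(
                sid, "A", "B",
                self.posteriors[k, :, 1] + 2.0 * self.posteriors[k, :, 2],
            )
            for k, sid in enumerate(self.snp_ids)
        ]
        iqio.write_dose(paths["dose"], self.sample_ids, drecs)
        iqio.write_annotation(paths["annotation"], self.annotation)
        typed_rows = [
            {"snp_id": f"typed_{c}_{p}", "chrom": c, "pos": p, "maf": np.nan}
            for c, arr in sorted(self.typed_positions.items())
            for p in arr
        ]
        pd.DataFrame(typed_rows).to_csv(paths["typed"], sep="\t", index=False)
        self.panel_counts.reset_index().to_csv(
            paths["panel_counts"], sep="\t", index=False
        )
        nb = self.baf_genotypes.shape[1]
        iqio.write_truth(
            paths["baf_truth"], self.snp_ids, [f"P{i + 1}" for i in range(nb)],
            self.baf_genotypes,
        )
        iqio.write_hotspots(paths["hotspots"], self.hotspots)
        return paths

    @classmethod
    def from_files(
        cls,
        truth: str | Path,
        gprobs: str | Path,
        annotation: str | Path,
        typed: str | Path,
        panel_counts: str | Path,
        baf_truth: str | Path,
        hotspots: str | Path,
    ) -> "ImputationScenario":
        snp_ids, sample_ids, geno = iqio.read_truth(truth)
        gp_samples, records = iqio.read_gprobs(gprobs)
        by_marker = {r.marker: r.posteriors for r in records}
        missing = [s for s in snp_ids if s not in by_marker]
        if missing:
            raise ValueError(f"gprobs lacks posteriors for SNPs: {missing[:5]} ...")
        post = np.stack([by_marker[s] for s in snp_ids])
        ann = iqio.read_annotation(annotation)
        typed_df = pd.read_csv(typed, sep="\t")
        typed_positions = {
            int(c): np.sort(g["pos"].to_numpy(dtype=np.int64))
            for c, g in typed_df.groupby("chrom")
        }
        counts = pd.read_csv(panel_counts, sep="\t").set_index("snp_id")
        _, _, baf_geno = iqio.read_truth(baf_truth)
        return cls(
            snp_ids=snp_ids,
            annotation=ann.loc[snp_ids],
            typed_positions=typed_positions,
            hotspots=iqio.read_hotspots(hotspots),
            truth=geno,
            posteriors=post,
            panel_counts=counts.loc[snp_ids],
            baf_genotypes=baf_geno,
            sample_ids=sample_ids,
        )


# -- SNP filters --------------------------------------------------------------


def _reconcile_alleles(
    platform: Tuple[str, str],
    panel: Tuple[str, str],
    platform_freq: Optional[float],
    panel_freq: Optional[float],
) -> bool:
    """True if platform and panel allele pairs describe the same SNP.

    Direct match is accepted, then a strand-complement match. Strand-ambiguous
    A/T and C/G SNPs (their complement is themselves) are resolved by
    allele-frequency proximity and dropped when either frequency lies within
    0.1 of 0.5, where orientation is genuinely undecidable.
    """
    pa = frozenset(a.upper() for a in platform)
    qa = frozenset(a.upper() for a in panel)
    ambiguous = pa in ({frozenset("AT"), frozenset("CG")})
    if pa == qa:
        if not ambiguous:
            return True
        if platform_freq is None or panel_freq is None:
            return True  # no frequency evidence; keep by direct match
        if abs(platform_freq - 0.5) < 0.1 or abs(panel_freq - 0.5) < 0.1:
            return False
        return True
    flipped = frozenset(_COMPLEMENT.get(a, "?") for a in pa)
    return flipped == qa


def apply_snp_filters(
    snps: pd.DataFrame,
    maf_threshold: float = 0.01,
    drop_undefined_iqs: Optional[pd.Series] = None,
) -> Tuple[pd.Index, Dict[str, int]]:
    """Apply the pre-imputation SNP filters; returns (retained ids, filter log).

    ``snps`` is indexed by snp_id with a ``panel_maf`` column and, optionally,
    allele columns ``platform_a/platform_b/panel_a/panel_b`` (plus
    ``platform_freq/panel_freq`` for ambiguous-strand resolution). Rules:

    * reference-panel MAF strictly below ``maf_threshold`` (1%) → dropped;
    * alleles irreconcilable with the panel (after strand-flip) → dropped;
    * optionally, SNPs whose true IQS is undefined (monomorphic) → dropped.
    """
    log = {"input": len(snps), "maf_below_threshold": 0, "inconsistent_alleles": 0,
           "undefined_iqs": 0}
    keep = pd.Series(True, index=snps.index)

    low = snps["panel_maf"] < maf_threshold  # strict: MAF == threshold is kept
    log["maf_below_threshold"] = int(low.sum())
    keep &= ~low

    has_alleles = {"platform_a", "platform_b", "panel_a", "panel_b"}.issubset(
        snps.columns
    )
    if has_alleles:
        for sid, row in snps[keep].iterrows():
            ok = _reconcile_alleles(
                (row["platform_a"], row["platform_b"]),
                (row["panel_a"], row["panel_b"]),
                row.get("platform_freq"),
                row.get("panel_freq"),
            )
            if not ok:
                keep.loc[sid] = False
                log["inconsistent_alleles"] += 1

    if drop_undefined_iqs is not None:
        undef = drop_undefined_iqs.reindex(snps.index).isna() & keep
        log["undefined_iqs"] = int(undef.sum())
        keep &= ~undef

    log["retained"] = int(keep.sum())
    logger.info("SNP filters: %s", log)
    return snps.index[keep], log


def mask_training_snps(
    typed_set: Sequence[str],
    fraction: float = 0.10,
    seed: int = 0,
) -> Tuple[List[str], List[str]]:
    """Randomly erase a fraction of typed SNPs to create truth-labelled examples.

    Returns (kept, masked): a seeded, exact partition with
    ``len(masked) = round(fraction * n)``.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("mask fraction must be in (0, 1)")
    typed = list(typed_set)
    if len(typed) < 10:
        raise ValueError("need at least 10 typed SNPs to mask")
    rng = np.random.default_rng(seed)
    n_mask = int(round(fraction * len(typed)))
    masked_idx = rng.choice(len(typed), size=n_mask, replace=False)
    masked_flags = np.zeros(len(typed), dtype=bool)
    masked_flags[masked_idx] = True
    masked = [s for s, f in zip(typed, masked_flags) if f]
    kept = [s for s, f in zip(typed, masked_flags) if not f]
    return kept, masked


# -- metrics ------------------------------------------------------------------


def regression_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> Tuple[float, float]:
    """(mean squared error, Pearson r); r is NaN if either vector is constant."""
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.shape != yp.shape or yt.size == 0:
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    mse = float(np.mean((yt - yp) ** 2))
    if np.ptp(yt) == 0 or np.ptp(yp) == 0:
        return mse, float("nan")
    return mse, float(sps.pearsonr(yt, yp).statistic)


def filtering_labels(true_iqs: np.ndarray, threshold: float) -> np.ndarray:
    """Presumed-false-positive labels: positive iff true IQS strictly below threshold."""
    iqs_arr = np.asarray(true_iqs, dtype=float)
    if np.isnan(iqs_arr).any():
        raise ValueError("true IQS must be defined for all SNPs before labelling")
    return iqs_arr < threshold


def roc_auc(
    scores: np.ndarray, labels: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, float]:
    """ROC curve and AUC for quality-based filtering.

    ``scores`` are predicted quality (higher = better imputation);
    ``labels`` mark SNPs that should be filtered out. Ranking uses the
    negated score so low predicted quality drives the positive class; ties
    average per the Mann-Whitney statistic. Returns (fpr, tpr, auc).
    """
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = skm.roc_curve(y, -s)
    return fpr, tpr, float(skm.auc(fpr, tpr))


# -- end-to-end ---------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Regression and filtering metrics for one train/test scenario pair."""

    regression: Dict[str, Dict[str, float]]        # target -> {mse, pearson_r}
    filtering: Dict[str, Dict[str, float]]         # "0.5"/"0.9" -> named AUCs
    counts: Dict[str, Dict[str, int]]              # filter logs + set sizes
    selected_nu: Dict[str, float]
    combined_iqs: Dict[str, float]                 # Po/Pc-combined IQS metrics

    def to_dict(self) -> dict:
        return {
            "regression": self.regression,
            "filtering": self.filtering,
            "counts": self.counts,
            "selected_nu": self.selected_nu,
            "combined_iqs": self.combined_iqs,
        }

    def to_json(self, path: Optional[str | Path] = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def run_scenario(
    train: ImputationScenario,
    test: ImputationScenario,
    mode: str = "soft",
    thresholds: Sequence[float] = FILTER_THRESHOLDS,
    seed: int = 42,
    maf_threshold: float = 0.01,
    targets: Sequence[str] = ("IQS", "Po", "Pc"),
) -> Tuple[EvaluationReport, pd.DataFrame, Dict[str, RegressionModel]]:
    """Train quality-regression models on ``train`` and evaluate on ``test``.

    Returns the report, a per-test-SNP table of true and predicted targets,
    and the fitted models keyed by target kind.
    """
    counts: Dict[str, Dict[str, int]] = {}
    frames = {}
    for name, scn in (("train", train), ("test", test)):
        sc = scn.scores(mode=mode)
        snps = pd.DataFrame(
            {"panel_maf": [
                ReferencePanelStats(*scn.panel_counts.loc[s][
                    ["count_aa", "count_ab", "count_bb"]
                ]).maf
                for s in scn.snp_ids
            ]},
            index=pd.Index(scn.snp_ids, name="snp_id"),
        )
        retained, log = apply_snp_filters(
            snps, maf_threshold=maf_threshold, drop_undefined_iqs=sc["iqs"]
        )
        counts[name] = log
        feats = scn.feature_matrix().loc[retained]
        frames[name] = (feats, sc.loc[retained])

    X_train, y_train = frames["train"]
    X_test, y_test = frames["test"]
    if len(X_train) < 20:
        raise ValueError(f"only {len(X_train)} training SNPs after filters")

    target_col = {"IQS": "iqs", "Po": "po", "Pc": "pc"}
    models: Dict[str, RegressionModel] = {}
    regression: Dict[str, Dict[str, float]] = {}
    preds = pd.DataFrame(index=X_test.index)
    selected = {}
    for kind in targets:
        col = target_col[kind]
        model = fit_with_selection(
            X_train.to_numpy(), y_train[col].to_numpy(), target_kind=kind, seed=seed
        )
        models[kind] = model
        selected[kind] = model.nu
        yhat = model.predict(X_test.to_numpy())
        preds[f"true_{col}"] = y_test[col]
        preds[f"pred_{col}"] = yhat
        mse, r = regression_metrics(y_test[col].to_numpy(), yhat)
        regression[kind] = {"mse": mse, "pearson_r": r}
        logger.info("%s model: nu=%.1f test MSE=%.4g r=%.3f", kind, model.nu, mse, r)

    combined: Dict[str, float] = {}
    if {"Po", "Pc"}.issubset(models):
        iqs_combined = combine_po_pc(
            preds["pred_po"].to_numpy(), preds["pred_pc"].to_numpy()
        )
        preds["pred_iqs_combined"] = iqs_combined
        ok = ~np.isnan(iqs_combined)
        mse, r = regression_metrics(
            y_test["iqs"].to_numpy()[ok], iqs_combined[ok]
        )
        combined = {"mse": mse, "pearson_r": r}

    filtering: Dict[str, Dict[str, float]] = {}
    for thr in thresholds:
        labels = filtering_labels(y_test["iqs"].to_numpy(), thr)
        if labels.all() or not labels.any():
            logger.warning("threshold %.1f: single-class labels, AUC skipped", thr)
            continue
        entry = {}
        if "IQS" in targets:
            entry["auc_predicted_iqs"] = roc_auc(
                preds["pred_iqs"].to_numpy(), labels
            )[2]
        if "Po" in targets:
            entry["auc_predicted_accuracy"] = roc_auc(
                preds["pred_po"].to_numpy(), labels
            )[2]
        entry["auc_true_accuracy"] = roc_auc(y_test["po"].to_numpy(), labels)[2]
        filtering[f"{thr:g}"] = entry

    counts["train"]["used_for_training"] = len(X_train)
    counts["test"]["used_for_testing"] = len(X_test)
    report = EvaluationReport(
        regression=regression,
        filtering=filtering,
        counts=counts,
        selected_nu=selected,
        combined_iqs=combined,
    )
    return report, preds, models
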