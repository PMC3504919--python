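"""Imputation quality score (IQS): Cohen's kappa on the imputed-vs-true genotype table.

For one biallelic SNP imputed in N individuals, the 3x3 cross-classification
``n[i, j]`` counts (or accumulates posterior mass for) individuals with imputed
genotype ``i`` and true genotype ``j``, where genotypes are ordered AA, AB, BB.
From the table:

    Po  = trace(n) / n..                   (observed agreement)
    Pc  = sum_i n_i. * n_.i / n..**2       (chance agreement)
    IQS = (Po - Pc) / (1 - Pc)             (Cohen's kappa)

IQS corrects raw concordance for the agreement expected by chance under the
observed margins; it is <= 1, can be negative (worse than chance), and is
undefined for monomorphic tables (Pc = 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AA",
    "AB",
    "BB",
    "MISSING",
    "GENOTYPE_LABELS",
    "AgreementScores",
    "ContingencyTable",
    "genotypes_from_labels",
    "normalize_posteriors",
    "build_contingency",
    "observed_agreement",
    "chance_agreement",
    "iqs",
]

# Genotype codes: the integer equals the B-allele count of the genotype.
AA, AB, BB = 0, 1, 2
MISSING = -1
GENOTYPE_LABELS = ("AA", "AB", "BB")

_LABEL_TO_CODE = {"AA": AA, "AB": AB, "BA": AB, "BB": BB}
_MISSING_LABELS = {"NA", "NN", "??", "--", ".", ""}


def genotypes_from_labels(labels: Iterable[str]) -> np.ndarray:
    """Convert AA/AB/BB/NA string labels to integer codes (-1 for missing)."""
    out = []
    for lab in labels:
        lab = str(lab).strip().upper()
        if lab in _MISSING_LABELS:
            out.append(MISSING)
        elif lab in _LABEL_TO_CODE:
            out.append(_LABEL_TO_CODE[lab])
        else:
            raise ValueError(f"unrecognized genotype label {lab!r}")
    return np.asarray(out, dtype=np.int8)


def normalize_posteriors(posteriors: np.ndarray, tol: float = 1e-3) -> np.ndarray:
    """Validate and renormalize an (N, 3) array of genotype posteriors.

    Each row must be nonnegative with a sum within ``tol`` of 1; rows are
    renormalized to sum exactly to 1.
    """
    p = np.asarray(posteriors, dtype=float)
    if p.ndim == 1:
        p = p.reshape(1, 3)
    if p.ndim != 2 or p.shape[1] != 3:
        raise ValueError(f"posteriors must have shape (N, 3), got {p.shape}")
    if np.any(p < -1e-12):
        raise ValueError("posterior probabilities must be nonnegative")
    s = p.sum(axis=1)
    bad = np.abs(s - 1.0) > tol
    if np.any(bad):
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"posterior triple {i} sums to {s[i]:.6g}, outside 1 +/- {tol:g}"
        )
    return np.clip(p, 0.0, None) / s[:, None]


@dataclass(frozen=True)
class ContingencyTable:
    """3x3 imputed-vs-true mass table; rows = imputed genotype, cols = truth."""

    n: np.ndarray  # (3, 3), nonnegative reals

    def __post_init__(self) -> None:
        n = np.asarray(self.n, dtype=float)
        if n.shape != (3, 3):
            raise ValueError(f"table must be 3x3, got {n.shape}")
        if np.any(n < 0):
            raise ValueError("table cells must be nonnegative")
        object.__setattr__(self, "n", n)

    @property
    def row_margins(self) -> np.ndarray:
        """n_i. — mass per imputed genotype."""
        return self.n.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        """n_.i — mass per true genotype."""
        return self.n.sum(axis=0)

    @property
    def total(self) -> float:
        """n.. — number of individuals with non-missing truth."""
        return float(self.n.sum())


def build_contingency(
    truth: Sequence[int] | np.ndarray,
    posteriors: np.ndarray,
    mode: str = "soft",
) -> ContingencyTable:
    """Accumulate the imputed-vs-true table over individuals.

    Parameters
    ----------
    truth
        Integer genotype codes per individual (0/1/2, -1 = missing). String
        labels are accepted and converted.
    posteriors
        (N, 3) posterior probabilities P(AA), P(AB), P(BB) per individual.
    mode
        ``"soft"`` (default): each individual adds its full posterior triple to
        the column of its true genotype, so cells may be fractional.
        ``"hard"``: each individual adds 1 to the cell of its maximum-posterior
        genotype; ties resolve to the lowest genotype code (AA < AB < BB).

    Individuals with missing truth are skipped; the column margins therefore
    equal the truth genotype counts in both modes.
    """
    t = np.asarray(truth)
    if t.dtype.kind in "UOS":
        t = genotypes_from_labels(t)
    t = t.astype(np.int64)
    p = normalize_posteriors(posteriors)
    if len(t) != len(p):
        raise ValueError(f"truth ({len(t)}) and posteriors ({len(p)}) differ in length")
    keep = t != MISSING
    t, p = t[keep], p[keep]
    if len(t) == 0:
        raise ValueError("no informative individuals (all truth genotypes missing)")
    if np.any((t < 0) | (t > 2)):
        raise ValueError("truth codes must be in {0, 1, 2} or -1 (missing)")

    n = np.zeros((3, 3))
    if mode == "soft":
        for j in range(3):
            n[:, j] = p[t == j].sum(axis=0)
    elif mode == "hard":
        calls = p.argmax(axis=1)  # argmax takes first max: AA < AB < BB tie rule
        np.add.at(n, (calls, t), 1.0)
    else:
        raise ValueError(f"mode must be 'soft' or 'hard', got {mode!r}")
    return ContingencyTable(n)


def observed_agreement(table: ContingencyTable) -> float:
    """Po: diagonal mass over total mass."""
    tot = table.total
    if tot <= 0:
        raise ValueError("empty contingency table (n.. = 0)")
    return float(np.trace(table.n) / tot)


def chance_agreement(table: ContingencyTable) -> float:
    """Pc: agreement expected if imputed and true genotypes were independent."""
    tot = table.total
    if tot <= 0:
        raise ValueError("empty contingency table (n.. = 0)")
    return float(np.dot(table.row_margins, table.col_margins) / tot**2)


@dataclass(frozen=True)
class AgreementScores:
    """Observed agreement, chance agreement and their kappa combination."""

    po: float
    pc: float
    iqs: float  # NaN when undefined (Pc = 1, monomorphic table)

    @property
    def defined(self) -> bool:
        return not math.isnan(self.iqs)


def iqs(table: ContingencyTable, pc_tol: float = 1e-12) -> AgreementScores:
    """Compute Po, Pc and IQS = (Po - Pc) / (1 - Pc) for one SNP.

    When Pc = 1 within ``pc_tol`` (a monomorphic table: all margin mass on one
    genotype) kappa is undefined and IQS is returned as NaN; such SNPs are
    excluded from regression training and evaluation upstream.
    """
    po = observed_agreement(table)
    pc = chance_agreement(table)
    if pc >= 1.0 - pc_tol:
        return AgreementScores(po=po, pc=pc, iqs=float("nan"))
    return AgreementScores(po=po, pc=pc, iqs=(po - pc) / (1.0 - pc))
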