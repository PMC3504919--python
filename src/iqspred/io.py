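"""Readers and writers for the pipeline's text formats.

Native formats follow the Beagle 3 era of imputation tooling:

* ``.gprobs`` — whitespace table, header ``marker alleleA alleleB`` then each
  sample id repeated three times; one row per marker with P(AA) P(AB) P(BB)
  per individual.
* ``.dose``  — same layout with one dosage per individual. Dosages here are
  B-allele dosages (0*P(AA) + 1*P(AB) + 2*P(BB)); classic Beagle prints
  allele-A dosages, which are ``2 - x``.
* truth TSV — header ``snp_id`` + sample ids; cells AA/AB/BB/NA.
* annotation TSV — header ``snp_id chrom pos maf``.
* hotspot table — HapMap-style whitespace columns ``Chromosome Position(bp)
  Rate(cM/Mb) Map(cM)`` (Map optional), or a bare two-column (pos, rate) TSV
  taken to be a single chromosome 1.

All parse errors name the file and the 1-based line number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .features import HotspotMap
from .iqs import GENOTYPE_LABELS, MISSING, genotypes_from_labels

logger = logging.getLogger("iqspred")

__all__ = [
    "GprobsRecord",
    "DoseRecord",
    "read_gprobs",
    "write_gprobs",
    "read_dose",
    "write_dose",
    "read_truth",
    "write_truth",
    "read_annotation",
    "write_annotation",
    "read_hotspots",
    "write_hotspots",
]


@dataclass(frozen=True)
class GprobsRecord:
    marker: str
    allele_a: str
    allele_b: str
    posteriors: np.ndarray  # (N, 3)


@dataclass(frozen=True)
class DoseRecord:
    marker: str
    allele_a: str
    allele_b: str
    dosages: np.ndarray  # (N,), B-allele dosage in [0, 2]


def _err(path: Path, lineno: int, msg: str) -> ValueError:
    return ValueError(f"{path}:{lineno}: {msg}")


def read_gprobs(path: str | Path) -> Tuple[List[str], List[GprobsRecord]]:
    """Parse a Beagle 3 genotype-probabilities file.

    Returns (sample_ids, records). The individual count is inferred from the
    header and enforced on every row; each per-individual probability triple
    must sum to 1 within 1e-3 and is renormalized on ingest.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().split()
        if len(header) < 6 or (len(header) - 3) % 3 != 0:
            raise _err(path, 1, "gprobs header must list 3 id columns per sample")
        n = (len(header) - 3) // 3
        sample_ids = header[3::3]
        records: List[GprobsRecord] = []
        for lineno, line in enumerate(fh, start=2):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 3 + 3 * n:
                raise _err(
                    path, lineno,
                    f"expected {3 + 3 * n} fields for {n} samples, got {len(tok)}",
                )
            try:
                probs = np.asarray(tok[3:], dtype=float).reshape(n, 3)
            except ValueError:
                raise _err(path, lineno, "non-numeric probability field") from None
            s = probs.sum(axis=1)
            bad = np.abs(s - 1.0) > 1e-3
            if np.any(bad):
                raise _err(
                    path, lineno,
                    f"probability triple for sample {sample_ids[int(np.flatnonzero(bad)[0])]}"
                    f" sums to {s[bad][0]:.6g}, outside 1 +/- 0.001",
                )
            # renormalize only when off by more than fp noise, so files the
            # package wrote itself round-trip token-exactly
            fix = np.abs(s - 1.0) > 1e-9
            if np.any(fix):
                probs[fix] /= s[fix, None]
            records.append(GprobsRecord(tok[0], tok[1], tok[2], probs))
    return sample_ids, records


def _fmt_float(v: float, fmt: str | None) -> str:
    # repr gives the shortest decimal that parses back to the same float,
    # which is what keeps write -> read -> write token-identical
    return repr(float(v)) if fmt is None else fmt % v


def write_gprobs(
    path: str | Path,
    sample_ids: Sequence[str],
    records: Sequence[GprobsRecord],
    fmt: str | None = None,
) -> None:
    with Path(path).open("w") as fh:
        fh.write("marker alleleA alleleB")
        for sid in sample_ids:
            fh.write(f" {sid} {sid} {sid}")
        fh.write("\n")
        for rec in records:
            fields = [rec.marker, rec.allele_a, rec.allele_b]
            fields += [_fmt_float(v, fmt) for v in rec.posteriors.ravel()]
            fh.write(" ".join(fields) + "\n")


def read_dose(path: str | Path) -> Tuple[List[str], List[DoseRecord]]:
    """Parse a dosage file (one B-allele dosage in [0, 2] per individual)."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().split()
        if len(header) < 4:
            raise _err(path, 1, "dose header must list at least one sample id")
        sample_ids = header[3:]
        n = len(sample_ids)
        records: List[DoseRecord] = []
        for lineno, line in enumerate(fh, start=2):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 3 + n:
                raise _err(path, lineno, f"expected {3 + n} fields, got {len(tok)}")
            try:
                dos = np.asarray(tok[3:], dtype=float)
            except ValueError:
                raise _err(path, lineno, "non-numeric dosage field") from None
            if np.any((dos < -1e-9) | (dos > 2 + 1e-9)):
                raise _err(path, lineno, "dosage outside [0, 2]")
            records.append(DoseRecord(tok[0], tok[1], tok[2], np.clip(dos, 0.0, 2.0)))
    return sample_ids, records


def write_dose(
    path: str | Path,
    sample_ids: Sequence[str],
    records: Sequence[DoseRecord],
    fmt: str | None = None,
) -> None:
    with Path(path).open("w") as fh:
        fh.write("marker alleleA alleleB " + " ".join(sample_ids) + "\n")
        for rec in records:
            fields = [rec.marker, rec.allele_a, rec.allele_b]
            fields += [_fmt_float(v, fmt) for v in rec.dosages]
            fh.write(" ".join(fields) + "\n")


def read_truth(path: str | Path) -> Tuple[List[str], List[str], np.ndarray]:
    """Read a truth TSV: returns (snp_ids, sample_ids, genotype codes (M, N))."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "snp_id":
        raise _err(path, 1, "first truth column must be 'snp_id'")
    sample_ids = list(df.columns[1:])
    snp_ids = df["snp_id"].tolist()
    geno = np.empty((len(snp_ids), len(sample_ids)), dtype=np.int8)
    for i, (_, row) in enumerate(df.iterrows()):
        try:
            geno[i] = genotypes_from_labels(row.iloc[1:])
        except ValueError as exc:
            raise _err(path, i + 2, str(exc)) from None
    return snp_ids, sample_ids, geno


def write_truth(
    path: str | Path,
    snp_ids: Sequence[str],
    sample_ids: Sequence[str],
    genotypes: np.ndarray,
) -> None:
    with Path(path).open("w") as fh:
        fh.write("snp_id\t" + "\t".join(sample_ids) + "\n")
        for sid, row in zip(snp_ids, genotypes):
            labels = [GENOTYPE_LABELS[g] if g != MISSING else "NA" for g in row]
            fh.write(sid + "\t" + "\t".join(labels) + "\n")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read the platform annotation TSV (snp_id, chrom, pos, maf), snp_id-indexed."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"snp_id", "chrom", "pos", "maf"}
    if not required.issubset(df.columns):
        raise _err(path, 1, f"annotation needs columns {sorted(required)}")
    return df.set_index("snp_id")


def write_annotation(path: str | Path, df: pd.DataFrame) -> None:
    out = df.reset_index() if df.index.name == "snp_id" else df
    out.to_csv(path, sep="\t", index=False)


def read_hotspots(path: str | Path) -> HotspotMap:
    """Read a recombination-hotspot table into a per-chromosome sorted map.

    Accepts the HapMap-style header (``Chromosome Position(bp) Rate(cM/Mb)``,
    with ``Map(cM)`` optional and ignored) or a headerless/2-column (pos,
    rate) TSV interpreted as chromosome 1. Duplicate positions collapse to
    the maximum rate; unsorted input is sorted with a log line.
    """
    path = Path(path)
    hmap = HotspotMap()
    with path.open() as fh:
        lines = [ln.split() for ln in fh if ln.strip()]
    if not lines:
        raise _err(path, 1, "empty hotspot file")
    first = lines[0]
    has_header = not _looks_like_data(first[0])
    rows = lines[1:] if has_header else lines
    start = 2 if has_header else 1
    ncol = len(first)
    unsorted_seen = False
    last_pos: dict = {}
    for lineno, tok in enumerate(rows, start=start):
        try:
            if ncol >= 3:
                chrom = int(str(tok[0]).lower().removeprefix("chr"))
                pos, rate = int(float(tok[1])), float(tok[2])
            else:
                chrom, pos, rate = 1, int(float(tok[0])), float(tok[1])
        except (ValueError, IndexError):
            raise _err(path, lineno, f"malformed hotspot row: {' '.join(tok)}") from None
        if rate < 0:
            raise _err(path, lineno, f"negative recombination rate {rate}")
        if chrom in last_pos and pos < last_pos[chrom]:
            unsorted_seen = True
        last_pos[chrom] = pos
        hmap.add(chrom, pos, rate)
    if unsorted_seen:
        logger.info("%s: hotspot positions not sorted; sorting on load", path)
    return hmap.finalize()


def write_hotspots(path: str | Path, hmap: HotspotMap) -> None:
    with Path(path).open("w") as fh:
        fh.write("Chromosome Position(bp) Rate(cM/Mb) Map(cM)\n")
        for chrom in sorted(hmap.by_chrom):
            cm = 0.0
            prev = None
            for pos, rate in hmap.by_chrom[chrom]:
                if prev is not None:
                    cm += rate * (pos - prev) / 1e6
                prev = pos
                fh.write(f"chr{chrom} {pos} {repr(float(rate))} {cm:.6f}\n")


def _looks_like_data(tok: str) -> bool:
    """True for numeric or chrN-style first fields (i.e. not a header line)."""
    t = tok.lower().removeprefix("chr")
    try:
        float(t)
        return True
    except ValueError:
        return False
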