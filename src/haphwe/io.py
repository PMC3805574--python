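"""Linkage-pedigree (PED) input, haplotype-block files and block-wise analysis.

The supported input is the standard whitespace-delimited 6-column linkage
pedigree format: family, individual, father, mother, sex, phenotype,
followed by two allele tokens per SNP ("0" = missing).  Only founders
(father and mother both "0") enter the analysis; within each haplotype
block, individuals missing any in-block SNP are excluded.

Allele labels may be arbitrary (1/2 or A/C/G/T); per SNP they are mapped
to codes 1 and 2 in order of first appearance, and the mapping is carried
in the report so results are label-stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._engine import ClassData, fit_hwe_core, fit_im_core, fit_niu_core
from .haplotypes import Haplotype
from .hwe_tests import lrt_from_fits
from .estimators import FitResult

logger = logging.getLogger(__name__)

__all__ = [
    "PedRecord",
    "BlockDefinition",
    "read_ped",
    "select_founders",
    "read_blocks",
    "analyze_blocks",
    "write_results",
    "BlockReport",
    "AnalysisReport",
]

MISSING = "0"


@dataclass
class PedRecord:
    """One row of a linkage pedigree file."""

    family_id: str
    individual_id: str
    father_id: str
    mother_id: str
    sex: str
    phenotype: str
    alleles: tuple[tuple[str, str], ...]  # two tokens per SNP

    @property
    def is_founder(self) -> bool:
        return self.father_id == MISSING and self.mother_id == MISSING


@dataclass
class BlockDefinition:
    """Ordered SNP identifiers (names or 1-based indices) of one block."""

    snps: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.snps) < 2:
            raise ValueError(f"a haplotype block needs >= 2 SNPs, got {self.snps}")


def read_ped(
    path, n_snps: int | None = None
) -> tuple[list[PedRecord], list[tuple[int, str]]]:
    """Parse a PED file.

    Returns (records, rejected) where ``rejected`` holds (1-based line
    number, reason) for malformed rows.  All well-formed rows must agree
    on the SNP count (6 + 2M columns).
    """
    records: list[PedRecord] = []
    rejected: list[tuple[int, str]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) < 8 or (len(tokens) - 6) % 2 != 0:
            rejected.append((lineno, f"expected 6 + 2*M columns, got {len(tokens)}"))
            continue
        m = (len(tokens) - 6) // 2
        if n_snps is None:
            n_snps = m
        if m != n_snps:
            rejected.append((lineno, f"expected {n_snps} SNPs, row has {m}"))
            continue
        alleles = tuple(
            (tokens[6 + 2 * j], tokens[7 + 2 * j]) for j in range(m)
        )
        records.append(PedRecord(*tokens[:6], alleles=alleles))
    for lineno, reason in rejected:
        logger.warning("rejected PED line %d: %s", lineno, reason)
    return records, rejected


def select_founders(records: Sequence[PedRecord]) -> list[PedRecord]:
    """Keep founders only (both parent ids \"0\"); error if none remain."""
    founders = [r for r in records if r.is_founder]
    if not founders:
        raise ValueError("no founders in the pedigree data")
    excluded = len(records) - len(founders)
    if excluded:
        logger.info("excluded %d nonfounders", excluded)
    return founders


def read_blocks(path) -> list[BlockDefinition]:
    """One block per line: whitespace-separated SNP names or 1-based indices."""
    blocks = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        blocks.append(BlockDefinition(tuple(line.split())))
    if not blocks:
        raise ValueError("block file defines no blocks")
    return blocks


def _resolve_block_columns(
    block: BlockDefinition, snp_names: Sequence[str] | None, n_snps: int
) -> list[int]:
    cols = []
    for snp in block.snps:
        if snp_names is not None and snp in snp_names:
            cols.append(list(snp_names).index(snp))
        elif snp.isdigit() and 1 <= int(snp) <= n_snps:
            cols.append(int(snp) - 1)  # 1-based index
        else:
            raise KeyError(f"SNP {snp!r} not found in the PED map")
    return cols


def _dosage_matrix(
    records: Sequence[PedRecord], cols: Sequence[int]
) -> tuple[np.ndarray, np.ndarray, list[dict[str, int]]]:
    """Map allele labels to {1, 2} per SNP and build the dosage matrix.

    Returns (X, complete_mask, per-SNP label maps); rows with any missing
    in-block allele get dosage -1 there and a False mask entry.
    """
    n = len(records)
    X = np.full((n, len(cols)), -1, dtype=np.int64)
    maps: list[dict[str, int]] = []
    for jj, col in enumerate(cols):
        label_map: dict[str, int] = {}
        for i, rec in enumerate(records):
            a, b = rec.alleles[col]
            if a == MISSING or b == MISSING:
                continue
            dosage = 0
            for tok in (a, b):
                if tok not in label_map:
                    if len(label_map) == 2:
                        raise ValueError(
                            f"more than 2 alleles at SNP column {col + 1}: "
                            f"{sorted(label_map)} and {tok!r}"
                        )
                    # first-seen label -> allele 1, second -> allele 2
                    label_map[tok] = len(label_map) + 1
                dosage += label_map[tok] - 1
            X[i, jj] = dosage
        maps.append(label_map)
    mask = (X >= 0).all(axis=1)
    return X, mask, maps


@dataclass
class BlockReport:
    """Per-block fits, tests and bookkeeping."""

    block_index: int
    snps: tuple[str, ...]
    n_used: int
    n_excluded_missing: int
    skipped_reason: str | None = None
    allele_maps: list[dict[str, int]] = field(default_factory=list)
    hwe_fit: FitResult | None = None
    nm_fit: FitResult | None = None
    im_fit: FitResult | None = None
    lrt_nm_stat: float | None = None
    lrt_nm_p: float | None = None
    lrt_im_stat: float | None = None
    lrt_im_p: float | None = None


@dataclass
class AnalysisReport:
    blocks: list[BlockReport]
    alpha: float
    bonferroni: bool

    @property
    def n_tested(self) -> int:
        return sum(1 for b in self.blocks if b.skipped_reason is None)

    def significance_threshold(self) -> float:
        if self.bonferroni and self.n_tested:
            return self.alpha / self.n_tested
        return self.alpha


def analyze_blocks(
    records: Sequence[PedRecord],
    blocks: Sequence[BlockDefinition],
    snp_names: Sequence[str] | None = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
    alpha: float = 0.05,
    bonferroni: bool = True,
    min_individuals: int = 20,
    report_threshold: float = 1e-3,
) -> AnalysisReport:
    """Fit all three models and run both HWE tests block by block.

    ``records`` should already be founders (see :func:`select_founders`).
    Within each block, individuals with any missing in-block genotype are
    excluded; blocks with fewer than ``min_individuals`` usable individuals
    are skipped with a reason.
    """
    if not records:
        raise ValueError("no individuals to analyze")
    n_snps = len(records[0].alleles)
    out: list[BlockReport] = []
    for b_idx, block in enumerate(blocks):
        cols = _resolve_block_columns(block, snp_names, n_snps)
        X, mask, maps = _dosage_matrix(records, cols)
        n_used = int(mask.sum())
        n_missing = len(records) - n_used
        rep = BlockReport(
            block_index=b_idx,
            snps=block.snps,
            n_used=n_used,
            n_excluded_missing=n_missing,
            allele_maps=maps,
        )
        if n_used < min_individuals:
            rep.skipped_reason = (
                f"only {n_used} usable individuals (< {min_individuals})"
            )
            logger.warning("block %d skipped: %s", b_idx + 1, rep.skipped_reason)
            out.append(rep)
            continue
        cd = ClassData.from_dosage(X[mask])
        hwe = fit_hwe_core(cd, tol, max_iter)
        nm = fit_niu_core(cd, tol, max_iter)
        im = fit_im_core(cd, tol, max_iter)
        rep.hwe_fit = FitResult._from_core(hwe, len(cols))
        rep.nm_fit = FitResult._from_core(nm, len(cols))
        rep.im_fit = FitResult._from_core(im, len(cols))
        t_nm = lrt_from_fits(rep.hwe_fit, rep.nm_fit)
        t_im = lrt_from_fits(rep.hwe_fit, rep.im_fit)
        rep.lrt_nm_stat, rep.lrt_nm_p = t_nm.statistic, t_nm.p_value
        rep.lrt_im_stat, rep.lrt_im_p = t_im.statistic, t_im.p_value
        logger.info(
            "block %d: n=%d, theta=%.4f (p=%.4g), f=%.4f (p=%.4g)",
            b_idx + 1, n_used, nm.theta, t_nm.p_value, im.f, t_im.p_value,
        )
        out.append(rep)
    report = AnalysisReport(blocks=out, alpha=alpha, bonferroni=bonferroni)
    _attach_report_threshold(report, report_threshold)
    return report


def _attach_report_threshold(report: AnalysisReport, threshold: float) -> None:
    report.report_threshold = threshold  # type: ignore[attr-defined]


def _freq_rows(rep: BlockReport, threshold: float) -> list[dict]:
    rows = []
    assert rep.hwe_fit and rep.nm_fit and rep.im_fit
    support = sorted(
        {str(h) for h, _ in rep.hwe_fit.freqs.items()}
        | {str(h) for h, _ in rep.nm_fit.freqs.items()}
        | {str(h) for h, _ in rep.im_fit.freqs.items()}
    )
    for hap in support:
        h = Haplotype.from_string(hap)
        p_em = rep.hwe_fit.freqs.get(h)
        p_ecm = rep.nm_fit.freqs.get(h)
        p_iem = rep.im_fit.freqs.get(h)
        if max(p_em, p_ecm, p_iem) <= threshold:
            continue
        rows.append(
            {
                "block": rep.block_index + 1,
                "haplotype": hap,
                "freq_em": p_em,
                "freq_ecm": p_ecm,
                "freq_iem": p_iem,
            }
        )
    return rows


def write_results(report: AnalysisReport, path) -> None:
    """Write a human-readable results file plus a delimited sidecar.

    ``path`` gets the text report; ``path`` with suffix ``.tsv`` appended
    gets one machine-readable row per analyzed block.
    """
    path = Path(path)
    threshold = getattr(report, "report_threshold", 1e-3)
    sig = report.significance_threshold()
    lines: list[str] = []
    side_rows: list[dict] = []
    lines.append("Haplotype-based HWE test results")
    lines.append(
        f"alpha = {report.alpha}"
        + (f" (Bonferroni across {report.n_tested} blocks: {sig:.6g})"
           if report.bonferroni else "")
    )
    for rep in report.blocks:
        lines.append("")
        lines.append(f"Block {rep.block_index + 1}: SNPs {' '.join(rep.snps)}")
        lines.append(
            f"  individuals used: {rep.n_used} "
            f"(excluded for in-block missingness: {rep.n_excluded_missing})"
        )
        if rep.skipped_reason is not None:
            lines.append(f"  SKIPPED: {rep.skipped_reason}")
            continue
        assert rep.hwe_fit and rep.nm_fit and rep.im_fit
        for maps, snp in zip(rep.allele_maps, rep.snps):
            lines.append(f"  allele coding {snp}: {maps}")
        lines.append(
            "  convergence: EM %d it (%s), ECM %d it (%s), IEM %d it (%s)"
            % (
                rep.hwe_fit.n_iter, "ok" if rep.hwe_fit.converged else "NOT converged",
                rep.nm_fit.n_iter, "ok" if rep.nm_fit.converged else "NOT converged",
                rep.im_fit.n_iter, "ok" if rep.im_fit.converged else "NOT converged",
            )
        )
        lines.append(f"  haplotype frequencies (> {threshold:g}):")
        lines.append("    haplotype      EM        ECM       IEM")
        for row in _freq_rows(rep, threshold):
            lines.append(
                f"    {row['haplotype']:<12s} {row['freq_em']:.6f}  "
                f"{row['freq_ecm']:.6f}  {row['freq_iem']:.6f}"
            )
        lines.append(
            f"  Niu's model: theta = {rep.nm_fit.theta_hat:.6f}, "
            f"LRT_NM = {rep.lrt_nm_stat:.6f}, P = {rep.lrt_nm_p:.6g}"
            + ("  *" if rep.lrt_nm_p is not None and rep.lrt_nm_p < sig else "")
        )
        lines.append(
            f"  inbreeding model: f = {rep.im_fit.f_hat:.6f}, "
            f"LRT_IM = {rep.lrt_im_stat:.6f}, P = {rep.lrt_im_p:.6g}"
            + ("  *" if rep.lrt_im_p is not None and rep.lrt_im_p < sig else "")
        )
        side_rows.append(
            {
                "block": rep.block_index + 1,
                "snps": ",".join(rep.snps),
                "n_used": rep.n_used,
                "n_excluded_missing": rep.n_excluded_missing,
                "theta_hat": rep.nm_fit.theta_hat,
                "f_hat": rep.im_fit.f_hat,
                "lrt_nm": rep.lrt_nm_stat,
                "p_nm": rep.lrt_nm_p,
                "lrt_im": rep.lrt_im_stat,
                "p_im": rep.lrt_im_p,
            }
        )
    path.write_text("\n".join(lines) + "\n")
    side = pd.DataFrame(
        side_rows,
        columns=[
            "block", "snps", "n_used", "n_excluded_missing",
            "theta_hat", "f_hat", "lrt_nm", "p_nm", "lrt_im", "p_im",
        ],
    )
    side.to_csv(path.with_suffix(path.suffix + ".tsv"), sep="\t", index=False)
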