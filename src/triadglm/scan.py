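"""Genome-wide per-SNP fitting of the joint model from PLINK filesets.

For every retained SNP: orient doses to the minor allele (computed from
genotyped parents, each parent counted once), tabulate family units into
triad/dyad cells, fit the requested model (EM when dyads are present), and
report relative risks, Benjamini-Hochberg q-values, the HWE test, and the
genomic inflation factor.  Per-SNP failures are captured in the status
column and never abort the scan.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .cells import CountTable, tabulate_doses
from .design import ModelSpec, build_design
from .fit import fit_complete, fit_with_missing, hwe_test, wald_effects
from .plink import PedigreeIndex, build_pedigree_index, read_bed, read_bim, read_fam

__all__ = [
    "SCAN_COLUMNS",
    "scan_genotypes",
    "scan_plink",
    "scan_dose_table",
    "compute_maf",
    "bh_qvalues",
    "genomic_lambda",
    "write_results",
    "qq_table",
    "manhattan_table",
    "export_qq_manhattan_tables",
]

logger = logging.getLogger(__name__)

#: Fixed output column order of the scan TSV.
SCAN_COLUMNS = [
    "snp",
    "chr",
    "pos",
    "effect_allele",
    "ref_allele",
    "maf",
    "n_triads",
    "n_md",
    "n_fd",
    "n_mendel_err",
    "rr_single",
    "ci_lo_single",
    "ci_hi_single",
    "p_single",
    "q_single",
    "rr_double",
    "ci_lo_double",
    "ci_hi_double",
    "p_double",
    "rr_int",
    "ci_lo_int",
    "ci_hi_int",
    "p_int",
    "q_int",
    "hwe_p",
    "status",
]

#: Median of the 1-df chi-square distribution.
CHI2_1_MEDIAN = 0.4549364


def compute_maf(parent_doses: np.ndarray) -> float:
    """Allele frequency folded to [0, 0.5] from genotyped parents' doses."""
    doses = np.asarray(parent_doses, dtype=float)
    doses = doses[~np.isnan(doses)]
    if doses.size == 0:
        raise ValueError("no genotyped parents")
    freq = doses.sum() / (2.0 * doses.size)
    return float(min(freq, 1.0 - freq))


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, mapped back to input order.

    NaN entries are ignored (and returned as NaN); q_(i) = min over j >= i of
    p_(j) * n / j, capped at one.
    """
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if pv.size == 0:
        return q
    if (pv < 0).any() or (pv > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = pv.size
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


def genomic_lambda(p: np.ndarray) -> float:
    """Genomic inflation factor: median implied 1-df chi-square over 0.4549364."""
    p = np.asarray(p, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no p-values")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def _nan_effects() -> dict[str, float]:
    return {
        k: math.nan
        for k in (
            "rr_single",
            "ci_lo_single",
            "ci_hi_single",
            "p_single",
            "rr_double",
            "ci_lo_double",
            "ci_hi_double",
            "p_double",
            "rr_int",
            "ci_lo_int",
            "ci_hi_int",
            "p_int",
        )
    }


def _fit_one(table: CountTable, design) -> tuple[dict[str, float], str]:
    values = _nan_effects()
    if table.n_total <= 0:
        return values, "no-data"
    try:
        if table.n_md or table.n_fd:
            fit = fit_with_missing(table, design)
        else:
            fit = fit_complete(table.triad, design)
    except (ValueError, np.linalg.LinAlgError) as exc:
        logger.warning("fit failed: %s", exc)
        return values, "failed"
    if fit.covariance is None or not fit.converged:
        return values, fit.status
    eff = wald_effects(fit)
    if eff.rr_fetal_single is not None:
        e = eff.rr_fetal_single
        values.update(
            rr_single=e.estimate, ci_lo_single=e.ci_low, ci_hi_single=e.ci_high, p_single=e.p
        )
    if eff.rr_fetal_double is not None:
        e = eff.rr_fetal_double
        values.update(
            rr_double=e.estimate, ci_lo_double=e.ci_low, ci_hi_double=e.ci_high, p_double=e.p
        )
    if eff.rr_interaction is not None:
        e = eff.rr_interaction
        values.update(rr_int=e.estimate, ci_lo_int=e.ci_low, ci_hi_int=e.ci_high, p_int=e.p)
    return values, fit.status


def scan_genotypes(
    doses: np.ndarray,
    bim: pd.DataFrame,
    index: PedigreeIndex,
    spec: ModelSpec,
    min_maf: float = 0.01,
) -> pd.DataFrame:
    """Per-SNP joint-model scan over an (n_snps, n_individuals) dose matrix.

    ``doses`` count the bim A1 allele with -1 for missing; the effect allele
    is re-oriented per SNP to the minor allele among genotyped parents
    (ties kept at A1 with a warning).  SNPs below ``min_maf`` or with no
    genotyped parents are excluded.  Output rows follow ``SCAN_COLUMNS``
    (q-value columns filled across the retained SNPs at the end).
    """
    design = build_design(spec)
    mother_rows = sorted({u.mother_row for u in index.units if u.mother_row is not None})
    father_rows = sorted({u.father_row for u in index.units if u.father_row is not None})
    parent_rows = np.array(mother_rows + father_rows, dtype=int)

    m_rows = np.array([-1 if u.mother_row is None else u.mother_row for u in index.units])
    f_rows = np.array([-1 if u.father_row is None else u.father_row for u in index.units])
    c_rows = np.array([u.child_row for u in index.units])

    rows = []
    for s in range(doses.shape[0]):
        snp = doses[s].astype(float)
        snp[snp < 0] = np.nan
        pdose = snp[parent_rows]
        genotyped = ~np.isnan(pdose)
        if not genotyped.any():
            logger.info("SNP %s: all parents missing, excluded", bim["snp"].iat[s])
            continue
        freq_a1 = float(np.nansum(pdose) / (2.0 * genotyped.sum()))
        maf = min(freq_a1, 1.0 - freq_a1)
        if maf < min_maf:
            continue
        if freq_a1 <= 0.5:
            effect, ref = bim["a1"].iat[s], bim["a2"].iat[s]
            oriented = snp
            if freq_a1 == 0.5:
                logger.warning(
                    "SNP %s: allele frequencies tied at 0.5; keeping bim A1 "
                    "as effect allele",
                    bim["snp"].iat[s],
                )
        else:
            effect, ref = bim["a2"].iat[s], bim["a1"].iat[s]
            oriented = 2.0 - snp

        po = oriented[parent_rows]
        hwe = hwe_test(
            float(np.nansum(po == 0)), float(np.nansum(po == 1)), float(np.nansum(po == 2))
        )

        g_m = np.where(m_rows >= 0, oriented[np.maximum(m_rows, 0)], np.nan)
        g_f = np.where(f_rows >= 0, oriented[np.maximum(f_rows, 0)], np.nan)
        g_c = oriented[c_rows]
        table = tabulate_doses(g_m, g_f, g_c)

        values, status = _fit_one(table, design)
        row = {
            "snp": bim["snp"].iat[s],
            "chr": bim["chrom"].iat[s],
            "pos": int(bim["pos"].iat[s]),
            "effect_allele": effect,
            "ref_allele": ref,
            "maf": maf,
            "n_triads": int(table.n_triads),
            "n_md": int(table.n_md),
            "n_fd": int(table.n_fd),
            "n_mendel_err": int(table.n_mendel_errors),
            **values,
            "hwe_p": hwe.p,
            "status": status,
        }
        rows.append(row)

    out = pd.DataFrame(rows, columns=SCAN_COLUMNS)
    if len(out):
        out["q_single"] = bh_qvalues(out["p_single"].to_numpy())
        out["q_int"] = bh_qvalues(out["p_int"].to_numpy())
    return out


def scan_plink(
    bed_path,
    bim_path,
    fam_path,
    spec: ModelSpec,
    min_maf: float = 0.01,
) -> pd.DataFrame:
    """Scan a PLINK 1 bed/bim/fam fileset (see :func:`scan_genotypes`)."""
    fam = read_fam(fam_path)
    bim = read_bim(bim_path)
    doses = read_bed(bed_path, n_individuals=len(fam), n_snps=len(bim))
    index = build_pedigree_index(fam)
    if index.n_dropped:
        logger.warning("%d children had no genotyped parent and were dropped", index.n_dropped)
    return scan_genotypes(doses, bim, index, spec, min_maf=min_maf)


def scan_dose_table(
    table: pd.DataFrame, spec: ModelSpec, min_maf: float = 0.01
) -> pd.DataFrame:
    """Scan a long-format per-family dose table (datasets.DOSE_COLUMNS)."""
    design = build_design(spec)
    rows = []
    for snp, group in table.groupby("snp", sort=True):
        g_m = group["g_m"].to_numpy(dtype=float)
        g_f = group["g_f"].to_numpy(dtype=float)
        g_c = group["g_c"].to_numpy(dtype=float)
        pdose = np.concatenate([g_m[~np.isnan(g_m)], g_f[~np.isnan(g_f)]])
        if pdose.size == 0:
            continue
        freq = pdose.sum() / (2.0 * pdose.size)
        maf = min(freq, 1.0 - freq)
        if maf < min_maf:
            continue
        if freq > 0.5:  # orient to the minor allele
            g_m, g_f, g_c, pdose = 2 - g_m, 2 - g_f, 2 - g_c, 2 - pdose
            effect, ref = "ref", "alt"
        else:
            effect, ref = "alt", "ref"
        hwe = hwe_test(
            float((pdose == 0).sum()), float((pdose == 1).sum()), float((pdose == 2).sum())
        )
        ct = tabulate_doses(g_m, g_f, g_c)
        values, status = _fit_one(ct, design)
        rows.append(
            {
                "snp": snp,
                "chr": group["chrom"].iat[0],
                "pos": int(group["pos"].iat[0]),
                "effect_allele": effect,
                "ref_allele": ref,
                "maf": maf,
                "n_triads": int(ct.n_triads),
                "n_md": int(ct.n_md),
                "n_fd": int(ct.n_fd),
                "n_mendel_err": int(ct.n_mendel_errors),
                **values,
                "hwe_p": hwe.p,
                "status": status,
            }
        )
    out = pd.DataFrame(rows, columns=SCAN_COLUMNS)
    if len(out):
        out["q_single"] = bh_qvalues(out["p_single"].to_numpy())
        out["q_int"] = bh_qvalues(out["p_int"].to_numpy())
    return out


def write_results(results: pd.DataFrame, path) -> None:
    """Write scan rows as TSV with the fixed documented column order."""
    results.loc[:, SCAN_COLUMNS].to_csv(path, sep="\t", index=False)


def qq_table(p: np.ndarray) -> pd.DataFrame:
    """Expected vs observed -log10 p-values, sorted ascending in p."""
    p = np.sort(np.asarray(p, dtype=float)[~np.isnan(np.asarray(p, dtype=float))])
    n = p.size
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)[::-1]
    observed = -np.log10(p)[::-1]
    return pd.DataFrame({"expected_neglog10p": expected, "observed_neglog10p": observed})


def manhattan_table(results: pd.DataFrame, p_column: str = "p_single") -> pd.DataFrame:
    out = results.loc[:, ["chr", "pos"]].copy()
    out["neglog10p"] = -np.log10(results[p_column])
    return out


def export_qq_manhattan_tables(
    results: pd.DataFrame,
    qq_path,
    manhattan_path: Optional[object] = None,
    p_column: str = "p_single",
) -> None:
    """Write plot-ready QQ (and optionally Manhattan) tables as TSV."""
    qq_table(results[p_column].to_numpy()).to_csv(qq_path, sep="\t", index=False)
    if manhattan_path is not None:
        ok = results[p_column].notna()
        manhattan_table(results[ok], p_column).to_csv(manhattan_path, sep="\t", index=False)
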