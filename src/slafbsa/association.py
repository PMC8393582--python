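"""Allele-frequency contrast testing between the two extreme bulks.

Each filtered locus contributes a 2x2 table of focal-allele read depths,
bulk {HEBV, LEBV} x allele {ref, alt}.  Pearson's chi-square (1 df, no
continuity correction) tests for an allele-frequency difference; raw
p-values are adjusted by Benjamini-Hochberg FDR and Bonferroni, and
candidates are taken either as the Bonferroni survivors at the 5%
family-wise level or as the top-k smallest p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class AlleleCountTable:
    """2x2 focal-allele depths for one locus: rows HEBV/LEBV, cols ref/alt."""

    locus_id: str
    counts: tuple[tuple[float, float], tuple[float, float]]


def chi_square_bulk_test(table: AlleleCountTable | np.ndarray) -> tuple[float, float]:
    """Pearson chi-square (1 df, no Yates correction) on a 2x2 depth table.

    Returns ``(chi2, p)``.  A monomorphic locus (a zero allele column) is
    not testable and yields ``(nan, nan)``; a bulk with zero total depth
    raises.
    """
    counts = np.asarray(table.counts if isinstance(table, AlleleCountTable) else table, float)
    if counts.shape != (2, 2) or np.any(counts < 0):
        raise ValueError("expected a non-negative 2x2 table")
    if np.any(counts.sum(axis=1) <= 0):
        raise ValueError("both bulks need positive total depth")
    if np.any(counts.sum(axis=0) <= 0):
        return (np.nan, np.nan)
    n = counts.sum()
    (a, b), (c, d) = counts
    chi2 = n * (a * d - b * c) ** 2 / (
        (a + b) * (c + d) * (a + c) * (b + d)
    )
    return (float(chi2), float(stats.chi2.sf(chi2, df=1)))


def screen_bulk_loci(scored: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Chi-square screen over a scored locus table (vectorised).

    ``scored`` must carry ``locus_id, m_H, p_H, m_L, p_L`` (focal-allele
    depths from the scoring stage).  Returns a table with ``chi2, p_raw,
    p_fdr, p_bonf, rank`` sorted by ``(p_raw, locus_id)``; non-testable
    loci (monomorphic across bulks) are dropped.
    """
    m_h = scored["m_H"].to_numpy(float)
    p_h = scored["p_H"].to_numpy(float)
    m_l = scored["m_L"].to_numpy(float)
    p_l = scored["p_L"].to_numpy(float)
    row_h = m_h + p_h
    row_l = m_l + p_l
    col_ref = p_h + p_l
    col_alt = m_h + m_l
    testable = (row_h > 0) & (row_l > 0) & (col_ref > 0) & (col_alt > 0)
    n = row_h + row_l
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = n * (p_h * m_l - m_h * p_l) ** 2 / (row_h * row_l * col_ref * col_alt)
    p_raw = stats.chi2.sf(chi2, df=1)

    out = scored.loc[testable, ["locus_id"]].copy()
    out["chi2"] = chi2[testable]
    out["p_raw"] = p_raw[testable]
    out["p_fdr"] = adjust_pvalues(out["p_raw"].to_numpy(), "fdr")
    out["p_bonf"] = adjust_pvalues(out["p_raw"].to_numpy(), "bonferroni")
    out = out.sort_values(["p_raw", "locus_id"], kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def adjust_pvalues(p_raw: np.ndarray | list[float], method: str) -> np.ndarray:
    """Multiplicity adjustment, preserving input order.

    ``method`` is ``"fdr"`` (Benjamini-Hochberg step-up with monotonicity
    enforcement) or ``"bonferroni"`` (``min(1, m * p)``).
    """
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    name = {"fdr": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if name is None:
        raise ValueError(f"unknown method {method!r}")
    return multipletests(p, method=name)[1]


def select_candidates(
    results: pd.DataFrame,
    stage: str = "bonferroni_hits",
    k: int = 31,
    alpha: float = 0.05,
) -> list[str]:
    """Staged candidate selection from a ranked association table.

    ``bonferroni_hits`` returns loci with ``p_bonf < alpha``; ``top_k``
    the ``k`` smallest raw p-values (ties broken by locus_id).  Asking for
    more loci than are testable returns all of them with a warning.
    """
    ranked = results.sort_values(["p_raw", "locus_id"], kind="mergesort")
    if stage == "bonferroni_hits":
        return ranked.loc[ranked["p_bonf"] < alpha, "locus_id"].tolist()
    if stage == "top_k":
        if k > len(ranked):
            warnings.warn(
                f"requested top {k} of only {len(ranked)} testable loci",
                stacklevel=2,
            )
        return ranked["locus_id"].head(k).tolist()
    raise ValueError(f"unknown selection stage {stage!r}")
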