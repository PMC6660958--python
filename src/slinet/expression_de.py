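"""Paired tumor/normal differential expression and the unpaired pan-cancer mode.

The paired design compares, per gene, tumor against matched normal tissue
from the same patients (RSEM gene-normalized RNA-seq values, non-negative
continuous). The analysis chain is:

1. zero filter — a gene is analyzed only if every tumor and every normal
   value is strictly positive (zeros mean missing transcripts, not biology);
2. Shapiro-Wilk normality summary per tissue (diagnostic only — the pipeline
   uses the rank test regardless);
3. two-sided Wilcoxon signed-rank test on the paired values;
4. Benjamini-Hochberg step-up adjustment across all tested genes;
5. fold change as the mean over patients of log2(tumor/normal) — the mean of
   per-patient log2 ratios, not the log2 of a ratio of means;
6. regulation calls: down iff mean log2 ratio <= -1 and adjusted P < 0.05
   (2-fold cutoff), symmetrically for up.

The unpaired mode (independent tumor and normal cohorts, e.g. other cancer
types) uses a two-sided Mann-Whitney U test per gene with the direction
taken from the group medians.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PairedExpressionData",
    "WilcoxonOutcome",
    "NormalitySummary",
    "filter_nonzero",
    "normality_summary",
    "paired_wilcoxon",
    "bh_adjust",
    "fold_change",
    "differential_expression",
    "call_regulation",
    "unpaired_compare",
    "pan_cancer_profile",
]

logger = logging.getLogger(__name__)

STATUS_DOWN = "down"
STATUS_UP = "up"
STATUS_NS = "ns"
STATUS_FILTERED = "filtered_zero"

# Exhaustive sign-flip enumeration is used up to this effective n; beyond it
# the exact no-ties distribution (n <= 25) or the continuity-corrected normal
# approximation applies.
_ENUM_MAX_N = 13
_EXACT_MAX_N = 25


@dataclass(frozen=True)
class PairedExpressionData:
    """Aligned tumor and normal expression matrices (genes x patients)."""

    tumor: pd.DataFrame
    normal: pd.DataFrame

    def __post_init__(self) -> None:
        if self.tumor.shape != self.normal.shape:
            raise ValueError("tumor and normal matrices must have identical shape")
        if not self.tumor.index.equals(self.normal.index):
            raise ValueError("gene indices differ between tumor and normal")
        if not self.tumor.columns.equals(self.normal.columns):
            raise ValueError("patient columns differ between tumor and normal")
        if self.tumor.columns.has_duplicates or self.tumor.index.has_duplicates:
            raise ValueError("gene and patient identifiers must be unique")
        for name, mat in (("tumor", self.tumor), ("normal", self.normal)):
            values = mat.to_numpy()
            if not np.isfinite(values).all() or (values < 0).any():
                raise ValueError(f"{name} matrix must be non-negative and finite")

    @property
    def genes(self) -> list[str]:
        return list(self.tumor.index)

    @property
    def patients(self) -> list[str]:
        return list(self.tumor.columns)

    @property
    def n_patients(self) -> int:
        return self.tumor.shape[1]


def filter_nonzero(data: PairedExpressionData) -> tuple[PairedExpressionData, list[str]]:
    """Drop genes with any zero value in either tissue.

    A gene is kept iff every tumor AND every normal value is > 0. Returns the
    reduced data and the list of removed gene symbols (order of appearance).
    """
    keep = (data.tumor > 0).all(axis=1) & (data.normal > 0).all(axis=1)
    removed = list(data.tumor.index[~keep])
    kept = PairedExpressionData(
        tumor=data.tumor.loc[keep], normal=data.normal.loc[keep]
    )
    logger.info("filter_nonzero: kept %d genes, removed %d", len(kept.genes), len(removed))
    return kept, removed


class NormalitySummary(NamedTuple):
    frac_normal_tumor: float
    frac_normal_normal: float
    n_indeterminate_tumor: int
    n_indeterminate_normal: int


def normality_summary(data: PairedExpressionData, alpha: float = 0.05) -> NormalitySummary:
    """Fraction of genes whose per-tissue values pass Shapiro-Wilk at ``alpha``.

    A gene passes when the test does not reject normality (P > alpha).
    Constant vectors are indeterminate and excluded from the fraction's
    denominator. Diagnostic only: the result never gates the pipeline.
    """
    if data.n_patients < 3:
        raise ValueError("normality test requires at least 3 patients")
    fracs = []
    indets = []
    for mat in (data.tumor, data.normal):
        n_pass = 0
        n_indet = 0
        for row in mat.to_numpy():
            if np.ptp(row) == 0:
                n_indet += 1
                continue
            if stats.shapiro(row).pvalue > alpha:
                n_pass += 1
        denom = mat.shape[0] - n_indet
        fracs.append(n_pass / denom if denom else float("nan"))
        indets.append(n_indet)
    return NormalitySummary(fracs[0], fracs[1], indets[0], indets[1])


class WilcoxonOutcome(NamedTuple):
    p_value: float
    n_effective: int
    degenerate: bool


def paired_wilcoxon(
    tumor_row: Sequence[float], normal_row: Sequence[float]
) -> WilcoxonOutcome:
    """Two-sided Wilcoxon signed-rank test on one gene's paired values.

    Zero differences are dropped before ranking (classic Wilcoxon). The null
    distribution is exhausted exactly for small effective n (sign-flip
    enumeration when ties are present, the standard exact distribution when
    not, up to n=25); larger samples use the normal approximation with
    continuity correction. All differences zero is a degenerate case: P = 1
    with the ``degenerate`` flag set.
    """
    t = np.asarray(tumor_row, dtype=float)
    n = np.asarray(normal_row, dtype=float)
    if t.shape != n.shape or t.ndim != 1:
        raise ValueError("rows must be 1-D and of equal length")
    if t.size < 2:
        raise ValueError("paired test requires at least 2 patients")
    d = t - n
    d = d[d != 0]
    n_eff = d.size
    if n_eff == 0:
        return WilcoxonOutcome(1.0, 0, True)
    has_ties = np.unique(np.abs(d)).size < n_eff
    if n_eff <= _ENUM_MAX_N:
        # PermutationMethod with n_resamples >= 2**n_eff enumerates all sign
        # assignments exactly; midranks handle ties correctly.
        method = stats.PermutationMethod(n_resamples=1 << _ENUM_MAX_N)
        res = stats.wilcoxon(d, alternative="two-sided", method=method)
    elif n_eff <= _EXACT_MAX_N and not has_ties:
        res = stats.wilcoxon(d, alternative="two-sided", method="exact")
    else:
        res = stats.wilcoxon(
            d, alternative="two-sided", method="approx", correction=True
        )
    return WilcoxonOutcome(float(res.pvalue), int(n_eff), False)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values, original order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(tumor_row: Sequence[float], normal_row: Sequence[float]) -> float:
    """Mean over patients of log2(tumor/normal).

    Requires strictly positive values (the zero filter must already have
    run); the mean of per-patient log2 ratios, not the log2 of the ratio of
    means.
    """
    t = np.asarray(tumor_row, dtype=float)
    n = np.asarray(normal_row, dtype=float)
    if t.shape != n.shape:
        raise ValueError("rows must have equal length")
    if (t <= 0).any() or (n <= 0).any():
        raise ValueError("fold change requires strictly positive values (zero filter violated)")
    return float(np.mean(np.log2(t / n)))


def differential_expression(
    data: PairedExpressionData,
    alpha: float = 0.05,
    fc_cut_log2: float = 1.0,
    shapiro_alpha: float = 0.05,
    run_normality: bool = True,
) -> pd.DataFrame:
    """Run the full paired chain: zero filter, test, BH, fold change, calls.

    Returns one row per input gene with columns ``gene``, ``n``,
    ``mean_log2_ratio``, ``p_raw``, ``p_adj``, ``normal_tumor``,
    ``normal_normal``, ``degenerate``, ``status``. Genes removed by the zero
    filter get status ``filtered_zero`` and NaN statistics. BH is applied
    once across all genes surviving the filter.
    """
    kept, removed = filter_nonzero(data)
    rows = []
    tumor = kept.tumor.to_numpy()
    normal = kept.normal.to_numpy()
    for i, gene in enumerate(kept.genes):
        t, n = tumor[i], normal[i]
        outcome = paired_wilcoxon(t, n)
        norm_t = norm_n = None
        if run_normality and t.size >= 3:
            norm_t = bool(np.ptp(t) > 0 and stats.shapiro(t).pvalue > shapiro_alpha)
            norm_n = bool(np.ptp(n) > 0 and stats.shapiro(n).pvalue > shapiro_alpha)
        rows.append(
            {
                "gene": gene,
                "n": t.size,
                "mean_log2_ratio": fold_change(t, n),
                "p_raw": outcome.p_value,
                "normal_tumor": norm_t,
                "normal_normal": norm_n,
                "degenerate": outcome.degenerate,
            }
        )
    results = pd.DataFrame(
        rows,
        columns=[
            "gene", "n", "mean_log2_ratio", "p_raw",
            "normal_tumor", "normal_normal", "degenerate",
        ],
    )
    results["p_adj"] = bh_adjust(results["p_raw"]) if len(results) else []
    results = call_regulation(results, fc_cut_log2=fc_cut_log2, alpha=alpha)
    if removed:
        filtered = pd.DataFrame({"gene": removed})
        filtered["status"] = STATUS_FILTERED
        results = pd.concat([results, filtered], ignore_index=True)
    return results


def call_regulation(
    results: pd.DataFrame, fc_cut_log2: float = 1.0, alpha: float = 0.05
) -> pd.DataFrame:
    """Assign down/up/ns status from mean log2 ratio and adjusted P.

    down iff mean_log2_ratio <= -fc_cut_log2 and p_adj < alpha; up
    symmetrically; everything else ns. Rows without a ``p_adj`` (e.g.
    zero-filtered) keep their existing status.
    """
    results = results.copy()
    tested = results["p_adj"].notna()
    sig = tested & (results["p_adj"] < alpha)
    down = sig & (results["mean_log2_ratio"] <= -fc_cut_log2)
    up = sig & (results["mean_log2_ratio"] >= fc_cut_log2)
    status = results.get("status", pd.Series(STATUS_NS, index=results.index)).copy()
    status[tested] = STATUS_NS
    status[down] = STATUS_DOWN
    status[up] = STATUS_UP
    results["status"] = status
    return results


def unpaired_compare(
    tumor_matrix: pd.DataFrame, normal_matrix: pd.DataFrame
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per gene between independent cohorts.

    The cohorts need not align on samples but must share the gene index.
    Direction is the sign of (median tumor - median normal): ``down``, ``up``
    or ``none``. A gene constant across both groups gets P = 1.
    """
    if not tumor_matrix.index.equals(normal_matrix.index):
        raise ValueError("gene indices must match")
    if tumor_matrix.shape[1] < 2 or normal_matrix.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    rows = []
    for gene in tumor_matrix.index:
        t = tumor_matrix.loc[gene].to_numpy(dtype=float)
        n = normal_matrix.loc[gene].to_numpy(dtype=float)
        pooled = np.concatenate([t, n])
        if np.ptp(pooled) == 0:
            rows.append({"gene": gene, "p_value": 1.0, "direction": "none"})
            continue
        p = _mannwhitney_p(t, n)
        diff = np.median(t) - np.median(n)
        direction = "down" if diff < 0 else ("up" if diff > 0 else "none")
        rows.append({"gene": gene, "p_value": p, "direction": direction})
    return pd.DataFrame(rows).set_index("gene")


def _mannwhitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney p: exact for small tie-free groups, else normal."""
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.size <= 8 and y.size <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        stats.mannwhitneyu(
            x, y, alternative="two-sided", method=method, use_continuity=True
        ).pvalue
    )


def pan_cancer_profile(
    per_cancer_results: Mapping[str, pd.DataFrame],
    gene_panel: Iterable[str],
    min_down: int = 8,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.Series]:
    """Which cancer types share the panel's down-regulation signature.

    ``per_cancer_results`` maps cancer type -> the :func:`unpaired_compare`
    output for that type. A panel gene counts as down in a cancer when its P
    is below ``alpha`` with direction ``down``. A cancer type is included iff
    at least ``min_down`` panel genes are down (default 8, i.e. strictly more
    than 7 of a 15-gene panel). Returns the per-gene x per-cancer call
    matrix (entries down/up/ns) and a boolean inclusion Series per cancer.
    """
    panel = list(gene_panel)
    calls = {}
    for cancer, res in per_cancer_results.items():
        col = []
        for gene in panel:
            if gene not in res.index:
                col.append(STATUS_NS)
                continue
            row = res.loc[gene]
            if row["p_value"] < alpha and row["direction"] in ("down", "up"):
                col.append(row["direction"])
            else:
                col.append(STATUS_NS)
        calls[cancer] = col
    matrix = pd.DataFrame(calls, index=panel)
    included = (matrix == STATUS_DOWN).sum(axis=0) >= min_down
    return matrix, included
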