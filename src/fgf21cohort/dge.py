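"""Cohort differential expression: Wilcoxon-Mann-Whitney, BH-FDR, DEG calls.

A gene is a DEG for a cohort contrast when its BH-adjusted rank-sum p is
< .05 and the magnitude of the cohort signed fold change (median patient
value against the control reference) is >= 1.5.  Per-patient direction
concordance then measures, for each cohort DEG, the fraction of that
cohort's patients whose individual direction call matches the cohort-level
DEG sign.

The rank-sum test uses mid-ranks for ties.  For small samples
(n_a + n_b <= 12) the two-sided p comes from exact enumeration of all
C(n, n_a) assignments of the pooled mid-ranks, which remains valid under
ties; larger samples use the tie-corrected normal approximation with
continuity correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb, erf, sqrt

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from fgf21cohort.stratify import ControlReference, signed_fc

logger = logging.getLogger("fgf21cohort")

EXACT_MAX_N = 12
DEG_Q_THRESHOLD = 0.05
DEG_FC_THRESHOLD = 1.5


def rank_sum_test(group_a, group_b) -> tuple[float, float]:
    """Mann-Whitney U of ``group_a`` and the two-sided p value.

    Exact enumeration for n_a + n_b <= 12 (counts assignments whose U is at
    least as far from the null mean n_a*n_b/2 as observed); otherwise the
    normal approximation with mid-rank tie correction and continuity
    correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n_a, n_b = len(a), len(b)
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs >= 2 values")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    u_a = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    mu = n_a * n_b / 2

    n = n_a + n_b
    if n <= EXACT_MAX_N:
        obs_dev = abs(u_a - mu)
        total = comb(n, n_a)
        hits = 0
        offset = n_a * (n_a + 1) / 2
        for idx in combinations(range(n), n_a):
            u = ranks[list(idx)].sum() - offset
            if abs(u - mu) >= obs_dev - 1e-12:
                hits += 1
        return float(u_a), hits / total

    # tie-corrected normal approximation
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum()
    sigma2 = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return float(u_a), 1.0
    diff = u_a - mu
    cc = 0.5 if diff != 0 else 0.0
    z = (abs(diff) - cc) / sqrt(sigma2)
    z = max(z, 0.0)
    p = 2.0 * 0.5 * (1.0 - erf(z / sqrt(2.0)))
    return float(u_a), min(p, 1.0)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q values, order-preserving with input."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ConcordanceSummary:
    """Direction concordance of per-patient calls with cohort-level DEGs."""

    cohort: str
    per_gene: pd.Series          # DEG gene -> fraction of patients matching sign
    summary: float               # fraction of DEGs with per-gene concordance > 0.5
    n_degs: int


def call_degs(expression: pd.DataFrame, meta: pd.DataFrame, cohort_samples,
              reference: ControlReference, cohort_id: str = "cohort",
              q_threshold: float = DEG_Q_THRESHOLD,
              fc_threshold: float = DEG_FC_THRESHOLD) -> pd.DataFrame:
    """Per-gene DEG table for one cohort-vs-controls contrast.

    Columns: gene_id, cohort, statistic (Mann-Whitney U of the cohort),
    signed_fc (cohort median vs control reference), p, q, is_deg.
    """
    cohort_samples = [s for s in cohort_samples if s in expression.columns]
    if len(cohort_samples) < 2:
        raise ValueError("cohort must contain >= 2 patients")
    controls = [s for s in meta.index[meta["group"] == "control"]
                if s in expression.columns]
    genes = reference.values.index.intersection(expression.index)
    cohort_vals = expression.loc[genes, cohort_samples].to_numpy()
    control_vals = expression.loc[genes, controls].to_numpy()

    stats = np.empty(len(genes))
    pvals = np.empty(len(genes))
    for i in range(len(genes)):
        stats[i], pvals[i] = rank_sum_test(cohort_vals[i], control_vals[i])

    medians = np.median(cohort_vals, axis=1)
    fcs = signed_fc(medians, reference.values[genes].to_numpy())
    qvals = bh_fdr(pvals)
    is_deg = (qvals < q_threshold) & (np.abs(fcs) >= fc_threshold)

    return pd.DataFrame(
        {
            "gene_id": genes,
            "cohort": cohort_id,
            "statistic": stats,
            "signed_fc": fcs,
            "p": pvals,
            "q": qvals,
            "is_deg": is_deg,
        }
    ).set_index("gene_id", drop=False)


def concordance(deg_table: pd.DataFrame, calls: pd.DataFrame, cohort_samples,
                cohort_id: str = "cohort") -> ConcordanceSummary:
    """Fraction of cohort patients whose direction call matches each DEG's
    cohort-level sign (zero calls count as non-matching); the summary is the
    fraction of DEGs concordant in > 50% of patients."""
    degs = deg_table[deg_table["is_deg"]]
    cohort_samples = [s for s in cohort_samples if s in calls.columns]
    if degs.empty:
        logger.warning("concordance: no DEGs for cohort %s", cohort_id)
        return ConcordanceSummary(cohort=cohort_id,
                                  per_gene=pd.Series(dtype=float),
                                  summary=float("nan"), n_degs=0)
    genes = [g for g in degs["gene_id"] if g in calls.index]
    signs = np.sign(degs.loc[genes, "signed_fc"].to_numpy())[:, None]
    sub = calls.loc[genes, cohort_samples].to_numpy()
    frac = (sub == signs).mean(axis=1)
    per_gene = pd.Series(frac, index=genes, name="concordance")
    return ConcordanceSummary(
        cohort=cohort_id,
        per_gene=per_gene,
        summary=float((per_gene > 0.5).mean()),
        n_degs=len(genes),
    )
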