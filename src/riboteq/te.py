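"""Per-gene translational efficiency (TE) and its differential analysis.

TE(g, s) is footprint expression divided by mRNA expression for a paired
(age, replicate) sample.  Age contrasts are summarized as log2 ratios of
geometric-mean TE, tested per gene with a variance-moderated two-sample t on
log2 replicate values (sample variances shrunk toward the across-genes mean
variance with prior weight ``d0``), and FDR-controlled with Benjamini-
Hochberg.  "Significantly decreased" requires both q below the cutoff and a
negative log2 fold change, matching the one-directional nature of a global
translational decline.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import AnalysisError
from .models import (
    ExpressionMatrix,
    STATUS_OK,
    STATUS_RIBO_ZERO,
    STATUS_RNA_ZERO,
    TETable,
)

DEFAULT_D0 = 4.0


def translational_efficiency(ribo: ExpressionMatrix, rna: ExpressionMatrix) -> TETable:
    """Per-sample TE = ribo / rna over paired (age, replicate) samples.

    Genes with zero RNA expression in any paired sample are flagged
    ``undefined_rna_zero`` (zero footprint: ``undefined_ribo_zero``) and are
    excluded from downstream testing; the counts are reported in the table.
    """
    if set(ribo.values.index) != set(rna.values.index):
        only_ribo = set(ribo.values.index) - set(rna.values.index)
        only_rna = set(rna.values.index) - set(ribo.values.index)
        raise AnalysisError(
            f"gene sets differ (ribo-only {len(only_ribo)}, rna-only {len(only_rna)})"
        )
    ribo_pairs = {
        (row["age"], row["replicate"]): s for s, row in ribo.samples.iterrows()
    }
    rna_pairs = {
        (row["age"], row["replicate"]): s for s, row in rna.samples.iterrows()
    }
    orphans = set(ribo_pairs) ^ set(rna_pairs)
    if orphans:
        raise AnalysisError(f"unpaired (age, replicate) samples: {sorted(orphans)}")

    keys = sorted(rna_pairs)
    cols, meta = [], []
    te_cols = {}
    rna_vals = rna.values.reindex(ribo.values.index)
    for age, rep in keys:
        label = f"{age}_rep{rep}"
        r = ribo.values[ribo_pairs[(age, rep)]].to_numpy(dtype=float)
        m = rna_vals[rna_pairs[(age, rep)]].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            te_cols[label] = np.where(m > 0, r / np.where(m > 0, m, 1.0), np.nan)
        cols.append(label)
        meta.append((age, rep))
    te = pd.DataFrame(te_cols, index=ribo.values.index)
    pairs = pd.DataFrame(meta, index=cols, columns=["age", "replicate"])

    rna_zero = (rna_vals[[rna_pairs[k] for k in keys]] <= 0).any(axis=1)
    ribo_zero = (ribo.values[[ribo_pairs[k] for k in keys]] <= 0).any(axis=1)
    status = pd.Series(STATUS_OK, index=te.index)
    status[ribo_zero.to_numpy()] = STATUS_RIBO_ZERO
    status[rna_zero.to_numpy()] = STATUS_RNA_ZERO  # rna flag wins if both
    table = pd.DataFrame({"status": status})
    table.index.name = "gene_id"
    return TETable(te=te, pairs=pairs, table=table)


def te_change(tetable: TETable) -> TETable:
    """Fill per-age geometric-mean TE and log2 fold changes vs young."""
    ages = sorted(set(tetable.pairs["age"]))
    if "young" not in ages:
        raise AnalysisError("missing age group 'young'")
    ok = tetable.table["status"] == STATUS_OK
    for age in ("young", "mid", "old"):
        cols = tetable.columns_for(age)
        if not cols:
            continue
        vals = tetable.te.loc[ok.to_numpy(), cols].to_numpy(dtype=float)
        gm = np.exp(np.log(vals).mean(axis=1))
        tetable.table[f"te_{age}"] = np.nan
        tetable.table.loc[ok, f"te_{age}"] = gm
    for age in ("mid", "old"):
        if f"te_{age}" in tetable.table:
            tetable.table[f"log2fc_{age}"] = np.log2(
                tetable.table[f"te_{age}"] / tetable.table["te_young"]
            )
    if "log2fc_old" not in tetable.table:
        raise AnalysisError("missing age group 'old'")
    return tetable


def moderated_ttest(
    a: np.ndarray, b: np.ndarray, d0: float = DEFAULT_D0
) -> pd.DataFrame:
    """Row-wise moderated two-sample t-test (a minus b).

    Per-row pooled variances are shrunk toward their across-rows mean with
    prior weight ``d0``; the statistic is referred to a t distribution with
    ``d0 + n_a + n_b - 2`` degrees of freedom.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise AnalysisError("moderated t-test needs >= 2 replicates per group")
    d = n1 + n2 - 2
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    s2 = ((n1 - 1) * var_a + (n2 - 1) * var_b) / d
    s0_sq = float(np.nanmean(s2))
    if s0_sq == 0:
        raise AnalysisError("all per-gene variances are zero; nothing to moderate")
    s2_mod = (d0 * s0_sq + d * s2) / (d0 + d)
    diff = a.mean(axis=1) - b.mean(axis=1)
    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    t = diff / se
    p = 2.0 * stats.t.sf(np.abs(t), df=d0 + d)
    return pd.DataFrame({"diff": diff, "t": t, "p": p})


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(pvalues, method="fdr_bh")[1]


def differential_te(
    tetable: TETable,
    alpha: float = 0.05,
    d0: float = DEFAULT_D0,
    moderated: bool = True,
) -> TETable:
    """Old-vs-young moderated test on log2 TE replicate values, BH-corrected.

    Fills ``p``, ``q`` and ``significant_decrease`` (q < alpha AND negative
    log2 fold change) across the ``ok`` gene universe.
    """
    if not 0 < alpha < 1:
        raise AnalysisError(f"alpha must be in (0, 1), got {alpha}")
    young_cols = tetable.columns_for("young")
    old_cols = tetable.columns_for("old")
    if len(young_cols) < 2 or len(old_cols) < 2:
        raise AnalysisError("differential TE needs >= 2 replicates per age group")
    ok = (tetable.table["status"] == STATUS_OK).to_numpy()
    log_old = np.log2(tetable.te.loc[ok, old_cols].to_numpy(dtype=float))
    log_young = np.log2(tetable.te.loc[ok, young_cols].to_numpy(dtype=float))
    if moderated:
        res = moderated_ttest(log_old, log_young, d0=d0)
    else:
        t, p = stats.ttest_ind(log_old, log_young, axis=1, equal_var=False)
        res = pd.DataFrame(
            {"diff": log_old.mean(axis=1) - log_young.mean(axis=1), "t": t, "p": p}
        )
    tetable.table["p"] = np.nan
    tetable.table["q"] = np.nan
    tetable.table.loc[ok, "p"] = res["p"].to_numpy()
    tetable.table.loc[ok, "q"] = bh_qvalues(res["p"].to_numpy())
    if "log2fc_old" not in tetable.table:
        te_change(tetable)
    tetable.table["significant_decrease"] = (
        (tetable.table["q"] < alpha) & (tetable.table["log2fc_old"] < 0)
    ).fillna(False)
    return tetable


def rank_genes(tetable: TETable) -> TETable:
    """Rank ``ok`` genes by ascending old/young log2 TE change (most reduced
    first); ties break lexicographically by gene id."""
    if "log2fc_old" not in tetable.table:
        raise AnalysisError("log2 fold changes not filled; run te_change first")
    ok = tetable.table["status"] == STATUS_OK
    sub = tetable.table.loc[ok, ["log2fc_old"]].copy()
    sub["_gid"] = sub.index
    order = sub.sort_values(["log2fc_old", "_gid"], kind="stable").index
    tetable.table["rank"] = np.nan
    tetable.table.loc[order, "rank"] = np.arange(1, len(order) + 1)
    return tetable


def differential_expression(
    expr: ExpressionMatrix,
    age_a: str = "old",
    age_b: str = "young",
    assay: str | None = None,
    alpha: float = 0.05,
    d0: float = DEFAULT_D0,
) -> pd.DataFrame:
    """Per-gene moderated test on log2 expression between two age groups.

    Used for transcript-level (RNA) contrasts such as the ribosomal-protein
    class; genes with zero expression in a used sample are excluded (flagged
    in the returned ``status``).
    """
    meta = expr.samples
    cols_a = [s for s, r in meta.iterrows()
              if r["age"] == age_a and (assay is None or r["assay"] == assay)]
    cols_b = [s for s, r in meta.iterrows()
              if r["age"] == age_b and (assay is None or r["assay"] == assay)]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise AnalysisError("differential expression needs >= 2 replicates per group")
    vals_a = expr.values[cols_a]
    vals_b = expr.values[cols_b]
    ok = ((vals_a > 0).all(axis=1) & (vals_b > 0).all(axis=1)).to_numpy()
    res = moderated_ttest(
        np.log2(vals_a.to_numpy(dtype=float)[ok]),
        np.log2(vals_b.to_numpy(dtype=float)[ok]),
        d0=d0,
    )
    out = pd.DataFrame(index=expr.values.index)
    out["status"] = np.where(ok, STATUS_OK, "undefined_zero")
    out["log2fc"] = np.nan
    out.loc[ok, "log2fc"] = res["diff"].to_numpy()
    out["p"] = np.nan
    out.loc[ok, "p"] = res["p"].to_numpy()
    out["q"] = np.nan
    out.loc[ok, "q"] = bh_qvalues(res["p"].to_numpy())
    out["significant_decrease"] = (
        (out["q"] < alpha) & (out["log2fc"] < 0)
    ).fillna(False)
    return out


_EXACT_ENUMERATION_LIMIT = 20000


def class_change_test(values: pd.Series, class_mask: pd.Series | np.ndarray):
    """Two-sided Wilcoxon rank-sum of a gene class against its complement.

    Exact permutation enumeration when the number of class assignments is
    small enough (covers any total n <= 10); otherwise the tie-corrected
    normal approximation.  Returns (W, p) with W the class rank-sum.
    """
    values = pd.Series(values)
    mask = np.asarray(class_mask, dtype=bool)
    x = values.to_numpy(dtype=float)
    n = len(x)
    n1 = int(mask.sum())
    n2 = n - n1
    if n1 == 0 or n2 == 0:
        raise AnalysisError("class and complement must both be non-empty")
    ranks = stats.rankdata(x, method="average")
    w = float(ranks[mask].sum())
    mu = n1 * (n + 1) / 2.0
    k = min(n1, n2)
    if math.comb(n, k) <= _EXACT_ENUMERATION_LIMIT:
        take = n1 if n1 == k else n2
        dev_obs = abs(w - mu) if take == n1 else abs((ranks.sum() - w) - (n2 * (n + 1) / 2.0))
        mu_take = take * (n + 1) / 2.0
        hits = total = 0
        for combo in itertools.combinations(range(n), take):
            s = sum(ranks[i] for i in combo)
            total += 1
            if abs(s - mu_take) >= dev_obs - 1e-9:
                hits += 1
        return w, hits / total
    # tie-corrected normal approximation
    _, tie_counts = np.unique(x, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return w, 1.0
    z = (w - mu) / math.sqrt(sigma2)
    return w, float(2.0 * stats.norm.sf(abs(z)))


def abundance_effect_correlation(
    young_expression: pd.Series, te_log2fc: pd.Series
) -> tuple[float, pd.DataFrame]:
    """Spearman correlation of log2 young abundance against TE log2 change.

    Returns the correlation and the paired scatter table (genes with
    non-positive abundance or missing values are dropped).
    """
    df = pd.DataFrame({"young": young_expression, "te_log2fc": te_log2fc}).dropna()
    df = df[df["young"] > 0]
    if len(df) < 3:
        raise AnalysisError("need >= 3 matched genes")
    table = pd.DataFrame(
        {"log2_young": np.log2(df["young"]), "te_log2fc": df["te_log2fc"]},
        index=df.index,
    )
    if table["log2_young"].nunique() < 2 or table["te_log2fc"].nunique() < 2:
        raise AnalysisError("correlation undefined for a constant vector")
    rho = stats.spearmanr(table["log2_young"], table["te_log2fc"]).statistic
    return float(rho), table
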