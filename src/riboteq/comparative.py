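"""Cross-dataset and gene-set statistics.

Two TE-change rankings from different experiments are compared by sorting the
matched pairs, averaging consecutive groups (bins of five by default) and
correlating both the binned dots and the raw pairs.  Set overlaps are scored
with the two-sided Fisher exact test (minimum-likelihood convention) and
multi-set enrichment is BH-corrected across sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import AnalysisError


@dataclass
class ComparisonResult:
    binned: pd.DataFrame  # columns x_mean, y_mean; one row per bin
    r_binned: float
    r_unbinned: float
    n_pairs: int
    n_dropped: int
    bin_size: int
    sort_axis: str = "x"
    flags: tuple[str, ...] = ()


@dataclass
class EnrichmentResult:
    name: str
    overlap: int
    expected: float
    odds_ratio: float
    p: float
    q: float | None = None
    table: tuple[tuple[int, int], tuple[int, int]] = ((0, 0), (0, 0))
    or_continuity: bool = False


def binned_correlation(
    x: pd.Series, y: pd.Series, bin_size: int = 5, sort_axis: str = "x"
) -> ComparisonResult:
    """Sort matched pairs, average consecutive groups of ``bin_size``, and
    report Pearson r on both binned and unbinned pairs.

    Pairs missing in either vector are dropped (count reported); the sort key
    is configurable because published binned-dot plots rarely state theirs.
    """
    if bin_size < 1:
        raise AnalysisError("bin_size must be >= 1")
    if sort_axis not in ("x", "y"):
        raise AnalysisError("sort_axis must be 'x' or 'y'")
    df = pd.DataFrame({"x": x, "y": y})
    n_total = len(df)
    df = df.dropna()
    n_dropped = n_total - len(df)
    if len(df) < 2 * bin_size:
        raise AnalysisError(f"need >= {2 * bin_size} matched pairs, have {len(df)}")
    df = df.sort_values([sort_axis, "y" if sort_axis == "x" else "x"], kind="stable")

    flags = []
    if df["x"].nunique() < 2 or df["y"].nunique() < 2:
        flags.append("constant_vector")
        r_unbinned = float("nan")
    else:
        r_unbinned = float(stats.pearsonr(df["x"], df["y"]).statistic)

    groups = np.arange(len(df)) // bin_size
    binned = df.groupby(groups).mean()
    binned.columns = ["x_mean", "y_mean"]
    if binned["x_mean"].nunique() < 2 or binned["y_mean"].nunique() < 2:
        flags.append("constant_binned_vector")
        r_binned = float("nan")
    else:
        r_binned = float(stats.pearsonr(binned["x_mean"], binned["y_mean"]).statistic)
    return ComparisonResult(
        binned=binned.reset_index(drop=True),
        r_binned=r_binned,
        r_unbinned=r_unbinned,
        n_pairs=len(df),
        n_dropped=n_dropped,
        bin_size=bin_size,
        sort_axis=sort_axis,
        flags=tuple(flags),
    )


def overlap_fisher(set_a: set, set_b: set, universe: set,
                   name: str = "overlap") -> EnrichmentResult:
    """Two-sided Fisher exact test of the overlap of two gene sets.

    The 2x2 table counts membership in/out of each set over the universe; the
    odds ratio is the sample (cross-product) ratio, with a Haldane 0.5
    continuity correction applied (and flagged) only when a cell is zero.
    """
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    stray = (set_a | set_b) - universe
    if stray:
        raise AnalysisError(
            f"sets contain ids outside the universe: {sorted(stray)[:5]}"
        )
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if min(a, b, c, d) == 0:
        oddsr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        continuity = True
    else:
        oddsr = (a * d) / (b * c)
        continuity = False
    expected = len(set_a) * len(set_b) / len(universe) if universe else 0.0
    return EnrichmentResult(
        name=name,
        overlap=a,
        expected=float(expected),
        odds_ratio=float(oddsr),
        p=float(min(p, 1.0)),
        table=((a, b), (c, d)),
        or_continuity=continuity,
    )


def set_enrichment(
    query: set, collections: dict[str, set], universe: set
) -> list[EnrichmentResult]:
    """Fisher overlap of a query set against each named collection set,
    BH-corrected across sets, sorted by q ascending then odds ratio descending."""
    if not collections:
        raise AnalysisError("collections must be non-empty")
    results = [
        overlap_fisher(query, members, universe, name=name)
        for name, members in collections.items()
    ]
    qvals = multipletests([r.p for r in results], method="fdr_bh")[1]
    for r, q in zip(results, qvals):
        r.q = float(q)
    results.sort(key=lambda r: (r.q, -r.odds_ratio, r.name))
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set": r.name,
                "overlap": r.overlap,
                "expected": r.expected,
                "odds_ratio": r.odds_ratio,
                "p": r.p,
                "q": r.q,
                "or_continuity": r.or_continuity,
            }
            for r in results
        ]
    ).set_index("set")
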