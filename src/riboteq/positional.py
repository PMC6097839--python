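"""Positional footprint diagnostics.

These operations interrogate where ribosomes sit along ORFs rather than how
many there are: metagene (gene-body-averaged) profiles, pause peaks, start-
proximal enrichment, uORF/main-ORF density ratios, and z-tests comparing
gene-body coverage slopes between conditions.  All scores are ratios of a
common profile and therefore invariant to sequencing depth.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError
from .models import MetageneProfile, PositionalProfile


def metagene_profile(
    profiles: list[PositionalProfile], n_bins: int = 100
) -> MetageneProfile:
    """Average unit-mean, length-rescaled coverage across genes.

    Each gene is scaled to unit mean and linearly interpolated onto ``n_bins``
    gene-body positions; all-zero genes are excluded (counted).
    """
    if not profiles:
        raise AnalysisError("need >= 1 profile")
    if n_bins < 1:
        raise AnalysisError("n_bins must be >= 1")
    acc = np.zeros(n_bins)
    used = excluded = 0
    grid = (np.arange(n_bins) + 0.5) / n_bins
    for prof in profiles:
        cov = np.asarray(prof.main_counts, dtype=float)
        mean = cov.mean()
        if mean <= 0:
            excluded += 1
            continue
        pos = (np.arange(len(cov)) + 0.5) / len(cov)
        acc += np.interp(grid, pos, cov / mean)
        used += 1
    if used == 0:
        raise AnalysisError("all profiles had zero coverage")
    return MetageneProfile(values=acc / used, n_genes=used, n_excluded=excluded)


def pause_score(profile: PositionalProfile, smooth_window: int = 3) -> float:
    """max(smoothed coverage) / mean(coverage); ~1 for uniform occupancy.

    Smoothing is a centered moving average over ``smooth_window`` codons
    (edges average over the codons actually available)."""
    cov = np.asarray(profile.main_counts, dtype=float)
    if smooth_window < 1 or smooth_window >= len(cov):
        raise AnalysisError("smooth_window must be in [1, profile length)")
    mean = cov.mean()
    if mean <= 0:
        raise AnalysisError(f"{profile.gene_id}: zero total coverage, pause score undefined")
    smoothed = (
        pd.Series(cov).rolling(smooth_window, center=True, min_periods=1).mean().to_numpy()
    )
    return float(smoothed.max() / mean)


def start_enrichment(profile: PositionalProfile, head_codons: int = 50) -> float:
    """Mean coverage over the first ``head_codons`` relative to the whole ORF.

    ~1 means no initiation-proximal pile-up and no body enrichment; < 1 is the
    elongation-defect signature (ribosomes enriched within the body)."""
    cov = np.asarray(profile.main_counts, dtype=float)
    if len(cov) <= head_codons:
        raise AnalysisError("ORF must be longer than head_codons")
    total_mean = cov.mean()
    if total_mean <= 0:
        raise AnalysisError(f"{profile.gene_id}: zero coverage, enrichment undefined")
    return float(cov[:head_codons].mean() / total_mean)


def uorf_main_ratio(profile: PositionalProfile):
    """Footprint density (reads/nt) in uORFs vs the main ORF.

    Returns (uorf_density, main_density, ratio); ratio is NaN when the main
    ORF has zero reads (densities are still returned)."""
    if not profile.uorf_counts:
        raise AnalysisError(f"{profile.gene_id}: profile has no uORF intervals")
    uorf_reads = float(sum(np.sum(u) for u in profile.uorf_counts))
    uorf_nt = 3 * sum(len(u) for u in profile.uorf_counts)
    main_reads = float(np.sum(profile.main_counts))
    main_nt = 3 * len(profile.main_counts)
    uorf_density = uorf_reads / uorf_nt
    main_density = main_reads / main_nt
    ratio = uorf_density / main_density if main_reads > 0 else float("nan")
    return uorf_density, main_density, ratio


def body_slope_ztest(profile_a: MetageneProfile, profile_b: MetageneProfile):
    """z-test for equality of gene-body coverage slopes between two profiles.

    Ordinary least-squares of coverage against normalized position per
    profile; z = (slope_a - slope_b) / sqrt(se_a^2 + se_b^2), two-sided
    normal p.  Returns (slope_a, slope_b, se_a, se_b, z, p).
    """
    if profile_a.n_bins != profile_b.n_bins:
        raise AnalysisError("profiles must have equal bin counts")
    if profile_a.n_bins < 3:
        raise AnalysisError("need >= 3 bins")
    x = (np.arange(profile_a.n_bins) + 0.5) / profile_a.n_bins
    fit_a = stats.linregress(x, profile_a.values)
    fit_b = stats.linregress(x, profile_b.values)
    se = math.sqrt(fit_a.stderr**2 + fit_b.stderr**2)
    if se == 0:
        z = 0.0 if fit_a.slope == fit_b.slope else math.inf
    else:
        z = (fit_a.slope - fit_b.slope) / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return (
        float(fit_a.slope),
        float(fit_b.slope),
        float(fit_a.stderr),
        float(fit_b.stderr),
        float(z),
        p,
    )


def profile_diagnostics(
    profiles: list[PositionalProfile],
    smooth_window: int = 3,
    head_codons: int = 50,
    pause_flag_threshold: float = 5.0,
) -> pd.DataFrame:
    """Tabulate per-gene positional scores (pause, start enrichment, uORF ratio)."""
    rows = []
    for prof in profiles:
        row = {"gene_id": prof.gene_id, "age": prof.age}
        try:
            row["pause_score"] = pause_score(prof, smooth_window)
            row["start_enrichment"] = (
                start_enrichment(prof, head_codons)
                if prof.n_codons > head_codons
                else float("nan")
            )
        except AnalysisError:
            row["pause_score"] = float("nan")
            row["start_enrichment"] = float("nan")
        row["pause_flag"] = (
            bool(row["pause_score"] > pause_flag_threshold)
            if np.isfinite(row["pause_score"])
            else False
        )
        if prof.uorf_counts:
            ud, md, ratio = uorf_main_ratio(prof)
            row.update(uorf_density=ud, main_density=md, uorf_main_ratio=ratio)
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")
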