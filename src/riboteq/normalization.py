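"""Count normalization: spike-anchored per-cell expression vs naive FPKM.

The spike-anchored route divides each library's gene counts by a per-sample
scale factor estimated from the pooled spike-in species, yielding expression
per cell-equivalent per kilobase (up to one global capture-efficiency constant
that cancels in every downstream ratio).  The naive route is classic FPKM and
is deliberately blind to global per-cell shifts: it is retained as the
contrast mode that motivates spike-ins in the first place.

Replicate alignment (mean scaling, quantile normalization) is applied only
within an age x assay group — pooling ages would erase exactly the global
signal the spike-ins preserve.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import AnalysisError, DataFormatError
from .models import CountMatrix, ExpressionMatrix, SPIKE_PREFIX, SpikeInReference


def spike_scale_factors(
    counts: CountMatrix, spikes: list[SpikeInReference], trimmed: float = 0.0
) -> pd.Series:
    """Per-sample cell-equivalents sequenced, up to one global constant.

    factor_s = sum_spike count(spike, s) / sum_spike (length_kb * molecules).
    With ``trimmed`` > 0, that fraction of spike species is symmetrically
    dropped by per-species ratio before pooling (robust variant).
    """
    spike_df = counts.spike_counts()
    ref = {SPIKE_PREFIX + s.spike_id: s for s in spikes}
    missing = [sid for sid in spike_df.index if sid not in ref]
    if missing:
        raise DataFormatError(
            f"spike ids absent from reference: {sorted(missing)[:5]}"
        )
    if spike_df.empty:
        raise AnalysisError("count matrix contains no spike rows")

    mass = pd.Series(
        {sid: ref[sid].length_kb * ref[sid].molecules_per_cell_equivalent
         for sid in spike_df.index}
    )
    factors = {}
    for sample in spike_df.columns:
        col = spike_df[sample]
        if col.sum() <= 0:
            raise AnalysisError(f"sample {sample!r} has zero spike reads")
        if trimmed > 0 and len(col) > 2:
            ratio = (col / mass).sort_values(kind="stable")
            k = int(np.floor(trimmed * len(ratio) / 2))
            keep = ratio.index[k: len(ratio) - k if k else None]
            factors[sample] = float(col[keep].sum() / mass[keep].sum())
        else:
            factors[sample] = float(col.sum() / mass.sum())
    return pd.Series(factors, name="cell_equivalents")


def per_cell_expression(
    counts: CountMatrix, factors: pd.Series, lengths_kb: pd.Series
) -> ExpressionMatrix:
    """Per-cell-equivalent reads per kilobase: count / (length_kb * factor)."""
    if (factors <= 0).any():
        raise AnalysisError("scale factors must be positive")
    genes = counts.gene_counts()
    missing = genes.index.difference(lengths_kb.index)
    if len(missing):
        raise DataFormatError(f"missing gene lengths: {list(missing[:5])}")
    lk = lengths_kb.loc[genes.index]
    if (lk <= 0).any():
        raise DataFormatError("gene lengths must be positive")
    fac = factors.reindex(genes.columns)
    if fac.isna().any():
        raise AnalysisError(
            f"no scale factor for samples: {list(genes.columns[fac.isna()])}"
        )
    values = genes.div(lk, axis=0).div(fac, axis=1)
    return ExpressionMatrix(
        values=values,
        mode="spike",
        samples=counts.samples.copy(),
        steps=("spike_scale", "per_cell_per_kb"),
    )


def library_size_expression(
    counts: CountMatrix, lengths_kb: pd.Series
) -> ExpressionMatrix:
    """Classic FPKM against total gene-mapped reads of each sample."""
    genes = counts.gene_counts()
    missing = genes.index.difference(lengths_kb.index)
    if len(missing):
        raise DataFormatError(f"missing gene lengths: {list(missing[:5])}")
    totals = genes.sum(axis=0)
    if (totals <= 0).any():
        raise AnalysisError(
            f"samples with zero gene-mapped reads: {list(totals.index[totals <= 0])}"
        )
    lk = lengths_kb.loc[genes.index]
    # count * 1e9 / (length_nt * total) == count * 1e6 / (length_kb * total)
    values = genes.div(lk, axis=0).div(totals, axis=1) * 1.0e6
    return ExpressionMatrix(
        values=values,
        mode="naive",
        samples=counts.samples.copy(),
        steps=("fpkm",),
    )


def replicate_groups(matrix: ExpressionMatrix) -> dict[str, list[str]]:
    """Default sample partition: replicates within the same age x assay."""
    groups: dict[str, list[str]] = {}
    for sample, row in matrix.samples.iterrows():
        groups.setdefault(f"{row['age']}_{row['assay']}", []).append(sample)
    return groups


def _resolve_groups(matrix: ExpressionMatrix, groups) -> dict[str, list[str]]:
    if groups is None:
        groups = replicate_groups(matrix)
    if isinstance(groups, dict):
        resolved = {str(k): list(v) for k, v in groups.items()}
    else:
        resolved = {f"group{i}": list(g) for i, g in enumerate(groups)}
    seen: set[str] = set()
    for name, members in resolved.items():
        unknown = set(members) - set(matrix.values.columns)
        if unknown:
            raise DataFormatError(f"group {name!r} names unknown samples {sorted(unknown)}")
        if seen & set(members):
            raise DataFormatError("groups must not overlap")
        seen |= set(members)
    return resolved


def quantile_normalize(matrix: ExpressionMatrix, groups=None) -> ExpressionMatrix:
    """Within-group quantile normalization to the mean-of-sorted reference.

    Each group's columns are replaced by the across-column mean of sorted
    values, assigned back by sort position (ties resolved by stable order, so
    every column ends up with the identical sorted values).  Groups of size 1
    are passed through with a warning record; cross-group distributions are
    never pooled.
    """
    resolved = _resolve_groups(matrix, groups)
    out = matrix.values.copy()
    warnings: list[str] = []
    for name, members in resolved.items():
        if len(members) < 2:
            warnings.append(f"group {name!r} has a single sample; left unchanged")
            continue
        block = matrix.values[members].to_numpy(dtype=float)
        ref = np.sort(block, axis=0).mean(axis=1)
        for j, col in enumerate(members):
            order = np.argsort(block[:, j], kind="stable")
            new = np.empty_like(ref)
            new[order] = ref
            out[col] = new
    return matrix.with_values(out, "quantile_normalize(within-group)", tuple(warnings))


def mean_scale(matrix: ExpressionMatrix, groups=None) -> ExpressionMatrix:
    """Scale each column so within-group column means equal the group grand mean."""
    resolved = _resolve_groups(matrix, groups)
    out = matrix.values.copy()
    warnings: list[str] = []
    for name, members in resolved.items():
        if len(members) < 2:
            warnings.append(f"group {name!r} has a single sample; left unchanged")
            continue
        means = matrix.values[members].mean(axis=0)
        if (means == 0).any():
            bad = list(means.index[means == 0])
            raise AnalysisError(f"zero-mean columns in group {name!r}: {bad}")
        grand = float(means.mean())
        for col in members:
            out[col] = matrix.values[col] * (grand / means[col])
    return matrix.with_values(out, "mean_scale(within-group)", tuple(warnings))
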