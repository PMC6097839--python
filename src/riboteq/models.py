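"""Core data containers.

The pipeline operates on a small set of typed containers:

* :class:`GeneModel` / :class:`SpikeInReference` — per-feature ground truth used
  by the simulator and the annotation writers.
* :class:`AgingScenario` — the knobs of a synthetic replicative-aging
  experiment (gene universe, effect prevalence and ceiling, spike-in depth,
  replication, count noise).
* :class:`CountMatrix` — integer reads per (feature x sample); features include
  both genes and spike-ins, samples carry age/assay/replicate labels.
* :class:`ExpressionMatrix` — per-cell-equivalent (spike mode) or FPKM (naive
  mode) length-normalized expression, spikes removed.
* :class:`TETable` — per-gene translational efficiency, fold changes and
  significance calls.
* :class:`PositionalProfile` / :class:`MetageneProfile` — per-codon footprint
  coverage along single genes and gene-body-normalized averages.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .errors import AnalysisError, ConfigurationError, DataFormatError

AGES = ("young", "mid", "old")
ASSAYS = ("rna", "ribo")
SPIKE_PREFIX = "spike:"

_SAMPLE_RE = re.compile(r"^(young|mid|old)_(rna|ribo)_rep(\d+)$")


def parse_sample_name(name: str) -> tuple[str, str, int]:
    """Parse ``<age>_<assay>_rep<k>`` into (age, assay, replicate)."""
    m = _SAMPLE_RE.match(name)
    if m is None:
        raise DataFormatError(
            f"sample name {name!r} does not match '<age>_<assay>_rep<k>' "
            f"with age in {AGES} and assay in {ASSAYS}"
        )
    return m.group(1), m.group(2), int(m.group(3))


def sample_name(age: str, assay: str, replicate: int) -> str:
    return f"{age}_{assay}_rep{replicate}"


@dataclass(frozen=True)
class GeneModel:
    """One gene's ORF geometry, class flags and baseline expression.

    ``uorfs`` are (offset_nt, length_nt) intervals in the 5' leader, offsets
    counted from the transcript start; the main ORF begins at ``leader_nt``.
    """

    gene_id: str
    orf_length_nt: int
    is_rpg: bool = False
    is_gcn4_target: bool = False
    uorfs: tuple[tuple[int, int], ...] = ()
    leader_nt: int = 0
    base_mrna_per_cell: float = 1.0
    base_te: float = 1.0

    def __post_init__(self) -> None:
        if self.orf_length_nt < 30:
            raise ConfigurationError(
                f"{self.gene_id}: orf_length_nt must be >= 30, got {self.orf_length_nt}"
            )
        if self.orf_length_nt % 3 != 0:
            raise ConfigurationError(
                f"{self.gene_id}: orf_length_nt must be a multiple of 3"
            )
        if self.base_mrna_per_cell <= 0 or self.base_te <= 0:
            raise ConfigurationError(
                f"{self.gene_id}: base_mrna_per_cell and base_te must be > 0"
            )
        if self.leader_nt < 0:
            raise ConfigurationError(f"{self.gene_id}: leader_nt must be >= 0")
        prev_end = 0
        for off, length in sorted(self.uorfs):
            if off < prev_end:
                raise ConfigurationError(f"{self.gene_id}: uORF intervals overlap")
            if length <= 0:
                raise ConfigurationError(f"{self.gene_id}: uORF length must be > 0")
            prev_end = off + length
        if prev_end > self.leader_nt:
            raise ConfigurationError(
                f"{self.gene_id}: uORFs must lie upstream of the main ORF "
                f"(leader is {self.leader_nt} nt)"
            )

    @property
    def n_codons(self) -> int:
        return self.orf_length_nt // 3

    @property
    def length_kb(self) -> float:
        return self.orf_length_nt / 1000.0


@dataclass(frozen=True)
class SpikeInReference:
    """One synthetic spike-in species of known per-cell-equivalent amount."""

    spike_id: str
    length_nt: int
    molecules_per_cell_equivalent: float

    def __post_init__(self) -> None:
        if self.length_nt <= 0:
            raise ConfigurationError(f"{self.spike_id}: length_nt must be > 0")
        if self.molecules_per_cell_equivalent <= 0:
            raise ConfigurationError(
                f"{self.spike_id}: molecules_per_cell_equivalent must be > 0"
            )

    @property
    def length_kb(self) -> float:
        return self.length_nt / 1000.0


@dataclass(frozen=True)
class AgingScenario:
    """Parameters of a synthetic replicative-aging translatome experiment.

    Defaults encode the study conditions this generator emulates: a 6553-gene
    universe with 3472 genes whose translational efficiency falls by up to
    40-fold (more for abundant transcripts), a 136-gene ribosomal-protein class
    whose per-cell transcripts drop ~23%, a two-fold global per-cell transcript
    increase in old cells, three replicates per age group, and ERCC-like
    spike-ins read against arbitrary per-library sequencing depths.
    """

    n_genes: int = 6553
    n_rpg: int = 136
    n_affected: int = 3472
    max_te_fold_reduction: float = 40.0
    min_te_fold_reduction: float = 1.5
    te_effect_abundance_coupling: float = 0.6
    global_transcript_increase_old: float = 2.0
    rpg_transcript_decrease_frac: float = 0.23
    replicates_per_group: int = 3
    dispersion: float = 0.004
    mean_reads_per_gene: float = 4000.0
    depth_fold_range: float = 4.0
    abundance_sdlog: float = 1.2
    n_spikes: int = 92
    spike_read_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if not 0 <= self.n_rpg <= self.n_genes:
            raise ConfigurationError("n_rpg must be in [0, n_genes]")
        if not 0 <= self.n_affected <= self.n_genes:
            raise ConfigurationError("n_affected must be in [0, n_genes]")
        if self.max_te_fold_reduction < 1:
            raise ConfigurationError("max_te_fold_reduction must be >= 1")
        if not 1 <= self.min_te_fold_reduction <= self.max_te_fold_reduction:
            raise ConfigurationError(
                "min_te_fold_reduction must be in [1, max_te_fold_reduction]"
            )
        if not 0 <= self.te_effect_abundance_coupling <= 1:
            raise ConfigurationError("te_effect_abundance_coupling must be in [0, 1]")
        if self.global_transcript_increase_old <= 0:
            raise ConfigurationError("global_transcript_increase_old must be > 0")
        if not 0 <= self.rpg_transcript_decrease_frac < 1:
            raise ConfigurationError("rpg_transcript_decrease_frac must be in [0, 1)")
        if self.replicates_per_group < 1:
            raise ConfigurationError("replicates_per_group must be >= 1")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        if self.mean_reads_per_gene <= 0:
            raise ConfigurationError("mean_reads_per_gene must be > 0")
        if self.depth_fold_range < 1:
            raise ConfigurationError("depth_fold_range must be >= 1")
        if self.abundance_sdlog <= 0:
            raise ConfigurationError("abundance_sdlog must be > 0")
        if self.n_spikes < 1:
            raise ConfigurationError("n_spikes must be >= 1")
        if not 0 < self.spike_read_fraction < 1:
            raise ConfigurationError("spike_read_fraction must be in (0, 1)")

    def replace(self, **kwargs) -> "AgingScenario":
        known = {f.name for f in fields(self)}
        unknown = set(kwargs) - known
        if unknown:
            raise ConfigurationError(f"unknown scenario fields: {sorted(unknown)}")
        return AgingScenario(**{**self.as_dict(), **kwargs})

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def null_scenario(**overrides) -> AgingScenario:
    """Scenario with no true effect anywhere (TE, global mRNA, RPG all flat)."""
    base = AgingScenario(
        n_affected=0,
        global_transcript_increase_old=1.0,
        rpg_transcript_decrease_frac=0.0,
    )
    return base.replace(**overrides)


def uniform_collapse_scenario(fold: float = 2.0, **overrides) -> AgingScenario:
    """Every gene's TE reduced by exactly ``fold`` in old cells, mRNA flat.

    This is the configuration used to contrast spike-anchored against naive
    library-size normalization: the collapse is invisible to within-library
    proportions but fully visible per cell-equivalent.
    """
    base = AgingScenario(
        n_affected=AgingScenario.n_genes,
        min_te_fold_reduction=fold,
        max_te_fold_reduction=fold,
        global_transcript_increase_old=1.0,
        rpg_transcript_decrease_frac=0.0,
    )
    if "n_genes" in overrides and "n_affected" not in overrides:
        overrides = {**overrides, "n_affected": overrides["n_genes"]}
    return base.replace(**overrides)


@dataclass
class CountMatrix:
    """Integer reads per (feature x sample) with sample metadata.

    ``counts`` rows are feature ids (spike-ins carry the ``spike:`` prefix);
    ``samples`` is indexed by sample name with columns age/assay/replicate.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts.index.name = "feature_id"
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise DataFormatError(f"duplicate feature ids: {list(dupes[:5])}")
        if self.samples is None:
            meta = [parse_sample_name(s) for s in self.counts.columns]
            self.samples = pd.DataFrame(
                meta, index=self.counts.columns, columns=["age", "assay", "replicate"]
            )
        vals = self.counts.to_numpy()
        if not np.isfinite(vals).all():
            raise DataFormatError("counts contain non-finite values")
        if (vals < 0).any():
            raise DataFormatError("counts contain negative values")

    @property
    def is_spike(self) -> pd.Series:
        return pd.Series(
            self.counts.index.str.startswith(SPIKE_PREFIX), index=self.counts.index
        )

    def gene_counts(self) -> pd.DataFrame:
        return self.counts.loc[~self.is_spike.to_numpy()]

    def spike_counts(self) -> pd.DataFrame:
        return self.counts.loc[self.is_spike.to_numpy()]

    def samples_for(self, age: str | None = None, assay: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.samples.index)
        if age is not None:
            mask &= self.samples["age"] == age
        if assay is not None:
            mask &= self.samples["assay"] == assay
        return list(self.samples.index[mask])


@dataclass
class ExpressionMatrix:
    """Length-normalized gene expression per sample, spike rows removed.

    ``mode`` is ``"spike"`` (per-cell-equivalent reads per kilobase) or
    ``"naive"`` (FPKM).  ``steps`` accumulates the normalization history so the
    chosen ordering is recorded in the output header.
    """

    values: pd.DataFrame
    mode: str
    samples: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    steps: tuple[str, ...] = ()
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("spike", "naive"):
            raise ConfigurationError(f"unknown normalization mode {self.mode!r}")
        if self.samples is None:
            meta = [parse_sample_name(s) for s in self.values.columns]
            self.samples = pd.DataFrame(
                meta, index=self.values.columns, columns=["age", "assay", "replicate"]
            )
        if self.values.index.str.startswith(SPIKE_PREFIX).any():
            raise DataFormatError("ExpressionMatrix must not contain spike rows")
        if not np.isfinite(self.values.to_numpy()).all():
            raise DataFormatError("expression values contain non-finite entries")

    def with_values(self, values: pd.DataFrame, step: str,
                    warnings: tuple[str, ...] = ()) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=values,
            mode=self.mode,
            samples=self.samples.copy(),
            steps=self.steps + (step,),
            warnings=self.warnings + warnings,
        )

    def samples_for(self, age: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.samples.index)
        if age is not None:
            mask &= self.samples["age"] == age
        return list(self.samples.index[mask])


STATUS_OK = "ok"
STATUS_RNA_ZERO = "undefined_rna_zero"
STATUS_RIBO_ZERO = "undefined_ribo_zero"


@dataclass
class TETable:
    """Per-gene translational efficiency and differential-TE results.

    ``te`` holds per-(age, replicate) TE ratios (columns ``<age>_rep<k>``);
    ``table`` accumulates per-age geometric means, log2 fold changes,
    moderated-test p/q values, ranks and the status flag.
    """

    te: pd.DataFrame
    pairs: pd.DataFrame  # index: te columns; columns: age, replicate
    table: pd.DataFrame  # index: gene ids

    def ok_genes(self) -> pd.Index:
        return self.table.index[self.table["status"] == STATUS_OK]

    def columns_for(self, age: str) -> list[str]:
        return list(self.pairs.index[self.pairs["age"] == age])


@dataclass(frozen=True)
class PositionalProfile:
    """Per-codon footprint coverage along one gene, with uORF sub-intervals."""

    gene_id: str
    main_counts: np.ndarray
    uorf_counts: tuple[np.ndarray, ...] = ()
    age: str | None = None

    def __post_init__(self) -> None:
        for arr in (self.main_counts, *self.uorf_counts):
            a = np.asarray(arr)
            if not np.isfinite(a).all() or (a < 0).any():
                raise DataFormatError(
                    f"{self.gene_id}: profile counts must be finite and non-negative"
                )

    @property
    def n_codons(self) -> int:
        return len(self.main_counts)

    def scaled(self, factor: float) -> "PositionalProfile":
        return PositionalProfile(
            gene_id=self.gene_id,
            main_counts=np.asarray(self.main_counts, dtype=float) * factor,
            uorf_counts=tuple(
                np.asarray(u, dtype=float) * factor for u in self.uorf_counts
            ),
            age=self.age,
        )


@dataclass(frozen=True)
class MetageneProfile:
    """Mean unit-normalized coverage over a fixed number of gene-body bins."""

    values: np.ndarray
    n_genes: int
    n_excluded: int = 0

    @property
    def n_bins(self) -> int:
        return len(self.values)


def geometric_mean(values: np.ndarray, axis=None):
    """Geometric mean of strictly positive values."""
    arr = np.asarray(values, dtype=float)
    if (arr <= 0).any():
        raise AnalysisError("geometric mean requires positive values")
    return np.exp(np.log(arr).mean(axis=axis))


def check_probability(x: float, name: str) -> None:
    if not (0 < x < 1) or not math.isfinite(x):
        raise ConfigurationError(f"{name} must be in (0, 1), got {x}")
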