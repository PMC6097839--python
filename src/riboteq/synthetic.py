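"""Synthetic replicative-aging translatome experiments with known ground truth.

The generator builds a yeast-like gene universe (heavy-tailed mRNA abundance,
a highly expressed ribosomal-protein class, one GCN4-like gene with inhibitory
uORFs), an ERCC-like spike-in reference, and negative-binomial count matrices
for RNA-seq and Ribo-seq libraries over three age groups.  Per-library
sequencing depth is deliberately confounded (log-uniform over a several-fold
range) so that naive library-size normalization cannot see global per-cell
shifts while the spike-ins can.

True per-gene translational-efficiency effects are drawn log-uniform between a
floor and ceiling fold reduction and assigned preferentially to abundant
transcripts via a Gaussian-copula rank coupling; middle-aged cells carry the
old effects at half log-magnitude.  The full truth table is returned alongside
the counts for parameter-recovery testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .errors import AnalysisError, ConfigurationError
from .models import (
    AgingScenario,
    CountMatrix,
    GeneModel,
    PositionalProfile,
    SPIKE_PREFIX,
    SpikeInReference,
    sample_name,
)

AGES = ("young", "mid", "old")
ASSAYS = ("rna", "ribo")

# Disjoint sub-stream keys so each generation stage is reproducible on its own.
_STREAM_MODELS = 11
_STREAM_SPIKES = 12
_STREAM_EFFECTS = 13
_STREAM_COUNTS = 14

PROFILE_MODES = ("uniform", "paused", "start_enriched", "gcn4_like")

# Per-mRNA footprint weights of the GCN4-like gene: dense uORF occupancy and a
# sparse main ORF in young cells; in old cells uORF occupancy drops by
# UORF_OLD_FACTOR while main-ORF occupancy stays flat (leaky-scanning loss
# without downstream derepression).
GCN4_UORF_WEIGHT = 5.0
GCN4_MAIN_WEIGHT = 0.5
UORF_OLD_FACTOR = 0.4


def _rng(scenario_seed: int, stream: int, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(scenario_seed), spawn_key=(stream, extra))
    )


def make_gene_models(scenario: AgingScenario) -> list[GeneModel]:
    """Build the gene universe for a scenario.

    Base mRNA abundance is log-normal (an abundant minority dominates the
    library); the ``n_rpg`` ribosomal-protein genes are placed in the top
    abundance decile (hence top quartile); exactly one non-RPG gene is
    GCN4-like, carrying four short inhibitory uORFs in a 600-nt leader.
    """
    scenario.validate()
    rng = _rng(scenario.seed, _STREAM_MODELS)
    n = scenario.n_genes

    abundance = rng.lognormal(mean=0.0, sigma=scenario.abundance_sdlog, size=n)
    lengths = rng.lognormal(mean=math.log(1200.0), sigma=0.45, size=n)
    lengths = np.clip(lengths, 300, 9000)
    lengths = (np.round(lengths / 3.0).astype(int) * 3)
    base_te = rng.lognormal(mean=0.0, sigma=0.5, size=n)

    is_rpg = np.zeros(n, dtype=bool)
    if scenario.n_rpg:
        rpg_idx = rng.choice(n, size=scenario.n_rpg, replace=False)
        is_rpg[rpg_idx] = True
        # co-regulated, highly expressed class: top decile of the abundance law
        q = rng.uniform(0.90, 0.995, size=scenario.n_rpg)
        abundance[rpg_idx] = np.exp(scenario.abundance_sdlog * ndtri(q))

    gcn4_candidates = np.flatnonzero(~is_rpg)
    gcn4_idx = int(gcn4_candidates[0]) if gcn4_candidates.size else -1

    width = len(str(n))
    models: list[GeneModel] = []
    for i in range(n):
        gid = f"g{i + 1:0{width}d}"
        uorfs: tuple[tuple[int, int], ...] = ()
        leader = 0
        if i == gcn4_idx:
            uorfs = ((60, 12), (180, 12), (330, 12), (480, 12))
            leader = 600
        models.append(
            GeneModel(
                gene_id=gid,
                orf_length_nt=int(lengths[i]),
                is_rpg=bool(is_rpg[i]),
                is_gcn4_target=(i == gcn4_idx),
                uorfs=uorfs,
                leader_nt=leader,
                base_mrna_per_cell=float(abundance[i]),
                base_te=float(base_te[i]),
            )
        )
    return models


def make_spikein_reference(n_species: int, seed: int) -> list[SpikeInReference]:
    """ERCC-like spike-in reference: log-spaced nominal amounts over >= 4 orders
    of magnitude (for ``n_species >= 2``) and fragment-scale lengths."""
    if n_species < 1:
        raise ConfigurationError("n_species must be >= 1")
    rng = _rng(seed, _STREAM_SPIKES)
    if n_species == 1:
        amounts = np.array([1.0])
    else:
        amounts = np.logspace(-1.5, 3.0, n_species)  # 4.5 orders of magnitude
    lengths = rng.integers(250, 2001, size=n_species)
    width = len(str(n_species))
    return [
        SpikeInReference(
            spike_id=f"ERCC-{i + 1:0{width}d}",
            length_nt=int(lengths[i]),
            molecules_per_cell_equivalent=float(amounts[i]),
        )
        for i in range(n_species)
    ]


def culture_age_distribution(k_max: int) -> tuple[np.ndarray, float]:
    """Division-count distribution of an exponentially growing culture.

    Each division doubles the population and mints one brand-new daughter, so
    p(k divisions) = 2^-(k+1): half the cells have never divided, a quarter
    divided once, an eighth twice, and so on.  Returns the probabilities for
    k = 0..k_max and the residual tail mass 2^-(k_max+1); the two sum to 1
    exactly.
    """
    if k_max < 0:
        raise ConfigurationError("k_max must be >= 0")
    k = np.arange(k_max + 1)
    p = 0.5 ** (k + 1)
    tail = 0.5 ** (k_max + 1)
    return p, float(tail)


@dataclass
class SimulationTruth:
    """Ground truth accompanying a simulated count matrix."""

    genes: pd.DataFrame  # per-gene truth (multipliers, effects, class flags)
    depth_factors: pd.Series  # per-library depth confounder
    scenario: AgingScenario


def _draw_effect_folds(rng: np.random.Generator, n: int,
                       fold_min: float, fold_max: float) -> np.ndarray:
    """Log-uniform fold reductions in [fold_min, fold_max]; the configured
    ceiling is always realized so the maximum effect is part of ground truth."""
    if n == 0:
        return np.empty(0)
    u = rng.random(n)
    folds = np.exp(math.log(fold_min) + u * (math.log(fold_max) - math.log(fold_min)))
    folds[np.argmax(u)] = fold_max  # pin the ceiling exactly
    return folds


def _coupled_scores(rng: np.random.Generator, abundance: np.ndarray,
                    coupling: float) -> np.ndarray:
    """Gaussian scores rank-correlated with abundance (Gaussian copula)."""
    n = len(abundance)
    order = np.argsort(np.argsort(abundance, kind="stable"), kind="stable")
    z_ab = ndtri((order + 1) / (n + 1))
    noise = rng.standard_normal(n)
    return coupling * z_ab + math.sqrt(max(0.0, 1 - coupling**2)) * noise


def assign_te_effects(models: list[GeneModel], scenario: AgingScenario,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Select affected genes and assign old-age TE fold reductions.

    Selection and magnitude both couple to young abundance through independent
    Gaussian-copula scores, so the within-affected Spearman correlation between
    abundance and effect size targets the scenario's coupling parameter.
    """
    n = len(models)
    abundance = np.array([m.base_mrna_per_cell for m in models])
    c = scenario.te_effect_abundance_coupling

    affected = np.zeros(n, dtype=bool)
    folds = np.ones(n)
    if scenario.n_affected:
        select_scores = _coupled_scores(rng, abundance, c)
        idx = np.argsort(-select_scores, kind="stable")[: scenario.n_affected]
        affected[idx] = True
        drawn = np.sort(
            _draw_effect_folds(
                rng,
                scenario.n_affected,
                scenario.min_te_fold_reduction,
                scenario.max_te_fold_reduction,
            )
        )
        assign_scores = _coupled_scores(rng, abundance[idx], c)
        rank_within = np.argsort(np.argsort(assign_scores, kind="stable"), kind="stable")
        folds[idx] = drawn[rank_within]

    is_rpg = np.array([m.is_rpg for m in models])
    g = scenario.global_transcript_increase_old
    mrna_old = np.where(is_rpg, 1.0 - scenario.rpg_transcript_decrease_frac, g)
    mrna_mid = np.sqrt(mrna_old)  # geometric midpoint of the age trajectory

    return pd.DataFrame(
        {
            "base_mrna_per_cell": abundance,
            "base_te": [m.base_te for m in models],
            "orf_length_nt": [m.orf_length_nt for m in models],
            "is_rpg": is_rpg,
            "is_gcn4_target": [m.is_gcn4_target for m in models],
            "affected": affected,
            "te_fold_old": folds,
            "true_log2fc_te_old": -np.log2(folds),
            "true_log2fc_te_mid": -0.5 * np.log2(folds),
            "mrna_mult_old": mrna_old,
            "mrna_mult_mid": mrna_mid,
            "true_log2fc_rna_old": np.log2(mrna_old),
        },
        index=pd.Index([m.gene_id for m in models], name="gene_id"),
    )


def simulate_experiment(
    models: list[GeneModel],
    spikes: list[SpikeInReference],
    scenario: AgingScenario,
) -> tuple[CountMatrix, SimulationTruth]:
    """Simulate one complete aging experiment.

    Expected counts per library are depth x cells x per-cell molecules x
    length (TE additionally multiplies Ribo-seq expectations); spike species
    scale with their nominal per-cell amounts.  A log-uniform per-library depth
    factor multiplies every expectation of that library, and counts are drawn
    negative-binomial with the scenario's dispersion.
    """
    scenario.validate()
    if not models:
        raise ConfigurationError("simulate_experiment requires a non-empty model list")
    if not spikes:
        raise ConfigurationError("simulate_experiment requires spike-in species")
    gene_ids = [m.gene_id for m in models]
    spike_ids = [SPIKE_PREFIX + s.spike_id for s in spikes]
    if set(gene_ids) & {s.spike_id for s in spikes}:
        raise ConfigurationError("spike ids must be disjoint from gene ids")

    rng_fx = _rng(scenario.seed, _STREAM_EFFECTS)
    truth_genes = assign_te_effects(models, scenario, rng_fx)

    len_kb = truth_genes["orf_length_nt"].to_numpy() / 1000.0
    abundance = truth_genes["base_mrna_per_cell"].to_numpy()
    base_te = truth_genes["base_te"].to_numpy()
    folds = truth_genes["te_fold_old"].to_numpy()

    mrna = {
        "young": abundance,
        "mid": abundance * truth_genes["mrna_mult_mid"].to_numpy(),
        "old": abundance * truth_genes["mrna_mult_old"].to_numpy(),
    }
    te = {
        "young": base_te,
        "mid": base_te / np.sqrt(folds),
        "old": base_te / folds,
    }

    # Assay-wide constants chosen so the mean young gene count per library is
    # scenario.mean_reads_per_gene (before the per-library depth jitter).
    n = len(models)
    c_rna = scenario.mean_reads_per_gene * n / float(np.sum(mrna["young"] * len_kb))
    c_ribo = scenario.mean_reads_per_gene * n / float(
        np.sum(mrna["young"] * te["young"] * len_kb)
    )

    spike_kb = np.array([s.length_kb for s in spikes])
    spike_mol = np.array([s.molecules_per_cell_equivalent for s in spikes])
    spike_mass = spike_mol * spike_kb
    k_spike = {
        assay: scenario.spike_read_fraction
        * scenario.mean_reads_per_gene
        * n
        / float(np.sum(spike_mass))
        for assay in ASSAYS
    }

    rng_counts = _rng(scenario.seed, _STREAM_COUNTS)
    reps = range(1, scenario.replicates_per_group + 1)
    names = [sample_name(a, assay, r) for a in AGES for assay in ASSAYS for r in reps]
    span = math.sqrt(scenario.depth_fold_range)
    depth = pd.Series(
        np.exp(rng_counts.uniform(-math.log(span), math.log(span), size=len(names))),
        index=names,
        name="depth_factor",
    )

    mu_cols = {}
    for name in names:
        age, assay, _rep = name.split("_")[0], name.split("_")[1], name
        if assay == "rna":
            mu_genes = c_rna * mrna[age] * len_kb
        else:
            mu_genes = c_ribo * mrna[age] * te[age] * len_kb
        mu_spikes = k_spike[assay] * spike_mass
        mu_cols[name] = depth[name] * np.concatenate([mu_genes, mu_spikes])
    mu = pd.DataFrame(mu_cols, index=gene_ids + spike_ids)
    if not np.isfinite(mu.to_numpy()).all():
        raise AnalysisError("non-finite expected counts; check scenario parameters")

    counts = pd.DataFrame(
        _nb_draw(rng_counts, mu.to_numpy(), scenario.dispersion),
        index=mu.index,
        columns=mu.columns,
    )
    cm = CountMatrix(counts=counts)
    return cm, SimulationTruth(genes=truth_genes, depth_factors=depth, scenario=scenario)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with Var = mu + dispersion * mu^2."""
    if dispersion == 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    p = shape / (shape + mu)
    return rng.negative_binomial(shape, p)


def simulate_profiles(
    model: GeneModel,
    age: str,
    scenario: AgingScenario,
    mode: str,
    seed: int,
    depth_per_codon: float = 60.0,
    pause_fold: float = 10.0,
    start_fold: float = 5.0,
    head_codons: int = 50,
) -> PositionalProfile:
    """Simulate a per-codon footprint profile for one gene.

    Position weights encode the requested occupancy pattern (uniform, a single
    paused codon, a start-proximal block, or GCN4-like uORF-dominated
    occupancy); total reads are Poisson in the summed weights and distributed
    multinomially, so profile totals track per-mRNA occupancy across ages.
    """
    if mode not in PROFILE_MODES:
        raise ConfigurationError(f"unknown profile mode {mode!r}; use one of {PROFILE_MODES}")
    if age not in AGES:
        raise ConfigurationError(f"unknown age {age!r}; use one of {AGES}")
    if model.orf_length_nt < 30:
        raise ConfigurationError("model ORF must be >= 30 nt")
    scenario.validate()

    n_codons = model.n_codons
    main_w = np.ones(n_codons)
    uorf_w: list[np.ndarray] = []
    if mode == "paused":
        main_w[n_codons // 2] = pause_fold
    elif mode == "start_enriched":
        main_w[: min(head_codons, n_codons)] = start_fold
    elif mode == "gcn4_like":
        if not model.uorfs:
            raise ConfigurationError("gcn4_like mode requires a model with uORFs")
        age_factor = {"young": 1.0, "mid": math.sqrt(UORF_OLD_FACTOR),
                      "old": UORF_OLD_FACTOR}[age]
        main_w = np.full(n_codons, GCN4_MAIN_WEIGHT)
        for _off, length in model.uorfs:
            uorf_w.append(np.full(max(1, length // 3), GCN4_UORF_WEIGHT * age_factor))

    weights = np.concatenate([main_w] + uorf_w) if uorf_w else main_w
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(21,))
    )
    total = rng.poisson(depth_per_codon * weights.sum())
    counts = rng.multinomial(total, weights / weights.sum()).astype(float)

    main_counts = counts[:n_codons]
    uorf_counts = []
    pos = n_codons
    for w in uorf_w:
        uorf_counts.append(counts[pos : pos + len(w)])
        pos += len(w)
    return PositionalProfile(
        gene_id=model.gene_id,
        main_counts=main_counts,
        uorf_counts=tuple(uorf_counts),
        age=age,
    )


def expected_profile(model: GeneModel, age: str, mode: str,
                     depth_per_codon: float = 60.0, pause_fold: float = 10.0,
                     start_fold: float = 5.0, head_codons: int = 50) -> PositionalProfile:
    """Noise-free expectation of :func:`simulate_profiles` (analysis oracle)."""
    n_codons = model.n_codons
    main_w = np.ones(n_codons)
    uorf_w: list[np.ndarray] = []
    if mode == "paused":
        main_w[n_codons // 2] = pause_fold
    elif mode == "start_enriched":
        main_w[: min(head_codons, n_codons)] = start_fold
    elif mode == "gcn4_like":
        age_factor = {"young": 1.0, "mid": math.sqrt(UORF_OLD_FACTOR),
                      "old": UORF_OLD_FACTOR}[age]
        main_w = np.full(n_codons, GCN4_MAIN_WEIGHT)
        for _off, length in model.uorfs:
            uorf_w.append(np.full(max(1, length // 3), GCN4_UORF_WEIGHT * age_factor))
    elif mode != "uniform":
        raise ConfigurationError(f"unknown profile mode {mode!r}")
    return PositionalProfile(
        gene_id=model.gene_id,
        main_counts=depth_per_codon * main_w,
        uorf_counts=tuple(depth_per_codon * w for w in uorf_w),
        age=age,
    )
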