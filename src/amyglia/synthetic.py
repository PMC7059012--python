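"""Synthetic bulk, GWAS-table, marker-set and single-cell data generators.

The generators emulate a two-strain mouse cohort (an amyloid model and a tau
model), each with a 2 x 2 age x genotype design, together with the companion
single-microglia experiment.  Every latent parameter (true interaction
effects, risk-gene placement, state fractions, microgliosis) is recorded in a
:class:`~amyglia.containers.GroundTruth` so downstream recovery can be tested
against a known answer.

Model
-----
Bulk counts are negative binomial with a single dispersion ``alpha``
(``var = mu + alpha * mu**2``) and log-normally distributed gene abundances.
An "amyloid program" of genes carries a log2 interaction effect only in the
amyloid-like strain's TG-10M cell, plus a shared per-sample activity factor
that induces the within-group co-expression a module-detection step needs.
Cell-type marker genes carry group-level abundance multipliers: microglial
markers scale with a per-group microgliosis factor, neuronal markers are
depressed in the tau-like strain's transgenic groups.  Technical structure is
a multiplicative batch factor on library size plus a scalar concentration
covariate.

Single-cell UMIs are multinomial draws from state-specific expression
profiles; per-group state fractions default to the activated-microglia
expansion observed in amyloid models (26.5% -> 56.7% across age in the
amyloid TG groups, 14.9% -> 21.3% in the tau TG groups, 4-10% in WT).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import anndata as ad
import numpy as np
import pandas as pd

from .containers import (
    AGES,
    GENOTYPES,
    GROUPS,
    STRAINS,
    BulkExperiment,
    GroundTruth,
    ParameterError,
    group_label,
)

MARKER_SET_NAMES = (
    "pyramidal_neurons",
    "interneurons",
    "astrocytes",
    "microglia",
    "oligodendrocytes",
    "endothelial",
    "ependymal",
)

#: marker-set sizes of the reference cell-type panels (desk scale by default)
DESK_MARKER_SIZES = (120, 120, 120, 120, 120, 120, 120)
FULL_MARKER_SIZES = (701, 364, 239, 435, 452, 352, 483)

DEFAULT_MICROGLIOSIS = {
    "APP_TG_4M": 1.5,
    "APP_TG_10M": 3.0,
    "TAU_TG_10M": 1.1,
}
DEFAULT_NEURONAL_FACTOR = {
    "TAU_TG_4M": 0.85,
    "TAU_TG_10M": 0.7,
}

#: activated-microglia fraction per group (remainder is homeostatic)
DEFAULT_ARM_FRACTIONS = {
    "APP_WT_4M": 0.05,
    "APP_WT_10M": 0.08,
    "APP_TG_4M": 0.265,
    "APP_TG_10M": 0.567,
    "TAU_WT_4M": 0.04,
    "TAU_WT_10M": 0.10,
    "TAU_TG_4M": 0.149,
    "TAU_TG_10M": 0.213,
}


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named child generator: all randomness flows from one seed per sub-step."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


@dataclass
class BulkConfig:
    """Settings for the bulk-count generator.

    ``interaction_lfc`` (log2) is applied to program genes only in
    ``amyloid_strain``'s TG-10M samples.  ``dispersion`` is the NB
    overdispersion alpha.  ``library_size`` defaults to ~1e6 reads/sample for
    desk speed.
    """

    n_genes: int = 2000
    n_per_group: int = 12
    program_size: int = 150
    interaction_lfc: float = 2.0
    dispersion: float = 0.1
    library_size: float = 1.0e6
    seed: int = 0
    amyloid_strain: str = "APP"
    program_activity_sd: float = 0.3
    program_microglia_overlap: float = 0.25
    marker_sizes: tuple = DESK_MARKER_SIZES
    microgliosis: dict = field(default_factory=lambda: dict(DEFAULT_MICROGLIOSIS))
    neuronal_factor: dict = field(
        default_factory=lambda: dict(DEFAULT_NEURONAL_FACTOR)
    )
    batch_factors: tuple = (1.0, 1.3)
    abundance_sigma: float = 1.2
    mito_fraction_of_universe: float = 0.05

    def null(self) -> "BulkConfig":
        """A copy with every planted effect switched off."""
        return replace(
            self,
            interaction_lfc=0.0,
            program_activity_sd=0.0,
            microgliosis={},
            neuronal_factor={},
        )


def gene_universe(n_genes: int) -> pd.Index:
    return pd.Index([f"G{i:05d}" for i in range(n_genes)], name="gene")


def assign_gene_roles(config: BulkConfig) -> dict:
    """Deterministically partition the gene universe into functional roles.

    Returns a dict with ``marker_sets`` (name -> list of genes, pairwise
    disjoint), ``program`` (list), and ``mito`` (a designated slice for the
    single-cell mitochondrial-fraction QC rule).  Driven by the config seed
    only, so every generator sees the same roles.
    """
    genes = gene_universe(config.n_genes)
    if sum(config.marker_sizes) + config.program_size > config.n_genes:
        raise ParameterError(
            "marker sets plus program oversubscribe the gene universe"
        )
    rng = _rng(config.seed, "roles")
    perm = rng.permutation(config.n_genes)
    marker_sets: dict[str, list[str]] = {}
    pos = 0
    for name, size in zip(MARKER_SET_NAMES, config.marker_sizes):
        marker_sets[name] = sorted(genes[perm[pos : pos + size]])
        pos += size
    n_overlap = int(round(config.program_microglia_overlap * config.program_size))
    n_overlap = min(n_overlap, len(marker_sets["microglia"]))
    overlap = list(
        rng.choice(marker_sets["microglia"], size=n_overlap, replace=False)
    )
    free = genes[perm[pos:]]
    n_free = config.program_size - n_overlap
    if n_free > len(free):
        raise ParameterError("program oversubscribes the non-marker universe")
    program = sorted(overlap + list(free[:n_free]))
    n_mito = int(round(config.mito_fraction_of_universe * config.n_genes))
    mito_pool = [g for g in free[n_free:] if True][:n_mito]
    return {"marker_sets": marker_sets, "program": program, "mito": sorted(mito_pool)}


def _sample_table(config: BulkConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for strain in STRAINS:
        for genotype in GENOTYPES:
            for age in AGES:
                for i in range(config.n_per_group):
                    rows.append(
                        {
                            "sample_id": f"{strain}_{genotype}_{age}_{i:02d}",
                            "strain": strain,
                            "age": age,
                            "genotype": genotype,
                        }
                    )
    df = pd.DataFrame(rows).set_index("sample_id")
    n = len(df)
    df["batch"] = [f"B{i % len(config.batch_factors)}" for i in range(n)]
    df["concentration"] = np.round(rng.normal(100.0, 10.0, size=n), 2)
    return df


def generate_bulk_counts(config: BulkConfig) -> tuple[BulkExperiment, GroundTruth]:
    """Draw a full two-strain factorial bulk experiment.

    Returns the raw count matrix plus the ground truth holding the planted
    interaction effects, program membership and microgliosis factors.
    """
    if config.n_genes < 1 or config.program_size < 1 or config.n_per_group < 2:
        raise ParameterError("non-positive or degenerate generator sizes")
    if config.program_size > config.n_genes:
        raise ParameterError("program_size exceeds n_genes")
    if config.dispersion <= 0:
        raise ParameterError("dispersion must be > 0")

    roles = assign_gene_roles(config)
    genes = gene_universe(config.n_genes)
    samples = _sample_table(config, _rng(config.seed, "samples"))
    n_s = len(samples)

    rng = _rng(config.seed, "bulk_counts")
    # log-normal relative abundances; marker/program genes clipped into a
    # mid-abundance band: high enough to survive the low-count filter, low
    # enough that planted fold changes stay a small share of the library
    # (large shares would depress every other gene's CPM, a compositional
    # artifact the real experiment does not suffer at its gene count)
    log_mu = rng.normal(0.0, config.abundance_sigma, size=config.n_genes)
    special = set(roles["program"])
    for s in roles["marker_sets"].values():
        special |= set(s)
    idx_special = genes.get_indexer(sorted(special))
    log_mu[idx_special] = np.clip(log_mu[idx_special], -3.0, -1.5)
    w = np.exp(log_mu)
    w /= w.sum()

    group = pd.Series(
        [group_label(r.strain, r.genotype, r.age) for r in samples.itertuples()],
        index=samples.index,
    )
    log2_effect = np.zeros((config.n_genes, n_s))

    prog_idx = genes.get_indexer(roles["program"])
    amyloid_cell = group_label(config.amyloid_strain, "TG", "10M")
    in_cell = (group == amyloid_cell).to_numpy()
    interaction = {g: float(config.interaction_lfc) for g in roles["program"]}
    log2_effect[np.ix_(prog_idx, np.where(in_cell)[0])] += config.interaction_lfc
    if config.program_activity_sd > 0:
        # shared per-sample program activity, only where amyloid pathology
        # exists: it is the amyloid response whose strength varies per mouse
        in_amyloid = (samples["strain"] == config.amyloid_strain).to_numpy()
        activity = rng.normal(0.0, config.program_activity_sd, size=n_s)
        activity[~in_amyloid] = 0.0
        log2_effect[prog_idx, :] += activity[None, :]

    mg_idx = genes.get_indexer(roles["marker_sets"]["microglia"])
    neu_idx = genes.get_indexer(roles["marker_sets"]["pyramidal_neurons"])
    microgliosis = {g: float(config.microgliosis.get(g, 1.0)) for g in GROUPS}
    neuronal = {g: float(config.neuronal_factor.get(g, 1.0)) for g in GROUPS}
    for g in GROUPS:
        cols = np.where((group == g).to_numpy())[0]
        if microgliosis[g] != 1.0:
            log2_effect[np.ix_(mg_idx, cols)] += np.log2(microgliosis[g])
        if neuronal[g] != 1.0:
            log2_effect[np.ix_(neu_idx, cols)] += np.log2(neuronal[g])

    batch_fac = np.array(
        [config.batch_factors[int(b[1:])] for b in samples["batch"]]
    )
    conc_fac = (samples["concentration"].to_numpy() / 100.0) ** 0.25
    lib = config.library_size * batch_fac * conc_fac

    mu = w[:, None] * lib[None, :] * np.exp2(log2_effect)
    r = 1.0 / config.dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)

    experiment = BulkExperiment(
        counts=pd.DataFrame(counts, index=genes, columns=samples.index),
        samples=samples,
    )
    truth = GroundTruth(
        seed=config.seed,
        de_genes=set(roles["program"]) if config.interaction_lfc != 0 else set(),
        interaction_lfc=interaction if config.interaction_lfc != 0 else {},
        module_assignment={g: "program" for g in roles["program"]},
        microgliosis_factor=microgliosis,
        marker_sets=roles["marker_sets"],
    )
    truth.validate(experiment.counts)
    return experiment, truth


def generate_gwas_table(
    ground_truth: GroundTruth,
    n_background: int,
    enrichment_strength: float,
    n_risk: int = 300,
    universe: pd.Index | None = None,
) -> pd.DataFrame:
    """Emit a (gene, P_mar) association table.

    ``enrichment_strength`` is the fraction of risk genes drawn from the
    amyloid program; the remainder land uniformly in the background.  Risk
    genes receive Bonferroni-style adjusted p-values log-uniform in
    [1e-8, 5e-2); background genes are uniform in [5e-2, 1].
    """
    if not 0.0 <= enrichment_strength <= 1.0:
        raise ParameterError("enrichment_strength must be in [0, 1]")
    program = sorted(ground_truth.module_assignment)
    if not program:
        raise ParameterError("ground truth has no program genes")
    if universe is None:
        n_total = max(
            n_background,
            1 + max(int(g[1:]) for g in program),
        )
        universe = gene_universe(n_total)
    rng = _rng(ground_truth.seed, "gwas_table")

    n_risk = min(n_risk, len(universe))
    n_from_program = min(int(round(enrichment_strength * n_risk)), len(program))
    risk = list(rng.choice(program, size=n_from_program, replace=False))
    outside = universe.difference(pd.Index(risk))
    extra = rng.choice(outside, size=n_risk - n_from_program, replace=False)
    risk += list(extra)

    background = pd.Index(risk).union(
        pd.Index(rng.choice(universe, size=min(n_background, len(universe)),
                            replace=False))
    )
    p = pd.Series(
        rng.uniform(5e-2, 1.0, size=len(background)), index=background, name="P_mar"
    )
    p.loc[risk] = 10.0 ** rng.uniform(-8, np.log10(5e-2), size=len(risk))
    ground_truth.risk_genes = p.loc[risk].to_dict()
    table = p.rename_axis("gene").reset_index().sort_values("P_mar")
    return table.reset_index(drop=True)


def generate_marker_sets(config: BulkConfig) -> dict[str, list[str]]:
    """Named cell-type marker gene sets, pairwise disjoint, within the universe."""
    return assign_gene_roles(config)["marker_sets"]


@dataclass
class SingleCellConfig:
    """Settings for the single-microglia UMI generator."""

    n_genes: int = 1000
    n_cells_per_group: int = 800
    arm_fractions: dict = field(default_factory=lambda: dict(DEFAULT_ARM_FRACTIONS))
    signature_size: int = 50
    signature_lfc: float = 2.0
    mean_depth: float = 2500.0
    depth_sigma: float = 0.45
    mito_fraction_of_universe: float = 0.05
    mito_share: float = 0.025
    mito_share_sigma: float = 0.35
    seed: int = 0
    states: tuple = ("ARM", "HM")

    def state_fractions(self) -> dict[str, dict[str, float]]:
        out = {}
        for g in GROUPS:
            arm = float(self.arm_fractions.get(g, 0.05))
            if not 0.0 <= arm <= 1.0:
                raise ParameterError(f"ARM fraction for {g} outside [0, 1]")
            out[g] = {"ARM": arm, "HM": 1.0 - arm}
        return out


def generate_single_cell_counts(
    config: SingleCellConfig,
) -> tuple[ad.AnnData, GroundTruth]:
    """Draw per-group multinomial UMI counts from a two-state microglia mixture.

    Returns an AnnData (cells x genes; obs: group, true_state, total_counts,
    mito_frac) and the ground truth with the planted state fractions and
    signatures.
    """
    fracs = config.state_fractions()
    for g, fr in fracs.items():
        tot = sum(fr.values())
        if abs(tot - 1.0) > 1e-9:
            raise ParameterError(f"state fractions for {g} sum to {tot}")

    genes = pd.Index([f"G{i:05d}" for i in range(config.n_genes)], name="gene")
    rng = _rng(config.seed, "single_cell")
    n_mito = int(round(config.mito_fraction_of_universe * config.n_genes))
    perm = rng.permutation(config.n_genes)
    mito_idx = perm[:n_mito]
    arm_sig_idx = perm[n_mito : n_mito + config.signature_size]
    hm_sig_idx = perm[
        n_mito + config.signature_size : n_mito + 2 * config.signature_size
    ]

    base = np.exp(rng.normal(0.0, 1.0, size=config.n_genes))
    base[mito_idx] = (
        config.mito_share * base.sum() / max(n_mito, 1)
    )  # mito genes sum to ~mito_share of expression

    profiles = {}
    for state in config.states:
        prof = base.copy()
        if state == "ARM":
            prof[arm_sig_idx] *= 2.0 ** config.signature_lfc
            prof[hm_sig_idx] *= 2.0 ** (-config.signature_lfc / 2.0)
        else:
            prof[hm_sig_idx] *= 2.0 ** config.signature_lfc
            prof[arm_sig_idx] *= 2.0 ** (-config.signature_lfc / 2.0)
        profiles[state] = prof

    obs_rows = []
    count_blocks = []
    for g in GROUPS:
        n = config.n_cells_per_group
        states = rng.choice(
            list(fracs[g]), size=n, p=[fracs[g][s] for s in fracs[g]]
        )
        depths = np.maximum(
            rng.lognormal(np.log(config.mean_depth), config.depth_sigma, size=n),
            50,
        ).astype(int)
        mito_mult = rng.lognormal(0.0, config.mito_share_sigma, size=n)
        p = np.stack([profiles[s] for s in states])
        p[:, mito_idx] *= mito_mult[:, None]
        p /= p.sum(axis=1, keepdims=True)
        count_blocks.append(rng.multinomial(depths, p))
        for i, (s, d) in enumerate(zip(states, depths)):
            obs_rows.append(
                {"barcode": f"{g}-{i:04d}", "group": g, "true_state": s}
            )

    counts = np.vstack(count_blocks)
    obs = pd.DataFrame(obs_rows).set_index("barcode")
    obs["total_counts"] = counts.sum(axis=1)
    obs["mito_frac"] = counts[:, mito_idx].sum(axis=1) / obs["total_counts"]
    adata = ad.AnnData(
        X=counts.astype(np.int64),
        obs=obs,
        var=pd.DataFrame(
            {"mito": np.isin(np.arange(config.n_genes), mito_idx)}, index=genes
        ),
    )
    truth = GroundTruth(
        seed=config.seed,
        state_fractions={
            (g, s): fracs[g][s] for g in GROUPS for s in fracs[g]
        },
        state_signatures={
            "ARM": sorted(genes[arm_sig_idx]),
            "HM": sorted(genes[hm_sig_idx]),
        },
    )
    truth.validate()
    return adata, truth


def generate_deconv_panel(
    m_g: pd.Series,
    fractions: pd.DataFrame,
    mu_hm: pd.DataFrame,
    mu_arm: pd.DataFrame,
    n_noise_frac: float = 0.10,
    n_control: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Observed bulk group means for a microglial panel (plus optional controls).

    Each panel gene's group means equal ``M_g * (f_HM*mu_HM + f_ARM*mu_ARM)``
    plus Gaussian noise with sd = ``n_noise_frac`` of the predicted range.
    Control genes (``panel=False``) have means independent of microgliosis.
    """
    rng = _rng(seed, "deconv_panel")
    pred = m_g.to_numpy()[None, :] * (
        fractions["HM"].to_numpy()[None, :] * mu_hm.to_numpy()
        + fractions["ARM"].to_numpy()[None, :] * mu_arm.to_numpy()
    )
    rng_span = pred.max(axis=1) - pred.min(axis=1)
    noise = rng.normal(0.0, 1.0, size=pred.shape) * (
        n_noise_frac * rng_span[:, None]
    )
    obs = pd.DataFrame(pred + noise, index=mu_hm.index, columns=m_g.index)
    obs["panel"] = True
    if n_control:
        ctrl = rng.normal(2.0, 1.0, size=(n_control, len(m_g)))
        ctrl_df = pd.DataFrame(
            ctrl,
            index=[f"CTRL{i:03d}" for i in range(n_control)],
            columns=m_g.index,
        )
        ctrl_df["panel"] = False
        obs = pd.concat([obs, ctrl_df])
    return obs
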