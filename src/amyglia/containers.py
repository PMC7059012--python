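"""Core data containers shared across the analysis stages.

The bulk experiment follows a 2 x 2 x 2 factorial layout: two transgenic
strains (an amyloid model, ``APP``, and a tau model, ``TAU``), two ages
(``4M`` and ``10M``) and two genotypes (``WT`` and ``TG``).  Counts are raw
read counts (genes x samples); normalized values are log2 counts-per-million.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STRAINS = ("APP", "TAU")
AGES = ("4M", "10M")
GENOTYPES = ("WT", "TG")

#: canonical experimental-group label, e.g. ``APP_TG_10M``
def group_label(strain: str, genotype: str, age: str) -> str:
    return f"{strain}_{genotype}_{age}"


GROUPS = tuple(
    group_label(s, g, a) for s in STRAINS for g in GENOTYPES for a in AGES
)


class ParameterError(ValueError):
    """Raised when a configuration or argument violates a precondition."""


@dataclass
class BulkExperiment:
    """Raw bulk RNA-seq counts plus per-sample design factors.

    Parameters
    ----------
    counts
        Gene x sample matrix of non-negative integer read counts.
    samples
        One row per sample (index = sample id) with columns ``strain``,
        ``age``, ``genotype``, ``batch`` (categorical) and ``concentration``
        (scalar technical covariate).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise ParameterError("counts columns must match samples index")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ParameterError("counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise ParameterError("counts must be integral")
        for col in ("strain", "age", "genotype"):
            if col not in self.samples.columns:
                raise ParameterError(f"samples missing required column {col!r}")
        cell_sizes = self.samples.groupby(
            ["strain", "age", "genotype"], observed=True
        ).size()
        if (cell_sizes < 2).any():
            raise ParameterError(
                "every (strain, age, genotype) cell needs at least 2 samples"
            )

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def group(self) -> pd.Series:
        """Canonical strain_genotype_age label per sample."""
        s = self.samples
        return pd.Series(
            [group_label(r.strain, r.genotype, r.age) for r in s.itertuples()],
            index=s.index,
            name="group",
        )

    def subset_strain(self, strain: str) -> "BulkExperiment":
        keep = self.samples.index[self.samples["strain"] == strain]
        if len(keep) == 0:
            raise ParameterError(f"no samples for strain {strain!r}")
        return BulkExperiment(self.counts[keep], self.samples.loc[keep])


@dataclass
class NormalizedMatrix:
    """log2 counts-per-million expression with the library sizes that made it."""

    values: pd.DataFrame
    library_sizes: pd.Series
    pseudocount: float = 0.5

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class GroundTruth:
    """Latent parameters behind a synthetic scenario, for recovery tests.

    ``interaction_lfc`` is the true log2 interaction effect applied to the
    amyloid-like strain's TG-10M cell; ``state_fractions`` maps
    ``(group, state)`` to the true microglial state mixture; the
    ``microgliosis_factor`` is the relative microglial abundance per group
    (>= 1, dimensionless, lowest group = 1).
    """

    seed: int
    de_genes: set = field(default_factory=set)
    interaction_lfc: dict = field(default_factory=dict)
    risk_genes: dict = field(default_factory=dict)
    module_assignment: dict = field(default_factory=dict)
    state_fractions: dict = field(default_factory=dict)
    microgliosis_factor: dict = field(default_factory=dict)
    marker_sets: dict = field(default_factory=dict)
    state_signatures: dict = field(default_factory=dict)

    def validate(self, counts: pd.DataFrame | None = None) -> None:
        groups = {g for g, _ in self.state_fractions}
        for g in groups:
            tot = sum(v for (gg, _), v in self.state_fractions.items() if gg == g)
            if abs(tot - 1.0) > 1e-12:
                raise ParameterError(f"state fractions for {g} sum to {tot}")
        if counts is not None:
            missing = self.de_genes - set(counts.index)
            if missing:
                raise ParameterError(
                    f"{len(missing)} de_genes absent from the count matrix"
                )


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
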