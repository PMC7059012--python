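"""Microgliosis-aware prediction of bulk expression from microglial states.

For a candidate gene, the observed bulk group mean is modelled as driven by
(i) overall microglial abundance (microgliosis) and (ii) the mixture of
homeostatic (HM) versus activated (ARM+) microglial states:

    P_g = M_g * (f_HM(g) * mu_HM(g) + f_ARM+(g) * mu_ARM+(g))

where M_g is a marker-based microgliosis index from the bulk z-matrix
(normalized so the lowest group sits at 1), f are per-group state fractions
from the single-cell data and mu are state mean expressions.  An OLS fit of
observed on predicted group means yields r^2 and a slope p-value; a gene is
called "explained" by microglia when r^2 >= 0.67 and the BY-adjusted p is
significant.  A first-order variance decomposition attributes predicted
variation to microgliosis versus state-fraction change.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

from .bulk_de import adjust_by
from .containers import ParameterError, warn
from .single_cell import StateAssignment, _dense


@dataclass
class MicrogliosisIndex:
    raw: pd.Series  # group -> mean marker z
    m_g: pd.Series  # group -> index, min = 1

    def __post_init__(self) -> None:
        if abs(float(self.m_g.min()) - 1.0) > 1e-12:
            raise ParameterError("microgliosis index must have minimum 1")


def microgliosis_index(
    z_matrix: pd.DataFrame,
    microglia_set,
    groups: pd.Series,
    convention: str = "additive",
) -> MicrogliosisIndex:
    """Mean microglial-marker z per group, anchored so the lowest group is 1.

    ``additive`` uses ``M_g = raw_g - min(raw) + 1`` (z means can be
    negative, making a ratio ill-defined); ``divisive`` divides by the
    minimum and requires all-positive raw values.
    """
    genes = z_matrix.index.intersection(pd.Index(sorted(set(microglia_set))))
    if len(genes) == 0:
        raise ParameterError("microglia set does not intersect the z-matrix")
    uniq = list(pd.unique(groups))
    if len(uniq) < 2:
        raise ParameterError("need at least 2 groups")
    raw = pd.Series(
        {
            g: float(z_matrix.loc[genes, groups.index[groups == g]].to_numpy().mean())
            for g in uniq
        }
    )
    if convention == "additive":
        m = raw - raw.min() + 1.0
    elif convention == "divisive":
        if raw.min() <= 0:
            raise ParameterError("divisive convention needs positive raw values")
        m = raw / raw.min()
    else:
        raise ParameterError(f"unknown convention {convention!r}")
    return MicrogliosisIndex(raw=raw, m_g=m)


def state_mean_expression(
    cells: ad.AnnData,
    assignment: StateAssignment,
    gene: str,
    group: str,
    homeostatic_states=("HM",),
) -> dict:
    """Mean normalized expression of one gene in all / HM / ARM+ cells of a group.

    ARM+ is every cell whose assigned state is not homeostatic.  Missing
    compartments are reported as NaN.
    """
    if gene not in cells.var_names:
        raise ParameterError(f"gene {gene!r} absent from the matrix")
    in_group = cells.obs["group"] == group
    states = assignment.states.reindex(cells.obs_names)
    is_hm = states.isin(homeostatic_states).to_numpy()
    col = _dense(cells[:, gene].X).ravel()
    sel = in_group.to_numpy()
    out = {}
    for name, mask in (
        ("mu_all", sel),
        ("mu_HM", sel & is_hm),
        ("mu_ARMplus", sel & ~is_hm),
    ):
        out[name] = float(col[mask].mean()) if mask.any() else float("nan")
    return out


def predicted_bulk(
    m_g: pd.Series,
    fractions: pd.DataFrame,
    mu_hm: pd.Series,
    mu_armplus: pd.Series,
) -> pd.Series:
    """P_g = M_g * (f_HM * mu_HM + f_ARM+ * mu_ARM+) per group."""
    groups = m_g.index
    f = fractions.loc[groups]
    if not np.allclose(f.sum(axis=1), 1.0, atol=1e-9):
        raise ParameterError("state fractions must sum to 1 per group")
    hm = mu_hm.reindex(groups)
    arm = mu_armplus.reindex(groups)
    if (pd.concat([hm, arm]).dropna() < 0).any() or (m_g < 0).any():
        raise ParameterError("negative inputs")
    if hm.isna().any() or arm.isna().any():
        warn("missing compartment mean(s) contribute 0 to the prediction")
    hm = hm.fillna(0.0)
    arm = arm.fillna(0.0)
    return m_g * (f["HM"] * hm + f.drop(columns="HM").sum(axis=1) * arm)


def driver_decomposition(
    m_g: pd.Series,
    fractions: pd.DataFrame,
    mu_hm: pd.Series,
    mu_armplus: pd.Series,
) -> dict:
    """First-order variance shares of the prediction: microgliosis vs states.

    Varies one factor with the other held at its across-group mean
    (a Sobol-style first-order share, normalized to sum to 1).
    """
    s_g = predicted_bulk(
        pd.Series(1.0, index=m_g.index), fractions, mu_hm, mu_armplus
    )
    var_m = float(np.var(m_g * s_g.mean()))
    var_s = float(np.var(float(m_g.mean()) * s_g))
    tot = var_m + var_s
    if tot == 0:
        return {"microgliosis": 0.5, "state_fractions": 0.5}
    return {"microgliosis": var_m / tot, "state_fractions": var_s / tot}


@dataclass
class DeconvFit:
    table: pd.DataFrame  # per gene: r2, p, p_adj, explained, driver shares


def fit_contribution(
    predicted: pd.DataFrame,
    observed: pd.DataFrame,
    r2_threshold: float = 0.67,
    alpha: float = 0.05,
    driver_shares: pd.DataFrame | None = None,
) -> DeconvFit:
    """OLS of observed on predicted group means, per gene, with the 67% rule.

    ``predicted`` and ``observed`` are gene x group frames over >= 4 groups.
    A gene is explained by microglial expression when r^2 >= ``r2_threshold``
    and the BY-adjusted slope p < alpha.
    """
    groups = predicted.columns.intersection(observed.columns)
    if len(groups) < 4:
        raise ParameterError("need at least 4 groups for the fit")
    rows = []
    for gene in predicted.index:
        x = predicted.loc[gene, groups].to_numpy(dtype=float)
        y = observed.loc[gene, groups].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rows.append(
                {"gene": gene, "r2": np.nan, "p": np.nan, "reason": "constant_prediction"}
            )
            continue
        fit = stats.linregress(x, y)
        rows.append(
            {"gene": gene, "r2": fit.rvalue**2, "p": fit.pvalue, "reason": ""}
        )
    tab = pd.DataFrame(rows).set_index("gene")
    ok = tab["p"].notna()
    p_adj = pd.Series(np.nan, index=tab.index)
    if ok.any():
        p_adj[ok] = adjust_by(tab.loc[ok, "p"].to_numpy())
    tab["p_adj"] = p_adj
    tab["explained"] = (
        ok & (tab["r2"] >= r2_threshold) & (tab["p_adj"] < alpha)
    )
    if driver_shares is not None:
        tab = tab.join(driver_shares)
    return DeconvFit(table=tab)
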