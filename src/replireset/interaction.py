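"""Synthetic-essentiality interaction calling.

Given per-gene fitness (log2 fold change) in a control and an experimental
condition, genes whose experimental fitness deviates from the genome-wide
linear relationship between the two conditions are called as interactions.
"Removing the gene significantly improves the regression fit" is
operationalised as the externally studentized deleted-residual outlier
test, which is exactly equivalent to a per-gene leave-one-out F-test on the
reduction in residual sum of squares (t_i^2 = F_i).  P-values are two-sided
from a t distribution on G-3 degrees of freedom and Holm-adjusted across
genes.

Usage follows the statsmodels pattern::

    model = InteractionModel.from_gene_fitness(control_df, experimental_df)
    res = model.fit(alpha_level=0.05)
    res.calls            # tidy DataFrame, one row per gene
    print(res.summary())
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["InteractionModel", "InteractionResults"]

MIN_SHARED_GENES = 10


class InteractionModel:
    """OLS of experimental gene fitness on control gene fitness.

    Parameters
    ----------
    x, y : array-like
        Control-condition and experimental-condition gene log2 fold
        changes, aligned with ``genes``.
    genes : sequence of str
        Gene identifiers.
    """

    def __init__(self, x, y, genes):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        genes = list(genes)
        if not (len(x) == len(y) == len(genes)):
            raise ValueError("x, y and genes must be aligned")
        if len(genes) < MIN_SHARED_GENES:
            raise ValueError(f"need at least {MIN_SHARED_GENES} shared genes")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite fitness values")
        if np.ptp(x) == 0:
            raise ValueError("control fitness has zero variance; regression degenerate")
        self.x = x
        self.y = y
        self.genes = genes

    @classmethod
    def from_gene_fitness(
        cls, control: pd.DataFrame, experimental: pd.DataFrame
    ) -> "InteractionModel":
        """Join two gene-fitness tables (columns gene, lfc) on shared genes."""
        merged = control[["gene", "lfc"]].merge(
            experimental[["gene", "lfc"]], on="gene", suffixes=("_control", "_experimental")
        )
        only = (set(control["gene"]) | set(experimental["gene"])) - set(merged["gene"])
        if only:
            warnings.warn(
                f"{len(only)} gene(s) present in only one condition excluded "
                "from the interaction regression",
                UserWarning,
                stacklevel=2,
            )
        return cls(
            merged["lfc_control"].to_numpy(),
            merged["lfc_experimental"].to_numpy(),
            list(merged["gene"]),
        )

    def fit(self, alpha_level: float = 0.05) -> "InteractionResults":
        X = sm.add_constant(self.x)
        ols = sm.OLS(self.y, X).fit()
        infl = ols.get_influence()
        t_stat = infl.resid_studentized_external
        G = len(self.genes)
        df = G - 3  # external studentization removes one more observation
        p = 2 * stats.t.sf(np.abs(t_stat), df)
        _, p_adj, _, _ = multipletests(p, method="holm")
        residual = ols.resid
        calls = pd.DataFrame(
            {
                "gene": self.genes,
                "x": self.x,
                "y": self.y,
                "residual": residual,
                "t_stat": t_stat,
                "p": p,
                "p_adj": p_adj,
                "direction": np.where(residual >= 0, "enriched", "depleted"),
                "called": p_adj < alpha_level,
            }
        )
        return InteractionResults(self, ols, calls, alpha_level)


class InteractionResults:
    """Fitted interaction regression with per-gene outlier calls."""

    def __init__(self, model: InteractionModel, ols_results, calls: pd.DataFrame,
                 alpha_level: float):
        self.model = model
        self._ols = ols_results
        self.calls = calls
        self.alpha_level = alpha_level

    @property
    def intercept(self) -> float:
        return float(self._ols.params[0])

    @property
    def slope(self) -> float:
        return float(self._ols.params[1])

    @property
    def residual_variance(self) -> float:
        return float(self._ols.mse_resid)

    @property
    def leverages(self) -> np.ndarray:
        return self._ols.get_influence().hat_matrix_diag

    @property
    def df(self) -> int:
        return int(self._ols.df_resid)

    @property
    def called_genes(self) -> list[str]:
        return list(self.calls.loc[self.calls["called"], "gene"])

    def to_tsv(self, path) -> None:
        self.calls.to_csv(path, sep="\t", index=False)

    def regression_report(self) -> str:
        return (
            "interaction regression: y = slope * x + intercept\n"
            f"slope\t{self.slope:.6g}\n"
            f"intercept\t{self.intercept:.6g}\n"
            f"residual_variance\t{self.residual_variance:.6g}\n"
            f"genes\t{len(self.model.genes)}\n"
            f"alpha_level\t{self.alpha_level:g}\n"
            f"called\t{int(self.calls['called'].sum())}\n"
        )

    def plot(self, ax=None):
        """Scatter of experimental vs control fitness with the fitted line;
        called genes highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        calls = self.calls
        hit = calls["called"]
        ax.scatter(calls.loc[~hit, "x"], calls.loc[~hit, "y"], s=8, alpha=0.4,
                   color="grey", label="genes")
        if hit.any():
            ax.scatter(calls.loc[hit, "x"], calls.loc[hit, "y"], s=18,
                       color="crimson", label="called")
        xs = np.linspace(calls["x"].min(), calls["x"].max(), 50)
        ax.plot(xs, self.slope * xs + self.intercept, color="black", lw=1)
        ax.set_xlabel("control gene log2 fold change")
        ax.set_ylabel("experimental gene log2 fold change")
        ax.legend(frameon=False)
        return ax

    def summary(self) -> str:
        n_call = int(self.calls["called"].sum())
        lines = [
            "Interaction calling (leave-one-out regression outlier test)",
            f"  genes:             {len(self.model.genes)}",
            f"  fit:               y = {self.slope:.4g} x + {self.intercept:.4g}",
            f"  residual variance: {self.residual_variance:.4g}",
            f"  alpha (Holm FWER): {self.alpha_level:g}",
            f"  called:            {n_call}",
        ]
        if n_call:
            top = self.calls.loc[self.calls["called"]].sort_values("p_adj")
            for _, row in top.head(10).iterrows():
                lines.append(
                    f"    {row['gene']}: t={row['t_stat']:.2f} "
                    f"p_adj={row['p_adj']:.3g} ({row['direction']})"
                )
        return "\n".join(lines)
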