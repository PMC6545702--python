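"""Cohort-level analyses: season-of-conception Fourier regression and
cross-tissue methylation-expression association.

The seasonal model regresses per-site methylation on first-order (by
default) Fourier harmonics of the conception day,

    m_s = b0 + a * sin(2*pi*d/P) + b * cos(2*pi*d/P) + e,   P = 365.25,

tests the harmonic terms jointly against the intercept-only model with an
F-test, converts (a, b) to an amplitude sqrt(a^2 + b^2) (percentage points)
and a peak day (365.25/2*pi) * atan2(a, b) mod P, and controls the FDR over
sites with Benjamini-Hochberg.  A pure cosine with positive coefficient
peaks at day 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

PERIOD = 365.25


def fourier_seasonality(
    meth: pd.DataFrame,
    days: np.ndarray,
    harmonics: int = 1,
    fdr: float = 0.20,
) -> pd.DataFrame:
    """Fit the seasonal Fourier model at every site.

    Parameters
    ----------
    meth : subjects x sites methylation (percent) DataFrame.
    days : conception day-of-year per subject, in [0, 365.25).
    harmonics : number of Fourier harmonics (k = 1..harmonics).
    fdr : BH threshold defining the ``significant`` flag.

    Returns a per-site DataFrame with ``baseline, amplitude, peak_day, p, q,
    significant`` (amplitude and peak day from the first harmonic).
    """
    days = np.asarray(days, dtype=float)
    n = len(days)
    if n < 20:
        raise ValueError("need at least 20 subjects")
    if np.ptp(days) == 0:
        raise ValueError("all conception dates identical: no seasonal contrast")
    if days.min() < 0 or days.max() >= PERIOD:
        raise ValueError("days must lie in [0, 365.25)")
    Y = np.asarray(meth, dtype=float)
    if Y.shape[0] != n:
        raise ValueError("meth rows must match subjects")

    cols = [np.ones(n)]
    for k in range(1, harmonics + 1):
        w = 2 * np.pi * k * days / PERIOD
        cols += [np.sin(w), np.cos(w)]
    X = np.column_stack(cols)
    p_terms = 2 * harmonics
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    rss = (resid**2).sum(axis=0)
    tss = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    df_resid = n - p_terms - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        F = ((tss - rss) / p_terms) / (rss / df_resid)
    pvals = stats.f.sf(F, p_terms, df_resid)
    pvals = np.where(np.isnan(F), 1.0, pvals)

    a, b = beta[1], beta[2]
    amplitude = np.hypot(a, b)
    peak_day = (PERIOD / (2 * np.pi)) * np.arctan2(a, b) % PERIOD
    q = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "site_id": list(meth.columns),
            "baseline": beta[0],
            "amplitude": amplitude,
            "peak_day": peak_day,
            "p": pvals,
            "q": q,
            "significant": q < fdr,
        }
    )


@dataclass
class FourierSeasonality:
    """Model object for the seasonal analysis of one cohort."""

    meth: pd.DataFrame
    days: np.ndarray
    harmonics: int = 1

    def fit(self, fdr: float = 0.20) -> "SeasonalityResults":
        table = fourier_seasonality(self.meth, self.days, self.harmonics, fdr)
        return SeasonalityResults(model=self, table=table, fdr=fdr)


@dataclass
class SeasonalityResults:
    model: FourierSeasonality
    table: pd.DataFrame
    fdr: float

    def summary(self) -> str:
        t = self.table
        sig = t[t["significant"]]
        lines = [
            "Seasonal Fourier regression",
            "===========================",
            f"subjects: {len(self.model.days)}   sites: {len(t)}   "
            f"harmonics: {self.model.harmonics}",
            f"significant sites (FDR < {self.fdr:.0%}): {len(sig)}",
        ]
        if len(sig):
            lines.append(
                f"median significant amplitude: {sig['amplitude'].median():.2f} pp; "
                f"median peak day: {sig['peak_day'].median():.0f}"
            )
        return "\n".join(lines)

    def enrichment(self, classes: pd.Series) -> pd.DataFrame:
        return seasonal_enrichment(self.table, classes, fdr=self.fdr)

    def plot_fit(self, site_id: str, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        row = self.table.set_index("site_id").loc[site_id]
        d = np.linspace(0, PERIOD, 200)
        ax.scatter(self.model.days, self.model.meth[site_id], s=8, alpha=0.5)
        ax.plot(
            d,
            row["baseline"]
            + row["amplitude"] * np.cos(2 * np.pi * (d - row["peak_day"]) / PERIOD),
            "r-",
        )
        ax.set_xlabel("conception day of year")
        ax.set_ylabel("methylation (%)")
        return ax


def seasonal_enrichment(
    fits: pd.DataFrame, classes: pd.Series, fdr: float = 0.20
) -> pd.DataFrame:
    """Fisher's exact test of seasonal-significance enrichment per site class.

    For each class: 2x2 of (significant, non-significant) x (in class,
    pooled other classes), tested one-sided for enrichment (a depleted class
    scores p near 1, matching the convention that only an excess of seasonal
    sites counts).  Classes with zero sites are excluded.
    """
    fits = fits.set_index("site_id") if "site_id" in fits.columns else fits
    sig = fits["q"] < fdr if "q" in fits.columns else fits["significant"]
    classes = classes.reindex(fits.index)
    rows = []
    for cls in classes.dropna().unique():
        inc = (classes == cls).to_numpy()
        if inc.sum() == 0:
            continue
        a = int((sig & inc).sum())
        b = int((~sig & inc).sum())
        c = int((sig & ~inc).sum())
        d = int((~sig & ~inc).sum())
        table = [[a, b], [c, d]]
        _, p = stats.fisher_exact(table, alternative="greater")
        if min(a, b, c, d) == 0:
            a2, b2, c2, d2 = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        else:
            a2, b2, c2, d2 = a, b, c, d
        rows.append(
            {"cls": cls, "n_sites": int(inc.sum()), "n_significant": a,
             "odds_ratio": (a2 * d2) / (b2 * c2), "p": float(p)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# methylation-expression association


def meth_expr_association(
    meth: pd.DataFrame,
    expr: dict[str, pd.DataFrame],
    mapping: pd.DataFrame,
    p_cut: float = 0.05,
):
    """Cross-tissue association of region methylation with gene expression.

    Spearman correlation per (region, gene, expression tissue) over shared
    subjects; BH correction within each expression-tissue family.  The
    concordance summary counts genes significantly associated (raw p <
    ``p_cut``) in the first (assayed) tissue that are also significant in
    each other tissue and in both.

    Returns ``(table, concordance)``.
    """
    tissues = list(expr)
    shared = meth.index
    for t in tissues:
        shared = shared.intersection(expr[t].index)
    if len(shared) < 8:
        raise ValueError("fewer than 8 shared subjects")
    meth = meth.loc[shared]
    rows = []
    for t in tissues:
        E = expr[t].loc[shared]
        for corsiv_id, gene_id in zip(mapping["corsiv_id"], mapping["gene_id"]):
            if corsiv_id not in meth.columns or gene_id not in E.columns:
                continue
            rho, p = stats.spearmanr(meth[corsiv_id], E[gene_id])
            rows.append(
                {"corsiv_id": corsiv_id, "gene_id": gene_id, "tissue": t,
                 "rho": float(rho), "p": float(p)}
            )
    table = pd.DataFrame(rows, columns=["corsiv_id", "gene_id", "tissue", "rho", "p"])
    table["q"] = np.nan
    for t in tissues:
        sel = table["tissue"] == t
        if sel.any():
            table.loc[sel, "q"] = multipletests(
                table.loc[sel, "p"].to_numpy(), method="fdr_bh"
            )[1]

    first = tissues[0]
    sig_genes = {
        t: set(table.loc[(table["tissue"] == t) & (table["p"] < p_cut), "gene_id"])
        for t in tissues
    }
    base = sig_genes[first]
    concordance = {"tissue_a": first, "n_significant_a": len(base)}
    others = tissues[1:]
    for t in others:
        concordance[f"also_{t}"] = len(base & sig_genes[t])
    if len(others) >= 2:
        concordance["also_all_others"] = len(
            base.intersection(*(sig_genes[t] for t in others))
        )
        concordance["also_any_other"] = len(
            base & set().union(*(sig_genes[t] for t in others))
        )
    return table, concordance
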