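"""Cohort-level statistics: summaries, correlation matrices, clustering.

The modelling surface follows the statsmodels convention: a
:class:`CohortCorrelation` model is built from a per-case metric table
(one row per biopsy, one column per morphometric or visual measure, NaN for
missing), and ``fit()`` returns a :class:`CorrelationResults` object
carrying the pairwise-complete Pearson r matrix, two-sided P values,
per-pair sample sizes, qualitative strength bands, hierarchical variable
clustering and a ``summary()`` table.

Correlation strength is interpreted on |r| with the conventional bands
negligible < 0.30 <= low < 0.50 <= moderate < 0.70 <= high < 0.90 <= very
high; band boundaries are assigned to the upper band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average as _average_linkage
from scipy.cluster.hierarchy import leaves_list
from scipy.spatial.distance import squareform

__all__ = [
    "summarize",
    "interpret_r",
    "CohortCorrelation",
    "CorrelationResults",
    "BANDS",
]

#: (lower bound on |r|, label); boundaries belong to the upper band.
BANDS = [
    (0.90, "very high"),
    (0.70, "high"),
    (0.50, "moderate"),
    (0.30, "low"),
    (0.00, "negligible"),
]

#: Bands counted as "Highly correlated" in the cortex/medulla ranking table.
HIGH_BANDS = ("very high", "high")

_RANK_GROUP = {
    "very high": "Highly correlated",
    "high": "Highly correlated",
    "moderate": "Moderately correlated",
    "low": "Weakly correlated",
    "negligible": "Negligibly correlated",
}


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-column N / mean / sample SD / min / max, dropping missing values.

    Mirrors the descriptive cohort table: heterogeneous per-metric Ns are
    expected and reported.  Non-numeric columns (e.g. case identifiers) are
    ignored.
    """
    num = table.select_dtypes(include=[np.number])
    rows = {}
    for col in num.columns:
        x = num[col].dropna()
        if len(x) == 0:
            rows[col] = {"N": 0, "mean": np.nan, "sd": np.nan, "min": np.nan, "max": np.nan}
        else:
            rows[col] = {
                "N": int(len(x)),
                "mean": float(x.mean()),
                "sd": float(x.std(ddof=1)) if len(x) > 1 else np.nan,
                "min": float(x.min()),
                "max": float(x.max()),
            }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "measurement"
    return out


def interpret_r(r: float) -> str:
    """Qualitative strength band of a correlation coefficient.

    The band is a function of |r|; report the sign separately.  Exact band
    boundaries go to the stronger band (0.70 -> "high", 0.90 -> "very high").
    """
    if np.isnan(r):
        raise ValueError("r is undefined (NaN)")
    a = abs(r)
    if a > 1.0:
        raise ValueError(f"|r| must be <= 1, got {r}")
    for lo, label in BANDS:
        if a >= lo:
            return label
    return "negligible"  # pragma: no cover — 0.0 handled above


class CohortCorrelation:
    """Pairwise-correlation model for a cohort metric table.

    Parameters
    ----------
    data : DataFrame
        One row per case.  A ``case_id`` column (or the index) identifies
        cases; all numeric columns enter the correlation analysis.  Missing
        values are allowed and handled by pairwise-complete deletion — with
        per-metric Ns varying widely across stains, listwise deletion would
        discard most of the cohort.
    case_id : str
        Name of the identifier column, dropped from the analysis if present.
    """

    def __init__(self, data: pd.DataFrame, case_id: str = "case_id"):
        data = pd.DataFrame(data)
        if case_id in data.columns:
            ids = data[case_id]
            if ids.duplicated().any():
                dupes = ids[ids.duplicated()].unique().tolist()
                raise ValueError(f"duplicate case_id values: {dupes}")
            data = data.drop(columns=[case_id]).set_axis(ids, axis=0)
        self.data = data.select_dtypes(include=[np.number])
        if self.data.columns.duplicated().any():
            raise ValueError("metric column names must be unique")
        if len(self.data) < 3:
            raise ValueError("at least 3 cases are required for correlation analysis")

    @classmethod
    def from_csv(cls, path, case_id: str = "case_id") -> "CohortCorrelation":
        return cls(pd.read_csv(path), case_id=case_id)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def fit(self, min_n: int = 3) -> "CorrelationResults":
        """Compute the pairwise-complete Pearson correlation matrix.

        Pairs with fewer than ``min_n`` complete observations, and pairs
        involving a constant column, are reported as NaN.  P values are from
        the two-sided t test on r.
        """
        cols = self.variables
        k = len(cols)
        r = np.full((k, k), np.nan)
        p = np.full((k, k), np.nan)
        n = np.zeros((k, k), dtype=int)
        X = self.data.to_numpy(dtype=float)
        notna = ~np.isnan(X)
        for i in range(k):
            r[i, i] = 1.0
            p[i, i] = 0.0
            n[i, i] = int(notna[:, i].sum())
            for j in range(i + 1, k):
                sel = notna[:, i] & notna[:, j]
                m = int(sel.sum())
                n[i, j] = n[j, i] = m
                if m < min_n:
                    continue
                x, y = X[sel, i], X[sel, j]
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    warnings.warn(
                        f"constant column in pair ({cols[i]!r}, {cols[j]!r}); "
                        "correlation undefined"
                    )
                    continue
                res = stats.pearsonr(x, y)
                r[i, j] = r[j, i] = res.statistic
                p[i, j] = p[j, i] = res.pvalue
        return CorrelationResults(
            model=self,
            r=pd.DataFrame(r, index=cols, columns=cols),
            p=pd.DataFrame(p, index=cols, columns=cols),
            n=pd.DataFrame(n, index=cols, columns=cols),
            min_n=min_n,
        )


@dataclass
class CorrelationResults:
    """Fitted pairwise-correlation results.

    Attributes
    ----------
    r, p, n : DataFrame
        Symmetric Pearson r matrix (unit diagonal), two-sided P values, and
        pairwise-complete sample sizes.
    """

    model: CohortCorrelation
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    min_n: int = 3
    _cluster_cache: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def variables(self) -> list[str]:
        return list(self.r.columns)

    def band(self, var1: str, var2: str) -> str:
        return interpret_r(float(self.r.loc[var1, var2]))

    def to_long(self, adjust: str | None = None) -> pd.DataFrame:
        """Long-format table: var1, var2, n, r, p, band — one row per pair.

        ``adjust="bh"`` appends a Benjamini–Hochberg adjusted P column
        (``p_adj``); raw P values are always reported, matching the source
        analysis which applied no multiplicity correction.
        """
        rows = []
        cols = self.variables
        for i, a in enumerate(cols):
            for b in cols[i + 1:]:
                rr = float(self.r.loc[a, b])
                rows.append(
                    {
                        "var1": a,
                        "var2": b,
                        "n": int(self.n.loc[a, b]),
                        "r": rr,
                        "p": float(self.p.loc[a, b]),
                        "band": interpret_r(rr) if not np.isnan(rr) else "undefined",
                    }
                )
        out = pd.DataFrame(rows)
        if adjust == "bh":
            ok = out["p"].notna()
            adj = np.full(len(out), np.nan)
            if ok.any():
                adj[ok.to_numpy()] = stats.false_discovery_control(
                    out.loc[ok, "p"].to_numpy(), method="bh"
                )
            out["p_adj"] = adj
        elif adjust is not None:
            raise ValueError(f"unknown adjustment {adjust!r}")
        return out

    def cluster_variables(self) -> tuple[list[str], np.ndarray]:
        """Order variables by agglomerative clustering of their correlations.

        Distance is ``1 - r`` (not ``1 - |r|``: anti-correlated measures
        should sit far apart on the color map), linkage is average.
        Undefined pairs are imputed to r = 0 with a warning.  Returns the
        leaf ordering and the scipy linkage matrix.
        """
        if self._cluster_cache is not None:
            return self._cluster_cache
        cols = self.variables
        if len(cols) < 2:
            raise ValueError("clustering needs at least 2 variables")
        r = self.r.to_numpy(dtype=float).copy()
        off_diag_nan = np.isnan(r)
        np.fill_diagonal(off_diag_nan, False)
        if off_diag_nan.any():
            warnings.warn(
                f"{int(off_diag_nan.sum()) // 2} undefined correlation pairs "
                "imputed to r=0 for clustering"
            )
            r[off_diag_nan] = 0.0
        d = 1.0 - r
        np.fill_diagonal(d, 0.0)
        d = np.maximum(d, 0.0)
        d = (d + d.T) / 2.0
        linkage = _average_linkage(squareform(d, checks=False))
        order = [cols[i] for i in leaves_list(linkage)]
        self._cluster_cache = (order, linkage)
        return self._cluster_cache

    def rank_compartment_correlations(
        self, pairs: list[tuple[str, str]] | None = None
    ) -> pd.DataFrame:
        """Rank measures by the strength of their cortex/medulla correlation.

        ``pairs`` lists (cortex column, medulla column) tuples; when omitted,
        every ``Ctx-X`` column with a matching ``Med-X`` column is paired
        automatically.  The result is sorted by descending r and labelled
        with the strength band plus the coarse "Highly"/"Moderately"/...
        grouping used to present the ranking.  Pairs with a missing member
        or undefined r are skipped with a warning.
        """
        if pairs is None:
            pairs = []
            for c in self.variables:
                if "Ctx-" in c:
                    med = c.replace("Ctx-", "Med-", 1)
                    if med in self.variables:
                        pairs.append((c, med))
        rows = []
        for a, b in pairs:
            if a not in self.variables or b not in self.variables:
                warnings.warn(f"pair ({a!r}, {b!r}) missing from table; skipped")
                continue
            rr = float(self.r.loc[a, b])
            if np.isnan(rr):
                warnings.warn(f"pair ({a!r}, {b!r}) has undefined r; skipped")
                continue
            band = interpret_r(rr)
            rows.append(
                {
                    "measure": a.replace("Ctx-", "", 1) if "Ctx-" in a else f"{a}~{b}",
                    "ctx_var": a,
                    "med_var": b,
                    "n": int(self.n.loc[a, b]),
                    "r": rr,
                    "p": float(self.p.loc[a, b]),
                    "band": band,
                    "group": _RANK_GROUP[band],
                }
            )
        out = pd.DataFrame(rows)
        if len(out):
            out = out.sort_values("r", ascending=False).reset_index(drop=True)
        return out

    def summary(self) -> str:
        """Human-readable report: cohort size, strongest pairs, band counts."""
        long = self.to_long()
        defined = long.dropna(subset=["r"])
        lines = [
            "Cohort correlation analysis",
            "===========================",
            f"Cases: {len(self.model.data)}    Variables: {len(self.variables)}",
            f"Pairs: {len(long)} ({len(defined)} defined, "
            f"pairwise-complete n >= {self.min_n})",
            "",
            "Strength bands (|r|, boundaries to the upper band):",
        ]
        counts = defined["band"].value_counts()
        for _, label in BANDS:
            lines.append(f"  {label:<10s} {int(counts.get(label, 0)):4d}")
        lines.append("")
        lines.append("Strongest correlations:")
        top = defined.reindex(defined["r"].abs().sort_values(ascending=False).index).head(10)
        for _, row in top.iterrows():
            lines.append(
                f"  {row.var1:<22s} ~ {row.var2:<22s} "
                f"r={row.r:+.3f}  n={row.n:3d}  p={row.p:.2e}  [{row.band}]"
            )
        return "\n".join(lines)

    def plot_heatmap(self, path=None, figsize=(10, 9)):
        """Clustered correlation color map (the figure-2-style analogue).

        Variables are ordered by :meth:`cluster_variables`; the heatmap shows
        r on a diverging scale.  Returns the matplotlib figure; saves to
        ``path`` when given.
        """
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        order, _ = self.cluster_variables()
        r = self.r.loc[order, order]
        fig, ax = plt.subplots(figsize=figsize)
        im = ax.imshow(r.to_numpy(), cmap="RdBu_r", vmin=-1.0, vmax=1.0)
        ax.set_xticks(range(len(order)), order, rotation=90, fontsize=7)
        ax.set_yticks(range(len(order)), order, fontsize=7)
        fig.colorbar(im, ax=ax, label="Pearson r")
        ax.set_title("Clustered correlation map of cohort measures")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig
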