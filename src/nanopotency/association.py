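"""Factorial ANOVA on fold-effect data and correlation screens.

ANOVA follows the study design: fixed-effects factorial models with all main
effects and two-way interactions, optionally on the rank-transformed response
(mid-ranks over the whole response vector) when normality/equal-variance
assumptions fail.  Type II sums of squares are used so unbalanced layouts
remain interpretable; on balanced data Type II coincides with Type I/III.

Correlation screens relate consensus potency (beta_avg) to physicochemical
descriptors or mechanistic markers, per particle, with pairwise deletion of
missing values and explicit subset masks (pristine/coated, crystal form).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from nanopotency.errors import DesignError
from nanopotency.potency import ConsensusPotency

#: Descriptor columns of a physicochemical table.
PHYSCHEM_PROPERTIES = [
    "tem_size",
    "bet_sa",
    "dls_size",
    "pdi",
    "zeta_potential",
    "tga_groups",
    "total_metals",
    "transition_metals",
    "transition_metals_no_ti",
]


@dataclass(frozen=True)
class CorrelationResult:
    """One screened association between two named variables."""

    x_name: str
    y_name: str
    method: str
    n: int
    r: float
    p: float
    subset: str = "all"


def holm_sidak(pvalues: Sequence[float]) -> np.ndarray:
    """Holm-Sidak step-down adjustment, returned in input order.

    Sorted ascending, the i-th (1-based) adjusted value is
    ``1 - (1 - p_(i)) ** (m - i + 1)``, made monotone non-decreasing along
    the sorted order and capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-d sequence")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def _rank_transform(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def anova_factorial(
    dr: pd.DataFrame,
    factors: Sequence[str],
    rank_transform: bool = False,
    response: str = "fe",
) -> pd.DataFrame:
    """Fixed-effects factorial ANOVA of ``response`` on ``factors``.

    The model contains every main effect and every two-way interaction.
    With ``rank_transform`` the whole response vector is replaced by
    mid-ranks before fitting.  Returns the Type II ANOVA table (term, df,
    sum_sq, F, p) with a ``Residual`` row; the table's ``attrs`` record
    whether ranks were used.

    Raises
    ------
    DesignError
        If a factor has fewer than 2 levels or a term leaves no residual
        degrees of freedom.
    """
    factors = list(factors)
    if not factors:
        raise DesignError("at least one factor required")
    for f in factors:
        if f not in dr.columns:
            raise DesignError(f"factor column {f!r} not in table")
        if dr[f].nunique() < 2:
            raise DesignError(f"factor {f!r} has fewer than 2 levels")
    if response not in dr.columns:
        raise DesignError(f"response column {response!r} not in table")

    data = dr[factors + [response]].copy()
    data.columns = [f"f_{i}" for i in range(len(factors))] + ["y"]
    if rank_transform:
        data["y"] = _rank_transform(data["y"].to_numpy(dtype=float))

    terms = [f"C(f_{i})" for i in range(len(factors))]
    terms += [
        f"C(f_{i}):C(f_{j})"
        for i in range(len(factors))
        for j in range(i + 1, len(factors))
    ]
    formula = "y ~ " + " + ".join(terms)
    fit = smf.ols(formula, data=data).fit()
    if fit.df_resid < 1:
        raise DesignError(
            "no residual degrees of freedom; the interaction terms "
            f"{terms[len(factors):]} are not estimable with this replication"
        )
    with warnings.catch_warnings():
        # constant responses trigger harmless 0/0 in the F columns
        warnings.simplefilter("ignore", RuntimeWarning)
        table = sm.stats.anova_lm(fit, typ=2)

    table = table.reset_index().rename(
        columns={"index": "term", "df": "df", "sum_sq": "sum_sq", "F": "F", "PR(>F)": "p"}
    )
    # restore user-facing factor names in term labels
    for i, f in enumerate(factors):
        table["term"] = table["term"].str.replace(f"C(f_{i})", f, regex=False)
    table["F"] = table["F"].fillna(0.0)
    table["p"] = table["p"].fillna(1.0)
    # a (near-)constant response leaves only rounding noise in the SS columns
    y = data["y"].to_numpy(dtype=float)
    tss = float(np.sum((y - y.mean()) ** 2))
    negligible = table["sum_sq"].abs() <= max(tss, 1.0) * 1e-12
    table.loc[negligible & (table["term"] != "Residual"), ["F", "p"]] = [0.0, 1.0]
    table.attrs["rank_transformed"] = bool(rank_transform)
    return table


def _correlate(
    x: np.ndarray, y: np.ndarray, method: str
) -> tuple[float, float, int]:
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 3:
        raise ValueError(f"fewer than 3 complete pairs (n={n})")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p), n


def _consensus_series(consensus: "Sequence[ConsensusPotency] | pd.DataFrame") -> pd.Series:
    if isinstance(consensus, pd.DataFrame):
        return consensus.set_index("particle")["beta_avg"].astype(float)
    return pd.Series(
        {c.particle: c.beta_avg for c in consensus}, dtype=float, name="beta_avg"
    )


def correlate_potency_physchem(
    consensus: "Sequence[ConsensusPotency] | pd.DataFrame",
    table: pd.DataFrame,
    subset: "Callable[[pd.Series], bool] | None" = None,
    method: str = "pearson",
    properties: Iterable[str] | None = None,
    subset_name: str = "all",
) -> list[CorrelationResult]:
    """Correlate beta_avg against each physicochemical descriptor.

    ``table`` must be indexed (or keyed by a ``particle`` column) per
    particle.  ``subset`` is an explicit predicate over table rows (e.g.
    ``lambda row: row["coating"] == "pristine"``); membership is never
    inferred from particle names.  Missing values are removed pairwise and
    the per-property n is reported.  Properties with fewer than 3 complete
    pairs, or zero variance, are skipped with a warning rather than
    silently dropped.
    """
    beta = _consensus_series(consensus)
    tab = table.set_index("particle") if "particle" in table.columns else table.copy()
    if subset is not None:
        keep = tab.apply(subset, axis=1).astype(bool)
        tab = tab.loc[keep]
    common = [p for p in beta.index if p in tab.index]
    if len(common) < 3:
        warnings.warn(
            f"subset {subset_name!r}: only {len(common)} particles overlap; "
            "no correlations computed",
            stacklevel=2,
        )
        return []
    beta = beta.loc[common]
    tab = tab.loc[common]

    props = list(properties) if properties is not None else [
        c for c in PHYSCHEM_PROPERTIES if c in tab.columns
    ]
    results: list[CorrelationResult] = []
    for prop in props:
        x = pd.to_numeric(tab[prop], errors="coerce").to_numpy(dtype=float)
        try:
            r, p, n = _correlate(x, beta.to_numpy(dtype=float), method)
        except ValueError as exc:
            warnings.warn(f"skipping {prop!r} ({subset_name}): {exc}", stacklevel=2)
            continue
        results.append(
            CorrelationResult(
                x_name=prop,
                y_name="beta_avg",
                method=method,
                n=n,
                r=r,
                p=p,
                subset=subset_name,
            )
        )
    return results


def correlate_potency_markers(
    consensus: "Sequence[ConsensusPotency] | pd.DataFrame",
    markers: pd.DataFrame,
    method: str = "pearson",
    marker_columns: Iterable[str] | None = None,
) -> list[CorrelationResult]:
    """Correlate beta_avg against mechanistic marker fold changes.

    ``markers`` holds one row per particle (a ``particle`` column or index)
    with marker columns such as GSH/GSSG ratio or cytokine fold change,
    measured at the mechanistic dose.  Semantics match
    :func:`correlate_potency_physchem`.
    """
    beta = _consensus_series(consensus)
    tab = markers.set_index("particle") if "particle" in markers.columns else markers.copy()
    common = [p for p in beta.index if p in tab.index]
    if len(common) < 3:
        warnings.warn("fewer than 3 particles shared with marker panel", stacklevel=2)
        return []
    beta = beta.loc[common]
    tab = tab.loc[common]

    cols = list(marker_columns) if marker_columns is not None else [
        c for c in tab.columns if pd.api.types.is_numeric_dtype(tab[c]) and c != "dose"
    ]
    results: list[CorrelationResult] = []
    for col in cols:
        x = pd.to_numeric(tab[col], errors="coerce").to_numpy(dtype=float)
        try:
            r, p, n = _correlate(x, beta.to_numpy(dtype=float), method)
        except ValueError as exc:
            warnings.warn(f"skipping marker {col!r}: {exc}", stacklevel=2)
            continue
        results.append(
            CorrelationResult(
                x_name=col, y_name="beta_avg", method=method, n=n, r=r, p=p
            )
        )
    return results


def correlation_results_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    """Tabulate a list of :class:`CorrelationResult` for export."""
    return pd.DataFrame(
        [
            {
                "x": res.x_name,
                "y": res.y_name,
                "method": res.method,
                "subset": res.subset,
                "n": res.n,
                "r": res.r,
                "p": res.p,
            }
            for res in results
        ]
    )
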