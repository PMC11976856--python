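"""Fold-effect normalization, power-law potency fitting, consensus and ranking.

The dose-response model is ``FE = (dose + 1) ** beta`` with dose in ug/cm^2,
fitted through the origin on the log-log scale: ``ln FE = beta * ln(dose + 1)``.
The ``+1`` offset pins FE(0) = 1 and is unit-dependent (doses must be supplied
in ug/cm^2).

Potency magnitudes are reported as ``beta = |signed_slope|``: declining
endpoints (ATP, CTB) fit a negative slope but potency tables print the
magnitude; the sign is kept in :attr:`PotencyEstimate.signed_slope`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from nanopotency.errors import FitError, NormalizationError

logger = logging.getLogger(__name__)

ENDPOINTS = ("LDH", "ATP", "CTB")

#: Columns required of a plate-measurements table.
PLATE_COLUMNS = [
    "particle",
    "cell_line",
    "assay",
    "dose",
    "experiment",
    "technical_rep",
    "cell_free",
    "signal",
]

#: Columns of a dose-response (fold effect) table.
DR_COLUMNS = [
    "particle",
    "cell_line",
    "assay",
    "dose",
    "experiment",
    "technical_rep",
    "fe",
]

_GROUP_KEY = ["particle", "cell_line", "assay", "experiment"]


@dataclass(frozen=True)
class PotencyEstimate:
    """Fitted power-law potency for one particle x cell line x endpoint.

    ``beta`` is the reported magnitude; ``signed_slope`` keeps the fitted
    direction (negative for endpoints that decline with dose).
    """

    particle: str
    cell_line: str
    endpoint: str
    beta: float
    signed_slope: float
    se_beta: float
    r_squared: float
    n_points: int

    def __post_init__(self):
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"unknown endpoint {self.endpoint!r}")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if not np.isclose(self.beta, abs(self.signed_slope)):
            raise ValueError("beta must equal |signed_slope|")


@dataclass(frozen=True)
class ConsensusPotency:
    """Arithmetic mean of the LDH/ATP/CTB potency magnitudes."""

    particle: str
    cell_line: str
    beta_avg: float
    components: Mapping[str, float] = field(default_factory=dict)


def compute_fold_effect(raw: pd.DataFrame, subtract_cell_free: bool = False) -> pd.DataFrame:
    """Normalize raw plate signals to fold effects.

    FE = signal / mean(dose-0 signals) within each
    (particle, cell_line, assay, experiment) group.  With
    ``subtract_cell_free`` the mean cell-free signal at the matching
    particle x dose x assay is subtracted from every signal (numerator and
    denominator) before normalization; records whose corrected signal is
    non-positive are dropped with a warning.

    Raises
    ------
    NormalizationError
        If a group lacks dose-0 records, or loses all its records to the
        cell-free correction.
    """
    missing = [c for c in PLATE_COLUMNS if c not in raw.columns]
    if missing:
        raise NormalizationError(f"plate table missing columns: {missing}")

    cells = raw.loc[~raw["cell_free"].astype(bool)].copy()
    if cells.empty:
        raise NormalizationError("no cell-containing records in plate table")

    if subtract_cell_free:
        blanks = raw.loc[raw["cell_free"].astype(bool)]
        if not blanks.empty:
            offset = (
                blanks.groupby(["particle", "assay", "dose"])["signal"]
                .mean()
                .rename("cf_offset")
            )
            cells = cells.merge(offset, on=["particle", "assay", "dose"], how="left")
            cells["cf_offset"] = cells["cf_offset"].fillna(0.0)
        else:
            cells["cf_offset"] = 0.0
        cells["signal"] = cells["signal"] - cells.pop("cf_offset")
        bad = cells["signal"] <= 0
        if bad.any():
            logger.warning(
                "dropping %d records with non-positive cell-free-corrected signal",
                int(bad.sum()),
            )
            cells = cells.loc[~bad]

    out = []
    for key, grp in cells.groupby(_GROUP_KEY, sort=False):
        zeros = grp.loc[grp["dose"] == 0, "signal"]
        if zeros.empty:
            raise NormalizationError(f"group {key} has no dose-0 records")
        denom = zeros.mean()
        if denom <= 0:
            raise NormalizationError(f"group {key} has non-positive dose-0 mean")
        g = grp.copy()
        g["fe"] = g["signal"] / denom
        out.append(g)
    if not out:
        raise NormalizationError("all groups empty after correction")
    dr = pd.concat(out, ignore_index=True)
    return dr[DR_COLUMNS]


def _check_fe_table(dr: pd.DataFrame) -> None:
    missing = [c for c in DR_COLUMNS if c not in dr.columns]
    if missing:
        raise FitError(f"dose-response table missing columns: {missing}")


def fit_potency(
    dr: pd.DataFrame,
    particle: str,
    cell_line: str,
    endpoint: str,
    on_means: bool = False,
) -> PotencyEstimate:
    """Fit ``FE = (dose + 1) ** beta`` for one particle x cell line x endpoint.

    Least-squares through the origin of ln(FE) on ln(dose + 1).  By default
    every replicate-level record enters the fit; with ``on_means`` the mean
    FE per dose is fitted instead.  Records with FE <= 0 are excluded with a
    warning.  Dose-0 records sit at x = 0 and carry no leverage.

    ``se_beta`` propagates two variance sources: per-well log-FE noise
    (pooled within experiment x dose cells when replicated, residual
    variance otherwise) and the shared dose-0 control mean each experiment
    divides by.  Without the second term the interval ``beta +/- 2 se``
    badly undercovers, because all fold effects in an experiment share one
    noisy denominator.
    """
    _check_fe_table(dr)
    sub = dr.loc[
        (dr["particle"] == particle)
        & (dr["cell_line"] == cell_line)
        & (dr["assay"] == endpoint)
    ].copy()
    if sub.empty:
        raise FitError(f"no records for {particle}/{cell_line}/{endpoint}")

    nonpos = sub["fe"] <= 0
    if nonpos.any():
        warnings.warn(
            f"excluding {int(nonpos.sum())} records with FE <= 0 for "
            f"{particle}/{cell_line}/{endpoint}",
            stacklevel=2,
        )
        sub = sub.loc[~nonpos]

    if (sub["dose"] > 0).sum() < 1 or len(sub) < 2:
        raise FitError(
            f"fewer than 2 usable records (or no positive-dose record) for "
            f"{particle}/{cell_line}/{endpoint}"
        )

    if on_means:
        sub = (
            sub.groupby("dose", as_index=False)
            .agg(fe=("fe", "mean"))
            .assign(experiment=0)
        )

    x = np.log(sub["dose"].to_numpy(dtype=float) + 1.0)
    y = np.log(sub["fe"].to_numpy(dtype=float))
    n = len(x)
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise FitError("no positive-dose records with usable FE")
    slope = float(np.sum(x * y) / sxx)
    resid = y - slope * x
    dof = n - 1
    s2_resid = float(np.sum(resid**2) / dof) if dof > 0 else 0.0

    # Per-well variance pooled over experiment x dose cells (preferred when
    # technical replication exists -- residuals also absorb the shared
    # control-mean offset and would double count it).
    s2_well, well_df = _pooled_cell_variance(sub)
    if well_df < 3:
        s2_well = s2_resid

    var = s2_well / sxx
    if not on_means:
        for _, grp in sub.groupby("experiment"):
            n0 = int((grp["dose"] == 0).sum())
            if n0 > 0:
                sx_e = float(np.log(grp["dose"].to_numpy(dtype=float) + 1.0).sum())
                var += (s2_well / n0) * sx_e**2 / sxx**2
    se = float(np.sqrt(var))

    tss = float(np.sum(y**2))
    r2 = 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else 1.0
    r2 = min(max(r2, 0.0), 1.0)

    return PotencyEstimate(
        particle=particle,
        cell_line=cell_line,
        endpoint=endpoint,
        beta=abs(slope),
        signed_slope=slope,
        se_beta=se,
        r_squared=r2,
        n_points=n,
    )


def _pooled_cell_variance(sub: pd.DataFrame) -> tuple[float, int]:
    """Pooled within-(experiment, dose)-cell variance of ln FE."""
    y = np.log(sub["fe"].to_numpy(dtype=float))
    frame = pd.DataFrame(
        {"y": y, "experiment": sub["experiment"].to_numpy(), "dose": sub["dose"].to_numpy()}
    )
    sse = 0.0
    dof = 0
    for _, cell in frame.groupby(["experiment", "dose"]):
        if len(cell) > 1:
            yy = cell["y"].to_numpy()
            sse += float(np.sum((yy - yy.mean()) ** 2))
            dof += len(yy) - 1
    return (sse / dof if dof > 0 else 0.0), dof


def fit_all_potencies(dr: pd.DataFrame, on_means: bool = False) -> pd.DataFrame:
    """Fit every (particle, cell_line, endpoint) combination present.

    Returns one row per fit; combinations that fail their preconditions are
    skipped with a warning.
    """
    _check_fe_table(dr)
    rows = []
    combos = dr[["particle", "cell_line", "assay"]].drop_duplicates()
    for particle, cell_line, assay in combos.itertuples(index=False):
        try:
            est = fit_potency(dr, particle, cell_line, assay, on_means=on_means)
        except FitError as exc:
            warnings.warn(f"skipping {particle}/{cell_line}/{assay}: {exc}", stacklevel=2)
            continue
        rows.append(
            {
                "particle": est.particle,
                "cell_line": est.cell_line,
                "endpoint": est.endpoint,
                "beta": est.beta,
                "signed_slope": est.signed_slope,
                "se_beta": est.se_beta,
                "r_squared": est.r_squared,
                "n_points": est.n_points,
            }
        )
    return pd.DataFrame(rows)


def consensus_potency(
    betas: Mapping[str, "PotencyEstimate | float"],
    particle: str | None = None,
    cell_line: str | None = None,
) -> ConsensusPotency:
    """Average the three endpoint potency magnitudes into beta_avg.

    ``betas`` maps each endpoint in {LDH, ATP, CTB} to a
    :class:`PotencyEstimate` or a bare magnitude.  All three endpoints must
    be present; extraneous keys are an error.
    """
    keys = set(betas)
    if keys != set(ENDPOINTS):
        raise ValueError(f"need exactly endpoints {set(ENDPOINTS)}, got {keys}")
    mags = {}
    for ep, val in betas.items():
        if isinstance(val, PotencyEstimate):
            if particle is None:
                particle = val.particle
            if cell_line is None:
                cell_line = val.cell_line
            mags[ep] = val.beta
        else:
            mags[ep] = float(val)
    beta_avg = (mags["LDH"] + mags["ATP"] + mags["CTB"]) / 3.0
    return ConsensusPotency(
        particle=particle or "",
        cell_line=cell_line or "",
        beta_avg=beta_avg,
        components=mags,
    )


def consensus_from_fits(fits: pd.DataFrame) -> pd.DataFrame:
    """Roll a fit table (from :func:`fit_all_potencies`) up to beta_avg rows."""
    rows = []
    for (particle, cell_line), grp in fits.groupby(["particle", "cell_line"]):
        eps = dict(zip(grp["endpoint"], grp["beta"]))
        if set(eps) != set(ENDPOINTS):
            warnings.warn(
                f"{particle}/{cell_line}: missing endpoints "
                f"{set(ENDPOINTS) - set(eps)}; no consensus formed",
                stacklevel=2,
            )
            continue
        cp = consensus_potency(eps, particle=particle, cell_line=cell_line)
        rows.append(
            {
                "particle": particle,
                "cell_line": cell_line,
                "beta_ldh": eps["LDH"],
                "beta_atp": eps["ATP"],
                "beta_ctb": eps["CTB"],
                "beta_avg": cp.beta_avg,
            }
        )
    return pd.DataFrame(rows)


def rank_particles(
    consensus: "Sequence[ConsensusPotency] | pd.DataFrame",
    precision: int = 3,
) -> pd.DataFrame:
    """Dense-rank particles by rounded beta_avg, descending.

    beta_avg is rounded to ``precision`` decimals first; equal rounded
    values share a rank and the next distinct value receives the next
    consecutive integer (so ranks are always {1..k} for k distinct rounded
    values).  All entries must come from a single cell line.
    """
    if isinstance(consensus, pd.DataFrame):
        if consensus.empty:
            raise ValueError("empty consensus table")
        particles = consensus["particle"].tolist()
        cell_lines = set(consensus["cell_line"]) if "cell_line" in consensus else {""}
        values = consensus["beta_avg"].to_numpy(dtype=float)
    else:
        if len(consensus) == 0:
            raise ValueError("empty consensus list")
        particles = [c.particle for c in consensus]
        cell_lines = {c.cell_line for c in consensus}
        values = np.array([c.beta_avg for c in consensus], dtype=float)
    if len(cell_lines) > 1:
        raise ValueError(f"rank_particles expects a single cell line, got {cell_lines}")

    rounded = np.round(values, precision)
    distinct = sorted(set(rounded.tolist()), reverse=True)
    rank_of = {v: i + 1 for i, v in enumerate(distinct)}
    return pd.DataFrame(
        {
            "particle": particles,
            "cell_line": list(cell_lines)[0],
            "rounded_beta_avg": rounded,
            "rank": [rank_of[v] for v in rounded.tolist()],
        }
    )
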