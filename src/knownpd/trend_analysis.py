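"""Trend regression on log contributions and per-order summaries.

The decline of marginal PD contributions over the discovery record is
summarized by an ordinary least-squares fit of log(mean contribution) on
either description year or discovery count, one point per species.  The
fitted slope b translates into a percent decline per unit x of
100 x (1 - exp(b)) — the multiplicative "percent relative to the previous
value" reading — with a delta-method standard error 100 x exp(b) x SE(b).
A second fit restricted to species described from a cutoff year onwards
(1780 by default in the pipeline) removes the influence of the initial burst
of descriptions.

Per-order accumulation curves, decade-by-order fraction matrices, the most
distinctive species of each decade, and the recent mean per-discovery PD
increment complete the summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .pd_accumulation import ContributionTable

__all__ = [
    "TrendFit",
    "OrderSummary",
    "FitError",
    "fit_decline",
    "per_order_curves",
    "decade_fractions",
    "distinctive_per_decade",
    "recent_increment",
]


class FitError(Exception):
    pass


@dataclass
class TrendFit:
    slope: float
    slope_se: float
    intercept: float
    percent_decline: float
    percent_decline_se: float
    x_variable: str
    from_x: float | None
    n_points: int

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "slope_se": self.slope_se,
            "intercept": self.intercept,
            "percent_decline": self.percent_decline,
            "percent_decline_se": self.percent_decline_se,
            "x_variable": self.x_variable,
            "from_x": self.from_x,
            "n_points": self.n_points,
        }


@dataclass
class OrderSummary:
    order: str
    years: np.ndarray
    pd_cum: np.ndarray  # unnormalized cumulative contribution, Myr
    pd_fraction: np.ndarray  # cumulative / order total
    richness_cum: np.ndarray
    richness_fraction: np.ndarray
    decade_new_pd: pd.Series  # decade -> new PD described in that decade


def _as_frame(contribs, table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Normalize input to a frame with species/year/contribution (+order)."""
    if isinstance(contribs, ContributionTable):
        df = contribs.to_frame().rename(columns={"mean_pd": "contribution"})
    else:
        df = contribs.copy()
        for cand in ("contribution", "mean_pd", "mean"):
            if cand in df.columns:
                df = df.rename(columns={cand: "contribution"})
                break
        else:
            raise ValueError("no contribution column found")
    if table is not None:
        extra = [c for c in ("order", "family", "year") if c not in df.columns]
        if extra:
            df = df.merge(table[["species"] + extra], on="species", how="left")
    if "year" not in df.columns:
        raise ValueError("no year column found")
    return df


def fit_decline(
    contribs,
    table: pd.DataFrame | None = None,
    x: str = "year",
    from_x: float | None = None,
) -> TrendFit:
    """OLS of log(mean contribution) on year or discovery count.

    One point per species; species sharing a year share an x on the year
    axis, and on the count axis ranks are assigned by (year, species name).
    ``from_x`` keeps only species with x at or after the cutoff.
    """
    df = _as_frame(contribs, table)
    if (df["contribution"] <= 0).any():
        raise FitError("contributions must be positive for log fitting")
    if x == "year":
        xv = df["year"].to_numpy(dtype=float)
    elif x == "count":
        rank_order = np.lexsort((df["species"].to_numpy(), df["year"].to_numpy()))
        xv = np.empty(len(df))
        xv[rank_order] = np.arange(1, len(df) + 1)
    else:
        raise ValueError(f"unknown x variable {x!r}")
    y = np.log(df["contribution"].to_numpy(dtype=float))
    if from_x is not None:
        keep = xv >= from_x
        xv, y = xv[keep], y[keep]
    if len(xv) < 3:
        raise FitError(f"need at least 3 points, got {len(xv)}")
    model = sm.OLS(y, sm.add_constant(xv)).fit()
    slope = float(model.params[1])
    se = float(model.bse[1])
    return TrendFit(
        slope=slope,
        slope_se=se,
        intercept=float(model.params[0]),
        percent_decline=100.0 * (1.0 - math.exp(slope)),
        percent_decline_se=100.0 * math.exp(slope) * se,
        x_variable=x,
        from_x=from_x,
        n_points=int(len(xv)),
    )


def _decade(year: np.ndarray, decade_start: int = 1750) -> np.ndarray:
    return decade_start + 10 * ((year - decade_start) // 10)


def per_order_curves(
    contribs, table: pd.DataFrame | None = None, decade_start: int = 1750
) -> dict[str, OrderSummary]:
    """Cumulative PD and richness curves per order, normalized to the order's
    final totals, plus decade-wise new-PD totals."""
    df = _as_frame(contribs, table)
    if "order" not in df.columns or df["order"].isna().any():
        raise ValueError("every species needs an order label")
    out: dict[str, OrderSummary] = {}
    for order_name, sub in df.groupby("order", sort=True):
        per_year = sub.groupby("year")["contribution"].agg(["sum", "count"]).sort_index()
        years = per_year.index.to_numpy()
        pd_cum = per_year["sum"].to_numpy().cumsum()
        rich_cum = per_year["count"].to_numpy().cumsum()
        decade_new = (
            sub.assign(decade=_decade(sub["year"].to_numpy(), decade_start))
            .groupby("decade")["contribution"]
            .sum()
        )
        out[order_name] = OrderSummary(
            order=order_name,
            years=years,
            pd_cum=pd_cum,
            pd_fraction=pd_cum / pd_cum[-1],
            richness_cum=rich_cum,
            richness_fraction=rich_cum / rich_cum[-1],
            decade_new_pd=decade_new,
        )
    return out


def decade_fractions(
    contribs,
    table: pd.DataFrame | None = None,
    mode: str = "within",
    decade_start: int = 1750,
) -> pd.DataFrame:
    """Decade x order matrix of PD-contribution fractions.

    ``within``: each decade's new PD split across orders (rows sum to 1 for
    decades with discoveries).  ``cumulative``: running PD per order divided
    by the running total (the final row is each order's share of total PD).
    Decades are calendar decades from ``decade_start``.
    """
    df = _as_frame(contribs, table)
    if "order" not in df.columns:
        raise ValueError("order labels required")
    df = df.assign(decade=_decade(df["year"].to_numpy(), decade_start))
    mat = df.pivot_table(
        index="decade", columns="order", values="contribution", aggfunc="sum", fill_value=0.0
    ).sort_index()
    if mode == "within":
        totals = mat.sum(axis=1)
        return mat.div(totals.where(totals > 0, np.nan), axis=0)
    if mode == "cumulative":
        cum = mat.cumsum(axis=0)
        return cum.div(cum.sum(axis=1), axis=0)
    raise ValueError(f"unknown mode {mode!r}")


def distinctive_per_decade(
    contribs, table: pd.DataFrame | None = None, decade_start: int = 1750
) -> pd.DataFrame:
    """The species with the largest mean contribution in each decade.

    Ties go to the earlier description year, then to the lexicographically
    smaller name.
    """
    df = _as_frame(contribs, table)
    df = df.assign(decade=_decade(df["year"].to_numpy(), decade_start))
    df = df.sort_values(
        ["decade", "contribution", "year", "species"],
        ascending=[True, False, True, True],
        kind="stable",
    )
    best = df.groupby("decade", sort=True).head(1)
    return best[["decade", "species", "year", "contribution"]].reset_index(drop=True)


def recent_increment(
    contribs, table: pd.DataFrame | None = None, window_years: int = 50
) -> float:
    """Mean per-species contribution over the trailing window of years —
    the asymptotic per-discovery PD increment estimate."""
    df = _as_frame(contribs, table)
    last = int(df["year"].max())
    sel = df["year"] > last - window_years
    if not sel.any():
        raise FitError("no species described within the window")
    return float(df.loc[sel, "contribution"].mean())
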