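"""Statistical comparisons and models over pairwise connectivity.

Covers the analyses typically run on a PCI matrix:

* log10 transforms (PCI is scaled by 1000 before the log so that values
  down to 0.001 stay non-negative on the log scale);
* matrix-vs-matrix Pearson correlation on the inner join of two edge
  lists, overall and per origin place;
* power-law distance-decay fits y = a * d^(-b), nonlinear least squares
  on the raw scale initialized from the log-log OLS solution;
* the boundary-effect regression of connectivity on a same-parent
  indicator controlling for centroid distance;
* focal-place association models regressing a per-place outcome on
  connectivity to one focal place (PCI scaled by 1000 in the design).

Regression summaries reproduce the conventional table layout:
coefficient, standard error, significance stars (* p<0.1, ** p<0.05,
*** p<0.01), adjusted R^2, observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .geodata_io import EdgeList, GeoDataError, PlaceSummary, canonical_pair


class AnalysisError(ValueError):
    """Raised on inputs a model cannot be fit to."""


# ---------------------------------------------------------------------------
# transforms and joins


def log_transform(
    values: np.ndarray | pd.Series, kind: str = "plain"
) -> tuple[np.ndarray, int]:
    """log10 transform; ``kind='pci'`` multiplies by 1000 first.

    Non-positive inputs (after scaling) are dropped; returns the
    transformed values and the dropped count.
    """
    v = np.asarray(values, dtype=float)
    if kind == "pci":
        v = 1000.0 * v
    elif kind != "plain":
        raise AnalysisError(f"unknown transform kind: {kind!r}")
    ok = v > 0
    if not ok.any():
        raise AnalysisError("all values non-positive; nothing to transform")
    return np.log10(v[ok]), int((~ok).sum())


def _apply_transform(v: np.ndarray, kind: str | None) -> tuple[np.ndarray, np.ndarray]:
    """Element-wise transform returning (values, keep-mask)."""
    v = np.asarray(v, dtype=float)
    if kind is None:
        return v, np.ones(len(v), dtype=bool)
    if kind == "pci":
        v = 1000.0 * v
    elif kind != "plain":
        raise AnalysisError(f"unknown transform kind: {kind!r}")
    ok = v > 0
    out = np.full(len(v), np.nan)
    out[ok] = np.log10(v[ok])
    return out, ok


def pair_edges(
    a: EdgeList,
    b: EdgeList,
    distances: EdgeList | None = None,
    parent_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Inner join of two symmetric edge lists on unordered pair keys.

    Only pairs present (i.e. nonzero) in both inputs are kept.  Optional
    decorations: ``distance_miles`` from a distance edge list and
    ``same_parent`` (1 when both places share a parent id).
    """
    left = a.df.rename(columns={"value": "x"})
    right = b.df.rename(columns={"value": "y"})
    table = left.merge(right, on=["place_i", "place_j"], how="inner")
    if distances is not None:
        dd = distances.df.rename(columns={"value": "distance_miles"})
        table = table.merge(dd, on=["place_i", "place_j"], how="left")
    if parent_map is not None:
        pi = table["place_i"].map(parent_map)
        pj = table["place_j"].map(parent_map)
        table["same_parent"] = (
            pi.notna() & pj.notna() & (pi == pj)
        ).astype(int)
    return table.reset_index(drop=True)


# ---------------------------------------------------------------------------
# correlation


def correlate(
    table: pd.DataFrame,
    transform_x: str | None = None,
    transform_y: str | None = None,
) -> tuple[float, int]:
    """Pearson r of the (optionally log-transformed) x and y columns."""
    tx, okx = _apply_transform(table["x"].to_numpy(), transform_x)
    ty, oky = _apply_transform(table["y"].to_numpy(), transform_y)
    ok = okx & oky
    n = int(ok.sum())
    if n < 3:
        raise AnalysisError(f"need >= 3 records after transforms, got {n}")
    r = float(stats.pearsonr(tx[ok], ty[ok]).statistic)
    return r, n


def per_origin_stats(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Per-origin Pearson r and OLS slope of y on x.

    Every pair (i, j) contributes to both origins i and j.  Origins with
    fewer than 3 incident pairs are omitted and tallied.
    """
    long = pd.concat(
        [
            table.rename(columns={"place_i": "origin"})[["origin", "x", "y"]],
            table.rename(columns={"place_j": "origin"})[["origin", "x", "y"]],
        ],
        ignore_index=True,
    )
    rows = []
    n_omitted = 0
    for origin, g in long.groupby("origin"):
        if len(g) < 3 or g["x"].nunique() < 2:
            n_omitted += 1
            continue
        slope, _, r, _, _ = stats.linregress(g["x"], g["y"])
        rows.append(
            {"origin": origin, "pearson_r": r, "ols_slope": slope, "n": len(g)}
        )
    return pd.DataFrame(rows, columns=["origin", "pearson_r", "ols_slope", "n"]), n_omitted


# ---------------------------------------------------------------------------
# distance decay


@dataclass
class DecayFit:
    """Power-law fit y = amplitude * d^(-exponent)."""

    amplitude: float
    exponent: float
    r_squared: float
    n_pairs: int
    fallback: bool = False  # True when only the log-log fit converged

    def predict(self, d: np.ndarray) -> np.ndarray:
        return self.amplitude * np.asarray(d, float) ** (-self.exponent)


def _loglog_powerlaw(d: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form OLS of log y on log d -> (amplitude, exponent)."""
    slope, intercept, *_ = stats.linregress(np.log(d), np.log(y))
    return float(np.exp(intercept)), float(-slope)


def fit_distance_decay(
    distance: np.ndarray, y: np.ndarray, method: str = "nls"
) -> DecayFit:
    """Fit y = a * d^(-b) to pairwise values against distance.

    ``method='nls'`` (default) fits by raw-scale nonlinear least
    squares initialized from the log-log OLS solution — appropriate for
    a single origin, where the amplitude is common to all pairs and the
    raw-scale R^2 is the quantity of interest.  ``method='loglog'``
    returns the closed-form OLS fit of log y on log d — the standard
    estimator of a *common exponent* across pairs pooled over many
    origins, where amplitudes vary by orders of magnitude and would
    otherwise dominate the raw-scale objective.  R^2 is always reported
    on the raw scale.  If the nonlinear fit fails, the log-log closed
    form is returned with ``fallback=True``.
    """
    if method not in ("nls", "loglog"):
        raise AnalysisError(f"unknown decay fit method: {method!r}")
    d = np.asarray(distance, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = (d > 0) & (y > 0) & np.isfinite(d) & np.isfinite(y)
    d, y = d[ok], y[ok]
    if len(d) < 3:
        raise AnalysisError(f"need >= 3 positive pairs, got {len(d)}")
    if np.ptp(y) == 0:  # constant response: flat power law
        return DecayFit(float(y[0]), 0.0, 1.0, len(d))
    a0, b0 = _loglog_powerlaw(d, y)

    def model(dd: np.ndarray, a: float, b: float) -> np.ndarray:
        return a * dd ** (-b)

    fallback = False
    if method == "loglog":
        a, b = a0, b0
    else:
        try:
            (a, b), _ = optimize.curve_fit(model, d, y, p0=(a0, b0), maxfev=20000)
            a, b = float(a), float(b)
        except (RuntimeError, optimize.OptimizeWarning):
            a, b, fallback = a0, b0, True
    resid = y - model(d, a, b)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return DecayFit(a, b, r2, len(d), fallback)


def decay_for_origin(
    pci: EdgeList, distances: EdgeList, origin: str
) -> DecayFit:
    """Distance-decay fit restricted to one origin's incident pairs."""
    table = pair_edges(pci, distances)
    inc = table.loc[
        (table["place_i"] == origin) | (table["place_j"] == origin)
    ]
    return fit_distance_decay(inc["y"], inc["x"])


# ---------------------------------------------------------------------------
# regression summaries


@dataclass
class RegressionSummary:
    """OLS fit in the conventional table layout."""

    terms: pd.DataFrame  # name, coefficient, standard_error, p_value
    adjusted_r_squared: float
    n_observations: int

    def coefficient(self, name: str) -> float:
        return float(self.terms.set_index("name").loc[name, "coefficient"])

    def p_value(self, name: str) -> float:
        return float(self.terms.set_index("name").loc[name, "p_value"])

    def to_text(self) -> str:
        """Plain-text table with significance stars."""
        lines = [f"{'term':<14}{'coefficient':>14}{'SE':>12}  sig"]
        for _, row in self.terms.iterrows():
            lines.append(
                f"{row['name']:<14}{row['coefficient']:>14.6g}"
                f"{row['standard_error']:>12.4g}  {_stars(row['p_value'])}"
            )
        lines.append(f"Adjusted R2: {self.adjusted_r_squared:.4f}")
        lines.append(f"Observations: {self.n_observations}")
        lines.append("*p < 0.1, **p < 0.05, ***p < 0.01")
        return "\n".join(lines)


def _stars(p: float) -> str:
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


def _ols_summary(y: np.ndarray, design: pd.DataFrame) -> RegressionSummary:
    x = sm.add_constant(design, has_constant="add")
    if np.linalg.matrix_rank(x.to_numpy()) < x.shape[1]:
        raise AnalysisError("collinear design matrix")
    fit = sm.OLS(np.asarray(y, float), x).fit()
    terms = pd.DataFrame(
        {
            "name": ["intercept"] + list(design.columns),
            "coefficient": fit.params.to_numpy(),
            "standard_error": fit.bse.to_numpy(),
            "p_value": fit.pvalues.to_numpy(),
        }
    )
    return RegressionSummary(
        terms=terms,
        adjusted_r_squared=float(fit.rsquared_adj),
        n_observations=int(fit.nobs),
    )


def boundary_regression(table: pd.DataFrame) -> RegressionSummary:
    """OLS of y on a same-parent indicator and distance.

    Quantifies the boundary effect: the excess connectivity between
    places sharing an administrative parent, at fixed centroid distance.
    Requires ``same_parent`` and ``distance_miles`` decorations.
    """
    for col in ("same_parent", "distance_miles"):
        if col not in table.columns:
            raise AnalysisError(f"table lacks required column {col!r}")
    if len(table) < 10:
        raise AnalysisError(f"need >= 10 records, got {len(table)}")
    design = table[["same_parent", "distance_miles"]].astype(float)
    design.columns = ["same_parent", "distance"]
    return _ols_summary(table["y"].to_numpy(), design)


def focal_association(
    outcomes: PlaceSummary | pd.DataFrame,
    connectivity_to_focal: EdgeList,
    focal: str,
    outcome_col: str = "outcome",
    distances_to_focal: EdgeList | None = None,
    scale: float = 1000.0,
) -> RegressionSummary:
    """Regress a per-place outcome on connectivity to one focal place.

    Connectivity is scaled (default x1000) so coefficients are readable;
    an optional distance-to-focal control can be added.  Used e.g. to
    relate epidemic seeding (infection rates) or evacuation destination
    counts to connectivity with an epicenter or an evacuated place.
    """
    out_df = outcomes.df if isinstance(outcomes, PlaceSummary) else outcomes
    conn = _edges_to_focal(connectivity_to_focal, focal, "connectivity")
    joined = out_df.merge(conn, on="place_id", how="inner")
    if distances_to_focal is not None:
        dist = _edges_to_focal(distances_to_focal, focal, "distance")
        joined = joined.merge(dist, on="place_id", how="inner")
    if len(joined) < 10:
        raise AnalysisError(f"need >= 10 joined rows, got {len(joined)}")
    design = pd.DataFrame({"connectivity": scale * joined["connectivity"]})
    if distances_to_focal is not None:
        design["distance"] = joined["distance"]
    return _ols_summary(joined[outcome_col].to_numpy(), design)


def _edges_to_focal(edges: EdgeList, focal: str, name: str) -> pd.DataFrame:
    df = edges.df
    inc = df.loc[(df["place_i"] == focal) | (df["place_j"] == focal)].copy()
    inc["place_id"] = np.where(
        inc["place_i"] == focal, inc["place_j"], inc["place_i"]
    )
    return inc[["place_id", "value"]].rename(columns={"value": name})
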