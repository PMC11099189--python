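"""Dose-response and drug-combination pharmacology.

Two fitted models and the Chou-Talalay combination analysis built on them:

* ``FourPLModel`` — four-parameter logistic (4PL) nonlinear regression of
  viability on dose, V(d) = bottom + (top - bottom) / (1 + (d/ic50)^h);
  the reported IC50 is the relative EC50 (the inflection dose), the usual
  convention for nonlinear-regression IC50s.
* ``MedianEffectModel`` — the median-effect equation
  fa/(1-fa) = (d/Dm)^m fitted by linear regression of the logit of the
  fraction affected on log dose; Dm is the dose giving fa = 0.5 and m the
  sigmoidicity.
* ``combination_index`` — non-constant-ratio combination index: for each
  observed dose pair (d1, d2) with combined fraction affected fa, the
  single-agent doses Dx_j = Dm_j * (fa/(1-fa))^(1/m_j) that would alone
  produce fa, and CI = d1/Dx1 + d2/Dx2. CI < 1 is synergy, about 1
  additivity (Loewe), > 1 antagonism. ``isobologram_points`` gives the
  normalized isobologram coordinates (d1/Dx1, d2/Dx2), where the
  additivity line is x + y = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

FA_EPS = 1e-4  # clip for logit transforms; CalcuSyn-style handling of fa in {0,1}
CI_ADDITIVE_BAND = (0.9, 1.1)


def four_pl(d, top, bottom, ic50, hill):
    d = np.asarray(d, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(d > 0, (d / ic50) ** hill, 0.0)
    return bottom + (top - bottom) / (1.0 + ratio)


def fraction_affected(table: pd.DataFrame) -> pd.DataFrame:
    """Per-dose fraction affected fa = 1 - V(d)/V(0).

    Replicate viabilities are averaged per dose before the ratio; the
    control is the mean viability of the dose-0 rows. fa is clipped to
    [FA_EPS, 1 - FA_EPS] with clipped points flagged.
    """
    if "replicate" not in table.columns:
        table = table.assign(replicate=1)
    mean_v = table.groupby("dose")["viability"].mean()
    if 0 not in mean_v.index:
        raise ValueError("no dose-0 control rows")
    v0 = mean_v.loc[0]
    if v0 <= 0:
        raise ValueError(f"control viability must be positive, got {v0}")
    doses = mean_v.index[mean_v.index > 0]
    fa_raw = 1.0 - mean_v.loc[doses] / v0
    fa = fa_raw.clip(FA_EPS, 1.0 - FA_EPS)
    out = pd.DataFrame(
        {
            "dose": doses.to_numpy(dtype=float),
            "fa": fa.to_numpy(),
            "clipped": (fa_raw != fa).to_numpy(),
        }
    ).reset_index(drop=True)
    n_clip = int(out["clipped"].sum())
    if n_clip:
        logger.info("fraction_affected: clipped %d points to (%g, %g)", n_clip, FA_EPS, 1 - FA_EPS)
    return out


# ---------------------------------------------------------------------------
# 4PL dose-response


@dataclass(frozen=True)
class FourPLResults:
    """Fitted 4PL parameters with residual sum of squares."""

    top: float
    bottom: float
    ic50: float
    hill: float
    rss: float
    n_points: int

    def predict(self, d):
        return four_pl(d, self.top, self.bottom, self.ic50, self.hill)

    def summary(self) -> str:
        lines = [
            "Four-parameter logistic dose-response fit",
            "=" * 46,
            f"{'n points':<14}{self.n_points:>12d}",
            f"{'top':<14}{self.top:>12.4g}",
            f"{'bottom':<14}{self.bottom:>12.4g}",
            f"{'IC50':<14}{self.ic50:>12.4g}",
            f"{'Hill slope':<14}{self.hill:>12.4g}",
            f"{'RSS':<14}{self.rss:>12.4g}",
        ]
        return "\n".join(lines)

    def plot(self, table: pd.DataFrame | None = None, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if table is not None:
            pos = table[table["dose"] > 0]
            ax.scatter(pos["dose"], pos["viability"], s=12, color="k", zorder=3)
        lo = self.ic50 / 100 if table is None else max(table["dose"][table["dose"] > 0].min(), 1e-12)
        hi = self.ic50 * 100 if table is None else table["dose"].max()
        grid = np.geomspace(lo, hi, 200)
        ax.plot(grid, self.predict(grid))
        ax.set_xscale("log")
        ax.set_xlabel("dose")
        ax.set_ylabel("viability")
        return ax


class FourPLModel:
    """4PL nonlinear regression of viability on dose.

    ``table`` needs columns dose and viability (replicate optional).
    Fitting uses least squares with multi-start initialization over a
    log-spaced IC50 grid and several Hill slopes; the best start wins.
    """

    def __init__(self, table: pd.DataFrame, flat_tol: float = 1e-6):
        if not {"dose", "viability"} <= set(table.columns):
            raise ValueError("table needs 'dose' and 'viability' columns")
        self.table = table.reset_index(drop=True)
        self.flat_tol = flat_tol
        if (self.table["dose"] > 0).sum() and self.table[self.table["dose"] > 0]["dose"].nunique() < 4:
            raise ValueError("need at least 4 distinct nonzero doses")

    def fit(self) -> FourPLResults:
        d = self.table["dose"].to_numpy(dtype=float)
        v = self.table["viability"].to_numpy(dtype=float)
        if np.var(v) < self.flat_tol:
            raise ValueError(
                "degenerate fit: response is flat (variance below tolerance)"
            )
        pos = d[d > 0]
        top0, bot0 = float(v.max()), float(v.min())
        starts = [
            (top0, bot0, ic50, h)
            for ic50 in np.geomspace(pos.min(), pos.max(), 5)
            for h in (0.5, 1.0, 2.0, 4.0)
        ]
        span = v.max() - v.min()
        bounds = (
            [v.min() - span, v.min() - span, pos.min() / 1e3, 1e-3],
            [v.max() + span, v.max() + span, pos.max() * 1e3, 50.0],
        )
        best: tuple[float, np.ndarray] | None = None
        failures = []
        for p0 in starts:
            try:
                popt, _ = optimize.curve_fit(
                    four_pl, d, v, p0=p0, bounds=bounds, maxfev=20000
                )
            except RuntimeError as err:  # pragma: no cover - depends on data
                failures.append(str(err))
                continue
            rss = float(np.sum((v - four_pl(d, *popt)) ** 2))
            if best is None or rss < best[0]:
                best = (rss, popt)
        if best is None:
            raise RuntimeError(
                f"4PL fit failed to converge from {len(starts)} starts: {failures[-1]}"
            )
        rss, (top, bottom, ic50, hill) = best
        if top < bottom:  # canonicalize: top is the high-response asymptote
            top, bottom, hill = bottom, top, -hill
        return FourPLResults(
            top=float(top),
            bottom=float(bottom),
            ic50=float(ic50),
            hill=float(hill),
            rss=rss,
            n_points=len(d),
        )


def fit_4pl(table: pd.DataFrame) -> FourPLResults:
    """Convenience wrapper: fit a 4PL model to a dose-response table."""
    return FourPLModel(table).fit()


# ---------------------------------------------------------------------------
# Median-effect model


@dataclass(frozen=True)
class MedianEffectResults:
    """Median-effect parameters: Dm (dose at fa=0.5), m, and the r^2 of the
    linearized fit."""

    dm: float
    m: float
    r2: float
    n_points: int

    def dose_for_fa(self, fa) -> np.ndarray:
        """Single-agent dose Dx producing fraction affected fa."""
        fa = np.asarray(fa, dtype=float)
        return self.dm * (fa / (1.0 - fa)) ** (1.0 / self.m)

    def fa_at(self, dose) -> np.ndarray:
        ratio = (np.asarray(dose, dtype=float) / self.dm) ** self.m
        return ratio / (1.0 + ratio)

    def summary(self) -> str:
        lines = [
            "Median-effect fit  (fa/(1-fa) = (d/Dm)^m)",
            "=" * 46,
            f"{'n points':<14}{self.n_points:>12d}",
            f"{'Dm':<14}{self.dm:>12.6g}",
            f"{'m':<14}{self.m:>12.6g}",
            f"{'r^2':<14}{self.r2:>12.6g}",
        ]
        return "\n".join(lines)


class MedianEffectModel:
    """Linearized median-effect fit: regress log(fa/(1-fa)) on log(d).

    Only points with fa strictly inside (FA_EPS, 1-FA_EPS) and d > 0 are
    used; the slope is m and the intercept -m*log(Dm).
    """

    def __init__(self, doses, fa):
        doses = np.asarray(doses, dtype=float)
        fa = np.asarray(fa, dtype=float)
        usable = (doses > 0) & (fa > FA_EPS) & (fa < 1.0 - FA_EPS)
        if usable.sum() < 2:
            raise ValueError(
                f"need >= 2 points with fa strictly in ({FA_EPS}, {1 - FA_EPS}); "
                f"got {int(usable.sum())}"
            )
        self.doses = doses[usable]
        self.fa = fa[usable]

    def fit(self) -> MedianEffectResults:
        x = np.log(self.doses)
        y = np.log(self.fa / (1.0 - self.fa))
        res = stats.linregress(x, y)
        m = float(res.slope)
        if m <= 0:
            raise ValueError(f"median-effect slope m must be positive, got {m:.4g}")
        dm = float(np.exp(-res.intercept / m))
        return MedianEffectResults(dm=dm, m=m, r2=float(res.rvalue**2), n_points=len(x))


def median_effect_fit(doses, fa) -> MedianEffectResults:
    return MedianEffectModel(doses, fa).fit()


# ---------------------------------------------------------------------------
# Combination index and isobologram


def ci_call(ci: float, band: tuple[float, float] = CI_ADDITIVE_BAND) -> str:
    if ci < band[0]:
        return "synergy"
    if ci > band[1]:
        return "antagonism"
    return "additive"


def combination_index(
    grid: pd.DataFrame,
    fit1: MedianEffectResults,
    fit2: MedianEffectResults,
    band: tuple[float, float] = CI_ADDITIVE_BAND,
) -> pd.DataFrame:
    """Non-constant-ratio combination index per observed dose pair.

    ``grid`` needs columns d1, d2, fa (combined fraction affected at that
    pair). Pairs with fa outside the open clipping interval are skipped
    with a warning. A zero dose contributes nothing to its CI term, so a
    single-agent row reproduces CI = 1 when its fa matches its own fit.
    """
    need = {"d1", "d2", "fa"}
    if not need <= set(grid.columns):
        raise ValueError(f"grid needs columns {sorted(need)}")
    usable = (grid["fa"] > FA_EPS) & (grid["fa"] < 1.0 - FA_EPS)
    n_skip = int((~usable).sum())
    if n_skip:
        logger.warning("combination_index: skipped %d pairs with boundary fa", n_skip)
    g = grid[usable].reset_index(drop=True)
    dx1 = fit1.dose_for_fa(g["fa"])
    dx2 = fit2.dose_for_fa(g["fa"])
    ci = g["d1"].to_numpy() / dx1 + g["d2"].to_numpy() / dx2
    out = g[["d1", "d2", "fa"]].copy()
    out["dx1"] = dx1
    out["dx2"] = dx2
    out["ci"] = ci
    out["call"] = [ci_call(c, band) for c in ci]
    return out


def isobologram_points(
    ci_results: pd.DataFrame, fa_level: float, fa_tol: float = 0.05
) -> pd.DataFrame:
    """Normalized isobologram coordinates for pairs near an effect level.

    Each pair with |fa - fa_level| <= fa_tol maps to (d1/Dx1, d2/Dx2) in
    the unit-square frame; the Loewe additivity line is x + y = 1.
    Returns an empty table (with a warning) if no pair is close enough.
    """
    near = ci_results[(ci_results["fa"] - fa_level).abs() <= fa_tol]
    if len(near) == 0:
        logger.warning("isobologram_points: no pairs within %g of fa=%g", fa_tol, fa_level)
        return pd.DataFrame(columns=["x", "y", "fa", "ci"])
    return pd.DataFrame(
        {
            "x": near["d1"].to_numpy() / near["dx1"].to_numpy(),
            "y": near["d2"].to_numpy() / near["dx2"].to_numpy(),
            "fa": near["fa"].to_numpy(),
            "ci": near["ci"].to_numpy(),
        }
    )


def plot_fa_ci(ci_results: pd.DataFrame, ax=None):
    """Fraction-affected vs combination-index plot with the CI=1 line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(ci_results["fa"], ci_results["ci"], s=14)
    ax.axhline(1.0, ls="--", color="gray")
    ax.set_xlabel("fraction affected (Fa)")
    ax.set_ylabel("combination index (CI)")
    return ax


def plot_isobologram(points: pd.DataFrame, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot([0, 1], [1, 0], ls="--", color="gray")  # additivity line
    if len(points):
        ax.scatter(points["x"], points["y"], s=14)
    ax.set_xlabel("d1 / Dx1")
    ax.set_ylabel("d2 / Dx2")
    return ax
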