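"""Dosimetric model comparison: percent differences, RMSE, averages.

Effective-dose series from different codes and models (reference-phantom
tabulations, Monte Carlo runs, machine-learning predictions) rarely
share a complete energy grid.  All statistics here are
pairwise-complete-case: an energy enters a pairwise statistic only when
both series have a value there, and the multi-model average at an energy
is taken over the models that define it.  Display rounding follows the
conventions of published dose tables (4 significant figures for ED,
2 decimals for percent differences); internal arithmetic is full
precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

_DATA_PACKAGE = "voxdose.data"
_TABLE1_RESOURCE = "ap_effective_dose_models.csv"


@dataclass(frozen=True)
class DoseSeries:
    """One model's effective-dose column on an energy grid.

    Missing entries are NaN and are excluded from every statistic.
    """

    name: str
    energies_mev: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.energies_mev, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if e.shape != v.shape:
            raise ValueError(f"{self.name}: grid and values differ in length")
        object.__setattr__(self, "energies_mev", e)
        object.__setattr__(self, "values", v)

    @property
    def mask(self) -> np.ndarray:
        """True where a value is defined."""
        return ~np.isnan(self.values)


def percent_diff(value: float, reference: float) -> float:
    """(value - reference) / reference * 100."""
    if reference == 0:
        raise ZeroDivisionError("percent difference undefined for zero reference")
    return (value - reference) / reference * 100.0


def series_percent_diff(a: DoseSeries, b: DoseSeries) -> np.ndarray:
    """Per-energy percent difference of ``a`` vs reference ``b`` (NaN
    where either is missing)."""
    _check_grids(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (a.values - b.values) / b.values * 100.0


def _check_grids(a: DoseSeries, b: DoseSeries) -> None:
    if a.energies_mev.shape != b.energies_mev.shape or not np.allclose(
            a.energies_mev, b.energies_mev):
        raise ValueError(f"series {a.name!r} and {b.name!r} are on different grids")


def rmse(a: DoseSeries, b: DoseSeries) -> float:
    """Root mean square difference over the pairwise-complete energies."""
    v, _ = rmse_with_n(a, b)
    return v


def rmse_with_n(a: DoseSeries, b: DoseSeries) -> tuple[float, int]:
    _check_grids(a, b)
    m = a.mask & b.mask
    if not m.any():
        raise ValueError(f"series {a.name!r} and {b.name!r} share no energies")
    d = a.values[m] - b.values[m]
    return float(np.sqrt(np.mean(d * d))), int(m.sum())


def model_average(series: list[DoseSeries], name: str = "SA-Average") -> DoseSeries:
    """Per-energy arithmetic mean over the models that define a value."""
    if not series:
        raise ValueError("model_average needs at least one series")
    grid = series[0].energies_mev
    for s in series[1:]:
        _check_grids(series[0], s)
    stack = np.vstack([s.values for s in series])
    with np.errstate(invalid="ignore"):
        avg = np.where(np.all(np.isnan(stack), axis=0), np.nan,
                       np.nanmean(stack, axis=0))
    return DoseSeries(name, grid.copy(), avg)


@dataclass
class ComparisonReport:
    """Pairwise statistics for a set of dose series.

    ``rmse_matrix``/``n_matrix`` are symmetric DataFrames (zero/N on the
    diagonal); ``percent_diff`` holds per-energy percent differences of
    every model against the reference; ``max_abs_diff`` maps each
    unordered pair to ``(max |percent difference|, energy)``.
    """

    reference: str
    rmse_matrix: pd.DataFrame
    n_matrix: pd.DataFrame
    percent_diff: pd.DataFrame
    max_abs_diff: dict[tuple[str, str], tuple[float, float]]


def build_report(series: list[DoseSeries], reference: str) -> ComparisonReport:
    """Full pairwise percent-difference and RMSE report."""
    names = [s.name for s in series]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate model names: {names}")
    if reference not in names:
        raise ValueError(f"reference {reference!r} not among {names}")
    by_name = {s.name: s for s in series}
    ref = by_name[reference]

    r = pd.DataFrame(0.0, index=names, columns=names)
    n = pd.DataFrame(0, index=names, columns=names)
    maxdiff: dict[tuple[str, str], tuple[float, float]] = {}
    for i, a in enumerate(names):
        n.loc[a, a] = int(by_name[a].mask.sum())
        for b in names[i + 1:]:
            v, k = rmse_with_n(by_name[a], by_name[b])
            r.loc[a, b] = r.loc[b, a] = v
            n.loc[a, b] = n.loc[b, a] = k
            # convention: the later model compared against the earlier one
            pd_ba = series_percent_diff(by_name[b], by_name[a])
            idx = np.nanargmax(np.abs(pd_ba))
            maxdiff[(a, b)] = (float(pd_ba[idx]),
                               float(by_name[b].energies_mev[idx]))

    pdiff = pd.DataFrame(
        {s.name: series_percent_diff(s, ref) for s in series if s.name != reference},
        index=pd.Index(ref.energies_mev, name="energy_MeV"),
    )
    return ComparisonReport(reference, r, n, pdiff, maxdiff)


# ----------------------------------------------------------------------
# Published AP effective-dose table

def load_published_series(path_or_buf=None):
    """Load the packaged AP effective-dose comparison table.

    Returns ``(series, openmc_uncertainty)`` where ``series`` is the list
    of published model columns (ICRP-116, XGB-SA, MCNPX, OpenMC) as
    :class:`DoseSeries` on the common 20-energy grid.
    """
    if path_or_buf is None:
        with resources.files(_DATA_PACKAGE).joinpath(_TABLE1_RESOURCE).open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path_or_buf)
    e = df["energy_MeV"].to_numpy(dtype=float)
    series = [
        DoseSeries(c, e, df[c].to_numpy(dtype=float))
        for c in df.columns
        if c not in ("energy_MeV",) and not c.endswith("_uncertainty")
    ]
    unc = (df["OpenMC_uncertainty"].to_numpy(dtype=float)
           if "OpenMC_uncertainty" in df.columns else None)
    return series, unc


def saudi_average(series: list[DoseSeries]) -> DoseSeries:
    """Average of the Saudi-phantom models (everything but ICRP-116)."""
    own = [s for s in series if s.name != "ICRP-116"]
    return model_average(own, name="SA-Average")


# ----------------------------------------------------------------------
# Plots

def plot_series(series: list[DoseSeries], path=None, ax=None):
    """Log-log ED vs E line plot for a set of models."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for s in series:
        m = s.mask
        ax.plot(s.energies_mev[m], s.values[m], marker="o", ms=3, label=s.name)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("photon energy (MeV)")
    ax.set_ylabel("effective dose (pSv cm$^2$)")
    ax.legend(fontsize=8)
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_organ_heatmap(dose_df: pd.DataFrame, path=None):
    """Heatmap of organ DCCs (organs x energies), log colour scale."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LogNorm

    fig, ax = plt.subplots(figsize=(8, 6))
    data = dose_df.to_numpy(dtype=float)
    vmin = np.nanmin(data[data > 0]) if np.any(data > 0) else 1e-12
    im = ax.imshow(data, aspect="auto", cmap="viridis",
                   norm=LogNorm(vmin=vmin, vmax=np.nanmax(data)))
    ax.set_yticks(range(len(dose_df.index)), dose_df.index, fontsize=6)
    ax.set_xticks(range(len(dose_df.columns)),
                  [f"{e:g}" for e in dose_df.columns], rotation=90, fontsize=6)
    ax.set_xlabel("photon energy (MeV)")
    fig.colorbar(im, ax=ax, label="organ dose (pGy cm$^2$)")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return ax
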