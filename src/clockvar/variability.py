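"""Correlated / uncorrelated transcriptional variability of a gene pair.

The segmentation-clock genes *her1* and *her7* are read out together in each
cell by smFISH.  Across a population of cells in the same oscillation phase
(a single-cell-wide posterior-anterior slice of the PSM), cell-to-cell
variability of the two transcripts decomposes, exactly as in dual-reporter
noise analysis, into

* **correlated variability** — normalised covariance
  ``(<xy> - <x><y>) / (<x><y>)``, the component shared by both genes
  (extrinsic-like: cell volume, shared upstream factors, burst co-firing);
* **uncorrelated variability** — ``1/2 <(x/<x> - y/<y>)^2>``, the component
  independent between the genes (intrinsic-like: birth-death counting noise,
  independent bursts);
* **total variability** — their sum, which algebraically equals
  ``(CV^2(x) + CV^2(y)) / 2``.

All angle brackets are plain population averages (1/n moments, not 1/(n-1));
this convention is used consistently throughout the package.

The module also provides the slice-level pipeline: per-slice variability
points, quantile binning of those points into a variability-versus-mean
curve, cell-volume normalisation, and a statsmodels-style
:class:`VariabilityModel` / :class:`VariabilityResults` pair wrapping it all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateStatisticError, EmptyInputError, ValidationError

__all__ = [
    "uncorrelated_variability",
    "correlated_variability",
    "total_variability",
    "volume_correct",
    "slice_statistics",
    "SliceStatistics",
    "bin_curve",
    "BinnedCurve",
    "mean_spatial_profile",
    "VariabilityModel",
    "VariabilityResults",
]

#: Columns of a slice-level variability-point table.
POINT_COLUMNS = [
    "embryo_id",
    "half",
    "slice_index",
    "n_cells",
    "mean_her",
    "correlated",
    "uncorrelated",
    "total",
]


def _as_paired_arrays(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(
            f"x and y must be matched 1-d vectors; got shapes {x.shape} and {y.shape}"
        )
    if x.size < 2:
        raise ValidationError("variability needs at least 2 cells")
    mx, my = x.mean(), y.mean()
    if mx <= 0 or my <= 0:
        raise DegenerateStatisticError(
            f"variability undefined for non-positive mean expression "
            f"(<x>={mx:g}, <y>={my:g})"
        )
    return x, y


def uncorrelated_variability(x, y) -> float:
    """Uncorrelated (intrinsic-like) variability of a paired gene readout.

    ``1/2 <(x_i/<x> - y_i/<y>)^2>`` with population (1/n) averages.
    Non-negative; zero iff the two normalised profiles are identical.
    """
    x, y = _as_paired_arrays(x, y)
    d = x / x.mean() - y / y.mean()
    return float(0.5 * np.mean(d * d))


def correlated_variability(x, y) -> float:
    """Correlated (extrinsic-like) variability: ``(<xy> - <x><y>)/(<x><y>)``.

    May be negative (the estimator is unbiased around 0 for independent
    genes and is reported as-is, without flooring).
    """
    x, y = _as_paired_arrays(x, y)
    mx, my = x.mean(), y.mean()
    return float((np.mean(x * y) - mx * my) / (mx * my))


def total_variability(x, y) -> float:
    """Total variability: correlated + uncorrelated = (CV^2_x + CV^2_y)/2."""
    return correlated_variability(x, y) + uncorrelated_variability(x, y)


def volume_correct(table):
    """Convert per-cell counts to concentrations (molecules / um^3).

    Returns a table of the same shape with ``her1_count`` and ``her7_count``
    divided by ``volume``.  Uncorrelated variability is essentially
    unaffected by this transform, while any component of correlated
    variability that is proportional to cell volume is removed.
    """
    from .io import CellTable  # local import to avoid a cycle

    df = table.df if isinstance(table, CellTable) else table
    vol = df["volume"].to_numpy(dtype=float)
    if np.any(vol <= 0):
        bad = int(np.flatnonzero(vol <= 0)[0])
        raise ValidationError(f"non-positive volume at row {bad}")
    out = df.copy()
    out["her1_count"] = df["her1_count"].to_numpy(dtype=float) / vol
    out["her7_count"] = df["her7_count"].to_numpy(dtype=float) / vol
    if isinstance(table, CellTable):
        prov = dict(table.provenance)
        prov["volume_corrected"] = True
        return CellTable(out, provenance=prov, validate=False)
    return out


@dataclass
class SliceStatistics:
    """Per-slice variability points plus a report of excluded slices."""

    points: pd.DataFrame  # columns POINT_COLUMNS, one row per retained slice
    n_dropped: int
    dropped: pd.DataFrame  # (embryo_id, half, slice_index, n_cells) of rejects


def slice_statistics(table, min_cells: int = 5) -> SliceStatistics:
    """Compute variability for every (embryo, half, slice) cell group.

    Groups with fewer than ``min_cells`` cells are dropped and reported.
    Groups where either gene has zero mean expression are likewise dropped
    (the statistics are undefined there).
    """
    from .io import CellTable

    df = table.df if isinstance(table, CellTable) else table
    rows, dropped = [], []
    for (embryo, half, sl), g in df.groupby(
        ["embryo_id", "half", "slice_index"], sort=True
    ):
        n = len(g)
        x = g["her1_count"].to_numpy(dtype=float)
        y = g["her7_count"].to_numpy(dtype=float)
        if n < min_cells or x.mean() <= 0 or y.mean() <= 0:
            dropped.append((embryo, half, sl, n))
            continue
        corr = correlated_variability(x, y)
        unc = uncorrelated_variability(x, y)
        rows.append(
            (embryo, half, sl, n, float(x.mean() + y.mean()), corr, unc, corr + unc)
        )
    if not rows:
        raise EmptyInputError(
            f"no slice has >= {min_cells} cells with positive mean expression"
        )
    points = pd.DataFrame(rows, columns=POINT_COLUMNS)
    report = pd.DataFrame(
        dropped, columns=["embryo_id", "half", "slice_index", "n_cells"]
    )
    return SliceStatistics(points=points, n_dropped=len(dropped), dropped=report)


@dataclass
class BinnedCurve:
    """A variability-versus-mean-expression curve with ``n_bins`` bins.

    Slice-level points are sorted by mean her (her1+her7) expression and
    split into near-equal-count quantile bins; each bin stores the mean of
    the member points and the standard error of each variability component
    (population SD / sqrt(n); error bars of 2 SE are applied at plot time).
    """

    bin_mean_her: np.ndarray
    mean_correlated: np.ndarray
    mean_uncorrelated: np.ndarray
    mean_total: np.ndarray
    se_correlated: np.ndarray
    se_uncorrelated: np.ndarray
    n_slices: np.ndarray
    n_bins: int
    volume_corrected: bool = False
    genotype: str = ""

    def component(self, which: str) -> np.ndarray:
        try:
            return {
                "correlated": self.mean_correlated,
                "uncorrelated": self.mean_uncorrelated,
                "total": self.mean_total,
            }[which]
        except KeyError:
            raise ValueError(f"unknown component {which!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_mean_her": self.bin_mean_her,
                "mean_correlated": self.mean_correlated,
                "mean_uncorrelated": self.mean_uncorrelated,
                "mean_total": self.mean_total,
                "se_correlated": self.se_correlated,
                "se_uncorrelated": self.se_uncorrelated,
                "n_slices": self.n_slices,
            }
        )


def bin_curve(
    points: pd.DataFrame,
    n_bins: int = 5,
    volume_corrected: bool = False,
    genotype: str = "",
) -> BinnedCurve:
    """Group slice points into ``n_bins`` quantile bins by mean expression."""
    if len(points) < n_bins:
        raise ValidationError(
            f"need at least n_bins={n_bins} slice points, got {len(points)}"
        )
    # stable sort so ties keep input order (deterministic binning)
    order = np.argsort(points["mean_her"].to_numpy(), kind="stable")
    sorted_pts = points.iloc[order]
    chunks = [sorted_pts.iloc[idx]
              for idx in np.array_split(np.arange(len(sorted_pts)), n_bins)]

    def _agg(col):
        mean = np.array([c[col].mean() for c in chunks])
        se = np.array([c[col].std(ddof=0) / np.sqrt(len(c)) for c in chunks])
        return mean, se

    mean_corr, se_corr = _agg("correlated")
    mean_unc, se_unc = _agg("uncorrelated")
    return BinnedCurve(
        bin_mean_her=np.array([c["mean_her"].mean() for c in chunks]),
        mean_correlated=mean_corr,
        mean_uncorrelated=mean_unc,
        mean_total=np.array([c["total"].mean() for c in chunks]),
        se_correlated=se_corr,
        se_uncorrelated=se_unc,
        n_slices=np.array([len(c) for c in chunks]),
        n_bins=n_bins,
        volume_corrected=volume_corrected,
        genotype=genotype,
    )


def mean_spatial_profile(
    table, embryo_id: str, half: str, gene: str = "her7"
) -> pd.DataFrame:
    """Posterior-to-anterior mean expression profile of one PSM half.

    Returns one row per slice with the mean count of ``gene`` and an error
    bar of 2 SEM (population SD / sqrt(n)), the convention used to display
    the kinematic waves of clock expression.
    """
    from .io import CellTable

    df = table.df if isinstance(table, CellTable) else table
    if gene not in ("her1", "her7"):
        raise ValueError("gene must be 'her1' or 'her7'")
    sel = df[(df["embryo_id"] == embryo_id) & (df["half"] == half)]
    if sel.empty:
        raise EmptyInputError(f"no cells for embryo {embryo_id!r}, half {half!r}")
    col = f"{gene}_count"
    rows = []
    for sl, g in sel.groupby("slice_index", sort=True):
        v = g[col].to_numpy(dtype=float)
        sem = v.std(ddof=0) / np.sqrt(len(v))
        rows.append((int(sl), float(v.mean()), 2.0 * float(sem), len(v)))
    return pd.DataFrame(rows, columns=["slice_index", "mean", "two_sem", "n_cells"])


class VariabilityModel:
    """Transcriptional-variability decomposition of a per-cell count table.

    Parameters
    ----------
    table
        A :class:`~clockvar.io.CellTable` (or equivalent DataFrame) of
        per-cell her1/her7 counts with slice coordinates.
    volume_correct
        Normalise counts to concentrations before computing statistics.
    min_cells
        Minimum cells per slice for a slice to contribute a point.
    genotype
        Label attached to the fitted curve; defaults to the single genotype
        present in the table if unambiguous.
    """

    def __init__(
        self,
        table,
        volume_correct: bool = False,
        min_cells: int = 5,
        genotype: str | None = None,
    ):
        from .io import CellTable

        df = table.df if isinstance(table, CellTable) else table
        if genotype is None:
            labels = df["genotype"].unique()
            genotype = labels[0] if len(labels) == 1 else ""
        self.table = table
        self.volume_corrected = bool(volume_correct)
        self.min_cells = int(min_cells)
        self.genotype = genotype

    def fit(self, n_bins: int = 5) -> "VariabilityResults":
        """Compute per-slice points and the binned variability curve."""
        work = volume_correct(self.table) if self.volume_corrected else self.table
        stats = slice_statistics(work, min_cells=self.min_cells)
        curve = bin_curve(
            stats.points,
            n_bins=n_bins,
            volume_corrected=self.volume_corrected,
            genotype=self.genotype,
        )
        return VariabilityResults(model=self, slice_stats=stats, curve=curve)


@dataclass
class VariabilityResults:
    """Fitted variability decomposition: slice points + binned curve."""

    model: VariabilityModel
    slice_stats: SliceStatistics
    curve: BinnedCurve

    @property
    def points(self) -> pd.DataFrame:
        return self.slice_stats.points

    def component_share(self, which: str = "correlated") -> float:
        """Fraction of total variability carried by one component.

        Averaged over slices (each slice one observation), so the headline
        'correlated contributes X% of total variability' number can be
        quoted directly.
        """
        pts = self.points
        num = pts["correlated" if which == "correlated" else "uncorrelated"].mean()
        return float(num / pts["total"].mean())

    def summary(self) -> str:
        pts, c = self.points, self.curve
        lines = [
            "Transcriptional variability decomposition",
            "=" * 57,
            f"genotype:            {c.genotype or '(mixed)'}",
            f"volume corrected:    {c.volume_corrected}",
            f"slices retained:     {len(pts)}"
            f"  (dropped {self.slice_stats.n_dropped})",
            f"cells:               {int(pts['n_cells'].sum())}",
            f"correlated share:    {100 * self.component_share('correlated'):.1f}%",
            f"uncorrelated share:  {100 * self.component_share('uncorrelated'):.1f}%",
            "",
            f"{'bin':>3} {'mean her':>10} {'corr':>8} {'(2SE)':>8} "
            f"{'uncorr':>8} {'(2SE)':>8} {'n':>4}",
        ]
        for i in range(c.n_bins):
            lines.append(
                f"{i:>3} {c.bin_mean_her[i]:>10.2f} {c.mean_correlated[i]:>8.4f} "
                f"{2 * c.se_correlated[i]:>8.4f} {c.mean_uncorrelated[i]:>8.4f} "
                f"{2 * c.se_uncorrelated[i]:>8.4f} {c.n_slices[i]:>4d}"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot correlated and uncorrelated variability vs mean expression
        with 2 SE error bars."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.curve
        ax.errorbar(
            c.bin_mean_her, c.mean_correlated, yerr=2 * c.se_correlated,
            marker="o", label="correlated",
        )
        ax.errorbar(
            c.bin_mean_her, c.mean_uncorrelated, yerr=2 * c.se_uncorrelated,
            marker="s", label="uncorrelated",
        )
        unit = "molecules/um^3" if c.volume_corrected else "molecules"
        ax.set_xlabel(f"mean her1+her7 ({unit})")
        ax.set_ylabel("variability")
        ax.legend()
        if c.genotype:
            ax.set_title(c.genotype)
        return ax
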