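"""Binned specific-energy distributions and microdosimetric summary metrics.

In microdosimetry the specific energy ``z = eps / m`` (energy imparted per unit
mass of a microscopic sensitive volume, here the cell nucleus) is the stochastic
per-cell analogue of the macroscopic absorbed dose ``D``.  Its distribution over
a cell population, ``f(z, D)``, is represented here as a uniformly binned
probability mass vector (:class:`BinnedDistribution`).  The module provides

* histogramming of per-cell specific energies (:func:`build_distribution`),
* the cumulative form ``F(z, D) = P(Z <= z; D)`` (:func:`cumulative`),
* moments and the dispersion ``sigma / zbar`` (:func:`summarize`),
* a matched normal reference with the same mean and standard deviation
  (:func:`normal_reference`) and the per-bin RMSE against it (:func:`rmse`),
* the v-fold self-convolution of a single-event spectrum ``f1`` giving the
  multi-event spectrum ``f_v`` at cumulative dose ``D = v * D1``
  (:func:`convolution_count`, :func:`convolve`),
* replicate-averaged distributions with per-bin error bars
  (:func:`replicate_frequency_errors`).

All distributions use uniform bins (mandatory for bin-wise comparability),
half-open ``[left, right)`` with the last bin closed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BinnedDistribution",
    "CellDoseSample",
    "DistributionSummary",
    "build_distribution",
    "cumulative",
    "summarize",
    "normal_reference",
    "rmse",
    "convolution_count",
    "convolve",
    "rebin",
    "replicate_frequency_errors",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_cell_dose_csv",
    "write_cell_dose_csv",
]

_MASS_TOL = 1e-9
_UNIFORM_RTOL = 1e-9


@dataclass(frozen=True)
class BinnedDistribution:
    """Uniformly binned probability distribution.

    Parameters
    ----------
    bin_edges : array of shape (n + 1,)
        Strictly increasing, equally spaced bin edges (mGy for dose spectra,
        dimensionless for expression ratios).
    probabilities : array of shape (n,)
        Non-negative per-bin probability mass summing to 1.
    bin_errors : array of shape (n,), optional
        Standard deviation of per-bin probability across replicate runs.
    label : str
        Free-text description.
    """

    bin_edges: np.ndarray
    probabilities: np.ndarray
    bin_errors: Optional[np.ndarray] = None
    label: str = ""

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        probs = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "probabilities", probs)
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("bin_edges must be a 1-d vector of length >= 2")
        if probs.ndim != 1 or probs.size != edges.size - 1:
            raise ValueError("probabilities must have length len(bin_edges) - 1")
        widths = np.diff(edges)
        if np.any(widths <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if not np.allclose(widths, widths[0], rtol=_UNIFORM_RTOL, atol=0.0):
            raise ValueError("bins must be uniform (equal widths)")
        if np.any(probs < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(float(probs.sum()) - 1.0) > _MASS_TOL:
            raise ValueError(
                f"probabilities must sum to 1 (got {probs.sum()!r})"
            )
        if self.bin_errors is not None:
            errs = np.asarray(self.bin_errors, dtype=float)
            object.__setattr__(self, "bin_errors", errs)
            if errs.shape != probs.shape:
                raise ValueError("bin_errors must match probabilities in length")
            if np.any(errs < 0):
                raise ValueError("bin_errors must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.probabilities.size

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        """Tabular form (bin_left, bin_right, probability, bin_error)."""
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "probability": self.probabilities,
                "bin_error": (
                    self.bin_errors
                    if self.bin_errors is not None
                    else np.full(self.n_bins, np.nan)
                ),
            }
        )


@dataclass(frozen=True)
class CellDoseSample:
    """Per-cell specific energies for one simulated population replicate.

    ``values`` are specific energies z (mGy) of individual cell nuclei;
    ``macroscopic_dose`` is the cumulative absorbed dose D (mGy) of the run.
    """

    values: np.ndarray
    macroscopic_dose: float
    replicate_id: int = 0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError("values must be a non-empty 1-d vector")
        if not np.all(np.isfinite(vals)):
            raise ValueError("specific energies must be finite")
        if np.any(vals < 0):
            raise ValueError("specific energies cannot be negative")


@dataclass(frozen=True)
class DistributionSummary:
    """Mean, population standard deviation and dispersion sigma/zbar."""

    mean: float
    std: float
    dispersion: float

    @property
    def dispersion_percent(self) -> float:
        return 100.0 * self.dispersion


def _resolve_binning(
    lo: float,
    hi: float,
    n_bins: Optional[int],
    bin_width: Optional[float],
) -> np.ndarray:
    """Uniform edges over [lo, hi]; with bin_width, hi is padded up to an
    integer number of bins."""
    if (n_bins is None) == (bin_width is None):
        raise ValueError("specify exactly one of n_bins or bin_width")
    if hi <= lo:
        raise ValueError(f"empty bin range [{lo}, {hi}]")
    if bin_width is not None:
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        n = int(math.ceil((hi - lo) / bin_width - 1e-12))
        n = max(n, 1)
        return lo + bin_width * np.arange(n + 1)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    return np.linspace(lo, hi, n_bins + 1)


def build_distribution(
    samples: Union[np.ndarray, Sequence[float], CellDoseSample],
    n_bins: Optional[int] = None,
    bin_width: Optional[float] = None,
    range: Optional[tuple] = None,
    label: str = "",
) -> BinnedDistribution:
    """Bin per-cell values into a frequency (probability) distribution.

    Per-bin probability = count in bin / total count; bins are half-open
    ``[left, right)`` with the last bin closed.  The default range is
    ``[0, max(samples)]``, padded up to an integer number of bins when
    ``bin_width`` is given.
    """
    if isinstance(samples, CellDoseSample):
        samples = samples.values
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("samples must be a non-empty 1-d vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("samples must be finite")
    if np.any(x < 0):
        raise ValueError("samples must be non-negative")
    lo, hi = (0.0, float(x.max())) if range is None else (float(range[0]), float(range[1]))
    if range is None and hi <= lo:
        # all samples zero: one bin around zero
        hi = bin_width if bin_width is not None else 1.0
    edges = _resolve_binning(lo, hi, n_bins, bin_width)
    if x.min() < edges[0] or x.max() > edges[-1]:
        raise ValueError(
            f"binning range [{edges[0]}, {edges[-1]}] does not cover samples "
            f"[{x.min()}, {x.max()}]"
        )
    counts, _ = np.histogram(x, bins=edges)
    return BinnedDistribution(edges, counts / x.size, label=label)


def cumulative(dist: BinnedDistribution) -> np.ndarray:
    """Cumulative form F(z, D) evaluated at the right edge of each bin."""
    return np.cumsum(dist.probabilities)


def summarize(
    source: Union[BinnedDistribution, CellDoseSample, np.ndarray, Sequence[float]],
) -> DistributionSummary:
    """Mean, population std (divisor N) and dispersion sigma/zbar.

    For a :class:`BinnedDistribution` the moments use bin midpoints; raw
    samples are preferred when available.
    """
    if isinstance(source, BinnedDistribution):
        mids = source.midpoints
        p = source.probabilities
        mean = float(np.dot(p, mids))
        var = float(np.dot(p, (mids - mean) ** 2))
        std = math.sqrt(max(var, 0.0))
    else:
        if isinstance(source, CellDoseSample):
            source = source.values
        x = np.asarray(source, dtype=float)
        if x.size == 0:
            raise ValueError("cannot summarize an empty sample")
        mean = float(x.mean())
        std = float(x.std(ddof=0))
    if mean == 0.0:
        raise ValueError("dispersion undefined: mean is zero")
    return DistributionSummary(mean=mean, std=std, dispersion=std / mean)


def normal_reference(
    summary: DistributionSummary,
    bin_edges: np.ndarray,
) -> BinnedDistribution:
    """Normal distribution with the same mean and std, binned on the same grid.

    Per-bin mass is the CDF difference across the bin, renormalized to sum to 1
    over the supplied range.  Renormalization handles the truncation at the
    lower range limit: specific energies (and expression ratios) cannot be
    negative, while the matched normal extends over the whole real line.
    """
    edges = np.asarray(bin_edges, dtype=float)
    mu, sigma = summary.mean, summary.std
    if sigma == 0.0:
        probs = np.zeros(edges.size - 1)
        idx = int(np.clip(np.searchsorted(edges, mu, side="right") - 1, 0, probs.size - 1))
        probs[idx] = 1.0
        return BinnedDistribution(edges, probs, label="normal reference (degenerate)")
    cdf = stats.norm.cdf(edges, loc=mu, scale=sigma)
    masses = np.diff(cdf)
    total = masses.sum()
    if total <= 0.0:
        raise ValueError("bin range carries zero normal probability mass")
    return BinnedDistribution(edges, masses / total, label="normal reference")


def rmse(dist_mc: BinnedDistribution, dist_ref: BinnedDistribution) -> float:
    """Root mean square error between two per-bin probability vectors.

    ``sqrt(sum_i (f_ref,i - f_mc,i)^2 / N)`` with N the number of bins.  Both
    distributions must share identical bin edges; no silent rebinning, since
    bin-wise comparability requires a common uniform grid.
    """
    a, b = dist_mc, dist_ref
    if a.n_bins != b.n_bins or not np.allclose(
        a.bin_edges, b.bin_edges, rtol=1e-9, atol=0.0
    ):
        raise ValueError("RMSE requires identical bin edges on both inputs")
    diff = b.probabilities - a.probabilities
    return float(np.sqrt(np.mean(diff**2)))


def convolution_count(D: float, D1: float) -> int:
    """Number of events v = D / D1 for cumulative dose D and per-event dose D1.

    v must be an integer; ratios off an integer by more than a relative 1e-6
    are rejected rather than silently rounded.
    """
    if D <= 0 or D1 <= 0:
        raise ValueError("doses must be positive")
    ratio = D / D1
    v = int(round(ratio))
    if v < 1 or abs(ratio - v) > 1e-6 * v:
        raise ValueError(
            f"D/D1 = {ratio!r} is not an integer event count; "
            "choose commensurate doses"
        )
    return v


def _self_convolve_power(p: np.ndarray, v: int) -> np.ndarray:
    """v-fold discrete self-convolution by binary exponentiation."""
    result: Optional[np.ndarray] = None
    base = p
    e = v
    while e > 0:
        if e & 1:
            result = base if result is None else np.convolve(result, base)
        e >>= 1
        if e > 0:
            base = np.convolve(base, base)
    assert result is not None
    return result


def convolve(
    f1: BinnedDistribution,
    v: int,
    rebin_bins: Optional[int] = None,
    sequential: bool = False,
) -> BinnedDistribution:
    """Multi-event spectrum f_v: the v-fold self-convolution of f1.

    The single-event spectrum must be uniformly binned starting at 0.  Bin
    masses are treated as atoms at bin midpoints; the v-fold sum places mass at
    ``(k + v/2) * w``.  For even v these points fall exactly on bin edges of
    the output grid and are split half/half between the adjacent bins, which
    preserves the mean exactly (mean(f_v) = v * mean(f1)).  The output grid is
    ``[0, v * z_max]`` at the native width; pass ``rebin_bins`` to map onto a
    coarser uniform grid for comparison or plotting.

    ``sequential=True`` uses the literal one-at-a-time convolution instead of
    binary exponentiation (same result; used for cross-checking).
    """
    if v < 1:
        raise ValueError("v must be >= 1")
    if abs(float(f1.bin_edges[0])) > 1e-12 * max(f1.bin_width, 1.0):
        raise ValueError("single-event spectrum bins must start at 0")
    if v == 1:
        return f1
    w = f1.bin_width
    n = f1.n_bins
    if sequential:
        raw = f1.probabilities
        for _ in range(v - 1):
            raw = np.convolve(raw, f1.probabilities)
    else:
        raw = _self_convolve_power(f1.probabilities, v)
    # raw[k] is the mass of index-sum k, i.e. at value (k + v/2) * w
    n_out = v * n
    out = np.zeros(n_out)
    k = np.arange(raw.size)
    if v % 2 == 1:
        np.add.at(out, k + (v - 1) // 2, raw)
    else:
        j = k + v // 2
        np.add.at(out, j - 1, 0.5 * raw)
        np.add.at(out, np.minimum(j, n_out - 1), 0.5 * raw)
    total = out.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("convolution produced no probability mass")
    out /= total  # guards floating-point drift; convolution conserves mass
    edges = w * np.arange(n_out + 1)
    fv = BinnedDistribution(edges, out, label=f"{f1.label or 'f1'} ** {v}")
    if rebin_bins is not None:
        fv = rebin(fv, n_bins=rebin_bins)
    return fv


def rebin(
    dist: BinnedDistribution,
    n_bins: Optional[int] = None,
    bin_width: Optional[float] = None,
    range: Optional[tuple] = None,
) -> BinnedDistribution:
    """Mass-preserving rebin onto a coarser (or shifted) uniform grid.

    Mass is redistributed by proportional overlap, treating each source bin as
    uniform density.  The target range must cover the source support.
    """
    lo = float(dist.bin_edges[0]) if range is None else float(range[0])
    hi = float(dist.bin_edges[-1]) if range is None else float(range[1])
    new_edges = _resolve_binning(lo, hi, n_bins, bin_width)
    if new_edges[0] > dist.bin_edges[0] + 1e-12 or new_edges[-1] < dist.bin_edges[-1] - 1e-12:
        raise ValueError("rebin target range must cover the source support")
    cum = np.concatenate([[0.0], np.cumsum(dist.probabilities)])
    cum_new = np.interp(new_edges, dist.bin_edges, cum, left=0.0, right=1.0)
    probs = np.diff(cum_new)
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum()
    return BinnedDistribution(new_edges, probs, label=dist.label)


def replicate_frequency_errors(
    samples: Sequence[Union[CellDoseSample, np.ndarray]],
    n_bins: Optional[int] = None,
    bin_width: Optional[float] = None,
    range: Optional[tuple] = None,
    label: str = "",
) -> BinnedDistribution:
    """Replicate-averaged distribution with per-bin error bars.

    Each replicate is binned on a common grid (default range covers all
    replicates); probabilities are the per-bin mean across replicates and
    ``bin_errors`` the per-bin sample standard deviation (divisor N - 1), the
    convention for an error bar estimated from repeated independent runs.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 replicates to estimate per-bin errors")
    arrays = [
        s.values if isinstance(s, CellDoseSample) else np.asarray(s, dtype=float)
        for s in samples
    ]
    if range is None:
        hi = max(float(a.max()) for a in arrays)
        range = (0.0, hi)
    dists = [
        build_distribution(a, n_bins=n_bins, bin_width=bin_width, range=range)
        for a in arrays
    ]
    edges = dists[0].bin_edges
    mat = np.vstack([d.probabilities for d in dists])
    return BinnedDistribution(
        edges,
        mat.mean(axis=0),
        bin_errors=mat.std(axis=0, ddof=1),
        label=label,
    )


# ---------------------------------------------------------------------------
# CSV interchange


def write_spectrum_csv(dist: BinnedDistribution, path, units: str = "mGy") -> None:
    """Spectrum CSV: bin_left, bin_right, probability, bin_error; a leading
    '# units=...' comment line declares the abscissa units."""
    frame = dist.to_frame()
    with open(path, "w") as fh:
        fh.write(f"# units={units}\n")
        frame.to_csv(fh, index=False)


def read_spectrum_csv(path) -> BinnedDistribution:
    frame = pd.read_csv(path, comment="#")
    required = {"bin_left", "bin_right", "probability"}
    if not required.issubset(frame.columns):
        raise ValueError(f"spectrum CSV must have columns {sorted(required)}")
    left = frame["bin_left"].to_numpy(float)
    right = frame["bin_right"].to_numpy(float)
    if not np.allclose(left[1:], right[:-1], rtol=1e-9):
        raise ValueError("spectrum bins must be contiguous")
    edges = np.concatenate([left, right[-1:]])
    errors = None
    if "bin_error" in frame.columns and frame["bin_error"].notna().any():
        errors = frame["bin_error"].to_numpy(float)
    return BinnedDistribution(edges, frame["probability"].to_numpy(float), bin_errors=errors)


def write_cell_dose_csv(samples: Sequence[CellDoseSample], path) -> None:
    """Per-cell dose CSV (one macroscopic dose per file): cell_id,
    replicate_id, specific_energy_mGy."""
    doses = {s.macroscopic_dose for s in samples}
    if len(doses) != 1:
        raise ValueError("one per-cell dose file holds a single macroscopic dose")
    rows = []
    for s in samples:
        rows.append(
            pd.DataFrame(
                {
                    "cell_id": np.arange(s.values.size),
                    "replicate_id": s.replicate_id,
                    "specific_energy_mGy": s.values,
                }
            )
        )
    with open(path, "w") as fh:
        fh.write(f"# macroscopic_dose_mGy={doses.pop()!r}\n")
        pd.concat(rows, ignore_index=True).to_csv(fh, index=False)


def read_cell_dose_csv(path) -> list:
    with open(path) as fh:
        header = fh.readline()
    dose = 0.0
    if header.startswith("#") and "macroscopic_dose_mGy=" in header:
        dose = float(header.split("=", 1)[1])
    frame = pd.read_csv(path, comment="#")
    out = []
    for rep, grp in frame.groupby("replicate_id", sort=True):
        out.append(
            CellDoseSample(
                values=grp["specific_energy_mGy"].to_numpy(float),
                macroscopic_dose=dose,
                replicate_id=int(rep),
            )
        )
    return out
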