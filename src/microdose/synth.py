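"""Synthetic data generators with known ground truth.

Two generators feed the pipeline:

* :func:`sample_population_dose` draws per-cell nucleus specific energies for a
  population receiving ``v`` independent radiation events each.  It emulates
  per-cell Monte-Carlo transport output: each cell accumulates ``v`` draws from
  a single-event energy spectrum and the total is modulated by the cell's
  nucleus mass (lognormal, configurable coefficient of variation), since
  ``z = eps / m``.  Mass heterogeneity is the population-level variance
  component that event-count averaging cannot shrink, so the population
  dispersion plateaus at ``mass_cv`` for large ``v``.

* :func:`simulate_sc_experiment` draws multi-group single-cell count matrices
  (negative binomial with per-cell library-size factors) containing planted
  gene classes whose expression-difference distributions carry the signatures
  the screen looks for — dispersion decreasing with dose (class A), increasing
  (class B), null (class C), mean fold change (class D), low-dose-up /
  high-dose-down (class E), and the A+D combination ("AD") carrying both the
  statistical and the microdosimetric signature.

Both generators are pure functions of (configuration, seed); replicate and
group streams are spawned deterministically from the master seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .distributions import BinnedDistribution, CellDoseSample
from .expression import ExpressionGroup

__all__ = [
    "SingleEventModel",
    "ScSimConfig",
    "GroundTruth",
    "sample_population_dose",
    "simulate_sc_experiment",
    "GENE_CLASSES",
]

GENE_CLASSES = ("A", "B", "C", "D", "E", "AD")


@dataclass(frozen=True)
class SingleEventModel:
    """Parametric single-event specific-energy spectrum plus cell-mass model.

    Parameters
    ----------
    family : {"gamma", "lognormal", "tabulated"}
        Shape family of the per-event nucleus energy deposit.  Gamma is the
        default: non-negative and right-skewed like photon single-event
        spectra.  "tabulated" draws from a user-supplied binned spectrum
        (e.g. imported Monte-Carlo output) at bin midpoints.
    shape : float
        Gamma shape, or lognormal sigma (of log), for the parametric families.
    d1 : float
        Macroscopic dose per event, mGy (the per-event dose increment; the
        cumulative dose after v events is ``v * d1``).
    mass_cv : float
        Coefficient of variation of per-cell nucleus mass (lognormal, mean 1).
    nucleus_dose_ratio : float
        Mean nucleus specific energy / macroscopic dose.  Default 1.2: the
        nucleus receives on average 1.2x the dose of the surrounding medium.
    table : BinnedDistribution, optional
        Tabulated single-event spectrum for ``family="tabulated"``; used as
        the nucleus spectrum as-is.
    """

    family: str = "gamma"
    shape: float = 2.0
    d1: float = 5.0
    mass_cv: float = 0.0
    nucleus_dose_ratio: float = 1.2
    table: Optional[BinnedDistribution] = None

    def __post_init__(self) -> None:
        if self.family not in ("gamma", "lognormal", "tabulated"):
            raise ValueError(f"unknown single-event family {self.family!r}")
        if self.d1 <= 0:
            raise ValueError("d1 must be positive")
        if self.mass_cv < 0:
            raise ValueError("mass_cv must be non-negative")
        if self.nucleus_dose_ratio <= 0:
            raise ValueError("nucleus_dose_ratio must be positive")
        if self.family == "tabulated" and self.table is None:
            raise ValueError("tabulated family requires a table")
        if self.family != "tabulated" and self.shape <= 0:
            raise ValueError("shape must be positive")

    @property
    def event_mean(self) -> float:
        """Mean nucleus specific energy deposited per event (mGy)."""
        if self.family == "tabulated":
            p = self.table.probabilities
            return float(np.dot(p, self.table.midpoints))
        return self.d1 * self.nucleus_dose_ratio

    def draw_events(self, rng: np.random.Generator, size) -> np.ndarray:
        mean = self.d1 * self.nucleus_dose_ratio
        if self.family == "gamma":
            return rng.gamma(self.shape, mean / self.shape, size=size)
        if self.family == "lognormal":
            sigma = self.shape
            mu = math.log(mean) - 0.5 * sigma**2
            return rng.lognormal(mu, sigma, size=size)
        mids = self.table.midpoints
        idx = rng.choice(mids.size, size=size, p=self.table.probabilities)
        return mids[idx]


def sample_population_dose(
    model: SingleEventModel,
    v: int,
    n_cells: int,
    n_replicates: int = 1,
    seed: int = 0,
) -> List[CellDoseSample]:
    """Per-cell nucleus specific energies after ``v`` events per cell.

    Each cell's total deposit is the sum of ``v`` independent single-event
    draws, divided by the cell's relative nucleus mass (lognormal, mean 1,
    CV ``mass_cv``).  The mass factor is analytically normalized so the
    population mean equals ``v * event_mean`` exactly in expectation.
    Replicates use child streams spawned from ``seed``.
    """
    if v < 1 or n_cells < 1 or n_replicates < 1:
        raise ValueError("v, n_cells and n_replicates must all be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    macroscopic_dose = v * model.d1
    out: List[CellDoseSample] = []
    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        if model.mass_cv > 0:
            sigma2 = math.log(1.0 + model.mass_cv**2)
            mass = rng.lognormal(-0.5 * sigma2, math.sqrt(sigma2), size=n_cells)
            # E[1/mass] = exp(sigma2); normalize so E[z] is unbiased
            inv_mass = (1.0 / mass) * math.exp(-sigma2)
        else:
            inv_mass = 1.0
        events = model.draw_events(rng, (n_cells, v))
        z = events.sum(axis=1) * inv_mass
        out.append(
            CellDoseSample(values=z, macroscopic_dose=macroscopic_dose, replicate_id=rep)
        )
    return out


# ---------------------------------------------------------------------------
# Single-cell experiment simulator


@dataclass(frozen=True)
class ScSimConfig:
    """Configuration of the synthetic multi-group single-cell experiment.

    Defaults emulate the study shape: 23,517 genes x ~10,000 cells per group
    at doses 0 (control), 10, 100 and 1000 mGy.  Gene classes:

    ======  ==================================================================
    A       dispersion of the expression-difference distribution strictly
            decreases with dose (NB size grows ``dispersion_step``-fold per
            dose step); mean unchanged
    B       dispersion increases with dose (reversed size schedule)
    C       null — exchangeable with control (the unlisted remainder)
    D       mean fold change ``fc_de`` in every irradiated group
    E       up-regulated at low dose with the differential increasing with
            dose, down-regulated at the highest dose (``class_e_fc``)
    AD      class A dispersion schedule combined with class D fold change
    ======  ==================================================================
    """

    n_genes: int = 23517
    n_cells_per_group: int = 10000
    dose_groups: Tuple[float, ...] = (0.0, 10.0, 100.0, 1000.0)
    class_counts: Dict[str, int] = field(
        default_factory=lambda: {"A": 200, "B": 200, "D": 200, "E": 50, "AD": 100}
    )
    fc_de: float = 2.0
    dispersion_step: float = 4.0
    class_e_fc: Tuple[float, ...] = (1.5, 2.0, 0.6)
    nb_size: float = 2.0
    base_mean_median: float = 3.0
    base_mean_sigma: float = 0.8
    planted_mean_floor: float = 2.0
    library_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_cells_per_group < 1:
            raise ValueError("n_genes and n_cells_per_group must be positive")
        if len(self.dose_groups) < 2 or self.dose_groups[0] != 0.0:
            raise ValueError("dose_groups must start with the control dose 0")
        if list(self.dose_groups) != sorted(set(self.dose_groups)):
            raise ValueError("dose_groups must be strictly increasing")
        unknown = set(self.class_counts) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown gene classes: {sorted(unknown)}")
        if any(c < 0 for c in self.class_counts.values()):
            raise ValueError("class counts must be non-negative")
        if sum(self.class_counts.values()) > self.n_genes:
            raise ValueError("class counts exceed n_genes")
        if self.class_counts.get("E", 0) > 0 and len(self.class_e_fc) != len(
            self.dose_groups
        ) - 1:
            raise ValueError(
                "class_e_fc must give one fold change per irradiated group"
            )
        if self.nb_size <= 0 or self.dispersion_step <= 1:
            raise ValueError("nb_size must be > 0 and dispersion_step > 1")
        if self.fc_de <= 0 or self.library_cv < 0:
            raise ValueError("fc_de must be > 0 and library_cv >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @property
    def irradiated_doses(self) -> Tuple[float, ...]:
        return self.dose_groups[1:]


@dataclass(frozen=True)
class GroundTruth:
    """Planted per-gene parameters of a simulated experiment.

    ``table`` holds one row per gene: gene_id, gene_class, and per-dose true
    NB mean (``mean_<dose>``) and true coefficient of variation
    (``cv_<dose>``) of the per-cell expression distribution.
    """

    table: pd.DataFrame

    def gene_class(self) -> pd.Series:
        return self.table.set_index("gene_id")["gene_class"]

    def genes_of_class(self, label: str) -> List[str]:
        t = self.table
        return list(t.loc[t["gene_class"] == label, "gene_id"])


def _class_schedules(cfg: ScSimConfig) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-gene, per-group NB mean multipliers and size values.

    Returns (labels, fc_matrix, size_matrix) with shape (n_genes, n_groups).
    """
    n_doses = len(cfg.dose_groups)
    n_irr = n_doses - 1
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])

    labels = np.array(["C"] * cfg.n_genes, dtype=object)
    planted = [lab for lab in GENE_CLASSES if cfg.class_counts.get(lab, 0) > 0]
    n_planted = sum(cfg.class_counts.get(lab, 0) for lab in planted)
    perm = rng.permutation(cfg.n_genes)
    pos = 0
    for lab in planted:
        k = cfg.class_counts[lab]
        labels[perm[pos : pos + k]] = lab
        pos += k

    fc = np.ones((cfg.n_genes, n_doses))
    size = np.full((cfg.n_genes, n_doses), cfg.nb_size)
    # dispersion schedules: NB size grows step-fold per irradiated dose step
    # starting from the baseline (class A: CV shrinks with dose); class B
    # runs the same schedule in reverse
    a_sizes = cfg.nb_size * cfg.dispersion_step ** np.arange(0, n_irr)
    b_sizes = a_sizes[::-1]
    for g in range(cfg.n_genes):
        lab = labels[g]
        if lab in ("A", "AD"):
            size[g, 1:] = a_sizes
        elif lab == "B":
            size[g, 1:] = b_sizes
        if lab in ("D", "AD"):
            fc[g, 1:] = cfg.fc_de
        elif lab == "E":
            fc[g, 1:] = np.asarray(cfg.class_e_fc)
    return labels, fc, size


def simulate_sc_experiment(
    cfg: ScSimConfig,
) -> Tuple[List[ExpressionGroup], GroundTruth]:
    """Draw the multi-group count matrices and the planted ground truth.

    Counts are negative binomial: ``counts[g, c] ~ NB(mean_g * L_c, size_g)``
    with per-cell library factors L (lognormal, mean 1, CV ``library_cv``).
    Per-gene baseline means are lognormal over genes (median
    ``base_mean_median``, log-sigma ``base_mean_sigma``), shared across groups
    so that expression differences are driven only by the planted schedules.
    """
    labels, fc, size = _class_schedules(cfg)
    ss = np.random.SeedSequence(cfg.seed)
    # child 0 is consumed by _class_schedules; gene/group streams follow
    children = ss.spawn(2 + len(cfg.dose_groups))
    gene_rng = np.random.default_rng(children[1])
    base_mean = gene_rng.lognormal(
        math.log(cfg.base_mean_median), cfg.base_mean_sigma, size=cfg.n_genes
    )
    # planted signal genes sit at detectable expression (the study's marker
    # genes are highly expressed ribosomal proteins); nulls keep the full range
    base_mean = np.where(
        labels != "C", np.maximum(base_mean, cfg.planted_mean_floor), base_mean
    )
    means = base_mean[:, None] * fc  # (n_genes, n_groups)

    width = len(str(cfg.n_genes))
    gene_ids = np.array(
        [f"G{i:0{width}d}" for i in range(cfg.n_genes)], dtype=object
    )

    groups: List[ExpressionGroup] = []
    block = 4096
    for gi, dose in enumerate(cfg.dose_groups):
        rng = np.random.default_rng(children[2 + gi])
        if cfg.library_cv > 0:
            s2 = math.log(1.0 + cfg.library_cv**2)
            lib = rng.lognormal(-0.5 * s2, math.sqrt(s2), size=cfg.n_cells_per_group)
        else:
            lib = np.ones(cfg.n_cells_per_group)
        counts = np.empty((cfg.n_genes, cfg.n_cells_per_group), dtype=np.int32)
        for start in range(0, cfg.n_genes, block):
            stop = min(start + block, cfg.n_genes)
            mu = means[start:stop, gi][:, None] * lib[None, :]
            s = size[start:stop, gi][:, None]
            counts[start:stop] = rng.negative_binomial(s, s / (s + mu))
        barcodes = np.array(
            [f"BC{c:06d}-{gi + 1}" for c in range(cfg.n_cells_per_group)],
            dtype=object,
        )
        groups.append(
            ExpressionGroup(
                gene_ids=gene_ids,
                barcodes=barcodes,
                counts=counts,
                dose_mGy=float(dose),
            )
        )

    truth = pd.DataFrame({"gene_id": gene_ids, "gene_class": labels})
    for gi, dose in enumerate(cfg.dose_groups):
        tag = int(dose) if float(dose).is_integer() else dose
        mu = means[:, gi]
        s = size[:, gi]
        truth[f"mean_{tag}"] = mu
        # NB: var = mu + mu^2/size; library factors add CV_lib^2 (+ cross term)
        cv2_nb = 1.0 / mu + 1.0 / s
        cv2 = cv2_nb + cfg.library_cv**2 * (1.0 + cv2_nb)
        truth[f"cv_{tag}"] = np.sqrt(cv2)
    return groups, GroundTruth(table=truth)
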