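"""Deconvolution of subpopulation origin usage from a marker-frequency
profile.

An observed profile is modelled as a non-negative mixture of per-cell-class
model profiles.  Weights are fitted by non-negative least squares on the
unmasked bins and renormalised to cell fractions; optionally the
inter-initiation period tau is fitted by grid search.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import nnls

from .genome_model import ChromosomeMap
from .mfa_pipeline import LoessConfig, circular_loess
from .replication_engine import (
    CellClass,
    MarkerFrequencyProfile,
    SimulationParams,
    class_profile,
)

__all__ = ["MixtureModel", "class_basis", "fit_mixture"]


@dataclass
class MixtureModel:
    """Fitted cell-class mixture: non-negative weights summing to 1."""

    classes: list[CellClass]
    weights: np.ndarray
    fit_rss: float
    fitted_params: SimulationParams
    non_identifiable: bool = False
    tau_grid_rss: dict[float, float] = field(default_factory=dict)

    def weight_of(self, cell_class: CellClass) -> float:
        return float(self.weights[self.classes.index(cell_class)])

    def to_dict(self) -> dict:
        return {
            "classes": [c.label for c in self.classes],
            "weights": [float(w) for w in self.weights],
            "rss": self.fit_rss,
            "tau_min": self.fitted_params.tau_min,
            "non_identifiable": self.non_identifiable,
        }


def class_basis(
    cmap: ChromosomeMap,
    classes: list[CellClass],
    params: SimulationParams,
    bin_size: int = 1000,
    smooth: LoessConfig | None = None,
) -> list[MarkerFrequencyProfile]:
    """One model profile per class on identical bins, mean-scaled to 1.

    If ``smooth`` is given the basis profiles are LOESS-smoothed with the
    same settings as the observed profile, so that smoothing cancels out of
    the fit instead of biasing it.
    """
    basis = []
    for c in classes:
        prof = class_profile(cmap, c, params, bin_size)
        if smooth is not None:
            prof = circular_loess(prof, smooth)
        basis.append(replace(prof, values=prof.values / prof.values.mean()))
    return basis


def _class_means(
    cmap: ChromosomeMap,
    classes: list[CellClass],
    params: SimulationParams,
    bin_size: int,
) -> np.ndarray:
    """Mean copy number of each origin-normalised class profile; converts
    fitted basis coefficients back to cell fractions."""
    return np.array(
        [class_profile(cmap, c, params, bin_size).values.mean() for c in classes]
    )


def fit_mixture(
    observed: MarkerFrequencyProfile,
    classes: list[CellClass],
    cmap: ChromosomeMap,
    params: SimulationParams,
    fit_tau: bool = False,
    tau_grid: np.ndarray | None = None,
    smooth: LoessConfig | None = None,
    basis: list[MarkerFrequencyProfile] | None = None,
) -> MixtureModel:
    """Fit non-negative cell-class weights to an observed profile.

    The solve runs on mean-1 basis profiles; raw coefficients are divided
    by each class's mean copy number before renormalisation, so the
    returned weights are fractions of cells, invariant to any common
    rescaling of the observed and basis profiles.  Two classes with
    (numerically) identical profiles raise the ``non_identifiable`` flag.
    A precomputed ``basis`` (from `class_basis`, matching ``classes`` and
    ``params``) skips the per-call model evaluation; it is ignored when
    ``fit_tau`` is set.
    """
    if not classes:
        raise ValueError("need at least one candidate class")
    if len(set(classes)) != len(classes):
        raise ValueError("candidate classes must be distinct")

    taus = [params.tau_min]
    if fit_tau:
        taus = list(tau_grid if tau_grid is not None else np.arange(15.0, 41.0, 1.0))
        basis = None

    best: MixtureModel | None = None
    grid_rss: dict[float, float] = {}
    for tau in taus:
        p = replace(params, tau_min=tau)
        B = basis
        if B is None or tau != params.tau_min:
            B = class_basis(cmap, classes, p, observed.bin_size, smooth=smooth)
        for bp in B:
            if not observed.same_binning(bp):
                raise ValueError("observed and basis profiles on different bins")
        valid = observed.mask.copy()
        for bp in B:
            valid &= bp.mask
        X = np.column_stack([bp.values[valid] for bp in B])
        y = observed.values[valid]
        coef, rnorm = nnls(X, y)
        rss = float(rnorm**2)
        grid_rss[float(tau)] = rss

        non_ident = False
        for i in range(len(classes)):
            for j in range(i + 1, len(classes)):
                if np.allclose(X[:, i], X[:, j], rtol=1e-9, atol=1e-12):
                    non_ident = True
        if np.linalg.matrix_rank(X) < len(classes):
            non_ident = True

        means = _class_means(cmap, classes, p, observed.bin_size)
        fractions = coef / means
        total = fractions.sum()
        if total <= 0:
            raise ValueError("degenerate fit: all weights zero")
        weights = fractions / total
        model = MixtureModel(
            classes=list(classes),
            weights=weights,
            fit_rss=rss,
            fitted_params=p,
            non_identifiable=non_ident,
        )
        if best is None or rss < best.fit_rss:
            best = model
    assert best is not None
    best.tau_grid_rss = grid_rss
    return best
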