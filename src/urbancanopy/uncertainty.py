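"""Monte Carlo propagation of biomass uncertainty.

Three error sources feed allometric AGB estimates:

``qsm``     per-tree volume uncertainty, a Gaussian parametrised by the
            spread of the QSM reconstructions (or by the allometry's
            residual sd when applied to airborne crowns);
``als``     crown-measurement uncertainty of H and Ar, estimated per crown
            by repeated random subsampling of the crown's points (fraction
            retained 0.75, 100 iterations by default);
``density`` wood density, a non-parametric (empirical) distribution over
            the per-tree densities mapped from a street-tree database.

Each simulation redraws the active components, recomputes every crown's
volume and biomass, and accumulates per-crown and total-AGB samples.
Freezing all but one component isolates that component's variance share.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import crown_area, crown_height

__all__ = ["MCConfig", "VolumePDF", "CrownMetricPDF", "DensityPDF",
           "MCResult", "crown_metric_uncertainty", "crown_metric_pdfs",
           "build_density_pdf", "run_monte_carlo", "variance_decomposition"]

_COMPONENTS = ("qsm", "als", "density")


@dataclass
class MCConfig:
    n_sims: int = 100
    subsample_iterations: int = 100
    subsample_fraction: float = 0.75
    seed: int | None = None
    active_components: frozenset = frozenset(_COMPONENTS)

    def __post_init__(self):
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must be in (0, 1]")
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        self.active_components = frozenset(self.active_components)
        unknown = self.active_components - set(_COMPONENTS)
        if unknown:
            raise ValueError(f"unknown components: {sorted(unknown)}")


@dataclass
class VolumePDF:
    """Gaussian volume uncertainty (m^3)."""
    mean: float
    sd: float

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass
class CrownMetricPDF:
    """Per-crown measurement sds of H (m) and Ar (m^2) from subsampling."""
    crown_id: int
    sd_H: float
    sd_Ar: float

    def __post_init__(self):
        if self.sd_H < 0 or self.sd_Ar < 0:
            raise ValueError("sds must be >= 0")


class DensityPDF:
    """Empirical wood-density distribution; draws are uniform with
    replacement over the mapped per-tree values (kg m^-3)."""

    def __init__(self, samples):
        self.samples = np.asarray(samples, dtype=float).ravel()
        if self.samples.size == 0:
            raise ValueError("empty wood-density table")
        if (self.samples <= 0).any():
            raise ValueError("wood densities must be positive")

    @property
    def mean(self) -> float:
        return float(self.samples.mean())

    def draw(self, rng: np.random.Generator, size=None) -> np.ndarray:
        return rng.choice(self.samples, size=size, replace=True)


@dataclass
class MCResult:
    """Per-crown and aggregate AGB sample summaries."""
    per_crown: pd.DataFrame          # crown_id, agb_mean, agb_sd, q025, q975
    total_agb: np.ndarray            # one total-AGB sample (Mg) per simulation
    variance_share: dict | None = None

    @property
    def total_mean(self) -> float:
        return float(self.total_agb.mean())

    @property
    def total_sd(self) -> float:
        if self.total_agb.size < 2 or np.ptp(self.total_agb) == 0:
            return 0.0  # identical samples: sd is exactly zero
        return float(self.total_agb.std(ddof=1))


def crown_metric_uncertainty(crown, config: MCConfig,
                             rng: np.random.Generator | None = None
                             ) -> CrownMetricPDF:
    """Subsampling sds of a crown's H and Ar.

    Repeats ``subsample_iterations`` times: retain a uniformly random
    ``subsample_fraction`` of the crown's points and recompute the maximum
    height and hull area; the across-iteration standard deviations are the
    crown's measurement uncertainty.
    """
    f = config.subsample_fraction
    n = int(np.asarray(crown.points).shape[0])
    min_n = int(np.ceil(1.0 / max(1.0 - f, 1e-12))) if f < 1 else 1
    if n < min_n:
        raise ValueError(f"crown has too few points ({n}) for subsampling "
                         f"at fraction {f}")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    keep = max(int(round(f * n)), 1)
    Hs = np.empty(config.subsample_iterations)
    Ars = np.empty(config.subsample_iterations)
    for i in range(config.subsample_iterations):
        idx = rng.choice(n, size=keep, replace=False)
        pts = crown.points[idx]
        Hs[i] = crown_height(pts)
        Ars[i] = crown_area(pts)
    return CrownMetricPDF(crown.id, float(Hs.std(ddof=1)),
                          float(Ars.std(ddof=1)))


def crown_metric_pdfs(crowns, config: MCConfig,
                      max_sampled: int | None = None) -> dict:
    """Per-crown measurement PDFs for a whole crown set.

    Crowns with too few points for subsampling inherit the mean *relative*
    sd of the crowns that could be sampled, scaled by their own H and Ar.
    For very large crown sets ``max_sampled`` caps how many crowns are
    subsampled directly (a random template sample); the rest inherit the
    template's mean relative sds the same way.
    """
    crowns = list(crowns)
    rng = np.random.default_rng(config.seed)
    sampled = set(range(len(crowns)))
    if max_sampled is not None and len(crowns) > max_sampled:
        sampled = set(rng.choice(len(crowns), size=max_sampled,
                                 replace=False).tolist())
    pdfs, too_small = {}, []
    rel_H, rel_Ar = [], []
    for i, c in enumerate(crowns):
        if i not in sampled:
            too_small.append(c)
            continue
        try:
            pdf = crown_metric_uncertainty(c, config, rng)
        except ValueError:
            too_small.append(c)
            continue
        pdfs[c.id] = pdf
        if c.H > 0:
            rel_H.append(pdf.sd_H / c.H)
        if c.Ar > 0:
            rel_Ar.append(pdf.sd_Ar / c.Ar)
    mean_rel_H = float(np.mean(rel_H)) if rel_H else 0.0
    mean_rel_Ar = float(np.mean(rel_Ar)) if rel_Ar else 0.0
    for c in too_small:
        pdfs[c.id] = CrownMetricPDF(c.id, mean_rel_H * c.H,
                                    mean_rel_Ar * c.Ar)
    return pdfs


def build_density_pdf(table) -> DensityPDF:
    """Empirical wood-density PDF from a CSV path, DataFrame (``density``
    column, kg m^-3) or array of per-tree densities."""
    if isinstance(table, (str, bytes)) or hasattr(table, "read"):
        table = pd.read_csv(table)
    if isinstance(table, pd.DataFrame):
        if "density" not in table.columns:
            raise ValueError("density table needs a 'density' column")
        values = table["density"].to_numpy(dtype=float)
    else:
        values = np.asarray(table, dtype=float)
    return DensityPDF(values)


def _point_estimates(crowns, model):
    H = np.array([c.H for c in crowns], dtype=float)
    Ar = np.array([c.Ar for c in crowns], dtype=float)
    V, _ = model.predict(H, Ar)
    return H, Ar, np.asarray(V, dtype=float)


def run_monte_carlo(crowns, model, pdfs: dict, config: MCConfig) -> MCResult:
    """Propagate the active uncertainty components to per-crown and total AGB.

    ``pdfs`` maps component names to their distributions:
    ``{"qsm": {crown_id: VolumePDF}, "als": {crown_id: CrownMetricPDF},
    "density": DensityPDF}``.  Inactive components are frozen at their point
    values (the density point value is the empirical mean when a density PDF
    is supplied, else crowns must carry a density via ``pdfs["density"]``).
    H/Ar perturbations are Gaussian with the subsampling sds, truncated at
    zero; volumes and AGB are likewise floored at zero.
    """
    crowns = list(crowns)
    active = config.active_components
    for comp in active:
        if comp not in pdfs or pdfs[comp] is None:
            raise ValueError(f"missing PDF for active component {comp!r}")
    if "density" not in pdfs or pdfs["density"] is None:
        raise ValueError("a density PDF (or single-value table) is required "
                         "to convert volume to biomass")
    density_pdf: DensityPDF = pdfs["density"]
    rho0 = density_pdf.mean
    H0, Ar0, V0 = _point_estimates(crowns, model)
    n = len(crowns)
    qsm_sd = np.zeros(n)
    if "qsm" in active:
        vol_pdfs = pdfs["qsm"]
        qsm_sd = np.array([vol_pdfs[c.id].sd for c in crowns], dtype=float)
    sd_H = np.zeros(n)
    sd_Ar = np.zeros(n)
    if "als" in active:
        mpdfs = pdfs["als"]
        sd_H = np.array([mpdfs[c.id].sd_H for c in crowns], dtype=float)
        sd_Ar = np.array([mpdfs[c.id].sd_Ar for c in crowns], dtype=float)

    rng = np.random.default_rng(config.seed)
    agb = np.empty((config.n_sims, n))
    for s in range(config.n_sims):
        H = np.maximum(H0 + rng.normal(0.0, 1.0, n) * sd_H, 0.0) \
            if "als" in active else H0
        Ar = np.maximum(Ar0 + rng.normal(0.0, 1.0, n) * sd_Ar, 0.0) \
            if "als" in active else Ar0
        if "als" in active:
            V, _ = model.predict(H, Ar)
            V = np.asarray(V, dtype=float)
        else:
            V = V0.copy()
        if "qsm" in active:
            V = np.maximum(V + rng.normal(0.0, 1.0, n) * qsm_sd, 0.0)
        rho = density_pdf.draw(rng, size=n) if "density" in active else rho0
        agb[s] = V * rho / 1000.0
    per_crown = pd.DataFrame({
        "crown_id": [c.id for c in crowns],
        "agb_mean": agb.mean(axis=0),
        "agb_sd": agb.std(axis=0, ddof=1) if config.n_sims > 1 else 0.0,
        "q025": np.percentile(agb, 2.5, axis=0),
        "q975": np.percentile(agb, 97.5, axis=0),
    })
    return MCResult(per_crown=per_crown, total_agb=agb.sum(axis=1))


def variance_decomposition(crowns, model, pdfs: dict,
                           config: MCConfig) -> dict:
    """Share of total-AGB variance attributable to each active component.

    Runs one Monte Carlo per component with the others frozen; shares are
    each single-component variance over the sum of single-component
    variances (the convention under which shares total 100%).
    """
    components = sorted(config.active_components & set(pdfs))
    if not components:
        raise ValueError("no active components with PDFs to decompose")
    seeds = np.random.SeedSequence(config.seed).generate_state(len(components))
    variances = {}
    for comp, seed in zip(components, seeds):
        cfg = MCConfig(n_sims=config.n_sims,
                       subsample_iterations=config.subsample_iterations,
                       subsample_fraction=config.subsample_fraction,
                       seed=int(seed) % (2**31), active_components={comp})
        res = run_monte_carlo(crowns, model, pdfs, cfg)
        variances[comp] = res.total_sd ** 2
    total = sum(variances.values())
    if total == 0:
        return {comp: 0.0 for comp in components}
    return {comp: v / total for comp, v in variances.items()}
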