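"""Population-specific QTL effects, phenotype simulation and standardization.

The simulated genetic architecture deliberately builds in divergence between
families: every QTL q has an overall additive effect a_q ~ N(0, 1), and each
population j carries its own effect a_jq ~ N(a_q, tau_q^2).  The amount of
divergence is controlled by the relative standard deviation

    rSD = tau_q / |a_q|,

so tau_q = rSD * |a_q| per QTL; rSD = 0 collapses to one shared architecture.
Phenotypes are the summed QTL effects plus i.i.d. Gaussian noise whose variance
is calibrated so the across-population heritability var(g)/var(y) hits a target
(default 0.70).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .popgen import MarkerData

__all__ = [
    "QTLArchitecture",
    "TraitRealization",
    "sample_qtl",
    "sample_effects",
    "genetic_values",
    "apply_noise",
    "standardize_phenotypes",
    "simulate_trait",
]


@dataclass(frozen=True)
class QTLArchitecture:
    """Simulation truth: overall and population-specific additive QTL effects."""

    overall_effects: np.ndarray  # (Q,) a_q
    specific_effects: np.ndarray  # (P, Q) a_jq, row j for population label j+1
    tau: np.ndarray  # (Q,) tau_q = rSD * |a_q|
    rsd: float
    qtl_marker_ids: np.ndarray | None = None
    populations: np.ndarray | None = None  # labels matching specific_effects rows

    def __post_init__(self):
        a = np.asarray(self.overall_effects, dtype=float)
        aj = np.asarray(self.specific_effects, dtype=float)
        tau = np.asarray(self.tau, dtype=float)
        if aj.ndim != 2 or aj.shape[1] != a.size or tau.size != a.size:
            raise ValueError("effect array shapes are inconsistent")
        if np.any(tau < 0):
            raise ValueError("tau must be nonnegative")
        pops = self.populations
        if pops is None:
            pops = np.arange(1, aj.shape[0] + 1)
        pops = np.asarray(pops, dtype=np.int64)
        if pops.size != aj.shape[0]:
            raise ValueError("populations must match specific_effects rows")
        object.__setattr__(self, "overall_effects", a)
        object.__setattr__(self, "specific_effects", aj)
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "populations", pops)

    @property
    def n_qtl(self) -> int:
        return int(self.overall_effects.size)

    @property
    def n_populations(self) -> int:
        return int(self.specific_effects.shape[0])


@dataclass(frozen=True)
class TraitRealization:
    """Simulated genetic values, phenotypes and realized heritabilities."""

    genetic_values: np.ndarray
    phenotypes: np.ndarray
    noise_variance: float
    target_h2: float
    realized_h2_overall: float
    realized_h2_within_family: float


def sample_qtl(data: MarkerData, n_qtl: int, seed: int) -> tuple[MarkerData, MarkerData]:
    """Pick ``n_qtl`` markers uniformly as QTL and remove them from the data.

    Returns ``(qtl_data, reduced_data)``: the QTL genotype columns (kept for
    computing true genetic values) and the remaining observed markers.
    """
    if n_qtl < 0:
        raise ValueError("n_qtl must be >= 0")
    if n_qtl >= data.n_markers and n_qtl > 0:
        raise ValueError("n_qtl must be smaller than the marker count")
    if n_qtl == 0:
        return data.subset_markers([]), data
    rng = np.random.default_rng(seed)
    pick = np.sort(rng.choice(data.n_markers, size=n_qtl, replace=False))
    qtl_ids = data.map.marker_ids[pick]
    rest = np.delete(np.arange(data.n_markers), pick)
    return data.subset_markers(qtl_ids), data.subset_markers(data.map.marker_ids[rest])


def sample_effects(
    n_qtl: int,
    n_populations: int,
    rsd: float,
    seed: int,
    qtl_marker_ids=None,
    populations=None,
) -> QTLArchitecture:
    """Draw a_q ~ N(0,1), tau_q = rSD * |a_q|, and a_jq ~ N(a_q, tau_q^2)."""
    if n_qtl < 1 or n_populations < 1:
        raise ValueError("n_qtl and n_populations must be >= 1")
    if rsd < 0:
        raise ValueError("rSD must be nonnegative")
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(n_qtl)
    tau = rsd * np.abs(a)
    aj = a[None, :] + tau[None, :] * rng.standard_normal((n_populations, n_qtl))
    return QTLArchitecture(
        a,
        aj,
        tau,
        float(rsd),
        None if qtl_marker_ids is None else np.asarray(qtl_marker_ids, dtype=object),
        populations,
    )


def genetic_values(
    qtl_genotypes: np.ndarray, arch: QTLArchitecture, population_labels
) -> np.ndarray:
    """True genetic value per line: g_i = sum_q count_iq * a_{j(i),q}.

    QTL genotypes are raw reference-allele counts; each line uses the specific
    effects of its own population.
    """
    C = np.asarray(qtl_genotypes, dtype=float)
    labels = np.asarray(population_labels, dtype=np.int64)
    if C.ndim != 2 or C.shape[1] != arch.n_qtl:
        raise ValueError("qtl_genotypes must be lines x n_qtl")
    if labels.size != C.shape[0]:
        raise ValueError("one population label per line is required")
    row = {int(p): j for j, p in enumerate(arch.populations)}
    missing = set(np.unique(labels).tolist()) - set(row)
    if missing:
        raise ValueError(f"populations {sorted(missing)} absent from the architecture")
    g = np.empty(C.shape[0])
    for p in np.unique(labels):
        rows = labels == p
        g[rows] = C[rows] @ arch.specific_effects[row[int(p)]]
    return g


def apply_noise(
    g: np.ndarray,
    target_h2: float,
    seed: int,
    population_labels=None,
) -> TraitRealization:
    """Add i.i.d. Gaussian noise calibrated to a target across-population h^2.

    noise variance = var(g) * (1 - h^2) / h^2, with var(g) the empirical
    (denominator n) variance over all lines; realized h^2 fields are computed
    on the generated sample.  Mean within-family h^2 uses the same noise
    variance against within-population genetic variances.
    """
    g = np.asarray(g, dtype=float)
    if not 0.0 < target_h2 <= 1.0:
        raise ValueError("target_h2 must be in (0, 1]")
    var_g = float(np.var(g))
    if var_g == 0.0 and target_h2 < 1.0:
        raise ValueError("genetic values are constant: no signal to calibrate noise against")
    noise_var = var_g * (1.0 - target_h2) / target_h2
    rng = np.random.default_rng(seed)
    y = g + rng.normal(0.0, np.sqrt(noise_var), size=g.size) if noise_var > 0 else g.copy()
    var_y = float(np.var(y))
    h2_overall = var_g / var_y if var_y > 0 else 1.0
    if population_labels is not None:
        labels = np.asarray(population_labels)
        within = []
        for p in np.unique(labels):
            vg = float(np.var(g[labels == p]))
            within.append(vg / (vg + noise_var) if vg + noise_var > 0 else 1.0)
        h2_within = float(np.mean(within))
    else:
        h2_within = float("nan")
    return TraitRealization(g, y, noise_var, float(target_h2), h2_overall, h2_within)


def standardize_phenotypes(y: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Center to mean 0 and scale to unit variance (denominator-n SD).

    Returns the standardized values and the (mean, sd) record needed to map
    predictions back to the original scale.
    """
    y = np.asarray(y, dtype=float)
    mu = float(np.mean(y))
    sd = float(np.std(y))
    if sd <= 0.0 or not np.isfinite(sd):
        raise ValueError("phenotypes are constant; cannot standardize")
    return (y - mu) / sd, (mu, sd)


def simulate_trait(
    data: MarkerData,
    n_qtl: int = 20,
    rsd: float = 1.0,
    target_h2: float = 0.70,
    seed: int = 0,
) -> tuple[MarkerData, TraitRealization, QTLArchitecture]:
    """QTL sampling, effect drawing and noise in one seeded call.

    Returns ``(reduced_data, trait, architecture)`` where ``reduced_data``
    excludes the QTL columns (they are unobserved in the analyses).
    """
    ss = np.random.SeedSequence(seed).generate_state(3) % (2**31)
    qtl_data, reduced = sample_qtl(data, n_qtl, int(ss[0]))
    pops = data.populations
    arch = sample_effects(
        n_qtl,
        pops.size,
        rsd,
        int(ss[1]),
        qtl_marker_ids=qtl_data.map.marker_ids,
        populations=pops,
    )
    g = genetic_values(qtl_data.genotypes, arch, data.population_labels)
    trait = apply_noise(g, target_h2, int(ss[2]), population_labels=data.population_labels)
    return reduced, trait, arch
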