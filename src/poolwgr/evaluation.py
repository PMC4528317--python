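"""Training/testing protocol for comparing pooling approaches.

A split draws P populations into the training group Pi; within each, a set
Lambda_p of lines is used for training and the remainder Lambda_bar_p for
testing.  Populations outside Pi ("new" populations, Pi_bar) contribute no
training lines.  Three approaches are compared on identical splits:

* no pooling       — BayesA fitted to each Lambda_p separately,
* complete pooling — BayesA fitted to the concatenated training set,
* partial pooling  — the multilevel model fitted to the concatenated set.

GEBVs are linear scores of centered test genotypes on posterior-mean marker
effects (population-specific effects u_jk for Lambda_bar_p under partial
pooling; overall effects u_k for new populations and for complete pooling).
Accuracy is the within-population Pearson correlation of GEBV with the target
(observed phenotypes, or true genetic values in simulations), averaged over
Pi (r_Pi) and over Pi_bar (r_Pi_bar; undefined for no pooling).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .popgen import CenteredGenotypes, MarkerData, center_genotypes, impute_missing
from .traits import simulate_trait, standardize_phenotypes
from .wgr import BayesARegressor, ChainSettings, MultilevelRegressor

__all__ = [
    "SplitPlan",
    "AccuracyResult",
    "ExperimentConfig",
    "ExperimentResult",
    "make_split",
    "make_split_by_fraction",
    "predict_gebv",
    "evaluate_split",
    "run_experiment",
    "paired_comparison",
    "summarize",
]

logger = logging.getLogger(__name__)

APPROACHES = ("no_pooling", "partial_pooling", "complete_pooling")


@dataclass(frozen=True)
class SplitPlan:
    """Index sets of one estimation-testing split.

    ``training_indices``/``testing_indices`` map each population label in Pi
    to global line indices; populations in ``pi_bar_populations`` contribute
    only test lines (all of them).
    """

    pi_populations: np.ndarray
    pi_bar_populations: np.ndarray
    training_indices: dict[int, np.ndarray]
    testing_indices: dict[int, np.ndarray]

    def __post_init__(self):
        for p in self.pi_populations:
            tr = self.training_indices[int(p)]
            te = self.testing_indices[int(p)]
            if np.intersect1d(tr, te).size:
                raise ValueError(f"training and testing lines of population {p} overlap")

    @property
    def P(self) -> int:
        return int(self.pi_populations.size)

    @property
    def N(self) -> int:
        return int(sum(v.size for v in self.training_indices.values()))

    @property
    def all_training(self) -> np.ndarray:
        return np.sort(
            np.concatenate([self.training_indices[int(p)] for p in self.pi_populations])
        )


@dataclass(frozen=True)
class AccuracyResult:
    """Per-population accuracies of one approach on one split."""

    approach: str
    per_population_r: dict[int, float]
    r_pi: float
    r_pi_bar: float | None
    replicate_id: int = 0
    divergence: float | None = None
    excluded_populations: tuple = ()


@dataclass(frozen=True)
class ExperimentConfig:
    """Replicated pooling-comparison experiment.

    Either ``Np`` (per-population training size, may be fractional — the
    fractional remainder is assigned to one random population) together with
    ``P``, or ``training_fraction`` (all populations trained on that fraction
    of their lines; no new populations) must be given, not both.
    In simulation mode (``rsd`` not None) the trait is regenerated per
    replicate: QTL positions and effects anew each time, accuracy measured
    against true genetic values.
    """

    P: int | None = None
    Np: float | None = None
    training_fraction: float | None = None
    n_replicates: int = 10
    approaches: tuple = APPROACHES
    settings: ChainSettings | dict = field(default_factory=ChainSettings)
    accuracy_target: str = "observed_phenotype"
    seed: int = 0
    # simulation mode
    rsd: float | None = None
    n_qtl: int = 20
    target_h2: float = 0.70

    def __post_init__(self):
        if (self.Np is None) == (self.training_fraction is None):
            raise ValueError("exactly one of Np and training_fraction must be given")
        if self.Np is not None and self.P is None:
            raise ValueError("P is required with Np")
        if self.accuracy_target not in ("observed_phenotype", "true_genetic_value"):
            raise ValueError("unknown accuracy_target")
        bad = set(self.approaches) - set(APPROACHES)
        if bad:
            raise ValueError(f"unknown approaches {sorted(bad)}")

    def settings_for(self, approach: str) -> ChainSettings:
        if isinstance(self.settings, dict):
            return self.settings[approach]
        return self.settings


@dataclass(frozen=True)
class ExperimentResult:
    """Long per-population accuracies plus a per-replicate summary table."""

    per_population: pd.DataFrame  # replicate, approach, population, set, r
    summary: pd.DataFrame  # replicate, approach, r_pi, r_pi_bar, divergence


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


def make_split(population_labels, P: int, Np: float, seed: int) -> SplitPlan:
    """Random split: P populations into Pi, about Np training lines in each.

    floor(Np) lines are drawn per population; the total fractional remainder
    round(P*Np) - P*floor(Np) is added to ONE randomly chosen population, so
    N = round(P*Np) exactly (e.g. P=20, Np=12.5: nineteen populations
    contribute 12 lines and one contributes 22).
    """
    labels = np.asarray(population_labels, dtype=np.int64)
    pops = np.unique(labels)
    if P > pops.size:
        raise ValueError(f"P={P} exceeds the {pops.size} available populations")
    if Np < 1:
        raise ValueError("Np must be >= 1")
    rng = np.random.default_rng(seed)
    pi = np.sort(rng.choice(pops, size=P, replace=False))
    pi_bar = np.setdiff1d(pops, pi)
    base = int(np.floor(Np))
    remainder = int(round(P * Np)) - P * base
    lucky = int(rng.integers(P)) if remainder else -1
    training, testing = {}, {}
    for idx, p in enumerate(pi):
        rows = np.flatnonzero(labels == p)
        want = base + (remainder if idx == lucky else 0)
        if want > rows.size:
            raise ValueError(
                f"population {p} has {rows.size} lines; cannot draw {want} training lines"
            )
        if want == rows.size:
            raise ValueError(f"population {p} would have an empty test set")
        tr = np.sort(rng.choice(rows, size=want, replace=False))
        training[int(p)] = tr
        testing[int(p)] = np.setdiff1d(rows, tr)
    return SplitPlan(pi, pi_bar, training, testing)


def make_split_by_fraction(population_labels, fraction: float, seed: int) -> SplitPlan:
    """Train on round(fraction * size) lines of EVERY population (Pi_bar empty)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    labels = np.asarray(population_labels, dtype=np.int64)
    pops = np.unique(labels)
    rng = np.random.default_rng(seed)
    training, testing = {}, {}
    for p in pops:
        rows = np.flatnonzero(labels == p)
        want = int(round(fraction * rows.size))
        if want == 0 or want == rows.size:
            raise ValueError(
                f"fraction {fraction} leaves population {p} with an empty "
                f"training or test set ({rows.size} lines)"
            )
        tr = np.sort(rng.choice(rows, size=want, replace=False))
        training[int(p)] = tr
        testing[int(p)] = np.setdiff1d(rows, tr)
    return SplitPlan(pops, np.empty(0, dtype=np.int64), training, testing)


# ---------------------------------------------------------------------------
# prediction and accuracy
# ---------------------------------------------------------------------------


def predict_gebv(Z_test, effects) -> np.ndarray:
    """GEBV = Z_test @ effects (no intercept; correlations are shift-invariant).

    ``Z_test`` must be centered with the training set's stored frequencies.
    """
    if isinstance(Z_test, CenteredGenotypes):
        Z = Z_test.values
    else:
        Z = np.asarray(Z_test, dtype=float)
    effects = np.asarray(effects, dtype=float).ravel()
    if Z.shape[1] != effects.size:
        raise ValueError("marker count of Z_test and effect vector differ")
    return Z @ effects


def _pearson(a, b) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 3 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def _centered_subset(data: MarkerData, rows, frequencies) -> np.ndarray:
    sub = data.subset_lines(rows)
    return center_genotypes(sub, "training", frequencies=frequencies).values


def evaluate_split(
    data: MarkerData,
    y,
    split: SplitPlan,
    approach: str,
    settings: ChainSettings | None = None,
    target=None,
    replicate_id: int = 0,
) -> AccuracyResult:
    """Train one pooling approach on a split and score per-population accuracy.

    Allele frequencies for centering are computed on exactly the training
    lines the model sees (per population under no pooling, pooled otherwise)
    and reused to code the corresponding test lines.  Phenotypes are
    standardized on the same training lines.  ``target`` defaults to the
    observed phenotypes; pass true genetic values in simulations.
    """
    if approach not in APPROACHES:
        raise ValueError(f"unknown approach {approach!r}")
    y = np.asarray(y, dtype=float).ravel()
    if y.size != data.n_lines:
        raise ValueError("phenotype length must match data lines")
    target = y if target is None else np.asarray(target, dtype=float).ravel()
    if target.size != data.n_lines:
        raise ValueError("target length must match data lines")
    st = settings or ChainSettings()
    if data.missing_mask.any():
        data = impute_missing(data, "pooled")

    per_pop: dict[int, float] = {}
    divergence = None

    if approach == "no_pooling":
        for p in split.pi_populations:
            tr = split.training_indices[int(p)]
            te = split.testing_indices[int(p)]
            train = data.subset_lines(tr)
            Z_train = center_genotypes(train, "training")
            y_std, _ = standardize_phenotypes(y[tr])
            model = BayesARegressor(
                n_samples=st.n_samples, burn_in=st.burn_in, thin=st.thin, random_state=st.seed
            ).fit(Z_train.values, y_std)
            Z_te = _centered_subset(data, te, Z_train.reference_frequencies)
            per_pop[int(p)] = _pearson(predict_gebv(Z_te, model.coef_), target[te])
    else:
        tr_all = split.all_training
        train = data.subset_lines(tr_all)
        Z_train = center_genotypes(train, "training")
        y_std, _ = standardize_phenotypes(y[tr_all])
        if approach == "complete_pooling":
            model = BayesARegressor(
                n_samples=st.n_samples, burn_in=st.burn_in, thin=st.thin, random_state=st.seed
            ).fit(Z_train.values, y_std)
            specific = {int(p): model.coef_ for p in split.pi_populations}
            overall = model.coef_
        else:
            model = MultilevelRegressor(
                n_samples=st.n_samples, burn_in=st.burn_in, thin=st.thin, random_state=st.seed
            ).fit(Z_train.values, y_std, populations=data.population_labels[tr_all])
            row = {int(p): j for j, p in enumerate(model.populations_)}
            specific = {
                int(p): model.coef_specific_[row[int(p)]] for p in split.pi_populations
            }
            overall = model.coef_overall_
            divergence = model.divergence_
        for p in split.pi_populations:
            te = split.testing_indices[int(p)]
            Z_te = _centered_subset(data, te, Z_train.reference_frequencies)
            per_pop[int(p)] = _pearson(predict_gebv(Z_te, specific[int(p)]), target[te])
        for p in split.pi_bar_populations:
            rows = data.lines_of(int(p))
            Z_te = _centered_subset(data, rows, Z_train.reference_frequencies)
            per_pop[int(p)] = _pearson(predict_gebv(Z_te, overall), target[rows])

    excluded = tuple(int(p) for p, r in per_pop.items() if np.isnan(r))
    if excluded:
        logger.warning(
            "replicate %d, %s: correlation undefined for population(s) %s; excluded",
            replicate_id,
            approach,
            excluded,
        )
    pi_r = [per_pop[int(p)] for p in split.pi_populations if int(p) not in excluded]
    r_pi = float(np.mean(pi_r)) if pi_r else float("nan")
    if approach == "no_pooling" or split.pi_bar_populations.size == 0:
        r_pi_bar = None
    else:
        bar_r = [per_pop[int(p)] for p in split.pi_bar_populations if int(p) not in excluded]
        r_pi_bar = float(np.mean(bar_r)) if bar_r else float("nan")
    return AccuracyResult(approach, per_pop, r_pi, r_pi_bar, replicate_id, divergence, excluded)


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------


def run_experiment(
    config: ExperimentConfig, data: MarkerData, y=None, target=None
) -> ExperimentResult:
    """Replicate splits (and, in simulation mode, traits) and score approaches.

    All approaches of a replicate are evaluated on the SAME split (and, in
    simulation mode, the same simulated trait), so sampling variation between
    replicates does not enter the comparison among approaches.
    """
    simulate = config.rsd is not None
    if not simulate and y is None:
        raise ValueError("observed phenotypes are required outside simulation mode")
    ss = np.random.SeedSequence(config.seed)
    rows_pp, rows_sum = [], []
    for rep, child in enumerate(ss.spawn(config.n_replicates)):
        s_trait, s_split, s_chain = child.generate_state(3) % (2**31)
        if simulate:
            fit_data, trait, _ = simulate_trait(
                data, config.n_qtl, config.rsd, config.target_h2, int(s_trait)
            )
            y_rep = trait.phenotypes
            target_rep = (
                trait.genetic_values
                if config.accuracy_target == "true_genetic_value"
                else y_rep
            )
        else:
            fit_data, y_rep = data, np.asarray(y, float)
            target_rep = y_rep if target is None else np.asarray(target, float)
        if config.Np is not None:
            split = make_split(fit_data.population_labels, config.P, config.Np, int(s_split))
        else:
            split = make_split_by_fraction(
                fit_data.population_labels, config.training_fraction, int(s_split)
            )
        train_hash = hash(split.all_training.tobytes())
        for approach in config.approaches:
            st = config.settings_for(approach)
            st = ChainSettings(st.n_samples, st.burn_in, st.thin, int(s_chain))
            assert hash(split.all_training.tobytes()) == train_hash
            res = evaluate_split(
                fit_data, y_rep, split, approach, st, target=target_rep, replicate_id=rep
            )
            for p, r in res.per_population_r.items():
                rows_pp.append(
                    {
                        "replicate": rep,
                        "approach": approach,
                        "population": p,
                        "set": "pi" if p in split.pi_populations else "pi_bar",
                        "r": r,
                    }
                )
            rows_sum.append(
                {
                    "replicate": rep,
                    "approach": approach,
                    "r_pi": res.r_pi,
                    "r_pi_bar": np.nan if res.r_pi_bar is None else res.r_pi_bar,
                    "divergence": np.nan if res.divergence is None else res.divergence,
                }
            )
    return ExperimentResult(pd.DataFrame(rows_pp), pd.DataFrame(rows_sum))


def paired_comparison(results_a, results_b, metric: str = "r_pi"):
    """Two-sided paired t-test on per-replicate accuracies of two approaches.

    Inputs are summary frames (``replicate`` + metric columns) or plain
    sequences aligned by replicate.  Returns (mean difference, t, p).
    """

    def _values(r):
        if isinstance(r, pd.DataFrame):
            return r.sort_values("replicate")[metric].to_numpy(float), r.sort_values(
                "replicate"
            )["replicate"].to_numpy()
        return np.asarray(r, dtype=float), None

    a, ra = _values(results_a)
    b, rb = _values(results_b)
    if ra is not None and rb is not None and not np.array_equal(ra, rb):
        raise ValueError("replicate ids of the two result sets differ")
    if a.size != b.size:
        raise ValueError("result sets must pair one-to-one")
    if a.size < 3:
        raise ValueError("need at least 3 replicate pairs")
    diff = a - b
    mean = float(diff.mean())
    if np.std(diff, ddof=1) == 0.0:
        # degenerate: constant difference
        return (mean, 0.0, 1.0) if mean == 0.0 else (mean, float("inf"), 0.0)
    t, p = stats.ttest_rel(a, b)
    return mean, float(t), float(p)


def summarize(results: pd.DataFrame | ExperimentResult) -> pd.DataFrame:
    """Per-approach means and standard errors (sd / sqrt(n)) over replicates."""
    df = results.summary if isinstance(results, ExperimentResult) else results
    rows = []
    for approach, grp in df.groupby("approach", sort=False):
        for metric in ("r_pi", "r_pi_bar"):
            vals = grp[metric].dropna().to_numpy(float)
            if vals.size == 0:
                continue
            if vals.size == 1:
                logger.warning("single replicate for %s/%s: SE reported as 0", approach, metric)
                se = 0.0
            else:
                se = float(np.std(vals, ddof=1) / np.sqrt(vals.size))
            rows.append(
                {
                    "approach": approach,
                    "metric": metric,
                    "mean": float(vals.mean()),
                    "se": se,
                    "n": int(vals.size),
                }
            )
    return pd.DataFrame(rows)
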