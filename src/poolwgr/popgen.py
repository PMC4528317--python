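"""Synthetic multi-population biparental genotypes and genotype preprocessing.

This module emulates the structure of multi-parent maize breeding designs:
many biparental families that share parents — in particular NAM-like designs,
where a panel of diverse donor inbreds is each crossed to one common parent and
recombinant inbred lines (RILs) are derived from every cross, and IB-like
designs of interconnected doubled-haploid (DH) families.  Meiosis follows the
Haldane (no-interference) map function; chromosomes assort independently.

It also provides the genotype preprocessing used by every model fit:
marker thinning (by map spacing or at random), mean imputation of missing
genotypes by twice the reference-allele frequency, and centering of
reference-allele counts by twice the reference-allele frequency.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GeneticMap",
    "FounderPanel",
    "MarkerData",
    "CenteredGenotypes",
    "make_genetic_map",
    "simulate_founder_panel",
    "derive_population",
    "assemble_multi_population",
    "simulate_nam_like",
    "thin_markers_by_spacing",
    "thin_markers_random",
    "impute_missing",
    "allele_frequencies",
    "center_genotypes",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker map: ids, chromosome numbers (>=1) and positions in cM.

    Markers are stored chromosome-blockwise with strictly increasing positions
    within each chromosome.
    """

    marker_ids: np.ndarray
    chromosome: np.ndarray
    position: np.ndarray

    def __post_init__(self):
        mid = np.asarray(self.marker_ids, dtype=object)
        chrom = np.asarray(self.chromosome, dtype=np.int64)
        pos = np.asarray(self.position, dtype=float)
        if not (mid.size == chrom.size == pos.size):
            raise ValueError("marker_ids, chromosome and position must have equal length")
        if mid.size and len(set(mid.tolist())) != mid.size:
            raise ValueError("marker ids must be unique")
        if np.any(chrom < 1):
            raise ValueError("chromosome numbers must be >= 1")
        if np.any(pos < 0):
            raise ValueError("positions must be >= 0 cM")
        # chromosome-blockwise ordering, strictly increasing within chromosome
        for c in np.unique(chrom):
            idx = np.flatnonzero(chrom == c)
            if np.any(np.diff(idx) != 1):
                raise ValueError(f"markers of chromosome {c} are not contiguous")
            if np.any(np.diff(pos[idx]) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")
        object.__setattr__(self, "marker_ids", mid)
        object.__setattr__(self, "chromosome", chrom)
        object.__setattr__(self, "position", pos)

    @property
    def n_markers(self) -> int:
        return int(self.marker_ids.size)

    def adjacent_recombination(self) -> np.ndarray:
        """Recombination probability between adjacent markers (length K-1).

        Haldane: r = (1 - exp(-2 d / 100)) / 2 for d cM on the same chromosome;
        0.5 across chromosome boundaries (independent assortment).
        """
        if self.n_markers < 2:
            return np.empty(0)
        d = np.diff(self.position)
        r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
        r[np.diff(self.chromosome) != 0] = 0.5
        return r

    def index_of(self, marker_ids) -> np.ndarray:
        lookup = {m: i for i, m in enumerate(self.marker_ids.tolist())}
        try:
            return np.array([lookup[m] for m in marker_ids], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - message only
            raise KeyError(f"marker {exc.args[0]!r} not in map") from None

    def subset(self, marker_ids) -> "GeneticMap":
        idx = np.sort(self.index_of(marker_ids))
        return GeneticMap(self.marker_ids[idx], self.chromosome[idx], self.position[idx])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"marker": self.marker_ids, "chromosome": self.chromosome, "position_cM": self.position}
        )


@dataclass(frozen=True)
class FounderPanel:
    """Fully inbred founder haplotypes (founders x markers, binary: 1 = reference)."""

    founder_ids: np.ndarray
    haplotypes: np.ndarray
    common_parent_index: int = 0

    def __post_init__(self):
        fid = np.asarray(self.founder_ids, dtype=object)
        hap = np.asarray(self.haplotypes, dtype=np.int8)
        if hap.ndim != 2 or hap.shape[0] != fid.size:
            raise ValueError("haplotypes must be founders x markers")
        if not np.isin(hap, (0, 1)).all():
            raise ValueError("founder haplotypes must be binary (fully inbred founders)")
        if not 0 <= self.common_parent_index < fid.size:
            raise ValueError("common_parent_index out of range")
        object.__setattr__(self, "founder_ids", fid)
        object.__setattr__(self, "haplotypes", hap)

    @property
    def n_founders(self) -> int:
        return int(self.founder_ids.size)


@dataclass(frozen=True)
class MarkerData:
    """Lines x markers reference-allele counts with population labels and a map.

    ``genotypes`` is a float matrix; entries are in {0, 1, 2} or NaN (missing).
    Imputed data may carry non-integer entries (see :func:`impute_missing`).
    """

    line_ids: np.ndarray
    population_labels: np.ndarray
    genotypes: np.ndarray
    map: GeneticMap
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        lid = np.asarray(self.line_ids, dtype=object)
        lab = np.asarray(self.population_labels, dtype=np.int64)
        g = np.asarray(self.genotypes, dtype=float)
        if g.ndim != 2:
            raise ValueError("genotypes must be a 2-D lines x markers matrix")
        if g.shape[0] != lid.size or lab.size != lid.size:
            raise ValueError("line_ids, population_labels and genotype rows must align")
        if g.shape[1] != self.map.n_markers:
            raise ValueError("genotype columns must match the map's marker count")
        object.__setattr__(self, "line_ids", lid)
        object.__setattr__(self, "population_labels", lab)
        object.__setattr__(self, "genotypes", g)

    @property
    def n_lines(self) -> int:
        return int(self.line_ids.size)

    @property
    def n_markers(self) -> int:
        return self.map.n_markers

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.genotypes)

    @property
    def populations(self) -> np.ndarray:
        return np.unique(self.population_labels)

    def lines_of(self, population: int) -> np.ndarray:
        return np.flatnonzero(self.population_labels == population)

    def subset_lines(self, indices) -> "MarkerData":
        idx = np.asarray(indices, dtype=np.int64)
        return replace(
            self,
            line_ids=self.line_ids[idx],
            population_labels=self.population_labels[idx],
            genotypes=self.genotypes[idx],
        )

    def subset_markers(self, marker_ids) -> "MarkerData":
        sub = self.map.subset(marker_ids)
        cols = self.map.index_of(sub.marker_ids)
        return replace(self, genotypes=self.genotypes[:, cols], map=sub)

    @classmethod
    def concatenate(cls, parts: list["MarkerData"]) -> "MarkerData":
        if not parts:
            raise ValueError("nothing to concatenate")
        m = parts[0].map
        for p in parts[1:]:
            if p.map.n_markers != m.n_markers or np.any(p.map.marker_ids != m.marker_ids):
                raise ValueError("all parts must share the same marker map")
        return cls(
            np.concatenate([p.line_ids for p in parts]),
            np.concatenate([p.population_labels for p in parts]),
            np.vstack([p.genotypes for p in parts]),
            m,
        )


@dataclass(frozen=True)
class CenteredGenotypes:
    """Reference-allele counts centered by twice the reference-allele frequency."""

    values: np.ndarray
    reference_frequencies: np.ndarray
    frequency_scope: str
    marker_ids: np.ndarray

    @property
    def n_lines(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_markers(self) -> int:
        return int(self.values.shape[1])


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def make_genetic_map(
    n_chromosomes: int, chromosome_length: float, n_markers: int, seed: int
) -> GeneticMap:
    """Random marker map: markers spread near-equally over chromosomes,
    positions uniform on (0, chromosome_length), sorted within chromosome."""
    if n_chromosomes < 1 or n_markers < 1 or chromosome_length <= 0:
        raise ValueError("n_chromosomes, n_markers and chromosome_length must be positive")
    if n_markers < n_chromosomes:
        raise ValueError("need at least one marker per chromosome")
    rng = np.random.default_rng(seed)
    base, extra = divmod(n_markers, n_chromosomes)
    counts = np.full(n_chromosomes, base, dtype=int)
    counts[:extra] += 1
    ids, chroms, pos = [], [], []
    i = 0
    for c, k in enumerate(counts, start=1):
        p = np.sort(rng.uniform(0.0, chromosome_length, size=k))
        while np.any(np.diff(p) <= 0):  # ties have probability ~0; resample defensively
            p = np.sort(rng.uniform(0.0, chromosome_length, size=k))
        for x in p:
            ids.append(f"M{i + 1:04d}")
            chroms.append(c)
            pos.append(x)
            i += 1
    return GeneticMap(np.array(ids, dtype=object), np.array(chroms), np.array(pos))


def simulate_founder_panel(
    map: GeneticMap,
    n_founders: int,
    reference_maf_low: float = 0.1,
    reference_maf_high: float = 0.5,
    seed: int = 0,
) -> FounderPanel:
    """Simulate a diverse panel of fully inbred founders.

    Per marker, a reference-allele frequency is drawn uniformly from
    [maf_low, maf_high] or its mirror [1-maf_high, 1-maf_low] (each side with
    probability 1/2); founder alleles are independent Bernoulli draws.  Markers
    monomorphic across the panel are resampled until polymorphic, so the panel
    carries only polymorphic SNPs.  Founder 0 is the designated common parent.
    """
    if not (0.0 < reference_maf_low <= reference_maf_high <= 0.5):
        raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
    if n_founders < 2:
        raise ValueError("need at least two founders")
    rng = np.random.default_rng(seed)
    K = map.n_markers

    def draw(k):
        f = rng.uniform(reference_maf_low, reference_maf_high, size=k)
        flip = rng.random(k) < 0.5
        return np.where(flip, 1.0 - f, f)

    freq = draw(K)
    hap = (rng.random((n_founders, K)) < freq).astype(np.int8)
    mono = np.flatnonzero(hap.min(axis=0) == hap.max(axis=0))
    while mono.size:
        f = draw(mono.size)
        hap[:, mono] = rng.random((n_founders, mono.size)) < f
        mono = mono[hap[:, mono].min(axis=0) == hap[:, mono].max(axis=0)]
    ids = np.array(
        ["CP"] + [f"F{i:02d}" for i in range(1, n_founders)], dtype=object
    )
    return FounderPanel(ids, hap, common_parent_index=0)


def _gametes(hap_a: np.ndarray, hap_b: np.ndarray, recomb: np.ndarray, rng) -> np.ndarray:
    """One meiotic gamete per row of the diploid (hap_a, hap_b) parents.

    ``hap_a``/``hap_b`` are (n, K) haplotype matrices; ``recomb`` the adjacent
    recombination probabilities (K-1,).  Crossover phase is a cumulative XOR of
    independent Bernoulli(r) interval events (Haldane, no interference).
    """
    n, K = hap_a.shape
    phase = np.empty((n, K), dtype=bool)
    phase[:, 0] = rng.random(n) < 0.5
    if K > 1:
        phase[:, 1:] = rng.random((n, K - 1)) < recomb
        np.logical_xor.accumulate(phase, axis=1, out=phase)
    return np.where(phase, hap_b, hap_a)


def derive_population(
    panel: FounderPanel,
    donor_index: int,
    n_lines: int,
    line_type: str = "RIL",
    selfing_generations: int = 6,
    map: GeneticMap | None = None,
    seed: int = 0,
    population_label: int = 1,
    line_prefix: str | None = None,
) -> MarkerData:
    """Derive one biparental population from the common parent x donor cross.

    DH: a single meiosis of the F1, doubled (fully homozygous).
    RIL: single-seed descent from the F1 for ``selfing_generations``
    generations; residual heterozygotes are retained and coded as count 1.
    """
    if map is None:
        raise ValueError("a GeneticMap is required")
    if donor_index == panel.common_parent_index:
        raise ValueError("donor must differ from the common parent")
    if not 0 <= donor_index < panel.n_founders:
        raise ValueError("donor_index out of range")
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    if line_type not in ("RIL", "DH"):
        raise ValueError("line_type must be 'RIL' or 'DH'")
    if map.n_markers != panel.haplotypes.shape[1]:
        raise ValueError("map and panel marker counts differ")
    rng = np.random.default_rng(seed)
    recomb = map.adjacent_recombination()
    h0 = np.broadcast_to(panel.haplotypes[panel.common_parent_index], (n_lines, map.n_markers))
    h1 = np.broadcast_to(panel.haplotypes[donor_index], (n_lines, map.n_markers))
    if line_type == "DH":
        gam = _gametes(h0, h1, recomb, rng)
        geno = (2 * gam).astype(float)
    else:
        ha, hb = np.array(h0), np.array(h1)
        for _ in range(selfing_generations):
            ha, hb = (
                _gametes(ha, hb, recomb, rng),
                _gametes(ha, hb, recomb, rng),
            )
        geno = (ha + hb).astype(float)
    prefix = line_prefix or f"P{population_label:02d}"
    ids = np.array([f"{prefix}_L{i + 1:03d}" for i in range(n_lines)], dtype=object)
    labels = np.full(n_lines, population_label, dtype=np.int64)
    meta = {
        "seed": int(seed),
        "line_type": line_type,
        "donor": str(panel.founder_ids[donor_index]),
    }
    return MarkerData(ids, labels, geno, map, metadata=meta)


def assemble_multi_population(
    panel: FounderPanel,
    donor_indices,
    lines_per_population,
    line_type: str = "RIL",
    map: GeneticMap | None = None,
    seed: int = 0,
    selfing_generations: int = 6,
) -> MarkerData:
    """Concatenate biparental populations (labels 1..P) sharing the panel."""
    donor_indices = list(donor_indices)
    lines_per_population = list(lines_per_population)
    if not donor_indices:
        raise ValueError("empty cross list")
    if len(donor_indices) != len(lines_per_population):
        raise ValueError("donor_indices and lines_per_population must have equal length")
    child_seeds = np.random.SeedSequence(seed).generate_state(len(donor_indices)) % (2**31)
    parts = [
        derive_population(
            panel,
            donor,
            n_lines,
            line_type=line_type,
            selfing_generations=selfing_generations,
            map=map,
            seed=int(s),
            population_label=j + 1,
        )
        for j, (donor, n_lines, s) in enumerate(zip(donor_indices, lines_per_population, child_seeds))
    ]
    out = MarkerData.concatenate(parts)
    return replace(out, metadata={"seed": int(seed), "line_type": line_type})


def simulate_nam_like(
    n_populations: int = 25,
    lines_per_population=188,
    n_markers: int = 285,
    n_chromosomes: int = 10,
    chromosome_length: float = 140.0,
    line_type: str = "RIL",
    selfing_generations: int = 6,
    reference_maf_low: float = 0.1,
    reference_maf_high: float = 0.5,
    seed: int = 0,
) -> MarkerData:
    """Convenience generator for a NAM-like design.

    ``n_populations`` diverse donors are each crossed to one common parent and
    a RIL (or DH) family is derived per cross.  Defaults mirror the scale of
    the maize NAM panel: 25 families, 188 lines each, 285 markers on a
    10 x 140 cM map.
    """
    ss = np.random.SeedSequence(seed).generate_state(3) % (2**31)
    gmap = make_genetic_map(n_chromosomes, chromosome_length, n_markers, int(ss[0]))
    panel = simulate_founder_panel(
        gmap, n_populations + 1, reference_maf_low, reference_maf_high, int(ss[1])
    )
    if np.isscalar(lines_per_population):
        lines = [int(lines_per_population)] * n_populations
    else:
        lines = list(lines_per_population)
    return assemble_multi_population(
        panel,
        range(1, n_populations + 1),
        lines,
        line_type=line_type,
        map=gmap,
        seed=int(ss[2]),
        selfing_generations=selfing_generations,
    )


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def thin_markers_by_spacing(map: GeneticMap, target_spacing: float, seed: int) -> np.ndarray:
    """One marker per ``target_spacing``-cM bin, sampled uniformly per bin.

    Each chromosome is partitioned into consecutive bins of ``target_spacing``
    cM; empty bins are skipped.  Returns the retained marker ids in map order.
    """
    if target_spacing <= 0:
        raise ValueError("target_spacing must be positive")
    rng = np.random.default_rng(seed)
    keep = []
    for c in np.unique(map.chromosome):
        idx = np.flatnonzero(map.chromosome == c)
        bins = np.floor(map.position[idx] / target_spacing).astype(int)
        for b in np.unique(bins):
            members = idx[bins == b]
            keep.append(int(rng.choice(members)))
    keep = np.sort(np.array(keep, dtype=int))
    return map.marker_ids[keep]


def thin_markers_random(marker_ids, n: int, seed: int) -> np.ndarray:
    """Uniform sample of ``n`` marker ids without replacement."""
    marker_ids = np.asarray(marker_ids, dtype=object)
    if n > marker_ids.size:
        raise ValueError(f"cannot sample {n} markers from {marker_ids.size}")
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(marker_ids.size, size=n, replace=False))
    return marker_ids[keep]


def _frequency_groups(data: MarkerData, frequency_scope: str):
    """Yield (row-index array, scope name) per frequency-scope group."""
    if frequency_scope == "pooled":
        yield np.arange(data.n_lines), "pooled"
    elif frequency_scope == "per_population":
        for p in data.populations:
            yield data.lines_of(int(p)), f"population {p}"
    else:
        raise ValueError("frequency_scope must be 'pooled' or 'per_population'")


def impute_missing(data: MarkerData, frequency_scope: str = "pooled") -> MarkerData:
    """Replace missing genotypes with twice the reference-allele frequency.

    Frequencies are computed among the observed genotypes within the scope
    (pooled over all lines, or within each population).  Imputed entries may be
    non-integer.
    """
    if not data.missing_mask.any():
        return data
    g = data.genotypes.copy()
    for rows, name in _frequency_groups(data, frequency_scope):
        block = g[rows]
        n_obs = np.sum(~np.isnan(block), axis=0)
        if np.any(n_obs == 0):
            k = int(np.flatnonzero(n_obs == 0)[0])
            raise ValueError(
                f"marker {data.map.marker_ids[k]!r} has no observed genotype in scope {name}"
            )
        freq = np.nanmean(block, axis=0) / 2.0
        fill = np.broadcast_to(2.0 * freq, block.shape)
        g[rows] = np.where(np.isnan(block), fill, block)
    return replace(data, genotypes=g)


def allele_frequencies(data: MarkerData) -> np.ndarray:
    """Per-marker reference-allele frequency over all (non-missing) lines."""
    return np.nanmean(data.genotypes, axis=0) / 2.0


def center_genotypes(
    data: MarkerData,
    frequency_scope: str = "pooled",
    frequencies: np.ndarray | None = None,
) -> CenteredGenotypes:
    """Center reference-allele counts by twice the reference-allele frequency.

    With ``frequencies=None``, frequencies are computed over all lines in
    ``data`` (which should then be exactly the line set named by
    ``frequency_scope``); to code test lines consistently with a training set,
    pass the training set's stored ``reference_frequencies``.
    """
    if data.missing_mask.any():
        raise ValueError("genotypes contain missing entries; run impute_missing first")
    if frequencies is None:
        frequencies = allele_frequencies(data)
    else:
        frequencies = np.asarray(frequencies, dtype=float)
        if frequencies.size != data.n_markers:
            raise ValueError("frequency vector length must match marker count")
    values = data.genotypes - 2.0 * frequencies
    return CenteredGenotypes(values, frequencies, frequency_scope, data.map.marker_ids)
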