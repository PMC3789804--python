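"""Synthetic multi-population haplotype cohorts, array definitions and case-control draws.

The generative model is a founder mosaic: a founder haplotype pool is drawn
site-by-site from a site-frequency distribution with most of its mass near zero,
and each sample haplotype is a recombinant copy of founders (switch points placed
with per-interval probability derived from a per-base rate) with per-site flip
noise.  Populations sharing a variant list but drawing their own founder pools
acquire drift-like allele-frequency differentiation; populations with more
founders carry more haplotype diversity and weaker LD, emulating the contrast
between African-ancestry and out-of-Africa cohorts.  This is deliberately not a
coalescent model: every knob (SFS shape, recombination, founder count, noise)
maps directly onto a property the downstream coverage and power machinery is
sensitive to, and everything is seeded and desk-scale.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "PopulationConfig",
    "SimulationConfig",
    "HaplotypePanel",
    "ArrayDefinition",
    "CaseControlDraw",
    "simulate_founders",
    "simulate_population",
    "build_cohort",
    "design_array",
    "simulate_case_control",
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class PopulationConfig:
    """One population nested inside an ancestry group.

    ``recomb_rate`` is per base per meiosis-equivalent: the probability of a
    founder-switch between adjacent variants d bases apart is 1 - exp(-rate*d).
    ``mutation_rate`` is the per-site allele flip probability applied after
    copying.
    """

    label: str
    ancestry_group: str
    n_samples: int
    n_founder_haplotypes: int
    recomb_rate: float
    mutation_rate: float

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ConfigurationError(f"population {self.label!r}: n_samples must be >= 1")
        if self.n_founder_haplotypes < 2:
            raise ConfigurationError(
                f"population {self.label!r}: n_founder_haplotypes must be >= 2"
            )
        for name in ("recomb_rate", "mutation_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"population {self.label!r}: {name} must be in [0,1]")


@dataclass(frozen=True)
class SimulationConfig:
    populations: tuple[PopulationConfig, ...]
    n_variants: int
    chrom_length: int
    sfs_shape: float
    seed: int
    chrom: str = "1"

    def validate(self) -> None:
        if not self.populations:
            raise ConfigurationError("at least one population is required")
        for pop in self.populations:
            pop.validate()
        if self.n_variants < 1:
            raise ConfigurationError("n_variants must be >= 1")
        if self.chrom_length < self.n_variants:
            raise ConfigurationError("chrom_length must be >= n_variants")
        if not self.sfs_shape > 0:
            raise ConfigurationError("sfs_shape must be > 0")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        pops = tuple(
            PopulationConfig(
                label=p["label"],
                ancestry_group=p["ancestry_group"],
                n_samples=int(p["n_samples"]),
                n_founder_haplotypes=int(p["n_founder_haplotypes"]),
                recomb_rate=float(p["recomb_rate"]),
                mutation_rate=float(p["mutation_rate"]),
            )
            for p in d["populations"]
        )
        return cls(
            populations=pops,
            n_variants=int(d["n_variants"]),
            chrom_length=int(d["chrom_length"]),
            sfs_shape=float(d["sfs_shape"]),
            seed=int(d["seed"]),
            chrom=str(d.get("chrom", "1")),
        )

    def to_dict(self) -> dict:
        return {
            "populations": [
                {
                    "label": p.label,
                    "ancestry_group": p.ancestry_group,
                    "n_samples": p.n_samples,
                    "n_founder_haplotypes": p.n_founder_haplotypes,
                    "recomb_rate": p.recomb_rate,
                    "mutation_rate": p.mutation_rate,
                }
                for p in self.populations
            ],
            "n_variants": self.n_variants,
            "chrom_length": self.chrom_length,
            "sfs_shape": self.sfs_shape,
            "seed": self.seed,
            "chrom": self.chrom,
        }


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes with sample -> population -> ancestry-group labels.

    ``haplotypes`` is a (2*n_samples, n_variants) uint8 matrix (0=ref, 1=alt);
    sample i owns rows 2i and 2i+1.  ``variants`` has columns
    chrom, pos (1-based), variant_id, ref, alt with strictly increasing
    positions per chromosome.
    """

    samples: pd.DataFrame  # columns: sample_id, population, ancestry_group
    variants: pd.DataFrame  # columns: chrom, pos, variant_id, ref, alt
    haplotypes: np.ndarray

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def ancestry_groups(self) -> list[str]:
        return list(dict.fromkeys(self.samples["ancestry_group"]))

    def validate(self) -> None:
        if self.haplotypes.shape != (2 * self.n_samples, self.n_variants):
            raise ValueError("haplotype matrix shape does not match samples x variants")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype entries must be 0 or 1")
        for _, sub in self.variants.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValueError("positions must be strictly increasing within a chromosome")

    def genotypes(self) -> np.ndarray:
        """(n_samples, n_variants) alt-allele counts in {0,1,2}."""
        return self.haplotypes[0::2].astype(np.int64) + self.haplotypes[1::2]

    def sample_index(self, sample_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples["sample_id"])}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=np.int64)
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"unknown sample id {e.args[0]!r}") from None

    def group_sample_ids(self, group: str) -> list[str]:
        mask = self.samples["ancestry_group"] == group
        if not mask.any():
            raise KeyError(f"unknown ancestry group {group!r}")
        return list(self.samples.loc[mask, "sample_id"])

    def haplotype_rows(self, sample_idx: np.ndarray) -> np.ndarray:
        rows = np.empty(2 * len(sample_idx), dtype=np.int64)
        rows[0::2] = 2 * np.asarray(sample_idx)
        rows[1::2] = 2 * np.asarray(sample_idx) + 1
        return rows

    def positions(self) -> set[tuple[str, int]]:
        return set(zip(self.variants["chrom"], self.variants["pos"].astype(int)))


@dataclass(frozen=True)
class ArrayDefinition:
    """A named set of (chrom, pos) genomic positions an array assays."""

    name: str
    positions: frozenset = field(default_factory=frozenset)

    @classmethod
    def from_pairs(cls, name: str, pairs) -> "ArrayDefinition":
        return cls(name=name, positions=frozenset((str(c), int(p)) for c, p in pairs))

    def __len__(self) -> int:
        return len(self.positions)

    def typed_mask(self, panel: HaplotypePanel) -> np.ndarray:
        """Boolean mask over panel variants: True where the array assays the position."""
        keys = list(zip(panel.variants["chrom"], panel.variants["pos"].astype(int)))
        return np.fromiter((k in self.positions for k in keys), dtype=bool, count=len(keys))


@dataclass(frozen=True)
class CaseControlDraw:
    """Genotype counts (aa, Aa, AA) among N cases and N controls per replicate.

    ``case_counts`` and ``control_counts`` have shape (reps, 3), counts of
    risk-allele dosage 0/1/2; each row sums to N.
    """

    case_counts: np.ndarray
    control_counts: np.ndarray
    model: object  # power.DiseaseModel; kept untyped to avoid a cyclic import
    n_per_arm: int
    seed: int | None


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_founders(
    n_founder_haplotypes: int, n_variants: int, sfs_shape: float, seed
) -> tuple[np.ndarray, np.ndarray]:
    """Draw founder allele frequencies and haplotypes.

    Per-site alt-allele frequencies follow Beta(sfs_shape, 1), which puts its
    mass near zero as sfs_shape -> 0 (a rare-variant-heavy site-frequency
    spectrum) and has analytic mean sfs_shape / (sfs_shape + 1).  Each founder
    haplotype is an independent Bernoulli draw per site at that frequency.

    Returns (freqs, founders) with founders of shape
    (n_founder_haplotypes, n_variants), dtype uint8.
    """
    if n_founder_haplotypes < 2 or n_variants < 1:
        raise ConfigurationError("need >= 2 founder haplotypes and >= 1 variant")
    if not sfs_shape > 0:
        raise ConfigurationError("sfs_shape must be > 0")
    rng = _as_rng(seed)
    freqs = rng.beta(sfs_shape, 1.0, size=n_variants)
    founders = (rng.random((n_founder_haplotypes, n_variants)) < freqs).astype(np.uint8)
    return freqs, founders


def simulate_mosaic_haplotypes(
    founders: np.ndarray,
    n_haplotypes: int,
    recomb_rate: float,
    mutation_rate: float,
    positions: np.ndarray,
    seed,
) -> np.ndarray:
    """Recombinant founder copies with flip noise.

    Switch points between adjacent variants d bases apart occur with probability
    1 - exp(-recomb_rate * d); at each switch a founder is re-drawn uniformly
    (geometric copy-tract lengths).  After copying, each allele flips
    independently with probability mutation_rate.
    """
    founders = np.asarray(founders, dtype=np.uint8)
    if founders.size == 0:
        raise ConfigurationError("founder set must be non-empty")
    if not (0.0 <= recomb_rate <= 1.0 and 0.0 <= mutation_rate <= 1.0):
        raise ConfigurationError("rates must be in [0,1]")
    rng = _as_rng(seed)
    n_f, L = founders.shape
    pos = np.asarray(positions, dtype=np.float64)
    if pos.shape != (L,):
        raise ConfigurationError("positions must have one entry per variant")

    switch_p = 1.0 - np.exp(-recomb_rate * np.diff(pos)) if L > 1 else np.empty(0)
    # founder ids drawn at every site; carried forward from the last switch point
    draws = rng.integers(0, n_f, size=(n_haplotypes, L))
    switch = np.empty((n_haplotypes, L), dtype=bool)
    switch[:, 0] = True
    if L > 1:
        switch[:, 1:] = rng.random((n_haplotypes, L - 1)) < switch_p
    last_switch = np.maximum.accumulate(np.where(switch, np.arange(L), 0), axis=1)
    founder_id = np.take_along_axis(draws, last_switch, axis=1)
    haps = founders[founder_id, np.arange(L)]
    if mutation_rate > 0:
        flips = rng.random((n_haplotypes, L)) < mutation_rate
        haps = haps ^ flips
    return haps.astype(np.uint8)


def simulate_population(
    founders: np.ndarray,
    n_samples: int,
    recomb_rate: float,
    mutation_rate: float,
    labels: tuple[str, str],
    seed,
    positions: np.ndarray,
    variants: pd.DataFrame,
    sample_prefix: str | None = None,
) -> HaplotypePanel:
    """Simulate one population's HaplotypePanel from a founder pool.

    ``labels`` is (population, ancestry_group).
    """
    population, group = labels
    haps = simulate_mosaic_haplotypes(
        founders, 2 * n_samples, recomb_rate, mutation_rate, positions, seed
    )
    prefix = sample_prefix if sample_prefix is not None else population
    samples = pd.DataFrame(
        {
            "sample_id": [f"{prefix}_{i:04d}" for i in range(n_samples)],
            "population": population,
            "ancestry_group": group,
        }
    )
    panel = HaplotypePanel(samples=samples, variants=variants.copy(), haplotypes=haps)
    panel.validate()
    return panel


def _variant_table(rng: np.random.Generator, n_variants: int, chrom_length: int, chrom: str) -> tuple[pd.DataFrame, np.ndarray]:
    pos = np.sort(rng.choice(chrom_length, size=n_variants, replace=False)) + 1
    table = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos.astype(np.int64),
            "variant_id": [f"{chrom}:{p}" for p in pos],
            "ref": "A",
            "alt": "C",
        }
    )
    return table, pos.astype(np.float64)


def build_cohort(config: SimulationConfig) -> HaplotypePanel:
    """Assemble a multi-population cohort on a shared variant list.

    Randomness is split from the master seed with fixed-order SeedSequence
    spawning (one child for the shared site set and frequencies, then one per
    population), so appending a population leaves earlier populations' draws
    untouched.  Each population draws its own founder pool from the shared
    per-site frequencies, giving drift-like differentiation between
    populations.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(1 + len(config.populations))
    site_rng = np.random.default_rng(children[0])
    variants, pos = _variant_table(site_rng, config.n_variants, config.chrom_length, config.chrom)
    freqs = site_rng.beta(config.sfs_shape, 1.0, size=config.n_variants)

    panels = []
    for pop, child in zip(config.populations, children[1:]):
        rng = np.random.default_rng(child)
        founders = (
            rng.random((pop.n_founder_haplotypes, config.n_variants)) < freqs
        ).astype(np.uint8)
        panels.append(
            simulate_population(
                founders,
                pop.n_samples,
                pop.recomb_rate,
                pop.mutation_rate,
                (pop.label, pop.ancestry_group),
                rng,
                pos,
                variants,
            )
        )

    first = panels[0]
    for p in panels[1:]:
        if not p.variants["pos"].equals(first.variants["pos"]):
            raise RuntimeError("internal error: populations must share the founder site set")
    samples = pd.concat([p.samples for p in panels], ignore_index=True)
    haps = np.concatenate([p.haplotypes for p in panels], axis=0)
    panel = HaplotypePanel(samples=samples, variants=first.variants, haplotypes=haps)
    panel.validate()
    return panel


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation between two dosage vectors; 0 if degenerate."""
    x = x.astype(np.float64)
    y = y.astype(np.float64)
    vx = x.var()
    vy = y.var()
    if vx == 0.0 or vy == 0.0:
        return 0.0
    c = ((x - x.mean()) * (y - y.mean())).mean()
    return float(c * c / (vx * vy))


def design_array(
    panel: HaplotypePanel,
    n_positions: int,
    strategy: str = "maf_stratified_random",
    seed: int | None = None,
    name: str | None = None,
    r2_threshold: float = 0.8,
    window: int = 50,
) -> ArrayDefinition:
    """Choose array positions from a panel.

    ``maf_stratified_random`` samples positions with weight 10 at pooled
    MAF > 0.05 and weight 1 otherwise, mimicking the common-variant GWAS
    backbone of commercial arrays.  ``greedy_tagging`` repeatedly picks the
    variant whose pairwise dosage r2 >= r2_threshold (within ``window``
    variants) covers the most uncovered variants, ties broken toward the
    lower variant index.
    """
    L = panel.n_variants
    if n_positions > L:
        raise ValueError(f"n_positions={n_positions} exceeds panel variant count {L}")
    if name is None:
        name = f"{strategy}_{n_positions}"
    pairs = list(zip(panel.variants["chrom"], panel.variants["pos"].astype(int)))
    if n_positions == 0:
        return ArrayDefinition.from_pairs(name, [])

    G = panel.genotypes()
    if strategy == "maf_stratified_random":
        rng = _as_rng(seed)
        freq = G.mean(axis=0) / 2.0
        maf = np.minimum(freq, 1.0 - freq)
        w = np.where(maf > 0.05, 10.0, 1.0)
        idx = rng.choice(L, size=n_positions, replace=False, p=w / w.sum())
        idx = np.sort(idx)
    elif strategy == "greedy_tagging":
        covered = np.zeros(L, dtype=bool)
        Gf = G.astype(np.float64)
        # adjacency: variants tagged at r2 >= threshold within the window
        adj: list[np.ndarray] = []
        for j in range(L):
            lo, hi = max(0, j - window), min(L, j + window + 1)
            hits = [j]
            for i in range(lo, hi):
                if i != j and _pairwise_r2(Gf[:, j], Gf[:, i]) >= r2_threshold:
                    hits.append(i)
            adj.append(np.array(sorted(hits), dtype=np.int64))
        # lazy-max greedy set cover; heap keys are (-gain, index)
        heap = [(-len(a), j) for j, a in enumerate(adj)]
        heapq.heapify(heap)
        chosen: list[int] = []
        while len(chosen) < n_positions and heap:
            neg_gain, j = heapq.heappop(heap)
            gain = int((~covered[adj[j]]).sum())
            if j in chosen:
                continue
            if -neg_gain != gain:  # stale entry: re-push with current gain
                heapq.heappush(heap, (-gain, j))
                continue
            chosen.append(j)
            covered[adj[j]] = True
        idx = np.sort(np.array(chosen, dtype=np.int64))
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    return ArrayDefinition.from_pairs(name, [pairs[i] for i in idx])


def simulate_case_control(model, n_per_arm: int, seed, reps: int = 1) -> CaseControlDraw:
    """Draw genotype counts for N cases and N controls under a disease model.

    Case genotypes follow P(G|case) and control genotypes P(G|control), each a
    multinomial with N draws (``reps`` independent replicates).
    """
    if n_per_arm < 1:
        raise ConfigurationError("n_per_arm must be >= 1")
    rng = _as_rng(seed)
    p_case, p_control = model.genotype_probs_case(), model.genotype_probs_control()
    case = rng.multinomial(n_per_arm, p_case, size=reps)
    control = rng.multinomial(n_per_arm, p_control, size=reps)
    return CaseControlDraw(
        case_counts=case,
        control_counts=control,
        model=model,
        n_per_arm=n_per_arm,
        seed=None if isinstance(seed, np.random.Generator) else seed,
    )
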