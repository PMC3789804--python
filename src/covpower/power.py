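"""Case-control GWAS power under an additive genotype-relative-risk disease model.

Per-variant power for the 1-df allelic chi-square test is computed from a
non-centrality parameter (NCP) built out of the case and control risk-allele
frequencies implied by (GRR, prevalence K, risk allele frequency p); imputed
variants enter with an effective sample size N_eff = N * r2, the imputation-r2
discounting of information.  Genome-wide power is the variant-count-weighted
mean over a MAF x r2 binned summary of a metrics table.

Conventions (both switchable):

* penetrances — "additive" means additive relative risk, f1 = GRR*f0 and
  f2 = (2*GRR - 1)*f0; "multiplicative" uses f2 = GRR^2 * f0.
* NCP variance — "unpooled" (default) sums the two arm-wise binomial variances;
  "pooled" uses twice the pooled-frequency variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ModelInfeasibleError",
    "DiseaseModel",
    "PowerGrid",
    "penetrances",
    "case_control_freqs",
    "allelic_ncp",
    "power_chisq1",
    "variant_power",
    "default_maf_bin_edges",
    "default_r2_bin_edges",
    "build_power_grid",
    "genome_power",
    "genome_power_exact",
    "full_reference_power",
    "monte_carlo_power",
    "DEFAULT_PREVALENCE",
    "DEFAULT_ALPHA",
    "DEFAULT_GRR_VALUES",
    "DEFAULT_N_VALUES",
]

DEFAULT_PREVALENCE = 0.05
DEFAULT_ALPHA = 5e-8
DEFAULT_GRR_VALUES = (1.1, 1.2, 1.3, 1.4)
DEFAULT_N_VALUES = tuple(range(1000, 10001, 50))


class ModelInfeasibleError(ValueError):
    """Penetrances exceed 1 for the requested (grr, K, p)."""


def penetrances(grr, K: float, p, mode: str = "additive"):
    """Penetrances (f0, f1, f2) for risk-allele dosage 0/1/2.

    f0 solves K = f0*(1-p)^2 + f1*2p(1-p) + f2*p^2 under the chosen
    relative-risk model.  Accepts array ``grr``/``p``; raises
    ModelInfeasibleError if any f2 > 1.
    """
    grr = np.asarray(grr, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if np.any(grr < 1):
        raise ModelInfeasibleError("grr must be >= 1")
    if not (0 < K < 1):
        raise ModelInfeasibleError("prevalence K must be in (0,1)")
    if np.any(p <= 0) or np.any(p > 0.5):
        raise ModelInfeasibleError("risk allele frequency p must be in (0, 0.5]")
    if mode == "additive":
        r2rel = 2.0 * grr - 1.0
    elif mode == "multiplicative":
        r2rel = grr**2
    else:
        raise ValueError(f"unknown penetrance mode {mode!r}")
    f0 = K / ((1 - p) ** 2 + 2 * p * (1 - p) * grr + p**2 * r2rel)
    f1 = grr * f0
    f2 = r2rel * f0
    if np.any(f2 > 1.0):
        raise ModelInfeasibleError(
            f"penetrance f2 > 1 for grr={grr}, K={K}, p={p} (mode={mode})"
        )
    return f0, f1, f2


@dataclass(frozen=True)
class DiseaseModel:
    """Additive-GRR case-control disease model at a single variant.

    ``risk_allele_freq`` is the population frequency of the risk allele, taken
    to be the minor allele (p <= 0.5 enforced).
    """

    grr: float
    prevalence: float
    risk_allele_freq: float
    penetrance_mode: str = "additive"

    def __post_init__(self):
        f0, f1, f2 = penetrances(
            self.grr, self.prevalence, self.risk_allele_freq, self.penetrance_mode
        )
        # K reconstruction guard
        p = self.risk_allele_freq
        k = f0 * (1 - p) ** 2 + f1 * 2 * p * (1 - p) + f2 * p**2
        assert abs(k - self.prevalence) < 1e-12

    @cached_property
    def penetrances(self) -> tuple[float, float, float]:
        return tuple(
            float(x)
            for x in penetrances(
                self.grr, self.prevalence, self.risk_allele_freq, self.penetrance_mode
            )
        )

    def genotype_probs(self) -> np.ndarray:
        """Hardy-Weinberg genotype probabilities for risk-allele dosage 0/1/2."""
        p = self.risk_allele_freq
        return np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])

    def genotype_probs_case(self) -> np.ndarray:
        f = np.array(self.penetrances)
        g = self.genotype_probs()
        return f * g / self.prevalence

    def genotype_probs_control(self) -> np.ndarray:
        f = np.array(self.penetrances)
        g = self.genotype_probs()
        return (1 - f) * g / (1 - self.prevalence)

    @cached_property
    def case_control_freqs(self) -> tuple[float, float]:
        return case_control_freqs(self)


def case_control_freqs(model: DiseaseModel) -> tuple[float, float]:
    """Risk-allele frequency among cases and among controls (Bayes inversion).

    p_case = (p^2 f2 + p(1-p) f1) / K and the control analogue with 1-f; the
    law of total probability K*p_case + (1-K)*p_control = p holds exactly.
    """
    p, K = model.risk_allele_freq, model.prevalence
    f0, f1, f2 = model.penetrances
    p_case = (p**2 * f2 + p * (1 - p) * f1) / K
    p_control = (p**2 * (1 - f2) + p * (1 - p) * (1 - f1)) / (1 - K)
    return float(p_case), float(p_control)


def allelic_ncp(p_case, p_control, n_per_arm, variance: str = "unpooled"):
    """Non-centrality parameter of the 1-df allelic test, N cases + N controls.

    Each arm contributes 2N alleles.  With the default unpooled variance,
    NCP = 2N * (p_case - p_control)^2 / [p_case(1-p_case) + p_control(1-p_control)].
    """
    pc = np.asarray(p_case, dtype=np.float64)
    pd_ = np.asarray(p_control, dtype=np.float64)
    n = np.asarray(n_per_arm, dtype=np.float64)
    if variance == "unpooled":
        denom = pc * (1 - pc) + pd_ * (1 - pd_)
    elif variance == "pooled":
        pbar = 0.5 * (pc + pd_)
        denom = 2.0 * pbar * (1 - pbar)
    else:
        raise ValueError(f"unknown variance form {variance!r}")
    out = 2.0 * n * (pc - pd_) ** 2 / denom
    return out if out.ndim else float(out)


def power_chisq1(ncp, alpha: float):
    """Power of a 1-df chi-square test with the given non-centrality at level alpha.

    Uses the exact identity: a noncentral chi-square(1, ncp) variate is
    (Z + sqrt(ncp))^2, so power = Phi(sqrt(ncp) - sqrt(c)) + Phi(-sqrt(ncp) - sqrt(c))
    with c the central critical value.  ncp = 0 returns alpha exactly; output is
    clamped to [alpha, 1].
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    if alpha == 1.0:
        return np.ones_like(np.asarray(ncp, dtype=np.float64)) if np.ndim(ncp) else 1.0
    ncp = np.asarray(ncp, dtype=np.float64)
    if np.any(ncp < 0):
        raise ValueError("ncp must be >= 0")
    sqrt_c = np.sqrt(stats.chi2.isf(alpha, df=1))
    root = np.sqrt(ncp)
    pw = stats.norm.sf(sqrt_c - root) + stats.norm.sf(sqrt_c + root)
    pw = np.where(ncp == 0.0, alpha, np.clip(pw, alpha, 1.0))
    return pw if pw.ndim else float(pw)


def variant_power(
    maf,
    r2,
    n_per_arm,
    grr: float,
    K: float = DEFAULT_PREVALENCE,
    alpha: float = DEFAULT_ALPHA,
    penetrance_mode: str = "additive",
    variance: str = "unpooled",
):
    """Power at a variant with the given MAF and imputation r2.

    The risk allele is the minor allele (p = maf).  Imputation discounts the
    information: the NCP is evaluated at N_eff = N * r2, so r2 = 1 reproduces
    direct-observation power and r2 = 0 yields alpha.
    """
    maf = np.asarray(maf, dtype=np.float64)
    r2 = np.asarray(r2, dtype=np.float64)
    if np.any((r2 < 0) | (r2 > 1)):
        raise ValueError("r2 must be in [0, 1]")
    f0, f1, f2 = penetrances(grr, K, maf, penetrance_mode)
    p_case = (maf**2 * f2 + maf * (1 - maf) * f1) / K
    p_control = (maf**2 * (1 - f2) + maf * (1 - maf) * (1 - f1)) / (1 - K)
    ncp = allelic_ncp(p_case, p_control, np.asarray(n_per_arm) * r2, variance)
    return power_chisq1(ncp, alpha)


def default_maf_bin_edges() -> np.ndarray:
    """MAF bin edges: 0-0.05 by 0.005, 0.05-0.10 by 0.01, 0.10-0.50 by 0.05 (23 bins)."""
    return np.round(
        np.concatenate(
            [np.arange(0.0, 0.05, 0.005), np.arange(0.05, 0.10, 0.01), np.arange(0.10, 0.501, 0.05)]
        ),
        10,
    )


def default_r2_bin_edges() -> np.ndarray:
    """r2 bin edges: 0 to 1 by 0.05 (20 bins)."""
    return np.round(np.arange(0.0, 1.001, 0.05), 10)


@dataclass(frozen=True)
class PowerGrid:
    """Occupied (MAF, r2) bins of a metrics table: means and variant-count weights."""

    bins: pd.DataFrame  # columns: maf_bin, r2_bin, mean_maf, mean_r2, count, weight
    maf_edges: np.ndarray
    r2_edges: np.ndarray
    maf_filter: float
    n_variants: int


def _bin_index(x: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Left-open right-closed binning; values at the lowest edge fall in bin 0."""
    idx = np.digitize(x, edges, right=True) - 1
    return np.clip(idx, 0, len(edges) - 2)


def build_power_grid(
    metrics: pd.DataFrame,
    maf_edges: np.ndarray | None = None,
    r2_edges: np.ndarray | None = None,
    maf_filter: float = 0.0,
) -> PowerGrid:
    """Bin a metrics table (columns maf, r2) by MAF x r2.

    ``maf_filter`` keeps variants with MAF strictly above the threshold (0
    keeps everything with maf > 0; the mac >= 2 filter upstream already
    removes monomorphic sites).  Weights are bin counts normalized within the
    filtered universe and sum to 1.
    """
    if maf_edges is None:
        maf_edges = default_maf_bin_edges()
    if r2_edges is None:
        r2_edges = default_r2_bin_edges()
    maf_edges = np.asarray(maf_edges, dtype=np.float64)
    r2_edges = np.asarray(r2_edges, dtype=np.float64)
    if len(maf_edges) < 2 or len(r2_edges) < 2 or np.any(np.diff(maf_edges) <= 0) or np.any(
        np.diff(r2_edges) <= 0
    ):
        raise ValueError("bin edges must be strictly increasing with >= 2 entries")
    sub = metrics[metrics["maf"] > maf_filter]
    if len(sub) == 0:
        raise ValueError(f"no variants pass maf_filter > {maf_filter}")
    maf = sub["maf"].to_numpy(dtype=np.float64)
    r2 = sub["r2"].to_numpy(dtype=np.float64)
    mi = _bin_index(maf, maf_edges)
    ri = _bin_index(r2, r2_edges)
    df = pd.DataFrame({"maf_bin": mi, "r2_bin": ri, "maf": maf, "r2": r2})
    g = df.groupby(["maf_bin", "r2_bin"], as_index=False).agg(
        mean_maf=("maf", "mean"), mean_r2=("r2", "mean"), count=("maf", "size")
    )
    g["weight"] = g["count"] / g["count"].sum()
    return PowerGrid(
        bins=g,
        maf_edges=maf_edges,
        r2_edges=r2_edges,
        maf_filter=maf_filter,
        n_variants=len(sub),
    )


def genome_power(
    grid: PowerGrid,
    n_values=DEFAULT_N_VALUES,
    grr_values=DEFAULT_GRR_VALUES,
    K: float = DEFAULT_PREVALENCE,
    alpha: float = DEFAULT_ALPHA,
    penetrance_mode: str = "additive",
    variance: str = "unpooled",
) -> pd.DataFrame:
    """Genome-wide power: weighted mean over bins of per-bin-mean variant power.

    Returns a long table with columns (n_per_arm, grr, power).
    """
    maf = grid.bins["mean_maf"].to_numpy()
    r2 = grid.bins["mean_r2"].to_numpy()
    w = grid.bins["weight"].to_numpy()
    rows = []
    for grr in grr_values:
        f0, f1, f2 = penetrances(grr, K, maf, penetrance_mode)
        p_case = (maf**2 * f2 + maf * (1 - maf) * f1) / K
        p_control = (maf**2 * (1 - f2) + maf * (1 - maf) * (1 - f1)) / (1 - K)
        for n in n_values:
            ncp = allelic_ncp(p_case, p_control, n * r2, variance)
            rows.append((n, grr, float(np.sum(w * power_chisq1(ncp, alpha)))))
    return pd.DataFrame(rows, columns=["n_per_arm", "grr", "power"])


def genome_power_exact(
    metrics: pd.DataFrame,
    n_values=DEFAULT_N_VALUES,
    grr_values=DEFAULT_GRR_VALUES,
    K: float = DEFAULT_PREVALENCE,
    alpha: float = DEFAULT_ALPHA,
    maf_filter: float = 0.0,
    penetrance_mode: str = "additive",
    variance: str = "unpooled",
) -> pd.DataFrame:
    """Unbinned reference: mean per-variant power over the filtered metrics table."""
    sub = metrics[metrics["maf"] > maf_filter]
    if len(sub) == 0:
        raise ValueError(f"no variants pass maf_filter > {maf_filter}")
    maf = sub["maf"].to_numpy(dtype=np.float64)
    r2 = sub["r2"].to_numpy(dtype=np.float64)
    rows = []
    for grr in grr_values:
        f0, f1, f2 = penetrances(grr, K, maf, penetrance_mode)
        p_case = (maf**2 * f2 + maf * (1 - maf) * f1) / K
        p_control = (maf**2 * (1 - f2) + maf * (1 - maf) * (1 - f1)) / (1 - K)
        for n in n_values:
            ncp = allelic_ncp(p_case, p_control, n * r2, variance)
            rows.append((n, grr, float(np.mean(power_chisq1(ncp, alpha)))))
    return pd.DataFrame(rows, columns=["n_per_arm", "grr", "power"])


def full_reference_power(
    metrics: pd.DataFrame,
    n_values=DEFAULT_N_VALUES,
    grr_values=DEFAULT_GRR_VALUES,
    K: float = DEFAULT_PREVALENCE,
    alpha: float = DEFAULT_ALPHA,
    maf_filter: float = 0.0,
    maf_edges: np.ndarray | None = None,
    r2_edges: np.ndarray | None = None,
    penetrance_mode: str = "additive",
    variance: str = "unpooled",
) -> pd.DataFrame:
    """Power of the hypothetical array typing every reference variant (r2 = 1)."""
    forced = metrics.copy()
    forced["r2"] = 1.0
    grid = build_power_grid(forced, maf_edges, r2_edges, maf_filter)
    return genome_power(grid, n_values, grr_values, K, alpha, penetrance_mode, variance)


def monte_carlo_power(
    model: DiseaseModel,
    n_per_arm: int,
    alpha: float,
    reps: int,
    seed,
    dosage_r2: float | None = None,
    variance: str = "unpooled",
) -> tuple[float, float]:
    """Empirical power from seeded case-control simulation; returns (power, SE).

    With ``dosage_r2`` None, each replicate draws genotype counts per arm and
    applies the 1-df allelic chi-square test (z^2 on allele frequencies with
    the chosen variance form).  With ``dosage_r2`` in (0, 1], true genotype
    dosages are degraded with Gaussian noise calibrated so the squared
    correlation between noisy and true dosage is dosage_r2 in expectation, and
    a 1-df score test of the continuous dosage against case status is applied
    (T = n_total * corr^2(dosage, status)).
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    if dosage_r2 is not None and not (0 < dosage_r2 <= 1):
        raise ValueError("dosage_r2 must be in (0, 1]")
    from .simulate import simulate_case_control

    rng = np.random.default_rng(seed)
    draw = simulate_case_control(model, n_per_arm, rng, reps=reps)
    crit = stats.chi2.isf(alpha, df=1)
    two_n = 2.0 * n_per_arm
    dosage = np.arange(3, dtype=np.float64)

    if dosage_r2 is None:
        a_case = draw.case_counts @ dosage
        a_control = draw.control_counts @ dosage
        pc = a_case / two_n
        pd_ = a_control / two_n
        if variance == "unpooled":
            var = pc * (1 - pc) / two_n + pd_ * (1 - pd_) / two_n
        else:
            pbar = 0.5 * (pc + pd_)
            var = 2.0 * pbar * (1 - pbar) / two_n
        with np.errstate(divide="ignore", invalid="ignore"):
            z2 = np.where(var > 0, (pc - pd_) ** 2 / var, 0.0)
        rejections = int((z2 > crit).sum())
    else:
        # analytic mixture variance of the true dosage over the two arms
        pc_probs, pd_probs = model.genotype_probs_case(), model.genotype_probs_control()
        mix = 0.5 * (pc_probs + pd_probs)
        var_g = float(mix @ dosage**2 - (mix @ dosage) ** 2)
        sigma2 = var_g * (1.0 - dosage_r2) / dosage_r2
        n_tot = 2 * n_per_arm
        rejections = 0
        chunk = max(1, int(5e6 // n_tot))
        y = np.concatenate([np.ones(n_per_arm), np.zeros(n_per_arm)])
        yc = y - y.mean()
        ss_y = float(yc @ yc)
        for start in range(0, reps, chunk):
            k = min(chunk, reps - start)
            cc = draw.case_counts[start : start + k]
            dc = draw.control_counts[start : start + k]
            # expand counts into per-individual genotype vectors
            g = np.empty((k, n_tot))
            for r in range(k):
                g[r, :n_per_arm] = np.repeat(dosage, cc[r])
                g[r, n_per_arm:] = np.repeat(dosage, dc[r])
            d = g + rng.normal(0.0, np.sqrt(sigma2), size=g.shape)
            dcen = d - d.mean(axis=1, keepdims=True)
            num = dcen @ yc
            ss_d = np.einsum("ij,ij->i", dcen, dcen)
            with np.errstate(divide="ignore", invalid="ignore"):
                corr2 = np.where(ss_d > 0, num**2 / (ss_d * ss_y), 0.0)
            rejections += int((n_tot * corr2 > crit).sum())

    rate = rejections / reps
    se = float(np.sqrt(rate * (1 - rate) / reps))
    return rate, se
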