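"""Per-variant imputation accuracy metrics and array coverage summaries.

Every variant is scored within an ancestry group by three metrics: imputation
r2 (squared Pearson correlation between observed 0/1/2 dosage and imputed
expected dosage), genotype concordance (agreement of observed and most likely
imputed genotype) and minor-allele (MA) concordance (the same agreement,
restricted to samples where either genotype carries at least one copy of the
group's minor allele).  Typed (array) variants score 1 on all three; variants
with fewer than two minor-allele copies in the group are excluded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import ArrayDefinition, HaplotypePanel

__all__ = [
    "group_allele_stats",
    "imputation_r2",
    "best_guess_genotype",
    "genotype_concordance",
    "ma_concordance",
    "compute_variant_metrics",
    "coverage_summary",
    "array_overlap_summary",
    "DEFAULT_MAF_BINS",
    "DEFAULT_R2_THRESHOLD",
    "MIN_MINOR_ALLELE_COPIES",
]

#: MAF bin queries used in the standard summaries: (lo, hi], possibly overlapping.
DEFAULT_MAF_BINS = ((0.0, 0.01), (0.01, 0.05), (0.01, 0.5), (0.05, 0.5))
DEFAULT_R2_THRESHOLD = 0.8
MIN_MINOR_ALLELE_COPIES = 2


def group_allele_stats(panel: HaplotypePanel, group: str) -> pd.DataFrame:
    """Allele frequencies resolved within one ancestry group.

    Returns one row per panel variant with columns chrom, pos, variant_id,
    alt_freq, minor_is_alt, maf, mac, n_samples.  The minor allele is alt when
    the alt frequency is <= 0.5 (ties go to alt); mac counts minor-allele
    copies over the group's 2n chromosomes.
    """
    ids = panel.group_sample_ids(group)
    idx = panel.sample_index(ids)
    haps = panel.haplotypes[panel.haplotype_rows(idx)]
    two_n = haps.shape[0]
    alt_count = haps.sum(axis=0).astype(np.int64)
    alt_freq = alt_count / two_n
    minor_is_alt = alt_freq <= 0.5
    mac = np.where(minor_is_alt, alt_count, two_n - alt_count)
    out = panel.variants[["chrom", "pos", "variant_id"]].copy()
    out["alt_freq"] = alt_freq
    out["minor_is_alt"] = minor_is_alt
    out["maf"] = np.minimum(alt_freq, 1.0 - alt_freq)
    out["mac"] = mac
    out["n_samples"] = len(ids)
    return out


def imputation_r2(observed, imputed) -> float:
    """Squared Pearson correlation between observed and imputed allelic dosage.

    Orientation-invariant (relabelling ref/alt maps x -> 2-x on both vectors).
    Returns 0 when either vector is constant: such a variant carries no
    imputed-dosage information.
    """
    observed = np.asarray(observed, dtype=np.float64)
    imputed = np.asarray(imputed, dtype=np.float64)
    if observed.shape != imputed.shape:
        raise ValueError("observed and imputed dosage vectors must have equal length")
    vo = observed.var()
    vi = imputed.var()
    if vo == 0.0 or vi == 0.0:
        return 0.0
    cov = ((observed - observed.mean()) * (imputed - imputed.mean())).mean()
    return float(cov * cov / (vo * vi))


def best_guess_genotype(p0, p1, p2):
    """Most likely genotype from posterior probabilities; ties break toward
    the smaller alt-dosage genotype.  Accepts scalars or arrays."""
    probs = np.stack(
        [np.asarray(p0, dtype=np.float64), np.asarray(p1, dtype=np.float64), np.asarray(p2, dtype=np.float64)],
        axis=-1,
    )
    if np.any(probs < 0):
        raise ValueError("genotype probabilities must be non-negative")
    bg = np.argmax(probs, axis=-1)  # first max wins: the documented tie rule
    return int(bg) if bg.ndim == 0 else bg


def genotype_concordance(observed, best_guess) -> float:
    """Fraction of samples whose observed and best-guess genotypes agree."""
    observed = np.asarray(observed)
    best_guess = np.asarray(best_guess)
    if observed.shape != best_guess.shape:
        raise ValueError("genotype vectors must have equal length")
    return float(np.mean(observed == best_guess))


def ma_concordance(observed, best_guess, minor_is_alt: bool) -> float:
    """Genotype concordance over samples where either genotype carries the minor allele.

    If no sample qualifies (possible only in degenerate inputs; never when the
    observed genotypes pass the mac >= 2 filter) the convention is 1.
    """
    observed = np.asarray(observed)
    best_guess = np.asarray(best_guess)
    if observed.shape != best_guess.shape:
        raise ValueError("genotype vectors must have equal length")
    if minor_is_alt:
        keep = (observed > 0) | (best_guess > 0)
    else:
        keep = (observed < 2) | (best_guess < 2)
    if not keep.any():
        return 1.0
    return float(np.mean(observed[keep] == best_guess[keep]))


def _columnwise_r2(obs: np.ndarray, dos: np.ndarray) -> np.ndarray:
    """Vectorized per-column squared Pearson correlation; 0 where degenerate."""
    oc = obs - obs.mean(axis=0)
    dc = dos - dos.mean(axis=0)
    vo = np.einsum("ij,ij->j", oc, oc)
    vd = np.einsum("ij,ij->j", dc, dc)
    cov = np.einsum("ij,ij->j", oc, dc)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where((vo > 0) & (vd > 0), cov**2 / (vo * vd), 0.0)
    return r2


def compute_variant_metrics(
    panel: HaplotypePanel,
    imputed,
    group: str,
    array: ArrayDefinition,
) -> pd.DataFrame:
    """Score every mac>=2 variant of one ancestry group against imputed results.

    ``imputed`` is an ImputedDosages covering all panel variants for at least
    the group's samples.  Typed variants (array positions present in the
    panel) score 1 on all three metrics; the rest are scored from the group's
    samples only.  Returns columns chrom, pos, variant_id, group, typed, maf,
    mac, n_samples, r2, geno_conc, ma_conc, ma_conc_defined.
    """
    stats = group_allele_stats(panel, group)
    ids = panel.group_sample_ids(group)
    panel_idx = panel.sample_index(ids)
    obs = panel.genotypes()[panel_idx].astype(np.float64)  # (n_g, L)

    imp_lookup = {s: i for i, s in enumerate(imputed.sample_ids)}
    missing = [s for s in ids if s not in imp_lookup]
    if missing:
        raise ValueError(f"imputed dosages missing for group samples: {missing[:5]}")
    imp_idx = np.array([imp_lookup[s] for s in ids])
    probs = imputed.probs[imp_idx]  # (n_g, L, 3)
    dos = probs[:, :, 1] + 2.0 * probs[:, :, 2]
    typed = imputed.typed.astype(bool)

    keep = stats["mac"].to_numpy() >= MIN_MINOR_ALLELE_COPIES
    bg = np.argmax(probs, axis=2).astype(np.float64)

    r2 = _columnwise_r2(obs, dos)
    gc = (obs == bg).mean(axis=0)
    minor_is_alt = stats["minor_is_alt"].to_numpy()
    obs_carrier = np.where(minor_is_alt[None, :], obs > 0, obs < 2)
    bg_carrier = np.where(minor_is_alt[None, :], bg > 0, bg < 2)
    pair_keep = obs_carrier | bg_carrier
    den = pair_keep.sum(axis=0)
    num = (pair_keep & (obs == bg)).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mac_conc = np.where(den > 0, num / np.maximum(den, 1), 1.0)
    ma_defined = den > 0

    out = stats[["chrom", "pos", "variant_id", "maf", "mac", "n_samples"]].copy()
    out["group"] = group
    out["typed"] = typed
    out["r2"] = np.where(typed, 1.0, r2)
    out["geno_conc"] = np.where(typed, 1.0, gc)
    out["ma_conc"] = np.where(typed, 1.0, mac_conc)
    out["ma_conc_defined"] = np.where(typed, True, ma_defined)
    out = out.loc[keep].reset_index(drop=True)
    return out[
        [
            "chrom",
            "pos",
            "variant_id",
            "group",
            "typed",
            "maf",
            "mac",
            "n_samples",
            "r2",
            "geno_conc",
            "ma_conc",
            "ma_conc_defined",
        ]
    ]


def coverage_summary(
    metrics: pd.DataFrame,
    maf_bins=DEFAULT_MAF_BINS,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> pd.DataFrame:
    """Per-MAF-bin coverage summary in the style of the standard array tables.

    ``maf_bins`` are (lo, hi] interval queries and may overlap (e.g. both
    MAF > 0.01 and MAF > 0.05).  Rows flagged ma_conc_defined == False are
    excluded from the MA-concordance mean only.
    """
    if len(metrics) == 0:
        raise ValueError("metrics table is empty")
    for lo, hi in maf_bins:
        if not (0 <= lo < hi <= 0.5):
            raise ValueError(f"malformed MAF bin ({lo}, {hi}]")
    rows = []
    maf = metrics["maf"].to_numpy()
    for lo, hi in maf_bins:
        sel = metrics[(maf > lo) & (maf <= hi)]
        n = len(sel)
        if n == 0:
            rows.append((lo, hi, 0, np.nan, np.nan, np.nan, np.nan))
            continue
        ma_rows = sel[sel["ma_conc_defined"]] if "ma_conc_defined" in sel else sel
        rows.append(
            (
                lo,
                hi,
                n,
                float((sel["r2"] >= r2_threshold).mean()),
                float(sel["r2"].mean()),
                float(ma_rows["ma_conc"].mean()) if len(ma_rows) else np.nan,
                float(sel["geno_conc"].mean()),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "maf_lo",
            "maf_hi",
            "n_variants",
            "frac_r2_ge_threshold",
            "mean_r2",
            "mean_ma_conc",
            "mean_geno_conc",
        ],
    )


def array_overlap_summary(
    panel: HaplotypePanel, array: ArrayDefinition, groups=None
) -> dict:
    """Array-versus-panel overlap report.

    Percentages use the array's unique position count as denominator: overlap
    at any frequency, and overlap restricted to positions with at least two
    minor-allele copies in at least one ancestry group (the "MAF filtered"
    column of the standard array summary).
    """
    if groups is None:
        groups = panel.ancestry_groups
    panel_positions = panel.positions()
    n_array = len(array.positions)
    in_panel = array.positions & panel_positions
    mask = array.typed_mask(panel)
    passes = np.zeros(panel.n_variants, dtype=bool)
    for g in groups:
        passes |= group_allele_stats(panel, g)["mac"].to_numpy() >= MIN_MINOR_ALLELE_COPIES
    n_filtered = int((mask & passes).sum())
    return {
        "array": array.name,
        "n_positions": n_array,
        "n_in_panel": len(in_panel),
        "pct_in_panel": 100.0 * len(in_panel) / n_array if n_array else np.nan,
        "n_in_panel_maf_filtered": n_filtered,
        "pct_in_panel_maf_filtered": 100.0 * n_filtered / n_array if n_array else np.nan,
    }
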