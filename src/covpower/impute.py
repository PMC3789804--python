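"""Haploid Li-Stephens imputation of untyped variants from a typed scaffold.

Each target haplotype is modelled as a mosaic of the reference haplotypes: a
hidden Markov chain over "copied haplotype" states runs along the variant
index, switching to a uniformly chosen reference haplotype with probability
``switch_rate`` per inter-site interval, and emitting the copied allele with
per-site miscopy probability ``miscopy_rate`` at typed sites.  Untyped sites
have no emission; their alt-allele posterior is the state posterior folded
through the miscopy emission model.

Because the transition kernel is "stay or jump to uniform", its g-step
composition is closed form — stay weight (1-switch_rate)^g plus a uniform
remainder — so forward-backward runs over typed sites only and untyped sites
are filled in exactly by interval interpolation.  The recursion is in linear
space with per-site renormalization (posteriors are scale-free), and is
vectorized across all target haplotypes of a batch.

Diploid posteriors combine the two haploid alt posteriors under independence
given known phase: P2 = a1*a2, P1 = a1(1-a2) + (1-a1)a2, P0 = (1-a1)(1-a2).
Typed sites are then overwritten with the observed genotype at probability 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .simulate import ArrayDefinition, HaplotypePanel

__all__ = [
    "HmmParams",
    "ImputedDosages",
    "ZeroTypedSitesWarning",
    "ls_posteriors",
    "impute_sample",
    "impute_batch",
]


class ZeroTypedSitesWarning(UserWarning):
    """No typed sites overlap the panel: posteriors fall back to the state prior."""


@dataclass(frozen=True)
class HmmParams:
    """Li-Stephens chain parameters.

    switch_rate: probability of changing the copied haplotype per inter-site
    interval (uniform genetic map).  miscopy_rate: probability the emitted
    allele differs from the copied haplotype's allele.  effective_states: if
    set, the reference is thinned to at most this many haplotypes (evenly
    spaced, deterministic).
    """

    switch_rate: float = 0.01
    miscopy_rate: float = 0.002
    effective_states: int | None = None

    def __post_init__(self):
        if not (0.0 < self.switch_rate < 1.0):
            raise ValueError("switch_rate must be in (0,1)")
        if not (0.0 < self.miscopy_rate < 0.5):
            raise ValueError("miscopy_rate must be in (0,0.5)")
        if self.effective_states is not None and self.effective_states < 1:
            raise ValueError("effective_states must be >= 1")


@dataclass
class ImputedDosages:
    """Posterior genotype probabilities and dosages for a set of samples.

    probs has shape (n_samples, n_variants, 3) = (P0, P1, P2); typed flags
    which variants were on the array scaffold.  Dosage is the expected alt
    count 2*P2 + P1.
    """

    sample_ids: list
    variants: object  # the panel's variant table (shared, not copied)
    probs: np.ndarray
    typed: np.ndarray

    @property
    def dosage(self) -> np.ndarray:
        return self.probs[:, :, 1] + 2.0 * self.probs[:, :, 2]

    def validate(self) -> None:
        s = self.probs.sum(axis=2)
        if not np.allclose(s, 1.0, atol=1e-9):
            raise ValueError("posterior probabilities must sum to 1 per site")
        if np.any(self.probs < -1e-12):
            raise ValueError("negative posterior probability")

    @classmethod
    def concatenate(cls, parts: list["ImputedDosages"]) -> "ImputedDosages":
        if not parts:
            raise ValueError("nothing to concatenate")
        typed = parts[0].typed
        for p in parts[1:]:
            if not np.array_equal(p.typed, typed):
                raise ValueError("typed flags differ between batches")
        return cls(
            sample_ids=[s for p in parts for s in p.sample_ids],
            variants=parts[0].variants,
            probs=np.concatenate([p.probs for p in parts], axis=0),
            typed=typed,
        )

    def reorder(self, sample_ids: list) -> "ImputedDosages":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([lookup[s] for s in sample_ids])
        return ImputedDosages(
            sample_ids=list(sample_ids),
            variants=self.variants,
            probs=self.probs[idx],
            typed=self.typed,
        )


def _thin_reference(ref: np.ndarray, cap: int | None) -> np.ndarray:
    if cap is None or ref.shape[0] <= cap:
        return ref
    idx = np.unique(np.linspace(0, ref.shape[0] - 1, cap).round().astype(int))
    return ref[idx]


def _haploid_alt_posteriors(
    targets: np.ndarray,
    ref: np.ndarray,
    typed_idx: np.ndarray,
    params: HmmParams,
) -> np.ndarray:
    """Alt-allele posterior at every site for each target haplotype.

    targets: (n_t, m) alleles at the m typed sites; ref: (K, L) reference
    haplotypes over all L sites; typed_idx: sorted indices of the typed sites
    within 0..L-1.  Returns (n_t, L).
    """
    ref = np.asarray(ref, dtype=np.float64)
    if ref.ndim != 2 or ref.shape[0] == 0:
        raise ValueError("reference haplotype set must be a non-empty 2-D matrix")
    ref = _thin_reference(ref, params.effective_states)
    K, L = ref.shape
    typed_idx = np.asarray(typed_idx, dtype=np.int64)
    m = len(typed_idx)
    targets = np.atleast_2d(np.asarray(targets, dtype=np.float64))
    n_t = targets.shape[0]
    if targets.shape[1] != m:
        raise ValueError("target alleles must match the number of typed sites")
    mu = params.miscopy_rate
    rho = params.switch_rate

    if m == 0:
        warnings.warn(
            "no typed sites: returning state-prior posteriors", ZeroTypedSitesWarning
        )
        prior_alt = mu + (1 - 2 * mu) * ref.mean(axis=0)
        return np.broadcast_to(prior_alt, (n_t, L)).copy()
    if np.any(np.diff(typed_idx) <= 0) or typed_idx[0] < 0 or typed_idx[-1] >= L:
        raise ValueError("typed site indices must be sorted, unique and within range")

    # emission matrices at typed sites: (m, n_t, K)
    ref_t = ref[:, typed_idx]  # (K, m)
    stay = (1.0 - rho) ** np.diff(typed_idx)  # (m-1,) composed stay weights

    def emission(j: int) -> np.ndarray:
        eq = targets[:, j][:, None] == ref_t[:, j][None, :]
        return np.where(eq, 1.0 - mu, mu)

    # backward: V[j] = normalize(E_j * B_j), B_{m-1} = const
    V = np.empty((m, n_t, K))
    v = emission(m - 1)
    V[m - 1] = v / v.sum(axis=1, keepdims=True)
    for j in range(m - 2, -1, -1):
        s = stay[j]
        b = s * V[j + 1] + (1.0 - s) / K  # A_g applied to normalized V
        v = emission(j) * b
        V[j] = v / v.sum(axis=1, keepdims=True)

    out = np.empty((n_t, L))

    def fill_interval(h_cols: np.ndarray, s1, c1, s2, c2, F, Vn, FV, FVsum, Fh, Vh, hsum):
        """p_alt for a block of untyped columns between two typed anchors.

        gamma_u ∝ (s1*F + c1) ⊙ (s2*V + c2); all dot products with the allele
        columns h are expanded so the per-site work is three GEMMs.
        """
        num = (
            (s1 * s2)[None, :] * (FV @ h_cols if FV is not None else 0.0)
            + (s1 * c2)[None, :] * (Fh if Fh is not None else 0.0)
            + (c1 * s2)[None, :] * (Vh if Vh is not None else 0.0)
            + (c1 * c2)[None, :] * hsum[None, :]
        )
        den = (s1 * s2)[None, :] * FVsum[:, None] + (s1 * c2 + c1 * s2 + K * c1 * c2)[None, :]
        return mu + (1.0 - 2.0 * mu) * num / den

    # forward pass, streaming untyped-interval posteriors
    f = emission(0) / K
    F = f / f.sum(axis=1, keepdims=True)

    # untyped sites before the first typed site: gamma = s2*V0 + c2 (unit mass)
    u = np.arange(0, typed_idx[0])
    if len(u) > 0:
        h = ref[:, u]  # (K, n_u)
        s2 = (1.0 - rho) ** (typed_idx[0] - u)
        c2 = (1.0 - s2) / K
        num = s2[None, :] * (V[0] @ h) + c2[None, :] * h.sum(axis=0)[None, :]
        out[:, u] = mu + (1.0 - 2.0 * mu) * num

    ht = ref[:, typed_idx]  # (K, m)
    for j in range(m):
        # posterior at typed site j: F_j ⊙ B_j with B from the stored V
        if j < m - 1:
            b = stay[j] * V[j + 1] + (1.0 - stay[j]) / K
        else:
            b = np.full((n_t, K), 1.0 / K)
        g = F * b
        g /= g.sum(axis=1, keepdims=True)
        out[:, typed_idx[j]] = mu + (1.0 - 2.0 * mu) * (g @ ht[:, j])

        if j < m - 1:
            lo, hi = typed_idx[j], typed_idx[j + 1]
            u = np.arange(lo + 1, hi)
            if len(u) > 0:
                h = ref[:, u]
                s1 = (1.0 - rho) ** (u - lo)
                c1 = (1.0 - s1) / K
                s2 = (1.0 - rho) ** (hi - u)
                c2 = (1.0 - s2) / K
                FVn = F * V[j + 1]
                out[:, u] = fill_interval(
                    h,
                    s1,
                    c1,
                    s2,
                    c2,
                    F,
                    V[j + 1],
                    FVn,
                    FVn.sum(axis=1),
                    F @ h,
                    V[j + 1] @ h,
                    h.sum(axis=0),
                )
            # advance forward to typed site j+1
            s = stay[j]
            f = (s * F + (1.0 - s) / K) * emission(j + 1)
            F = f / f.sum(axis=1, keepdims=True)

    # untyped sites after the last typed site: gamma = s1*F_last + c1
    u = np.arange(typed_idx[-1] + 1, L)
    if len(u) > 0:
        h = ref[:, u]
        s1 = (1.0 - rho) ** (u - typed_idx[-1])
        c1 = (1.0 - s1) / K
        num = s1[None, :] * (F @ h) + c1[None, :] * h.sum(axis=0)[None, :]
        out[:, u] = mu + (1.0 - 2.0 * mu) * num

    return out


def ls_posteriors(
    target_haplotype_at_typed_sites,
    reference_haplotypes,
    typed_site_index,
    params: HmmParams,
) -> np.ndarray:
    """Per-site alt-allele posterior for one target haplotype.

    The reference covers all sites; the target is observed at the typed subset
    only.  Returns a length-L vector of P(alt emitted at site) given the typed
    observations, normalized exactly.
    """
    out = _haploid_alt_posteriors(
        np.asarray(target_haplotype_at_typed_sites, dtype=np.float64)[None, :],
        reference_haplotypes,
        typed_site_index,
        params,
    )
    return out[0]


def _combine_diploid(a1: np.ndarray, a2: np.ndarray) -> np.ndarray:
    """(…, 3) genotype posteriors from two haploid alt posteriors."""
    p2 = a1 * a2
    p0 = (1 - a1) * (1 - a2)
    p1 = 1.0 - p0 - p2
    return np.stack([p0, p1, p2], axis=-1)


def impute_sample(
    sample_typed_haplotypes: np.ndarray,
    reference_haplotypes: np.ndarray,
    typed_site_index,
    params: HmmParams,
    observed_typed_genotypes: np.ndarray | None = None,
    sample_id=None,
    reference_sample_ids=None,
) -> np.ndarray:
    """Genotype posteriors (L, 3) for one phased sample.

    ``sample_typed_haplotypes`` is (2, m): the two phased haplotypes at the
    typed sites.  If ``sample_id`` and ``reference_sample_ids`` are given, the
    sample must not appear in the reference (leakage guard).  Typed sites are
    re-assigned probability 1 on the observed genotype.
    """
    if sample_id is not None and reference_sample_ids is not None:
        if sample_id in set(reference_sample_ids):
            raise ValueError(f"sample {sample_id!r} is present in the reference panel")
    typed_idx = np.asarray(typed_site_index, dtype=np.int64)
    haps = np.asarray(sample_typed_haplotypes, dtype=np.float64)
    if haps.shape[0] != 2:
        raise ValueError("expected exactly 2 phased haplotypes")
    alt = _haploid_alt_posteriors(haps, reference_haplotypes, typed_idx, params)
    probs = _combine_diploid(alt[0], alt[1])
    if observed_typed_genotypes is None:
        observed_typed_genotypes = haps.sum(axis=0)
    g = np.asarray(observed_typed_genotypes).astype(np.int64)
    probs[typed_idx] = 0.0
    probs[typed_idx, g] = 1.0
    return probs


def impute_batch(
    panel: HaplotypePanel,
    array: ArrayDefinition,
    batch_samples,
    params: HmmParams,
    chunk_floats: float = 4e7,
) -> ImputedDosages:
    """Impute one batch of samples against the rest of the panel.

    The reference is every panel sample outside the batch; the typed scaffold
    is the intersection of the array with the panel positions.  Every batch
    sample is imputed at every panel variant, with typed sites carrying the
    observed genotype.  ``chunk_floats`` bounds the forward-backward working
    set (number of stored doubles) and only affects speed/memory.
    """
    batch_samples = list(batch_samples)
    batch_set = set(batch_samples)
    if not batch_set:
        raise ValueError("batch is empty")
    all_ids = list(panel.samples["sample_id"])
    ref_ids = [s for s in all_ids if s not in batch_set]
    if not ref_ids:
        raise ValueError("batch contains every panel sample: reference would be empty")
    unknown = batch_set - set(all_ids)
    if unknown:
        raise KeyError(f"batch samples not in panel: {sorted(unknown)[:5]}")

    typed_mask = array.typed_mask(panel)
    typed_idx = np.flatnonzero(typed_mask)
    if len(typed_idx) == 0:
        raise ValueError(
            f"array {array.name!r} shares no positions with the panel; cannot impute"
        )

    ref_rows = panel.haplotype_rows(panel.sample_index(ref_ids))
    ref = panel.haplotypes[ref_rows].astype(np.float64)
    K = ref.shape[0] if params.effective_states is None else min(
        ref.shape[0], params.effective_states
    )

    batch_idx = panel.sample_index(batch_samples)
    tgt_rows = panel.haplotype_rows(batch_idx)
    targets = panel.haplotypes[tgt_rows][:, typed_idx].astype(np.float64)
    n_hap = targets.shape[0]
    L = panel.n_variants

    # chunk so the stored backward quantities stay within chunk_floats doubles
    per_hap = max(1, len(typed_idx)) * K
    chunk = int(max(2, min(n_hap, chunk_floats // max(per_hap, 1))))
    if chunk % 2 == 1:
        chunk -= 1  # keep haplotype pairs together
    chunk = max(chunk, 2)

    alt = np.empty((n_hap, L))
    for start in range(0, n_hap, chunk):
        alt[start : start + chunk] = _haploid_alt_posteriors(
            targets[start : start + chunk], ref, typed_idx, params
        )

    probs = _combine_diploid(alt[0::2], alt[1::2])  # (n_batch, L, 3)
    obs = panel.genotypes()[batch_idx]  # (n_batch, L)
    g = obs[:, typed_idx]
    probs[:, typed_idx, :] = 0.0
    n_b = probs.shape[0]
    ii = np.repeat(np.arange(n_b), len(typed_idx))
    jj = np.tile(typed_idx, n_b)
    probs[ii, jj, g.ravel()] = 1.0

    out = ImputedDosages(
        sample_ids=batch_samples,
        variants=panel.variants,
        probs=probs,
        typed=typed_mask,
    )
    out.validate()
    return out
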