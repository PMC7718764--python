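"""Marker-based pairwise relatedness estimators for autopolyploids.

Three dosage (biallelic) estimators:

* **VR** — extension of the VanRaden genomic relationship matrix to
  dosages 0..2v: ``A = Z Z' / sum_l s_l^2`` with ``Z`` the column-centered
  dosage matrix and ``s_l^2`` the observed dosage variance of locus ``l``.
* **PD** — "pseudo-diploid": all heterozygous dosages are collapsed to
  code 1 (homozygotes keep 0/2) before a diploid-style correlation
  ``(1/L) sum_l (m_x - 2p)(m_y - 2p) / (2p(1-p))``.
* **FA** — "full-autopolyploid" (general model): each locus expands into
  2v+1 genotype-class indicators scored against the class frequency,
  confounding additive and non-additive effects.

Three multiallelic similarity-index estimators (LO, RI, WE) work on the
within-genotype allele frequencies ``S_ijx`` (the fraction of individual
x's 2v alleles at locus j that are allele i) against sample allele
frequencies ``p_ij``.  RI self-normalizes, so self-relatedness is exactly
1 by construction.

All estimators use plain sample allele frequencies including the focal
pair.  Zero-variance (monomorphic) loci are dropped and counted in the
result's ``meta``; with missing data, each pair is evaluated on its
pairwise-complete loci.
"""

from __future__ import annotations

import numpy as np

from .containers import DosageMatrix, MultiallelicGenotypes, RelationshipMatrix
from .markers import locus_similarity

__all__ = [
    "est_vr",
    "est_pd",
    "est_fa",
    "est_lo",
    "est_ri",
    "est_we",
    "estimate",
    "BIALLELIC_METHODS",
    "MULTIALLELIC_METHODS",
]

BIALLELIC_METHODS = ("vr", "pd", "fa")
MULTIALLELIC_METHODS = ("lo", "ri", "we")


def _matrix(ids, values, method, n_used, n_dropped, extra=None):
    meta = {
        "method": method,
        "n_loci_used": int(n_used),
        "n_loci_dropped": int(n_dropped),
    }
    if extra:
        meta.update(extra)
    return RelationshipMatrix(ids=list(ids), values=values, meta=meta)


def _pairwise_ratio(num_terms: np.ndarray, den_terms: np.ndarray,
                    mask: np.ndarray) -> np.ndarray:
    """Pairwise-complete sum(num)/sum(den) over loci.

    ``num_terms`` is (n, n, L)-broadcastable via outer products handled by
    the caller as X with per-locus columns; here we take per-locus factor
    matrices: num_terms (n, L), den_terms (L,), mask (n, L) observedness.
    Returns (n, n) ratio using only loci observed in both row individuals.
    """
    n, L = num_terms.shape
    out = np.empty((n, n))
    for i in range(n):
        both = mask[i] & mask
        num = (num_terms[i] * num_terms) * both
        out[i] = num.sum(axis=1) / np.where(
            (den_terms * both).sum(axis=1) > 0,
            (den_terms * both).sum(axis=1),
            np.nan,
        )
    return out


def est_vr(d: DosageMatrix) -> RelationshipMatrix:
    """VanRaden-type genomic relationship matrix on 0..2v dosages.

    ``A = Z Z' / sum_l s_l^2`` with columns of ``Z`` centered by the
    sample mean dosage and ``s_l^2`` the observed (denominator n) dosage
    variance.  Off-diagonal entries are the pairwise estimates; centering
    makes an individual whose dosages sit at the sample mean unrelated to
    everyone.
    """
    keep = d.polymorphic_mask()
    if keep.sum() == 0:
        raise ValueError("VR: all loci have zero dosage variance")
    M = d.values[:, keep]
    obs = np.isfinite(M)
    if obs.all():
        Z = M - M.mean(axis=0)
        s2 = M.var(axis=0)
        values = (Z @ Z.T) / s2.sum()
    else:
        mean = np.nanmean(M, axis=0)
        s2 = np.nanvar(M, axis=0)
        Z = np.where(obs, M - mean, 0.0)
        values = _pairwise_ratio(Z, s2, obs)
    return _matrix(d.ids, values, "vr", keep.sum(), (~keep).sum())


def est_pd(d: DosageMatrix) -> RelationshipMatrix:
    """Pseudo-diploid estimator: heterozygous dosages collapse to one class.

    Dosages are recoded 0 / 1 / 2 (0 and 2v keep the homozygous codes,
    every intermediate dosage becomes 1); the reference frequency is taken
    from the recoded matrix, ``p_l = mean(m) / 2``, and loci with
    ``p_l`` of 0 or 1 are dropped.
    """
    m = d.values
    rec = np.where(m == 0, 0.0, np.where(m == d.ploidy, 2.0, 1.0))
    rec[~np.isfinite(m)] = np.nan
    obs = np.isfinite(rec)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(rec, axis=0) / 2.0
    keep = np.nan_to_num(p * (1.0 - p)) > 0
    if keep.sum() == 0:
        raise ValueError("PD: no polymorphic loci after recoding")
    rec, p, obs = rec[:, keep], p[keep], obs[:, keep]
    U = (rec - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    if obs.all():
        values = (U @ U.T) / keep.sum()
    else:
        U = np.where(obs, U, 0.0)
        values = _pairwise_ratio(U, np.ones(keep.sum()), obs)
    return _matrix(d.ids, values, "pd", keep.sum(), (~keep).sum())


def est_fa(d: DosageMatrix) -> RelationshipMatrix:
    """Full-autopolyploid ("general") estimator on genotype-class
    indicators.

    Each locus expands into 2v+1 indicator columns; a column's ``p'`` is
    the fraction of individuals in that genotype class.  Classes nobody or
    everybody occupies are dropped from the numerator, but the denominator
    stays ``(2v+1) L`` — the source of this estimator's compression toward
    zero.
    """
    n, L = d.values.shape
    classes = d.ploidy + 1
    m = d.values
    obs = np.isfinite(m)
    # (n, L, classes) one-hot
    X = (m[:, :, None] == np.arange(classes)[None, None, :]).astype(float)
    X[~obs] = np.nan
    with np.errstate(invalid="ignore"):
        p = np.nanmean(X, axis=0)  # (L, classes)
    w = p * (1.0 - p)
    retained = np.nan_to_num(w) > 0
    Xc = X - p[None, :, :]
    weight = np.where(retained, 1.0 / np.where(retained, w, 1.0), 0.0)
    Xc = np.nan_to_num(Xc) * obs[:, :, None]
    flat = Xc.reshape(n, -1)
    wflat = weight.reshape(-1)
    if obs.all():
        values = (flat * wflat) @ flat.T / (classes * L)
    else:
        obs_flat = np.repeat(obs, classes, axis=1)
        values = np.empty((n, n))
        for i in range(n):
            both = obs_flat[i] & obs_flat
            num = ((flat[i] * wflat) * flat) * both
            values[i] = num.sum(axis=1) / (
                classes * np.maximum((obs[i][None, :] & obs).sum(axis=1), 1)
            )
    return _matrix(
        d.ids, values, "fa", L, 0,
        extra={"n_classes_dropped": int((~retained).sum())},
    )


def _similarity_stack(g: MultiallelicGenotypes):
    """Stack similarity coefficients over polymorphic loci.

    Returns ``(S, p, locus_of_col, k, n_used, n_dropped, obs)`` where
    ``S`` is (n, total_alleles) within-genotype allele frequencies, ``p``
    the matching sample frequencies, ``k`` the allele count per retained
    locus, and ``obs`` the (n, n_used) per-locus observedness mask.
    """
    S_cols, p_cols, col_locus, ks = [], [], [], []
    missing = g.missing_mask()
    used = []
    for l in range(g.n_loci):
        codes, S, p = locus_similarity(g, l)
        if codes.size < 2:
            continue
        used.append(l)
        S_cols.append(S)
        p_cols.append(p)
        col_locus.extend([len(used) - 1] * codes.size)
        ks.append(codes.size)
    if not used:
        raise ValueError("no polymorphic loci")
    S = np.concatenate(S_cols, axis=1)
    p = np.concatenate(p_cols)
    obs = ~missing[:, used]
    return (
        S,
        p,
        np.asarray(col_locus),
        np.asarray(ks),
        len(used),
        g.n_loci - len(used),
        obs,
    )


def est_lo(g: MultiallelicGenotypes) -> RelationshipMatrix:
    """Similarity-index estimator weighting alleles by p(1-p):

    ``r = 2v * sum_j sum_i (S_ijx - p_ij)(S_ijy - p_ij)
    / sum_j sum_i p_ij (1 - p_ij)``.
    """
    S, p, col_locus, ks, n_used, n_dropped, obs = _similarity_stack(g)
    two_v = g.ploidy
    Xc = S - p[None, :]
    if obs.all():
        values = two_v * (Xc @ Xc.T) / (p * (1.0 - p)).sum()
    else:
        Xc = Xc * obs[:, col_locus]
        den_per_locus = np.bincount(
            col_locus, weights=p * (1.0 - p), minlength=n_used
        )
        num = np.empty((len(g.ids),) * 2)
        for i in range(len(g.ids)):
            both = obs[i] & obs
            numij = ((Xc[i] * Xc) * both[:, col_locus]).sum(axis=1)
            denij = (den_per_locus * both).sum(axis=1)
            num[i] = np.where(denij > 0, numij / denij, np.nan)
        values = two_v * num
    return _matrix(g.ids, values, "lo", n_used, n_dropped)


def est_ri(g: MultiallelicGenotypes) -> RelationshipMatrix:
    """Ritland-type similarity estimator with self-normalization.

    Kinship ``theta_XY = 2v * sum_j (sum_i S_ijx S_ijy / p_ij - 1)
    / sum_j (k_j - 1)`` is turned into relatedness by
    ``r = theta_XY (1/theta_XX + 1/theta_YY) / 2``; the leading constant
    cancels, and self-relatedness is exactly 1.  Pairs involving an
    individual with non-positive self-kinship are undefined (NaN).
    """
    S, p, col_locus, ks, n_used, n_dropped, obs = _similarity_stack(g)
    two_v = g.ploidy
    Y = S / np.sqrt(p[None, :])
    if obs.all():
        raw = Y @ Y.T - n_used
        theta = two_v * raw / (ks - 1).sum()
    else:
        Y = Y * obs[:, col_locus]
        theta = np.empty((len(g.ids),) * 2)
        for i in range(len(g.ids)):
            both = obs[i] & obs
            numij = ((Y[i] * Y) * both[:, col_locus]).sum(axis=1) - both.sum(
                axis=1
            )
            denij = ((ks - 1) * both).sum(axis=1)
            theta[i] = np.where(denij > 0, two_v * numij / denij, np.nan)
    self_theta = np.diag(theta).copy()
    bad = ~(self_theta > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.where(bad, np.nan, 1.0 / self_theta)
        values = 0.5 * theta * (inv[:, None] + inv[None, :])
    return _matrix(g.ids, values, "ri", n_used, n_dropped)


def est_we(g: MultiallelicGenotypes) -> RelationshipMatrix:
    """Weir-type similarity estimator:

    ``r = 2v * sum_j (sum_i S_ijx S_ijy - sum_i p_ij^2)
    / (L - sum_j sum_i p_ij^2)``.
    """
    S, p, col_locus, ks, n_used, n_dropped, obs = _similarity_stack(g)
    two_v = g.ploidy
    p2 = np.bincount(col_locus, weights=p * p, minlength=n_used)
    if obs.all():
        num = S @ S.T - p2.sum()
        den = n_used - p2.sum()
        if den <= 0:
            raise ValueError("WE: degenerate denominator (loci all fixed)")
        values = two_v * num / den
    else:
        Sm = S * obs[:, col_locus]
        values = np.empty((len(g.ids),) * 2)
        for i in range(len(g.ids)):
            both = obs[i] & obs
            numij = ((Sm[i] * Sm) * both[:, col_locus]).sum(axis=1) - (
                p2 * both
            ).sum(axis=1)
            denij = both.sum(axis=1) - (p2 * both).sum(axis=1)
            values[i] = np.where(denij > 0, two_v * numij / denij, np.nan)
    return _matrix(g.ids, values, "we", n_used, n_dropped)


_DOSAGE_ESTIMATORS = {"vr": est_vr, "pd": est_pd, "fa": est_fa}
_MULTI_ESTIMATORS = {"lo": est_lo, "ri": est_ri, "we": est_we}


def estimate(data, method: str) -> RelationshipMatrix:
    """Dispatch to an estimator by short name (vr, pd, fa, lo, ri, we)."""
    method = method.lower()
    if method in _DOSAGE_ESTIMATORS:
        if isinstance(data, MultiallelicGenotypes):
            from .markers import dosage_from_genotypes

            data = dosage_from_genotypes(data)
        if not isinstance(data, DosageMatrix):
            raise TypeError(f"{method} needs a DosageMatrix")
        return _DOSAGE_ESTIMATORS[method](data)
    if method in _MULTI_ESTIMATORS:
        if not isinstance(data, MultiallelicGenotypes):
            raise TypeError(f"{method} needs MultiallelicGenotypes")
        return _MULTI_ESTIMATORS[method](data)
    raise ValueError(f"unknown estimator {method!r}")
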