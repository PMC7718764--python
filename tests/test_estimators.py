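"""Marker-based estimators against per-definition reference
implementations and their algebraic properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from autokin.containers import DosageMatrix, MultiallelicGenotypes
from autokin.estimators import (
    est_fa,
    est_lo,
    est_pd,
    est_ri,
    est_vr,
    est_we,
    estimate,
)
from autokin.markers import (
    allele_frequencies,
    dosage_from_genotypes,
)

# ---------------------------------------------------------------------------
# naive per-definition reference implementations (the oracles)


def naive_vr(M, ploidy):
    keep = M.var(axis=0) > 0
    Mk = M[:, keep]
    Z = Mk - Mk.mean(axis=0)
    return Z @ Z.T / Mk.var(axis=0).sum()


def naive_pd(M, ploidy):
    rec = np.where(M == 0, 0.0, np.where(M == ploidy, 2.0, 1.0))
    p = rec.mean(axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    n = M.shape[0]
    out = np.zeros((n, n))
    for x in range(n):
        for y in range(n):
            out[x, y] = np.mean(
                [
                    (rec[x, l] - 2 * p[l])
                    * (rec[y, l] - 2 * p[l])
                    / (2 * p[l] * (1 - p[l]))
                    for l in np.flatnonzero(keep)
                ]
            )
    return out


def naive_fa(M, ploidy):
    n, L = M.shape
    classes = ploidy + 1
    out = np.zeros((n, n))
    for x in range(n):
        for y in range(n):
            s = 0.0
            for l in range(L):
                for c in range(classes):
                    p = np.mean(M[:, l] == c)
                    if p in (0.0, 1.0):
                        continue
                    s += (
                        ((M[x, l] == c) - p)
                        * ((M[y, l] == c) - p)
                        / (p * (1 - p))
                    )
            out[x, y] = s / (classes * L)
    return out


def _locus_sp(alleles, l, ploidy):
    a = alleles[:, :, l]
    codes = np.unique(a)
    S = np.stack([(a == c).sum(axis=1) / ploidy for c in codes], axis=1)
    p = np.array([(a == c).mean() for c in codes])
    return codes, S, p


def naive_multiallelic(alleles, ploidy):
    """Reference LO / RI-theta / WE computed by direct summation."""
    n, _, L = alleles.shape
    lo_num = np.zeros((n, n))
    lo_den = 0.0
    ri_num = np.zeros((n, n))
    ks = []
    we_num = np.zeros((n, n))
    sp2 = 0.0
    L_eff = 0
    for l in range(L):
        codes, S, p = _locus_sp(alleles, l, ploidy)
        if codes.size < 2:
            continue
        L_eff += 1
        ks.append(codes.size)
        lo_den += (p * (1 - p)).sum()
        sp2 += (p * p).sum()
        for x in range(n):
            for y in range(n):
                lo_num[x, y] += ((S[x] - p) * (S[y] - p)).sum()
                ri_num[x, y] += (S[x] * S[y] / p).sum() - 1
                we_num[x, y] += (S[x] * S[y]).sum() - (p * p).sum()
    lo = ploidy * lo_num / lo_den
    theta = ploidy * ri_num / (np.array(ks) - 1).sum()
    ri = 0.5 * theta * (
        1 / np.diag(theta)[:, None] + 1 / np.diag(theta)[None, :]
    )
    we = ploidy * we_num / (L_eff - sp2)
    return lo, ri, we


def random_dosage(rng, n=6, L=10, ploidy=4):
    M = rng.integers(0, ploidy + 1, size=(n, L)).astype(float)
    M[:, 0] = [0, ploidy] * (n // 2) + [0] * (n % 2)  # ensure polymorphism
    return DosageMatrix(
        ids=[f"i{k}" for k in range(n)],
        loci=[f"l{k}" for k in range(L)],
        ploidy=ploidy,
        values=M,
    )


def random_genotypes(rng, n=6, L=8, ploidy=4, k=4):
    al = rng.integers(1, k + 1, size=(n, ploidy, L)).astype(np.int64)
    al[0, 0, :] = 1
    al[1, 0, :] = 2  # ensure every locus is polymorphic
    return MultiallelicGenotypes(
        ids=[f"i{k_}" for k_ in range(n)],
        loci=[f"l{k_}" for k_ in range(L)],
        ploidy=ploidy,
        alleles=al,
    )


# ---------------------------------------------------------------------------


class TestAlleleFrequencies:
    def test_two_diploids_counting(self):
        g = MultiallelicGenotypes(
            ids=["x", "y"],
            loci=["l1"],
            ploidy=2,
            alleles=np.array([[[1], [1]], [[1], [2]]]),
        )
        freqs = allele_frequencies(g)
        np.testing.assert_allclose(freqs[0]["p"], [0.75, 0.25])

    def test_monomorphic_locus_flagged(self):
        g = MultiallelicGenotypes(
            ids=["x", "y"],
            loci=["l1"],
            ploidy=2,
            alleles=np.ones((2, 2, 1), dtype=int),
        )
        assert allele_frequencies(g)[0]["monomorphic"]

    def test_dosage_frequencies(self):
        d = DosageMatrix(
            ids=["x", "y"],
            loci=["l1", "l2"],
            ploidy=4,
            values=np.array([[4.0, 0.0], [2.0, 0.0]]),
        )
        freqs = allele_frequencies(d)
        assert freqs[0]["p"][1] == pytest.approx(0.75)
        assert freqs[1]["monomorphic"]


@pytest.mark.parametrize("ploidy", [2, 4, 6])
class TestDosageEstimators:
    def test_vr_matches_reference(self, ploidy):
        d = random_dosage(np.random.default_rng(ploidy), ploidy=ploidy)
        np.testing.assert_allclose(
            est_vr(d).values, naive_vr(d.values, ploidy)
        )

    def test_pd_matches_reference(self, ploidy):
        d = random_dosage(np.random.default_rng(ploidy + 10), ploidy=ploidy)
        np.testing.assert_allclose(
            est_pd(d).values, naive_pd(d.values, ploidy)
        )

    def test_fa_matches_reference(self, ploidy):
        d = random_dosage(np.random.default_rng(ploidy + 20), ploidy=ploidy)
        np.testing.assert_allclose(
            est_fa(d).values, naive_fa(d.values, ploidy)
        )


class TestDosageEstimatorProperties:
    def test_vr_mean_profile_individual_is_unrelated(self):
        # an individual sitting exactly at the column means has a zero
        # centered vector, so VR renders it unrelated to everyone
        M = np.array(
            [[0.0, 4.0, 2.0], [4.0, 0.0, 2.0], [2.0, 2.0, 2.0]]
        )
        d = DosageMatrix(
            ids=["a", "b", "m"], loci=["1", "2", "3"], ploidy=4, values=M
        )
        vals = est_vr(d).values
        np.testing.assert_allclose(vals[2], 0.0, atol=1e-12)

    def test_vr_all_monomorphic_rejected(self):
        d = DosageMatrix(
            ids=["a", "b"], loci=["1"], ploidy=4,
            values=np.array([[2.0], [2.0]]),
        )
        with pytest.raises(ValueError, match="variance"):
            est_vr(d)

    def test_pd_recoding_is_identity_for_diploids(self):
        rng = np.random.default_rng(0)
        d = random_dosage(rng, ploidy=2)
        # for 2v=2, the pseudo-diploid recoding changes nothing, so the
        # estimator is the plain diploid formula on raw dosages
        np.testing.assert_allclose(
            est_pd(d).values, naive_pd(d.values, 2)
        )

    def test_pd_homozygous_alternate_pair_closed_form(self):
        # both individuals all-homozygous-alternate, p = 0.5 at all loci:
        # each locus contributes (2 - 1)^2 / (2 * 0.25) = 2
        M = np.array([[4.0, 4.0], [4.0, 4.0], [0.0, 0.0], [0.0, 0.0]])
        d = DosageMatrix(
            ids=list("abcd"), loci=["1", "2"], ploidy=4, values=M
        )
        assert est_pd(d).get("a", "b") == pytest.approx(2.0)

    def test_fa_self_is_maximal(self):
        rng = np.random.default_rng(4)
        d = random_dosage(rng)
        vals = est_fa(d).values
        for i in range(d.n):
            assert vals[i, i] == pytest.approx(vals[i].max())


class TestMultiallelicEstimators:
    @pytest.mark.parametrize("ploidy,k", [(2, 3), (4, 4), (6, 10)])
    def test_match_reference(self, ploidy, k):
        g = random_genotypes(
            np.random.default_rng(ploidy * k), ploidy=ploidy, k=k
        )
        lo, ri, we = naive_multiallelic(g.alleles, ploidy)
        np.testing.assert_allclose(est_lo(g).values, lo)
        np.testing.assert_allclose(est_ri(g).values, ri)
        np.testing.assert_allclose(est_we(g).values, we)

    def test_ri_self_relatedness_exactly_one(self):
        for seed in range(5):
            g = random_genotypes(np.random.default_rng(seed))
            np.testing.assert_allclose(
                np.diag(est_ri(g).values), 1.0, atol=1e-12
            )

    def test_lo_zero_for_mean_profile(self):
        # if S equals p everywhere for one individual, every numerator
        # term involving it vanishes
        al = np.array(
            [
                [[1], [2], [1], [2]],
                [[1], [1], [1], [2]],
                [[1], [2], [2], [2]],
            ],
            dtype=np.int64,
        ).reshape(3, 4, 1)
        g = MultiallelicGenotypes(
            ids=["m", "x", "y"], loci=["l"], ploidy=4, alleles=al
        )
        # individual m has S = (0.5, 0.5) = p
        vals = est_lo(g).values
        np.testing.assert_allclose(vals[0, 1:], 0.0, atol=1e-12)

    def test_we_rare_allele_self_limit(self):
        # every individual carries its own 2v unique alleles, so all
        # frequencies are small: sum_i S^2 = 1/(2v) for a self pair and
        # r -> 1 as p -> 0; disjoint pairs sit just below 0.
        n, two_v, L = 40, 4, 5
        codes = (np.arange(n * two_v, dtype=np.int64) + 1).reshape(n, two_v)
        al = np.repeat(codes[:, :, None], L, axis=2)
        g = MultiallelicGenotypes(
            ids=[f"i{k}" for k in range(n)],
            loci=[f"l{k}" for k in range(L)],
            ploidy=two_v,
            alleles=al,
        )
        vals = est_we(g).values
        assert vals[0, 0] == pytest.approx(1.0, abs=0.05)
        assert -0.05 < vals[0, 1] <= 0.0


class TestDosageFromGenotypes:
    def test_counts_reference_allele(self):
        al = np.array([[[1], [1], [2], [2]]], dtype=np.int64)
        g = MultiallelicGenotypes(
            ids=["x"], loci=["l"], ploidy=4, alleles=al
        )
        d = dosage_from_genotypes(g)
        assert d.values[0, 0] == 2  # reference = lowest code (1)

    def test_complement_under_swapped_reference(self):
        g = random_genotypes(np.random.default_rng(2), k=2)
        d1 = dosage_from_genotypes(g, reference=1)
        d2 = dosage_from_genotypes(g, reference=2)
        np.testing.assert_allclose(d1.values + d2.values, g.ploidy)

    def test_more_than_two_codes_rejected(self):
        g = random_genotypes(np.random.default_rng(2), k=5)
        with pytest.raises(ValueError, match="2 allele"):
            dosage_from_genotypes(g)

    def test_estimate_dispatch(self):
        g = random_genotypes(np.random.default_rng(3), k=2)
        rm = estimate(g, "vr")  # auto-collapses to dosage
        assert rm.meta["method"] == "vr"
        with pytest.raises(ValueError, match="unknown"):
            estimate(g, "zz")


@st.composite
def dosage_matrices(draw):
    ploidy = draw(st.sampled_from([2, 4]))
    n = draw(st.integers(3, 6))
    L = draw(st.integers(2, 6))
    M = draw(
        hnp.arrays(
            np.int64,
            (n, L),
            elements=st.integers(0, ploidy),
        )
    )
    M = M.astype(float)
    M[0, :] = 0
    M[1, :] = ploidy  # guarantee polymorphism everywhere
    return DosageMatrix(
        ids=[f"i{k}" for k in range(n)],
        loci=[f"l{k}" for k in range(L)],
        ploidy=ploidy,
        values=M,
    )


class TestEstimatorInvariances:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(d=dosage_matrices(), method=st.sampled_from(["vr", "pd", "fa"]))
    def test_permutation_equivariance(self, d, method):
        """Reordering individuals permutes the estimate matrix."""
        rng = np.random.default_rng(0)
        perm = rng.permutation(d.n)
        base = estimate(d, method).values
        shuffled = DosageMatrix(
            ids=[d.ids[i] for i in perm],
            loci=d.loci,
            ploidy=d.ploidy,
            values=d.values[perm],
        )
        np.testing.assert_allclose(
            estimate(shuffled, method).values,
            base[np.ix_(perm, perm)],
            atol=1e-10,
        )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(d=dosage_matrices(), method=st.sampled_from(["vr", "pd", "fa"]))
    def test_locus_order_invariance(self, d, method):
        base = estimate(d, method).values
        rev = DosageMatrix(
            ids=d.ids,
            loci=d.loci[::-1],
            ploidy=d.ploidy,
            values=d.values[:, ::-1],
        )
        np.testing.assert_allclose(
            estimate(rev, method).values, base, atol=1e-10
        )

    def test_multiallelic_permutation_equivariance(self):
        g = random_genotypes(np.random.default_rng(8))
        perm = np.random.default_rng(1).permutation(g.n)
        for method in ("lo", "ri", "we"):
            base = estimate(g, method).values
            shuffled = MultiallelicGenotypes(
                ids=[g.ids[i] for i in perm],
                loci=g.loci,
                ploidy=g.ploidy,
                alleles=g.alleles[perm],
            )
            np.testing.assert_allclose(
                estimate(shuffled, method).values,
                base[np.ix_(perm, perm)],
                atol=1e-10,
            )


class TestMissingData:
    def test_vr_pairwise_complete(self):
        rng = np.random.default_rng(6)
        d = random_dosage(rng, n=5, L=12)
        vals = d.values.copy()
        vals[0, 3] = np.nan
        vals[2, 7] = np.nan
        dm = DosageMatrix(
            ids=d.ids, loci=d.loci, ploidy=d.ploidy, values=vals
        )
        got = est_vr(dm).values
        # oracle: per-pair restriction to loci observed in both
        mean = np.nanmean(vals, axis=0)
        s2 = np.nanvar(vals, axis=0)
        keep = s2 > 0
        for x in range(5):
            for y in range(5):
                ok = (
                    np.isfinite(vals[x]) & np.isfinite(vals[y]) & keep
                )
                num = (
                    (vals[x, ok] - mean[ok]) * (vals[y, ok] - mean[ok])
                ).sum()
                assert got[x, y] == pytest.approx(num / s2[ok].sum())

    def test_multiallelic_missing_pairwise_complete(self):
        g = random_genotypes(np.random.default_rng(7), n=5, L=6)
        al = g.alleles.copy()
        al[0, :, 2] = -1  # missing call
        gm = MultiallelicGenotypes(
            ids=g.ids, loci=g.loci, ploidy=g.ploidy, alleles=al
        )
        part = est_we(gm)
        # pairs involving individual 0 are evaluated on its complete loci,
        # i.e. on the dataset with locus 2 removed (allele frequencies at
        # the other loci are unaffected by the missing call)
        keep = [l for l in range(6) if l != 2]
        reduced = est_we(g.subset_loci(keep))
        np.testing.assert_allclose(
            part.values[0], reduced.values[0], atol=1e-10
        )
        assert np.isfinite(part.values).all()
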