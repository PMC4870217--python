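"""Diversity statistics, HWE/LD tests, Holm correction, partial correlation."""

import itertools
import math

import numpy as np
import pytest

from msatabc import diversity as dv
from msatabc.io import GenotypeDataset, GenotypeRecord, LocusDef

from conftest import make_dataset


def one_locus(genos, pop="P"):
    return make_dataset({pop: [[g] for g in genos]})


class TestHeterozygosity:
    @pytest.mark.parametrize(
        "genos, expected",
        [
            ([(10, 10), (12, 12)], 0.0),
            ([(10, 12), (10, 14)], 1.0),
            ([(10, 12)] * 3 + [(10, 10)] * 2, 0.6),
        ],
    )
    def test_observed(self, genos, expected):
        _, mean = dv.observed_heterozygosity(one_locus(genos), "P")
        assert mean == pytest.approx(expected)

    def test_expected_monomorphic_is_zero(self):
        _, mean = dv.expected_heterozygosity(one_locus([(10, 10)] * 4), "P")
        assert mean == 0.0

    def test_expected_hand_value(self):
        # 10 genes, allele counts {6, 4}: (10/9) * (1 - 0.52) = 0.5333
        genos = [(10, 10), (10, 10), (10, 12), (10, 12), (12, 12)]
        _, mean = dv.expected_heterozygosity(one_locus(genos), "P")
        assert mean == pytest.approx(10 / 9 * (1 - 0.36 - 0.16))

    def test_expected_large_sample_limit(self, rng):
        genos = [tuple(rng.choice([10, 12], 2)) for _ in range(4000)]
        _, mean = dv.expected_heterozygosity(one_locus(genos), "P")
        assert mean == pytest.approx(0.5, abs=0.02)

    def test_expected_undefined_below_two(self):
        _, mean = dv.expected_heterozygosity(one_locus([(10, 12)]), "P")
        assert math.isnan(mean)

    def test_relabeling_invariance(self):
        genos = [(10, 12), (10, 10), (12, 14)]
        relabeled = [(50, 52), (50, 50), (52, 54)]
        _, a = dv.expected_heterozygosity(one_locus(genos), "P")
        _, b = dv.expected_heterozygosity(one_locus(relabeled), "P")
        assert a == pytest.approx(b)


class TestAllelicRichness:
    def test_full_sample_equals_observed_count(self):
        genos = [(10, 12), (10, 14), (10, 10)]
        per, _ = dv.allelic_richness(one_locus(genos), "P", g=3)
        assert per["L1"] == pytest.approx(3.0)

    def test_monomorphic_is_one(self):
        per, _ = dv.allelic_richness(one_locus([(10, 10)] * 5), "P", g=2)
        assert per["L1"] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        # 6 individuals, allele copy counts {7, 4, 1}; rarefy to g=3 (6 genes)
        genes = [0] * 7 + [1] * 4 + [2]
        genos = [tuple(genes[2 * i: 2 * i + 2]) for i in range(6)]
        genos = [(10 + 2 * a, 10 + 2 * b) for a, b in genos]
        per, _ = dv.allelic_richness(one_locus(genos), "P", g=3)
        counts = [len(set(c)) for c in itertools.combinations(genes, 6)]
        assert per["L1"] == pytest.approx(np.mean(counts))

    def test_monotone_in_g(self):
        genos = [(10, 12), (10, 14), (14, 16), (10, 10), (12, 16)]
        ds = one_locus(genos)
        vals = [dv.allelic_richness(ds, "P", g)[0]["L1"] for g in range(1, 6)]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))
        assert vals[-1] == pytest.approx(4.0)  # observed count at g = N


def _enum_hwe_p(genos):
    """Complete enumeration of the 2-allele exact test (probability ordering)."""
    flat = [a for g in genos for a in g]
    alleles = sorted(set(flat))
    assert len(alleles) == 2
    nA = flat.count(alleles[0])
    na = flat.count(alleles[1])
    n = len(genos)

    def logprob(h):
        gAA, gaa = (nA - h) // 2, (na - h) // 2
        if gAA < 0 or gaa < 0 or (nA - h) % 2 or (na - h) % 2:
            return None
        return (
            math.lgamma(n + 1) + h * math.log(2)
            - math.lgamma(gAA + 1) - math.lgamma(h + 1) - math.lgamma(gaa + 1)
        )

    lps = {h: logprob(h) for h in range(min(nA, na) + 1) if logprob(h) is not None}
    mx = max(lps.values())
    pr = {h: math.exp(v - mx) for h, v in lps.items()}
    z = sum(pr.values())
    hobs = sum(1 for g in genos if g[0] != g[1])
    pobs = pr[hobs]
    return sum(v for v in pr.values() if v <= pobs + 1e-12) / z


class TestHWE:
    def test_perfect_hwe_probability_one(self):
        genos = [(10, 10)] * 25 + [(10, 12)] * 50 + [(12, 12)] * 25
        res = dv.hwe_exact_test(
            one_locus(genos), "P", "L1",
            dememorization=2000, batches=10, iterations_per_batch=2000, seed=1,
        )
        assert res.p_value > 0.95

    @pytest.mark.parametrize(
        "genos",
        [
            [(10, 10), (10, 12), (10, 12), (12, 12), (10, 10)],
            [(10, 10), (10, 10), (10, 12), (12, 12), (12, 12)],
            [(10, 12), (10, 12), (10, 12), (10, 10)],
            [(10, 10), (10, 10), (10, 10), (10, 12), (12, 12), (12, 12)],
        ],
    )
    def test_chain_matches_enumeration(self, genos):
        res = dv.hwe_exact_test(
            one_locus(genos), "P", "L1",
            dememorization=2000, batches=20, iterations_per_batch=4000, seed=5,
        )
        assert res.p_value == pytest.approx(_enum_hwe_p(genos), abs=0.02)

    def test_excess_heterozygosity_detected(self):
        res = dv.hwe_exact_test(
            one_locus([(10, 12)] * 20), "P", "L1",
            dememorization=5000, batches=10, iterations_per_batch=5000, seed=2,
        )
        assert res.p_value < 0.01

    def test_monomorphic_is_nan(self):
        res = dv.hwe_exact_test(one_locus([(10, 10)] * 5), "P", "L1", seed=0)
        assert math.isnan(res.p_value)


class TestLD:
    def test_duplicated_locus_maximal_association(self):
        # three genotype classes, second locus a copy of the first
        genos = [
            [(100 + 2 * (k % 3), 100 + 2 * (k % 3)),
             (200 + 2 * (k % 3), 200 + 2 * (k % 3))]
            for k in range(12)
        ]
        ds = make_dataset({"P": genos})
        p = dv.ld_permutation_test(ds, "P", ("L1", "L2"), n_perm=200, seed=0)
        assert p <= 2 / 201

    def test_null_calibration(self, rng):
        """Independent loci: rejection rate near nominal, p not skewed low."""
        hits = 0
        ps = []
        for rep in range(120):
            genos = [
                [tuple(100 + 2 * rng.integers(0, 4, 2)),
                 tuple(200 + 2 * rng.integers(0, 4, 2))]
                for _ in range(25)
            ]
            genos = [[tuple(map(int, g)) for g in row] for row in genos]
            ds = make_dataset({"P": genos})
            p = dv.ld_permutation_test(ds, "P", ("L1", "L2"), n_perm=99, seed=rep)
            ps.append(p)
            hits += p <= 0.05
        # binomial(120, 0.05): <= 13 rejections with prob > 0.999
        assert hits <= 13
        assert 0.35 < np.mean(ps) < 0.75

    def test_zero_permutations_error(self, two_pop_dataset):
        with pytest.raises(ValueError):
            dv.ld_permutation_test(two_pop_dataset, "north", ("L1", "L2"), n_perm=0)


class TestSequentialBonferroni:
    def test_single_test_plain_alpha(self):
        assert dv.sequential_bonferroni([0.04], 0.05).tolist() == [True]
        assert dv.sequential_bonferroni([0.06], 0.05).tolist() == [False]

    def test_holm_hand_example(self):
        # 0.001 <= 0.05/2, then 0.04 <= 0.05/1 -> both rejected
        assert dv.sequential_bonferroni([0.001, 0.04], 0.05).tolist() == [True, True]
        # step-down stops at the first failure
        assert dv.sequential_bonferroni([0.03, 0.04], 0.05).tolist() == [False, False]

    def test_no_rejections_at_one(self):
        assert not dv.sequential_bonferroni([1.0] * 5, 0.05).any()

    def test_empty(self):
        assert dv.sequential_bonferroni([]).size == 0


class TestPartialCorrelation:
    def test_uncorrelated_control_recovers_simple_r(self, rng):
        x = rng.normal(size=400)
        y = 0.6 * x + rng.normal(size=400)
        z = rng.normal(size=400)  # independent of both
        r_partial, _ = dv.partial_correlation(y, x, z.reshape(-1, 1))
        r_simple = np.corrcoef(x, y)[0, 1]
        assert r_partial == pytest.approx(r_simple, abs=0.05)

    def test_degenerate_identity_control(self, rng):
        z = rng.normal(size=50)
        with pytest.raises(ValueError, match="residual variance"):
            dv.partial_correlation(z, z + rng.normal(size=50), z.reshape(-1, 1))

    def test_known_partial_structure(self, rng):
        # y and x share z; the partial correlation given z is the direct path
        n = 10_000
        z = rng.normal(size=n)
        x = z + rng.normal(size=n)
        y = 0.5 * x - z + rng.normal(size=n)
        r, p = dv.partial_correlation(y, x, z.reshape(-1, 1))
        expected = 0.5 / math.sqrt(1 + 0.25)  # corr of (0.5 e_x + e) with e_x
        assert r == pytest.approx(expected, abs=0.02)
        assert p < 1e-6

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        n = 60
        z1, z2 = rng.normal(size=n), rng.normal(size=n)
        x = z1 + rng.normal(size=n)
        y = x - z2 + rng.normal(size=n)
        r, p = dv.partial_correlation(y, x, np.column_stack([z1, z2]))
        ref = pg.partial_corr(
            pd.DataFrame({"x": x, "y": y, "z1": z1, "z2": z2}),
            x="x", y="y", covar=["z1", "z2"],
        )
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)


def test_diversity_table_columns(two_pop_dataset):
    table = dv.diversity_table(two_pop_dataset, g=2)
    assert list(table.columns) == ["n", "H_O", "H_E", "A_R_2"]
    assert table.loc["north", "n"] == 3
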