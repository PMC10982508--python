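import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mrbiome.exceptions import ValidationError
from mrbiome.gwas_io import LDMatrix, validate_ld
from mrbiome.instruments import (
    Thresholds,
    build_instrument_set,
    exclude_outcome_associated,
    filter_exposure_pvalue,
    harmonize,
    instrument_strength,
    ld_clump,
)

from conftest import exposure_dataset, outcome_dataset, variant


def _ld(snp_ids, r2, positions=None):
    pos = positions or {s: ("1", 1000 * (i + 1)) for i, s in enumerate(snp_ids)}
    frame = pd.DataFrame(
        {"CHR": [pos[s][0] for s in snp_ids], "POS": [pos[s][1] for s in snp_ids]},
        index=snp_ids,
    )
    return validate_ld(LDMatrix(list(snp_ids), np.asarray(r2, float), frame))


class TestExposureFilter:
    def test_strict_boundary(self):
        ds = exposure_dataset(
            [
                variant("rs1", pvalue=2e-6),
                variant("rs2", pos=2000, pvalue=1e-5),
                variant("rs3", pos=3000, pvalue=0.5),
            ]
        )
        kept = filter_exposure_pvalue(ds, 1e-5)
        assert [r.snp_id for r in kept] == ["rs1"]

    def test_empty_dataset(self):
        assert filter_exposure_pvalue(exposure_dataset([]), 1e-5) == []

    def test_matches_brute_force_on_simulated_pvalues(self, rng):
        pvals = rng.uniform(0, 2e-5, 100)
        ds = exposure_dataset(
            [variant(f"rs{i}", pos=100 * (i + 1), pvalue=float(p))
             for i, p in enumerate(pvals)]
        )
        kept = {r.snp_id for r in filter_exposure_pvalue(ds, 1e-5)}
        oracle = {f"rs{i}" for i, p in enumerate(pvals) if p < 1e-5}
        assert kept == oracle


class TestLdClump:
    def test_single_candidate_retained(self):
        cand = [variant("rs1")]
        assert ld_clump(cand, _ld(["rs1"], [[1.0]])) == cand

    def test_perfect_ld_keeps_best_pvalue(self):
        cands = [variant("rs1", pvalue=1e-8), variant("rs2", pos=1500, pvalue=1e-6)]
        ld = _ld(["rs1", "rs2"], [[1, 1], [1, 1]])
        kept = ld_clump(cands, ld)
        assert [c.snp_id for c in kept] == ["rs1"]

    def test_hand_traced_greedy_pass(self):
        """A leads; B falls to A by r2; C survives below the r2 threshold."""
        a = variant("rsA", pos=100_000, pvalue=1e-8)
        b = variant("rsB", pos=150_000, pvalue=1e-6)  # 50 kb from A
        c = variant("rsC", pos=200_000, pvalue=1e-7)
        r2 = [[1, 0.5, 0.0002], [0.5, 1, 0.0], [0.0002, 0.0, 1]]
        ld = _ld(["rsA", "rsB", "rsC"],
                 r2, {"rsA": ("1", 100_000), "rsB": ("1", 150_000), "rsC": ("1", 200_000)})
        kept = ld_clump([a, b, c], ld)
        assert [k.snp_id for k in kept] == ["rsA", "rsC"]

    def test_cross_chromosome_never_clumped(self):
        a = variant("rsA", chrom="1", pvalue=1e-8)
        b = variant("rsB", chrom="2", pvalue=1e-6)
        ld = _ld(["rsA", "rsB"], [[1, 0.9], [0.9, 1]],
                 {"rsA": ("1", 1000), "rsB": ("2", 1000)})
        assert len(ld_clump([a, b], ld)) == 2

    def test_window_limit(self):
        a = variant("rsA", pos=1, pvalue=1e-8)
        b = variant("rsB", pos=10_000_002, pvalue=1e-6)  # just beyond 10,000 kb
        ld = _ld(["rsA", "rsB"], [[1, 0.9], [0.9, 1]],
                 {"rsA": ("1", 1), "rsB": ("1", 10_000_002)})
        assert len(ld_clump([a, b], ld)) == 2

    def test_missing_candidate_raises(self):
        with pytest.raises(ValidationError, match="rs1"):
            ld_clump([variant("rs1")], _ld(["rsX"], [[1.0]]))

    def test_greedy_equals_independent_oracle(self, rng):
        """Greedy clumping agrees with an independently coded p-ordered pass
        on random <=10-SNP panels."""
        for trial in range(25):
            n = int(rng.integers(2, 11))
            ids = [f"rs{j}" for j in range(n)]
            pos = {s: ("1", int(rng.integers(1, 3_000_000))) for s in ids}
            raw = rng.uniform(0, 1, (n, n))
            r2 = np.triu(raw, 1) * (rng.uniform(0, 1, (n, n)) < 0.5)
            r2 = r2 + r2.T + np.eye(n)
            r2 = np.clip(r2, 0, 1)
            np.fill_diagonal(r2, 1.0)
            pv = rng.uniform(0, 1e-5, n)
            cands = [variant(s, pos=pos[s][1], pvalue=float(pv[j]))
                     for j, s in enumerate(ids)]
            ld = _ld(ids, r2, pos)
            got = {c.snp_id for c in ld_clump(cands, ld, 0.1, 10_000)}

            # oracle: scan candidates in (p, chrom, pos, id) order; retain
            # unless conflicting with an already-retained SNP
            kept = []
            for c in sorted(cands, key=lambda r: (r.pvalue, r.chrom, r.pos, r.snp_id)):
                conflict = any(
                    k.chrom == c.chrom
                    and abs(k.pos - c.pos) <= 10_000 * 1000
                    and ld.lookup(k.snp_id, c.snp_id) >= 0.1
                    for k in kept
                )
                if not conflict:
                    kept.append(c)
            assert got == {k.snp_id for k in kept}, f"trial {trial}"


class TestOutcomeExclusion:
    def test_direct_association_dropped(self):
        cand = [variant("rs1")]
        out = outcome_dataset([variant("rs1", pvalue=1e-7)])
        kept, dropped = exclude_outcome_associated(cand, out, 1e-5)
        assert kept == [] and dropped == {"rs1": "outcome-associated"}

    def test_weak_association_retained(self):
        cand = [variant("rs1")]
        out = outcome_dataset([variant("rs1", pvalue=0.3)])
        kept, dropped = exclude_outcome_associated(cand, out, 1e-5)
        assert [k.snp_id for k in kept] == ["rs1"] and not dropped

    def test_missing_in_outcome_distinct_reason(self):
        kept, dropped = exclude_outcome_associated(
            [variant("rs1")], outcome_dataset([]), 1e-5
        )
        assert dropped == {"rs1": "missing-in-outcome"}


class TestHarmonize:
    def test_identical_alleles_copy(self):
        out = outcome_dataset([variant("rs1", beta=-0.05, pvalue=0.3)])
        pairs, dropped = harmonize([variant("rs1", beta=0.1)], out)
        assert not dropped and pairs[0].beta_outcome == -0.05

    def test_swapped_alleles_flip_sign(self):
        exp = variant("rs1", ea="A", oa="G", beta=0.1)
        out = outcome_dataset([variant("rs1", ea="G", oa="A", beta=-0.05, pvalue=0.3)])
        pairs, dropped = harmonize([exp], out)
        assert pairs[0].beta_outcome == pytest.approx(0.05)
        assert pairs[0].effect_allele == "A"

    def test_palindromic_dropped_unconditionally(self):
        exp = variant("rs1", ea="A", oa="T")
        out = outcome_dataset([variant("rs1", ea="A", oa="T", pvalue=0.3)])
        pairs, dropped = harmonize([exp], out)
        assert pairs == [] and dropped == {"rs1": "palindromic"}

    def test_allele_mismatch_dropped(self):
        exp = variant("rs1", ea="A", oa="G")
        out = outcome_dataset([variant("rs1", ea="A", oa="C", pvalue=0.3)])
        pairs, dropped = harmonize([exp], out)
        assert dropped == {"rs1": "mismatch"}


class TestInstrumentStrength:
    def test_null_effect(self):
        r2, f = instrument_strength(variant("rs1", beta=0.0))
        assert r2 == 0.0 and f == 0.0

    def test_printed_formulas(self):
        """R2 = b^2/(b^2 + se^2 N), F = R2 (N-2)/(1-R2) on a worked example."""
        r2, f = instrument_strength(variant("rs1", beta=0.1, se=0.02, n=14306))
        assert r2 == pytest.approx(0.0017445, rel=1e-4)
        assert f == pytest.approx(25.0, rel=1e-3)

    def test_small_n_rejected(self):
        with pytest.raises(ValidationError):
            instrument_strength(variant("rs1", n=2))


class TestBuildInstrumentSet:
    def _fixture(self):
        """Six candidates with known fates: 3 clean, 1 weak, 1 palindromic,
        1 clumped away."""
        strong = dict(beta=0.12, se=0.012, pvalue=1e-7, n=18340)
        exp = exposure_dataset(
            [
                variant("clean1", pos=1_000_000, **strong),
                variant("clean2", chrom="2", pos=1_000_000, **strong),
                variant("clean3", chrom="3", pos=1_000_000, **strong),
                variant("weak", chrom="4", pos=1_000_000, beta=0.032,
                        se=0.012, pvalue=9e-6, n=18340),
                variant("palin", chrom="5", pos=1_000_000, ea="C", oa="G", **strong),
                variant("shadow", pos=1_050_000, beta=0.12, se=0.012,
                        pvalue=1e-6, n=18340),
            ]
        )
        out = outcome_dataset(
            [variant(s, chrom=c, pos=p, ea=ea, oa=oa, beta=0.01, se=0.005,
                     pvalue=0.4, n=300000)
             for s, c, p, ea, oa in [
                 ("clean1", "1", 1_000_000, "A", "G"),
                 ("clean2", "2", 1_000_000, "A", "G"),
                 ("clean3", "3", 1_000_000, "A", "G"),
                 ("weak", "4", 1_000_000, "A", "G"),
                 ("palin", "5", 1_000_000, "C", "G"),
                 ("shadow", "1", 1_050_000, "A", "G"),
             ]]
        )
        ids = ["clean1", "clean2", "clean3", "weak", "palin", "shadow"]
        r2 = np.eye(6)
        r2[0, 5] = r2[5, 0] = 0.9  # shadow sits on clean1's locus
        ld = _ld(ids, r2, {s: (exp.records[s].chrom, exp.records[s].pos) for s in ids})
        return exp, out, ld

    def test_known_fates(self):
        exp, out, ld = self._fixture()
        iset = build_instrument_set(exp, out, ld)
        assert sorted(p.snp_id for p in iset.pairs) == ["clean1", "clean2", "clean3"]
        assert iset.audit["clumped"] == 1
        assert iset.audit["palindromic"] == 1
        assert iset.audit["weak"] == 1
        assert iset.audit["retained"] == 3

    def test_audit_counts_conserve(self):
        exp, out, ld = self._fixture()
        iset = build_instrument_set(exp, out, ld)
        a = iset.audit
        drops = sum(a[r] for r in ("exposure-p", "clumped", "missing-in-outcome",
                                   "outcome-associated", "palindromic", "mismatch",
                                   "weak"))
        assert drops + a["retained"] == a["total"]

    def test_no_candidates_below_threshold_gives_empty_flagged_set(self):
        exp = exposure_dataset([variant("rs1", pvalue=0.5)])
        out = outcome_dataset([variant("rs1", pvalue=0.5)])
        iset = build_instrument_set(exp, out, _ld(["rs1"], [[1.0]]))
        assert iset.empty and iset.audit["retained"] == 0

    def test_every_instrument_strong_and_non_palindromic(self, rng):
        from mrbiome.synthetic import SimulationConfig, simulate_pair

        exp, out, ld, _ = simulate_pair(
            SimulationConfig(n_snps=150, instrument_effect_sd=0.08,
                             frac_palindromic=0.2, seed=99)
        )
        iset = build_instrument_set(exp, out, ld)
        assert not iset.empty
        for pair in iset.pairs:
            rec = exp.records[pair.snp_id]
            assert not rec.is_palindromic
            _, f = instrument_strength(rec)
            assert f >= 10

    def test_pipeline_order_is_normative(self):
        """Clumping before the outcome filter matters: a best-by-p SNP that
        later fails the outcome filter still removes its LD partners."""
        strong = dict(beta=0.12, se=0.012, n=18340)
        exp = exposure_dataset(
            [
                variant("lead", pos=1_000_000, pvalue=1e-9, **strong),
                variant("partner", pos=1_010_000, pvalue=1e-6, **strong),
            ]
        )
        out = outcome_dataset(
            [
                variant("lead", pos=1_000_000, pvalue=1e-8),   # outcome-associated
                variant("partner", pos=1_010_000, pvalue=0.5),
            ]
        )
        r2 = [[1, 0.9], [0.9, 1]]
        ld = _ld(["lead", "partner"], r2,
                 {"lead": ("1", 1_000_000), "partner": ("1", 1_010_000)})
        iset = build_instrument_set(exp, out, ld)
        # the lead clumps the partner away, then dies itself: nothing remains
        assert iset.empty
        assert iset.audit["clumped"] == 1 and iset.audit["outcome-associated"] == 1
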