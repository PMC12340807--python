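"""Screen design rules and count statistics, each against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from codonspeed import screen as sc
from codonspeed.genetic_code import revcomp


def rand_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(4, size=n))


def brute_force_pam_matches(genome, protospacer, max_mm):
    """Exhaustive scan of every window on both strands."""
    hits = 0
    for seq in genome.values():
        for strand_seq in (seq, revcomp(seq)):
            for i in range(len(strand_seq) - 22):
                window = strand_seq[i : i + 20]
                pam = strand_seq[i + 20 : i + 23]
                if pam[1:] != "GG":
                    continue
                mm = sum(a != b for a, b in zip(window, protospacer))
                if mm <= max_mm:
                    hits += 1
    return hits


class TestSelectGuides:
    @staticmethod
    def plus_strand_case(rng):
        left, proto = rand_dna(rng, 50), rand_dna(rng, 20)
        codon_from = proto[17:20]
        codon_to = codon_from[:2] + ("A" if codon_from[2] != "A" else "G")
        genome = {"c": left + proto + "TGG" + rand_dna(rng, 50)}
        edit = sc.VariantEdit("g", 1, codon_from, codon_to, "S2F")
        return genome, edit, ("c", 50 + 17 + 1), proto

    def test_edit_in_seed_unique_genome_retained(self):
        genome, edit, locus, proto = self.plus_strand_case(np.random.default_rng(0))
        guides = sc.select_guides(genome, edit, locus)
        assert any(g.protospacer == proto and g.seed_disrupted for g in guides)

    def test_edit_far_from_pam_rejected(self):
        rng = np.random.default_rng(1)
        left, proto = rand_dna(rng, 50), rand_dna(rng, 20)
        genome = {"c": left + proto + "TGG" + rand_dna(rng, 50)}
        # edit 10+ bases from the PAM: protospacer positions 8-10
        codon_from = proto[7:10]
        codon_to = codon_from[:2] + ("A" if codon_from[2] != "A" else "G")
        edit = sc.VariantEdit("g", 1, codon_from, codon_to, "S2F")
        guides = sc.select_guides(genome, edit, ("c", 50 + 7 + 1))
        assert all(g.protospacer != proto for g in guides)

    def test_implanted_offtarget_rejected_matching_bruteforce(self):
        rng = np.random.default_rng(2)
        genome, edit, locus, proto = self.plus_strand_case(rng)
        # implant a 2-mismatch off-target followed by NGG
        mutated = list(proto)
        mutated[2] = "A" if proto[2] != "A" else "C"
        mutated[9] = "A" if proto[9] != "A" else "C"
        genome_ot = {"c": genome["c"] + rand_dna(rng, 20) + "".join(mutated) + "CGG" + rand_dna(rng, 10)}
        assert brute_force_pam_matches(genome_ot, proto, 2) > 1
        guides = sc.select_guides(genome_ot, edit, locus)
        assert all(g.protospacer != proto for g in guides)
        # and the brute-force count agrees with the implementation's scanner
        assert sc._count_matches_with_pam(genome_ot, proto, 2) == brute_force_pam_matches(
            genome_ot, proto, 2
        )

    def test_minus_strand_guides_found(self):
        rng = np.random.default_rng(3)
        left, window = rand_dna(rng, 50), rand_dna(rng, 20)
        genome = {"c": left + "CCT" + window + rand_dna(rng, 50)}
        c0 = 53
        codon_from = genome["c"][c0 : c0 + 3]
        codon_to = codon_from[:2] + ("A" if codon_from[2] != "A" else "G")
        edit = sc.VariantEdit("g", 1, codon_from, codon_to, "F2S")
        guides = sc.select_guides(genome, edit, ("c", c0 + 1))
        assert any(g.strand == "-" and g.protospacer == revcomp(window) for g in guides)

    def test_wrong_codon_at_locus_errors(self):
        genome = {"c": "A" * 100}
        edit = sc.VariantEdit("g", 1, "CCC", "CCG", "S2F")
        with pytest.raises(ValueError, match="expected"):
            sc.select_guides(genome, edit, ("c", 10))


def brute_force_has_repeat(seq, k):
    """All-substring-pairs oracle for the repeat rule."""
    for length in range(k, len(seq)):
        subs = {}
        for i in range(len(seq) - length + 1):
            subs.setdefault(seq[i : i + length], []).append(i)
        if any(len(v) > 1 for v in subs.values()):
            return True
    return False


class TestAssembleOligo:
    PARTS = {"homology5": "ACGTA" * 5, "retron": "CGTAC" * 5, "homology3": "GTACG" * 4 + "ACGT"}

    @staticmethod
    def setup_case(rng):
        genome = {"c": rand_dna(rng, 300)}
        c0 = 150
        codon_from = genome["c"][c0 : c0 + 3]
        codon_to = codon_from[:2] + ("A" if codon_from[2] != "A" else "G")
        edit = sc.VariantEdit("g", 1, codon_from, codon_to, "S2F")
        guide = sc.GuideCandidate(rand_dna(rng, 20), "+", 140, True, False)
        return genome, edit, guide, ("c", c0 + 1)

    def test_total_length_exactly_194(self):
        genome, edit, guide, locus = self.setup_case(np.random.default_rng(4))
        oligo = sc.assemble_oligo(edit, guide, genome, locus, self.PARTS)
        if oligo is not None:
            assert len(oligo.full_sequence) == 194
            assert edit.codon_to in oligo.donor

    def test_bad_part_lengths_error(self):
        genome, edit, guide, locus = self.setup_case(np.random.default_rng(5))
        bad = dict(self.PARTS, retron="AC")
        with pytest.raises(ValueError, match="194"):
            sc.assemble_oligo(edit, guide, genome, locus, bad)

    def test_polyA_repeat_rejected(self):
        assert sc.has_repeat("G" * 5 + "A" * 10 + "C" * 5 + "A" * 10, 10)

    def test_repeat_rule_matches_quadratic_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(40):
            seq = rand_dna(rng, int(rng.integers(20, 60)))
            assert sc.has_repeat(seq, 10) == brute_force_has_repeat(seq, 10)
        # forced repeats
        for _ in range(10):
            core = rand_dna(rng, 12)
            seq = rand_dna(rng, 15) + core + rand_dna(rng, 8) + core + rand_dna(rng, 15)
            assert sc.has_repeat(seq, 10) and brute_force_has_repeat(seq, 10)

    def test_donor_centred_on_codon(self):
        genome, edit, guide, locus = self.setup_case(np.random.default_rng(7))
        oligo = sc.assemble_oligo(edit, guide, genome, locus, self.PARTS)
        if oligo is not None:
            assert oligo.donor[48:51] == edit.codon_to


def brute_force_count(reads, donors, trim5, prefix_len, seed_len, max_seed_mm):
    counts = {vid: 0 for vid in donors}
    for read in reads:
        if len(read) < trim5 + prefix_len:
            continue
        r = read[trim5 : trim5 + prefix_len]
        best, best_vid, tie = None, None, False
        for vid, donor in donors.items():
            prefix = donor[:prefix_len]
            seed_mm = sum(a != b for a, b in zip(r[:seed_len], prefix[:seed_len]))
            if seed_mm > max_seed_mm:
                continue
            total = sum(a != b for a, b in zip(r, prefix))
            if best is None or total < best:
                best, best_vid, tie = total, vid, False
            elif total == best:
                tie = True
        if best is not None and not tie:
            counts[best_vid] += 1
    return counts


class TestCountReads:
    @staticmethod
    def library(rng, n=25):
        return pd.DataFrame(
            {"variant_id": [f"v{i}" for i in range(n)], "donor": [rand_dna(rng, 100) for _ in range(n)]}
        )

    def test_exact_read_counted_once(self):
        rng = np.random.default_rng(8)
        lib = self.library(rng)
        read = "A" * 28 + lib["donor"][3][:72]
        counts = sc.count_reads([read], lib)
        assert counts["v3"] == 1 and counts.sum() == 1

    def test_three_seed_mismatches_discarded(self):
        rng = np.random.default_rng(9)
        lib = self.library(rng)
        donor = lib["donor"][0]
        read = list("A" * 28 + donor[:72])
        for p in (2, 20, 40):  # three mismatches within the 58-base seed
            read[28 + p] = "A" if donor[p] != "A" else "C"
        counts = sc.count_reads(["".join(read)], lib)
        assert counts.sum() == 0

    def test_short_read_discarded(self):
        rng = np.random.default_rng(10)
        lib = self.library(rng)
        assert sc.count_reads(["ACGT" * 10], lib).sum() == 0

    def test_thousand_reads_match_bruteforce(self):
        rng = np.random.default_rng(11)
        lib = self.library(rng, n=20)
        donors = dict(zip(lib["variant_id"], lib["donor"]))
        reads = []
        for _ in range(1000):
            j = rng.integers(20)
            read = list("A" * 28 + donors[f"v{j}"][:72])
            for p in rng.choice(72, size=rng.integers(0, 5), replace=False):
                read[28 + p] = "ACGT"[rng.integers(4)]
            reads.append("".join(read))
        counts = sc.count_reads(reads, lib)
        oracle = brute_force_count(reads, donors, 28, 72, 58, 2)
        assert counts.to_dict() == oracle
        assert counts.sum() <= len(reads)

    def test_empty_library_errors(self):
        with pytest.raises(ValueError, match="empty"):
            sc.count_reads(["A" * 100], pd.DataFrame(columns=["variant_id", "donor"]))


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"s1": [10, 20, 30, 40], "s2": [10, 20, 30, 40]})
        assert np.allclose(sc.size_factors(counts), 1.0)

    def test_depth_equivariance(self):
        # variant means separated enough that doubling one column cannot
        # reorder the abundance ranking
        base_counts = pd.DataFrame(
            {"a": [10, 40, 160, 640, 2560], "b": [12, 50, 150, 700, 2400],
             "c": [9, 45, 170, 600, 2700]}
        )
        base = sc.size_factors(base_counts)
        # a global depth change cancels in the count/geomean ratios
        assert np.allclose(sc.size_factors(base_counts * 3), base)
        # doubling one sample doubles its factor relative to the others
        # (each factor also absorbs the 2^(1/n) shift of the geometric means)
        doubled = base_counts.copy()
        doubled["b"] = doubled["b"] * 2
        after = sc.size_factors(doubled)
        assert after["b"] / after["a"] == pytest.approx(2 * base["b"] / base["a"], rel=1e-9)
        assert after["a"] == pytest.approx(base["a"] * 2 ** (-1 / 3), rel=1e-9)
        assert after["b"] == pytest.approx(base["b"] * 2 ** (2 / 3), rel=1e-9)

    def test_matches_bruteforce_median_of_ratios(self):
        rng = np.random.default_rng(13)
        counts = pd.DataFrame(rng.integers(0, 500, size=(20, 4)), columns=list("abcd"),
                              index=[f"v{i}" for i in range(20)])
        got = sc.size_factors(counts, top_fraction=0.75)
        means = counts.mean(axis=1).sort_values(ascending=False, kind="mergesort")
        top = counts.loc[means.index[:15]]
        expected = {}
        for s in counts.columns:
            ratios = []
            for v in top.index:
                geo = np.exp(np.mean([np.log(c) if c > 0 else -np.inf for c in top.loc[v]]))
                if geo > 0:
                    ratios.append(top.loc[v, s] / geo)
            expected[s] = float(np.median(ratios))
        for s in counts.columns:
            assert got[s] == pytest.approx(expected[s], abs=1e-12)

    def test_row_and_column_order_invariance(self):
        rng = np.random.default_rng(14)
        counts = pd.DataFrame(rng.integers(1, 500, size=(15, 4)), columns=list("abcd"),
                              index=[f"v{i}" for i in range(15)])
        base = sc.size_factors(counts)
        shuffled = counts.sample(frac=1, random_state=1)[list("dcab")]
        after = sc.size_factors(shuffled)
        for s in counts.columns:
            assert after[s] == pytest.approx(base[s])


def simple_counts(lfc, n_rep=3, base=1000.0):
    start = {f"start_{i}": base * (1 + 0.01 * i) for i in range(n_rep)}
    end = {f"end_{i}": base * 2**lfc * (1 + 0.01 * i) for i in range(n_rep)}
    counts = pd.DataFrame({**start, **end}, index=["v0", "v1", "v2", "v3"])
    counts.iloc[1:] = base  # neutral companions
    design = {s: ("start" if s.startswith("start") else "end") for s in counts.columns}
    factors = pd.Series(1.0, index=counts.columns)
    return counts, factors, design


class TestWaldThresholdTest:
    def test_lfc_at_threshold_gives_p_one(self):
        counts, factors, design = simple_counts(0.58)
        calls = sc.wald_threshold_test(counts, factors, design, pseudo_mean=0.0)
        v0 = calls[0]
        assert abs(v0.log2fc) <= 0.58 + 1e-9
        assert v0.wald_p == 1.0

    def test_zero_threshold_reduces_to_standard_wald(self):
        counts, factors, design = simple_counts(0.3)
        calls = sc.wald_threshold_test(counts, factors, design, lfc_threshold=0.0, pseudo_mean=0.0)
        v0 = calls[0]
        from scipy.stats import norm
        assert v0.wald_p == pytest.approx(min(1, 2 * norm.sf(abs(v0.log2fc) / v0.se)))

    def test_all_zero_start_excluded(self):
        counts, factors, design = simple_counts(1.0)
        counts.loc["v0", [s for s in counts.columns if s.startswith("start")]] = 0
        calls = sc.wald_threshold_test(counts, factors, design)
        assert calls[0].excluded and calls[0].call == "ns"

    def test_bh_adjustment_monotone_and_calls_consistent(self):
        rng = np.random.default_rng(15)
        n = 50
        counts = pd.DataFrame(
            rng.negative_binomial(20, 20 / (20 + 500), size=(n, 6)),
            index=[f"v{i}" for i in range(n)],
            columns=[f"start_{i}" for i in range(3)] + [f"end_{i}" for i in range(3)],
        )
        counts.iloc[:5, 3:] = counts.iloc[:5, 3:] * 8  # strong planted effects
        design = {s: ("start" if s.startswith("start") else "end") for s in counts.columns}
        calls = sc.wald_threshold_test(counts, sc.size_factors(counts), design)
        df = sc.calls_to_frame(calls)
        tested = df[~df["excluded"]].sort_values("wald_p")
        assert tested["padj"].is_monotonic_increasing
        assert ((df["call"] == "ns") | (df["padj"] < 0.05)).all()
        assert (df.loc[df["log2fc"].abs() <= 0.58, "wald_p"].dropna() == 1.0).all()

    def test_too_few_replicates_error(self):
        counts, factors, design = simple_counts(0.3, n_rep=1)
        with pytest.raises(ValueError, match="replicates"):
            sc.wald_threshold_test(counts, factors, design)


class TestGrowthRates:
    def test_threshold_lfc_is_0_72_percent(self):
        assert round(100 * sc.lfc_to_growth_rate(0.58, 81), 2) == 0.72

    def test_zero_and_closed_form(self):
        assert sc.lfc_to_growth_rate(0.0, 40) == 0.0
        assert sc.lfc_to_growth_rate(0.81, 81) == pytest.approx(0.01)

    def test_constant_ratio_zero_rate(self):
        tc = [(0, 500, 500), (10, 800, 800), (20, 100, 100)]
        assert sc.head_to_head_rate(tc) == pytest.approx(0.0)

    def test_exact_exponential_recovered(self):
        s = 0.01
        tc = [(g, 1000 * 2 ** (s * g), 1000.0) for g in (0, 7, 14, 21, 28)]
        assert sc.head_to_head_rate(tc) == pytest.approx(s, abs=1e-9)

    def test_control_slope_subtracted(self):
        s = 0.02
        tc = [(g, 1000 * 2 ** (s * g), 1000.0) for g in (0, 10, 20)]
        assert sc.head_to_head_rate(tc, control_slope=0.005) == pytest.approx(s - 0.005, abs=1e-9)

    def test_sampling_noise_ci_coverage(self):
        rng = np.random.default_rng(16)
        s_true, hits = 0.01, 0
        n_rep = 100
        for _ in range(n_rep):
            gens = np.array([0.0, 6.0, 12.0, 18.0, 24.0, 30.0])
            frac = 0.5 * 2 ** (s_true * gens)
            frac = frac / (frac + 0.5)
            v = rng.binomial(10000, frac)
            r = 10000 - v
            y = np.log2(v / r)
            slope, intercept = np.polyfit(gens, y, 1)
            resid = y - (slope * gens + intercept)
            se = np.sqrt(resid @ resid / (len(gens) - 2) / ((gens - gens.mean()) @ (gens - gens.mean())))
            from scipy.stats import t as tdist
            half = tdist.ppf(0.975, len(gens) - 2) * se
            est = sc.head_to_head_rate(list(zip(gens, v, r)))
            assert est == pytest.approx(slope, abs=1e-12)
            if slope - half <= s_true <= slope + half:
                hits += 1
        assert hits / n_rep >= 0.9

    def test_single_timepoint_errors(self):
        with pytest.raises(ValueError):
            sc.head_to_head_rate([(0, 1, 1)])
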