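"""Pooled synonymous-variant fitness screen: design and count analysis.

Design side: for each target single-codon synonymous edit, pick a Cas9
guide whose protospacer-or-PAM span covers the edited codon, such that the
edit itself disrupts the guide's seed region (the 7 PAM-proximal bases) or
its NGG PAM — preventing re-cutting after repair — and such that the guide
has no off-target site elsewhere in the genome matching with two or fewer
mismatches followed by a valid PAM.  The guide and a 100-nt donor carrying
the edit are assembled with fixed vector parts into a 194-nt oligo;
oligos containing any internal repeat of length >= 10 are rejected as
hard to synthesise.

Analysis side: donor-guide reads are counted against the library by
mismatch-tolerant prefix matching, samples are depth-normalised with
median-of-ratios size factors over the most abundant variants, and
per-variant fitness calls come from a negative-binomial threshold Wald
test: a variant is called only when its |log2 fold change| between the
start and end of the competition credibly exceeds a biological-effect
threshold (0.58, i.e. ~0.72% growth-rate change over 81 generations),
with Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from codonspeed.genetic_code import DNA, revcomp

SPEED_CLASSES = ("S2F", "F2S", "S2S", "F2F", "CONTROL_NEG", "CONTROL_KO")


@dataclass
class VariantEdit:
    gene: str
    codon_position: int  # 1-based codon index within the CDS
    codon_from: str
    codon_to: str
    speed_class: str


@dataclass
class GuideCandidate:
    protospacer: str  # 20 nt, 5'->3' on its own strand
    strand: str  # '+' or '-'
    start: int  # 1-based genomic start of the protospacer window (+ strand coords)
    seed_disrupted: bool
    pam_disrupted: bool


@dataclass
class DonorGuideOligo:
    edit: VariantEdit
    guide: GuideCandidate
    donor: str
    full_sequence: str


@dataclass
class ScreenCall:
    variant: str
    log2fc: float
    se: float
    wald_p: float
    padj: float
    call: str  # deleterious / advantageous / ns
    growth_rate_change: float
    excluded: bool = False


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _count_matches_with_pam(genome: dict[str, str], protospacer: str, max_mm: int) -> int:
    """Number of genomic sites matching the protospacer with <= max_mm
    mismatches and followed by NGG on the matching strand (both strands)."""
    guide = _encode(protospacer)
    total = 0
    for seq in genome.values():
        for strand_seq in (seq, revcomp(seq)):
            arr = _encode(strand_seq)
            n = len(arr) - 23 + 1
            if n <= 0:
                continue
            # windows of 23: 20-mer protospacer + NGG PAM
            windows = np.lib.stride_tricks.sliding_window_view(arr, 23)[:n]
            pam_ok = (windows[:, 21] == ord("G")) & (windows[:, 22] == ord("G"))
            mm = (windows[:, :20] != guide).sum(axis=1)
            total += int((pam_ok & (mm <= max_mm)).sum())
    return total


def _apply_edit(seq: str, start0: int, codon_to: str) -> str:
    return seq[:start0] + codon_to + seq[start0 + len(codon_to):]


def select_guides(
    genome: dict[str, str],
    edit: VariantEdit,
    locus: tuple[str, int],
    max_offtarget_mismatches: int = 2,
    seed_len: int = 7,
) -> list[GuideCandidate]:
    """Guide candidates near an edit that pass the seed/PAM and off-target rules.

    ``locus`` is (chromosome, 1-based position of the first base of the
    edited codon on the + strand); the codon at that locus must equal
    ``edit.codon_from``.  Candidates are all 20-mers adjacent to NGG on
    either strand whose protospacer-or-PAM span covers the edited codon.
    A candidate is retained iff (a) the edit changes at least one base in
    its ``seed_len`` PAM-proximal protospacer bases or a G of its PAM, and
    (b) the protospacer matches no genomic site other than the target with
    <= ``max_offtarget_mismatches`` mismatches followed by a valid PAM.
    """
    chrom, pos1 = locus
    seq = genome[chrom]
    c0 = pos1 - 1
    if seq[c0 : c0 + 3] != edit.codon_from.upper():
        raise ValueError(
            f"genome at {chrom}:{pos1} has {seq[c0:c0 + 3]}, expected {edit.codon_from}"
        )
    edited = _apply_edit(seq, c0, edit.codon_to.upper())
    codon_span = range(c0, c0 + 3)

    candidates: list[GuideCandidate] = []
    # + strand: protospacer [i, i+19], PAM [i+20, i+22] = NGG
    for i in range(max(0, c0 - 22), min(len(seq) - 23, c0 + 2) + 1):
        if not (seq[i + 21] == "G" and seq[i + 22] == "G"):
            continue
        span = range(i, i + 23)
        if not (span.start <= codon_span[-1] and codon_span.start <= span[-1]):
            continue
        seed_lo = i + 20 - seed_len
        seed_disrupted = seq[seed_lo : i + 20] != edited[seed_lo : i + 20]
        pam_disrupted = seq[i + 21 : i + 23] != edited[i + 21 : i + 23]
        candidates.append(
            GuideCandidate(seq[i : i + 20], "+", i + 1, seed_disrupted, pam_disrupted)
        )
    # - strand: genome window [i, i+19] with CC at [i-3, i-2]; protospacer
    # is the reverse complement, seed maps to genome positions [i, i+seed_len)
    for i in range(max(3, c0 - 22), min(len(seq) - 20, c0 + 2) + 1):
        if not (seq[i - 3] == "C" and seq[i - 2] == "C"):
            continue
        span = range(i - 3, i + 20)
        if not (span.start <= codon_span[-1] and codon_span.start <= span[-1]):
            continue
        seed_disrupted = seq[i : i + seed_len] != edited[i : i + seed_len]
        pam_disrupted = seq[i - 3 : i - 1] != edited[i - 3 : i - 1]
        candidates.append(
            GuideCandidate(revcomp(seq[i : i + 20]), "-", i + 1, seed_disrupted, pam_disrupted)
        )

    kept = []
    for cand in candidates:
        if not (cand.seed_disrupted or cand.pam_disrupted):
            continue
        # the intact target site matches itself, so one hit is expected
        if _count_matches_with_pam(genome, cand.protospacer, max_offtarget_mismatches) > 1:
            continue
        kept.append(cand)
    return kept


def has_repeat(seq: str, max_repeat: int = 10) -> bool:
    """True iff any substring of length >= max_repeat occurs at two
    distinct start positions (equivalently, any duplicated max_repeat-mer)."""
    seen = set()
    for i in range(len(seq) - max_repeat + 1):
        kmer = seq[i : i + max_repeat]
        if kmer in seen:
            return True
        seen.add(kmer)
    return False


def assemble_oligo(
    edit: VariantEdit,
    guide: GuideCandidate,
    genome: dict[str, str],
    locus: tuple[str, int],
    vector_parts: dict[str, str],
    donor_len: int = 100,
    max_repeat: int = 10,
    total_len: int = 194,
) -> DonorGuideOligo | None:
    """Assemble the 194-nt donor-guide oligo, or None if it fails the
    repeat rule.

    The donor is a ``donor_len`` genomic window centred on the edited codon
    and carrying the edit; the full oligo is
    homology5 + donor + retron + guide(20 nt) + homology3 and must total
    ``total_len`` nucleotides.
    """
    part_len = sum(len(vector_parts[k]) for k in ("homology5", "retron", "homology3"))
    if part_len + donor_len + 20 != total_len:
        raise ValueError(
            f"vector parts ({part_len}) + donor ({donor_len}) + guide (20) != {total_len}"
        )
    chrom, pos1 = locus
    seq = genome[chrom]
    c0 = pos1 - 1
    edited = _apply_edit(seq, c0, edit.codon_to.upper())
    left = (donor_len - 3) // 2
    start = c0 - left
    if start < 0 or start + donor_len > len(edited):
        raise ValueError("edit too close to a contig end for a centred donor window")
    donor = edited[start : start + donor_len]
    full = (
        vector_parts["homology5"] + donor + vector_parts["retron"]
        + guide.protospacer + vector_parts["homology3"]
    )
    assert len(full) == total_len
    if has_repeat(full, max_repeat):
        return None
    return DonorGuideOligo(edit=edit, guide=guide, donor=donor, full_sequence=full)


def knockout_control_donor(
    genome: dict[str, str], locus: tuple[str, int], donor_len: int = 100
) -> str:
    """Donor carrying an ATGN -> TAA start-codon knockout (removes the
    start codon and frameshifts any downstream in-frame start)."""
    chrom, pos1 = locus
    seq = genome[chrom]
    c0 = pos1 - 1
    if seq[c0 : c0 + 3] != "ATG":
        raise ValueError(f"no ATG at {chrom}:{pos1}")
    edited = seq[:c0] + "TAA" + seq[c0 + 4 :]  # ATGN (4 nt) -> TAA (3 nt)
    left = (donor_len - 3) // 2
    start = c0 - left
    return edited[start : start + donor_len]


def count_reads(
    reads: list[str],
    library: pd.DataFrame,
    trim5: int = 28,
    prefix_len: int = 72,
    seed_len: int = 58,
    max_seed_mismatches: int = 2,
) -> pd.Series:
    """Assign reads to donors by mismatch-tolerant prefix matching.

    After removing the first ``trim5`` bases (vector homology), a read is
    compared against the first ``prefix_len`` bases of every donor; donors
    with more than ``max_seed_mismatches`` mismatches within the first
    ``seed_len`` bases are ineligible, and among eligible donors the one
    with the fewest total mismatches wins.  Ties and unmatched or too-short
    reads are discarded.  Returns per-donor counts indexed by variant id.
    """
    if library.empty:
        raise ValueError("empty donor library")
    short = library[library["donor"].str.len() < prefix_len]
    if not short.empty:
        raise ValueError(f"donor shorter than prefix_len: {short.iloc[0]['variant_id']}")
    ids = library["variant_id"].tolist()
    prefixes = np.stack([_encode(d[:prefix_len]) for d in library["donor"]])
    counts = pd.Series(0, index=pd.Index(ids, name="variant_id"), dtype=int)
    for read in reads:
        if len(read) < trim5 + prefix_len:
            continue
        r = _encode(read[trim5 : trim5 + prefix_len].upper())
        mm = prefixes != r
        seed_mm = mm[:, :seed_len].sum(axis=1)
        total_mm = mm.sum(axis=1)
        eligible = seed_mm <= max_seed_mismatches
        if not eligible.any():
            continue
        total_mm = np.where(eligible, total_mm, prefix_len + 1)
        best = total_mm.min()
        winners = np.flatnonzero(total_mm == best)
        if len(winners) != 1:
            continue
        counts.iloc[winners[0]] += 1
    return counts


def size_factors(counts: pd.DataFrame, top_fraction: float = 0.75) -> pd.Series:
    """Median-of-ratios depth normalisation over the most abundant variants.

    Variants are ranked by mean raw count across samples; the top
    ``top_fraction`` are retained.  Each sample's factor is the median over
    retained variants (with positive geometric mean across samples) of
    count / geometric mean.
    """
    if counts.shape[1] < 2 or counts.shape[0] < 4:
        raise ValueError("need >= 2 samples and >= 4 variants")
    means = counts.mean(axis=1)
    n_keep = max(1, int(round(top_fraction * len(counts))))
    order = means.sort_values(ascending=False, kind="mergesort")
    top = counts.loc[order.index[:n_keep]]
    with np.errstate(divide="ignore"):
        log_geo = np.log(top.to_numpy(float)).mean(axis=1)
    geo = np.exp(log_geo)
    ok = np.isfinite(log_geo) & (geo > 0)
    if not ok.any():
        raise ValueError("all geometric means are zero")
    ratios = top.to_numpy(float)[ok] / geo[ok, None]
    return pd.Series(np.median(ratios, axis=0), index=counts.columns, name="size_factor")


def wald_threshold_test(
    counts: pd.DataFrame,
    factors: pd.Series,
    design: dict[str, str],
    lfc_threshold: float = 0.58,
    padj_alpha: float = 0.05,
    pseudo_mean: float = 0.5,
    alpha_min: float = 1e-6,
    generations: int = 81,
) -> list[ScreenCall]:
    """Negative-binomial threshold Wald test of start-vs-end abundance.

    Per variant: counts are divided by the sample size factors; the log2
    fold change is ``log2((mean_end + pc) / (mean_start + pc))`` with
    pseudo-mean ``pc``; the NB dispersion is a per-variant moment estimate
    ``max(alpha_min, (s^2 - mu) / mu^2)`` pooled across timepoints; the
    standard error of the log2 fold change follows by the delta method
    under NB variance; and the Wald statistic tests ``|log2fc|`` against
    ``lfc_threshold`` (p = 1 when the estimate does not exceed the
    threshold).  Benjamini-Hochberg correction is applied over tested
    variants; calls are deleterious/advantageous by the sign of the fold
    change at ``padj < padj_alpha``.  Variants with zero counts in every
    start sample are flagged and excluded from testing.
    """
    start_samples = [s for s, t in design.items() if t == "start"]
    end_samples = [s for s, t in design.items() if t == "end"]
    if len(start_samples) < 2 or len(end_samples) < 2:
        raise ValueError("need >= 2 replicates per timepoint")
    norm = counts / factors
    calls: list[ScreenCall] = []
    tested_idx: list[int] = []
    pvals: list[float] = []
    for variant, row in norm.iterrows():
        raw_start = counts.loc[variant, start_samples]
        if (raw_start == 0).all():
            calls.append(ScreenCall(variant, np.nan, np.nan, np.nan, np.nan, "ns", np.nan, excluded=True))
            continue
        k_start = row[start_samples].to_numpy(float)
        k_end = row[end_samples].to_numpy(float)
        mu_s, mu_e = k_start.mean(), k_end.mean()
        lfc = float(np.log2((mu_e + pseudo_mean) / (mu_s + pseudo_mean)))

        # moment dispersion pooled across timepoints (df-weighted)
        num = den = 0.0
        for k in (k_start, k_end):
            mu = k.mean()
            if mu > 0 and len(k) > 1:
                a = (k.var(ddof=1) - mu) / mu**2
                num += a * (len(k) - 1)
                den += len(k) - 1
        alpha = max(alpha_min, num / den if den > 0 else alpha_min)

        sf_s = factors[start_samples].to_numpy(float)
        sf_e = factors[end_samples].to_numpy(float)
        mu_s_p, mu_e_p = mu_s + pseudo_mean, mu_e + pseudo_mean
        var_mean_s = (mu_s_p / sf_s + alpha * mu_s_p**2).sum() / len(sf_s) ** 2
        var_mean_e = (mu_e_p / sf_e + alpha * mu_e_p**2).sum() / len(sf_e) ** 2
        se = float(
            np.sqrt(var_mean_s / mu_s_p**2 + var_mean_e / mu_e_p**2) / np.log(2)
        )
        if abs(lfc) > lfc_threshold and se > 0:
            z = (abs(lfc) - lfc_threshold) / se
            p = float(min(1.0, 2 * sps.norm.sf(z)))
        else:
            p = 1.0
        tested_idx.append(len(calls))
        pvals.append(p)
        calls.append(
            ScreenCall(variant, lfc, se, p, np.nan, "ns", lfc_to_growth_rate(lfc, generations))
        )
    if tested_idx:
        padj = multipletests(pvals, method="fdr_bh")[1]
        for i, idx in enumerate(tested_idx):
            calls[idx].padj = float(padj[i])
            if calls[idx].padj < padj_alpha:
                calls[idx].call = "deleterious" if calls[idx].log2fc < 0 else "advantageous"
    return calls


def lfc_to_growth_rate(log2fc: float, generations: int = 81) -> float:
    """Log2 fold change over a competition -> growth-rate difference in
    doublings per generation (e.g. 0.58 over 81 generations ~ 0.72%)."""
    if generations <= 0:
        raise ValueError("generations must be positive")
    return log2fc / generations


def head_to_head_rate(
    timecourse: list[tuple[float, float, float]], control_slope: float | None = None
) -> float:
    """Relative growth rate from a paired competition timecourse.

    ``timecourse`` is (generation, variant_count, reference_count) tuples;
    the rate is the least-squares slope of log2(variant/reference) against
    generation, minus an optional variant-free control slope.
    """
    if len(timecourse) < 2:
        raise ValueError("need >= 2 timepoints")
    g = np.array([t[0] for t in timecourse], float)
    v = np.array([t[1] for t in timecourse], float)
    r = np.array([t[2] for t in timecourse], float)
    if (v <= 0).any() or (r <= 0).any():
        raise ValueError("counts must be positive")
    slope = float(np.polyfit(g, np.log2(v / r), 1)[0])
    return slope - (control_slope or 0.0)


def calls_to_frame(calls: list[ScreenCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variant": c.variant,
                "log2fc": c.log2fc,
                "se": c.se,
                "wald_p": c.wald_p,
                "padj": c.padj,
                "call": c.call,
                "growth_rate_change": c.growth_rate_change,
                "excluded": c.excluded,
            }
            for c in calls
        ]
    )
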