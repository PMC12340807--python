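"""Synthetic corpora and screens with planted, recoverable structure.

The generator emulates the statistical structure the analyses assume, not
yeast biology itself:

* multi-species homolog families whose pairwise identities span the
  clustering thresholds (40% family level, 70% subfamily level),
* per-position FAST/SLOW codon labels drawn from a logistic model over
  position (slow starts), a smoothed structure track standing in for
  pLDDT (fast structured regions), sparse functional-site flags (fast
  sites), and a per-gene codon-usage bias tied to expression,
* embeddings as a fixed seeded linear encoding of those same features plus
  Gaussian noise — the gene-level bias is part of the encoded features, so
  a head trained without class balancing can exploit it,
* screen count matrices with negative-binomial noise around planted
  per-generation fitness effects compounded over the competition.

Every generated dataset is accompanied by its planted truth, and all
randomness flows from one integer seed through numpy's PCG64 generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from codonspeed.codon_labels import CodonLabelSet, label_codons
from codonspeed.corpus import ProteinRecord
from codonspeed.genetic_code import AA_TO_CODONS, CODON_TO_AA
from codonspeed.io import EmbeddingStore

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: the eight amino acids with a wide synonymous elongation-rate spread
LABELED_AAS = "CPSRALIG"


@dataclass
class SyntheticConfig:
    # corpus
    n_genes: int = 500            # total proteins across all species
    mean_length: int = 300
    n_species: int = 14           # last one is the held-out test species
    embedding_dim: int = 64
    noise_sd: float = 0.3
    beta0: float = 0.0
    beta_start: float = 0.6       # slow-start strength (subtracted for pos <= 50)
    beta_struct: float = 1.0      # fast-structured strength per unit (plddt-50)/50
    beta_site: float = 1.5        # fast-site strength
    beta_postdomain: float = 0.0  # optional planted effect 35-40 codons past domain ends
    gene_bias_sd: float = 0.6
    start_window: int = 50
    site_rate: float = 0.02
    context_limit: int = 1024
    # screen
    n_variants: int = 2000
    fraction_nonneutral: float = 0.10
    s_range: tuple[float, float] = (0.005, 0.03)  # |s| per generation
    generations: int = 81
    dispersion: float = 0.05
    replicates: int = 4           # samples per timepoint (2 editing x 2 competition)
    mean_depth: float = 500.0     # mean reads per variant per sample
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0 or self.gene_bias_sd < 0 or self.dispersion < 0:
            raise ValueError("standard deviations and dispersion must be >= 0")
        if not 0 <= self.fraction_nonneutral <= 1:
            raise ValueError("fraction_nonneutral must be in [0, 1]")


@dataclass
class PlantedTruth:
    betas: dict[str, float]
    gene_bias: dict[str, float]
    positions: pd.DataFrame  # per (protein, position): features, logit, p_fast


@dataclass
class SyntheticCorpus:
    records: list[ProteinRecord]
    clusters40: dict[str, str]
    clusters70: dict[str, str]
    labels: CodonLabelSet
    store: EmbeddingStore
    annotations: pd.DataFrame
    plddt: pd.DataFrame
    expression: dict[str, float]
    test_species: str
    truth: PlantedTruth


def synthetic_rate_table(rng: np.random.Generator | None = None) -> pd.DataFrame:
    """A full 61-codon elongation-rate table with planted fast/slow structure.

    The eight wide-spread amino acids get synonymous rates straddling the
    0.85 threshold; all other amino acids get a narrow band so the spread
    filter removes them, mirroring the structure of empirical rate tables.
    """
    if rng is None:
        rng = np.random.default_rng(12345)
    rows = []
    for aa, codons in sorted(AA_TO_CODONS.items()):
        if aa in LABELED_AAS:
            n = len(codons)
            n_slow = max(1, n // 2)
            for i, codon in enumerate(codons):
                if i < n_slow:
                    rate = float(rng.uniform(0.45, 0.75))
                else:
                    rate = float(rng.uniform(0.95, 1.25))
                rows.append({"codon": codon, "rate": rate})
        else:
            base = float(rng.uniform(0.8, 1.0))
            for codon in codons:
                rows.append({"codon": codon, "rate": base + float(rng.uniform(0, 0.1))})
    return pd.DataFrame(rows)


def _smoothed_walk(rng: np.random.Generator, n: int, start: float = 70.0) -> np.ndarray:
    """Random walk clipped to [0, 100], smoothed — a stand-in pLDDT track."""
    steps = rng.normal(0, 8.0, size=n)
    walk = np.clip(start + np.cumsum(steps), 0, 100)
    kernel = np.ones(9) / 9
    pad = np.pad(walk, 4, mode="edge")
    return np.convolve(pad, kernel, mode="valid")


def _mutate(rng: np.random.Generator, seq: str, identity: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() > identity:
            out[i] = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
    return "".join(out)


def _pick_codon(rng: np.random.Generator, aa: str, labels: CodonLabelSet, p_fast: float) -> str:
    codons = AA_TO_CODONS[aa]
    labelled = [c for c in codons if labels.label_of(c) is not None]
    if not labelled:
        return codons[rng.integers(len(codons))]
    want = "FAST" if rng.random() < p_fast else "SLOW"
    pool = [c for c in labelled if labels.label_of(c) == want] or labelled
    return pool[rng.integers(len(pool))]


def simulate_corpus(config: SyntheticConfig) -> SyntheticCorpus:
    """Generate homolog families, labels, embeddings, annotations, tracks."""
    rng = np.random.default_rng(config.seed)
    labels = label_codons(synthetic_rate_table(np.random.default_rng(12345)))

    species = [f"sp{i:02d}" for i in range(1, config.n_species)] + ["testsp"]
    test_species = "testsp"
    n_families = max(1, config.n_genes // config.n_species)

    # fixed seeded linear map from features to embedding space
    n_feat = 4 + len(AMINO_ACIDS) + 1  # start, struct, site, postdomain, aa one-hot, gene bias
    A = np.random.default_rng(config.seed + 7919).normal(0, 1.0, size=(n_feat, config.embedding_dim))
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

    records: list[ProteinRecord] = []
    clusters40: dict[str, str] = {}
    clusters70: dict[str, str] = {}
    store = EmbeddingStore()
    ann_rows, plddt_rows, truth_rows = [], [], []
    gene_bias: dict[str, float] = {}
    expression: dict[str, float] = {}

    for fam in range(n_families):
        length = int(np.clip(rng.normal(config.mean_length, config.mean_length / 5), 60, config.context_limit))
        base = "".join(AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=length))
        # three divergent ancestors per family -> 70%-identity subclusters
        ancestors = [_mutate(rng, base, 0.55) for _ in range(3)]
        has_signal = rng.random() < 0.25
        has_transit = (not has_signal) and rng.random() < 0.10
        n_domains = int(rng.integers(1, 3))
        domains = []
        for _ in range(n_domains):
            if length < 120:
                break
            d_start = int(rng.integers(1, length - 80))
            d_end = min(length, d_start + int(rng.integers(40, 80)))
            domains.append((d_start, d_end))

        for sp in species:
            anc = int(rng.integers(3))
            aa_seq = _mutate(rng, ancestors[anc], rng.uniform(0.80, 0.95))
            pid = f"{sp}_fam{fam:04d}"
            clusters40[pid] = f"fam{fam:04d}"
            clusters70[pid] = f"fam{fam:04d}_anc{anc}"
            bias = float(rng.normal(0, config.gene_bias_sd))
            gene_bias[pid] = bias
            expression[pid] = float(np.exp(bias) * 10.0 * np.exp(rng.normal(0, 0.2)))

            plddt = _smoothed_walk(rng, length)
            site = rng.random(length) < config.site_rate
            pos = np.arange(1, length + 1)
            start_flag = (pos <= config.start_window).astype(float)
            postdom = np.zeros(length)
            for d_start, d_end in domains:
                lo, hi = d_end + 35, min(length, d_end + 40)
                if lo <= length:
                    postdom[lo - 1 : hi] = 1.0
            struct = (plddt - 50.0) / 50.0
            logit = (
                config.beta0
                - config.beta_start * start_flag
                + config.beta_struct * struct
                + config.beta_site * site.astype(float)
                + config.beta_postdomain * postdom
                + bias
            )
            p_fast = 1.0 / (1.0 + np.exp(-logit))

            codons = [_pick_codon(rng, aa, labels, p) for aa, p in zip(aa_seq, p_fast)]
            cds = "".join(codons) + "TAA"
            records.append(ProteinRecord(pid, sp, aa_seq, cds))

            feats = np.zeros((length, n_feat))
            feats[:, 0] = start_flag
            feats[:, 1] = struct
            feats[:, 2] = site.astype(float)
            feats[:, 3] = postdom
            for i, aa in enumerate(aa_seq):
                feats[i, 4 + aa_index[aa]] = 1.0
            feats[:, -1] = bias
            emb = feats @ A + rng.normal(0, config.noise_sd, size=(length, config.embedding_dim))
            store.add(pid, emb.astype(np.float32))

            if has_signal:
                ann_rows.append({"protein_id": pid, "kind": "signal_peptide", "start": 1, "end": 20})
            if has_transit:
                ann_rows.append({"protein_id": pid, "kind": "transit_peptide", "start": 1, "end": 25})
            for d_start, d_end in domains:
                ann_rows.append({"protein_id": pid, "kind": "pfam_domain", "start": d_start, "end": d_end})
            for p in np.flatnonzero(site) + 1:
                kind = "active_site" if rng.random() < 0.5 else "binding_site"
                ann_rows.append({"protein_id": pid, "kind": kind, "start": int(p), "end": int(p)})
            plddt_rows.append(pd.DataFrame({"protein_id": pid, "position": pos, "plddt": plddt}))
            truth_rows.append(
                pd.DataFrame(
                    {
                        "protein_id": pid,
                        "position": pos,
                        "start_flag": start_flag,
                        "struct": struct,
                        "site": site.astype(float),
                        "postdomain": postdom,
                        "logit": logit,
                        "p_fast": p_fast,
                    }
                )
            )

    truth = PlantedTruth(
        betas={
            "beta0": config.beta0,
            "beta_start": config.beta_start,
            "beta_struct": config.beta_struct,
            "beta_site": config.beta_site,
            "beta_postdomain": config.beta_postdomain,
        },
        gene_bias=gene_bias,
        positions=pd.concat(truth_rows, ignore_index=True),
    )
    return SyntheticCorpus(
        records=records,
        clusters40=clusters40,
        clusters70=clusters70,
        labels=labels,
        store=store,
        annotations=pd.DataFrame(ann_rows, columns=["protein_id", "kind", "start", "end"]),
        plddt=pd.concat(plddt_rows, ignore_index=True),
        expression=expression,
        test_species=test_species,
        truth=truth,
    )


@dataclass
class SyntheticScreen:
    counts: pd.DataFrame          # variants x samples
    design: dict[str, str]        # sample -> start/end
    true_s: pd.Series             # planted fitness effect per generation


def simulate_screen(config: SyntheticConfig) -> SyntheticScreen:
    """NB-distributed start/end counts with planted per-generation fitness.

    Start abundances are log-normal; end abundances compound the planted
    effect ``2^(s * generations)`` and are renormalised to constant
    sequencing depth; counts are negative-binomial with the configured
    dispersion, with sample-specific depth factors.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_variants
    variants = [f"var{i:05d}" for i in range(n)]
    n_hit = int(round(config.fraction_nonneutral * n))
    s = np.zeros(n)
    if n_hit:
        mags = rng.uniform(config.s_range[0], config.s_range[1], size=n_hit)
        signs = np.where(rng.random(n_hit) < 0.5, -1.0, 1.0)
        idx = rng.choice(n, size=n_hit, replace=False)
        s[idx] = mags * signs

    start_freq = rng.lognormal(0, 0.5, size=n)
    start_freq /= start_freq.sum()
    end_freq = start_freq * np.power(2.0, s * config.generations)
    end_freq /= end_freq.sum()

    counts = {}
    design = {}
    for tp, freq in (("start", start_freq), ("end", end_freq)):
        for rep in range(1, config.replicates + 1):
            sample = f"{tp}_{rep}"
            design[sample] = tp
            depth_factor = rng.lognormal(0, 0.2)
            mu = freq * n * config.mean_depth * depth_factor
            if config.dispersion > 0:
                r = 1.0 / config.dispersion
                p = r / (r + mu)
                counts[sample] = rng.negative_binomial(r, p)
            else:
                counts[sample] = rng.poisson(mu)
    frame = pd.DataFrame(counts, index=pd.Index(variants, name="variant_id"))
    return SyntheticScreen(counts=frame, design=design, true_s=pd.Series(s, index=frame.index))
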