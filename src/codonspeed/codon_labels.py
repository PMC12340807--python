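"""Binary fast/slow codon labels from empirical elongation rates.

The labelling pipeline has three stages:

1. ``label_codons`` — threshold per-codon elongation rates (inverse mean
   ribosome footprint density).  Amino acids whose synonymous codons do not
   spread widely enough in rate are dropped entirely; within retained amino
   acids, codons below the slow threshold are SLOW, above it FAST, and exact
   ties are excluded as intermediate.  A small override map handles codons
   labelled against the threshold (by default leucine CTC, rate 0.91, SLOW).
2. ``compute_tai_weights`` — per-species tRNA adaptation index (tAI) weights
   from tRNA gene copy numbers, using wobble-pairing penalties.
3. ``tai_consistency_filter`` — drop codons whose decoding capacity relative
   to their synonymous family is not consistent across species, so the
   retained codons can be assumed consistently slow or fast across the
   training species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from codonspeed.genetic_code import CODON_TO_AA, DNA, STOP_CODONS, revcomp

SLOW = "SLOW"
FAST = "FAST"

#: Wobble penalties s for (codon 3rd base, anticodon wobble base) pairs.
#: Watson-Crick pairs carry no penalty; the four recognised wobble pairs
#: carry the published constants (G:U 0.41, I:C 0.28, I:A 0.9999, U:G 0.68).
#: An anticodon starting with A is assumed deaminated to inosine where the
#: I:C / I:A rows apply.
DEFAULT_WOBBLE_PENALTIES: dict[tuple[str, str], float] = {
    ("T", "A"): 0.0,
    ("C", "G"): 0.0,
    ("A", "T"): 0.0,
    ("G", "C"): 0.0,
    ("T", "G"): 0.41,   # G:U wobble
    ("C", "A"): 0.28,   # I:C (inosine)
    ("A", "A"): 0.9999, # I:A (inosine)
    ("G", "T"): 0.68,   # U:G wobble
}

DEFAULT_OVERRIDES: dict[str, str] = {"CTC": SLOW}

EXCLUSION_REASONS = ("intermediate_rate", "low_spread", "variable_tai", "override")


@dataclass
class CodonLabelSet:
    """Fast/slow assignment for the retained codons plus an exclusion log.

    ``labels`` maps codon -> SLOW/FAST for every retained codon; ``rates``
    keeps the underlying elongation rate; ``excluded`` records every codon
    removed along the way with its reason; ``overridden`` records codons
    whose label came from the override map rather than the threshold.
    """

    labels: dict[str, str]
    rates: dict[str, float]
    excluded: list[tuple[str, str]] = field(default_factory=list)
    overridden: dict[str, str] = field(default_factory=dict)

    @property
    def amino_acids(self) -> set[str]:
        return {CODON_TO_AA[c] for c in self.labels}

    def label_of(self, codon: str) -> str | None:
        return self.labels.get(codon)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "codon": c,
                "amino_acid": CODON_TO_AA[c],
                "label": lab,
                "rate": self.rates.get(c, math.nan),
                "reason": "override" if c in self.overridden else "",
            }
            for c, lab in sorted(self.labels.items())
        ]
        rows += [
            {
                "codon": c,
                "amino_acid": CODON_TO_AA.get(c, ""),
                "label": "EXCLUDED",
                "rate": self.rates.get(c, math.nan),
                "reason": reason,
            }
            for c, reason in sorted(self.excluded)
        ]
        return pd.DataFrame(rows, columns=["codon", "amino_acid", "label", "rate", "reason"])


def _validate_rates(rates: pd.DataFrame) -> pd.DataFrame:
    if not {"codon", "rate"} <= set(rates.columns):
        raise ValueError("rate table needs columns 'codon' and 'rate'")
    rates = rates.copy()
    rates["codon"] = rates["codon"].str.upper()
    if rates["codon"].duplicated().any():
        dups = rates.loc[rates["codon"].duplicated(), "codon"].tolist()
        raise ValueError(f"duplicate codons in rate table: {dups}")
    bad = [c for c in rates["codon"] if c in STOP_CODONS or c not in CODON_TO_AA]
    if bad:
        raise ValueError(f"invalid or stop codons in rate table: {bad}")
    if not np.isfinite(rates["rate"]).all() or (rates["rate"] <= 0).any():
        raise ValueError("elongation rates must be finite and positive")
    return rates


def label_codons(
    rates: pd.DataFrame,
    min_spread: float = 0.35,
    slow_threshold: float = 0.85,
    overrides: dict[str, str] | None = None,
) -> CodonLabelSet:
    """Threshold elongation rates into SLOW/FAST labels.

    Amino acids whose synonymous rate spread (max - min) is below
    ``min_spread`` are excluded entirely.  Within retained amino acids a
    codon is SLOW if its rate is strictly below ``slow_threshold``, FAST if
    strictly above, and excluded as ``intermediate_rate`` on an exact tie.
    ``overrides`` (codon -> SLOW/FAST) are applied last and recorded.
    """
    rates = _validate_rates(rates)
    if overrides is None:
        overrides = dict(DEFAULT_OVERRIDES)
    missing = [c for c in overrides if c not in set(rates["codon"])]
    if missing:
        raise ValueError(f"override codons absent from rate table: {missing}")

    rate_of = dict(zip(rates["codon"], rates["rate"].astype(float)))
    labels: dict[str, str] = {}
    excluded: list[tuple[str, str]] = []
    by_aa: dict[str, list[str]] = {}
    for codon in rate_of:
        by_aa.setdefault(CODON_TO_AA[codon], []).append(codon)

    for aa, codons in by_aa.items():
        vals = [rate_of[c] for c in codons]
        if max(vals) - min(vals) < min_spread:
            excluded += [(c, "low_spread") for c in codons]
            continue
        for c in codons:
            if rate_of[c] < slow_threshold:
                labels[c] = SLOW
            elif rate_of[c] > slow_threshold:
                labels[c] = FAST
            else:
                excluded.append((c, "intermediate_rate"))

    overridden: dict[str, str] = {}
    for codon, lab in overrides.items():
        if lab not in (SLOW, FAST):
            raise ValueError(f"override label must be SLOW or FAST, got {lab!r}")
        # overrides only act within amino acids that survived the spread filter
        if any(c == codon for c, r in excluded if r == "low_spread"):
            continue
        excluded = [(c, r) for c, r in excluded if c != codon]
        if labels.get(codon) != lab:
            overridden[codon] = lab
        labels[codon] = lab

    return CodonLabelSet(labels=labels, rates=rate_of, excluded=excluded, overridden=overridden)


def _pairing_anticodons(
    codon: str, anticodons: list[str], penalties: dict[tuple[str, str], float]
) -> list[tuple[str, float]]:
    """Anticodons able to decode ``codon`` with their wobble penalty.

    Anticodon positions 2-3 must Watson-Crick pair codon positions 2-1
    (i.e. the reverse complement of the anticodon matches the codon at its
    first two bases); the codon 3rd base vs anticodon wobble (first) base
    must be a recognised pair in the penalty map.
    """
    out = []
    for ac in anticodons:
        if revcomp(ac)[:2] != codon[:2]:
            continue
        s = penalties.get((codon[2], ac[0]))
        if s is not None:
            out.append((ac, s))
    return out


def compute_tai_weights(
    counts: pd.DataFrame,
    pairing_params: dict[tuple[str, str], float] | None = None,
) -> pd.DataFrame:
    """tAI weights per (species, codon) from tRNA gene copy numbers.

    For codon *i*, the raw weight is ``W_i = sum_j (1 - s_ij) * count_j``
    over anticodons *j* able to pair with it.  Weights are normalised by the
    per-species maximum, and zero weights are replaced by the geometric mean
    of the nonzero weights so every sense codon carries positive decoding
    capacity.

    Parameters
    ----------
    counts : DataFrame with columns species, anticodon, count.
    pairing_params : (codon 3rd base, anticodon wobble base) -> penalty in
        [0, 1]; defaults to the published wobble constants.
    """
    if pairing_params is None:
        pairing_params = DEFAULT_WOBBLE_PENALTIES
    if counts.empty:
        raise ValueError("empty tRNA gene count table")
    if not {"species", "anticodon", "count"} <= set(counts.columns):
        raise ValueError("count table needs columns species, anticodon, count")
    counts = counts.copy()
    counts["anticodon"] = counts["anticodon"].str.upper().str.replace("U", "T")
    bad = [a for a in counts["anticodon"] if len(a) != 3 or set(a) - set(DNA)]
    if bad:
        raise ValueError(f"invalid anticodon strings: {sorted(set(bad))}")
    if counts.duplicated(["species", "anticodon"]).any():
        raise ValueError("duplicate (species, anticodon) rows")
    if (counts["count"] < 0).any():
        raise ValueError("tRNA gene counts must be non-negative")
    for s, v in pairing_params.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"wobble penalty out of [0,1] for {s}: {v}")

    sense = [c for c in CODON_TO_AA if c not in STOP_CODONS]
    rows = []
    for species, grp in counts.groupby("species", sort=True):
        acs = grp["anticodon"].tolist()
        n_of = dict(zip(grp["anticodon"], grp["count"].astype(float)))
        raw = {}
        for codon in sense:
            raw[codon] = sum(
                (1.0 - s) * n_of[ac] for ac, s in _pairing_anticodons(codon, acs, pairing_params)
            )
        wmax = max(raw.values())
        if wmax <= 0:
            raise ValueError(f"no positive tAI weight for species {species!r}")
        w = {c: v / wmax for c, v in raw.items()}
        nonzero = [v for v in w.values() if v > 0]
        gm = float(np.exp(np.mean(np.log(nonzero))))
        for codon in sense:
            rows.append(
                {"species": species, "codon": codon, "weight": w[codon] if w[codon] > 0 else gm}
            )
    return pd.DataFrame(rows, columns=["species", "codon", "weight"])


def tai_consistency_filter(
    labels: CodonLabelSet,
    tai: pd.DataFrame,
    min_agreement: float = 1.0,
) -> CodonLabelSet:
    """Drop codons whose tAI standing within their synonymous family varies
    across species.

    For each retained codon and species, compute the indicator
    ``tAI(codon) >= median tAI of its synonymous family``.  The codon is
    kept iff the majority indicator value is shared by at least
    ``min_agreement`` of the species (default: unanimity).  Amino acids left
    with fewer than two labelled codons are then excluded entirely.
    """
    if not {"species", "codon", "weight"} <= set(tai.columns):
        raise ValueError("tAI table needs columns species, codon, weight")
    species = sorted(tai["species"].unique())
    if len(species) < 2:
        raise ValueError("tAI consistency filter needs >= 2 species")

    w = tai.set_index(["species", "codon"])["weight"]
    fam_codons: dict[str, list[str]] = {}
    for codon in labels.labels:
        fam_codons.setdefault(CODON_TO_AA[codon], []).append(codon)
    # family = every sense codon of the amino acid present in the tAI table
    all_fam = {
        aa: sorted(c for c in CODON_TO_AA if CODON_TO_AA[c] == aa and c not in STOP_CODONS)
        for aa in fam_codons
    }

    kept = dict(labels.labels)
    excluded = list(labels.excluded)
    for codon in sorted(labels.labels):
        aa = CODON_TO_AA[codon]
        indicators = []
        for sp in species:
            if (sp, codon) not in w.index:
                raise ValueError(f"codon {codon} missing from tAI table for species {sp!r}")
            fam_w = [w[(sp, c)] for c in all_fam[aa] if (sp, c) in w.index]
            med = float(np.median(fam_w))
            indicators.append(w[(sp, codon)] >= med)
        n_true = sum(indicators)
        agreement = max(n_true, len(indicators) - n_true) / len(indicators)
        if agreement < min_agreement:
            del kept[codon]
            excluded.append((codon, "variable_tai"))

    # amino acids reduced below two labelled codons no longer support a
    # within-family fast/slow contrast; drop them entirely
    per_aa: dict[str, list[str]] = {}
    for codon in kept:
        per_aa.setdefault(CODON_TO_AA[codon], []).append(codon)
    for aa, codons in per_aa.items():
        if len(codons) < 2:
            for c in codons:
                del kept[c]
                excluded.append((c, "variable_tai"))

    overridden = {c: v for c, v in labels.overridden.items() if c in kept}
    return CodonLabelSet(labels=kept, rates=dict(labels.rates), excluded=excluded, overridden=overridden)
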