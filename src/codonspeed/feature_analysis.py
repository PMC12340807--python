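"""Positional and protein-feature analyses of model scores.

Comparisons between groups of positions (inside vs outside signal peptides,
structured vs disordered by pLDDT, active/binding sites vs other positions,
...) use a weighted variant of Welch's t-test: weighted means, weighted
variances with the reliability-weight correction
``s^2 = sum w (x - mu)^2 / (sum w - sum w^2 / sum w)``, Kish effective
sample sizes ``n_eff = (sum w)^2 / sum w^2``, Satterthwaite degrees of
freedom, and Cohen's d from the pooled weighted SD.  With unit weights all
of this reduces to the classical Welch test and pooled-SD Cohen's d.

Group membership composes from pandas boolean masks over an annotated
position frame (annotation-kind flags, pLDDT, position windows), so the
comparisons in the analyses — e.g. "sites vs other positions of the same
genes, within structured regions only" — are set algebra on masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from codonspeed.evaluation import join_scores

ANNOTATION_KINDS = ("signal_peptide", "transit_peptide", "pfam_domain", "active_site", "binding_site")


@dataclass
class ComparisonResult:
    mean_a: float
    mean_b: float
    t: float
    df: float
    p: float
    cohens_d: float
    n_eff_a: float
    n_eff_b: float


def _wmoments(x: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    """Weighted mean, reliability-corrected variance, Kish effective n."""
    sw = w.sum()
    if sw <= 0:
        raise ValueError("group has no positive weight")
    mu = float((w * x).sum() / sw)
    n_eff = float(sw**2 / (w**2).sum())
    denom = sw - (w**2).sum() / sw
    if denom <= 0:
        raise ValueError("group has <= 1 effective observation")
    s2 = float((w * (x - mu) ** 2).sum() / denom)
    return mu, s2, n_eff


def weighted_welch(
    x_a: np.ndarray, w_a: np.ndarray, x_b: np.ndarray, w_b: np.ndarray
) -> ComparisonResult:
    """Weighted Welch t-test of group A vs group B with Cohen's d."""
    x_a, w_a = np.asarray(x_a, float), np.asarray(w_a, float)
    x_b, w_b = np.asarray(x_b, float), np.asarray(w_b, float)
    mu_a, s2_a, n_a = _wmoments(x_a, w_a)
    mu_b, s2_b, n_b = _wmoments(x_b, w_b)
    if min(n_a, n_b) <= 1:
        raise ValueError("a group has <= 1 effective observation")
    v_a, v_b = s2_a / n_a, s2_b / n_b
    se = np.sqrt(v_a + v_b)
    t = (mu_a - mu_b) / se if se > 0 else 0.0
    df = (v_a + v_b) ** 2 / (v_a**2 / (n_a - 1) + v_b**2 / (n_b - 1)) if se > 0 else n_a + n_b - 2
    p = float(2 * stats.t.sf(abs(t), df)) if se > 0 else 1.0
    pooled = np.sqrt(((n_a - 1) * s2_a + (n_b - 1) * s2_b) / (n_a + n_b - 2))
    d = (mu_a - mu_b) / pooled if pooled > 0 else 0.0
    return ComparisonResult(mu_a, mu_b, float(t), float(df), p, float(d), n_a, n_b)


def annotate_positions(
    scores: pd.DataFrame,
    table: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
    plddt: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join scores to weights and attach per-position feature columns.

    Adds one boolean column per annotation kind (position inside any
    interval of that kind, 1-based inclusive) and a ``plddt`` column when a
    pLDDT track (protein_id, position, plddt) is given.
    """
    m = join_scores(scores, table)
    for kind in ANNOTATION_KINDS:
        m[kind] = False
    if annotations is not None and not annotations.empty:
        bad = annotations[(annotations["start"] < 1) | (annotations["start"] > annotations["end"])]
        if not bad.empty:
            raise ValueError(f"invalid annotation interval: {bad.iloc[0].to_dict()}")
        for row in annotations.itertuples():
            mask = (
                (m["protein_id"] == row.protein_id)
                & (m["position"] >= row.start)
                & (m["position"] <= row.end)
            )
            m.loc[mask, row.kind] = True
    if plddt is not None:
        m = m.merge(plddt, on=["protein_id", "position"], how="left", validate="one_to_one")
    return m


def region_comparison(
    annotated: pd.DataFrame, mask_a: pd.Series, mask_b: pd.Series
) -> ComparisonResult:
    """Weighted Welch comparison of the scores in two position sets."""
    a = annotated[mask_a & (annotated["weight"] > 0)]
    b = annotated[mask_b & (annotated["weight"] > 0)]
    if a.empty or b.empty:
        raise ValueError("both groups must be nonempty with positive weight")
    return weighted_welch(
        a["score"].to_numpy(), a["weight"].to_numpy(), b["score"].to_numpy(), b["weight"].to_numpy()
    )


def positional_profile(
    scores: pd.DataFrame,
    table: pd.DataFrame,
    max_position: int = 200,
    per_amino_acid: bool = False,
) -> pd.DataFrame:
    """Weighted mean score at each codon position across genes.

    Returns a frame indexed by position with a ``mean_score`` column (and
    one column per amino acid when ``per_amino_acid``).
    """
    m = join_scores(scores, table)
    m = m[(m["weight"] > 0) & (m["position"] <= max_position)]

    def wmean(g):
        return (g["weight"] * g["score"]).sum() / g["weight"].sum()

    prof = m.groupby("position").apply(wmean, include_groups=False).rename("mean_score").to_frame()
    if per_amino_acid:
        for aa, grp in m.groupby("amino_acid"):
            prof[f"aa_{aa}"] = grp.groupby("position").apply(wmean, include_groups=False)
    return prof


def domain_relative_profile(
    scores: pd.DataFrame,
    table: pd.DataFrame,
    annotations: pd.DataFrame,
    window: int = 60,
    summary_window: tuple[int, int] = (35, 40),
    kind: str = "pfam_domain",
) -> tuple[pd.DataFrame, float]:
    """Mean score at positions relative to domain starts/ends.

    For every annotated domain, positions at offsets ``-window..window``
    from its start and end are collected, each classified as inside or
    outside *any* domain of the same protein.  Returns the weighted mean
    per (anchor, offset, inside) and a summary statistic: the mean score at
    offsets ``summary_window`` past domain ends minus the global
    outside-domain mean (negative = slower codons after domains, the
    signature expected under cotranslational-folding pauses).
    """
    doms = annotations[annotations["kind"] == kind]
    m = join_scores(scores, table)
    m = m[m["weight"] > 0]
    if doms.empty or m.empty:
        return pd.DataFrame(columns=["anchor", "offset", "inside", "mean_score", "total_weight"]), float("nan")

    inside_sets: dict[str, set[int]] = {}
    for row in doms.itertuples():
        inside_sets.setdefault(row.protein_id, set()).update(range(row.start, row.end + 1))
    by_protein = {pid: g.set_index("position") for pid, g in m.groupby("protein_id")}

    acc: dict[tuple[str, int, bool], list[float]] = {}
    summary_num = summary_den = 0.0
    lo, hi = summary_window
    for row in doms.itertuples():
        prot = by_protein.get(row.protein_id)
        if prot is None:
            continue
        inside = inside_sets[row.protein_id]
        for anchor_name, anchor_pos in (("start", row.start), ("end", row.end)):
            for off in range(-window, window + 1):
                p = anchor_pos + off
                if p not in prot.index:
                    continue
                key = (anchor_name, off, p in inside)
                acc.setdefault(key, [0.0, 0.0])
                acc[key][0] += prot.at[p, "weight"] * prot.at[p, "score"]
                acc[key][1] += prot.at[p, "weight"]
        for p in range(row.end + lo, row.end + hi + 1):
            if p in prot.index and p not in inside:
                summary_num += prot.at[p, "weight"] * prot.at[p, "score"]
                summary_den += prot.at[p, "weight"]

    prof = pd.DataFrame(
        [
            {"anchor": a, "offset": o, "inside": i, "mean_score": num / den, "total_weight": den}
            for (a, o, i), (num, den) in sorted(acc.items())
        ]
    )
    outside = m[
        [p not in inside_sets.get(pid, set()) for pid, p in zip(m["protein_id"], m["position"])]
    ]
    out_mean = (outside["weight"] * outside["score"]).sum() / outside["weight"].sum()
    summary = (summary_num / summary_den - out_mean) if summary_den > 0 else float("nan")
    return prof, float(summary)
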