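"""Weighted evaluation of per-position codon speed predictions.

All test metrics are weighted: test positions carry per-(gene, amino acid)
weights that place equal total weight on SLOW and FAST codons, so the
chance level of every accuracy here is 50% by construction.  The accuracy
decomposition converts a weighted accuracy into the fraction of positions
that would need to be perfectly predictable (with the rest at chance) to
produce it, and compares the model against a simple random-forest baseline
built from pLDDT, position and amino acid identity alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

EPS = 1e-12


def join_scores(scores: pd.DataFrame, table: pd.DataFrame) -> pd.DataFrame:
    """Inner-join predictions to the position table on (protein, position)."""
    merged = scores.merge(
        table[["protein_id", "position", "amino_acid", "label", "weight"]],
        on=["protein_id", "position"],
        how="inner",
        validate="one_to_one",
    )
    return merged.sort_values(["protein_id", "position"], kind="mergesort").reset_index(drop=True)


def weighted_accuracy(scores: pd.DataFrame, table: pd.DataFrame, threshold: float = 0.5) -> float:
    """Weight-averaged 0/1 accuracy; score >= threshold counts as FAST."""
    m = join_scores(scores, table)
    m = m[m["weight"] > 0]
    total = m["weight"].sum()
    if total <= 0:
        raise ValueError("total weight is zero")
    correct = (m["score"] >= threshold) == (m["label"] == "FAST")
    return float((m["weight"] * correct).sum() / total)


def weighted_roc_auc(scores: pd.DataFrame, table: pd.DataFrame) -> float:
    """Weighted probability that a random FAST score exceeds a random SLOW
    score, ties counted half (weighted Mann-Whitney / ROC AUC)."""
    m = join_scores(scores, table)
    m = m[m["weight"] > 0]
    y = (m["label"] == "FAST").to_numpy(int)
    if y.min() == y.max():
        raise ValueError("need both classes with positive weight for ROC AUC")
    return float(roc_auc_score(y, m["score"], sample_weight=m["weight"]))


def _weighted_rank(scores: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Mid-mass cumulative weight rank u in (0,1) of each row under the
    weighted score distribution (ties broken by input order)."""
    order = np.argsort(scores, kind="mergesort")
    w = weights[order]
    cum = np.cumsum(w)
    u_sorted = (cum - w / 2) / cum[-1]
    u = np.empty_like(u_sorted)
    u[order] = u_sorted
    return u


def quantile_accuracy(
    scores: pd.DataFrame, table: pd.DataFrame, bins: list[float] = (0.01, 0.05, 0.10), threshold: float = 0.5
) -> dict[str, float]:
    """Accuracy in combined top+bottom score-quantile bins.

    ``bins=[0.01, 0.05, 0.10]`` gives three disjoint bins: the combined
    extreme 1% of the weighted score distribution, 1-5%, and 5-10%.  Bin
    membership uses the mid-mass weighted rank of each row.
    """
    bins = list(bins)
    if any(b2 <= b1 for b1, b2 in zip([0.0] + bins[:-1], bins)):
        raise ValueError("bin boundaries must be strictly increasing from 0")
    m = join_scores(scores, table)
    m = m[m["weight"] > 0].reset_index(drop=True)
    u = _weighted_rank(m["score"].to_numpy(float), m["weight"].to_numpy(float))
    correct = ((m["score"] >= threshold) == (m["label"] == "FAST")).to_numpy()
    w = m["weight"].to_numpy(float)
    out = {}
    prev = 0.0
    for b in bins:
        mask = ((u > prev) & (u <= b)) | ((u >= 1 - b) & (u < 1 - prev))
        label = f"{prev * 100:g}-{b * 100:g}%"
        if w[mask].sum() <= 0:
            raise ValueError(f"no weighted mass in quantile bin {label}")
        out[label] = float((w[mask] * correct[mask]).sum() / w[mask].sum())
        prev = b
    return out


def constraint_fraction(accuracy: float) -> float:
    """Fraction f of positions that would need perfect predictability (the
    rest at chance) to yield the observed accuracy: acc = f + (1-f)/2."""
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must be in [0, 1]")
    return 2.0 * (accuracy - 0.5)


def gain_fraction(model_acc: float, baseline_acc: float, chance: float = 0.5) -> float:
    """Share of the model's above-chance gain explained by a baseline."""
    if model_acc == chance:
        raise ValueError("model accuracy equals chance; gain fraction undefined")
    return (baseline_acc - chance) / (model_acc - chance)


@dataclass
class RandomForestReport:
    accuracy: float
    per_fold: list[float]
    params: dict = field(default_factory=dict)


def random_forest_baseline(
    table: pd.DataFrame,
    features: pd.DataFrame,
    params: dict | None = None,
    k: int = 5,
    seed: int = 0,
) -> RandomForestReport:
    """Weighted CV accuracy of a random forest on (pLDDT, position, amino acid).

    ``features`` supplies per-position pLDDT (columns protein_id, position,
    plddt).  Folds are gene-stratified: genes are shuffled under ``seed``
    and dealt round-robin, so no gene spans folds.  Amino acid identity is
    one-hot encoded.  Default forest: 500 trees, max depth 10, at least
    5000 samples to split a node.
    """
    if params is None:
        params = {"trees": 500, "max_depth": 10, "min_split": 5000}
    m = table.merge(features, on=["protein_id", "position"], how="left", validate="one_to_one")
    if m["plddt"].isna().any():
        bad = m.loc[m["plddt"].isna(), ["protein_id", "position"]].iloc[0]
        raise ValueError(f"missing pLDDT for {bad.protein_id} position {bad.position}")
    m = m[m["weight"] > 0].reset_index(drop=True)
    aa_dummies = pd.get_dummies(m["amino_acid"], prefix="aa")
    X = np.column_stack([m["plddt"].to_numpy(float), m["position"].to_numpy(float), aa_dummies.to_numpy(float)])
    y = (m["label"] == "FAST").to_numpy(int)
    w = m["weight"].to_numpy(float)

    genes = np.array(sorted(m["protein_id"].unique()))
    rng = np.random.default_rng(seed)
    rng.shuffle(genes)
    fold_of_gene = {g: i % k for i, g in enumerate(genes)}
    fold = m["protein_id"].map(fold_of_gene).to_numpy()

    per_fold = []
    for f in range(k):
        tr, te = fold != f, fold == f
        clf = RandomForestClassifier(
            n_estimators=params["trees"],
            max_depth=params["max_depth"],
            min_samples_split=params["min_split"],
            random_state=seed,
            n_jobs=1,
        )
        clf.fit(X[tr], y[tr], sample_weight=w[tr])
        pred = clf.predict(X[te])
        per_fold.append(float((w[te] * (pred == y[te])).sum() / w[te].sum()))
    return RandomForestReport(accuracy=float(np.mean(per_fold)), per_fold=per_fold, params=dict(params))


def gene_mean_loss(
    scores: pd.DataFrame,
    table: pd.DataFrame,
    min_total_weight: float = 20.0,
    select_fraction: float = 0.10,
) -> tuple[pd.DataFrame, list[str]]:
    """Rank genes by weighted mean binary cross entropy of their predictions.

    Genes whose total test weight is below ``min_total_weight`` are dropped
    from the reference set.  Returns the ranked reference table (ascending
    loss) and the genes in the lowest ``select_fraction`` of losses — the
    genes whose codon speed the model captures best.
    """
    m = join_scores(scores, table)
    m = m[m["weight"] > 0]
    p = np.clip(m["score"].to_numpy(float), EPS, 1 - EPS)
    y = (m["label"] == "FAST").to_numpy(float)
    m = m.assign(bce=-(y * np.log(p) + (1 - y) * np.log(1 - p)))
    per_gene = m.groupby("protein_id").apply(
        lambda g: pd.Series(
            {"total_weight": g["weight"].sum(), "loss": (g["weight"] * g["bce"]).sum() / g["weight"].sum()}
        ),
        include_groups=False,
    )
    ref = per_gene[per_gene["total_weight"] >= min_total_weight]
    if ref.empty:
        raise ValueError(f"no gene reaches total weight {min_total_weight}")
    ranked = ref.sort_values(["loss", "total_weight"]).reset_index()
    n_sel = max(1, int(np.floor(select_fraction * len(ranked))))
    return ranked, ranked["protein_id"].head(n_sel).tolist()


def per_gene_mean_score(scores: pd.DataFrame, table: pd.DataFrame, weighted: bool = False) -> pd.Series:
    """Mean predicted score per gene (index: protein_id).

    Unweighted by default: the gene-level summary asks what the model
    predicts for a gene's positions overall, independent of the class
    balance the test weights impose."""
    m = join_scores(scores, table)
    if weighted:
        m = m[m["weight"] > 0]
        return m.groupby("protein_id").apply(
            lambda g: (g["weight"] * g["score"]).sum() / g["weight"].sum(), include_groups=False
        )
    return m.groupby("protein_id")["score"].mean()


def per_gene_fast_fraction(table: pd.DataFrame) -> pd.Series:
    """Unweighted fraction of FAST-labelled positions per gene."""
    return table.groupby("protein_id")["label"].apply(lambda s: float((s == "FAST").mean()))


def expression_correlation(gene_values: pd.Series, expression: dict[str, float] | pd.Series) -> tuple[float, float]:
    """Pearson r (and p) of a per-gene statistic vs log expression."""
    expr = pd.Series(expression)
    common = gene_values.index.intersection(expr.index)
    if len(common) < 3:
        raise ValueError("need >= 3 genes with expression values")
    x = gene_values.loc[common].to_numpy(float)
    y = np.log(expr.loc[common].to_numpy(float))
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in correlation input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class EvalReport:
    weighted_accuracy: float
    weighted_roc_auc: float
    quantile_accuracies: dict[str, float]
    constraint_fraction: float
    expression_correlation: float | None = None

    def to_dict(self) -> dict:
        return {
            "weighted_accuracy": self.weighted_accuracy,
            "weighted_roc_auc": self.weighted_roc_auc,
            **{f"accuracy_{k}": v for k, v in self.quantile_accuracies.items()},
            "constraint_fraction": self.constraint_fraction,
            "expression_correlation": self.expression_correlation,
        }


def evaluate(
    scores: pd.DataFrame,
    table: pd.DataFrame,
    expression: dict[str, float] | None = None,
) -> EvalReport:
    """Full weighted evaluation report for a score table."""
    acc = weighted_accuracy(scores, table)
    report = EvalReport(
        weighted_accuracy=acc,
        weighted_roc_auc=weighted_roc_auc(scores, table),
        quantile_accuracies=quantile_accuracy(scores, table),
        constraint_fraction=constraint_fraction(acc),
    )
    if expression is not None:
        report.expression_correlation = expression_correlation(
            per_gene_mean_score(scores, table), expression
        )[0]
    return report
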