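"""Training/test corpus construction.

Builds the per-position dataset behind the codon speed classifier:

* sequence intake with translation-consistency validation,
* homology clustering at two identity levels (40% for family-size
  filtering, 70% for leakage-free fold assignment),
* per-position label extraction limited to the labelled codon set and the
  embedding context window,
* class-balanced undersampling of the training split (equal numbers of
  SLOW and FAST codons per amino acid per gene),
* test-position weighting placing equal total weight on both classes per
  amino acid per gene.

Homology clusters are normally supplied as TSV produced by an external
clustering tool; a small greedy identity clusterer is included so that
synthetic-scale runs need no external tool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from codonspeed.codon_labels import CodonLabelSet
from codonspeed.genetic_code import codons_of, translate_cds

logger = logging.getLogger(__name__)

TEST_FOLD = "TEST"

POSITION_COLUMNS = ["protein_id", "position", "amino_acid", "label", "weight", "fold"]


@dataclass
class ProteinRecord:
    """One protein with its coding sequence and cluster memberships."""

    protein_id: str
    species: str
    aa_sequence: str
    cds_sequence: str
    cluster40: str | None = None
    cluster70: str | None = None


@dataclass
class FoldMap:
    """Protein-level fold assignment: integer fold per 70%-cluster, with
    test-species proteins flagged TEST but still carrying their cluster's
    fold for out-of-fold routing."""

    fold: dict[str, int]
    is_test: dict[str, bool]
    removed: list[tuple[str, str]] = field(default_factory=list)

    def fold_label(self, protein_id: str) -> int | str:
        return TEST_FOLD if self.is_test[protein_id] else self.fold[protein_id]


def load_sequence_pairs(
    protein_fasta: dict[str, str],
    cds_fasta: dict[str, str],
    species: str,
) -> list[ProteinRecord]:
    """Pair protein and CDS sequences by id, keeping only consistent pairs.

    A pair is consistent when the CDS translates exactly to the protein
    sequence (a terminal stop codon is tolerated).  Ids present in only one
    file, or pairs that fail translation, are dropped with a logged reason.
    """
    records = []
    for pid in sorted(protein_fasta):
        if pid not in cds_fasta:
            logger.warning("dropping %s: no CDS for protein", pid)
            continue
        aa, cds = protein_fasta[pid], cds_fasta[pid]
        try:
            translated = translate_cds(cds)
        except ValueError as err:
            logger.warning("dropping %s: %s", pid, err)
            continue
        if translated != aa:
            logger.warning("dropping %s: CDS translation does not match protein", pid)
            continue
        records.append(ProteinRecord(pid, species, aa, cds))
    for pid in sorted(set(cds_fasta) - set(protein_fasta)):
        logger.warning("dropping %s: CDS with no corresponding protein", pid)
    return records


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def greedy_cluster(sequences: dict[str, str], identity: float, k: int = 3) -> dict[str, str]:
    """Greedy identity clustering by k-mer containment (synthetic scale only).

    Sequences are visited longest first; each joins the first established
    representative whose k-mer containment (shared k-mers / k-mers of the
    shorter sequence) reaches ``identity``, else founds a new cluster.
    Returns member id -> representative id.
    """
    order = sorted(sequences, key=lambda pid: (-len(sequences[pid]), pid))
    reps: list[str] = []
    rep_kmers: dict[str, set[str]] = {}
    assignment: dict[str, str] = {}
    for pid in order:
        km = _kmers(sequences[pid], k)
        for rep in reps:
            shared = len(km & rep_kmers[rep])
            denom = min(len(km), len(rep_kmers[rep])) or 1
            if shared / denom >= identity:
                assignment[pid] = rep
                break
        else:
            reps.append(pid)
            rep_kmers[pid] = km
            assignment[pid] = pid
    return assignment


def read_cluster_tsv(df: pd.DataFrame) -> dict[str, str]:
    """Two-column cluster TSV (representative_id, member_id) -> member map."""
    if not {"representative_id", "member_id"} <= set(df.columns):
        raise ValueError("cluster table needs columns representative_id, member_id")
    return dict(zip(df["member_id"], df["representative_id"]))


def cluster_and_fold(
    records: list[ProteinRecord],
    clusters40: dict[str, str] | None,
    clusters70: dict[str, str] | None,
    test_species: str,
    k_folds: int = 5,
    min_cluster_size: int = 4,
    seed: int = 0,
) -> FoldMap:
    """Filter by 40%-cluster family size and assign 70%-clusters to folds.

    Records in 40%-identity clusters with fewer than ``min_cluster_size``
    members are removed (logged).  All members of a 70%-cluster receive the
    same fold; clusters are shuffled under ``seed`` and dealt greedily to
    the currently smallest fold (by member count) to approximate equal fold
    sizes.  Test-species records are never training data but carry their
    cluster's fold so evaluation can route them to the head that never saw
    their homologs.
    """
    if not any(r.species == test_species for r in records):
        raise ValueError(f"test species {test_species!r} absent from records")
    if clusters40 is None:
        clusters40 = greedy_cluster({r.protein_id: r.aa_sequence for r in records}, 0.40)
    if clusters70 is None:
        clusters70 = greedy_cluster({r.protein_id: r.aa_sequence for r in records}, 0.70)
    missing = [r.protein_id for r in records if r.protein_id not in clusters40 or r.protein_id not in clusters70]
    if missing:
        raise ValueError(f"records missing from cluster assignments: {missing[:5]}")

    for r in records:
        r.cluster40 = clusters40[r.protein_id]
        r.cluster70 = clusters70[r.protein_id]

    sizes: dict[str, int] = {}
    for r in records:
        sizes[r.cluster40] = sizes.get(r.cluster40, 0) + 1
    removed = [
        (r.protein_id, f"cluster40 {r.cluster40} has {sizes[r.cluster40]} < {min_cluster_size} members")
        for r in records
        if sizes[r.cluster40] < min_cluster_size
    ]
    for pid, reason in removed:
        logger.info("removed %s: %s", pid, reason)
    kept = [r for r in records if sizes[r.cluster40] >= min_cluster_size]
    if not any(r.species == test_species for r in kept):
        raise ValueError(f"test species {test_species!r} fully removed by the family-size filter")

    members: dict[str, list[str]] = {}
    for r in kept:
        members.setdefault(r.cluster70, []).append(r.protein_id)
    cluster_ids = sorted(members)
    rng = np.random.default_rng(seed)
    rng.shuffle(cluster_ids)
    fold_sizes = [0] * k_folds
    fold_of_cluster: dict[str, int] = {}
    for cid in cluster_ids:
        f = int(np.argmin(fold_sizes))
        fold_of_cluster[cid] = f
        fold_sizes[f] += len(members[cid])

    fold = {r.protein_id: fold_of_cluster[r.cluster70] for r in kept}
    is_test = {r.protein_id: r.species == test_species for r in kept}
    return FoldMap(fold=fold, is_test=is_test, removed=removed)


def build_position_table(
    records: list[ProteinRecord],
    labels: CodonLabelSet,
    fold_map: FoldMap,
    context_limit: int = 1024,
) -> pd.DataFrame:
    """One row per labelled codon position, truncated to the context window.

    The label is that of the codon actually used in the CDS; positions are
    1-based codon indices.  Only records present in the fold map contribute.
    """
    if not labels.labels:
        raise ValueError("empty codon label set")
    rows = []
    for r in sorted(records, key=lambda r: r.protein_id):
        if r.protein_id not in fold_map.fold:
            continue
        fold = fold_map.fold_label(r.protein_id)
        for pos, codon in enumerate(codons_of(r.cds_sequence), start=1):
            if pos > context_limit:
                break
            lab = labels.label_of(codon)
            if lab is None:
                continue
            rows.append((r.protein_id, pos, r.aa_sequence[pos - 1], lab, 1.0, fold))
    return pd.DataFrame(rows, columns=POSITION_COLUMNS)


def balance_training(table: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Undersample training rows to equal SLOW/FAST counts per gene per
    amino acid.

    For each (protein, amino acid) group among non-TEST rows, ``n`` is the
    minority class count; exactly ``n`` rows of each class are sampled
    without replacement under ``seed``.  Groups with no minority examples
    are dropped entirely.  Input order does not matter: rows are sorted
    canonically before the seeded draw.
    """
    train = table[table["fold"] != TEST_FOLD]
    if train.empty:
        raise ValueError("no training rows to balance")
    train = train.sort_values(["protein_id", "position"], kind="mergesort").reset_index(drop=True)
    rng = np.random.default_rng(seed)
    keep_parts = []
    for (_, _), grp in train.groupby(["protein_id", "amino_acid"], sort=True):
        counts = grp["label"].value_counts()
        n = int(min(counts.get("SLOW", 0), counts.get("FAST", 0)))
        if n == 0:
            continue
        for lab in ("SLOW", "FAST"):
            idx = grp.index[grp["label"] == lab].to_numpy()
            chosen = rng.choice(idx, size=n, replace=False)
            keep_parts.append(np.sort(chosen))
    if not keep_parts:
        return train.iloc[0:0]
    keep = np.sort(np.concatenate(keep_parts))
    return train.loc[keep].reset_index(drop=True)


def compute_test_weights(table: pd.DataFrame) -> pd.DataFrame:
    """Weight TEST rows so both classes carry equal total weight per gene
    per amino acid.

    With ``n_s`` SLOW and ``n_f`` FAST rows in a group and
    ``m = min(n_s, n_f)``, each class receives total weight ``m``
    (per-position weight ``m / n_class``), so the group total is ``2 m``;
    one-class groups get weight 0.  Non-TEST rows pass through unchanged.
    """
    out = table.copy()
    test_mask = out["fold"] == TEST_FOLD
    if not test_mask.any():
        raise ValueError("no TEST rows present")
    sub = out[test_mask]
    weights = pd.Series(0.0, index=sub.index)
    for (_, _), grp in sub.groupby(["protein_id", "amino_acid"], sort=False):
        n_s = int((grp["label"] == "SLOW").sum())
        n_f = int((grp["label"] == "FAST").sum())
        m = min(n_s, n_f)
        if m == 0:
            continue
        weights[grp.index[grp["label"] == "SLOW"]] = m / n_s
        weights[grp.index[grp["label"] == "FAST"]] = m / n_f
    out.loc[test_mask, "weight"] = weights
    return out
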