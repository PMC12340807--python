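"""Readers and writers for the formats shared across the pipeline.

Tabular data is TSV with a mandatory header, UTF-8, no quoting.  Sequences
are FASTA (wrapping and case tolerated, canonicalised to upper case).
Per-protein embedding matrices live in a directory store with a manifest
TSV and one matrix file per protein, either a compact binary layout
(16-byte header: 4-byte magic ``EMB1``, uint32 n_rows, uint32 n_cols,
4 pad bytes, then row-major little-endian float32) or a plain-text TSV
matrix.  All coordinates at file boundaries are 1-based inclusive.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MAGIC = b"EMB1"


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> {id: upper-case sequence}; duplicate ids are an error."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


class EmbeddingStore:
    """Per-protein L x D float32 matrices with a manifest.

    Row *r* of a matrix is the embedding of (1-based) position *r*.  The
    feature dimension D is constant within a store.  Backed by an in-memory
    dict; ``save``/``load`` round-trip through the directory format.
    """

    def __init__(self, matrices: dict[str, np.ndarray] | None = None):
        self._m: dict[str, np.ndarray] = {}
        if matrices:
            for pid, mat in matrices.items():
                self.add(pid, mat)

    def add(self, protein_id: str, matrix: np.ndarray) -> None:
        mat = np.asarray(matrix, dtype=np.float32)
        if mat.ndim != 2:
            raise ValueError(f"embedding for {protein_id!r} must be 2-D, got {mat.ndim}-D")
        if self._m:
            d = next(iter(self._m.values())).shape[1]
            if mat.shape[1] != d:
                raise ValueError(
                    f"feature dimension mismatch for {protein_id!r}: {mat.shape[1]} != {d}"
                )
        self._m[protein_id] = mat

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._m

    def __len__(self) -> int:
        return len(self._m)

    def protein_ids(self) -> list[str]:
        return sorted(self._m)

    @property
    def dim(self) -> int:
        if not self._m:
            raise ValueError("empty embedding store")
        return next(iter(self._m.values())).shape[1]

    def get(self, protein_id: str) -> np.ndarray:
        if protein_id not in self._m:
            raise KeyError(f"no embedding for protein {protein_id!r}")
        return self._m[protein_id]

    def rows(self, protein_id: str, positions: np.ndarray) -> np.ndarray:
        """Embedding rows for 1-based positions of one protein."""
        mat = self.get(protein_id)
        pos = np.asarray(positions, dtype=int)
        if pos.min() < 1 or pos.max() > mat.shape[0]:
            bad = pos[(pos < 1) | (pos > mat.shape[0])][0]
            raise KeyError(f"no embedding row for {protein_id!r} position {bad}")
        return mat[pos - 1]

    def save(self, directory: str | Path, text: bool = False) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = []
        for pid in self.protein_ids():
            mat = self._m[pid]
            if text:
                fname = f"{pid}.tsv"
                np.savetxt(directory / fname, mat, delimiter="\t", fmt="%.8g")
            else:
                fname = f"{pid}.emb"
                header = MAGIC + struct.pack("<II4x", mat.shape[0], mat.shape[1])
                with open(directory / fname, "wb") as fh:
                    fh.write(header)
                    fh.write(mat.astype("<f4").tobytes(order="C"))
            manifest.append(
                {"protein_id": pid, "path": fname, "n_rows": mat.shape[0], "n_cols": mat.shape[1]}
            )
        write_tsv(pd.DataFrame(manifest), directory / "manifest.tsv")

    @classmethod
    def load(cls, directory: str | Path) -> "EmbeddingStore":
        directory = Path(directory)
        manifest = read_tsv(directory / "manifest.tsv")
        store = cls()
        for row in manifest.itertuples():
            path = directory / row.path
            if path.suffix == ".tsv":
                mat = np.loadtxt(path, delimiter="\t", dtype=np.float32, ndmin=2)
            else:
                raw = path.read_bytes()
                if raw[:4] != MAGIC:
                    raise ValueError(f"bad magic in {path}")
                n_rows, n_cols = struct.unpack("<II", raw[4:12])
                mat = np.frombuffer(raw[16:], dtype="<f4").reshape(n_rows, n_cols).copy()
            if mat.shape != (row.n_rows, row.n_cols):
                raise ValueError(f"manifest/matrix shape mismatch for {row.protein_id}")
            store.add(row.protein_id, mat)
        return store
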