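"""Readers and writers for the formats the toolkit exchanges.

* PHYLIP square distance matrices (relaxed labels: any whitespace-free
  string, no 10-character padding) — the native matrix format.
* Labeled CSV distance matrices (header row and index column are the taxon
  labels), via pandas.
* Newick trees with branch lengths, via dendropy.
* Aligned FASTA for simulated character matrices, via Biopython.
* NEXUS splits blocks (taxon indices and a weight per split) for split
  networks.

Matrix writers print 12 significant digits, enough for a written file to
re-read and re-write to the identical byte string.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .matrix import DEFAULT_TOL, DistanceMatrix, DistanceMatrixError
from .simulate import CharacterMatrix, SimConfig
from .splits import SplitRecord
from .tree import PhyloTree

__all__ = [
    "read_phylip_dm",
    "write_phylip_dm",
    "read_csv_dm",
    "write_csv_dm",
    "read_newick",
    "write_newick",
    "read_fasta",
    "write_fasta",
    "write_splits_nexus",
    "write_dataset",
]

_FLOAT_FMT = "{:.12g}"


def read_phylip_dm(path: str | os.PathLike, tol: float = DEFAULT_TOL) -> DistanceMatrix:
    """Read a PHYLIP square distance matrix: first line the taxon count,
    then one row per taxon (label followed by n distances)."""
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise DistanceMatrixError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except ValueError:
        raise DistanceMatrixError(f"{path}: first line must be the taxon count") from None
    if len(lines) - 1 != n:
        raise DistanceMatrixError(
            f"{path}: expected {n} matrix rows, found {len(lines) - 1}"
        )
    labels = []
    rows = []
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != n + 1:
            raise DistanceMatrixError(
                f"{path}: row {parts[0] if parts else '?'!r} has "
                f"{len(parts) - 1} values, expected {n}"
            )
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    return DistanceMatrix(labels, np.array(rows), tol=tol)


def write_phylip_dm(D: DistanceMatrix, path: str | os.PathLike) -> None:
    width = max(len(l) for l in D.labels)
    with open(path, "w") as fh:
        fh.write(f"{D.n}\n")
        for i, lab in enumerate(D.labels):
            row = " ".join(_FLOAT_FMT.format(x) for x in D.values[i])
            fh.write(f"{lab:<{width}} {row}\n")


def read_csv_dm(path: str | os.PathLike, tol: float = DEFAULT_TOL) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return DistanceMatrix.from_dataframe(df, tol=tol)


def write_csv_dm(D: DistanceMatrix, path: str | os.PathLike) -> None:
    D.to_dataframe().to_csv(path, float_format="%.12g")


def read_newick(path: str | os.PathLike) -> PhyloTree:
    return PhyloTree.from_newick(Path(path).read_text())


def write_newick(T: PhyloTree, path: str | os.PathLike) -> None:
    Path(path).write_text(T.to_newick() + "\n")


def read_fasta(path: str | os.PathLike, alphabet: str = "ACGT") -> CharacterMatrix:
    labels = []
    seqs = []
    lookup = {ch: i for i, ch in enumerate(alphabet)}
    for rec in SeqIO.parse(str(path), "fasta"):
        labels.append(rec.id)
        seqs.append([lookup[ch] for ch in str(rec.seq).upper()])
    states = np.array(seqs, dtype=np.uint8)
    return CharacterMatrix(tuple(labels), states, alphabet)


def write_fasta(M: CharacterMatrix, path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(M.sequence(lab)), id=lab, description="")
        for lab in M.labels
    ]
    SeqIO.write(records, str(path), "fasta")


def write_splits_nexus(
    splits: Sequence[SplitRecord], labels: Sequence[str], path: str | os.PathLike
) -> None:
    """NEXUS taxa + splits blocks (1-based taxon indices, weight = isolation
    index), readable by split-network viewers."""
    labels = list(labels)
    pos = {lab: i + 1 for i, lab in enumerate(labels)}
    lines = [
        "#nexus",
        "",
        "BEGIN Taxa;",
        f"DIMENSIONS ntax={len(labels)};",
        "TAXLABELS",
        *(f"[{i + 1}] '{lab}'" for i, lab in enumerate(labels)),
        ";",
        "END; [Taxa]",
        "",
        "BEGIN Splits;",
        f"DIMENSIONS ntax={len(labels)} nsplits={len(splits)};",
        "FORMAT labels=no weights=yes confidences=no intervals=no;",
        "MATRIX",
    ]
    for k, rec in enumerate(splits, start=1):
        idx = " ".join(str(pos[lab]) for lab in rec.side_a)
        lines.append(f"[{k}, size={len(rec.side_a)}] \t{rec.alpha:.10g} \t {idx},")
    lines += [";", "END; [Splits]", ""]
    Path(path).write_text("\n".join(lines))


def write_dataset(
    out_dir: str | os.PathLike,
    tree: PhyloTree,
    T: DistanceMatrix,
    D: DistanceMatrix,
    cfg: SimConfig,
    sequences: CharacterMatrix | None = None,
) -> None:
    """Export a simulated dataset directory: tree.nwk, T.phy, D.phy, a JSON
    manifest with the full configuration, and the alignment when present."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_newick(tree, out / "tree.nwk")
    write_phylip_dm(T, out / "T.phy")
    write_phylip_dm(D, out / "D.phy")
    if sequences is not None:
        write_fasta(sequences, out / "alignment.fasta")
    manifest = {
        "n_leaves": cfg.n_leaves,
        "topology_model": cfg.topology_model,
        "edge_length_law": [cfg.edge_length_law[0], cfg.edge_length_law[1]],
        "seed": cfg.seed,
        "seq_length": cfg.seq_length,
        "alphabet_size": cfg.alphabet_size,
        "epsilon": cfg.epsilon,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
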