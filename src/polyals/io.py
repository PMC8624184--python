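"""FASTA and newick serialisation.

FASTA headers carry metadata as ``key=value`` tokens after the id, e.g.::

    >16S-1-c003 population=16S plant=1 part=3prime

which round-trips through :func:`write_fasta` / :func:`read_fasta`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .seqcore import Sequence, TreeNode

FASTA_WIDTH = 60


def read_fasta(path: str | Path) -> list[Sequence]:
    out: list[Sequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        meta: dict[str, str] = {}
        for token in rec.description.split()[1:]:
            if "=" in token:
                k, v = token.split("=", 1)
                meta[k] = v
        out.append(Sequence(rec.id, str(rec.seq), meta))
    ids = [s.id for s in out]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate ids in {path}")
    return out


def write_fasta(seqs: Iterable[Sequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            header = s.id
            if s.meta:
                header += " " + " ".join(f"{k}={v}" for k, v in sorted(s.meta.items()))
            fh.write(f">{header}\n")
            for i in range(0, len(s.residues), FASTA_WIDTH):
                fh.write(s.residues[i:i + FASTA_WIDTH] + "\n")


def write_newick(tree: TreeNode, path: str | Path) -> None:
    Path(path).write_text(tree.newick() + "\n")
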