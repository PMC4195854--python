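"""Alignments, population maps, and their file formats.

Sequences live in memory as small integer matrices over the alphabet
``T, C, A, G`` (indices 0-3) — simulated data carry no gaps or ambiguity
codes.  FASTA is read and written through :mod:`Bio.SeqIO`; sequential
PHYLIP and the two-column population-map format (the common ``Imap``
convention: one ``sequence-label population-label`` pair per line) are plain
text.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "TCAG"
_CODE = {c: i for i, c in enumerate(ALPHABET)}

__all__ = ["Alignment", "read_fasta", "write_fasta", "read_phylip", "write_phylip",
           "read_popmap", "write_popmap", "compress_patterns"]


@dataclass
class Alignment:
    """A gap-free nucleotide alignment.

    Attributes
    ----------
    labels : list of str
        Unique sequence labels, one per row.
    data : ndarray of int8, shape (n_seqs, n_sites)
        Encoded states, 0=T, 1=C, 2=A, 3=G.
    kind : str
        Locus kind, ``"nuclear"`` or ``"mitochondrial"``.
    """

    labels: list[str]
    data: np.ndarray
    kind: str = "nuclear"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.ndim != 2:
            raise ValueError("alignment matrix must be 2-D")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("label count does not match row count")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate sequence labels")
        if self.data.size and (self.data.min() < 0 or self.data.max() > 3):
            raise ValueError("states must be in 0..3 (T,C,A,G)")

    @property
    def n_seqs(self) -> int:
        return self.data.shape[0]

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def sequence(self, label: str) -> str:
        i = self.labels.index(label)
        return "".join(ALPHABET[s] for s in self.data[i])

    def take(self, labels: list[str]) -> "Alignment":
        idx = [self.labels.index(l) for l in labels]
        return Alignment(list(labels), self.data[idx], self.kind)

    @classmethod
    def from_strings(cls, labels, seqs, kind="nuclear") -> "Alignment":
        lens = {len(s) for s in seqs}
        if len(lens) > 1:
            raise ValueError("sequences differ in length")
        data = np.empty((len(seqs), lens.pop() if lens else 0), dtype=np.int8)
        for i, s in enumerate(seqs):
            try:
                data[i] = [_CODE[c] for c in s.upper()]
            except KeyError as exc:
                raise ValueError(f"invalid character {exc} in sequence {labels[i]}") from exc
        return cls(list(labels), data, kind)


def read_fasta(path_or_handle, kind="nuclear") -> Alignment:
    records = list(SeqIO.parse(path_or_handle, "fasta"))
    return Alignment.from_strings([r.id for r in records], [str(r.seq) for r in records], kind)


def write_fasta(aln: Alignment, path_or_handle) -> None:
    records = [SeqRecord(Seq(aln.sequence(l)), id=l, description="") for l in aln.labels]
    SeqIO.write(records, path_or_handle, "fasta")


def read_phylip(path_or_handle, kind="nuclear") -> Alignment:
    close = False
    if isinstance(path_or_handle, (str, bytes, os.PathLike)):
        path_or_handle, close = open(path_or_handle), True
    try:
        header = path_or_handle.readline().split()
        n, m = int(header[0]), int(header[1])
        labels, seqs = [], []
        for line in path_or_handle:
            if not line.strip():
                continue
            name, seq = line.split(None, 1)
            labels.append(name)
            seqs.append(seq.replace(" ", "").strip())
        if len(labels) != n or any(len(s) != m for s in seqs):
            raise ValueError("PHYLIP header does not match the sequences")
        return Alignment.from_strings(labels, seqs, kind)
    finally:
        if close:
            path_or_handle.close()


def write_phylip(aln: Alignment, path_or_handle) -> None:
    close = False
    if isinstance(path_or_handle, (str, bytes, os.PathLike)):
        path_or_handle, close = open(path_or_handle, "w"), True
    try:
        path_or_handle.write(f"{aln.n_seqs} {aln.n_sites}\n")
        for label in aln.labels:
            path_or_handle.write(f"{label}  {aln.sequence(label)}\n")
    finally:
        if close:
            path_or_handle.close()


# ----------------------------------------------------------------------
# population maps


def read_popmap(path_or_handle) -> dict[str, str]:
    if isinstance(path_or_handle, (str, bytes, os.PathLike)):
        with open(path_or_handle) as fh:
            return read_popmap(fh)
    popmap = {}
    for line in path_or_handle:
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 2:
            raise ValueError(f"malformed population-map line: {line!r}")
        seq, pop = parts
        if seq in popmap:
            raise ValueError(f"sequence {seq} mapped twice")
        popmap[seq] = pop
    return popmap


def write_popmap(popmap: dict[str, str], path_or_handle) -> None:
    if isinstance(path_or_handle, (str, bytes, os.PathLike)):
        with open(path_or_handle, "w") as fh:
            write_popmap(popmap, fh)
        return
    for seq, pop in popmap.items():
        path_or_handle.write(f"{seq} {pop}\n")


# ----------------------------------------------------------------------
# site-pattern compression


def compress_patterns(aln: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """Collapse identical alignment columns.

    Returns ``(patterns, weights)`` where ``patterns`` has shape
    ``(n_seqs, n_patterns)`` and ``weights`` counts the multiplicity of each
    distinct column.  Likelihood evaluation cost is proportional to the
    number of distinct patterns, which for the weakly divergent sequences
    simulated here is far below the site count.
    """
    cols, counts = np.unique(aln.data, axis=1, return_counts=True)
    return cols.astype(np.int8), counts.astype(np.float64)
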