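"""Random-sequence peptide libraries and their amino-acid composition matrices.

A peptide library is an ordered collection of equal-length peptides over the
20 proteinogenic amino acids.  Its composition matrix ``X`` (one row per
peptide, one column per amino acid in alphabetical one-letter order) counts
residue occurrences and deliberately discards all positional information --
it is the design matrix of the composition-only regression.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Canonical ordering used for every 20-vector / 20-column object in this
#: package: the proteinogenic amino acids sorted by one-letter code.
ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"

_AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(ALPHABET)}

#: Matches any run of three identical consecutive residues.
_TRIPLE_RUN = re.compile(r"(.)\1\1")


class LibraryError(ValueError):
    """Raised for malformed peptide libraries (bad residues, ragged lengths,
    duplicate ids, empty input)."""


@dataclass(frozen=True)
class PeptideLibrary:
    """An ordered, equal-length peptide library.

    Parameters
    ----------
    ids : tuple of str
        Unique peptide identifiers, in library order.
    sequences : tuple of str
        Peptide sequences over the 20-letter alphabet, all of equal length.
    """

    ids: tuple[str, ...]
    sequences: tuple[str, ...]
    length: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.ids) == 0:
            raise LibraryError("peptide library is empty")
        if len(self.ids) != len(self.sequences):
            raise LibraryError("ids and sequences differ in number")
        if len(set(self.ids)) != len(self.ids):
            seen: set[str] = set()
            dups = sorted({i for i in self.ids if i in seen or seen.add(i)})
            raise LibraryError(f"duplicate peptide ids: {dups}")
        l = len(self.sequences[0])
        for pid, seq in zip(self.ids, self.sequences):
            if len(seq) != l:
                raise LibraryError(
                    f"peptide {pid!r} has length {len(seq)}, expected {l}"
                )
            bad = set(seq) - set(ALPHABET)
            if bad:
                raise LibraryError(
                    f"peptide {pid!r} contains unknown residue(s) {sorted(bad)}"
                )
        object.__setattr__(self, "length", l)

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(zip(self.ids, self.sequences))


def generate_library(
    n_pep: int,
    l: int,
    seed: int | np.random.Generator,
    *,
    unique: bool = False,
) -> PeptideLibrary:
    """Generate a random peptide library with no runs of three identical residues.

    Residues are drawn uniformly over the 20-letter alphabet position by
    position; any draw that would create a run of three identical residues is
    resampled, which keeps generation O(l) per peptide while leaving residue
    marginals uniform to good approximation.

    Parameters
    ----------
    n_pep : int
        Number of peptides (>= 1).
    l : int
        Peptide length (>= 1).
    seed : int or numpy Generator
        Source of randomness; a fixed integer seed makes the library
        reproducible.
    unique : bool
        If True, resample whole sequences until all ``n_pep`` are distinct.

    Returns
    -------
    PeptideLibrary
        Peptides with ids ``pep0001 .. pepNNNN``.
    """
    if n_pep < 1:
        raise ValueError(f"n_pep must be positive, got {n_pep}")
    if l < 1:
        raise ValueError(f"l must be positive, got {l}")
    if unique and n_pep > _count_run_free(l):
        raise ValueError(
            f"cannot draw {n_pep} unique run-free sequences of length {l}"
        )
    rng = np.random.default_rng(seed)

    def one_sequence() -> str:
        chars: list[str] = []
        for j in range(l):
            c = ALPHABET[rng.integers(20)]
            while j >= 2 and c == chars[-1] == chars[-2]:
                c = ALPHABET[rng.integers(20)]
            chars.append(c)
        return "".join(chars)

    seqs: list[str] = []
    seen: set[str] = set()
    while len(seqs) < n_pep:
        s = one_sequence()
        if unique and s in seen:
            continue
        seen.add(s)
        seqs.append(s)
    width = max(4, len(str(n_pep)))
    ids = tuple(f"pep{i + 1:0{width}d}" for i in range(n_pep))
    return PeptideLibrary(ids=ids, sequences=tuple(seqs))


def _count_run_free(l: int) -> int:
    """Number of length-l sequences over 20 letters with no 3-run, counted
    by run-length recurrence (capped at 10^9; enough for a feasibility check)."""
    ending_run1, ending_run2 = 20, 0
    for _ in range(l - 1):
        ending_run1, ending_run2 = 19 * (ending_run1 + ending_run2), ending_run1
        if ending_run1 > 10**9:
            return 10**9
    return ending_run1 + ending_run2


def has_triple_run(sequence: str) -> bool:
    """True if the sequence contains three identical consecutive residues."""
    return _TRIPLE_RUN.search(sequence) is not None


def composition_matrix(lib: PeptideLibrary) -> np.ndarray:
    """Count amino-acid occurrences per peptide.

    Returns an ``(n_pep, 20)`` integer array whose row i, column j entry is
    the number of times amino acid ``ALPHABET[j]`` occurs in peptide i.
    Every row sums to the peptide length; no positional information survives.
    """
    X = np.zeros((len(lib), 20), dtype=np.int64)
    for i, (pid, seq) in enumerate(lib):
        for ch in seq:
            # PeptideLibrary validation guarantees ch is known, but guard
            # anyway so raw sequences can be counted too.
            j = _AA_INDEX.get(ch)
            if j is None:
                raise LibraryError(f"peptide {pid!r}: unknown residue {ch!r}")
            X[i, j] += 1
    return X


def write_library(lib: PeptideLibrary, path, fmt: str = "fasta") -> None:
    """Write a library as FASTA or 2-column tab-separated text (id, sequence)."""
    if fmt == "fasta":
        records = [
            SeqRecord(Seq(seq), id=pid, description="") for pid, seq in lib
        ]
        SeqIO.write(records, str(path), "fasta")
    elif fmt == "tabular":
        pd.DataFrame({"id": lib.ids, "sequence": lib.sequences}).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'fasta' or 'tabular')")


def read_library(path, fmt: str = "fasta") -> PeptideLibrary:
    """Read a library from FASTA or tabular text; validates lengths, residues
    and id uniqueness, raising :class:`LibraryError` on violation."""
    if fmt == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise LibraryError(f"no sequences found in {path}")
        ids = tuple(r.id for r in records)
        seqs = tuple(str(r.seq).upper() for r in records)
    elif fmt == "tabular":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.empty:
            raise LibraryError(f"no peptides found in {path}")
        if not {"id", "sequence"}.issubset(df.columns):
            raise LibraryError("tabular library needs columns 'id' and 'sequence'")
        ids = tuple(df["id"])
        seqs = tuple(s.upper() for s in df["sequence"])
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'fasta' or 'tabular')")
    return PeptideLibrary(ids=ids, sequences=seqs)


def write_composition(X: np.ndarray, ids, path) -> None:
    """Export a composition matrix as tab-separated text with amino-acid
    letters as the header row and peptide ids as the first column."""
    pd.DataFrame(X, index=list(ids), columns=list(ALPHABET)).to_csv(
        path, sep="\t", index_label="id"
    )
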