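"""Tabular I/O: intensity tables, weight tables, experiment exports,
and the key-value run configuration format."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .library import ALPHABET, PeptideLibrary


class TableError(ValueError):
    """Raised for malformed or misaligned tabular inputs."""


def read_intensity_table(path, lib: PeptideLibrary | None = None) -> pd.DataFrame:
    """Read a tab-separated intensity table (peptide_id, intensity
    [, secondary_intensity]).

    If a library is given, rows are re-aligned to library order (the join is
    keyed on peptide id, so input order is irrelevant); missing or extra ids
    raise :class:`TableError` listing them.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    cols = list(df.columns)
    if len(cols) < 2 or cols[0] != "peptide_id":
        raise TableError(
            "intensity table needs a 'peptide_id' first column and at least "
            "one intensity column"
        )
    for col in cols[1:]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            raise TableError(
                f"non-numeric value in column {col!r} at row(s) "
                f"{[int(i) + 2 for i in bad]}"  # +2: header + 1-based
            )
        df[col] = vals
    if df["peptide_id"].duplicated().any():
        dups = sorted(df.loc[df["peptide_id"].duplicated(), "peptide_id"])
        raise TableError(f"duplicate peptide ids: {dups}")
    if lib is not None:
        have = set(df["peptide_id"])
        want = set(lib.ids)
        missing = sorted(want - have)
        extra = sorted(have - want)
        if missing or extra:
            raise TableError(
                f"intensity table does not match library: missing={missing}, "
                f"extra={extra}"
            )
        df = df.set_index("peptide_id").loc[list(lib.ids)].reset_index()
    return df


def write_profile_table(ids, raw, normalized, path) -> None:
    """Export a simulated profile as tab-separated text
    (peptide_id, raw Langmuir fraction, normalized signal)."""
    pd.DataFrame(
        {"peptide_id": list(ids), "raw_fraction": raw, "normalized": normalized}
    ).to_csv(path, sep="\t", index=False)


def write_aaws_table(w: np.ndarray, path) -> None:
    """Export a 20-row weight table (amino_acid, weight)."""
    w = np.asarray(w, dtype=float)
    if w.shape != (20,):
        raise ValueError("weight vector must have 20 entries")
    pd.DataFrame({"amino_acid": list(ALPHABET), "weight": w}).to_csv(
        path, sep="\t", index=False
    )


def read_aaws_table(path) -> np.ndarray:
    """Read a weight table back into a canonical-order 20-vector."""
    df = pd.read_csv(path, sep="\t")
    if not {"amino_acid", "weight"}.issubset(df.columns):
        raise TableError("weight table needs columns 'amino_acid' and 'weight'")
    df = df.set_index("amino_acid")
    missing = sorted(set(ALPHABET) - set(df.index))
    if missing:
        raise TableError(f"weight table missing amino acid(s): {missing}")
    return df.loc[list(ALPHABET), "weight"].to_numpy(dtype=float)


def read_scale_table(path) -> pd.DataFrame:
    """Read a property-scale table: tab-separated, amino-acid one-letter
    codes in the first column, one named scale per remaining column."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0])


def read_config(path) -> dict[str, str]:
    """Parse a simple ``key = value`` text configuration (one per line;
    '#' starts a comment; blank lines ignored)."""
    cfg: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise TableError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (part.strip() for part in line.split("=", 1))
            cfg[key] = val
    return cfg
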