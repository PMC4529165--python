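"""Bundled characterization tables for 21 wild Musa accessions.

Two published reference tables ship with the package: the per-accession
genome-size/karyotype table (2C DNA content mean ± SD over three plants,
monoploid genome size, DNA-content letter grouping, chromosome number and
45S/5S rDNA FISH signal counts for accessions of the sections Musa and
Callimusa) and the per-ITS-type sequence characteristics table (per-region
GC content, status of the three conserved 5.8S motifs with 1-based
``nt-`` change positions, ITS2/5.8S secondary-structure outcome, and the
putative-pseudogene note).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_accession_table",
    "load_its_type_table",
    "parse_motif_cell",
    "its_type_features",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("charkit.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_accession_table() -> pd.DataFrame:
    """Per-accession genome size, letter grouping, 2n and rDNA locus counts.

    ``two_n``, ``n_45s`` and ``n_5s`` are NaN for the two accessions whose
    chromosomes could not be counted.
    """
    df = _read("musa_accessions.csv")
    df["itc_code"] = df["itc_code"].astype(str)
    return df


def load_its_type_table() -> pd.DataFrame:
    """Per-ITS-type sequence characteristics (one row per cloned ITS type)."""
    df = _read("its_types.csv")
    df["note"] = df["note"].fillna("")
    return df


def parse_motif_cell(cell: str) -> tuple[int, bool]:
    """(number of changed positions, lost-to-deletion flag) from a motif cell.

    Cells are ``conserved``, ``not present-deletion``, or a ``;``-separated
    list of ``nt-<pos> '<base>'`` changes, possibly including a partial
    ``nt1-nt3 'deletion'`` entry.
    """
    cell = (cell or "").strip()
    if not cell or cell == "conserved":
        return 0, False
    if cell == "not present-deletion":
        return 0, True
    n_changes = 0
    deleted = False
    for token in cell.split(";"):
        token = token.strip()
        if "'deletion'" in token:
            deleted = True
        elif token.startswith("nt-"):
            n_changes += 1
    return n_changes, deleted


def its_type_features(row: pd.Series) -> dict:
    """Classifier features from one ITS-type table row."""
    n_changes = 0
    deleted = False
    for col in ("motif_m1", "motif_m2", "motif_m3"):
        c, d = parse_motif_cell(row[col])
        n_changes += c
        deleted = deleted or d
    return {
        "its2_formed": row["its2_structure"] == "four-helices",
        "r58s_formed": row["r58s_structure"] == "conserved",
        "gc_58s": float(row["gc_58s"]),
        "n_motif_changes": n_changes,
        "any_motif_deleted": deleted,
        "note_pseudogene": row["note"] == "pseudogene",
    }
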