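"""Readers and writers shared by the pipeline stages.

FASTA goes through Biopython; histograms are two-column (channel, count)
text; distance matrices are written as CSV or PHYLIP square format; each
run can emit a JSON manifest (config + seed + version) for reproducibility.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from skbio import DistanceMatrix

from .config import RunConfig
from .flowsize import FluorHistogram

__all__ = [
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "read_histogram",
    "write_distance_csv",
    "write_distance_phylip",
    "read_distance_csv",
    "write_type_report",
    "write_manifest",
]

_IUPAC = set("ACGTURYSWKMBDHVN")


class FastaParseError(ValueError):
    """Malformed FASTA record, with the offending line number."""


def _header_line_numbers(path: Path) -> dict[str, int]:
    numbers = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                label = line[1:].split(None, 1)[0].strip() if line[1:].strip() else ""
                numbers.setdefault(label, lineno)
    return numbers


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Ordered (label, uppercase sequence) pairs; validates IUPAC codes.

    Empty records and non-IUPAC characters raise :class:`FastaParseError`
    with the line number of the offending record header.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found (line 1)")
    lines = _header_line_numbers(path)
    out = []
    for rec in records:
        seq = str(rec.seq).upper()
        lineno = lines.get(rec.id, 0)
        if not seq:
            raise FastaParseError(f"{path}: empty sequence for {rec.id!r} (line {lineno})")
        bad = set(seq) - _IUPAC
        if bad:
            raise FastaParseError(
                f"{path}: non-IUPAC characters {sorted(bad)} in {rec.id!r} (line {lineno})"
            )
        out.append((rec.id, seq))
    return out


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for label, seq in records:
            fh.write(f">{label}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_histogram(path: str | Path, label: str | None = None) -> FluorHistogram:
    """Two-column (channel, count) whitespace- or comma-separated text."""
    path = Path(path)
    arr = np.loadtxt(path, delimiter=None if _is_whitespace(path) else ",")
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (channel, count)")
    return FluorHistogram.from_centers(arr[:, 0], arr[:, 1], label or path.stem)


def _is_whitespace(path: Path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return "," not in line
    return True


def write_distance_csv(path: str | Path, d: DistanceMatrix) -> None:
    pd.DataFrame(d.data, index=list(d.ids), columns=list(d.ids)).to_csv(path)


def read_distance_csv(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    return DistanceMatrix(df.to_numpy(), ids=[str(i) for i in df.index])


def write_distance_phylip(path: str | Path, d: DistanceMatrix) -> None:
    """PHYLIP square format (labels padded to 10 characters)."""
    with open(path, "w") as fh:
        fh.write(f"{len(d.ids)}\n")
        for i, label in enumerate(d.ids):
            row = " ".join(f"{v:.6f}" for v in d.data[i])
            fh.write(f"{label:<10s} {row}\n")


def write_type_report(path: str | Path, records: Sequence) -> pd.DataFrame:
    """Per-ITS-type CSV mirroring the published table layout.

    GC columns use two decimals; motif columns serialize changes in the
    ``nt-<pos> '<base>'`` notation.
    """
    rows = []
    for r in records:
        m1, m2, m3 = r.motif_report.motifs
        rows.append({
            "accession": r.accession,
            "its_type": r.type_id,
            "gc_its1": f"{r.gc_its1:.2f}",
            "gc_58s": f"{r.gc_58s:.2f}",
            "gc_its2": f"{r.gc_its2:.2f}",
            "motif_m1": m1.render_changes() or "conserved",
            "motif_m2": m2.render_changes() or "conserved",
            "motif_m3": m3.render_changes() or "conserved",
            "its2_structure": "four-helices" if r.fold_its2.formed else "not formed",
            "r58s_structure": "conserved" if r.fold_58s.formed else "not formed",
            "note": "pseudogene" if r.pseudogene else "",
            "n_reads": r.n_reads,
        })
    df = pd.DataFrame(rows, columns=[
        "accession", "its_type", "gc_its1", "gc_58s", "gc_its2",
        "motif_m1", "motif_m2", "motif_m3",
        "its2_structure", "r58s_structure", "note", "n_reads",
    ])
    df.to_csv(path, index=False)
    return df


def write_manifest(path: str | Path, config: RunConfig, extra: dict | None = None) -> None:
    """JSON manifest of config, seed and package version for re-runs."""
    from . import __version__

    data = {"version": __version__, "config": asdict(config)}
    if extra:
        data.update(extra)
    tmp = Path(str(path) + ".tmp")
    tmp.write_text(json.dumps(data, indent=2, default=str))
    tmp.replace(path)
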