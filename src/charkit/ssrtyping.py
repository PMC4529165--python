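"""SSR genotyping: binary coding, Nei's genetic distance, UPGMA dendrograms.

Allele-size profiles over up to 19 microsatellite loci are converted to a
presence/absence matrix (one column per observed locus:allele pair), from
which Nei's standard genetic distance (1972) is computed on per-accession
allele frequencies — each carried allele at a locus weighted equally — and
clustered with UPGMA.  A shared-band (Dice-complement) coefficient is
available as an alternative distance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import trees
from .trees import upgma, write_newick  # re-exported pipeline surface

__all__ = [
    "SSRProfile",
    "binarize",
    "nei_distance",
    "upgma",
    "write_newick",
    "DEFAULT_DISTANCE_CAP",
]

#: Cap substituted for an infinite Nei distance (no shared alleles at all).
DEFAULT_DISTANCE_CAP = 10.0


@dataclass(frozen=True)
class SSRProfile:
    """One accession's allele calls: locus -> set of allele sizes (bp)."""

    label: str
    calls: Mapping[str, frozenset[int]]

    def __post_init__(self):
        if not (1 <= len(self.calls) <= 19):
            raise ValueError("expected 1-19 loci per profile")
        flagged = [loc for loc, alleles in self.calls.items() if len(alleles) > 2]
        if flagged:
            warnings.warn(f"{self.label}: >2 alleles at {flagged} (flagged, kept)")


def binarize(profiles: Sequence[SSRProfile]) -> pd.DataFrame:
    """Presence/absence matrix over the union of observed (locus, allele) pairs.

    Rows are accessions, columns ``locus:size``; a missing locus leaves an
    all-zero block for that accession.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    columns = sorted({
        (locus, size)
        for p in profiles
        for locus, alleles in p.calls.items()
        for size in alleles
    })
    index = [p.label for p in profiles]
    data = np.zeros((len(profiles), len(columns)), dtype=int)
    col_idx = {c: i for i, c in enumerate(columns)}
    for r, p in enumerate(profiles):
        for locus, alleles in p.calls.items():
            for size in alleles:
                data[r, col_idx[(locus, size)]] = 1
    return pd.DataFrame(
        data, index=index, columns=[f"{locus}:{size}" for locus, size in columns]
    )


def _frequencies(profile: SSRProfile) -> dict[str, dict[int, float]]:
    """Within-accession allele frequencies; k carried alleles weigh 1/k each.

    A single observed allele size is treated as homozygous (frequency 1).
    """
    freqs: dict[str, dict[int, float]] = {}
    for locus, alleles in profile.calls.items():
        if not alleles:
            continue  # unscored locus
        k = len(alleles)
        freqs[locus] = {size: 1.0 / k for size in alleles}
    return freqs


def nei_distance(
    profiles: Sequence[SSRProfile],
    cap: float = DEFAULT_DISTANCE_CAP,
    method: str = "nei1972",
):
    """Pairwise genetic distances between accessions.

    ``nei1972`` is Nei's standard distance D = -ln(Jxy / sqrt(Jx * Jy))
    with the J identity terms averaged over the loci scored in both
    accessions (pairwise deletion).  A pair sharing no alleles anywhere has
    infinite D and is capped at ``cap`` with a warning.  ``shared_band``
    computes 1 - Dice similarity on the binary allele code instead.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    labels = [p.label for p in profiles]
    n = len(profiles)
    data = np.zeros((n, n))
    if method == "shared_band":
        bm = binarize(profiles).to_numpy()
        for i in range(n):
            for j in range(i + 1, n):
                shared = int(np.sum(bm[i] & bm[j]))
                total = int(bm[i].sum() + bm[j].sum())
                d = 1.0 - (2.0 * shared / total) if total else 0.0
                data[i, j] = data[j, i] = d
        return trees.distance_matrix(labels, data)
    if method != "nei1972":
        raise ValueError(f"unknown distance method {method!r}")

    freqs = [_frequencies(p) for p in profiles]
    capped = 0
    for i in range(n):
        for j in range(i + 1, n):
            shared_loci = sorted(set(freqs[i]) & set(freqs[j]))
            if not shared_loci:
                raise ValueError(
                    f"no loci scored in both {labels[i]!r} and {labels[j]!r}"
                )
            jxy = jx = jy = 0.0
            for locus in shared_loci:
                fi, fj = freqs[i][locus], freqs[j][locus]
                jxy += sum(fi.get(a, 0.0) * fj.get(a, 0.0) for a in set(fi) | set(fj))
                jx += sum(v * v for v in fi.values())
                jy += sum(v * v for v in fj.values())
            L = len(shared_loci)
            jxy, jx, jy = jxy / L, jx / L, jy / L
            if jxy == 0.0:
                capped += 1
                d = cap
            else:
                d = min(cap, -math.log(jxy / math.sqrt(jx * jy)))
            data[i, j] = data[j, i] = max(0.0, d)
    if capped:
        warnings.warn(
            f"{capped} accession pair(s) share no alleles; "
            f"infinite Nei distance capped at {cap}"
        )
    return trees.distance_matrix(labels, data)
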