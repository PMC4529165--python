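"""Default reference sequences and motifs for ITS annotation.

The three conserved 5.8S motifs are the widely used angiosperm defaults
(an ~16-nt, ~14-nt and ~10-nt block); they are configuration, not facts
about any particular dataset, and can be replaced through
:class:`charkit.config.RunConfig`.

The default 5.8S reference profile is a synthetic construct: it carries the
three motifs at fixed offsets inside designed G/C hairpins and filler, has
the canonical 155-nt length and a GC content inside the functional range.
It exists so that annotation, motif scanning and fold comparison run
without any external download; analyses of real material should supply a
curated 5.8S profile instead.
"""

from __future__ import annotations

__all__ = ["MOTIF_M1", "MOTIF_M2", "MOTIF_M3", "DEFAULT_MOTIFS", "REFERENCE_58S"]

#: Conserved angiosperm 5.8S motifs, 5' to 3'.
MOTIF_M1 = "CGATGAAGAACGTAGC"
MOTIF_M2 = "GAATTGCAGAATCC"
MOTIF_M3 = "TTTGAACGCA"

DEFAULT_MOTIFS: tuple[str, str, str] = (MOTIF_M1, MOTIF_M2, MOTIF_M3)


def _revcomp(s: str) -> str:
    return s[::-1].translate(str.maketrans("ACGT", "TGCA"))


def _hairpin(arm: str, loop: str = "AAAAA") -> str:
    return arm + loop + _revcomp(arm)


def _build_reference_58s() -> str:
    # synthetic 155-nt 5.8S: motifs in single-stranded context, two G/C
    # hairpins providing the foldable core, C/A filler tuning GC content
    parts = [
        "CACACA",               # 6
        MOTIF_M1,               # 16  -> offset 6
        "ACACA",                # 5
        _hairpin("CCGACGCACGAC"),   # 29
        "ACACA",                # 5
        MOTIF_M2,               # 14  -> offset 61
        "ACACA",                # 5
        _hairpin("CACGGACCGG"),     # 25
        "ACACA",                # 5
        MOTIF_M3,               # 10  -> offset 110
        _hairpin("CGGACGACCAGC", "AAAAA"),  # 29
        "CACACA",               # 6
    ]
    seq = "".join(parts)
    assert len(seq) == 155, len(seq)
    return seq


REFERENCE_58S = _build_reference_58s()

#: 1-based motif start offsets inside the reference 5.8S.
REFERENCE_58S_MOTIF_OFFSETS = {
    "M1": REFERENCE_58S.index(MOTIF_M1),
    "M2": REFERENCE_58S.index(MOTIF_M2),
    "M3": REFERENCE_58S.index(MOTIF_M3),
}
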