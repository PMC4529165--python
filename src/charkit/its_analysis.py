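"""Annotation and pseudogene screening of ITS1-5.8S-ITS2 sequences.

The internal transcribed spacers ITS1 and ITS2 flank the conserved 5.8S
rRNA gene.  Non-functional (pseudogenized) rDNA copies accumulate
substitutions in the conserved 5.8S motifs, lose GC content, and lose the
ability of ITS2 and 5.8S to fold into their conserved secondary
structures.  This module delineates the three regions against a 5.8S
reference profile, computes per-region GC content, scans the three
conserved 5.8S motifs, folds ITS2 and 5.8S, combines the evidence into a
putative-pseudogene call, collapses clone reads into ITS types, and
provides nucleotide diversity plus Jukes-Cantor/BioNJ phylogenetics with
bootstrap support.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import edlib
import numpy as np

from . import trees
from .fold import FoldResult, fold_58s, fold_its2
from .references import DEFAULT_MOTIFS, REFERENCE_58S

__all__ = [
    "ITSAnnotation",
    "MotifReport",
    "MotifResult",
    "ITSTypeRecord",
    "DiversityStats",
    "UnannotatableSequenceError",
    "SaturationError",
    "delineate_regions",
    "gc_content",
    "scan_58s_motifs",
    "classify_pseudogene",
    "classify_pseudogene_features",
    "collapse_to_types",
    "analyze_sequence",
    "nucleotide_diversity",
    "jukes_cantor",
    "jc_distance_matrix",
    "bionj",
    "bootstrap_support",
]

#: canonical 5.8S lengths (bp); other lengths are flagged as deletion-bearing
CANONICAL_58S_LENGTHS = (153, 155)

GAP_CHARS = "-."


class UnannotatableSequenceError(RuntimeError):
    """No credible 5.8S match found in the sequence."""


class SaturationError(ValueError):
    """Observed divergence at or beyond the Jukes-Cantor saturation bound."""


# ---------------------------------------------------------------------------
# annotation


@dataclass(frozen=True)
class ITSAnnotation:
    """Region spans of one ITS1-5.8S-ITS2 sequence (0-based, half-open)."""

    sequence: str
    its1_span: tuple[int, int]
    r58s_span: tuple[int, int]
    its2_span: tuple[int, int]
    identity_58s: float = 1.0

    def __post_init__(self):
        a, b = self.its1_span
        c, d = self.r58s_span
        e, f = self.its2_span
        if not (0 <= a <= b == c <= d == e <= f <= len(self.sequence)):
            raise ValueError("spans must be ordered, disjoint and contiguous")

    @property
    def its1(self) -> str:
        return self.sequence[slice(*self.its1_span)]

    @property
    def r58s(self) -> str:
        return self.sequence[slice(*self.r58s_span)]

    @property
    def its2(self) -> str:
        return self.sequence[slice(*self.its2_span)]

    @property
    def canonical_58s_length(self) -> bool:
        c, d = self.r58s_span
        return (d - c) in CANONICAL_58S_LENGTHS


def delineate_regions(
    seq: str,
    reference_58s: str = REFERENCE_58S,
    identity_threshold: float = 0.70,
) -> ITSAnnotation:
    """Locate the 5.8S gene and split the sequence into ITS1/5.8S/ITS2.

    The 5.8S is found by best semi-global (infix) alignment of the
    reference profile; everything upstream is ITS1 and everything
    downstream ITS2.  Raises :class:`UnannotatableSequenceError` when the
    best match falls below ``identity_threshold``.
    """
    seq = seq.upper()
    if len(seq) < 400:
        raise ValueError("sequence too short to contain ITS1-5.8S-ITS2")
    res = edlib.align(reference_58s.upper(), seq, mode="HW", task="locations")
    identity = 1.0 - res["editDistance"] / len(reference_58s)
    if identity < identity_threshold:
        raise UnannotatableSequenceError(
            f"best 5.8S match identity {identity:.2f} below {identity_threshold:.2f}"
        )
    start, end = res["locations"][0]
    end += 1  # edlib end is inclusive
    return ITSAnnotation(
        sequence=seq,
        its1_span=(0, start),
        r58s_span=(start, end),
        its2_span=(end, len(seq)),
        identity_58s=identity,
    )


def gc_content(seq: str) -> float:
    """GC percentage: 100 x (G + C + S) / (length - N count)."""
    seq = seq.upper()
    if not seq:
        raise ValueError("empty span")
    n_ambig = seq.count("N")
    denom = len(seq) - n_ambig
    if denom == 0:
        raise ValueError("span contains only ambiguous bases")
    gc = sum(seq.count(b) for b in "GCS")
    return 100.0 * gc / denom


# ---------------------------------------------------------------------------
# motif scanning


@dataclass(frozen=True)
class MotifResult:
    """Status of one conserved 5.8S motif in one sequence."""

    name: str
    status: str  # "conserved" | "changed" | "absent-deletion"
    changes: tuple[tuple[int, str], ...] = ()  # (1-based position, observed base)

    def __post_init__(self):
        if self.status == "conserved" and self.changes:
            raise ValueError("conserved motif cannot carry changes")

    def render_changes(self) -> str:
        """Table notation, e.g. ``nt-9 'A'``."""
        if self.status == "absent-deletion":
            return "not present-deletion"
        return "; ".join(f"nt-{p} '{b}'" for p, b in self.changes)


@dataclass(frozen=True)
class MotifReport:
    motifs: tuple[MotifResult, MotifResult, MotifResult]

    @property
    def n_changes(self) -> int:
        return sum(len(m.changes) for m in self.motifs)

    @property
    def any_deleted(self) -> bool:
        return any(m.status == "absent-deletion" for m in self.motifs)

    @property
    def all_conserved(self) -> bool:
        return all(m.status == "conserved" for m in self.motifs)


def _best_ungapped_match(region: str, motif: str) -> tuple[int, int]:
    """(offset, n_matches) of the best ungapped placement of motif in region."""
    best_off, best_matches = 0, -1
    L = len(motif)
    if len(region) < L:
        return 0, sum(a == b for a, b in zip(region, motif))
    for off in range(len(region) - L + 1):
        m = sum(region[off + k] == motif[k] for k in range(L))
        if m > best_matches:
            best_off, best_matches = off, m
    return best_off, best_matches


def scan_58s_motifs(
    r58s: str | ITSAnnotation,
    motif_refs: Sequence[str] = DEFAULT_MOTIFS,
    deletion_identity: float = 0.7,
) -> MotifReport:
    """Scan the 5.8S region for the three conserved motifs.

    Each motif is placed by best ungapped local match; mismatched positions
    are reported 1-based within the motif.  A best match below
    ``deletion_identity`` is reported as overlapping a deletion
    (``absent-deletion``).
    """
    if isinstance(r58s, ITSAnnotation):
        region = r58s.r58s
    else:
        region = r58s.upper()
    if not region:
        raise ValueError("5.8S span missing")
    if len(motif_refs) != 3:
        raise ValueError("exactly three motif references expected")
    results = []
    for name, motif in zip(("M1", "M2", "M3"), motif_refs):
        motif = motif.upper()
        off, matches = _best_ungapped_match(region, motif)
        if matches / len(motif) < deletion_identity:
            results.append(MotifResult(name=name, status="absent-deletion"))
            continue
        changes = tuple(
            (k + 1, region[off + k])
            for k in range(len(motif))
            if off + k < len(region) and region[off + k] != motif[k]
        )
        status = "conserved" if not changes else "changed"
        results.append(MotifResult(name=name, status=status, changes=changes))
    return MotifReport(motifs=tuple(results))


# ---------------------------------------------------------------------------
# pseudogene classification


@dataclass
class ITSTypeRecord:
    """One ITS sequence type of one accession, with all screened features."""

    accession: str
    type_id: str
    annotation: ITSAnnotation
    gc_its1: float
    gc_58s: float
    gc_its2: float
    motif_report: MotifReport
    fold_its2: FoldResult
    fold_58s: FoldResult
    pseudogene: bool = False
    reasons: tuple[str, ...] = ()
    n_reads: int = 1


#: Default thresholds of the pseudogene rule.  The GC floor sits just below
#: the lowest 5.8S GC seen in copies that retain both secondary structures;
#: the motif-change floor sits above the largest motif-change count seen in
#: structure-retaining copies, so isolated motif polymorphisms alone never
#: trigger the call.
GC_FLOOR = 48.0
CHANGES_FLOOR = 5


def classify_pseudogene_features(
    its2_formed: bool,
    r58s_formed: bool,
    gc_58s: float,
    n_motif_changes: int,
    any_motif_deleted: bool = False,
    gc_floor: float = GC_FLOOR,
    changes_floor: int = CHANGES_FLOOR,
) -> tuple[bool, tuple[str, ...]]:
    """Putative-pseudogene call from screened features.

    A copy is called a putative pseudogene when any criterion triggers:
    ITS2 fails to fold into the four-helix structure, 5.8S fails to fold
    into its conserved structure, 5.8S GC content falls below ``gc_floor``,
    at least ``changes_floor`` motif positions are changed across M1-M3, or
    a conserved motif is lost to a deletion.
    """
    reasons = []
    if not its2_formed:
        reasons.append("ITS2 secondary structure not formed")
    if not r58s_formed:
        reasons.append("5.8S secondary structure not formed")
    if gc_58s < gc_floor:
        reasons.append(f"5.8S GC content {gc_58s:.2f}% below {gc_floor:.1f}%")
    if n_motif_changes >= changes_floor:
        reasons.append(f"{n_motif_changes} motif positions changed (>= {changes_floor})")
    if any_motif_deleted:
        reasons.append("conserved motif lost to deletion")
    return bool(reasons), tuple(reasons)


def classify_pseudogene(
    record: ITSTypeRecord,
    gc_floor: float = GC_FLOOR,
    changes_floor: int = CHANGES_FLOOR,
) -> tuple[bool, tuple[str, ...]]:
    """Apply the pseudogene rule to a fully screened :class:`ITSTypeRecord`."""
    if record.fold_its2 is None or record.fold_58s is None or record.motif_report is None:
        raise ValueError("record is missing screened features")
    return classify_pseudogene_features(
        its2_formed=record.fold_its2.formed,
        r58s_formed=record.fold_58s.formed,
        gc_58s=record.gc_58s,
        n_motif_changes=record.motif_report.n_changes,
        any_motif_deleted=record.motif_report.any_deleted,
        gc_floor=gc_floor,
        changes_floor=changes_floor,
    )


def analyze_sequence(
    seq: str,
    accession: str = "",
    type_id: str = "",
    reference_58s: str = REFERENCE_58S,
    motif_refs: Sequence[str] = DEFAULT_MOTIFS,
    n_reads: int = 1,
    gc_floor: float = GC_FLOOR,
    changes_floor: int = CHANGES_FLOOR,
) -> ITSTypeRecord:
    """Full per-sequence screen: annotate, GC, motifs, folds, classify."""
    ann = delineate_regions(seq, reference_58s=reference_58s)
    report = scan_58s_motifs(ann, motif_refs=motif_refs)
    f_its2 = fold_its2(ann.its2)
    f_58s = fold_58s(ann.r58s, reference_58s)
    rec = ITSTypeRecord(
        accession=accession,
        type_id=type_id,
        annotation=ann,
        gc_its1=gc_content(ann.its1),
        gc_58s=gc_content(ann.r58s),
        gc_its2=gc_content(ann.its2),
        motif_report=report,
        fold_its2=f_its2,
        fold_58s=f_58s,
        n_reads=n_reads,
    )
    rec.pseudogene, rec.reasons = classify_pseudogene(
        rec, gc_floor=gc_floor, changes_floor=changes_floor
    )
    return rec


# ---------------------------------------------------------------------------
# type collapsing


def _pairwise_identity(a: str, b: str) -> float:
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def collapse_to_types(
    reads: Sequence[str],
    identity_threshold: float = 0.99,
) -> list[tuple[str, int]]:
    """Collapse clone reads into ITS types by single-linkage clustering.

    Reads at >= ``identity_threshold`` pairwise identity join one cluster;
    one consensus (per-column majority over reads of the modal length) is
    emitted per cluster, ordered by decreasing cluster size.  Returns
    ``(consensus, n_reads)`` pairs.
    """
    if not reads:
        raise ValueError("no reads")
    n = len(reads)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if find(i) != find(j) and _pairwise_identity(reads[i], reads[j]) >= identity_threshold:
                parent[find(i)] = find(j)

    clusters: dict[int, list[str]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(reads[i])

    out = []
    for members in clusters.values():
        modal_len = Counter(len(m) for m in members).most_common(1)[0][0]
        same = [m for m in members if len(m) == modal_len]
        consensus = "".join(
            Counter(col).most_common(1)[0][0] for col in zip(*same)
        )
        out.append((consensus, len(members)))
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


# ---------------------------------------------------------------------------
# diversity and phylogenetics


@dataclass(frozen=True)
class DiversityStats:
    n_sequences: int
    pi: float
    s: int
    n_haplotypes: int


def _pair_p_distance(a: str, b: str) -> float:
    """Proportion of differing sites, gaps excluded pairwise."""
    valid = diffs = 0
    for x, y in zip(a, b):
        if x in GAP_CHARS or y in GAP_CHARS:
            continue
        valid += 1
        if x != y:
            diffs += 1
    if valid == 0:
        raise ValueError("no shared ungapped sites")
    return diffs / valid


def nucleotide_diversity(alignment: Sequence[str]) -> DiversityStats:
    """Nucleotide diversity pi, segregating sites and haplotype count.

    ``pi`` is the average pairwise proportion of differing sites with
    pairwise gap deletion; ``s`` counts columns with at least two distinct
    non-gap states; haplotypes are exact-match groups.
    """
    seqs = [s.upper() for s in alignment]
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences must have equal (aligned) length")
    n = len(seqs)
    total = 0.0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += _pair_p_distance(seqs[i], seqs[j])
            pairs += 1
    s_count = 0
    for col in zip(*seqs):
        states = {c for c in col if c not in GAP_CHARS}
        if len(states) >= 2:
            s_count += 1
    return DiversityStats(
        n_sequences=n,
        pi=total / pairs,
        s=s_count,
        n_haplotypes=len(set(seqs)),
    )


def jukes_cantor(d_obs: float, cap: float | None = None) -> float:
    """Jukes-Cantor distance: -(3/4) ln(1 - (4/3) p).

    ``p`` must lie in [0, 0.75); at or beyond saturation either raises
    :class:`SaturationError` or returns ``cap`` when one is configured.
    """
    if d_obs < 0:
        raise ValueError("proportion of differing sites cannot be negative")
    if d_obs >= 0.75:
        if cap is not None:
            return cap
        raise SaturationError(f"observed difference {d_obs} is saturated (>= 0.75)")
    return -0.75 * math.log1p(-4.0 * d_obs / 3.0)


def jc_distance_matrix(
    labels: Sequence[str],
    alignment: Sequence[str],
    cap: float | None = None,
):
    """Labelled Jukes-Cantor distance matrix from an alignment."""
    n = len(alignment)
    data = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = jukes_cantor(_pair_p_distance(alignment[i], alignment[j]), cap=cap)
            data[i, j] = data[j, i] = d
    return trees.distance_matrix(labels, data)


bionj = trees.bionj


def bootstrap_support(
    labels: Sequence[str],
    alignment: Sequence[str],
    n_reps: int = 1000,
    seed: int = 0,
    cap: float | None = 5.0,
):
    """BioNJ tree with non-parametric bootstrap supports.

    Alignment columns are resampled with replacement ``n_reps`` times; each
    pseudoreplicate is rebuilt with Jukes-Cantor distances and BioNJ, and
    each internal edge of the full-data tree is annotated with the
    percentage of replicates containing the same leaf bipartition.
    Deterministic under a fixed ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if len(alignment) < 4:
        raise ValueError("need at least 4 sequences")
    L = len(alignment[0])
    cols = [list(col) for col in zip(*alignment)]
    full = bionj(jc_distance_matrix(labels, alignment, cap=cap))
    counts: dict[frozenset[str], int] = {p: 0 for p in trees.bipartitions(full)}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        idx = rng.integers(0, L, size=L)
        rep_aln = ["".join(cols[i][r] for i in idx) for r in range(len(alignment))]
        try:
            rep_tree = bionj(jc_distance_matrix(labels, rep_aln, cap=cap))
        except ValueError:
            continue
        for part in trees.bipartitions(rep_tree):
            if part in counts:
                counts[part] += 1
    all_leaves = frozenset(labels)
    for node in full.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        canon = min(side, all_leaves - side, key=lambda s: (len(s), sorted(s)))
        if canon in counts:
            node.name = f"{100.0 * counts[canon] / n_reps:.0f}"
    return full
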