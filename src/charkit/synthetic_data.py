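"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators emulate the data the characterization pipeline consumes:

* flow-cytometry histograms — two Gaussian G1 peaks (sample + internal
  standard at 2C = 2.5 pg) over a 1024-channel linear scale, with optional
  uniform debris;
* SSR allele panels — 19 microsatellite loci with planted group structure
  (within-group allele sharing far above between-group sharing);
* ITS clone families — an ITS1-5.8S-ITS2 template whose ITS2 folds into a
  designed four-helix structure (TGGT on helix III, pyrimidine-pyrimidine
  mismatch in helix II) and whose 5.8S carries the three conserved motifs;
  derived types apply motif disruptions, helix-arm scrambles, GC erosion
  or deletions, and clone reads carry uniform sequencing errors.

Every generator is deterministic under a fixed seed, and each returns a
truth record sufficient to score the downstream stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .flowsize import FluorHistogram
from .references import DEFAULT_MOTIFS, REFERENCE_58S, REFERENCE_58S_MOTIF_OFFSETS
from .ssrtyping import SSRProfile

__all__ = [
    "FlowSimSpec",
    "FlowTruth",
    "gen_flow_histogram",
    "SSRSimSpec",
    "gen_ssr_panel",
    "ITSSimSpec",
    "ITSTypeSpec",
    "ITSTypeTruth",
    "gen_its_family",
    "ITS2_TEMPLATE",
    "ITS2_HELIX3_ARM_SPAN",
]


# ---------------------------------------------------------------------------
# flow cytometry


@dataclass(frozen=True)
class FlowSimSpec:
    """Simulation settings for one two-peak G1 histogram."""

    true_2c_pg: float
    standard_2c_pg: float = 2.5
    cv_percent: float = 2.0
    n_nuclei: int = 5000
    debris_fraction: float = 0.0
    n_bins: int = 1024
    standard_channel: float = 500.0
    seed: int = 0

    def __post_init__(self):
        if self.cv_percent <= 0:
            raise ValueError("cv must be positive")
        if not (0 <= self.debris_fraction < 0.5):
            raise ValueError("debris_fraction must lie in [0, 0.5)")


@dataclass(frozen=True)
class FlowTruth:
    musa_channel: float
    standard_channel: float
    true_2c_pg: float


def gen_flow_histogram(spec: FlowSimSpec) -> tuple[FluorHistogram, FlowTruth]:
    """Simulate a bimodal G1 histogram of sample plus internal standard."""
    rng = np.random.default_rng(spec.seed)
    musa_channel = spec.standard_channel * spec.true_2c_pg / spec.standard_2c_pg
    sep = abs(musa_channel - spec.standard_channel)
    width = (spec.cv_percent / 100.0) * max(musa_channel, spec.standard_channel)
    if sep < 2 * width:
        warnings.warn("G1 peaks overlap within 2 CV; spec may be unresolvable")
    n_debris = int(spec.debris_fraction * 2 * spec.n_nuclei)
    values = np.concatenate([
        rng.normal(musa_channel, musa_channel * spec.cv_percent / 100.0, spec.n_nuclei),
        rng.normal(spec.standard_channel, spec.standard_channel * spec.cv_percent / 100.0,
                   spec.n_nuclei),
        rng.uniform(0, spec.n_bins, n_debris),
    ])
    edges = np.arange(spec.n_bins + 1, dtype=float)
    counts, _ = np.histogram(values, bins=edges)
    hist = FluorHistogram(edges, counts.astype(float), label=f"sim-2C-{spec.true_2c_pg}")
    return hist, FlowTruth(musa_channel, spec.standard_channel, spec.true_2c_pg)


# ---------------------------------------------------------------------------
# SSR panels


@dataclass(frozen=True)
class SSRSimSpec:
    """Planted two-level group structure over microsatellite loci."""

    n_groups: int = 2
    accessions_per_group: int = 5
    n_loci: int = 19
    alleles_per_locus: int = 8
    within_sharing: float = 0.9
    between_sharing: float = 0.05
    heterozygosity: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.between_sharing <= 1 and 0 <= self.within_sharing <= 1):
            raise ValueError("sharing probabilities must lie in [0, 1]")
        if self.within_sharing <= self.between_sharing:
            raise ValueError("within-group sharing must exceed between-group sharing")


def gen_ssr_panel(spec: SSRSimSpec) -> tuple[list[SSRProfile], dict[str, int]]:
    """Simulate SSR profiles with planted groups.

    Each group owns a core allele pair at every locus; an accession carries
    its group's core with probability ``within_sharing`` and otherwise
    draws from the common pool.  At a ``between_sharing`` fraction of loci
    the core is shared across groups (a conserved locus), which is the
    planted source of between-group similarity.  Returns the profiles and
    the truth map accession -> group index.
    """
    rng = np.random.default_rng(spec.seed)
    pools = []
    for locus in range(spec.n_loci):
        base = 100 + 20 * locus
        pools.append([base + 2 * k for k in range(spec.alleles_per_locus)])
    # core alleles per group at each locus; occasionally conserved across groups
    cores: list[list[tuple[int, int]]] = []
    for locus in range(spec.n_loci):
        if rng.random() < spec.between_sharing:
            picks = rng.choice(spec.alleles_per_locus, size=2, replace=False)
            cores.append([
                (pools[locus][picks[0]], pools[locus][picks[1]])
            ] * spec.n_groups)
        else:
            picks = rng.choice(spec.alleles_per_locus, size=2 * spec.n_groups,
                               replace=False)
            cores.append([
                (pools[locus][picks[2 * g]], pools[locus][picks[2 * g + 1]])
                for g in range(spec.n_groups)
            ])
    profiles: list[SSRProfile] = []
    truth: dict[str, int] = {}
    for g in range(spec.n_groups):
        for a in range(spec.accessions_per_group):
            label = f"G{g + 1}_A{a + 1}"
            calls: dict[str, frozenset[int]] = {}
            for locus in range(spec.n_loci):
                primary, secondary = cores[locus][g]
                alleles = set()
                if rng.random() < spec.within_sharing:
                    alleles.add(primary)
                else:
                    alleles.add(int(rng.choice(pools[locus])))
                if rng.random() < spec.heterozygosity:
                    alleles.add(secondary)
                calls[f"L{locus + 1:02d}"] = frozenset(alleles)
            profiles.append(SSRProfile(label=label, calls=calls))
            truth[label] = g
    return profiles, truth


# ---------------------------------------------------------------------------
# ITS families


def _revcomp(s: str) -> str:
    return s[::-1].translate(str.maketrans("ACGT", "TGCA"))


def _poisoned_arm(n: int, g_offsets: Sequence[int]) -> str:
    arm = ["C"] * n
    for o in g_offsets:
        arm[o] = "G"
    return "".join(arm)


def _helix(a5: str, loop: str = "AAAAA", mismatch_at: int | None = None) -> str:
    """Hairpin from a 5' arm; optional C·C mismatch inserted at ``mismatch_at``."""
    a3 = _revcomp(a5)
    if mismatch_at is not None:
        p = mismatch_at
        a5 = a5[:p] + "C" + a5[p:]
        a3 = a3[: len(a3) - p] + "C" + a3[len(a3) - p:]
    return a5 + loop + a3


def _build_its2_template() -> tuple[str, tuple[int, int]]:
    """Designed four-helix ITS2 (210 nt) and the span of the helix III 5' arm.

    The four stems are C-backbone arms poisoned with G at helix-specific
    offsets (3' arms are exact reverse complements), joined by inert all-A
    linkers; helix II carries a C·C pyrimidine mismatch and helix III the
    conserved TGGT on its 5' arm.
    """
    linker = "A" * 12
    h1 = _helix(_poisoned_arm(16, [2, 7, 11]))
    h2 = _helix(_poisoned_arm(15, [4, 9, 13]), mismatch_at=7)
    helix3_arm = _poisoned_arm(10, [1, 6]) + "TGGT" + _poisoned_arm(9, [3, 8])
    h3 = _helix(helix3_arm)
    h4 = _helix(_poisoned_arm(14, [0, 5, 10]))
    seq = linker + h1 + linker + h2 + linker + h3 + linker + h4 + "AAAA"
    start = seq.index(helix3_arm)
    return seq, (start, start + len(helix3_arm))


ITS2_TEMPLATE, ITS2_HELIX3_ARM_SPAN = _build_its2_template()


def _random_spacer(rng: np.random.Generator, length: int, gc: float) -> str:
    bases = np.array(list("GCAT"))
    p = np.array([gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2])
    return "".join(rng.choice(bases, size=length, p=p))


@dataclass(frozen=True)
class ITSTypeSpec:
    """Edits deriving one ITS type from the functional template.

    ``kind`` is a label recorded in the truth; the edit fields drive the
    construction.  ``motif_changes`` are (motif name, 1-based position,
    new base).  ``helix3_scramble`` destroys the ITS2 fold,
    ``gc_erosion`` converts that fraction of 5.8S G/C positions to A/T,
    and ``deletion_58s`` removes that many nucleotides from the 5.8S.
    """

    kind: str = "functional"
    motif_changes: tuple[tuple[str, int, str], ...] = ()
    helix3_scramble: bool = False
    gc_erosion: float = 0.0
    deletion_58s: int = 0
    n_divergent_sites: int = 0  # neutral ITS1 substitutions marking the type


@dataclass(frozen=True)
class ITSSimSpec:
    """One accession's simulated clone family."""

    accession: str = "SYN1"
    its1_length: int = 219
    type_specs: tuple[ITSTypeSpec, ...] = (ITSTypeSpec(),)
    reads_per_accession: int = 28
    read_error_rate: float = 0.001
    its1_gc: float = 0.61
    seed: int = 0

    def __post_init__(self):
        if not (215 <= self.its1_length <= 223):
            raise ValueError("ITS1 length must lie in [215, 223]")
        if not self.type_specs:
            raise ValueError("need at least one type spec")


@dataclass(frozen=True)
class ITSTypeTruth:
    type_id: str
    kind: str
    sequence: str
    n_reads: int
    pseudogene: bool
    motif_status: tuple[str, str, str]
    its2_formed: bool
    gc_58s: float


def _scramble_helix3(its2: str, rng: np.random.Generator, max_tries: int = 10) -> str:
    """Permute the helix III 5' arm until the four-helix fold is destroyed.

    A permutation preserves base composition, so occasionally the arm still
    pairs its complement; the generator folds the candidate and retries so
    the planted truth (ITS2 not formed) holds for every seed.
    """
    from .fold import fold_its2

    a, b = ITS2_HELIX3_ARM_SPAN
    for _ in range(max_tries):
        scrambled = "".join(rng.permutation(list(its2[a:b])))
        candidate = its2[:a] + scrambled + its2[b:]
        if not fold_its2(candidate).formed:
            return candidate
    raise RuntimeError("could not scramble helix III into a broken fold")


def _erode_gc(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i, b in enumerate(out):
        if b in "GC" and rng.random() < rate:
            out[i] = "A" if rng.random() < 0.5 else "T"
    return "".join(out)


def gen_its_family(spec: ITSSimSpec) -> tuple[list[tuple[str, str]], list[ITSTypeTruth]]:
    """Simulate one accession's clone reads and the per-type truth.

    Reads are labelled ``<accession>_clone<k>``; the truth lists each
    planted type's sequence, expected motif statuses, expected ITS2 fold
    outcome and pseudogene label.  The pseudogene truth follows the design
    intent of the edits: a type is planted as pseudogenic when its ITS2
    fold is destroyed, its 5.8S is eroded below the functional GC range,
    or a deletion removes part of the gene.
    """
    rng = np.random.default_rng(spec.seed)
    its1 = _random_spacer(rng, spec.its1_length, spec.its1_gc)
    motifs = dict(zip(("M1", "M2", "M3"), DEFAULT_MOTIFS))

    truths: list[ITSTypeTruth] = []
    sequences: list[str] = []
    n_types = len(spec.type_specs)
    base_reads = spec.reads_per_accession // n_types
    extra = spec.reads_per_accession % n_types

    for t_idx, tspec in enumerate(spec.type_specs):
        r58s = REFERENCE_58S
        # motif disruptions
        status = {"M1": "conserved", "M2": "conserved", "M3": "conserved"}
        for motif_name, pos, base in tspec.motif_changes:
            off = REFERENCE_58S_MOTIF_OFFSETS[motif_name] + pos - 1
            if r58s[off] == base:
                raise ValueError(f"change at {motif_name} nt-{pos} does not alter the base")
            r58s = r58s[:off] + base + r58s[off + 1:]
            status[motif_name] = "changed"
        if tspec.gc_erosion > 0:
            r58s = _erode_gc(r58s, tspec.gc_erosion, rng)
            status = {m: "eroded" for m in status}  # statuses unpredictable
        if tspec.deletion_58s > 0:
            if tspec.deletion_58s >= len(r58s):
                raise ValueError("deletion exceeds 5.8S length")
            # remove nucleotides from inside the first hairpin, away from motifs
            cut = REFERENCE_58S_MOTIF_OFFSETS["M1"] + len(motifs["M1"]) + 8
            r58s = r58s[:cut] + r58s[cut + tspec.deletion_58s:]

        its2 = ITS2_TEMPLATE
        if tspec.helix3_scramble:
            its2 = _scramble_helix3(its2, rng)

        # neutral divergence marking this type, confined to ITS1
        t_its1 = its1
        if tspec.n_divergent_sites:
            positions = rng.choice(len(t_its1), size=tspec.n_divergent_sites, replace=False)
            t_its1 = list(t_its1)
            for p in positions:
                t_its1[p] = rng.choice([b for b in "ACGT" if b != t_its1[p]])
            t_its1 = "".join(t_its1)

        seq = t_its1 + r58s + its2
        gc_58s = 100.0 * sum(b in "GC" for b in r58s) / len(r58s)
        pseudogene = bool(
            tspec.helix3_scramble or tspec.deletion_58s or gc_58s < 48.0
        )
        n_reads = base_reads + (1 if t_idx < extra else 0)
        truths.append(ITSTypeTruth(
            type_id=f"type{t_idx + 1}",
            kind=tspec.kind,
            sequence=seq,
            n_reads=n_reads,
            pseudogene=pseudogene,
            motif_status=(status["M1"], status["M2"], status["M3"]),
            its2_formed=not tspec.helix3_scramble,
            gc_58s=gc_58s,
        ))
        sequences.append(seq)

    reads: list[tuple[str, str]] = []
    clone = 1
    for truth, seq in zip(truths, sequences):
        for _ in range(truth.n_reads):
            read = list(seq)
            for i in range(len(read)):
                if rng.random() < spec.read_error_rate:
                    read[i] = rng.choice([b for b in "ACGT" if b != read[i]])
            reads.append((f"{spec.accession}_clone{clone:03d}", "".join(read)))
            clone += 1
    return reads, truths
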