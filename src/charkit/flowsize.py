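"""Flow-cytometric genome-size estimation with an internal standard.

A chopped leaf sample contains nuclei of the target accession together with
nuclei of a co-chopped internal standard of known DNA amount (soybean,
2C = 2.5 pg).  The fluorescence histogram of propidium-iodide stained nuclei
shows two dominant G1 peaks; the ratio of their positions converts directly
into the 2C DNA content of the target.  This module fits the G1 peaks,
performs the pg -> Mbp conversion (1 pg = 978 Mbp), aggregates replicate
plants, and provides the statistical comparisons used on such panels:
all-pairwise Bonferroni letter grouping and tie-corrected Spearman rank
correlation between chromosome number and DNA content.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "FluorHistogram",
    "PeakFit",
    "DNAContentEstimate",
    "AccessionRecord",
    "PeaksUnresolvedError",
    "detect_g1_peaks",
    "compute_2c",
    "pg_to_mbp",
    "round_half_up",
    "aggregate_replicates",
    "reconstruct_plant_means",
    "bonferroni_letter_groups",
    "spearman_r",
]

#: Soybean (Glycine max) internal reference standard, 2C DNA amount in pg.
STANDARD_2C_PG = 2.5

#: Mbp of double-stranded DNA per picogram (0.978 x 10^9 bp/pg).
MBP_PER_PG = 978.0


class PeaksUnresolvedError(RuntimeError):
    """Fewer resolvable G1 peaks than requested."""


@dataclass(frozen=True)
class FluorHistogram:
    """Binned fluorescence intensities for one chopped sample."""

    bin_edges: np.ndarray
    counts: np.ndarray
    label: str = ""

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        if edges.ndim != 1 or counts.ndim != 1:
            raise ValueError("bin_edges and counts must be 1-D")
        if len(counts) != len(edges) - 1:
            raise ValueError("len(counts) must equal len(bin_edges) - 1")
        if len(counts) < 2:
            raise ValueError("histogram needs at least 2 bins")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @classmethod
    def from_centers(cls, centers, counts, label: str = "") -> "FluorHistogram":
        """Build from (bin_center, count) columns assuming uniform bin width."""
        centers = np.asarray(centers, dtype=float)
        if len(centers) < 2:
            raise ValueError("need at least 2 bins")
        width = np.median(np.diff(centers))
        edges = np.concatenate([centers - width / 2, [centers[-1] + width / 2]])
        return cls(edges, np.asarray(counts, dtype=float), label)


@dataclass(frozen=True)
class PeakFit:
    """A fitted G1 peak: position, spread, and attributed nuclei."""

    mean: float
    cv: float  # coefficient of variation, percent
    nuclei: float

    def __post_init__(self):
        if self.cv <= 0:
            raise ValueError("cv must be positive")


@dataclass(frozen=True)
class DNAContentEstimate:
    """Accession-level 2C estimate aggregated over replicate plants."""

    two_c_pg: float
    sd_pg: float
    n_plants: int
    monoploid_mbp: int

    def __post_init__(self):
        if self.two_c_pg <= 0:
            raise ValueError("two_c_pg must be positive")
        if self.sd_pg < 0:
            raise ValueError("sd_pg must be non-negative")


@dataclass
class AccessionRecord:
    """Per-accession metadata: genome size, chromosome number, rDNA loci."""

    name: str
    itc_code: str
    section: str
    estimate: DNAContentEstimate
    two_n: int | None = None
    n_45s_loci: int | None = None
    n_5s_loci: int | None = None
    bonferroni_letters: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.two_n is not None and self.two_n not in (18, 20, 22):
            raise ValueError("2n must be 18, 20 or 22 for these diploids")
        for v in (self.n_45s_loci, self.n_5s_loci):
            if v is not None and v < 0:
                raise ValueError("rDNA locus counts must be non-negative")


def _gaussian(x, amp, mu, sigma):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def detect_g1_peaks(
    hist: FluorHistogram,
    n_expected: int,
    smooth_window: int = 5,
    noise_floor: float = 0.05,
    min_separation: int = 10,
) -> list[PeakFit]:
    """Locate and Gaussian-fit the ``n_expected`` dominant G1 peaks.

    The histogram is smoothed with a moving average of ``smooth_window``
    bins; local maxima above ``noise_floor`` times the global maximum are
    candidate peaks.  The tallest candidates at least ``min_separation``
    bins apart are each fitted with a least-squares Gaussian over a window
    of three half-widths at half height around the maximum.  Returned
    sorted by fitted mean.
    """
    if n_expected < 1:
        raise ValueError("n_expected must be >= 1")
    counts = hist.counts
    if counts.sum() == 0:
        raise ValueError("empty histogram")
    x = hist.bin_centers
    kernel = np.ones(smooth_window) / smooth_window
    smooth = np.convolve(counts, kernel, mode="same")
    floor = noise_floor * smooth.max()

    candidates = []  # (height, index)
    for i in range(1, len(smooth) - 1):
        if smooth[i] >= smooth[i - 1] and smooth[i] > smooth[i + 1] and smooth[i] > floor:
            candidates.append((smooth[i], i))
    # suppress shoulders: keep a candidate only if it is the maximum within
    # the smoothing window
    half = max(1, smooth_window // 2)
    peaks = [
        (h, i)
        for h, i in candidates
        if smooth[i] == smooth[max(0, i - half): i + half + 1].max()
    ]
    peaks.sort(reverse=True)
    # greedy selection with a minimum separation, so noise twins on a
    # peak's flank are not reported as independent peaks
    selected: list[tuple[float, int]] = []
    for h, i in peaks:
        if all(abs(i - j) >= min_separation for _, j in selected):
            selected.append((h, i))
    if len(selected) < n_expected:
        raise PeaksUnresolvedError(
            f"found {len(selected)} resolvable peaks, expected {n_expected}"
        )

    fits: list[PeakFit] = []
    for _, idx in selected[:n_expected]:
        # half-width at half height of the smoothed peak
        h2 = smooth[idx] / 2
        left = idx
        while left > 0 and smooth[left] > h2:
            left -= 1
        right = idx
        while right < len(smooth) - 1 and smooth[right] > h2:
            right += 1
        hw = max(idx - left, right - idx, 2)
        lo, hi = max(0, idx - 3 * hw), min(len(x), idx + 3 * hw + 1)
        xs, ys = x[lo:hi], counts[lo:hi]
        p0 = (counts[idx], x[idx], hw * (x[1] - x[0]))
        try:
            popt, _ = optimize.curve_fit(_gaussian, xs, ys, p0=p0, maxfev=10000)
        except RuntimeError:
            popt = p0
        amp, mu, sigma = popt
        sigma = abs(sigma)
        if not (x[0] <= mu <= x[-1]) or sigma == 0:
            raise PeaksUnresolvedError(f"Gaussian fit diverged near channel {x[idx]:.0f}")
        nuclei = min(float(ys.sum()), float(counts.sum()))
        fits.append(PeakFit(mean=float(mu), cv=float(100 * sigma / mu), nuclei=nuclei))
    fits.sort(key=lambda p: p.mean)
    return fits


def compute_2c(
    musa_peak_mean: float,
    standard_peak_mean: float,
    standard_2c_pg: float = STANDARD_2C_PG,
) -> float:
    """2C DNA content (pg) from the ratio of sample and standard G1 peaks."""
    if musa_peak_mean <= 0 or standard_peak_mean <= 0:
        raise ValueError("peak means must be positive")
    return standard_2c_pg * musa_peak_mean / standard_peak_mean


def pg_to_mbp(pg: float) -> float:
    """Convert a DNA amount in pg to Mbp (1 pg = 978 Mbp)."""
    if pg < 0:
        raise ValueError("pg must be non-negative")
    return pg * MBP_PER_PG


def round_half_up(x: float) -> int:
    """Round to nearest integer with ties going up (table convention)."""
    return math.floor(x + 0.5)


def aggregate_replicates(per_plant_measurements: Sequence[Sequence[float]]) -> DNAContentEstimate:
    """Aggregate repeated 2C measurements into an accession estimate.

    ``per_plant_measurements[i]`` holds the replicate measurements of plant
    ``i``.  Plant means are computed first; the accession mean and sample SD
    are taken across plant means, matching a design of three plants measured
    on three different days.
    """
    if not per_plant_measurements or any(len(p) == 0 for p in per_plant_measurements):
        raise ValueError("each plant needs at least one measurement")
    plant_means = np.array([np.mean(p) for p in per_plant_measurements], dtype=float)
    mean = float(plant_means.mean())
    sd = float(plant_means.std(ddof=1)) if len(plant_means) > 1 else 0.0
    return DNAContentEstimate(
        two_c_pg=mean,
        sd_pg=sd,
        n_plants=len(plant_means),
        monoploid_mbp=round_half_up(pg_to_mbp(mean / 2)),
    )


def reconstruct_plant_means(
    mean: float, sd: float, sd_of: str = "measurements", n_measurements_per_plant: int = 3
) -> list[float]:
    """Deterministic triplet of plant means consistent with a printed mean +/- SD.

    ``{m - s', m, m + s'}`` has sample mean ``m`` and sample SD exactly
    ``s'``.  With ``sd_of="plant_means"`` the printed SD is taken to be the
    SD of the three plant means (``s' = s``).  With the default
    ``sd_of="measurements"`` the printed SD is read as the SD of all
    individual measurements, so each plant mean (an average of
    ``n_measurements_per_plant`` measurements) carries
    ``s' = s / sqrt(n_measurements_per_plant)``.
    """
    if sd_of == "plant_means":
        s = sd
    elif sd_of == "measurements":
        s = sd / math.sqrt(n_measurements_per_plant)
    else:
        raise ValueError("sd_of must be 'plant_means' or 'measurements'")
    return [mean - s, mean, mean + s]


def _pairwise_significance(
    samples: Mapping[str, Sequence[float]], alpha: float, adjust: bool
) -> set[tuple[str, str]]:
    """All-pairwise t-tests on the pooled one-way-ANOVA error MS."""
    labels = list(samples)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    ns = {}
    means = {}
    sse = 0.0
    for lab in labels:
        vals = np.asarray(samples[lab], dtype=float)
        if len(vals) < 2:
            raise ValueError(f"group {lab!r} needs >= 2 values to test")
        ns[lab] = len(vals)
        means[lab] = vals.mean()
        sse += float(((vals - vals.mean()) ** 2).sum())
    dfe = sum(ns.values()) - k
    mse = sse / dfe
    n_comp = k * (k - 1) // 2
    sig: set[tuple[str, str]] = set()
    for a, b in combinations(labels, 2):
        se = math.sqrt(mse * (1 / ns[a] + 1 / ns[b]))
        if se == 0:
            significant = means[a] != means[b]
        else:
            t = abs(means[a] - means[b]) / se
            p = 2 * stats.t.sf(t, dfe)
            if adjust:
                p = min(1.0, p * n_comp)
            significant = p < alpha
        if significant:
            sig.add((a, b))
            sig.add((b, a))
    return sig


def bonferroni_letter_groups(
    samples: Mapping[str, Sequence[float]],
    alpha: float = 0.01,
    adjust: bool = True,
) -> dict[str, frozenset[str]]:
    """Compact letter display from all-pairwise Bonferroni comparisons.

    Groups sharing a letter are not significantly different at familywise
    level ``alpha`` (Bonferroni-adjusted pairwise t-tests on the pooled
    ANOVA error MS; set ``adjust=False`` for per-comparison testing).
    Letters are assigned by the insert-and-absorb algorithm in ascending
    order of group mean.
    """
    sig = _pairwise_significance(samples, alpha, adjust)
    means = {lab: float(np.mean(samples[lab])) for lab in samples}
    order = sorted(samples, key=lambda lab: means[lab])
    letter_sets: list[set[str]] = []
    for lab in order:
        placed = False
        for s in letter_sets:
            if all((lab, other) not in sig for other in s):
                s.add(lab)
                placed = True
        if not placed:
            letter_sets.append({lab})
    # absorb letter sets wholly contained in another
    letter_sets = [
        s for s in letter_sets if not any(s < other for other in letter_sets if other is not s)
    ]
    letter_sets.sort(key=lambda s: min(means[lab] for lab in s))
    if len(letter_sets) > 26:
        raise ValueError("more than 26 letter groups")
    out: dict[str, set[str]] = {lab: set() for lab in samples}
    for i, s in enumerate(letter_sets):
        letter = chr(ord("A") + i)
        for lab in s:
            out[lab].add(letter)
    return {lab: frozenset(v) for lab, v in out.items()}


def n_letter_groups(letters: Mapping[str, frozenset[str]]) -> int:
    """Number of distinct letters in a compact letter display."""
    return len(set().union(*letters.values()))


def spearman_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Tie-corrected Spearman rank correlation (Pearson on average ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])
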