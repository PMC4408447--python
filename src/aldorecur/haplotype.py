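"""Shared-haplotype intervals and mutation-age estimation around a focal variant.

When the same rare mutation is found in several kindreds, the extent of the
haplotype they share around it discriminates a recent common ancestor (long
shared segment) from independent recurrence or very remote ancestry (short
or absent sharing).  Two interval statistics are provided:

* the **phased shared interval** — scanning outward from the focal variant,
  the innermost marker on each side at which any pair of carrier haplotypes
  is discordant bounds the maximal interval that could be shared identically
  by descent by all carriers;
* the **unphased homozygous-discordant bound** — without phase, the only
  genotype configuration that *excludes* sharing is two carriers homozygous
  for different alleles; the nearest such marker on each side gives a
  conservative (wider) bound that always contains the phased interval.

Generations to the carriers' most recent common ancestor are estimated by a
maximum-likelihood model in the spirit of recombination-clock estimators
(ESTIAGE and relatives): on each side of the focal variant, the ancestral
segment survives ``g`` meioses to marker ``k`` with probability
``(1 - theta_k)**g`` (``theta`` from the Haldane map function), beyond the
recombination breakpoint alleles match the ancestral haplotype only by
chance (population frequency ``f_m``), and a marker may also be discordant
through marker mutation.  The first observed discordance per carrier per
side is the datum; sides are treated as independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMap",
    "PhasedHaplotype",
    "SharedInterval",
    "SideObservation",
    "CarrierSharingObs",
    "AgeEstimate",
    "recomb_fraction",
    "shared_interval_phased",
    "discordance_bound_unphased",
    "consensus_ancestral",
    "observations_from_haplotypes",
    "sharing_log_likelihood",
    "estimate_age",
    "read_plink_map",
    "read_haplotypes_tsv",
    "read_genotypes_tsv",
]

Side = Literal["left", "right"]

CHI2_1_95_HALF = 3.841458820694124 / 2.0  # chi-square(1) 95% quantile / 2


def recomb_fraction(distance_bp: float, rate_cM_per_Mb: float = 2.9) -> float:
    """Recombination fraction over a physical distance via the Haldane map.

    ``theta = (1 - exp(-2 d)) / 2`` with ``d`` the map distance in Morgans,
    ``d = distance_bp * rate * 1e-8`` for a rate in cM/Mb.  Monotone in
    distance and bounded by 1/2.
    """
    if distance_bp < 0:
        raise ValueError("distance must be non-negative")
    morgans = distance_bp * rate_cM_per_Mb * 1e-8
    return 0.5 * -math.expm1(-2.0 * morgans)


@dataclass
class MarkerMap:
    """Ordered markers flanking a focal variant.

    Attributes
    ----------
    ids:
        Marker identifiers, in physical order.
    positions:
        1-based bp positions, strictly increasing.
    freqs:
        Population frequency of the *ancestral-haplotype* allele at each
        marker (the chance-match probability), each in (0, 1].
    focal_bp:
        Position of the focal variant; must lie strictly inside the map and
        not on a marker.
    rate_cM_per_Mb:
        Average recombination rate across the interval.
    mu_m:
        Per-marker per-generation mutation rate.
    """

    ids: list[str]
    positions: np.ndarray
    freqs: np.ndarray
    focal_bp: int
    rate_cM_per_Mb: float = 2.9
    mu_m: float = 2e-8

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if len(self.ids) != len(self.positions) or len(self.ids) != len(self.freqs):
            raise ValueError("ids, positions and freqs must have equal length")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("marker positions must be strictly increasing")
        if np.any((self.freqs <= 0) | (self.freqs > 1)):
            raise ValueError("allele frequencies must lie in (0, 1]")
        if not self.positions.min() < self.focal_bp < self.positions.max():
            raise ValueError("focal position must lie strictly inside the map")
        if self.focal_bp in self.positions:
            raise ValueError("focal position must not coincide with a marker")

    def __len__(self) -> int:
        return len(self.ids)

    def side_indices(self, side: Side) -> np.ndarray:
        """Marker indices on one side, ordered outward from the focal variant."""
        if side == "left":
            idx = np.where(self.positions < self.focal_bp)[0]
            return idx[::-1]
        idx = np.where(self.positions > self.focal_bp)[0]
        return idx

    def side_thetas(self, side: Side) -> np.ndarray:
        """Recombination fractions from the focal variant to each outward marker."""
        idx = self.side_indices(side)
        dists = np.abs(self.positions[idx] - self.focal_bp)
        return np.array([recomb_fraction(d, self.rate_cM_per_Mb) for d in dists])

    def side_freqs(self, side: Side) -> np.ndarray:
        return self.freqs[self.side_indices(side)]


@dataclass(frozen=True)
class PhasedHaplotype:
    """One phased haplotype aligned to a marker map."""

    subject: str
    alleles: tuple
    carries_focal: bool = True

    @staticmethod
    def from_sequence(subject: str, alleles: Sequence, carries_focal: bool = True):
        return PhasedHaplotype(subject, tuple(alleles), carries_focal)


@dataclass(frozen=True)
class SharedInterval:
    """Interval bounded by the innermost discordant markers on each side."""

    start: int
    end: int
    left_marker: str | None
    right_marker: str | None
    censored_left: bool = False  # no discordance found: bound is the map edge
    censored_right: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def censored(self) -> bool:
        return self.censored_left or self.censored_right


@dataclass(frozen=True)
class SideObservation:
    """First discordance from the ancestral haplotype for one carrier side.

    ``j`` is the 1-based outward marker index of the first discordant marker,
    or ``None`` when the carrier is concordant through the last typed marker
    (censored).
    """

    carrier: str
    side: Side
    j: int | None

    @property
    def censored(self) -> bool:
        return self.j is None


@dataclass
class CarrierSharingObs:
    """Collection of per-carrier, per-side first-discordance observations."""

    observations: list[SideObservation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.observations:
            raise ValueError("empty observation set")

    def __iter__(self):
        return iter(self.observations)

    def __len__(self) -> int:
        return len(self.observations)


@dataclass
class AgeEstimate:
    """Maximum-likelihood age (generations to the MRCA) with profile CI."""

    g_hat: int
    ci_low: int
    ci_high: int
    g_grid: np.ndarray
    log_likelihood: np.ndarray
    at_boundary: bool = False

    def __post_init__(self) -> None:
        if not self.ci_low <= self.g_hat <= self.ci_high:
            raise ValueError("CI must bracket the estimate")


def _first_discordance(side_alleles: np.ndarray) -> int | None:
    """First outward column (1-based) where any pair of rows differs."""
    n_markers = side_alleles.shape[1]
    for k in range(n_markers):
        col = side_alleles[:, k]
        if np.any(col != col[0]):
            return k + 1
    return None


def shared_interval_phased(
    haplotypes: Sequence[PhasedHaplotype], mmap: MarkerMap
) -> tuple[SharedInterval, dict[tuple[str, str], SharedInterval]]:
    """Maximal interval around the focal variant shared by all carriers.

    Scans outward from the focal variant on each side and bounds the interval
    at the first marker where any pair of carrier haplotypes differs.  If a
    side is concordant through the last typed marker, the bound is the map
    edge and the interval is flagged censored on that side.

    Returns the all-carriers interval and the dictionary of pairwise
    intervals.
    """
    carriers = [h for h in haplotypes if h.carries_focal]
    if len(carriers) < 2:
        raise ValueError("need at least 2 carrier haplotypes")
    alleles = np.array([np.asarray(h.alleles, dtype=object) for h in carriers])
    if alleles.shape[1] != len(mmap):
        raise ValueError("haplotype length must match the marker map")

    def interval_for(rows: np.ndarray) -> SharedInterval:
        bounds, names, censored = {}, {}, {}
        for side in ("left", "right"):
            idx = mmap.side_indices(side)
            j = _first_discordance(rows[:, idx])
            if j is None:
                bounds[side] = int(mmap.positions[idx[-1]])
                names[side] = None
                censored[side] = True
            else:
                marker = idx[j - 1]
                bounds[side] = int(mmap.positions[marker])
                names[side] = mmap.ids[marker]
                censored[side] = False
        return SharedInterval(
            start=bounds["left"],
            end=bounds["right"],
            left_marker=names["left"],
            right_marker=names["right"],
            censored_left=censored["left"],
            censored_right=censored["right"],
        )

    overall = interval_for(alleles)
    pairwise = {}
    for i in range(len(carriers)):
        for j in range(i + 1, len(carriers)):
            key = (carriers[i].subject, carriers[j].subject)
            pairwise[key] = interval_for(alleles[[i, j]])
    return overall, pairwise


def discordance_bound_unphased(
    genotypes: dict[str, np.ndarray], mmap: MarkerMap
) -> SharedInterval:
    """Phase-free sharing bound from homozygous-discordant markers.

    ``genotypes`` maps subject -> array of shape (n_markers, 2) of allele
    codes (order within a genotype irrelevant).  Two carriers homozygous for
    different alleles at a marker cannot share either haplotype there; the
    nearest such marker on each side bounds the shared interval.  Where no
    marker excludes sharing, the bound is the map edge (flagged).  The bound
    always contains the phased interval.
    """
    subjects = list(genotypes)
    if len(subjects) < 2:
        raise ValueError("need at least 2 carriers")
    gt = {s: np.asarray(g) for s, g in genotypes.items()}
    for s, g in gt.items():
        if g.shape != (len(mmap), 2):
            raise ValueError(f"genotypes for {s} must have shape (n_markers, 2)")

    def hom_discordant(col: int) -> bool:
        homs = set()
        for g in gt.values():
            a, b = g[col]
            if a == b:
                homs.add(a)
        return len(homs) >= 2

    bounds, names, censored = {}, {}, {}
    for side in ("left", "right"):
        idx = mmap.side_indices(side)
        hit = next((m for m in idx if hom_discordant(m)), None)
        if hit is None:
            bounds[side] = int(mmap.positions[idx[-1]])
            names[side] = None
            censored[side] = True
        else:
            bounds[side] = int(mmap.positions[hit])
            names[side] = mmap.ids[hit]
            censored[side] = False
    return SharedInterval(
        start=bounds["left"],
        end=bounds["right"],
        left_marker=names["left"],
        right_marker=names["right"],
        censored_left=censored["left"],
        censored_right=censored["right"],
    )


def consensus_ancestral(haplotypes: Sequence[PhasedHaplotype]) -> np.ndarray:
    """Majority-vote ancestral haplotype; ties go to the first-listed carrier."""
    carriers = [h for h in haplotypes if h.carries_focal]
    if not carriers:
        raise ValueError("no carrier haplotypes")
    alleles = np.array([np.asarray(h.alleles, dtype=object) for h in carriers])
    out = []
    for col in alleles.T:
        values, counts = np.unique(col, return_counts=True)
        best = counts.max()
        winners = set(values[counts == best])
        out.append(col[0] if col[0] in winners else values[counts.argmax()])
    return np.array(out, dtype=object)


def observations_from_haplotypes(
    haplotypes: Sequence[PhasedHaplotype],
    mmap: MarkerMap,
    ancestral: np.ndarray | None = None,
) -> CarrierSharingObs:
    """First-discordance observations of each carrier against the ancestral.

    If no explicit ancestral haplotype is given, the consensus of the
    carriers is used.
    """
    carriers = [h for h in haplotypes if h.carries_focal]
    if ancestral is None:
        ancestral = consensus_ancestral(carriers)
    ancestral = np.asarray(ancestral, dtype=object)
    obs = []
    for h in carriers:
        alleles = np.asarray(h.alleles, dtype=object)
        for side in ("left", "right"):
            idx = mmap.side_indices(side)
            mismatch = np.nonzero(alleles[idx] != ancestral[idx])[0]
            j = int(mismatch[0]) + 1 if mismatch.size else None
            obs.append(SideObservation(h.subject, side, j))
    return CarrierSharingObs(obs)


def _side_log_likelihood(
    j: int | None,
    thetas: np.ndarray,
    freqs: np.ndarray,
    mu_m: float,
    g: np.ndarray,
) -> np.ndarray:
    """Log-likelihood of one side observation on a vector of candidate ages.

    ``S_k(g) = (1 - theta_k)**g`` is the probability the ancestral segment
    survives intact to marker ``k`` through ``g`` meioses (``S_0 = 1``).  A
    first discordance at ``j`` arises either from a recombination breakpoint
    in interval ``k`` (``k <= j``) followed by chance matches at markers
    ``k..j-1`` and a mismatch at ``j``, or from survival to ``j`` with a
    marker mutation there.  A censored side (concordant through the last
    marker ``M``) arises from survival to ``M`` or from a breakpoint followed
    by chance matches through ``M``.
    """
    g = np.asarray(g, dtype=float)
    n_markers = len(thetas)
    surv = np.concatenate([[1.0], 1.0 - thetas])[:, None] ** g[None, :]  # (M+1, G)
    if j is None:
        like = surv[n_markers].copy()
        for k in range(1, n_markers + 1):
            match = np.prod(freqs[k - 1 : n_markers])
            like += (surv[k - 1] - surv[k]) * match
    else:
        if not 1 <= j <= n_markers:
            raise ValueError("discordance index outside the side marker range")
        like = np.zeros_like(g)
        for k in range(1, j + 1):
            match = np.prod(freqs[k - 1 : j - 1]) * (1.0 - freqs[j - 1])
            like += (surv[k - 1] - surv[k]) * match
        like += surv[j] * -np.expm1(g * math.log1p(-mu_m))
    with np.errstate(divide="ignore"):
        return np.log(like)


def sharing_log_likelihood(
    obs: CarrierSharingObs, mmap: MarkerMap, g
) -> float | np.ndarray:
    """Total log-likelihood of the sharing observations at age(s) ``g``.

    Carrier sides are treated as independent.  ``g`` may be a scalar or an
    array of candidate ages (generations, >= 1).
    """
    g_arr = np.atleast_1d(np.asarray(g, dtype=float))
    if np.any(g_arr < 1):
        raise ValueError("g must be >= 1")
    sides = {s: (mmap.side_thetas(s), mmap.side_freqs(s)) for s in ("left", "right")}
    total = np.zeros_like(g_arr)
    for ob in obs:
        thetas, freqs = sides[ob.side]
        if len(thetas) == 0:
            raise ValueError(f"no markers on the {ob.side} side of the focal variant")
        total += _side_log_likelihood(ob.j, thetas, freqs, mmap.mu_m, g_arr)
    return total if np.ndim(g) else float(total[0])


def estimate_age(
    obs: CarrierSharingObs,
    mmap: MarkerMap,
    g_grid: np.ndarray | None = None,
) -> AgeEstimate:
    """Maximum-likelihood mutation age by grid search with a profile-likelihood CI.

    The 95% CI is the range of ``g`` whose log-likelihood lies within
    ``chi2_1(0.95)/2`` of the maximum.  Estimates or CI endpoints on the grid
    boundary are flagged, not treated as errors (a monotone likelihood is a
    legitimate outcome for degenerate observations).
    """
    if g_grid is None:
        g_grid = np.arange(1, 5001)
    g_grid = np.asarray(g_grid)
    ll = sharing_log_likelihood(obs, mmap, g_grid)
    best = int(np.argmax(ll))
    inside = np.nonzero(ll >= ll[best] - CHI2_1_95_HALF)[0]
    ci_low, ci_high = int(g_grid[inside[0]]), int(g_grid[inside[-1]])
    at_boundary = bool(
        best in (0, len(g_grid) - 1)
        or inside[0] == 0
        or inside[-1] == len(g_grid) - 1
    )
    return AgeEstimate(
        g_hat=int(g_grid[best]),
        ci_low=ci_low,
        ci_high=ci_high,
        g_grid=g_grid,
        log_likelihood=ll,
        at_boundary=at_boundary,
    )


# ---------------------------------------------------------------------------
# File readers (PLINK-style map, haplotype/genotype TSV, frequency sidecar)


def read_plink_map(
    map_path,
    freq_path,
    focal_bp: int,
    rate_cM_per_Mb: float = 2.9,
    mu_m: float = 2e-8,
) -> MarkerMap:
    """Build a :class:`MarkerMap` from a PLINK .map file and a frequency TSV.

    The .map file has whitespace-separated columns (chrom, id, cM, bp); the
    frequency sidecar has columns ``id`` and ``f`` (ancestral-allele
    frequency).
    """
    mp = pd.read_csv(
        map_path, sep=r"\s+", header=None, names=["chrom", "id", "cm", "bp"]
    )
    fr = pd.read_csv(freq_path, sep="\t")
    freqs = dict(zip(fr["id"].astype(str), fr["f"].astype(float)))
    mp = mp.sort_values("bp")
    try:
        f = [freqs[str(i)] for i in mp["id"]]
    except KeyError as exc:
        raise ValueError(f"marker missing from frequency sidecar: {exc}") from exc
    return MarkerMap(
        ids=[str(i) for i in mp["id"]],
        positions=mp["bp"].to_numpy(),
        freqs=np.array(f),
        focal_bp=focal_bp,
        rate_cM_per_Mb=rate_cM_per_Mb,
        mu_m=mu_m,
    )


def read_haplotypes_tsv(path, focal_hap_column: str = "focal_hap"):
    """Read phased haplotypes from TSV.

    One row per subject: a ``subject`` column, an integer column naming which
    haplotype (0 or 1) carries the focal variant, and one column per marker
    holding the phased genotype ``a|b``.  Returns the carrier haplotypes (the
    focal-bearing one per subject).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    marker_cols = [c for c in df.columns if c not in ("subject", focal_hap_column)]
    haps = []
    for _, row in df.iterrows():
        which = int(row[focal_hap_column])
        alleles = []
        for c in marker_cols:
            parts = str(row[c]).split("|")
            if len(parts) != 2:
                raise ValueError(f"unphased or malformed genotype {row[c]!r} in {c}")
            alleles.append(parts[which])
        haps.append(PhasedHaplotype.from_sequence(str(row["subject"]), alleles))
    return haps


def read_genotypes_tsv(path) -> dict[str, np.ndarray]:
    """Read unphased genotypes (``a/b`` cells) into per-subject (M, 2) arrays."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    marker_cols = [c for c in df.columns if c != "subject"]
    out = {}
    for _, row in df.iterrows():
        geno = []
        for c in marker_cols:
            parts = str(row[c]).replace("|", "/").split("/")
            if len(parts) != 2:
                raise ValueError(f"malformed genotype {row[c]!r} in {c}")
            geno.append(parts)
        out[str(row["subject"])] = np.array(geno, dtype=object)
    return out
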