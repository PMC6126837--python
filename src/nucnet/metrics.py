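"""Chromatin-pattern metrics: NFR geometry, the Jensen-Shannon Nucleosome
Phasing Index, and TSS-profile clustering.

The Phasing Index compares a binarized nucleosome profile downstream of a
TSS against a canonical +1..+4 phasing template on a 10-bp bin frame. Peak
bins sit at +100~+159, +290~+349, +480~+529 and +660~+719 bp; valley bins at
+210~+269, +390~+439 and +560~+619; the 20-50 bp spacers between a peak and
its neighboring valley are gaps and excluded. Both binary vectors are
normalized to discrete distributions and scored as

    index = 1 - [H((P0+P1)/2) - (H(P0)+H(P1))/2]

with base-2 entropies, so a profile identical to the template scores 1 and a
profile with disjoint support scores 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from nucnet.io import AnchorAnnotation, NucleosomeCall

logger = logging.getLogger(__name__)

BIN_BP = 10

PEAK_REGIONS = ((100, 159), (290, 349), (480, 529), (660, 719))
VALLEY_REGIONS = ((210, 269), (390, 439), (560, 619))


@dataclass(frozen=True)
class NFRRecord:
    """Geometry of one TSS's nucleosome-free region.

    ``length`` is the bp distance between the -1 and +1 nucleosome summits,
    ``depth`` the unitless dip of the NFR signal relative to the mean of the
    two flanking peaks, and ``size`` their product (bp). ``valid`` is False
    when a flanking nucleosome is missing, the summit-to-summit width exceeds
    the exclusion bound, or the flanking signal is zero.
    """

    anchor_id: str
    length: float
    depth: float
    size: float
    valid: bool

    @classmethod
    def invalid(cls, anchor_id: str) -> "NFRRecord":
        return cls(anchor_id, float("nan"), float("nan"), float("nan"), False)


@dataclass(frozen=True)
class PhasingTemplate:
    """The +1..+4 phasing template on the 10-bp bin frame.

    ``bin_starts`` holds the template-frame start coordinate of every
    non-gap bin (ascending); ``values`` the corresponding 1 (peak) / 0
    (valley) labels.
    """

    bin_starts: tuple[int, ...]
    values: tuple[int, ...]

    @classmethod
    def canonical(cls) -> "PhasingTemplate":
        starts, vals = [], []
        regions = [(lo, hi, 1) for lo, hi in PEAK_REGIONS] + [
            (lo, hi, 0) for lo, hi in VALLEY_REGIONS
        ]
        for lo, hi, v in sorted(regions):
            for s in range(lo, hi + 1 - (BIN_BP - 1), BIN_BP):
                starts.append(s)
                vals.append(v)
        order = np.argsort(starts)
        return cls(
            bin_starts=tuple(int(starts[i]) for i in order),
            values=tuple(int(vals[i]) for i in order),
        )


@dataclass(frozen=True)
class PhasingIndexRecord:
    anchor_id: str
    index: float


@dataclass
class OccupancyTrack:
    """A 10-bp-resolution occupancy signal per chromosome.

    ``profiles[chrom] = (origin_bp, values)`` where ``values[i]`` covers
    genomic bins ``[origin + 10 i, origin + 10 (i+1))``.
    """

    profiles: dict[str, tuple[int, np.ndarray]] = field(default_factory=dict)

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        """Mean bin value over [start, end); bins selected by midpoint."""
        if chrom not in self.profiles or end <= start:
            return float("nan")
        origin, vals = self.profiles[chrom]
        half = BIN_BP // 2
        # smallest i with origin + BIN_BP*i + half >= bound
        i_lo = max(0, -((origin + half - start) // BIN_BP))
        i_hi = min(len(vals), -((origin + half - end) // BIN_BP))
        if i_hi <= i_lo:
            return float("nan")
        return float(vals[i_lo:i_hi].mean())


def entropy(p) -> float:
    """Shannon entropy of a discrete distribution, in bits (0 log 0 = 0)."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("negative probability")
    if not math.isclose(float(p.sum()), 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError(f"distribution sums to {p.sum()}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def js_divergence(p0, p1) -> float:
    """Jensen-Shannon divergence H((P0+P1)/2) - (H(P0)+H(P1))/2, base 2.

    Symmetric and bounded in [0, 1]; 0 iff the distributions coincide, 1 for
    disjoint supports.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    if p0.shape != p1.shape:
        raise ValueError("distributions must have equal length")
    return entropy((p0 + p1) / 2) - (entropy(p0) + entropy(p1)) / 2


def phasing_index(
    template: PhasingTemplate,
    profile,
    anchor_id: str = "",
    literal_formula: bool = False,
) -> PhasingIndexRecord | None:
    """Nucleosome Phasing Index: similarity of a binary profile to the
    phasing template.

    Both 0/1 vectors (on the template's non-gap bin frame) are normalized to
    sum 1 and compared; ``index = 1 - JSD``, so template-vs-self gives 1 and
    the bitwise complement gives 0. ``literal_formula`` instead evaluates
    ``1 - H(mix) - (H(P0)+H(P1))/2`` (an alternative reading of the same
    definition; it is not bounded in [0, 1]). All-zero profiles are skipped
    with a warning (the normalization is undefined), returning None.
    """
    e0 = np.asarray(template.values, dtype=float)
    e1 = np.asarray(profile, dtype=float)
    if e1.shape != e0.shape:
        raise ValueError("profile not on the template bin frame")
    if e1.sum() == 0:
        logger.warning("anchor %s: all-zero binary profile, skipped", anchor_id)
        return None
    p0 = e0 / e0.sum()
    p1 = e1 / e1.sum()
    if literal_formula:
        val = 1.0 - entropy((p0 + p1) / 2) - (entropy(p0) + entropy(p1)) / 2
    else:
        val = 1.0 - js_divergence(p0, p1)
    return PhasingIndexRecord(anchor_id=anchor_id, index=float(val))


def binarize_profile(
    calls: list[NucleosomeCall],
    anchor: AnchorAnnotation,
    template: PhasingTemplate | None = None,
) -> np.ndarray:
    """Binary nucleosome signal on the template's bin frame for one anchor.

    A bin scores 1 when its midpoint (in genomic coordinates, after flipping
    the axis for minus-strand anchors) falls inside a called nucleosome
    footprint [start, end), else 0.
    """
    if template is None:
        template = PhasingTemplate.canonical()
    sign = -1 if anchor.strand == "-" else 1
    out = np.zeros(len(template.bin_starts), dtype=int)
    chrom_calls = sorted(
        (c for c in calls if c.chrom == anchor.chrom), key=lambda c: c.start
    )
    starts = np.array([c.start for c in chrom_calls])
    ends = np.array([c.end for c in chrom_calls])
    for i, s in enumerate(template.bin_starts):
        mid = anchor.center + sign * (s + BIN_BP // 2)
        j = int(np.searchsorted(starts, mid, side="right")) - 1
        # check the two nearest footprints (calls may overlap slightly)
        for jj in (j, j - 1):
            if 0 <= jj < len(starts) and starts[jj] <= mid < ends[jj]:
                out[i] = 1
                break
    return out


def nfr_geometry(
    anchor: AnchorAnnotation,
    indexed,
    occupancy: OccupancyTrack,
    max_flank_distance: int = 250,
) -> NFRRecord:
    """NFR length, depth and size for one TSS.

    length = summit(+1) - summit(-1) in bp (always positive); depth uses the
    mean 10-bp-bin occupancy of the NFR interior (between the two summits)
    against the mean of the two flanking nucleosome footprints::

        depth = 1 - NFR_signal / (0.5 (upstream_peak + downstream_peak))

    The record is invalid when the -1 or +1 nucleosome is missing, when the
    summit-to-summit width exceeds ``max_flank_distance`` bp, or when the
    flanking signal is zero (the ratio is undefined). Depth may be negative
    when the NFR signal exceeds the flank mean; such records stay valid.
    """
    mine = [nu for nu in indexed if nu.anchor_id == anchor.id]
    up = [nu for nu in mine if nu.slot == -1]
    down = [nu for nu in mine if nu.slot == 1]
    if not up or not down:
        return NFRRecord.invalid(anchor.id)
    c_up, c_down = up[0].nucleosome, down[0].nucleosome
    length = abs(c_down.summit - c_up.summit)
    if length > max_flank_distance or length <= 0:
        return NFRRecord.invalid(anchor.id)
    lo, hi = sorted((c_up.summit, c_down.summit))
    nfr_sig = occupancy.mean_over(anchor.chrom, lo, hi)
    up_sig = occupancy.mean_over(anchor.chrom, c_up.start, c_up.end)
    down_sig = occupancy.mean_over(anchor.chrom, c_down.start, c_down.end)
    flank = 0.5 * (up_sig + down_sig)
    if not np.isfinite(flank) or flank <= 0 or not np.isfinite(nfr_sig):
        return NFRRecord.invalid(anchor.id)
    depth = 1.0 - nfr_sig / flank
    return NFRRecord(anchor.id, float(length), float(depth), float(length * depth), True)


def cluster_profiles(
    profiles: np.ndarray, k_range=range(2, 9), seed: int = 0
) -> tuple[np.ndarray, int]:
    """Cluster per-anchor occupancy profiles by spherical k-means with
    BIC-based selection of k.

    Profiles are L2-normalized so Euclidean k-means acts on cosine
    geometry. For each k the Bayesian information criterion of a spherical
    Gaussian-mixture approximation of the clustering is computed, and the k
    with minimal BIC wins. All-identical input degenerates to k = 1.

    Returns (labels, chosen_k); deterministic given the seed.
    """
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2 or len(X) < 2 * max(k_range):
        raise ValueError("need at least 2*max(k) profiles")
    norms = np.linalg.norm(X, axis=1)
    norms[norms == 0] = 1.0
    Xn = X / norms[:, None]
    if np.allclose(Xn, Xn[0]):
        return np.zeros(len(X), dtype=int), 1

    m, d = Xn.shape
    best: tuple[float, int, np.ndarray] | None = None
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(Xn)
        rss = float(km.inertia_)
        sigma2 = max(rss / (m * d), np.finfo(float).tiny)
        loglik = -0.5 * m * d * (math.log(2 * math.pi * sigma2) + 1)
        n_params = k * d + 1  # centroids + shared spherical variance
        bic = n_params * math.log(m) - 2 * loglik
        if best is None or bic < best[0]:
            best = (bic, k, labels)
    assert best is not None
    return best[2], best[1]
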