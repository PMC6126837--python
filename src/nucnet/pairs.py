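"""Phased-nucleosome selection, anchor-relative indexing and pair extraction.

The modeled direction of information flow fixes which member of an adjacent
nucleosome pair is "before" and which is "after":

* TSS, CTCF and enhancer anchors: outward from the center on each side
  (for enhancers, from the enhancer center toward the nearest TSS);
* TTS anchors: upstream -> downstream in the transcription direction on both
  sides, i.e. toward the TTS on its upstream side and away on its downstream
  side.

Pairs touching the anchor point enter training according to a
"center-inclusion level": level 1 keeps only pairs with both nucleosomes
strictly on one side of the center, level 2 additionally keeps pairs with one
nucleosome footprint overlapping the center point, level 3 keeps every
adjacent pair including the one spanning the center.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from nucnet.io import AnchorAnnotation, NucleosomeCall

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhasingCriteria:
    """Selection rules for regularly phased nucleosomes.

    A nucleosome is retained when its inflection-point width lies in
    ``width_range`` (default 70–90 bp), both of its summit-to-summit
    adjacency distances lie in ``spacing_range`` (default 160–400 bp), and —
    when ``require_main_peak`` — its peak class is MainPeak. Bounds are
    inclusive. ``mode="any_two"`` instead retains nucleosomes satisfying any
    two of the three criteria.
    """

    width_range: tuple[float, float] = (70.0, 90.0)
    spacing_range: tuple[float, float] = (160.0, 400.0)
    require_main_peak: bool = True
    mode: str = "strict"  # strict: (1)+(2) mandatory, (3) per flag

    def __post_init__(self) -> None:
        if self.width_range[0] > self.width_range[1]:
            raise ValueError("width_range lower bound exceeds upper bound")
        if self.spacing_range[0] > self.spacing_range[1]:
            raise ValueError("spacing_range lower bound exceeds upper bound")
        if self.mode not in ("strict", "any_two"):
            raise ValueError(f"unknown criteria mode {self.mode!r}")


@dataclass(frozen=True)
class IndexedNucleosome:
    """A nucleosome assigned to a slot relative to an anchor.

    For TSS/TTS anchors slots are ..., -2, -1 upstream and +1, +2, ...
    downstream in transcription orientation. For strandless anchors (CTCF,
    enhancer) each flank is indexed 1, 2, ... outward from the center; the
    two flanks are distinguished by ``side`` (flank_left / flank_right in
    genome coordinates).
    """

    anchor_id: str
    slot: int
    side: str  # upstream | downstream | flank_left | flank_right
    nucleosome: NucleosomeCall


@dataclass(frozen=True)
class NucleosomePair:
    """An ordered (before, after) pair of adjacent phased nucleosomes."""

    anchor_id: str
    before: IndexedNucleosome
    after: IndexedNucleosome
    side: str  # upstream | downstream | flank
    crosses_center: str  # neither | one_overlaps | spans


def filter_phased(
    calls: list[NucleosomeCall], criteria: PhasingCriteria = PhasingCriteria()
) -> list[NucleosomeCall]:
    """Retain regularly phased nucleosomes.

    Adjacency distances are measured summit-to-summit against the immediate
    left and right neighbors on the same chromosome; chromosome-terminal
    calls, which lack one neighbor, are always rejected.
    """
    by_chrom: dict[str, list[NucleosomeCall]] = defaultdict(list)
    for c in calls:
        by_chrom[c.chrom].append(c)
    kept: list[NucleosomeCall] = []
    wlo, whi = criteria.width_range
    slo, shi = criteria.spacing_range
    for chrom in sorted(by_chrom):
        cs = sorted(by_chrom[chrom], key=lambda c: c.summit)
        for i in range(1, len(cs) - 1):
            c = cs[i]
            d_left = c.summit - cs[i - 1].summit
            d_right = cs[i + 1].summit - c.summit
            width_ok = wlo <= c.width_bp <= whi
            spacing_ok = slo <= d_left <= shi and slo <= d_right <= shi
            main_ok = c.peak_class == "MainPeak"
            if criteria.mode == "any_two":
                retain = (width_ok + spacing_ok + main_ok) >= 2
            else:
                retain = width_ok and spacing_ok and (
                    main_ok or not criteria.require_main_peak
                )
            if retain:
                kept.append(c)
    return kept


def index_to_anchors(
    calls: list[NucleosomeCall],
    anchors: list[AnchorAnnotation],
    window: int = 2000,
) -> list[IndexedNucleosome]:
    """Assign each call whose summit lies within ±``window`` bp of an anchor
    center to a signed slot (or positive flank slot for strandless anchors).

    Minus-strand TSS/TTS anchors flip upstream/downstream so slots follow the
    transcription orientation. Summits exactly at the center count as
    downstream (+1 side) for stranded anchors and as the right flank for
    strandless ones.
    """
    by_chrom: dict[str, list[NucleosomeCall]] = defaultdict(list)
    for c in calls:
        by_chrom[c.chrom].append(c)
    summits: dict[str, np.ndarray] = {}
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda c: c.summit)
        summits[chrom] = np.array([c.summit for c in by_chrom[chrom]])

    out: list[IndexedNucleosome] = []
    for a in anchors:
        if a.chrom not in by_chrom:
            continue
        s = summits[a.chrom]
        lo = int(np.searchsorted(s, a.center - window, side="left"))
        hi = int(np.searchsorted(s, a.center + window, side="right"))
        in_window = by_chrom[a.chrom][lo:hi]
        left = [c for c in in_window if c.summit < a.center]
        right = [c for c in in_window if c.summit >= a.center]
        stranded = a.anchor_kind in ("TSS", "TTS")
        flip = stranded and a.strand == "-"
        # genomic-left, counted outward: nearest to center first
        for k, c in enumerate(reversed(left), start=1):
            if stranded:
                slot, side = (k, "downstream") if flip else (-k, "upstream")
            else:
                slot, side = k, "flank_left"
            out.append(IndexedNucleosome(a.id, slot, side, c))
        for k, c in enumerate(right, start=1):
            if stranded:
                slot, side = (-k, "upstream") if flip else (k, "downstream")
            else:
                slot, side = k, "flank_right"
            out.append(IndexedNucleosome(a.id, slot, side, c))
    return out


def _pair_members_oriented(
    left: IndexedNucleosome, right: IndexedNucleosome, anchor: AnchorAnnotation
) -> tuple[IndexedNucleosome, IndexedNucleosome]:
    """Order a genomically adjacent (left, right) pair as (before, after)."""
    if anchor.anchor_kind == "TTS":
        # transcription direction on both sides
        return (left, right) if anchor.strand == "+" else (right, left)
    # TSS / CTCF / Enhancer: outward from the center; for cross-center pairs
    # the member whose summit is nearer the center leads (ties: genomic left)
    d_left = abs(left.nucleosome.summit - anchor.center)
    d_right = abs(right.nucleosome.summit - anchor.center)
    return (left, right) if d_left <= d_right else (right, left)


def _classify_center(
    left: IndexedNucleosome, right: IndexedNucleosome, center: int
) -> str:
    for m in (left, right):
        if m.nucleosome.start <= center < m.nucleosome.end:
            return "one_overlaps"
    if (left.nucleosome.summit - center) * (right.nucleosome.summit - center) < 0:
        return "spans"
    return "neither"


def extract_pairs(
    indexed: list[IndexedNucleosome],
    anchors: list[AnchorAnnotation],
    inclusion_level: int = 1,
    spacing_range: tuple[float, float] = (160.0, 400.0),
) -> list[NucleosomePair]:
    """Extract ordered adjacent-nucleosome pairs at a center-inclusion level.

    Adjacent slots whose summit-to-summit distance falls outside
    ``spacing_range`` are not paired: slot adjacency can bridge a gap left by
    a filtered-out nucleosome, and such a pair is no longer a phased
    neighboring pair. Pass ``spacing_range=None`` to pair every adjacent slot.
    """
    if inclusion_level not in (1, 2, 3):
        raise ValueError("inclusion level must be 1, 2 or 3")
    anchor_by_id = {a.id: a for a in anchors}
    by_anchor: dict[str, list[IndexedNucleosome]] = defaultdict(list)
    for nu in indexed:
        by_anchor[nu.anchor_id].append(nu)
    pairs: list[NucleosomePair] = []
    for anchor_id in sorted(by_anchor):
        anchor = anchor_by_id[anchor_id]
        seq = sorted(by_anchor[anchor_id], key=lambda nu: nu.nucleosome.summit)
        for left, right in zip(seq, seq[1:]):
            if spacing_range is not None:
                d = right.nucleosome.summit - left.nucleosome.summit
                if not spacing_range[0] <= d <= spacing_range[1]:
                    continue
            cls = _classify_center(left, right, anchor.center)
            if inclusion_level == 1 and cls != "neither":
                continue
            if inclusion_level == 2 and cls == "spans":
                continue
            before, after = _pair_members_oriented(left, right, anchor)
            side = after.side
            if side.startswith("flank"):
                side = "flank"
            pairs.append(NucleosomePair(anchor_id, before, after, side, cls))
    return pairs


def exclude_multi_region_pairs(
    pairs: list[NucleosomePair],
    anchors: list[AnchorAnnotation],
    window: int = 2000,
) -> list[NucleosomePair]:
    """Drop pairs with either member inside the ±window of two or more anchor
    centers (signal spillover between overlapping regions); the dropped
    fraction is logged. ``anchors`` should be the union of every anchor set
    in the analysis (TSS, TTS, CTCF) when more than one is in play.
    """
    centers: dict[str, np.ndarray] = {}
    by_chrom: dict[str, list[int]] = defaultdict(list)
    for a in anchors:
        by_chrom[a.chrom].append(a.center)
    for chrom, cs in by_chrom.items():
        centers[chrom] = np.sort(np.array(cs))

    def n_regions(chrom: str, summit: int) -> int:
        cs = centers.get(chrom)
        if cs is None:
            return 0
        lo = np.searchsorted(cs, summit - window, side="left")
        hi = np.searchsorted(cs, summit + window, side="right")
        return int(hi - lo)

    kept = [
        p
        for p in pairs
        if n_regions(p.before.nucleosome.chrom, p.before.nucleosome.summit) < 2
        and n_regions(p.after.nucleosome.chrom, p.after.nucleosome.summit) < 2
    ]
    if pairs:
        frac = 1.0 - len(kept) / len(pairs)
        logger.info(
            "multi-region exclusion dropped %.1f%% of pairs (%d of %d)",
            100 * frac, len(pairs) - len(kept), len(pairs),
        )
    return kept


PAIR_TSV_COLUMNS = [
    "anchor_id", "side", "crosses_center",
    "before_slot", "before_side", "before_chrom", "before_start", "before_end",
    "before_summit", "before_width", "before_class", "before_occupancy",
    "after_slot", "after_side", "after_chrom", "after_start", "after_end",
    "after_summit", "after_width", "after_class", "after_occupancy",
]


def pairs_to_frame(pairs: list[NucleosomePair]):
    """Flatten pairs into a DataFrame (one row per pair, both members inlined)."""
    import pandas as pd

    rows = []
    for p in pairs:
        row = [p.anchor_id, p.side, p.crosses_center]
        for nu in (p.before, p.after):
            c = nu.nucleosome
            row += [nu.slot, nu.side, c.chrom, c.start, c.end, c.summit,
                    c.width_bp, c.peak_class, c.occupancy]
        rows.append(row)
    return pd.DataFrame(rows, columns=PAIR_TSV_COLUMNS)


def frame_to_pairs(df) -> list[NucleosomePair]:
    """Inverse of :func:`pairs_to_frame`."""
    out = []
    for r in df.itertuples(index=False):
        members = {}
        for tag in ("before", "after"):
            call = NucleosomeCall(
                chrom=getattr(r, f"{tag}_chrom"),
                start=int(getattr(r, f"{tag}_start")),
                end=int(getattr(r, f"{tag}_end")),
                summit=int(getattr(r, f"{tag}_summit")),
                width_bp=float(getattr(r, f"{tag}_width")),
                peak_class=getattr(r, f"{tag}_class"),
                occupancy=float(getattr(r, f"{tag}_occupancy")),
            )
            members[tag] = IndexedNucleosome(
                r.anchor_id, int(getattr(r, f"{tag}_slot")),
                getattr(r, f"{tag}_side"), call,
            )
        out.append(NucleosomePair(r.anchor_id, members["before"],
                                  members["after"], r.side, r.crosses_center))
    return out
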