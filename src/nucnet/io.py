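"""Readers and writers for every external format the pipeline touches.

All interval arithmetic uses 0-based half-open coordinates. BED is read as
written (0-based half-open); refFlat txStart is 0-based and txEnd 1-based
exclusive (UCSC convention). Anchors are single-bp points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

TAG_COLUMNS = ["chrom", "start", "end", "strand"]

#: default column map for the nucleosome-call table (generic TSV; peak callers
#: differ in header naming, so the map is user-configurable)
DEFAULT_CALL_COLUMNS: Mapping[str, str] = {
    "chrom": "chrom",
    "start": "start",
    "end": "end",
    "summit": "summit",
    "width_bp": "width",
    "peak_class": "class",
    "occupancy": "occupancy",
}


class ParseError(ValueError):
    """A malformed record in an input file, with its line number."""


@dataclass(frozen=True)
class NucleosomeCall:
    """One called nucleosome: genomic footprint, summit, inflection width,
    peak-shape class and occupancy (peak signal)."""

    chrom: str
    start: int
    end: int
    summit: int
    width_bp: float
    peak_class: str  # MainPeak / Shoulder / Other
    occupancy: float = 0.0

    def is_valid(self) -> bool:
        return (
            self.start <= self.summit < self.end
            and self.width_bp > 0
            and self.occupancy >= 0
        )

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class AnchorAnnotation:
    """A genomic reference point around which nucleosomes are indexed.

    ``anchor_kind`` is one of TSS, TTS, CTCF, Enhancer. CTCF/Enhancer anchors
    are strandless (strand ``"none"``); TSS/TTS carry the gene strand.
    """

    id: str
    chrom: str
    anchor_kind: str
    center: int
    strand: str = "none"

    def __post_init__(self) -> None:
        if self.anchor_kind in ("CTCF", "Enhancer") and self.strand != "none":
            raise ValueError(f"{self.anchor_kind} anchors must be strandless")
        if self.anchor_kind in ("TSS", "TTS") and self.strand not in ("+", "-"):
            raise ValueError(f"{self.anchor_kind} anchor requires a gene strand")


def read_tag_bed(path) -> pd.DataFrame:
    """Read a tag-coordinate BED file into a DataFrame (chrom, start, end, strand).

    Strand comes from column 6 when present, else ``"unknown"``. Coordinates
    are kept as written (0-based half-open). Malformed coordinates raise
    :class:`ParseError` naming the offending line.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >=3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            if start >= end:
                raise ParseError(
                    f"{path}: line {lineno}: start {start} >= end {end}"
                )
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "unknown"
            rows.append((chrom, start, end, strand))
    df = pd.DataFrame(rows, columns=TAG_COLUMNS)
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def read_nucleosome_calls(
    path, column_map: Mapping[str, str] | None = None
) -> list[NucleosomeCall]:
    """Read a nucleosome-call table (tab-separated, headered).

    ``column_map`` maps the internal field names (chrom, start, end, summit,
    width_bp, peak_class, occupancy) to the file's column headers. Rows that
    violate the call invariants (summit outside footprint, non-positive width,
    negative occupancy) are rejected; the rejected count is logged.
    """
    cmap = dict(DEFAULT_CALL_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t")
    required = ["chrom", "start", "end", "summit", "width_bp", "peak_class"]
    missing = [f for f in required if cmap[f] not in df.columns]
    if missing:
        raise KeyError(
            f"{path}: missing required column(s) "
            + ", ".join(f"{cmap[f]!r} (for {f})" for f in missing)
        )
    has_occ = cmap["occupancy"] in df.columns
    occ_col = (
        df[cmap["occupancy"]].astype(float)
        if has_occ
        else pd.Series(0.0, index=df.index)
    )
    calls: list[NucleosomeCall] = []
    rejected = 0
    for chrom, start, end, summit, width, klass, occ in zip(
        df[cmap["chrom"]], df[cmap["start"]], df[cmap["end"]],
        df[cmap["summit"]], df[cmap["width_bp"]], df[cmap["peak_class"]],
        occ_col,
    ):
        call = NucleosomeCall(
            chrom=str(chrom), start=int(start), end=int(end),
            summit=int(summit), width_bp=float(width),
            peak_class=str(klass), occupancy=float(occ),
        )
        if call.is_valid():
            calls.append(call)
        else:
            rejected += 1
    if rejected:
        logger.warning("%s: rejected %d invalid nucleosome call(s)", path, rejected)
    return calls


def write_nucleosome_calls(calls: Iterable[NucleosomeCall], path) -> None:
    df = pd.DataFrame(
        [
            (c.chrom, c.start, c.end, c.summit, c.width_bp, c.peak_class, c.occupancy)
            for c in calls
        ],
        columns=["chrom", "start", "end", "summit", "width", "class", "occupancy"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_refflat(path) -> list[AnchorAnnotation]:
    """Read a refFlat gene table and emit one TSS and one TTS anchor per transcript.

    Plus strand: TSS = txStart, TTS = txEnd; minus strand: TSS = txEnd,
    TTS = txStart. Duplicate (chrom, center, strand, kind) anchors — many
    transcripts sharing a start — are collapsed to one. Records with an
    unknown strand symbol are skipped with a warning.
    """
    anchors: dict[tuple, AnchorAnnotation] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                f = line.split()
            if len(f) < 6:
                raise ParseError(f"{path}: line {lineno}: expected >=6 refFlat columns")
            gene, _name, chrom, strand = f[0], f[1], f[2], f[3]
            if strand not in ("+", "-"):
                logger.warning(
                    "%s: line %d: unknown strand %r, record skipped",
                    path, lineno, strand,
                )
                continue
            tx_start, tx_end = int(f[4]), int(f[5])
            tss = tx_start if strand == "+" else tx_end
            tts = tx_end if strand == "+" else tx_start
            for kind, center in (("TSS", tss), ("TTS", tts)):
                key = (chrom, center, strand, kind)
                if key not in anchors:
                    anchors[key] = AnchorAnnotation(
                        id=f"{gene}_{kind}", chrom=chrom, anchor_kind=kind,
                        center=center, strand=strand,
                    )
    return list(anchors.values())


def read_anchor_bed(path, kind: str) -> list[AnchorAnnotation]:
    """Read a BED of strandless anchor intervals (CTCF sites, enhancers);
    the anchor point is the interval midpoint."""
    if kind not in ("CTCF", "Enhancer"):
        raise ValueError("anchor BED kind must be CTCF or Enhancer")
    df = read_tag_bed(path)
    return [
        AnchorAnnotation(
            id=f"{kind}_{i}", chrom=row.chrom, anchor_kind=kind,
            center=(row.start + row.end) // 2, strand="none",
        )
        for i, row in enumerate(df.itertuples(index=False))
    ]


def write_signal_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a per-nucleosome x per-mark signal matrix as TSV
    (row ids 'chrom:start-end', columns = mark names)."""
    matrix.to_csv(path, sep="\t", index_label="nucleosome")


def read_signal_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_network(edges: Sequence[tuple], path) -> None:
    """Write a network edge list as TSV: source, target, directedness, support.

    ``edges`` is a sequence of (source, target, directedness, support) tuples;
    directedness is ``compelled`` or ``undirected``. Rows are sorted
    lexicographically by (source, target) so identical edge sets round-trip
    byte-identically.
    """
    df = pd.DataFrame(
        list(edges), columns=["source", "target", "directedness", "support"]
    ).sort_values(["source", "target"], kind="stable")
    df.to_csv(path, sep="\t", index=False)


def read_network(path) -> list[tuple]:
    df = pd.read_csv(path, sep="\t")
    return [
        (r.source, r.target, r.directedness, r.support)
        for r in df.itertuples(index=False)
    ]
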