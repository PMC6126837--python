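"""Self-contained synthetic fixtures: phased nucleosome landscapes around
anchors and mark signals generated from a planted transition network.

The landscape generator emulates the canonical promoter architecture — a
nucleosome-free region between the -1 and +1 nucleosomes and a regularly
spaced downstream/upstream array whose positional jitter grows with distance
from the anchor (phasing decay). The signal generator walks each
anchor-side nucleosome chain outward and produces mark values from a planted
before->after dependency graph with linear and log-saturating links plus
Gaussian noise, so structure-learning output can be scored against a known
truth.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nucnet.dbn import AFTER, BEFORE, node_label
from nucnet.io import AnchorAnnotation, NucleosomeCall
from nucnet.metrics import BIN_BP, OccupancyTrack

NUC_HALF = 73  # bp on either side of the summit in the emitted footprint


@dataclass(frozen=True)
class LandscapeConfig:
    """Parameters of the synthetic phased-nucleosome landscape.

    Defaults describe a realistic promoter array: ~190 bp repeat length,
    80 bp inflection widths, a 200 bp (summit-to-summit) NFR, and positional
    jitter that grows by ``jitter_growth`` bp of s.d. per slot away from the
    anchor.
    """

    n_anchors: int = 200
    anchor_kind: str = "TSS"
    n_upstream: int = 5
    n_downstream: int = 5
    nfr_mean: float = 200.0
    nfr_sd: float = 20.0
    spacing_mean: float = 190.0
    spacing_jitter_sd: float = 5.0
    jitter_growth: float = 2.0
    width_mean: float = 80.0
    width_sd: float = 3.0
    frac_main_peak: float = 0.95
    anchor_spacing: int = 20_000
    window: int = 2000
    chrom: str = "chrS"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.nfr_sd, self.spacing_jitter_sd, self.jitter_growth,
               self.width_sd) < 0:
            raise ValueError("standard deviations must be nonnegative")
        if not 150 <= self.spacing_mean <= 250:
            raise ValueError("spacing_mean outside plausible 150-250 bp")
        if self.nfr_mean > self.window:
            raise ValueError("NFR longer than the anchor window is infeasible")


@dataclass(frozen=True)
class PlantedModel:
    """A ground-truth transition network.

    ``edges`` are (source label, target label, link, param) with labels of
    the form 'mark@before' / 'mark@after'; targets are always after-slice.
    Links: ``linear`` (param = coefficient) or ``log_saturating``
    (param = scale, contribution = scale * ln(1+x)). After-marks without
    parents, and all chain-head before-marks, draw i.i.d. log-normal
    baselines. ``intercepts`` shifts marks with parents so anti-couplings
    stay nonnegative.
    """

    marks: tuple[str, ...]
    edges: tuple[tuple[str, str, str, float], ...]
    noise_sd: float = 0.3
    baseline_mu: float = 0.0
    baseline_sigma: float = 0.5
    intercepts: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        labels = {node_label(mk, s) for mk in self.marks for s in (BEFORE, AFTER)}
        for src, dst, link, _ in self.edges:
            if src not in labels or dst not in labels:
                raise ValueError(f"edge ({src}, {dst}) uses unknown node labels")
            if not dst.endswith(f"@{AFTER}"):
                raise ValueError(f"edge target {dst} must be after-slice")
            if link not in ("linear", "log_saturating"):
                raise ValueError(f"unknown link {link!r}")
        order = self._topo_after()
        if order is None:
            raise ValueError("intra-after edges form a cycle")

    def _topo_after(self) -> list[str] | None:
        """Topological order of after-marks under intra-after edges."""
        deps: dict[str, set[str]] = {mk: set() for mk in self.marks}
        for src, dst, _, _ in self.edges:
            if src.endswith(f"@{AFTER}"):
                deps[dst.split("@")[0]].add(src.split("@")[0])
        order, done = [], set()
        while len(order) < len(self.marks):
            ready = [mk for mk in self.marks if mk not in done and deps[mk] <= done]
            if not ready:
                return None
            for mk in ready:
                order.append(mk)
                done.add(mk)
        return order

    def truth_edges(self) -> frozenset[tuple[str, str]]:
        return frozenset((src, dst) for src, dst, _, _ in self.edges)


def simulate_landscape(
    cfg: LandscapeConfig = LandscapeConfig(),
) -> tuple[list[NucleosomeCall], list[AnchorAnnotation], OccupancyTrack]:
    """Generate nucleosome calls, anchors and a 10-bp occupancy track.

    Each anchor gets a -1 nucleosome, an NFR of sampled summit-to-summit
    length, and arrays on both sides at the sampled repeat length with
    slot-dependent jitter. Deterministic given ``cfg.seed``; the outputs are
    the same objects the package's readers produce from files.
    """
    rng = np.random.default_rng(cfg.seed)
    calls: list[NucleosomeCall] = []
    anchors: list[AnchorAnnotation] = []
    summits_amps: list[tuple[int, float]] = []
    margin = 10_000
    for i in range(cfg.n_anchors):
        center = margin + i * cfg.anchor_spacing
        aid = f"anchor{i:05d}"
        strand = "+" if cfg.anchor_kind in ("TSS", "TTS") else "none"
        anchors.append(
            AnchorAnnotation(aid, cfg.chrom, cfg.anchor_kind, center, strand)
        )
        nfr = cfg.nfr_mean + (rng.normal(0, cfg.nfr_sd) if cfg.nfr_sd else 0.0)
        nfr = max(nfr, 2 * BIN_BP)
        plus1 = center + nfr / 2
        minus1 = center - nfr / 2
        for side_sign, first, count in (
            (1, plus1, cfg.n_downstream),
            (-1, minus1, cfg.n_upstream),
        ):
            pos = first
            for slot in range(1, count + 1):
                if slot > 1:
                    sd = cfg.spacing_jitter_sd + cfg.jitter_growth * (slot - 2)
                    step = cfg.spacing_mean + (rng.normal(0, sd) if sd else 0.0)
                    pos = pos + side_sign * step
                summit = int(round(pos))
                width = cfg.width_mean + (
                    rng.normal(0, cfg.width_sd) if cfg.width_sd else 0.0
                )
                klass = (
                    "MainPeak" if rng.random() < cfg.frac_main_peak else "Shoulder"
                )
                amp = round(float(rng.lognormal(2.0, 0.25)), 4)
                calls.append(
                    NucleosomeCall(
                        chrom=cfg.chrom,
                        start=summit - NUC_HALF,
                        end=summit + NUC_HALF + 1,
                        summit=summit,
                        # 4-decimal values survive text round-trips exactly
                        width_bp=round(float(max(width, 40.0)), 4),
                        peak_class=klass,
                        occupancy=amp,
                    )
                )
                summits_amps.append((summit, amp))

    calls.sort(key=lambda c: c.start)
    length = margin + cfg.n_anchors * cfg.anchor_spacing + margin
    n_bins = length // BIN_BP
    track = np.zeros(n_bins)
    mids = BIN_BP * np.arange(n_bins) + BIN_BP // 2
    sd_bp = 40.0
    for summit, amp in summits_amps:
        lo = max(0, (summit - 200) // BIN_BP)
        hi = min(n_bins, (summit + 200) // BIN_BP + 1)
        track[lo:hi] += amp * np.exp(
            -0.5 * ((mids[lo:hi] - summit) / sd_bp) ** 2
        )
    occupancy = OccupancyTrack(profiles={cfg.chrom: (0, track)})
    return calls, anchors, occupancy


def _chains(pairs) -> list[list]:
    """Split pairs into before->after chains, one per (anchor, side),
    ordered so each pair's before nucleosome is the previous pair's after."""
    grouped: dict[tuple, list] = defaultdict(list)
    for p in pairs:
        grouped[(p.anchor_id, p.side)].append(p)
    chains = []
    for key in sorted(grouped):
        chain = grouped[key]
        after_ids = {p.after.nucleosome.id for p in chain}
        heads = [p for p in chain if p.before.nucleosome.id not in after_ids]
        by_before = {p.before.nucleosome.id: p for p in chain}
        for head in sorted(heads, key=lambda p: p.before.nucleosome.id):
            seq, cur = [], head
            while cur is not None:
                seq.append(cur)
                cur = by_before.get(cur.after.nucleosome.id)
            chains.append(seq)
    return chains


def simulate_signals(
    pairs,
    model: PlantedModel,
    seed: int = 0,
    calls: list[NucleosomeCall] | None = None,
) -> tuple[pd.DataFrame, frozenset[tuple[str, str]]]:
    """Generate a per-nucleosome signal matrix from the planted model.

    Each (anchor, side) chain of pairs is walked outward: the chain head's
    marks are i.i.d. log-normal, every subsequent nucleosome's marks are
    computed — in topological order of the intra-after edges — as intercept
    plus link contributions plus Gaussian noise, floored at 0. Nucleosomes in
    ``calls`` that belong to no pair receive baseline draws so the matrix
    covers the whole landscape. Returns the matrix and the truth edge set.
    """
    rng = np.random.default_rng(seed)
    marks = list(model.marks)
    intercepts = dict(model.intercepts)
    topo = model._topo_after()
    assert topo is not None
    parents: dict[str, list[tuple[str, str, str, float]]] = defaultdict(list)
    for e in model.edges:
        parents[e[1].split("@")[0]].append(e)

    values: dict[str, dict[str, float]] = {}

    def baseline() -> dict[str, float]:
        return {
            mk: float(rng.lognormal(model.baseline_mu, model.baseline_sigma))
            for mk in marks
        }

    for chain in _chains(pairs):
        head_id = chain[0].before.nucleosome.id
        if head_id not in values:
            values[head_id] = baseline()
        for p in chain:
            before_vals = values[p.before.nucleosome.id]
            after_vals: dict[str, float] = {}
            fresh = baseline()
            for mk in topo:
                edges_in = parents[mk]
                if not edges_in:
                    after_vals[mk] = fresh[mk]
                    continue
                v = intercepts.get(mk, 0.0)
                for src, _dst, link, param in edges_in:
                    src_mark, src_slice = src.split("@")
                    x = (
                        before_vals[src_mark]
                        if src_slice == BEFORE
                        else after_vals[src_mark]
                    )
                    v += param * (np.log1p(x) if link == "log_saturating" else x)
                if model.noise_sd:
                    v += rng.normal(0, model.noise_sd)
                after_vals[mk] = max(v, 0.0)
            values[p.after.nucleosome.id] = after_vals

    if calls is not None:
        for c in calls:
            if c.id not in values:
                values[c.id] = baseline()

    ids = sorted(values)
    matrix = pd.DataFrame(
        [[values[i][mk] for mk in marks] for i in ids], index=ids, columns=marks
    )
    return matrix, model.truth_edges()


def recovery_score(learned, truth: frozenset[tuple[str, str]]):
    """Precision/recall of a learned PDAG against planted truth edges.

    A predicted edge is correct iff its skeleton matches a truth edge and
    its orientation is compatible (compelled in the truth direction, or
    undirected). With no predicted edges precision is 1 by convention.
    """
    records = learned.records()
    correct = 0
    for rec in records:
        kind, a, b = rec
        if kind == "compelled":
            correct += (a, b) in truth
        else:
            correct += (a, b) in truth or (b, a) in truth
    precision = correct / len(records) if records else 1.0
    recovered = 0
    for src, dst in truth:
        und = ("undirected",) + tuple(sorted((src, dst)))
        if ("compelled", src, dst) in records or und in records:
            recovered += 1
    recall = recovered / len(truth) if truth else 1.0
    return precision, recall
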