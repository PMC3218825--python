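"""Structural-variant detection from abnormal read pairs.

A mate pair aligned in convergent (FR) orientation with a span inside
mu +/- 3 sigma of the library insert distribution is "normal"; everything
else is diagnostic of a rearrangement.  Pair signatures: FR with span
> mu + 3 sigma -> deletion; FR with span < mu - 3 sigma -> insertion;
same-strand mates (FF/RR) -> inversion; everted (RF) orientation -> tandem
duplication; mates on different chromosomes -> translocation.  Abnormal
pairs of one class are grouped into diagnostic paired-end clusters; clusters
with at least four supporting pairs become SV calls, typed and sized from
the member spans.  Calls overlapping assembly gaps are masked, and calls
whose breakpoint intervals overlap each other are flagged complex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import AlignedPair, Reference

PAIR_CLASSES = (
    "normal",
    "deletion",
    "insertion",
    "inversion",
    "duplication",
    "translocation",
)


class InsertStatsError(RuntimeError):
    """Insert statistics could not be estimated; supply mu and sigma."""


@dataclass
class InsertStats:
    """Library insert-size distribution (mean, sd) in bp."""

    mean: float
    sd: float
    n_pairs_used: int = 0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise InsertStatsError(
                "insert sd must be positive; supply mean/sd explicitly"
            )


@dataclass(frozen=True)
class PairClass:
    pair: AlignedPair
    sv_class: str  # one of PAIR_CLASSES


@dataclass
class SvCluster:
    """A diagnostic paired-end cluster: same-class pairs supporting one event."""

    sv_class: str
    chrom_left: str
    chrom_right: str
    members: list[AlignedPair] = field(default_factory=list)

    @property
    def support(self) -> int:
        return len(self.members)

    @property
    def left_anchor(self) -> tuple[int, int]:
        starts = [p.left.start for p in self.members]
        ends = [p.left.end for p in self.members]
        return min(starts), max(ends)

    @property
    def right_anchor(self) -> tuple[int, int]:
        starts = [p.right.start for p in self.members]
        ends = [p.right.end for p in self.members]
        return min(starts), max(ends)


@dataclass
class SvCall:
    chrom: str
    start: int  # breakpoint interval, 0-based half-open
    end: int
    type: str
    support: int
    predicted_length: float | None = None
    corrected_length: float | None = None
    chrom2: str | None = None  # translocations
    anchor_start: int = 0  # leftmost member read start
    anchor_end: int = 0  # rightmost member read end
    gap_masked: bool = False
    complex: bool = False


# ---------------------------------------------------------------------------
# Insert statistics
# ---------------------------------------------------------------------------


def estimate_insert_stats(
    pairs: list[AlignedPair], trim: float = 0.01, min_pairs: int = 100
) -> InsertStats:
    """Trimmed mean/sd of spans of correctly oriented same-chromosome pairs.

    The two-sided ``trim`` (default 1% per tail) guards the estimate against
    contamination by pairs straddling real SVs.  Orientation-normal pairs are
    used before any span-based classification, to avoid circularity.
    """
    spans = np.array(
        [
            p.span
            for p in pairs
            if not p.is_interchromosomal and p.orientation == "FR"
        ],
        dtype=float,
    )
    if len(spans) < min_pairs:
        raise InsertStatsError(
            f"only {len(spans)} usable pairs (< {min_pairs}); "
            "supply insert mean/sd explicitly"
        )
    lo, hi = np.quantile(spans, [trim, 1.0 - trim])
    kept = spans[(spans >= lo) & (spans <= hi)]
    mean = float(np.mean(kept))
    sd = float(np.std(kept, ddof=1))
    return InsertStats(mean=mean, sd=sd, n_pairs_used=len(kept))


# ---------------------------------------------------------------------------
# Pair classification
# ---------------------------------------------------------------------------


def classify_pair(
    pair: AlignedPair, stats: InsertStats, span_mult: float = 3.0
) -> PairClass:
    """Assign an SV class from chromosome, orientation and span."""
    if pair.is_interchromosomal:
        return PairClass(pair, "translocation")
    ori = pair.orientation
    if ori in ("FF", "RR"):
        return PairClass(pair, "inversion")
    if ori == "RF":
        return PairClass(pair, "duplication")
    span = pair.span
    if span > stats.mean + span_mult * stats.sd:
        return PairClass(pair, "deletion")
    if span < stats.mean - span_mult * stats.sd:
        return PairClass(pair, "insertion")
    return PairClass(pair, "normal")


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def cluster_abnormal(
    classified: list[PairClass],
    max_sep: float,
    min_support: int = 4,
) -> list[SvCluster]:
    """Group abnormal pairs into diagnostic paired-end clusters.

    Pairs of the same class on the same chromosome pair merge while their
    left-anchor starts stay within ``max_sep`` of the previous member and
    their right anchors, extended by ``max_sep``, still mutually overlap.
    Clusters supported by fewer than ``min_support`` pairs are discarded.
    """
    groups: dict[tuple[str, str, str], list[AlignedPair]] = {}
    for pc in classified:
        if pc.sv_class == "normal":
            continue
        key = (pc.sv_class, pc.pair.left.chrom, pc.pair.right.chrom)
        groups.setdefault(key, []).append(pc.pair)

    clusters: list[SvCluster] = []
    for (sv_class, chrom_l, chrom_r), members in groups.items():
        members.sort(key=lambda p: (p.left.start, p.right.start, p.qname))
        current: list[AlignedPair] = []
        # running intersection of extended right anchors
        r_lo = r_hi = 0.0
        for pair in members:
            p_lo = pair.right.start - max_sep
            p_hi = pair.right.end + max_sep
            if (
                current
                and pair.left.start - current[-1].left.start <= max_sep
                and p_lo < r_hi
                and p_hi > r_lo
            ):
                current.append(pair)
                r_lo = max(r_lo, p_lo)
                r_hi = min(r_hi, p_hi)
            else:
                if len(current) >= min_support:
                    clusters.append(SvCluster(sv_class, chrom_l, chrom_r, current))
                current = [pair]
                r_lo, r_hi = p_lo, p_hi
        if len(current) >= min_support:
            clusters.append(SvCluster(sv_class, chrom_l, chrom_r, current))
    clusters.sort(key=lambda c: (c.chrom_left, c.left_anchor[0]))
    return clusters


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------


def call_sv(
    cluster: SvCluster, stats: InsertStats, bias_correction: float = 0.0
) -> SvCall:
    """Turn one cluster into a typed, sized SV call.

    Deletion length = mean(member spans) - mu, further reduced by
    ``bias_correction`` (the span-mean estimate is biased upward because
    longer fragments are more likely to straddle a breakpoint); insertion
    length = mu - mean(member spans).  The breakpoint interval is the gap
    between the rightmost left-anchor end and the leftmost right-anchor
    start, clamped to >= 1 bp.
    """
    if cluster.support < 1:
        raise ValueError("empty cluster")
    classes = {cluster.sv_class}
    if len(classes) != 1:
        raise RuntimeError("mixed-class cluster: clustering contract violated")

    left = cluster.left_anchor
    right = cluster.right_anchor
    bp_start = left[1]
    bp_end = right[0]
    if bp_end <= bp_start:
        bp_end = bp_start + 1

    predicted = corrected = None
    if cluster.sv_class in ("deletion", "insertion"):
        spans = np.array([p.span for p in cluster.members], dtype=float)
        mean_span = float(np.mean(spans))
        if cluster.sv_class == "deletion":
            predicted = max(mean_span - stats.mean, 1.0)
            corrected = max(predicted - bias_correction, 1.0)
        else:
            predicted = max(stats.mean - mean_span, 1.0)
            corrected = max(predicted - bias_correction, 1.0)
    return SvCall(
        chrom=cluster.chrom_left,
        start=bp_start,
        end=bp_end,
        type=cluster.sv_class,
        support=cluster.support,
        predicted_length=predicted,
        corrected_length=corrected,
        chrom2=cluster.chrom_right if cluster.chrom_right != cluster.chrom_left else None,
        anchor_start=left[0],
        anchor_end=max(right[1], left[1]),
    )


def flag_complex(calls: list[SvCall]) -> list[SvCall]:
    """Flag calls whose breakpoint intervals overlap another call's interval."""
    by_chrom: dict[str, list[SvCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)
    for group in by_chrom.values():
        group.sort(key=lambda c: c.start)
        for i, a in enumerate(group):
            for b in group[i + 1 :]:
                if b.start >= a.end:
                    break
                a.complex = True
                b.complex = True
    return calls


def mask_gap_svs(
    calls: list[SvCall], ref: Reference, use_anchors: bool = True
) -> list[SvCall]:
    """Flag calls overlapping reference gap runs; return the unmasked ones.

    Overlap is tested on the breakpoint interval and (by default) the whole
    anchor span, since alignments crossing a gap are unreliable.  The input
    list keeps its flags so masked calls remain inspectable.
    """
    kept: list[SvCall] = []
    for call in calls:
        runs = ref.gap_runs.get(call.chrom, [])
        lo = min(call.start, call.anchor_start) if use_anchors else call.start
        hi = max(call.end, call.anchor_end) if use_anchors else call.end
        call.gap_masked = any(a < hi and b > lo for a, b in runs)
        if not call.gap_masked:
            kept.append(call)
    return kept


# ---------------------------------------------------------------------------
# Length-bias correction and the full caller
# ---------------------------------------------------------------------------


def estimate_length_bias(calls: list[SvCall], truth_svs) -> float:
    """Mean(predicted - true) over deletion calls matched to truth intervals.

    A regression of predicted on true lengths with the slope fixed at 1; the
    intercept is the additive correction applied by :func:`call_sv`.
    """
    residuals = []
    for call in calls:
        if call.type != "deletion" or call.predicted_length is None:
            continue
        match = _match_truth(call, truth_svs)
        if match is not None:
            residuals.append(call.predicted_length - match.length)
    if not residuals:
        raise ValueError("no deletion calls matched the truth set")
    return float(np.mean(residuals))


def _match_truth(call: SvCall, truth_svs):
    best = None
    for sv in truth_svs:
        if sv.type != call.type or sv.chrom != call.chrom:
            continue
        if sv.start < max(call.end, call.anchor_end) and sv.end > min(
            call.start, call.anchor_start
        ):
            if best is None or abs(sv.start - call.start) < abs(
                best.start - call.start
            ):
                best = sv
    return best


def call_structural_variants(
    pairs: list[AlignedPair],
    ref: Reference,
    stats: InsertStats | None = None,
    span_mult: float = 3.0,
    min_support: int = 4,
    max_sep: float | None = None,
    bias_correction: float = 0.0,
) -> tuple[list[SvCall], InsertStats]:
    """End-to-end SV calling: classify, cluster, call, flag, gap-mask."""
    if stats is None:
        stats = estimate_insert_stats(pairs)
    if max_sep is None:
        max_sep = stats.mean + span_mult * stats.sd
    classified = [classify_pair(p, stats, span_mult) for p in pairs]
    clusters = cluster_abnormal(classified, max_sep=max_sep, min_support=min_support)
    calls = [call_sv(c, stats, bias_correction) for c in clusters]
    flag_complex(calls)
    kept = mask_gap_svs(calls, ref)
    return kept, stats


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------


def write_sv_tsv(calls: list[SvCall], path) -> None:
    cols = (
        "chrom\tstart\tend\ttype\tsupport\tpredicted_length\t"
        "corrected_length\tflags\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for c in calls:
            flags = ",".join(
                f for f, on in (("gap_masked", c.gap_masked), ("complex", c.complex)) if on
            ) or "."
            pred = f"{c.predicted_length:.1f}" if c.predicted_length is not None else "."
            corr = f"{c.corrected_length:.1f}" if c.corrected_length is not None else "."
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.type}\t{c.support}\t"
                f"{pred}\t{corr}\t{flags}\n"
            )


def write_bedpe(calls: list[SvCall], clusters: list[SvCluster] | None, path) -> None:
    """BEDPE with both anchor intervals per call."""
    with open(path, "w") as fh:
        for c in calls:
            chrom2 = c.chrom2 or c.chrom
            fh.write(
                f"{c.chrom}\t{c.anchor_start}\t{c.start}\t"
                f"{chrom2}\t{c.end}\t{c.anchor_end}\t"
                f"{c.type}\t{c.support}\t+\t-\n"
            )
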