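"""SAM round-tripping for aligned pairs (via pysam).

The simulator emits truth alignments; writing them as plain-text SAM and
reading them back is the interchange path with real aligner output.  Errors
are substitutions only, so every CIGAR is a full-length match.
"""

from __future__ import annotations

import pysam

from .simulate import AlignedPair, Read, Reference

_MAPQ = 60


def sam_header(ref: Reference) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": name, "LN": length} for name, length in ref.chrom_lengths().items()
        ],
    }


def write_sam(pairs: list[AlignedPair], ref: Reference, path) -> None:
    header = pysam.AlignmentHeader.from_dict(sam_header(ref))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for pair in pairs:
            a = _segment(pair.qname, pair.read1, pair.read2, True, header)
            b = _segment(pair.qname, pair.read2, pair.read1, False, header)
            _set_tlen(pair, a, b)
            out.write(a)
            out.write(b)


def _segment(
    qname: str, read: Read, mate: Read, first: bool, header: pysam.AlignmentHeader
) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    seg.query_name = qname
    flag = 0x1 | (0x40 if first else 0x80)
    if read.strand == "-":
        flag |= 0x10
    if mate.strand == "-":
        flag |= 0x20
    seg.flag = flag
    seg.reference_name = read.chrom
    seg.reference_start = read.start
    seg.mapping_quality = _MAPQ
    seg.cigartuples = [(0, len(read.seq))]
    seg.next_reference_name = mate.chrom
    seg.next_reference_start = mate.start
    seg.query_sequence = read.seq
    seg.query_qualities = pysam.qualitystring_to_array(
        chr(read.qual + 33) * len(read.seq)
    )
    return seg


def _set_tlen(pair: AlignedPair, a: pysam.AlignedSegment, b: pysam.AlignedSegment):
    span = pair.span
    if span is None:
        return
    first_is_left = (pair.read1.chrom, pair.read1.start) <= (
        pair.read2.chrom,
        pair.read2.start,
    )
    a.template_length = span if first_is_left else -span
    b.template_length = -span if first_is_left else span


def read_sam(path) -> list[AlignedPair]:
    """Re-pair SAM records by query name into AlignedPair objects."""
    first: dict[str, Read] = {}
    second: dict[str, Read] = {}
    with pysam.AlignmentFile(str(path), "r") as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            read = Read(
                chrom=seg.reference_name,
                start=seg.reference_start,
                strand="-" if seg.is_reverse else "+",
                seq=seg.query_sequence,
                qual=int(seg.query_qualities[0]),
            )
            (first if seg.is_read1 else second)[seg.query_name] = read
    pairs = []
    for qname, r1 in first.items():
        r2 = second.get(qname)
        if r2 is not None:
            pairs.append(AlignedPair(qname, r1, r2))
    pairs.sort(key=lambda p: (p.left.chrom, p.left.start, p.qname))
    return pairs
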