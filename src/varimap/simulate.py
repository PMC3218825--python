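"""Synthetic diploid resequencing data.

Generates a reference genome with assembly gaps, implants SNPs and structural
variants into a diploid donor, and emits paired-end reads already placed in
reference coordinates (truth alignments).  The read simulator reproduces the
statistical structure the downstream callers rely on: insert sizes are
Normal(mu, sigma) truncated at twice the read length, sequencing errors are
independent substitutions at a per-base rate epsilon, and reads whose body
would cross a rearrangement breakpoint (or an N-gap) are dropped as
unmappable — so rearrangements are visible only through the span/orientation
signal of pairs that straddle them, exactly as with a short-read aligner.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

from ._util import (
    BASES,
    check_sorted_intervals,
    derive_seed,
    phred_from_error,
    revcomp,
)


class PlacementError(RuntimeError):
    """Requested variants could not be placed without overlap."""


# ---------------------------------------------------------------------------
# Reference
# ---------------------------------------------------------------------------


@dataclass
class Reference:
    """A genome as an ordered map of chromosome sequences over {A,C,G,T,N}.

    ``gap_runs`` lists, per chromosome, the half-open intervals of consecutive
    N bases (assembly gaps); they exactly tile the N positions, sorted and
    non-overlapping.
    """

    chromosomes: dict[str, str]
    gap_runs: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.gap_runs:
            self.gap_runs = {
                name: find_gap_runs(seq) for name, seq in self.chromosomes.items()
            }
        for name in self.chromosomes:
            runs = self.gap_runs.get(name, [])
            if not check_sorted_intervals(runs):
                raise ValueError(f"gap runs for {name} not sorted/non-overlapping")
        self._kmer_cache: dict[int, dict[str, int]] = {}

    @classmethod
    def from_sequences(cls, chromosomes: dict[str, str]) -> "Reference":
        return cls(dict(chromosomes))

    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def in_gap(self, chrom: str, pos: int) -> bool:
        runs = self.gap_runs.get(chrom, [])
        i = bisect.bisect_right([r[0] for r in runs], pos) - 1
        return i >= 0 and pos < runs[i][1]

    def kmer_counts(self, k: int) -> dict[str, int]:
        """Genome-wide k-mer occurrence counts (N-containing k-mers skipped).

        Cached on the instance; used by the flank copy-number filter.
        """
        if k not in self._kmer_cache:
            counts: dict[str, int] = {}
            for seq in self.chromosomes.values():
                for i in range(len(seq) - k + 1):
                    kmer = seq[i : i + k]
                    if "N" in kmer:
                        continue
                    counts[kmer] = counts.get(kmer, 0) + 1
            self._kmer_cache[k] = counts
        return self._kmer_cache[k]

    def write_fasta(self, path) -> None:
        write_fasta(self.chromosomes, path)

    @classmethod
    def read_fasta(cls, path) -> "Reference":
        from Bio import SeqIO

        chroms = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        return cls(chroms)


def find_gap_runs(seq: str) -> list[tuple[int, int]]:
    runs: list[tuple[int, int]] = []
    start = None
    for i, b in enumerate(seq):
        if b == "N":
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(seq)))
    return runs


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def generate_reference(
    n_chrom: int,
    chrom_len: int,
    gc: float = 0.41,
    gap_spec: tuple[int, int] = (0, 0),
    seed: int = 0,
) -> Reference:
    """Random reference with ``n_chrom`` chromosomes of ``chrom_len`` bp.

    ``gap_spec`` = (number of N-runs per chromosome, run length); runs are
    placed at non-overlapping random positions.  Base composition matches
    ``gc`` in expectation.  Deterministic for a given seed.
    """
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    n_gaps, gap_len = gap_spec
    if n_gaps * gap_len >= chrom_len:
        raise ValueError("total gap length must be smaller than chromosome length")
    rng = np.random.default_rng(derive_seed(seed, "reference"))
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    chroms: dict[str, str] = {}
    for c in range(n_chrom):
        codes = rng.choice(4, size=chrom_len, p=probs)
        arr = np.frombuffer(BASES.encode(), dtype=np.uint8)[codes].copy()
        for start in _place_nonoverlapping(rng, chrom_len, [gap_len] * n_gaps):
            arr[start : start + gap_len] = ord("N")
        chroms[f"chr{c + 1}"] = arr.tobytes().decode("ascii")
    return Reference(chroms)


def _place_nonoverlapping(
    rng: np.random.Generator,
    length: int,
    sizes: list[int],
    max_tries: int = 1000,
    occupied: list[tuple[int, int]] | None = None,
) -> list[int]:
    """Random non-overlapping placement of intervals of the given sizes."""
    placed: list[tuple[int, int]] = list(occupied or [])
    n_pre = len(placed)
    for size in sizes:
        for _ in range(max_tries):
            s = int(rng.integers(0, length - size + 1))
            if all(s + size <= a or s >= b for a, b in placed):
                placed.append((s, s + size))
                break
        else:
            raise PlacementError(f"could not place interval of size {size}")
    return [s for s, _ in placed[n_pre:]]


# ---------------------------------------------------------------------------
# Truth set
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SnpTruth:
    chrom: str
    pos: int
    ref: str
    alt: str
    zygosity: str  # "het" | "hom"


@dataclass(frozen=True)
class SvTruth:
    chrom: str
    start: int
    end: int
    type: str  # "deletion" | "insertion" | "inversion"
    length: int
    zygosity: str  # "het" | "hom"


@dataclass
class TruthSet:
    """Ground-truth variant list emitted by the simulator."""

    snps: list[SnpTruth] = field(default_factory=list)
    svs: list[SvTruth] = field(default_factory=list)
    placement_bias: dict[str, float] | None = None

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tstart\tend\ttype\tref\talt\tzygosity\n")
            for s in self.snps:
                fh.write(
                    f"{s.chrom}\t{s.pos}\t{s.pos + 1}\tsnp\t{s.ref}\t{s.alt}\t{s.zygosity}\n"
                )
            for v in self.svs:
                fh.write(
                    f"{v.chrom}\t{v.start}\t{v.end}\t{v.type}\t.\t.\t{v.zygosity}\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "TruthSet":
        ts = cls()
        with open(path) as fh:
            next(fh)
            for line in fh:
                chrom, start, end, typ, ref, alt, zyg = line.rstrip("\n").split("\t")
                if typ == "snp":
                    ts.snps.append(SnpTruth(chrom, int(start), ref, alt, zyg))
                else:
                    s, e = int(start), int(end)
                    length = e - s if typ != "insertion" else 0
                    ts.svs.append(SvTruth(chrom, s, e, typ, length, zyg))
        return ts


# ---------------------------------------------------------------------------
# Donor haplotypes and the donor -> reference coordinate map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Block:
    """Maps donor interval [donor_start, donor_end) onto the reference.

    strand "+": colinear, ref interval starts at ref_start.
    strand "-": inverted segment; donor position d maps to
    ref_end - 1 - (d - donor_start).
    strand ".": novel (inserted) sequence with no reference image.
    """

    donor_start: int
    donor_end: int
    ref_start: int
    ref_end: int
    strand: str


class Haplotype:
    """One donor haplotype: per-chromosome sequence plus coordinate map."""

    def __init__(self, name: str):
        self.name = name
        self.sequences: dict[str, str] = {}
        self.blocks: dict[str, list[Block]] = {}
        self._starts: dict[str, list[int]] = {}

    def add_chromosome(self, chrom: str, seq: str, blocks: list[Block]) -> None:
        self.sequences[chrom] = seq
        self.blocks[chrom] = blocks
        self._starts[chrom] = [b.donor_start for b in blocks]

    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def map_read(self, chrom: str, start: int, end: int):
        """Reference placement of donor interval [start, end).

        Returns (ref_start, flipped) if the interval lies entirely within one
        colinear or inverted block, else None (unmappable read).
        """
        starts = self._starts[chrom]
        i = bisect.bisect_right(starts, start) - 1
        if i < 0:
            return None
        b = self.blocks[chrom][i]
        if end > b.donor_end or b.strand == ".":
            return None
        if b.strand == "+":
            return b.ref_start + (start - b.donor_start), False
        return b.ref_end - (end - b.donor_start), True


def _apply_variants(
    ref: Reference,
    snps_by_chrom: dict[str, list[tuple[int, str]]],
    svs_by_chrom: dict[str, list[SvTruth]],
    name: str,
    rng: np.random.Generator,
) -> Haplotype:
    hap = Haplotype(name)
    for chrom, seq in ref.chromosomes.items():
        arr = bytearray(seq, "ascii")
        for pos, alt in snps_by_chrom.get(chrom, []):
            arr[pos] = ord(alt)
        edited = arr.decode("ascii")
        parts: list[str] = []
        blocks: list[Block] = []
        cursor = 0  # reference coordinate
        dpos = 0  # donor coordinate
        for sv in sorted(svs_by_chrom.get(chrom, []), key=lambda v: v.start):
            if sv.start > cursor:
                seg = edited[cursor : sv.start]
                blocks.append(Block(dpos, dpos + len(seg), cursor, sv.start, "+"))
                parts.append(seg)
                dpos += len(seg)
            if sv.type == "deletion":
                cursor = sv.end
            elif sv.type == "insertion":
                novel = "".join(rng.choice(list("ACGT"), size=sv.length))
                blocks.append(Block(dpos, dpos + sv.length, sv.start, sv.start, "."))
                parts.append(novel)
                dpos += sv.length
                cursor = sv.start
            elif sv.type == "inversion":
                seg = revcomp(edited[sv.start : sv.end])
                blocks.append(Block(dpos, dpos + len(seg), sv.start, sv.end, "-"))
                parts.append(seg)
                dpos += len(seg)
                cursor = sv.end
            else:
                raise ValueError(f"unsupported SV type for implanting: {sv.type}")
        if cursor < len(edited):
            seg = edited[cursor:]
            blocks.append(Block(dpos, dpos + len(seg), cursor, len(edited), "+"))
            parts.append(seg)
        hap.add_chromosome(chrom, "".join(parts), blocks)
    return hap


# ---------------------------------------------------------------------------
# Variant implanting
# ---------------------------------------------------------------------------


def deletion_length_sampler(
    rng: np.random.Generator,
    n: int,
    median: float = 184.0,
    log_sd: float = 1.0,
    min_len: int = 25,
    max_len: int = 10000,
) -> np.ndarray:
    """Log-normal deletion lengths, median ~184 bp, truncated to [25, 10 kb]."""
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        draw = np.rint(rng.lognormal(np.log(median), log_sd, size=2 * (n - filled)))
        draw = draw[(draw >= min_len) & (draw <= max_len)].astype(np.int64)
        take = min(len(draw), n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


@dataclass
class SvSpec:
    """Counts per SV type, their length distribution and placement bias.

    ``placement_bias`` maps genomic-element categories (intergenic, intronic,
    ...) to probabilities; honoured only when gene models are supplied to
    :func:`implant_variants`.  ``het_fraction`` is the probability an SV is
    carried on a single haplotype.
    """

    counts: dict[str, int] = field(default_factory=dict)
    length_dist: str = "lognormal"  # or "uniform"
    length_median: float = 184.0
    length_log_sd: float = 1.0
    min_len: int = 25
    max_len: int = 10000
    placement_bias: dict[str, float] | None = None
    het_fraction: float = 0.5

    def sample_lengths(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.length_dist == "uniform":
            return rng.integers(self.min_len, self.max_len + 1, size=n)
        return deletion_length_sampler(
            rng, n, self.length_median, self.length_log_sd, self.min_len, self.max_len
        )


def implant_variants(
    ref: Reference,
    het_rate: float,
    hom_rate: float,
    sv_spec: SvSpec | None = None,
    seed: int = 0,
    min_snp_spacing: int = 10,
    models=None,
) -> tuple[tuple[Haplotype, Haplotype], TruthSet]:
    """Implant SNPs and SVs into a diploid donor.

    Heterozygous/homozygous SNP rates are per eligible (non-N, non-SV) base.
    SNPs closer than ``min_snp_spacing`` are thinned; variants never fall in
    gap runs.  Returns the two haplotypes and the ground-truth variant list.
    """
    if het_rate < 0 or hom_rate < 0:
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(derive_seed(seed, "implant"))
    truth = TruthSet(placement_bias=sv_spec.placement_bias if sv_spec else None)

    element_index = None
    if sv_spec is not None and sv_spec.placement_bias and models is not None:
        from .annotate import ElementIndex

        element_index = ElementIndex(models, ref.chrom_lengths())

    # --- SVs first: SNPs then avoid their footprints -----------------------
    sv_by_chrom: dict[str, list[SvTruth]] = {c: [] for c in ref.chromosomes}
    if sv_spec is not None:
        chrom_names = list(ref.chromosomes)
        lengths_per_chrom = ref.chrom_lengths()
        weights = np.array([lengths_per_chrom[c] for c in chrom_names], dtype=float)
        weights /= weights.sum()
        occupied: dict[str, list[tuple[int, int]]] = {
            c: list(ref.gap_runs.get(c, [])) for c in chrom_names
        }
        for sv_type, count in sv_spec.counts.items():
            lengths = sv_spec.sample_lengths(rng, count)
            for L in lengths:
                L = int(L)
                placed = False
                for _ in range(2000):
                    chrom = chrom_names[int(rng.choice(len(chrom_names), p=weights))]
                    clen = lengths_per_chrom[chrom]
                    span = 1 if sv_type == "insertion" else L
                    if clen <= span + 2:
                        continue
                    start = int(rng.integers(1, clen - span))
                    end = start if sv_type == "insertion" else start + L
                    if any(start - 1 < b and end + 1 > a for a, b in occupied[chrom]):
                        continue
                    if element_index is not None:
                        mid = (start + max(end, start + 1)) // 2
                        cat = element_index.classify(chrom, mid, mid + 1)
                        p_accept = sv_spec.placement_bias.get(cat, 0.0)
                        if rng.random() >= p_accept:
                            continue
                    zyg = "het" if rng.random() < sv_spec.het_fraction else "hom"
                    sv = SvTruth(chrom, start, end, sv_type, L, zyg)
                    sv_by_chrom[chrom].append(sv)
                    truth.svs.append(sv)
                    occupied[chrom].append((start, max(end, start + 1)))
                    placed = True
                    break
                if not placed:
                    raise PlacementError(
                        f"could not place {sv_type} of length {L} without overlap"
                    )

    # --- SNPs ---------------------------------------------------------------
    snps_h0: dict[str, list[tuple[int, str]]] = {}
    snps_h1: dict[str, list[tuple[int, str]]] = {}
    for chrom, seq in ref.chromosomes.items():
        forbidden = list(ref.gap_runs.get(chrom, [])) + [
            (v.start, max(v.end, v.start + 1)) for v in sv_by_chrom[chrom]
        ]
        mask = np.ones(len(seq), dtype=bool)
        for a, b in forbidden:
            mask[a:b] = False
        eligible = np.flatnonzero(mask)
        n_het = rng.binomial(len(eligible), het_rate)
        n_hom = rng.binomial(len(eligible), hom_rate)
        total = min(n_het + n_hom, len(eligible))
        if total == 0:
            continue
        positions = rng.choice(eligible, size=total, replace=False)
        positions.sort()
        keep = _thin_spaced(positions, min_snp_spacing)
        positions = positions[keep]
        is_het = np.zeros(len(positions), dtype=bool)
        het_share = n_het / max(n_het + n_hom, 1)
        is_het[rng.random(len(positions)) < het_share] = True
        for pos, het in zip(positions, is_het):
            pos = int(pos)
            ref_base = seq[pos]
            alt = BASES[(BASES.index(ref_base) + int(rng.integers(1, 4))) % 4]
            zyg = "het" if het else "hom"
            truth.snps.append(SnpTruth(chrom, pos, ref_base, alt, zyg))
            if zyg == "hom":
                snps_h0.setdefault(chrom, []).append((pos, alt))
                snps_h1.setdefault(chrom, []).append((pos, alt))
            elif rng.random() < 0.5:
                snps_h0.setdefault(chrom, []).append((pos, alt))
            else:
                snps_h1.setdefault(chrom, []).append((pos, alt))

    svs_h0: dict[str, list[SvTruth]] = {c: [] for c in ref.chromosomes}
    svs_h1: dict[str, list[SvTruth]] = {c: [] for c in ref.chromosomes}
    for chrom, svs in sv_by_chrom.items():
        for sv in svs:
            if sv.zygosity == "hom":
                svs_h0[chrom].append(sv)
                svs_h1[chrom].append(sv)
            elif rng.random() < 0.5:
                svs_h0[chrom].append(sv)
            else:
                svs_h1[chrom].append(sv)

    hap0 = _apply_variants(ref, snps_h0, svs_h0, "hap0", rng)
    hap1 = _apply_variants(ref, snps_h1, svs_h1, "hap1", rng)
    truth.snps.sort(key=lambda s: (s.chrom, s.pos))
    truth.svs.sort(key=lambda v: (v.chrom, v.start))
    return (hap0, hap1), truth


def _thin_spaced(sorted_positions: np.ndarray, min_spacing: int) -> np.ndarray:
    """Greedy mask keeping positions at least min_spacing apart."""
    keep = np.zeros(len(sorted_positions), dtype=bool)
    last = -(10**12)
    for i, p in enumerate(sorted_positions):
        if p - last >= min_spacing:
            keep[i] = True
            last = p
    return keep


# ---------------------------------------------------------------------------
# Read pairs
# ---------------------------------------------------------------------------


@dataclass
class ReadPairParams:
    """Sequencing design: fold-coverage, read length, insert distribution.

    ``error_rate`` is the per-base substitution probability; all bases of a
    run share the single Phred value implied by it (capped at ``qual_cap``
    when the rate is 0).
    """

    depth: float = 11.56
    read_len: int = 44
    insert_mean: float = 200.0
    insert_sd: float = 20.0
    error_rate: float = 0.01
    seed: int = 0
    qual_cap: int = 40

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.read_len < 1:
            raise ValueError("read_len must be >= 1")
        if self.insert_mean < 2 * self.read_len:
            raise ValueError("insert_mean must be >= 2 * read_len")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")

    @property
    def base_quality(self) -> int:
        return phred_from_error(self.error_rate, cap=self.qual_cap)


@dataclass(frozen=True)
class Read:
    """A mapped read in reference-forward orientation (as SAM stores SEQ)."""

    chrom: str
    start: int  # 0-based reference start
    strand: str  # "+" | "-"
    seq: str
    qual: int  # single Phred value for all bases

    @property
    def end(self) -> int:
        return self.start + len(self.seq)


@dataclass(frozen=True)
class AlignedPair:
    """A mate pair placed on the reference; the unit of evidence downstream."""

    qname: str
    read1: Read
    read2: Read

    @property
    def is_interchromosomal(self) -> bool:
        return self.read1.chrom != self.read2.chrom

    def _ordered(self) -> tuple[Read, Read]:
        a, b = self.read1, self.read2
        if (a.chrom, a.start) <= (b.chrom, b.start):
            return a, b
        return b, a

    @property
    def left(self) -> Read:
        return self._ordered()[0]

    @property
    def right(self) -> Read:
        return self._ordered()[1]

    @property
    def span(self) -> int | None:
        """Outer distance between the outermost mapped coordinates."""
        if self.is_interchromosomal:
            return None
        left, right = self._ordered()
        return right.end - left.start

    @property
    def orientation(self) -> str:
        """Strand pattern ordered by position: 'FR', 'RF', 'FF' or 'RR'."""
        left, right = self._ordered()
        return ("F" if left.strand == "+" else "R") + (
            "F" if right.strand == "+" else "R"
        )


def simulate_read_pairs(
    donor: tuple[Haplotype, Haplotype],
    params: ReadPairParams,
) -> list[AlignedPair]:
    """Sample paired-end fragments from the diploid donor.

    The pair count is depth * genome_len / (2 * read_len).  Each fragment
    picks a haplotype uniformly, a chromosome proportional to its length and
    a uniform start; both reads are placed back into reference coordinates
    through the haplotype's block map.  Fragments containing N, or with a
    read crossing a block boundary (breakpoint/insertion), are dropped.
    """
    hap0, hap1 = donor
    if hap0.total_length() == 0 or hap1.total_length() == 0:
        raise ValueError("donor haplotypes are empty")
    rng = np.random.default_rng(derive_seed(params.seed, "reads"))
    genome_len = 0.5 * (hap0.total_length() + hap1.total_length())
    n_pairs = int(round(params.depth * genome_len / (2 * params.read_len)))
    r = params.read_len
    q = params.base_quality
    eps = params.error_rate

    haps = (hap0, hap1)
    chrom_tables = []
    for hap in haps:
        names = list(hap.sequences)
        lens = np.array([len(hap.sequences[c]) for c in names], dtype=float)
        chrom_tables.append((names, np.cumsum(lens / lens.sum())))

    hap_pick = rng.integers(0, 2, size=n_pairs)
    u = rng.random(n_pairs)
    chrom_pick = np.empty(n_pairs, dtype=np.int64)
    for h in (0, 1):
        sel = hap_pick == h
        chrom_pick[sel] = np.searchsorted(chrom_tables[h][1], u[sel], side="right")
    inserts = _truncated_normal_ints(
        rng, params.insert_mean, params.insert_sd, 2 * r, n_pairs
    )

    pairs: list[AlignedPair] = []
    other = np.array(list("ACGT"))
    for i in range(n_pairs):
        hap = haps[hap_pick[i]]
        names, _ = chrom_tables[hap_pick[i]]
        chrom = names[min(int(chrom_pick[i]), len(names) - 1)]
        seq = hap.sequences[chrom]
        L = int(inserts[i])
        if L > len(seq):
            continue
        s = int(rng.integers(0, len(seq) - L + 1))
        frag = seq[s : s + L]
        if "N" in frag:
            continue
        m1 = hap.map_read(chrom, s, s + r)
        m2 = hap.map_read(chrom, s + L - r, s + L)
        if m1 is None or m2 is None:
            continue
        reads = []
        for (start_ref, flipped), dslice, ostrand in (
            (m1, frag[:r], "+"),
            (m2, frag[L - r :], "-"),
        ):
            strand = ostrand
            ref_fwd = dslice
            if flipped:
                strand = "-" if strand == "+" else "+"
                ref_fwd = revcomp(dslice)
            if eps > 0:
                ref_fwd = _apply_errors(rng, ref_fwd, eps, other)
            reads.append(Read(chrom, start_ref, strand, ref_fwd, q))
        pairs.append(AlignedPair(f"sim{i}", reads[0], reads[1]))
    return pairs


def _truncated_normal_ints(
    rng: np.random.Generator, mu: float, sd: float, lower: int, n: int
) -> np.ndarray:
    out = np.rint(rng.normal(mu, sd, size=n)).astype(np.int64)
    for _ in range(100):
        bad = out < lower
        if not bad.any():
            break
        out[bad] = np.rint(rng.normal(mu, sd, size=int(bad.sum()))).astype(np.int64)
    np.clip(out, lower, None, out=out)
    return out


def _apply_errors(
    rng: np.random.Generator, seq: str, eps: float, alphabet: np.ndarray
) -> str:
    mask = rng.random(len(seq)) < eps
    if not mask.any():
        return seq
    arr = list(seq)
    for j in np.flatnonzero(mask):
        cur = arr[j]
        choices = [b for b in "ACGT" if b != cur]
        arr[j] = choices[int(rng.integers(0, 3))]
    return "".join(arr)


def generate_gene_models(
    ref: Reference,
    n_genes: int,
    seed: int = 0,
    exon_range: tuple[int, int] = (2, 6),
    cds_exon_len: int = 150,
    intron_len: int = 400,
    utr_len: int = 100,
):
    """Random non-overlapping protein-coding gene models on the reference.

    Each gene has ``k`` exons (k drawn from ``exon_range``): the first and
    last carry a UTR flank, every exon contributes a CDS chunk whose length
    is a multiple of 3, and exons are separated by fixed-length introns.
    Returns an :class:`~varimap.annotate.GeneModelSet`.
    """
    from .annotate import Gene, GeneModelSet, Transcript

    rng = np.random.default_rng(derive_seed(seed, "genes"))
    chrom_names = list(ref.chromosomes)
    lens = np.array([len(ref.chromosomes[c]) for c in chrom_names], dtype=float)
    shares = np.floor(n_genes * lens / lens.sum()).astype(int)
    while shares.sum() < n_genes:
        shares[int(np.argmax(lens))] += 1

    genes: list[Gene] = []
    gid = 0
    for chrom, n_here in zip(chrom_names, shares):
        if n_here == 0:
            continue
        ks = rng.integers(exon_range[0], exon_range[1] + 1, size=n_here)
        sizes = [
            2 * utr_len + int(k) * cds_exon_len + (int(k) - 1) * intron_len
            for k in ks
        ]
        starts = _place_nonoverlapping(
            rng,
            len(ref.chromosomes[chrom]),
            sizes,
            occupied=list(ref.gap_runs.get(chrom, [])),
        )
        for k, start in zip(ks, starts):
            k = int(k)
            strand = "+" if rng.random() < 0.5 else "-"
            exons: list[tuple[int, int]] = []
            cds: list[tuple[int, int]] = []
            cursor = start
            for i in range(k):
                lead = utr_len if i == 0 else 0
                tail = utr_len if i == k - 1 else 0
                exon = (cursor, cursor + lead + cds_exon_len + tail)
                cds.append((cursor + lead, cursor + lead + cds_exon_len))
                exons.append(exon)
                cursor = exon[1] + intron_len
            gid += 1
            name = f"gene{gid}"
            genes.append(
                Gene(
                    id=name,
                    chrom=chrom,
                    strand=strand,
                    transcripts=[
                        Transcript(f"{name}.t1", strand, exons, cds, f"{name}.p1")
                    ],
                )
            )
    return GeneModelSet(genes)


def write_fastq(pairs: list[AlignedPair], prefix: str) -> tuple[str, str]:
    """Write mates to <prefix>_1.fastq / <prefix>_2.fastq (sequenced orientation)."""
    p1, p2 = f"{prefix}_1.fastq", f"{prefix}_2.fastq"
    with open(p1, "w") as f1, open(p2, "w") as f2:
        for pair in pairs:
            for fh, read, suffix in ((f1, pair.read1, "/1"), (f2, pair.read2, "/2")):
                seq = read.seq if read.strand == "+" else revcomp(read.seq)
                qual = chr(read.qual + 33) * len(seq)
                fh.write(f"@{pair.qname}{suffix}\n{seq}\n+\n{qual}\n")
    return p1, p2
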