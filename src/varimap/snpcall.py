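"""Bayesian diploid genotype calling and the SNP filter cascade.

From pileups of aligned reads a posterior over the 10 unordered diploid
genotypes is computed per position using Phred-scaled base qualities
(P(b|a) = 1-e if b = a else e/3, alleles mixed half-and-half, reads
independent).  The consensus genotype is the posterior argmax, with its
Phred-scaled consensus quality.  Candidate variant sites then pass a filter
cascade: consensus quality >= Q20, flanking-sequence copy number < 2, depth
<= 100, at least four supporting reads per required allele, and a >= 5 bp
spacing between neighbouring candidates (both members of a closer pair are
removed).  A cumulative-Poisson bound gives the rate at which sequencing
errors alone could fake that level of allele support.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np
from scipy.special import logsumexp
from scipy.stats import poisson

from ._util import BASES, encode_bases, error_from_phred
from .simulate import Reference

logger = logging.getLogger(__name__)

#: the 10 unordered diploid genotypes, lexicographic
GENOTYPES: tuple[tuple[str, str], ...] = tuple(
    combinations_with_replacement(BASES, 2)
)
_GT_INDEX = {g: i for i, g in enumerate(GENOTYPES)}


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class PileupColumn:
    chrom: str
    pos: int
    ref_base: str
    observations: list[tuple[str, int]]  # (base, phred quality)

    @property
    def depth(self) -> int:
        return len(self.observations)


@dataclass
class GenotypeCall:
    chrom: str
    pos: int
    ref_base: str
    genotype: tuple[str, str]
    posterior: float
    cns_quality: int
    allele_depths: dict[str, int]

    @property
    def depth(self) -> int:
        return sum(self.allele_depths.values())

    @property
    def is_variant(self) -> bool:
        return self.genotype != (self.ref_base, self.ref_base)


@dataclass
class FilterCriteria:
    """Thresholds of the SNP filter cascade."""

    min_cns_quality: int = 20
    max_flank_copy_number: float = 2.0  # exclusive
    min_snp_spacing: int = 5  # >= passes
    max_depth: int = 100
    min_reads_per_allele: int = 4
    flank_window: int = 25
    kmer_size: int = 17

    def __post_init__(self) -> None:
        for name in (
            "min_cns_quality",
            "max_flank_copy_number",
            "min_snp_spacing",
            "max_depth",
            "min_reads_per_allele",
            "flank_window",
            "kmer_size",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SnpRecord:
    call: GenotypeCall
    zygosity: str | None  # "het" | "hom" | None (non-variant)
    filter_status: str  # "PASS" or first failing filter's name

    @property
    def passed(self) -> bool:
        return self.filter_status == "PASS"


# ---------------------------------------------------------------------------
# Prior
# ---------------------------------------------------------------------------


@dataclass
class GenotypePrior:
    """Diploid genotype prior given the reference base.

    theta_het is shared by the three heterozygous genotypes containing the
    reference allele, theta_hom by the three homozygous non-reference
    genotypes, theta_other by the three heterozygotes without the reference
    allele; the remaining mass goes to hom-ref.  Magnitudes follow the
    ~2 variants/kb scale of a primate resequencing study.
    """

    theta_het: float = 1e-3
    theta_hom: float = 5e-4
    theta_other: float = 1e-5

    def log_matrix(self) -> np.ndarray:
        """(4 ref bases x 10 genotypes) log-prior matrix."""
        out = np.empty((4, len(GENOTYPES)))
        for r, ref in enumerate(BASES):
            hom_ref_mass = 1.0 - self.theta_het - self.theta_hom - self.theta_other
            for g, (a1, a2) in enumerate(GENOTYPES):
                if a1 == a2 == ref:
                    p = hom_ref_mass
                elif a1 == a2:
                    p = self.theta_hom / 3
                elif ref in (a1, a2):
                    p = self.theta_het / 3
                else:
                    p = self.theta_other / 3
                out[r, g] = math.log(p)
        return out


def _log_obs_matrix(eps: float) -> np.ndarray:
    """(10 genotypes x 4 bases) log P(observed base | genotype) at error eps."""
    out = np.empty((len(GENOTYPES), 4))
    for g, (a1, a2) in enumerate(GENOTYPES):
        for b, base in enumerate(BASES):
            p1 = 1.0 - eps if base == a1 else eps / 3.0
            p2 = 1.0 - eps if base == a2 else eps / 3.0
            out[g, b] = math.log(0.5 * p1 + 0.5 * p2)
    return out


def _preference_orders() -> np.ndarray:
    """(4 ref bases x 10) genotype indices, ref-containing first, then lex."""
    out = np.empty((4, len(GENOTYPES)), dtype=np.int64)
    for r, ref in enumerate(BASES):
        order = sorted(
            range(len(GENOTYPES)), key=lambda g: (ref not in GENOTYPES[g], GENOTYPES[g])
        )
        out[r] = order
    return out


_PREF_ORDERS = _preference_orders()


# ---------------------------------------------------------------------------
# Pileup
# ---------------------------------------------------------------------------


def build_pileup(pairs, ref: Reference):
    """Yield one PileupColumn per covered, non-gap reference position.

    Reads overhanging the chromosome end are rejected with a diagnostic.
    Columns come out sorted by (chrom, pos).
    """
    columns: dict[str, dict[int, list[tuple[str, int]]]] = {}
    n_rejected = 0
    for pair in pairs:
        for read in (pair.read1, pair.read2):
            clen = len(ref.chromosomes[read.chrom])
            if read.start < 0 or read.end > clen:
                n_rejected += 1
                continue
            bychrom = columns.setdefault(read.chrom, {})
            for i, base in enumerate(read.seq):
                bychrom.setdefault(read.start + i, []).append((base, read.qual))
    if n_rejected:
        logger.warning("rejected %d reads overhanging chromosome ends", n_rejected)
    for chrom in sorted(columns):
        seq = ref.chromosomes[chrom]
        for pos in sorted(columns[chrom]):
            ref_base = seq[pos]
            if ref_base == "N":
                continue
            yield PileupColumn(chrom, pos, ref_base, columns[chrom][pos])


def pileup_counts(pairs, ref: Reference) -> dict[str, np.ndarray]:
    """Vectorised pileup: per chromosome a (4, L) array of base counts.

    Positions whose reference base is N are zeroed out (gap exclusion).
    Equivalent to :func:`build_pileup` when all base qualities are equal.
    """
    per_chrom_pos: dict[str, list[np.ndarray]] = {c: [] for c in ref.chromosomes}
    per_chrom_code: dict[str, list[np.ndarray]] = {c: [] for c in ref.chromosomes}
    n_rejected = 0
    for pair in pairs:
        for read in (pair.read1, pair.read2):
            clen = len(ref.chromosomes[read.chrom])
            if read.start < 0 or read.end > clen:
                n_rejected += 1
                continue
            codes = encode_bases(read.seq)
            per_chrom_pos[read.chrom].append(
                np.arange(read.start, read.end, dtype=np.int64)
            )
            per_chrom_code[read.chrom].append(codes.astype(np.int64))
    if n_rejected:
        logger.warning("rejected %d reads overhanging chromosome ends", n_rejected)
    out: dict[str, np.ndarray] = {}
    for chrom, seq in ref.chromosomes.items():
        L = len(seq)
        counts = np.zeros((4, L), dtype=np.uint32)
        if per_chrom_pos[chrom]:
            pos = np.concatenate(per_chrom_pos[chrom])
            code = np.concatenate(per_chrom_code[chrom])
            valid = code < 4
            flat = np.bincount(
                code[valid] * L + pos[valid], minlength=4 * L
            ).astype(np.uint32)
            counts = flat.reshape(4, L)
        ref_codes = encode_bases(seq)
        counts[:, ref_codes == 4] = 0
        out[chrom] = counts
    return out


# ---------------------------------------------------------------------------
# Genotype calling
# ---------------------------------------------------------------------------

_QUALITY_CAP = 99


def _phred_cns(posterior: np.ndarray | float, cap: int = _QUALITY_CAP):
    err = np.clip(1.0 - posterior, 1e-12, 1.0)
    q = np.rint(-10.0 * np.log10(err))
    return np.minimum(q, cap).astype(np.int64)


def call_genotype(
    column: PileupColumn, prior: GenotypePrior | None = None
) -> GenotypeCall | None:
    """Posterior-argmax diploid genotype for one pileup column.

    Handles per-base qualities.  Returns None (no call) for an empty column.
    Ties break toward genotypes containing the reference allele, then
    lexicographically.
    """
    if column.depth == 0:
        return None
    prior = prior or GenotypePrior()
    ref_code = BASES.index(column.ref_base) if column.ref_base in BASES else None
    log_prior = (
        prior.log_matrix()[ref_code]
        if ref_code is not None
        else np.full(len(GENOTYPES), -math.log(len(GENOTYPES)))
    )
    loglik = np.zeros(len(GENOTYPES))
    for base, q in column.observations:
        eps = error_from_phred(q)
        b = BASES.index(base)
        for g, (a1, a2) in enumerate(GENOTYPES):
            p1 = 1.0 - eps if b == BASES.index(a1) else eps / 3.0
            p2 = 1.0 - eps if b == BASES.index(a2) else eps / 3.0
            loglik[g] += math.log(0.5 * p1 + 0.5 * p2)
    total = loglik + log_prior
    lse = logsumexp(total)
    order = _PREF_ORDERS[ref_code] if ref_code is not None else np.arange(10)
    best = order[int(np.argmax(total[order]))]
    posterior = float(np.exp(total[best] - lse))
    depths: dict[str, int] = {}
    for base, _ in column.observations:
        depths[base] = depths.get(base, 0) + 1
    return GenotypeCall(
        chrom=column.chrom,
        pos=column.pos,
        ref_base=column.ref_base,
        genotype=GENOTYPES[best],
        posterior=posterior,
        cns_quality=int(_phred_cns(posterior)),
        allele_depths=depths,
    )


class Consensus:
    """Genome-wide consensus: per-chromosome call arrays plus accessors."""

    def __init__(self, ref: Reference):
        self.ref = ref
        self._data: dict[str, dict[str, np.ndarray]] = {}
        self._counts: dict[str, np.ndarray] = {}

    def add_chrom(self, chrom, positions, gt_idx, posterior, cns_q, counts):
        self._data[chrom] = {
            "pos": positions,
            "gt": gt_idx,
            "posterior": posterior,
            "cns_q": cns_q,
        }
        self._counts[chrom] = counts

    def _make_call(self, chrom: str, i: int) -> GenotypeCall:
        d = self._data[chrom]
        pos = int(d["pos"][i])
        col = self._counts[chrom][:, pos]
        depths = {BASES[b]: int(col[b]) for b in range(4) if col[b] > 0}
        return GenotypeCall(
            chrom=chrom,
            pos=pos,
            ref_base=self.ref.chromosomes[chrom][pos],
            genotype=GENOTYPES[int(d["gt"][i])],
            posterior=float(d["posterior"][i]),
            cns_quality=int(d["cns_q"][i]),
            allele_depths=depths,
        )

    def call_at(self, chrom: str, pos: int) -> GenotypeCall | None:
        d = self._data.get(chrom)
        if d is None:
            return None
        i = int(np.searchsorted(d["pos"], pos))
        if i >= len(d["pos"]) or d["pos"][i] != pos:
            return None
        return self._make_call(chrom, i)

    def candidates(self) -> list[GenotypeCall]:
        """Calls whose genotype differs from hom-ref, sorted by (chrom, pos)."""
        out: list[GenotypeCall] = []
        for chrom in sorted(self._data):
            d = self._data[chrom]
            ref_codes = encode_bases(self.ref.chromosomes[chrom])
            hom_ref_idx = np.array(
                [_GT_INDEX[(b, b)] for b in BASES], dtype=np.int64
            )
            site_ref = ref_codes[d["pos"]]
            is_var = d["gt"] != np.where(
                site_ref < 4, hom_ref_idx[np.clip(site_ref, 0, 3)], -1
            )
            for i in np.flatnonzero(is_var):
                out.append(self._make_call(chrom, int(i)))
        return out

    def n_called_sites(self) -> int:
        return sum(len(d["pos"]) for d in self._data.values())


def call_consensus(
    counts_by_chrom: dict[str, np.ndarray],
    ref: Reference,
    base_quality: int,
    prior: GenotypePrior | None = None,
) -> Consensus:
    """Vectorised genome-wide genotype calling for uniform base quality.

    Matches :func:`call_genotype` column-by-column when every observation in
    a column carries ``base_quality``.
    """
    prior = prior or GenotypePrior()
    eps = error_from_phred(base_quality)
    log_obs = _log_obs_matrix(eps)  # (10, 4)
    log_prior = prior.log_matrix()  # (4, 10)
    cns = Consensus(ref)
    for chrom, counts in counts_by_chrom.items():
        ref_codes = encode_bases(ref.chromosomes[chrom])
        depth = counts.sum(axis=0)
        covered = np.flatnonzero((depth > 0) & (ref_codes < 4))
        if len(covered) == 0:
            cns.add_chrom(
                chrom,
                covered,
                np.empty(0, np.int64),
                np.empty(0),
                np.empty(0, np.int64),
                counts,
            )
            continue
        sub = counts[:, covered].astype(np.float64)  # (4, n)
        total = log_obs @ sub  # (10, n)
        rc = ref_codes[covered]
        total += log_prior[rc].T
        lse = logsumexp(total, axis=0)
        pref = _PREF_ORDERS[rc]  # (n, 10)
        vals = np.take_along_axis(total.T, pref, axis=1)  # (n, 10)
        j = np.argmax(vals, axis=1)
        rows = np.arange(len(covered))
        gt_idx = pref[rows, j]
        posterior = np.exp(vals[rows, j] - lse)
        cns.add_chrom(chrom, covered, gt_idx, posterior, _phred_cns(posterior), counts)
    return cns


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def flank_copy_number(
    ref: Reference, chrom: str, pos: int, window: int = 25, k: int = 17
) -> float:
    """Mean genome-wide occurrence count of the k-mers overlapping the
    +/-window flank of a position.

    A unique region scores 1.0; an exact two-copy repeat scores 2.0.  If all
    flank k-mers contain N the estimate is undefined (returned as inf so the
    site fails the < 2 filter by convention).
    """
    if window < k:
        raise ValueError("window must be >= k")
    seq = ref.chromosomes[chrom]
    table = ref.kmer_counts(k)
    lo = max(0, pos - window - k + 1)
    hi = min(len(seq) - k, pos + window)
    vals = []
    for s in range(lo, hi + 1):
        kmer = seq[s : s + k]
        if "N" in kmer:
            continue
        vals.append(table.get(kmer, 0))
    if not vals:
        return math.inf
    return float(np.mean(vals))


def classify_zygosity(genotype: tuple[str, str], ref_base: str) -> str | None:
    """het for two distinct alleles, hom for identical non-reference alleles,
    None (non-variant) for hom-ref."""
    a1, a2 = genotype
    if a1 != a2:
        return "het"
    if a1 != ref_base:
        return "hom"
    return None


def filter_candidates(
    calls: list[GenotypeCall],
    ref: Reference,
    criteria: FilterCriteria | None = None,
) -> list[SnpRecord]:
    """Apply the filter cascade to position-sorted candidate calls.

    Each record carries PASS or the first failing filter's name, checked in
    the order: min_cns_quality, max_flank_copy_number, max_depth,
    min_reads_per_allele, min_snp_spacing.  A spacing violation removes both
    members of the close pair.
    """
    criteria = criteria or FilterCriteria()
    keys = [(c.chrom, c.pos) for c in calls]
    if keys != sorted(keys):
        raise ValueError("candidate calls must be sorted by (chrom, pos)")

    too_close = [False] * len(calls)
    for i in range(1, len(calls)):
        a, b = calls[i - 1], calls[i]
        if a.chrom == b.chrom and (b.pos - a.pos) < criteria.min_snp_spacing:
            too_close[i - 1] = True
            too_close[i] = True

    records: list[SnpRecord] = []
    for i, call in enumerate(calls):
        zyg = classify_zygosity(call.genotype, call.ref_base)
        status = "PASS"
        if call.cns_quality < criteria.min_cns_quality:
            status = "min_cns_quality"
        elif (
            flank_copy_number(
                ref, call.chrom, call.pos, criteria.flank_window, criteria.kmer_size
            )
            >= criteria.max_flank_copy_number
        ):
            status = "max_flank_copy_number"
        elif call.depth > criteria.max_depth:
            status = "max_depth"
        elif not _allele_support_ok(call, zyg, criteria.min_reads_per_allele):
            status = "min_reads_per_allele"
        elif too_close[i]:
            status = "min_snp_spacing"
        records.append(SnpRecord(call, zyg, status))
    return records


def _allele_support_ok(call: GenotypeCall, zygosity: str | None, min_reads: int) -> bool:
    if zygosity is None:
        return False
    if zygosity == "het":
        return all(call.allele_depths.get(a, 0) >= min_reads for a in call.genotype)
    return call.allele_depths.get(call.genotype[0], 0) >= min_reads


def poisson_support_fdr(depth_lambda: float, error_rate: float, k_min: int) -> float:
    """P(X >= k_min) for X ~ Poisson(depth * error_rate).

    The chance that sequencing errors alone supply k_min or more reads
    supporting a spurious allele at one site.
    """
    if depth_lambda <= 0:
        raise ValueError("depth_lambda must be positive")
    if not 0 <= error_rate <= 1:
        raise ValueError("error_rate must be in [0, 1]")
    if k_min < 0:
        raise ValueError("k_min must be >= 0")
    return float(poisson.sf(k_min - 1, depth_lambda * error_rate))


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------


def write_vcf(
    records: list[SnpRecord],
    ref: Reference,
    path,
    sample: str = "donor",
    include_failures: bool = False,
) -> None:
    """Write passing SNP records (optionally failures too) as VCF 4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=varimap\n")
        for name, length in ref.chrom_lengths().items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        for name in (
            "min_cns_quality",
            "max_flank_copy_number",
            "max_depth",
            "min_reads_per_allele",
            "min_snp_spacing",
        ):
            fh.write(f'##FILTER=<ID={name},Description="failed {name}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        for rec in records:
            if not rec.passed and not include_failures:
                continue
            call = rec.call
            alts = sorted({a for a in call.genotype if a != call.ref_base})
            if not alts:
                continue
            alleles = [call.ref_base] + alts
            gt = "/".join(
                str(alleles.index(a)) for a in sorted(call.genotype, key=alleles.index)
            )
            ad = ",".join(str(call.allele_depths.get(a, 0)) for a in alleles)
            fh.write(
                f"{call.chrom}\t{call.pos + 1}\t.\t{call.ref_base}\t{','.join(alts)}"
                f"\t{call.cns_quality}\t{rec.filter_status}\t.\tGT:DP:AD\t"
                f"{gt}:{call.depth}:{ad}\n"
            )
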