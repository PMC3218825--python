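"""Functional annotation of variants.

Covers: genomic-element classification (CDS > UTR > intron > intergenic by
the interval midpoint), synonymous/nonsynonymous consequence calls on the
longest transcript of each gene, reciprocal-best-hit orthology from
precomputed BLASTP-style hit tables, intersection of nonsynonymous SNPs with
protein (druggable) domain intervals, and a Monte-Carlo chi-squared test for
bias of an interval set's genomic distribution against length-matched random
regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from ._util import derive_seed, revcomp
from .simulate import Reference

CATEGORIES = ("CDS", "UTR", "intronic", "intergenic")


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


@dataclass
class Transcript:
    id: str
    strand: str
    exons: list[tuple[int, int]]  # 0-based half-open, sorted
    cds: list[tuple[int, int]]
    protein_id: str | None = None

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class Gene:
    id: str
    chrom: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)

    def longest_transcript(self) -> Transcript | None:
        """The representative transcript: longest CDS, frame-valid only."""
        valid = [t for t in self.transcripts if t.cds and t.cds_length % 3 == 0]
        if not valid:
            return None
        return max(valid, key=lambda t: (t.cds_length, t.id))

    @property
    def span(self) -> tuple[int, int]:
        starts = [t.span[0] for t in self.transcripts]
        ends = [t.span[1] for t in self.transcripts]
        return min(starts), max(ends)


class GeneModelSet:
    """Gene models keyed by id, with per-chromosome interval indexes."""

    def __init__(self, genes: list[Gene]):
        self.genes: dict[str, Gene] = {g.id: g for g in genes}

    def __len__(self) -> int:
        return len(self.genes)

    def by_chrom(self) -> dict[str, list[Gene]]:
        out: dict[str, list[Gene]] = {}
        for g in self.genes.values():
            out.setdefault(g.chrom, []).append(g)
        return out

    @classmethod
    def from_gff3(cls, path) -> "GeneModelSet":
        import gffutils

        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        genes: list[Gene] = []
        for grec in db.features_of_type("gene"):
            gene = Gene(id=grec.id, chrom=grec.seqid, strand=grec.strand)
            for trec in db.children(grec, featuretype=("mRNA", "transcript")):
                exons = [
                    (f.start - 1, f.end)
                    for f in db.children(trec, featuretype="exon")
                ]
                cds = [
                    (f.start - 1, f.end) for f in db.children(trec, featuretype="CDS")
                ]
                protein = trec.attributes.get("protein_id", [None])[0]
                if not exons:
                    exons = cds[:]
                gene.transcripts.append(
                    Transcript(trec.id, trec.strand, exons, cds, protein)
                )
            if gene.transcripts:
                genes.append(gene)
        return cls(genes)

    def to_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for gene in self.genes.values():
                gs, ge = gene.span
                fh.write(
                    f"{gene.chrom}\tvarimap\tgene\t{gs + 1}\t{ge}\t.\t"
                    f"{gene.strand}\t.\tID={gene.id}\n"
                )
                for t in gene.transcripts:
                    ts, te = t.span
                    attrs = f"ID={t.id};Parent={gene.id}"
                    if t.protein_id:
                        attrs += f";protein_id={t.protein_id}"
                    fh.write(
                        f"{gene.chrom}\tvarimap\tmRNA\t{ts + 1}\t{te}\t.\t"
                        f"{t.strand}\t.\t{attrs}\n"
                    )
                    for i, (s, e) in enumerate(t.exons):
                        fh.write(
                            f"{gene.chrom}\tvarimap\texon\t{s + 1}\t{e}\t.\t"
                            f"{t.strand}\t.\tID={t.id}.exon{i};Parent={t.id}\n"
                        )
                    phase = 0
                    cds_iter = t.cds if t.strand == "+" else t.cds[::-1]
                    for i, (s, e) in enumerate(cds_iter):
                        fh.write(
                            f"{gene.chrom}\tvarimap\tCDS\t{s + 1}\t{e}\t.\t"
                            f"{t.strand}\t{phase}\tID={t.id}.cds{i};Parent={t.id}\n"
                        )
                        phase = (3 - ((e - s) - phase) % 3) % 3


# ---------------------------------------------------------------------------
# Element classification
# ---------------------------------------------------------------------------


def _merge_intervals(ivs: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    if not ivs:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    ivs = sorted(ivs)
    starts, ends = [ivs[0][0]], [ivs[0][1]]
    for s, e in ivs[1:]:
        if s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.array(starts, np.int64), np.array(ends, np.int64)


class ElementIndex:
    """Per-chromosome merged interval tracks for CDS / UTR / intron lookup.

    Tracks come from the longest transcript of every gene; classification of
    a position applies the precedence CDS > UTR > intron > intergenic.
    """

    def __init__(self, models: GeneModelSet, chrom_lengths: dict[str, int]):
        self.chrom_lengths = chrom_lengths
        self._tracks: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
        cds_by, utr_by, intron_by = {}, {}, {}
        for gene in models.genes.values():
            t = gene.longest_transcript()
            if t is None:
                continue
            cds_by.setdefault(gene.chrom, []).extend(t.cds)
            cds_set = t.cds
            for es, ee in t.exons:
                # exon minus CDS = UTR pieces
                pieces = [(es, ee)]
                for cs, ce in cds_set:
                    new = []
                    for ps, pe in pieces:
                        if ce <= ps or cs >= pe:
                            new.append((ps, pe))
                        else:
                            if ps < cs:
                                new.append((ps, cs))
                            if ce < pe:
                                new.append((ce, pe))
                    pieces = new
                utr_by.setdefault(gene.chrom, []).extend(pieces)
            ts, te = t.span
            prev = ts
            for es, ee in t.exons:
                if es > prev:
                    intron_by.setdefault(gene.chrom, []).append((prev, es))
                prev = max(prev, ee)
        for chrom in chrom_lengths:
            self._tracks[chrom] = {
                "CDS": _merge_intervals(cds_by.get(chrom, [])),
                "UTR": _merge_intervals(utr_by.get(chrom, [])),
                "intronic": _merge_intervals(intron_by.get(chrom, [])),
            }

    def classify_positions(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Category codes (index into CATEGORIES) for an array of positions."""
        out = np.full(len(positions), CATEGORIES.index("intergenic"), dtype=np.int64)
        tracks = self._tracks.get(chrom)
        if tracks is None:
            return out
        for cat in ("intronic", "UTR", "CDS"):  # low to high precedence
            starts, ends = tracks[cat]
            if len(starts) == 0:
                continue
            i = np.searchsorted(starts, positions, side="right") - 1
            inside = (i >= 0) & (positions < ends[np.clip(i, 0, None)])
            out[inside] = CATEGORIES.index(cat)
        return out

    def classify(self, chrom: str, start: int, end: int) -> str:
        mid = (start + end) // 2
        code = self.classify_positions(chrom, np.array([mid], dtype=np.int64))[0]
        return CATEGORIES[int(code)]


def classify_element(
    chrom: str, interval: tuple[int, int], index: ElementIndex
) -> str:
    """Genomic-element category of an interval, judged at its midpoint."""
    return index.classify(chrom, interval[0], interval[1])


# ---------------------------------------------------------------------------
# Coding consequences
# ---------------------------------------------------------------------------


@dataclass
class ConsequenceRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str
    transcript_id: str
    protein_id: str | None
    cds_offset: int
    codon_before: str
    codon_after: str
    aa_before: str
    aa_after: str
    consequence: str  # "synonymous" | "nonsynonymous"

    @property
    def aa_pos(self) -> int:
        """1-based amino-acid position."""
        return self.cds_offset // 3 + 1


def cds_sequence(transcript: Transcript, ref: Reference, chrom: str) -> str:
    """Spliced coding sequence in translation orientation."""
    seq = "".join(ref.chromosomes[chrom][s:e] for s, e in transcript.cds)
    return revcomp(seq) if transcript.strand == "-" else seq


def _cds_offset(transcript: Transcript, pos: int) -> int | None:
    """Offset of a genomic position within the spliced CDS, strand-aware."""
    genomic = 0
    found = None
    for s, e in transcript.cds:
        if s <= pos < e:
            found = genomic + (pos - s)
            break
        genomic += e - s
    if found is None:
        return None
    if transcript.strand == "-":
        return transcript.cds_length - 1 - found
    return found


def annotate_coding_snp(
    chrom: str,
    pos: int,
    ref_base: str,
    alt: str,
    gene: Gene,
    ref: Reference,
) -> ConsequenceRecord | None:
    """Consequence of a single-base substitution on a gene's longest transcript.

    Returns None if the position is outside the transcript's CDS.  Codons are
    read from the spliced CDS; minus-strand transcripts use the reverse
    complement, so the substituted base is complemented before the codon
    comparison.  Synonymous iff the amino acid is unchanged under the
    standard genetic code.
    """
    t = gene.longest_transcript()
    if t is None:
        return None
    offset = _cds_offset(t, pos)
    if offset is None:
        return None
    cds = cds_sequence(t, ref, chrom)
    codon_idx = offset // 3
    within = offset % 3
    codon_before = cds[codon_idx * 3 : codon_idx * 3 + 3]
    sub = alt if t.strand == "+" else revcomp(alt)
    codon_after = (
        codon_before[:within] + sub + codon_before[within + 1 :]
    )
    aa_before = str(Seq(codon_before).translate())
    aa_after = str(Seq(codon_after).translate())
    return ConsequenceRecord(
        chrom=chrom,
        pos=pos,
        ref=ref_base,
        alt=alt,
        gene_id=gene.id,
        transcript_id=t.id,
        protein_id=t.protein_id,
        cds_offset=offset,
        codon_before=codon_before,
        codon_after=codon_after,
        aa_before=aa_before,
        aa_after=aa_after,
        consequence="synonymous" if aa_before == aa_after else "nonsynonymous",
    )


def annotate_snps(
    snps,
    models: GeneModelSet,
    ref: Reference,
) -> tuple[list[ConsequenceRecord], dict[str, int]]:
    """Annotate SNP records: coding consequences plus non-coding tallies.

    ``snps`` yields objects with chrom, pos, ref_base/ref and alternate
    alleles (het SNPs are annotated once per alternate allele).  Returns the
    coding consequence records and a count of element categories over all
    SNPs (each SNP contributing its midpoint category exactly once).
    """
    index = ElementIndex(models, ref.chrom_lengths())
    genes_by_chrom = models.by_chrom()
    consequences: list[ConsequenceRecord] = []
    category_counts = {c: 0 for c in CATEGORIES}
    for snp in snps:
        obj = getattr(snp, "call", None) or snp  # unwrap SnpRecord
        chrom, pos = obj.chrom, obj.pos
        ref_base = getattr(obj, "ref_base", None) or obj.ref
        alts = _alt_alleles(obj, ref_base)
        category_counts[index.classify(chrom, pos, pos + 1)] += 1
        for gene in genes_by_chrom.get(chrom, []):
            gs, ge = gene.span
            if not gs <= pos < ge:
                continue
            for alt in alts:
                rec = annotate_coding_snp(chrom, pos, ref_base, alt, gene, ref)
                if rec is not None:
                    consequences.append(rec)
    return consequences, category_counts


def _alt_alleles(snp, ref_base: str) -> list[str]:
    genotype = getattr(snp, "genotype", None)
    if genotype is None:
        call = getattr(snp, "call", None)
        if call is not None:
            genotype = call.genotype
    if genotype is not None:
        return sorted({a for a in genotype if a != ref_base})
    return [snp.alt]


# ---------------------------------------------------------------------------
# Reciprocal best hits
# ---------------------------------------------------------------------------


def read_hit_table(path) -> pd.DataFrame:
    """Read a hit table: 4-column TSV (query, subject, bitscore, evalue) with
    header, or headerless BLAST outfmt-6 (12 columns)."""
    first = open(path).readline().rstrip("\n").split("\t")
    if len(first) == 12:
        df = pd.read_csv(path, sep="\t", header=None)
        df = df[[0, 1, 11, 10]]
        df.columns = ["query", "subject", "bitscore", "evalue"]
    else:
        df = pd.read_csv(path, sep="\t")
        df = df[["query", "subject", "bitscore", "evalue"]]
    return df


def _best_hits(table: pd.DataFrame) -> pd.DataFrame:
    """Best subject per query: max bitscore, ties by min e-value then
    lexicographic subject id; a residual tie is flagged."""
    df = (
        table.sort_values(
            ["query", "bitscore", "evalue", "subject"],
            ascending=[True, False, True, True],
        )
        .drop_duplicates(["query", "subject"])
        .copy()
    )
    best_rows = []
    for query, grp in df.groupby("query", sort=False):
        top_score = grp["bitscore"].iloc[0]
        contenders = grp[grp["bitscore"] == top_score]
        row = contenders.iloc[0]
        best_rows.append(
            {
                "query": query,
                "subject": row["subject"],
                "tie": len(contenders) > 1,
            }
        )
    return pd.DataFrame(best_rows)


def reciprocal_best_hit(ab: pd.DataFrame, ba: pd.DataFrame) -> pd.DataFrame:
    """Ortholog pairs (a, b): b is a's best subject in ab AND a is b's best
    subject in ba.  Bitscore ties resolve by e-value then subject id and the
    pair is flagged ``tie``."""
    best_ab = _best_hits(ab)
    best_ba = _best_hits(ba)
    back = dict(zip(best_ba["query"], best_ba["subject"]))
    back_tie = dict(zip(best_ba["query"], best_ba["tie"]))
    rows = []
    for _, r in best_ab.iterrows():
        a, b = r["query"], r["subject"]
        if back.get(b) == a:
            rows.append(
                {"a": a, "b": b, "tie": bool(r["tie"] or back_tie.get(b, False))}
            )
    return pd.DataFrame(rows, columns=["a", "b", "tie"])


# ---------------------------------------------------------------------------
# Druggable domains
# ---------------------------------------------------------------------------


def read_domain_table(path) -> pd.DataFrame:
    """TSV of (protein_id, domain_id, start_aa, end_aa), 1-based inclusive."""
    df = pd.read_csv(path, sep="\t")
    return df[["protein_id", "domain_id", "start_aa", "end_aa"]]


def map_druggable_domains(
    consequences: list[ConsequenceRecord], domains: pd.DataFrame
) -> pd.DataFrame:
    """Nonsynonymous SNPs whose amino-acid position falls inside a domain
    interval of their protein; a SNP may hit several domains."""
    rows = []
    by_protein: dict[str, pd.DataFrame] = {
        str(pid): grp for pid, grp in domains.groupby("protein_id")
    }
    for rec in consequences:
        if rec.consequence != "nonsynonymous" or rec.protein_id is None:
            continue
        grp = by_protein.get(str(rec.protein_id))
        if grp is None:
            continue
        aa = rec.aa_pos
        hits = grp[(grp["start_aa"] <= aa) & (aa <= grp["end_aa"])]
        for _, d in hits.iterrows():
            rows.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "alt": rec.alt,
                    "gene_id": rec.gene_id,
                    "protein_id": rec.protein_id,
                    "domain_id": d["domain_id"],
                    "aa_pos": aa,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "alt", "gene_id", "protein_id", "domain_id", "aa_pos"],
    )


# ---------------------------------------------------------------------------
# Monte-Carlo genomic-distribution bias test
# ---------------------------------------------------------------------------


@dataclass
class BiasTestResult:
    statistic: float
    p_value: float
    observed_counts: dict[str, int]
    expected_props: dict[str, float]
    replicates: int


def _sample_midpoints(
    rng: np.random.Generator,
    ref: Reference,
    n: int,
    chrom_names: list[str],
    chrom_probs: np.ndarray | None,
    per_chrom: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Random interval midpoints avoiding gap runs.

    per_chrom=True draws n per chromosome; otherwise n total with chromosome
    probability proportional to length.
    """
    lengths = {c: len(ref.chromosomes[c]) for c in chrom_names}
    if per_chrom:
        chrom_idx = np.repeat(np.arange(len(chrom_names)), n)
    else:
        chrom_idx = rng.choice(len(chrom_names), size=n, p=chrom_probs)
    mids = np.empty(len(chrom_idx), dtype=np.int64)
    for ci, chrom in enumerate(chrom_names):
        sel = np.flatnonzero(chrom_idx == ci)
        if len(sel) == 0:
            continue
        L = lengths[chrom]
        runs = ref.gap_runs.get(chrom, [])
        gap_starts = np.array([a for a, _ in runs], dtype=np.int64)
        gap_ends = np.array([b for _, b in runs], dtype=np.int64)
        draw = rng.integers(0, L, size=len(sel))
        for _ in range(50):
            if len(gap_starts) == 0:
                break
            j = np.searchsorted(gap_starts, draw, side="right") - 1
            bad = (j >= 0) & (draw < gap_ends[np.clip(j, 0, None)])
            if not bad.any():
                break
            draw[bad] = rng.integers(0, L, size=int(bad.sum()))
        mids[sel] = draw
    return chrom_idx, mids


def monte_carlo_bias_test(
    observed: list[tuple[str, int, int]],
    models: GeneModelSet,
    ref: Reference,
    n_per_chrom: int = 1000,
    replicates: int = 1000,
    seed: int = 0,
) -> BiasTestResult:
    """Chi-squared test of an interval set's element distribution against
    random placement, with a Monte-Carlo null.

    Expected category proportions come from one draw of ``n_per_chrom``
    random gap-avoiding positions per chromosome.  The null distribution of
    the statistic comes from ``replicates`` re-draws of |observed| random
    positions; p = (1 + #{null >= observed}) / (replicates + 1).  Categories
    with expected count < 5 are merged into "other" before the statistic.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if not observed:
        raise ValueError("observed interval set is empty")
    rng = np.random.default_rng(derive_seed(seed, "mc-bias"))
    index = ElementIndex(models, ref.chrom_lengths())
    chrom_names = list(ref.chromosomes)
    lens = np.array([len(ref.chromosomes[c]) for c in chrom_names], dtype=float)
    chrom_probs = lens / lens.sum()
    K = len(CATEGORIES)
    n_obs = len(observed)

    def classify_many(chrom_idx: np.ndarray, mids: np.ndarray) -> np.ndarray:
        codes = np.empty(len(mids), dtype=np.int64)
        for ci, chrom in enumerate(chrom_names):
            sel = np.flatnonzero(chrom_idx == ci)
            if len(sel):
                codes[sel] = index.classify_positions(chrom, mids[sel])
        return codes

    # observed category counts (midpoint rule)
    obs_codes = np.empty(n_obs, dtype=np.int64)
    for i, (chrom, start, end) in enumerate(observed):
        mid = (start + end) // 2
        obs_codes[i] = index.classify_positions(chrom, np.array([mid]))[0]
    obs_counts = np.bincount(obs_codes, minlength=K).astype(float)

    # expected proportions from one structured draw
    ci_exp, mid_exp = _sample_midpoints(
        rng, ref, n_per_chrom, chrom_names, None, per_chrom=True
    )
    exp_counts = np.bincount(classify_many(ci_exp, mid_exp), minlength=K).astype(float)
    exp_props = exp_counts / exp_counts.sum()

    # merge categories whose expected count (at n_obs scale) is < 5
    exp_at_obs = exp_props * n_obs
    small = exp_at_obs < 5
    if small.sum() >= K - 1:
        raise ValueError("too few expected counts to form a statistic")

    def merged(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        big_counts = counts[~small]
        big_props = exp_props[~small]
        if small.any():
            big_counts = np.append(big_counts, counts[small].sum())
            big_props = np.append(big_props, exp_props[small].sum())
        return big_counts, big_props

    def statistic(counts: np.ndarray) -> float:
        c, p = merged(counts)
        exp = p * counts.sum()
        valid = exp > 0
        return float(np.sum((c[valid] - exp[valid]) ** 2 / exp[valid]))

    stat_obs = statistic(obs_counts)

    # null: replicate draws of n_obs random positions
    ci_null, mid_null = _sample_midpoints(
        rng, ref, replicates * n_obs, chrom_names, chrom_probs, per_chrom=False
    )
    null_codes = classify_many(ci_null, mid_null).reshape(replicates, n_obs)
    null_counts = np.stack(
        [np.bincount(null_codes[r], minlength=K) for r in range(replicates)]
    ).astype(float)
    null_stats = np.array([statistic(null_counts[r]) for r in range(replicates)])
    p = (1.0 + float(np.sum(null_stats >= stat_obs))) / (replicates + 1.0)

    return BiasTestResult(
        statistic=stat_obs,
        p_value=p,
        observed_counts={CATEGORIES[i]: int(obs_counts[i]) for i in range(K)},
        expected_props={CATEGORIES[i]: float(exp_props[i]) for i in range(K)},
        replicates=replicates,
    )
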