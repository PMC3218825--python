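"""Summary statistics and population-identity analysis.

Per-window SNP densities (1-Mb windows by default, sex chromosomes
excludable), exact SNP-sharing arithmetic between call sets, ordinary
(Felsenstein) bootstrap support for average-linkage hierarchical clustering
of genotype dosage profiles, and a resequencing summary report whose ratios
are always recomputed from their own integer fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, to_tree

from ._util import derive_seed


# ---------------------------------------------------------------------------
# Window densities
# ---------------------------------------------------------------------------


def window_density(
    snps,
    chrom_lengths: dict[str, int],
    window: int = 1_000_000,
    exclude: set[str] | frozenset[str] = frozenset(),
) -> pd.DataFrame:
    """SNP counts and densities (per kb) in fixed non-overlapping windows.

    The final partial window keeps its true span.  Chromosomes in
    ``exclude`` (e.g. sex chromosomes) are left out entirely; the sum of
    window counts equals the total SNP count on included chromosomes.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    counts: dict[str, np.ndarray] = {}
    for chrom, length in chrom_lengths.items():
        if chrom in exclude:
            continue
        n_windows = max(1, -(-length // window))
        counts[chrom] = np.zeros(n_windows, dtype=np.int64)
    for snp in snps:
        obj = getattr(snp, "call", None) or snp
        if obj.chrom in counts:
            counts[obj.chrom][obj.pos // window] += 1
    rows = []
    for chrom, arr in counts.items():
        length = chrom_lengths[chrom]
        for i, c in enumerate(arr):
            span = min(window, length - i * window)
            rows.append(
                {
                    "chrom": chrom,
                    "window_index": i,
                    "window_start": i * window,
                    "window_span": span,
                    "snp_count": int(c),
                    "density_per_kb": 1000.0 * c / span,
                }
            )
    return pd.DataFrame(rows)


def plot_window_density(densities: pd.DataFrame, path) -> None:
    """Cosmetic per-chromosome density plot (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    for chrom, grp in densities.groupby("chrom"):
        ax.plot(grp["window_start"] / 1e6, grp["density_per_kb"], label=chrom)
    ax.set_xlabel("position (Mb)")
    ax.set_ylabel("SNPs per kb")
    ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Call-set comparison
# ---------------------------------------------------------------------------


@dataclass
class SnpSetComparison:
    shared: int
    a_only: int
    b_only: int

    @property
    def shared_fraction_of_b(self) -> float | None:
        n_b = self.shared + self.b_only
        return self.shared / n_b if n_b else None


def compare_snp_sets(a: set, b: set) -> SnpSetComparison:
    """Exact set arithmetic on sites keyed by (chrom, pos, alt allele);
    the shared fraction is measured against b (the evaluation set)."""
    a, b = set(a), set(b)
    inter = a & b
    return SnpSetComparison(
        shared=len(inter), a_only=len(a - b), b_only=len(b - a)
    )


# ---------------------------------------------------------------------------
# Bootstrap hierarchical clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    samples: list[str]
    linkage: np.ndarray
    supports: dict[frozenset, float]

    def support_of(self, group) -> float:
        """Bootstrap support of a sample bipartition (group vs rest)."""
        g = frozenset(group)
        comp = frozenset(self.samples) - g
        return max(self.supports.get(g, 0.0), self.supports.get(comp, 0.0))

    def newick(self) -> str:
        tree = to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.samples[node.id]
            leaves = frozenset(self.samples[i] for i in node.pre_order(lambda n: n.id))
            support = self.supports.get(leaves)
            label = f"{support:.3f}" if support is not None else ""
            return f"({walk(node.left)},{walk(node.right)}){label}:{node.dist:.4f}"

        return walk(tree).rsplit(":", 1)[0] + ";"


def allele_sharing_distance(matrix: pd.DataFrame) -> np.ndarray:
    """Condensed allele-sharing dissimilarity: mean |dosage diff| / 2."""
    X = matrix.to_numpy(dtype=float)
    n = X.shape[0]
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            out.append(np.nanmean(np.abs(X[i] - X[j])) / 2.0)
    return np.array(out)


def _clades(Z: np.ndarray, samples: list[str]) -> set[frozenset]:
    tree = to_tree(Z)
    clades: set[frozenset] = set()

    def walk(node):
        if node.is_leaf():
            return frozenset([samples[node.id]])
        left = walk(node.left)
        right = walk(node.right)
        clade = left | right
        clades.add(clade)
        return clade

    walk(tree)
    return clades


def cluster_bootstrap(
    matrix: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> ClusterResult:
    """Average-linkage clustering of samples x loci dosages with ordinary
    bootstrap support.

    Loci are resampled with replacement ``n_boot`` times; the support of a
    branch is the fraction of replicates whose tree contains the same sample
    clade.  Samples are sorted by id first so the result is input-order
    invariant; seed-deterministic.
    """
    if matrix.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    if matrix.shape[1] < 10:
        raise ValueError("need at least 10 loci")
    matrix = matrix.sort_index()
    samples = list(matrix.index)
    rng = np.random.default_rng(derive_seed(seed, "bootstrap"))
    Z = average(allele_sharing_distance(matrix))
    ref_clades = _clades(Z, samples)
    hits = {c: 0 for c in ref_clades}
    n_loci = matrix.shape[1]
    for _ in range(n_boot):
        idx = rng.integers(0, n_loci, size=n_loci)
        Zb = average(allele_sharing_distance(matrix.iloc[:, idx]))
        for clade in _clades(Zb, samples):
            if clade in hits:
                hits[clade] += 1
    supports = {c: hits[c] / n_boot for c in ref_clades}
    return ClusterResult(samples=samples, linkage=Z, supports=supports)


# ---------------------------------------------------------------------------
# Summary report
# ---------------------------------------------------------------------------


@dataclass
class MappingStats:
    genome_size: int
    effective_length: int  # non-gap reference bases
    n_reads: int
    n_mapped_reads: int
    n_bases: int
    n_mapped_bases: int
    n_covered_bases: int | None = None


@dataclass
class SummaryReport:
    """Resequencing summary; every ratio is recomputed from its own counts."""

    mapping: MappingStats | None = None
    n_het: int = 0
    n_hom: int = 0
    sv_counts: dict[str, int] = field(default_factory=dict)
    n_deletions_repeat_overlap: int | None = None
    n_coding_snps: int | None = None
    n_nonsynonymous: int | None = None

    @property
    def n_snps(self) -> int:
        return self.n_het + self.n_hom

    @property
    def het_hom_ratio(self) -> float | None:
        return self.n_het / self.n_hom if self.n_hom else None

    @property
    def effective_depth(self) -> float | None:
        m = self.mapping
        if m is None or not m.effective_length:
            return None
        return m.n_mapped_bases / m.effective_length

    @property
    def mapped_read_fraction(self) -> float | None:
        m = self.mapping
        if m is None or not m.n_reads:
            return None
        return m.n_mapped_reads / m.n_reads

    @property
    def coverage_fraction(self) -> float | None:
        m = self.mapping
        if m is None or m.n_covered_bases is None or not m.genome_size:
            return None
        return m.n_covered_bases / m.genome_size

    @property
    def snp_density_per_kb(self) -> float | None:
        m = self.mapping
        if m is None or not m.effective_length:
            return None
        return self.n_snps / (m.effective_length / 1000.0)

    @property
    def n_svs(self) -> int:
        return sum(self.sv_counts.values())

    @property
    def deletion_fraction(self) -> float | None:
        total = self.n_svs
        return self.sv_counts.get("deletion", 0) / total if total else None

    @property
    def repeat_overlap_fraction(self) -> float | None:
        n_del = self.sv_counts.get("deletion", 0)
        if self.n_deletions_repeat_overlap is None or not n_del:
            return None
        return self.n_deletions_repeat_overlap / n_del

    @property
    def nonsynonymous_fraction(self) -> float | None:
        if self.n_coding_snps in (None, 0) or self.n_nonsynonymous is None:
            return None
        return self.n_nonsynonymous / self.n_coding_snps

    def summary(self) -> str:
        def fmt(x, scale=1.0, nd=2):
            return "NA" if x is None else f"{x * scale:.{nd}f}"

        lines = [
            "Resequencing summary",
            f"  SNPs total/het/hom: {self.n_snps}/{self.n_het}/{self.n_hom}",
            f"  het:hom ratio:      {fmt(self.het_hom_ratio)}",
            f"  effective depth:    {fmt(self.effective_depth)}",
            f"  mapped reads:       {fmt(self.mapped_read_fraction, 100)}%",
            f"  genome coverage:    {fmt(self.coverage_fraction, 100)}%",
            f"  SNP density:        {fmt(self.snp_density_per_kb)} /kb",
            f"  SVs by type:        {dict(sorted(self.sv_counts.items()))}",
            f"  deletion fraction:  {fmt(self.deletion_fraction, 100, 1)}%",
        ]
        if self.n_coding_snps is not None:
            lines.append(
                f"  coding/nonsyn SNPs: {self.n_coding_snps}/{self.n_nonsynonymous}"
                f" ({fmt(self.nonsynonymous_fraction, 100, 1)}%)"
            )
        return "\n".join(lines)


def summary_report(
    snps=None, svs=None, mapping: MappingStats | None = None, **extra
) -> SummaryReport:
    """Build a SummaryReport from SNP records, SV calls and mapping stats."""
    n_het = n_hom = 0
    for rec in snps or []:
        zyg = getattr(rec, "zygosity", None)
        if zyg == "het":
            n_het += 1
        elif zyg == "hom":
            n_hom += 1
    sv_counts: dict[str, int] = {}
    for sv in svs or []:
        sv_counts[sv.type] = sv_counts.get(sv.type, 0) + 1
    return SummaryReport(
        mapping=mapping, n_het=n_het, n_hom=n_hom, sv_counts=sv_counts, **extra
    )
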