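"""Independent oracles used by the test suite.

Each oracle recomputes a quantity along a different code path than the
implementation it checks: linear-space enumeration for the genotype
posterior, a double-argmax scan for reciprocal best hits, and whole-CDS
translation diffing for coding consequences.
"""

from itertools import combinations_with_replacement

import numpy as np
from Bio.Seq import Seq

from varimap import simulate as sim
from varimap.annotate import cds_sequence
from varimap.snpcall import GenotypePrior


def brute_force_genotype(column, prior=None):
    """Linear-space posterior over all 10 diploid genotypes."""
    prior = prior or GenotypePrior()
    bases = "ACGT"
    probs = {}
    for g in combinations_with_replacement(bases, 2):
        a1, a2 = g
        if a1 == a2 == column.ref_base:
            p = 1 - prior.theta_het - prior.theta_hom - prior.theta_other
        elif a1 == a2:
            p = prior.theta_hom / 3
        elif column.ref_base in g:
            p = prior.theta_het / 3
        else:
            p = prior.theta_other / 3
        for b, q in column.observations:
            eps = 10 ** (-q / 10)
            pb = 0.0
            for allele in g:
                pb += 0.5 * ((1 - eps) if b == allele else eps / 3)
            p *= pb
        probs[g] = p
    total = sum(probs.values())
    ordered = sorted(probs, key=lambda g: (-probs[g], column.ref_base not in g, g))
    best = ordered[0]
    return best, probs[best] / total


def brute_force_rbh(scores_ab: np.ndarray):
    """Double-argmax pairs on a dense score matrix (unique maxima only)."""
    pairs = []
    for i in range(scores_ab.shape[0]):
        j = int(np.argmax(scores_ab[i]))
        if (scores_ab[i] == scores_ab[i, j]).sum() > 1:
            continue
        i_back = int(np.argmax(scores_ab[:, j]))
        if (scores_ab[:, j] == scores_ab[i_back, j]).sum() > 1:
            continue
        if i_back == i:
            pairs.append((f"a{i}", f"b{j}"))
    return sorted(pairs)


def consequence_by_translation(transcript, ref, chrom, pos, alt):
    """Classify a substitution by translating the whole mutated CDS."""
    seq = ref.chromosomes[chrom]
    mutated = sim.Reference(
        {chrom: seq[:pos] + alt + seq[pos + 1 :]},
        {chrom: list(ref.gap_runs.get(chrom, []))},
    )
    before = str(Seq(cds_sequence(transcript, ref, chrom)).translate())
    after = str(Seq(cds_sequence(transcript, mutated, chrom)).translate())
    return "synonymous" if before == after else "nonsynonymous"
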