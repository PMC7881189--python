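"""Diversity and differentiation statistics on SNP genotype matrices.

All statistics work from per-locus allele counts with per-locus deletion
of missing data, except the folded site-frequency spectrum, which uses
only loci completely genotyped within the focal population.

Conventions
-----------
* Expected heterozygosity (gene diversity) carries the small-sample
  correction ``n/(n-1) * (1 - p^2 - q^2)`` with ``n`` the number of called
  alleles at the locus.
* Nucleotide diversity is the unbiased average pairwise difference per
  SNP, ``2 c (n - c) / (n (n - 1))`` — an ascertained, per-SNP scale
  (invariant sites are not in the denominator).
* Pairwise F_ST is the Weir & Cockerham (1984) theta, combined across
  loci as a ratio of sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "heterozygosity",
    "fis",
    "pairwise_fst",
    "fst_matrix",
    "nucleotide_diversity",
    "folded_sfs",
    "FoldedSFS",
    "diversity_table",
]


def _pop_locus_arrays(g: GenotypeMatrix, pop: str):
    """(alt count, called alleles, het genotypes, called genotypes) per locus."""
    sub = g.codes[g.pop_indices(pop)]
    called = sub != MISSING
    n_geno = called.sum(axis=0)
    n_al = 2 * n_geno
    alt = np.where(called, sub, 0).sum(axis=0)
    het = (sub == 1).sum(axis=0)
    return alt, n_al, het, n_geno


def heterozygosity(g: GenotypeMatrix, pop: str) -> tuple[float, float]:
    """Observed and expected heterozygosity, unweighted means over loci.

    Per locus with at least one called genotype, H_O is the fraction of
    heterozygotes among called individuals; H_E is the gene diversity
    ``(n/(n-1)) (1 - p^2 - q^2)`` (zero at monomorphic loci).  Loci with
    no called genotypes in the population are skipped.
    """
    alt, n_al, het, n_geno = _pop_locus_arrays(g, pop)
    use = n_geno >= 1
    if not use.any():
        raise ValueError(f"population {pop!r} has no called genotypes")
    ho = het[use] / n_geno[use]
    n = n_al[use].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt[use] / n, 0.0)
        he = np.where(n > 1, n / (n - 1) * (1 - p**2 - (1 - p) ** 2), 0.0)
    return float(ho.mean()), float(he.mean())


def fis(g: GenotypeMatrix, pop: str) -> float:
    """Inbreeding coefficient ``1 - H_O / H_E`` from multilocus means."""
    ho, he = heterozygosity(g, pop)
    if he == 0:
        raise ValueError(
            f"F_IS undefined for population {pop!r}: all loci monomorphic (H_E = 0)"
        )
    return 1.0 - ho / he


def _wc84_components(g: GenotypeMatrix, pop_a: str, pop_b: str):
    """Per-locus Weir & Cockerham (1984) variance components a, b, c."""
    alt1, nal1, het1, ng1 = _pop_locus_arrays(g, pop_a)
    alt2, nal2, het2, ng2 = _pop_locus_arrays(g, pop_b)
    use = (ng1 >= 1) & (ng2 >= 1) & (ng1 + ng2 >= 2)
    if not use.any():
        raise ValueError(f"no shared informative loci between {pop_a!r} and {pop_b!r}")
    n1 = ng1[use].astype(float)
    n2 = ng2[use].astype(float)
    p1 = alt1[use] / nal1[use]
    p2 = alt2[use] / nal2[use]
    h1 = het1[use] / n1
    h2 = het2[use] / n2

    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)

    with np.errstate(invalid="ignore", divide="ignore"):
        a = nbar / nc * (
            s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
        )
        b = nbar / (nbar - 1) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
    c = hbar / 2
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    return a[ok], b[ok], c[ok]


def pairwise_fst(g: GenotypeMatrix, pop_a: str, pop_b: str) -> float:
    """Multilocus Weir & Cockerham (1984) theta, ratio of sums over loci."""
    a, b, c = _wc84_components(g, pop_a, pop_b)
    denom = (a + b + c).sum()
    if denom == 0:
        raise ValueError(
            f"F_ST undefined between {pop_a!r} and {pop_b!r}: no variation"
        )
    return float(a.sum() / denom)


def fst_matrix(g: GenotypeMatrix, pops: list[str] | None = None) -> pd.DataFrame:
    """Symmetric pairwise F_ST matrix (diagonal 0)."""
    pops = pops or g.population_labels()
    m = np.zeros((len(pops), len(pops)))
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            m[i, j] = m[j, i] = pairwise_fst(g, pops[i], pops[j])
    return pd.DataFrame(m, index=pops, columns=pops)


def nucleotide_diversity(g: GenotypeMatrix, pop: str) -> float:
    """Mean per-SNP nucleotide diversity ``2 c (n-c) / (n (n-1))``.

    Equals the average pairwise allele difference at each SNP; the mean is
    taken over loci with at least two called alleles.  The value is on the
    ascertained per-SNP scale, not per genomic site.
    """
    alt, n_al, _, n_geno = _pop_locus_arrays(g, pop)
    use = n_al >= 2
    if not use.any():
        raise ValueError(f"population {pop!r} has no loci with >= 2 called alleles")
    n = n_al[use].astype(float)
    c = alt[use].astype(float)
    pi = 2 * c * (n - c) / (n * (n - 1))
    return float(pi.mean())


@dataclass
class FoldedSFS:
    """Folded site-frequency spectrum of one population.

    ``counts[i - 1]`` is the number of complete-data polymorphic loci with
    minor-allele count ``i``, for ``i`` in ``1..n//2`` (``n`` = haploid
    sample size).
    """

    population: str
    n: int
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_line(self) -> str:
        """One-line count format consumed by stairway-style tools.

        ``n - 1`` integers for minor-allele classes ``1 .. n-1``; classes
        above ``n//2`` are zero by folding.
        """
        full = np.zeros(self.n - 1, dtype=int)
        full[: len(self.counts)] = self.counts
        return "\t".join(str(int(x)) for x in full)


def folded_sfs(g: GenotypeMatrix, pop: str) -> FoldedSFS:
    """Folded SFS using only loci with no missing genotype in ``pop``.

    Loci monomorphic within the population are excluded; each remaining
    locus contributes one count to the class ``min(c, n - c)``.
    """
    idx = g.pop_indices(pop)
    sub = g.codes[idx]
    n = 2 * len(idx)
    complete = (sub != MISSING).all(axis=0)
    alt = sub.sum(axis=0)[complete]
    minor = np.minimum(alt, n - alt)
    minor = minor[(minor > 0)]
    counts = np.bincount(minor, minlength=n // 2 + 1)[1 : n // 2 + 1]
    return FoldedSFS(population=pop, n=n, counts=counts.astype(np.int64))


def diversity_table(g: GenotypeMatrix, pops: list[str] | None = None) -> pd.DataFrame:
    """Per-population H_O, H_E, F_IS and per-SNP nucleotide diversity."""
    pops = pops or g.population_labels()
    rows = []
    for p in pops:
        ho, he = heterozygosity(g, p)
        f = 1.0 - ho / he if he > 0 else np.nan
        rows.append((p, ho, he, f, nucleotide_diversity(g, p)))
    return pd.DataFrame(rows, columns=["population", "H_O", "H_E", "F_IS", "pi"]).set_index(
        "population"
    )
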