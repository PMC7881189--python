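"""Shared fixtures and independent brute-force oracles for the test-suite.

The oracle functions here are deliberately written in a plain, scalar,
loop-over-everything style, independent of the vectorised implementations
they are used to check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from bridgehead import GenotypeMatrix, MISSING
from bridgehead.genotypes import default_locus_frame


# ---------------------------------------------------------------------------
# fixture builders
# ---------------------------------------------------------------------------

def random_matrix(
    rng: np.random.Generator,
    n_per_pop: dict[str, int],
    n_loci: int,
    missing_rate: float = 0.0,
) -> GenotypeMatrix:
    """Random genotype matrix with exchangeable per-locus allele frequencies."""
    n_ind = sum(n_per_pop.values())
    p = rng.uniform(0.05, 0.95, size=n_loci)
    codes = rng.binomial(2, p[None, :], size=(n_ind, n_loci)).astype(np.int8)
    if missing_rate > 0:
        codes[rng.random(codes.shape) < missing_rate] = MISSING
    individuals, populations = [], []
    for pop, n in n_per_pop.items():
        individuals += [f"{pop}{i}" for i in range(n)]
        populations += [pop] * n
    return GenotypeMatrix(codes, individuals, populations,
                          default_locus_frame(n_loci))


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def wc84_fst_oracle(g: GenotypeMatrix, pop_a: str, pop_b: str) -> float:
    """Textbook two-population Weir & Cockerham (1984) theta, scalar loops."""
    idx = {pop_a: g.pop_indices(pop_a), pop_b: g.pop_indices(pop_b)}
    num = 0.0
    den = 0.0
    r = 2
    for j in range(g.n_loci):
        ns, ps, hs = [], [], []
        for pop in (pop_a, pop_b):
            genos = [int(g.codes[i, j]) for i in idx[pop] if g.codes[i, j] != MISSING]
            if not genos:
                break
            ns.append(len(genos))
            ps.append(sum(genos) / (2 * len(genos)))
            hs.append(sum(1 for x in genos if x == 1) / len(genos))
        else:
            n1, n2 = ns
            if n1 + n2 < 2:
                continue
            nbar = (n1 + n2) / r
            nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
            pbar = (n1 * ps[0] + n2 * ps[1]) / (r * nbar)
            s2 = (n1 * (ps[0] - pbar) ** 2 + n2 * (ps[1] - pbar) ** 2) / ((r - 1) * nbar)
            hbar = (n1 * hs[0] + n2 * hs[1]) / (r * nbar)
            if nbar <= 1 or nc == 0:
                continue
            a = nbar / nc * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            b = nbar / (nbar - 1) * (
                pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2
            if np.isfinite(a) and np.isfinite(b) and np.isfinite(c):
                num += a
                den += a + b + c
    return num / den


def pi_pairwise_oracle(g: GenotypeMatrix, pop: str) -> float:
    """Nucleotide diversity as the literal average difference over all
    pairs of sampled alleles, averaged over loci."""
    idx = g.pop_indices(pop)
    vals = []
    for j in range(g.n_loci):
        alleles: list[int] = []
        for i in idx:
            c = int(g.codes[i, j])
            if c == MISSING:
                continue
            alleles += [1] * c + [0] * (2 - c)
        n = len(alleles)
        if n < 2:
            continue
        diffs = sum(
            1
            for x in range(n)
            for y in range(x + 1, n)
            if alleles[x] != alleles[y]
        )
        vals.append(diffs / (n * (n - 1) / 2))
    return float(np.mean(vals))


def diversity_oracle(g: GenotypeMatrix, pop: str) -> tuple[float, float]:
    """Spreadsheet-style per-locus H_O / H_E means."""
    idx = g.pop_indices(pop)
    hos, hes = [], []
    for j in range(g.n_loci):
        genos = [int(g.codes[i, j]) for i in idx if g.codes[i, j] != MISSING]
        if not genos:
            continue
        hos.append(sum(1 for x in genos if x == 1) / len(genos))
        n = 2 * len(genos)
        p = sum(genos) / n
        hes.append(n / (n - 1) * (1 - p * p - (1 - p) ** 2) if n > 1 else 0.0)
    return float(np.mean(hos)), float(np.mean(hes))


# ---------------------------------------------------------------------------
# synthetic gaussian reference tables (for forest-level tests)
# ---------------------------------------------------------------------------

def gaussian_table(
    rng: np.random.Generator,
    n_per_label: int,
    n_stats: int,
    shifts: dict[str, float],
    param_fn=None,
):
    """ReferenceTable whose statistics are N(shift, 1) per scenario label.

    ``param_fn(stats_row, rng)`` may supply a ``par:theta`` column.
    """
    from bridgehead.simulate import ReferenceTable

    records = []
    for label, shift in shifts.items():
        for _ in range(n_per_label):
            stats = rng.normal(shift, 1.0, size=n_stats)
            rec = {"scenario": label}
            if param_fn is not None:
                rec["par:theta"] = param_fn(stats, rng)
            rec.update({f"stat:s{i}": v for i, v in enumerate(stats)})
            records.append(rec)
    return ReferenceTable(pd.DataFrame.from_records(records))
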