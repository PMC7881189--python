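"""The ABC summary-statistic vector.

For a fixed, ordered population roster the vector contains, in a
documented deterministic order:

* per population: mean and variance across loci of within-population gene
  diversity (``HW_mean[pop]``, ``HW_var[pop]``);
* per unordered pair: mean and variance of between-population
  heterozygosity ``pA(1-pB) + pB(1-pA)`` (``HB_mean``, ``HB_var``),
  multilocus Weir & Cockerham F_ST (``FST``) and Nei's (1972) standard
  genetic distance (``NeiD``);
* per ordered choice of a target population and unordered source pair:
  the admixture statistic ``f3[t;a,b]``, the mean across loci of
  ``(p_t - p_a)(p_t - p_b)`` (negative values indicate the target is an
  allele-frequency intermediate of the sources, the classic admixture
  signal).

Vector length is ``2P + 2*C(P,2) + 2*C(P,2) + 3*C(P,3)`` for ``P``
populations.  Missing data are handled by per-locus complete-pair
deletion; a statistic left with no usable loci is an error, never NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .popgen import _wc84_components

__all__ = ["SummaryVector", "stat_names", "summary_vector"]


def stat_names(roster: list[str]) -> list[str]:
    """The fixed statistic ordering for a population roster."""
    names = []
    for p in roster:
        names += [f"HW_mean[{p}]", f"HW_var[{p}]"]
    for a, b in combinations(roster, 2):
        names += [f"HB_mean[{a},{b}]", f"HB_var[{a},{b}]",
                  f"FST[{a},{b}]", f"NeiD[{a},{b}]"]
    for t in roster:
        others = [p for p in roster if p != t]
        for a, b in combinations(others, 2):
            names.append(f"f3[{t};{a},{b}]")
    return names


@dataclass
class SummaryVector:
    """Named, ordered summary statistics of one dataset."""

    roster: list[str]
    names: list[str]
    values: np.ndarray

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)

    def to_csv(self, path) -> None:
        """Single delimited row with header (same format as table rows)."""
        pd.DataFrame([self.values], columns=self.names).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, roster: list[str]) -> "SummaryVector":
        df = pd.read_csv(path)
        expected = stat_names(roster)
        if list(df.columns) != expected:
            raise ValueError("summary-vector file does not match the roster ordering")
        return cls(roster=list(roster), names=expected,
                   values=df.iloc[0].to_numpy(dtype=float))


def _freqs(g: GenotypeMatrix, roster: list[str]):
    """Per population: alt frequency, called-allele count, validity mask."""
    P, L = len(roster), g.n_loci
    freq = np.full((P, L), np.nan)
    n_al = np.zeros((P, L), dtype=np.int64)
    for k, pop in enumerate(roster):
        alt, nal, _ = g.allele_stats(pop)
        n_al[k] = nal
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[k] = np.where(nal > 0, alt / np.maximum(nal, 1), np.nan)
    return freq, n_al


def summary_vector(
    g: GenotypeMatrix,
    roster: list[str],
    f3_bias_correction: bool = False,
) -> SummaryVector:
    """Compute the full summary-statistic vector on a genotype matrix.

    Every roster population must have at least two called genotypes at
    some locus.  ``f3_bias_correction`` subtracts the within-target
    sampling term ``p(1-p)/(n-1)``; it is off by default (simulated and
    observed data are compared at matched sample sizes on ascertained
    SNPs, where the shared bias cancels).
    """
    for pop in roster:
        if pop not in g.populations:
            raise ValueError(f"roster population {pop!r} absent from data")

    freq, n_al = _freqs(g, roster)
    pos = {p: k for k, p in enumerate(roster)}
    values: list[float] = []
    names = stat_names(roster)

    def term(stat: str, x: np.ndarray) -> np.ndarray:
        x = x[np.isfinite(x)]
        if x.size == 0:
            raise ValueError(f"statistic {stat} has no usable loci")
        return x

    for p in roster:
        k = pos[p]
        n = n_al[k].astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            hw = np.where(
                n >= 2, n / np.maximum(n - 1, 1) * 2 * freq[k] * (1 - freq[k]), np.nan
            )
        hw = term(f"HW[{p}]", hw)
        values += [float(hw.mean()), float(hw.var())]

    for a, b in combinations(roster, 2):
        ka, kb = pos[a], pos[b]
        both = np.isfinite(freq[ka]) & np.isfinite(freq[kb])
        pa, pb = freq[ka][both], freq[kb][both]
        hb = term(f"HB[{a},{b}]", pa * (1 - pb) + pb * (1 - pa))
        values += [float(hb.mean()), float(hb.var())]

        va, vb, vc = _wc84_components(g, a, b)
        denom = (va + vb + vc).sum()
        # a pair monomorphic at every shared locus carries no measurable
        # differentiation: take the degenerate limit 0 rather than NaN
        values.append(float(va.sum() / denom) if denom != 0 else 0.0)

        jx = (pa**2 + (1 - pa) ** 2).mean()
        jy = (pb**2 + (1 - pb) ** 2).mean()
        jxy = (pa * pb + (1 - pa) * (1 - pb)).mean()
        values.append(float(-np.log(max(jxy, 1e-12) / np.sqrt(jx * jy))))

    for t in roster:
        others = [p for p in roster if p != t]
        for a, b in combinations(others, 2):
            kt, ka, kb = pos[t], pos[a], pos[b]
            ok = np.isfinite(freq[kt]) & np.isfinite(freq[ka]) & np.isfinite(freq[kb])
            if not ok.any():
                raise ValueError(f"statistic f3[{t};{a},{b}] has no usable loci")
            pt, pa, pb = freq[kt][ok], freq[ka][ok], freq[kb][ok]
            f3 = (pt - pa) * (pt - pb)
            if f3_bias_correction:
                nt = n_al[kt][ok].astype(float)
                f3 = f3 - pt * (1 - pt) / np.maximum(nt - 1, 1)
            values.append(float(f3.mean()))

    out = np.asarray(values, dtype=float)
    if not np.isfinite(out).all():
        bad = names[int(np.flatnonzero(~np.isfinite(out))[0])]
        raise ValueError(f"statistic {bad} evaluated to a non-finite value")
    return SummaryVector(roster=list(roster), names=names, values=out)
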