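"""Diploid SNP genotype container shared by real and simulated data.

Genotypes are stored as alternate-allele dosages (0, 1, 2) with ``-1``
marking a missing call.  Individuals carry population labels; loci carry
per-site metadata (id, chromosome, 1-based position, ref/alt alleles and
mean sequencing depth) in a pandas DataFrame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

LOCUS_COLUMNS = ["locus_id", "chrom", "pos", "ref", "alt", "mean_depth"]


def default_locus_frame(n_loci: int, mean_depth: float = 44.0) -> pd.DataFrame:
    """Synthesize locus metadata for simulated data (one SNP per locus)."""
    return pd.DataFrame(
        {
            "locus_id": [f"L{i + 1:06d}" for i in range(n_loci)],
            "chrom": ["sim"] * n_loci,
            "pos": np.arange(1, n_loci + 1, dtype=np.int64),
            "ref": ["A"] * n_loci,
            "alt": ["T"] * n_loci,
            "mean_depth": np.full(n_loci, float(mean_depth)),
        }
    )


@dataclass
class GenotypeMatrix:
    """Individuals x loci matrix of alt-allele dosages with population labels.

    Parameters
    ----------
    codes
        Integer array of shape ``(n_individuals, n_loci)`` with entries in
        ``{0, 1, 2, -1}``; ``-1`` is a missing genotype.
    individuals
        Sample identifiers, one per row.
    populations
        Population label of each individual (parallel to ``individuals``).
    loci
        Per-locus metadata frame with columns ``locus_id, chrom, pos, ref,
        alt, mean_depth``.  Synthesized when omitted.
    """

    codes: np.ndarray
    individuals: list[str]
    populations: list[str]
    loci: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-d individuals x loci array")
        self.individuals = list(self.individuals)
        self.populations = list(self.populations)
        if self.loci is None:
            self.loci = default_locus_frame(self.codes.shape[1])
        else:
            self.loci = self.loci.reset_index(drop=True)
        self.validate()

    # -- basic shape -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.codes.shape[1]

    def validate(self) -> None:
        if len(self.individuals) != self.codes.shape[0]:
            raise ValueError("individuals length does not match codes rows")
        if len(self.populations) != self.codes.shape[0]:
            raise ValueError("populations length does not match codes rows")
        if len(self.loci) != self.codes.shape[1]:
            raise ValueError("locus metadata length does not match codes columns")
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype code {self.codes[i, j]} at individual "
                f"{self.individuals[i]!r}, locus column {j}"
            )
        if (np.asarray(self.loci["pos"]) < 1).any():
            raise ValueError("locus positions must be 1-based (>= 1)")
        same = self.loci["ref"].astype(str) == self.loci["alt"].astype(str)
        if same.any():
            raise ValueError("ref and alt alleles must differ at every locus")

    # -- population access -------------------------------------------
    def population_labels(self) -> list[str]:
        """Unique population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p, None)
        return list(seen)

    def pop_indices(self, label: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.populations, dtype=object) == label)
        if idx.size == 0:
            raise KeyError(f"no individuals in population {label!r}")
        return idx

    def sample_sizes(self) -> dict[str, int]:
        """Number of diploid individuals per population."""
        out: dict[str, int] = {}
        for p in self.populations:
            out[p] = out.get(p, 0) + 1
        return out

    # -- derived quantities ------------------------------------------
    def missing_fraction_per_individual(self) -> np.ndarray:
        return (self.codes == MISSING).mean(axis=1)

    def allele_stats(self, label: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-locus (alt count, called allele count, het genotype count) in a population."""
        sub = self.codes[self.pop_indices(label)]
        called = sub != MISSING
        n_called = 2 * called.sum(axis=0)
        alt = np.where(called, sub, 0).sum(axis=0)
        het = (sub == 1).sum(axis=0)
        return alt.astype(np.int64), n_called.astype(np.int64), het.astype(np.int64)

    # -- subsetting ---------------------------------------------------
    def subset(self, individuals=None, loci=None) -> "GenotypeMatrix":
        """Return a copy restricted to the given individual / locus indices."""
        ind = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        if ind.dtype == bool:
            ind = np.flatnonzero(ind)
        loc = np.arange(self.n_loci) if loci is None else np.asarray(loci)
        if loc.dtype == bool:
            loc = np.flatnonzero(loc)
        return GenotypeMatrix(
            codes=self.codes[np.ix_(ind, loc)].copy(),
            individuals=[self.individuals[i] for i in ind],
            populations=[self.populations[i] for i in ind],
            loci=self.loci.iloc[loc].reset_index(drop=True),
        )

    def rename_populations(
        self, mapping: dict[str, str], drop_unmapped: bool = True
    ) -> "GenotypeMatrix":
        """Relabel (pool) populations; individuals without a mapping are dropped.

        With ``drop_unmapped=False`` unmapped labels pass through unchanged.
        """
        keep: list[int] = []
        labels: list[str] = []
        for i, p in enumerate(self.populations):
            if p in mapping:
                keep.append(i)
                labels.append(mapping[p])
            elif not drop_unmapped:
                keep.append(i)
                labels.append(p)
        if not keep:
            raise ValueError("population pooling removed every individual")
        g = self.subset(individuals=np.asarray(keep))
        g.populations = labels
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.populations == other.populations
            and np.array_equal(self.codes, other.codes)
            and self.loci[LOCUS_COLUMNS].equals(other.loci[LOCUS_COLUMNS])
        )
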