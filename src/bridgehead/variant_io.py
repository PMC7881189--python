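"""VCF ingestion and the RADseq SNP/individual filter chain.

Reading goes through :mod:`cyvcf2`; writing emits minimal VCF 4.2 text so
simulated genotypes can be round-tripped.  The filter chain mirrors common
RADseq practice for de-novo SNP catalogs: drop individuals with too much
missing data, then keep a SNP only if it is well called in every
population, is not a low-frequency allele (likely sequencing error), is
not excessively heterozygous (likely a collapsed paralog), and has a
credible mean sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "FilterReport",
    "read_popmap",
    "write_popmap",
    "read_vcf",
    "write_vcf",
    "filter_individuals",
    "filter_loci",
    "thin_one_snp_per_locus",
]


# ---------------------------------------------------------------------------
# popmap
# ---------------------------------------------------------------------------

def read_popmap(path) -> dict[str, str]:
    """Read a two-column whitespace-delimited individual -> population map."""
    mapping: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"popmap line {ln}: expected two columns, got {line!r}")
        mapping[parts[0]] = parts[1]
    return mapping


def write_popmap(g: GenotypeMatrix, path) -> None:
    lines = [f"{ind}\t{pop}" for ind, pop in zip(g.individuals, g.populations)]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

# cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
_GT_TYPE_TO_CODE = np.array([0, 1, MISSING, 2], dtype=np.int8)


def read_vcf(path, popmap: dict[str, str] | str, *, strict_biallelic: bool = True) -> GenotypeMatrix:
    """Read diploid biallelic genotypes from a VCF file.

    Parameters
    ----------
    path
        VCF file (plain or bgzipped).
    popmap
        Mapping individual id -> population label, or path to a two-column
        popmap file.  Every sample in the VCF must be present.
    strict_biallelic
        If True (default), a multiallelic record raises; otherwise such
        records are skipped.

    Phased and unphased genotypes are treated identically (alt dosage).
    Mean per-locus depth is taken from the ``MDP`` INFO field when present,
    otherwise from the mean of per-sample ``DP``, otherwise NaN.
    """
    from cyvcf2 import VCF

    if not isinstance(popmap, dict):
        popmap = read_popmap(popmap)

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise ValueError(f"could not parse VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    absent = [s for s in samples if s not in popmap]
    if absent:
        raise ValueError(f"individuals absent from popmap: {', '.join(absent)}")

    rows: list[np.ndarray] = []
    meta: list[tuple] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            if strict_biallelic:
                raise ValueError(
                    f"multiallelic site at {variant.CHROM}:{variant.POS} "
                    "(strict biallelic mode)"
                )
            continue
        codes = _GT_TYPE_TO_CODE[variant.gt_types]
        depth = variant.INFO.get("MDP")
        if depth is None:
            try:
                dp = variant.format("DP")
                depth = float(np.nanmean(np.where(dp < 0, np.nan, dp))) if dp is not None else np.nan
            except Exception:
                depth = np.nan
        locus_id = variant.ID if variant.ID not in (None, ".") else str(variant.CHROM)
        meta.append((locus_id, str(variant.CHROM), int(variant.POS),
                     str(variant.REF), str(variant.ALT[0]), float(depth)))
        rows.append(codes)
    vcf.close()

    loci = pd.DataFrame(meta, columns=["locus_id", "chrom", "pos", "ref", "alt", "mean_depth"])
    codes = np.asarray(rows, dtype=np.int8).T if rows else np.empty((len(samples), 0), np.int8)
    return GenotypeMatrix(
        codes=codes,
        individuals=samples,
        populations=[popmap[s] for s in samples],
        loci=loci,
    )


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write genotypes as minimal uncompressed VCF 4.2 text."""
    out = [
        "##fileformat=VCFv4.2",
        "##source=bridgehead",
        '##INFO=<ID=MDP,Number=1,Type=Float,Description="Mean per-individual sequencing depth">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    contigs = list(dict.fromkeys(g.loci["chrom"].astype(str)))
    out.extend(f"##contig=<ID={c}>" for c in contigs)
    out.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(g.individuals))
    for j in range(g.n_loci):
        row = g.loci.iloc[j]
        depth = row["mean_depth"]
        info = f"MDP={float(depth):.4g}" if np.isfinite(depth) else "."
        gts = "\t".join(_GT_STRINGS[int(c)] for c in g.codes[:, j])
        out.append(
            f"{row['chrom']}\t{int(row['pos'])}\t{row['locus_id']}\t{row['ref']}\t"
            f"{row['alt']}\t.\tPASS\t{info}\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# filter chain
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    """Counts of items removed per rule, in application order."""

    axis: str  # "individuals" or "loci"
    n_input: int
    stages: list[tuple[str, int]] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return sum(n for _, n in self.stages)

    @property
    def n_surviving(self) -> int:
        return self.n_input - self.n_removed

    def check_conservation(self) -> None:
        if self.n_removed + self.n_surviving != self.n_input:
            raise AssertionError("filter report does not conserve counts")

    def to_frame(self) -> pd.DataFrame:
        rows = [(rule, n) for rule, n in self.stages]
        rows.append(("surviving", self.n_surviving))
        return pd.DataFrame(rows, columns=["rule", "count"])

    def __str__(self) -> str:
        lines = [f"{self.axis}: {self.n_input} in"]
        lines += [f"  removed by {rule}: {n}" for rule, n in self.stages]
        lines.append(f"  surviving: {self.n_surviving}")
        return "\n".join(lines)


def filter_individuals(
    g: GenotypeMatrix, max_missing: float = 0.30
) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove individuals whose missing-genotype fraction is >= ``max_missing``.

    The threshold is inclusive: an individual missing exactly the threshold
    fraction of loci is removed.
    """
    if not (0 < max_missing <= 1):
        raise ValueError("max_missing must be in (0, 1]")
    frac = g.missing_fraction_per_individual()
    keep = frac < max_missing
    report = FilterReport("individuals", g.n_individuals,
                          [("missingness", int((~keep).sum()))])
    if not keep.any():
        raise ValueError("all individuals removed by missingness filter")
    report.check_conservation()
    return g.subset(individuals=keep), report


def _per_locus_stats(g: GenotypeMatrix):
    """Call rate per population, global alt frequency, observed het per locus."""
    pops = g.population_labels()
    call_rate = np.empty((len(pops), g.n_loci))
    for k, p in enumerate(pops):
        sub = g.codes[g.pop_indices(p)]
        call_rate[k] = (sub != MISSING).mean(axis=0)
    called = g.codes != MISSING
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt = np.where(called, g.codes, 0).sum(axis=0)
        p_alt = np.where(n_called > 0, alt / (2 * n_called), np.nan)
        het = np.where(n_called > 0, (g.codes == 1).sum(axis=0) / n_called, np.nan)
    return pops, call_rate, p_alt, het


def filter_loci(
    g: GenotypeMatrix,
    min_call_rate_per_pop: float = 0.5,
    min_maf: float = 0.05,
    max_obs_het: float = 0.7,
    depth_window: tuple[float, float] = (5.0, 200.0),
    maf_mode: str = "global",
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the per-SNP filter chain and attribute removals.

    A locus survives iff (a) its call rate is >= ``min_call_rate_per_pop``
    in **every** population, (b) its minor-allele frequency is >=
    ``min_maf``, (c) its observed heterozygosity is <= ``max_obs_het`` and
    (d) its mean depth lies in the closed ``depth_window``.  Rules are
    applied in that order and a removed locus is attributed to the first
    rule it fails.  ``maf_mode`` selects whether MAF is computed over all
    individuals (``"global"``, default) or as the maximum across per
    population frequencies (``"per_population"``).

    The surviving set does not depend on the rule order (each rule is an
    independent per-locus predicate); only the attribution does.
    """
    pops, call_rate, p_alt, het = _per_locus_stats(g)

    pass_call = (call_rate >= min_call_rate_per_pop).all(axis=0)

    if maf_mode == "global":
        maf = np.fmin(p_alt, 1 - p_alt)
    elif maf_mode == "per_population":
        per_pop = np.full((len(pops), g.n_loci), np.nan)
        for k, p in enumerate(pops):
            alt, n_called, _ = g.allele_stats(p)
            with np.errstate(invalid="ignore", divide="ignore"):
                f = np.where(n_called > 0, alt / n_called, np.nan)
            per_pop[k] = np.fmin(f, 1 - f)
        maf = np.nanmax(per_pop, axis=0)
    else:
        raise ValueError("maf_mode must be 'global' or 'per_population'")
    pass_maf = np.nan_to_num(maf, nan=-1.0) >= min_maf

    pass_het = np.nan_to_num(het, nan=2.0) <= max_obs_het

    depth = np.asarray(g.loci["mean_depth"], dtype=float)
    lo, hi = depth_window
    pass_depth = ~np.isfinite(depth) | ((depth >= lo) & (depth <= hi))

    report = FilterReport("loci", g.n_loci)
    alive = np.ones(g.n_loci, dtype=bool)
    for rule, mask in [
        ("call_rate", pass_call),
        ("maf", pass_maf),
        ("heterozygosity", pass_het),
        ("depth", pass_depth),
    ]:
        removed = alive & ~mask
        report.stages.append((rule, int(removed.sum())))
        alive &= mask
    report.check_conservation()
    return g.subset(loci=alive), report


def thin_one_snp_per_locus(g: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """Keep exactly one uniformly chosen SNP per shared ``locus_id``.

    Deterministic for a given seed; the retained SNPs keep their original
    column order.
    """
    rng = np.random.default_rng(seed)
    groups: dict[str, list[int]] = {}
    for j, lid in enumerate(g.loci["locus_id"].astype(str)):
        groups.setdefault(lid, []).append(j)
    chosen = sorted(int(rng.choice(idx)) for idx in groups.values())
    return g.subset(loci=np.asarray(chosen, dtype=int))
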