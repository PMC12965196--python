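"""Genotype matrices: I/O, SNP filtering, pairwise genetic distances.

The central object is :class:`GenotypeMatrix`, a samples x SNPs diploid
dosage matrix (0/1/2 copies of the alternate allele, -1 = missing) with
sample ids and variant metadata.  Distances treat missing data
pairwise-complete, rescaling to the full SNP count (PLINK-like) so values
stay comparable across pairs.

Six pairwise measures are provided: Hamming (allele-count substitutions),
allele-sharing distance (ASD), Euclidean, Nei's standard distance applied
to per-individual allele frequencies, pairwise Weir-Cockerham F_ST with
each individual treated as a population of one, and Rousset's
linearisation F_ST/(1 - F_ST).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from landgen.core import PairwiseMatrix

__all__ = [
    "GenotypeMatrix",
    "read_genotypes",
    "write_vcf",
    "write_ped",
    "filter_het_snps",
    "filter_maf",
    "genetic_distance",
    "prepare_climate",
    "TEMPERATURE_VARS",
    "MOISTURE_VARS",
]

MISSING = -1

DISTANCE_METHODS = ("hamming", "asd", "euclidean", "nei", "fst_wc_pairwise", "rousset")


@dataclass
class GenotypeMatrix:
    """Diploid dosages in {0, 1, 2, -1(missing)} for samples x SNPs."""

    dosage: np.ndarray
    sample_ids: list[str]
    variants: pd.DataFrame  # columns: chrom, pos, id, ref, alt

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (samples x SNPs)")
        if self.dosage.shape[0] != len(self.sample_ids):
            raise ValueError("dosage rows do not match sample ids")
        if self.dosage.shape[1] != len(self.variants):
            raise ValueError("dosage columns do not match variant table")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")
        bad = ~np.isin(self.dosage, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosages must be in {0, 1, 2, -1}")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per SNP over non-missing calls."""
        d = self.dosage
        ok = d != MISSING
        alt = np.where(ok, d, 0).sum(axis=0)
        tot = 2 * ok.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, alt / tot, np.nan)

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosage[:, keep],
            list(self.sample_ids),
            self.variants.iloc[np.flatnonzero(keep) if keep.dtype == bool else keep]
            .reset_index(drop=True),
        )

    def subset_samples(self, ids: list[str]) -> "GenotypeMatrix":
        pos = {s: k for k, s in enumerate(self.sample_ids)}
        idx = [pos[str(s)] for s in ids]
        return GenotypeMatrix(self.dosage[idx], list(ids), self.variants.copy())


# ---------------------------------------------------------------------------
# I/O


def read_genotypes(path, fmt: str | None = None, multiallelic: str = "error"):
    """Read a genotype matrix from VCF or PLINK ped/map.

    Parameters
    ----------
    path : VCF file, or the ``.ped`` file of a ped/map pair.
    fmt : "vcf" or "ped"; inferred from the suffix when None.
    multiallelic : "error" rejects multi-allelic records, "split" expands
        them into one biallelic pseudo-SNP per alternate allele.
    """
    path = Path(path)
    if fmt is None:
        fmt = "ped" if path.suffix == ".ped" else "vcf"
    if fmt == "vcf":
        return _read_vcf(path, multiallelic)
    if fmt == "ped":
        return _read_ped(path)
    raise ValueError(f"unknown genotype format: {fmt}")


def _read_vcf(path, multiallelic="error") -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, rows = [], []
    for k, var in enumerate(vcf):
        alts = [a for a in var.ALT if a != "."]
        if len(alts) > 1 and multiallelic == "error":
            raise ValueError(
                f"multi-allelic record at {var.CHROM}:{var.POS} "
                f"(record {k + 1}); re-run with multiallelic='split'"
            )
        # genotype allele indices; -1 encodes missing
        g = np.array([gt[:2] for gt in var.genotypes], dtype=np.int16)
        for ai, alt in enumerate(alts, start=1):
            dos = (g == ai).sum(axis=1).astype(np.int8)
            dos[(g < 0).any(axis=1)] = MISSING
            vid = var.ID if var.ID not in (None, ".") and len(alts) == 1 else (
                f"{var.CHROM}_{var.POS}_{alt}"
            )
            rows.append(dict(chrom=var.CHROM, pos=var.POS, id=vid,
                             ref=var.REF, alt=alt))
            cols.append(dos)
    if not cols:
        raise ValueError(f"no variant records in {path}")
    return GenotypeMatrix(np.stack(cols, axis=1), samples, pd.DataFrame(rows))


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write a minimal VCFv4.2 with GT-only genotype fields."""
    code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(G.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.sample_ids)
            + "\n"
        )
        for j, v in G.variants.iterrows():
            gts = "\t".join(code[int(d)] for d in G.dosage[:, j])
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_ped(G: GenotypeMatrix, prefix) -> None:
    """Write PLINK text ``<prefix>.ped`` and ``<prefix>.map``."""
    prefix = str(prefix)
    with open(prefix + ".map", "w") as fh:
        for _, v in G.variants.iterrows():
            fh.write(f"{v.chrom}\t{v.id}\t0\t{v.pos}\n")
    with open(prefix + ".ped", "w") as fh:
        for i, sid in enumerate(G.sample_ids):
            alleles = []
            for j in range(G.n_snps):
                ref, alt = G.variants.iloc[j][["ref", "alt"]]
                d = int(G.dosage[i, j])
                pair = {0: (ref, ref), 1: (ref, alt), 2: (alt, alt),
                        MISSING: ("0", "0")}[d]
                alleles.extend(pair)
            fh.write(f"{sid} {sid} 0 0 0 -9 " + " ".join(alleles) + "\n")


def _read_ped(ped_path) -> GenotypeMatrix:
    ped_path = Path(ped_path)
    map_path = ped_path.with_suffix(".map")
    variants = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{map_path}: malformed map record at line {ln}")
            variants.append(dict(chrom=parts[0], pos=int(parts[3]), id=parts[1]))
    nv = len(variants)
    sample_ids, rows = [], []
    # allele labels per locus discovered from the data; first-seen = ref
    alleles: list[dict[str, int]] = [dict() for _ in range(nv)]
    raw = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6 + 2 * nv:
                raise ValueError(
                    f"{ped_path}: line {ln} has {len(parts)} fields, "
                    f"expected {6 + 2 * nv}"
                )
            sample_ids.append(parts[1])
            raw.append(parts[6:])
    for rec in raw:
        for j in range(nv):
            for a in rec[2 * j: 2 * j + 2]:
                if a != "0" and a not in alleles[j]:
                    if len(alleles[j]) >= 2:
                        raise ValueError(
                            f"{ped_path}: more than two alleles at locus "
                            f"{variants[j]['id']}"
                        )
                    alleles[j][a] = len(alleles[j])
    # ped/map does not record which allele is the reference, so orient
    # deterministically: alphabetically first allele = ref (dosage counts
    # the second).  Loci seen with a single allele are coded dosage 0.
    for a in alleles:
        for rank, allele in enumerate(sorted(a)):
            a[allele] = rank
    for rec in raw:
        dos = np.empty(nv, dtype=np.int8)
        for j in range(nv):
            a1, a2 = rec[2 * j], rec[2 * j + 1]
            if a1 == "0" or a2 == "0":
                dos[j] = MISSING
            else:
                dos[j] = alleles[j][a1] + alleles[j][a2]
        rows.append(dos)
    vdf = pd.DataFrame(variants)
    lab = [sorted(a, key=a.get) + ["N"] * (2 - len(a)) for a in alleles]
    vdf["ref"] = [l[0] for l in lab]
    vdf["alt"] = [l[1] for l in lab]
    return GenotypeMatrix(np.array(rows, dtype=np.int8), sample_ids, vdf)


# ---------------------------------------------------------------------------
# Filters


def filter_het_snps(G: GenotypeMatrix, max_het: float = 0.05) -> GenotypeMatrix:
    """Drop SNPs whose heterozygote fraction exceeds ``max_het``.

    The fraction is heterozygous calls / non-missing calls; SNPs at exactly
    the threshold are retained (only strictly greater removed).
    """
    if not 0 <= max_het <= 1:
        raise ValueError("max_het must be in [0, 1]")
    ok = G.dosage != MISSING
    het = (G.dosage == 1).sum(axis=0)
    n = ok.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n > 0, het / n, 0.0)
    keep = frac <= max_het
    if not keep.any():
        warnings.warn("heterozygosity filter removed every SNP", stacklevel=2)
    return G.subset_snps(keep)


def filter_maf(G: GenotypeMatrix, min_maf: float = 0.05) -> GenotypeMatrix:
    """Keep SNPs with minor-allele frequency strictly above ``min_maf``.

    MAF is computed on non-missing calls; sites with MAF <= min_maf
    (including monomorphic sites) are removed.
    """
    p = G.allele_freq()
    maf = np.minimum(p, 1 - p)
    keep = np.nan_to_num(maf, nan=0.0) > min_maf
    if not keep.any():
        warnings.warn("MAF filter removed every SNP", stacklevel=2)
    return G.subset_snps(keep)


# ---------------------------------------------------------------------------
# Distances


def _pair_sums(G: GenotypeMatrix):
    """Cross-products needed by all measures, missing-aware.

    Returns indicator cross-count matrices: for a, b in {0,1,2}, N_ab[i,j] =
    number of loci where sample i has dosage a and j has dosage b and both
    are non-missing, plus Lc = pairwise-complete locus counts.
    """
    d = G.dosage
    A = [(d == v).astype(np.float64) for v in (0, 1, 2)]
    N = {(a, b): A[a] @ A[b].T for a in range(3) for b in range(3)}
    M = (d != MISSING).astype(np.float64)
    Lc = M @ M.T
    return N, Lc


def genetic_distance(G: GenotypeMatrix, method: str = "hamming") -> PairwiseMatrix:
    """Pairwise genetic distance between all samples.

    Methods: ``hamming`` (sum of |g_i - g_j| over pairwise-complete loci,
    rescaled to the full SNP count), ``asd`` (the same per-locus 0/1/2
    allele-sharing rule averaged per complete locus, range [0, 2]),
    ``euclidean`` (sqrt of rescaled squared differences), ``nei``
    (-ln of Nei's standard genetic identity on per-individual allele
    frequencies), ``fst_wc_pairwise`` (Weir-Cockerham theta with each
    individual a population of one; diagonal NaN, negatives kept) and
    ``rousset`` (theta / (1 - theta)).
    """
    if method not in DISTANCE_METHODS:
        raise ValueError(f"unknown distance method: {method}")
    if G.n_samples < 2 or G.n_snps < 1:
        raise ValueError("need at least 2 samples and 1 SNP")
    N, Lc = _pair_sums(G)
    L = G.n_snps
    none_shared = Lc == 0
    if none_shared.any():
        warnings.warn(
            "some sample pairs share no non-missing loci; distances set to NaN",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        if method in ("hamming", "asd", "euclidean"):
            diff1 = N[0, 1] + N[1, 0] + N[1, 2] + N[2, 1]
            diff2 = N[0, 2] + N[2, 0]
            if method == "hamming":
                vals = (diff1 + 2 * diff2) * (L / Lc)
                units = "substitutions"
            elif method == "asd":
                vals = (diff1 + 2 * diff2) / Lc
                units = "mean shared-allele distance"
            else:
                vals = np.sqrt((diff1 + 4 * diff2) * (L / Lc))
                units = "euclidean dosage distance"
        elif method == "nei":
            # per-individual allele freqs p in {0, .5, 1}; identity
            # I = J12 / sqrt(J1 J2) with J averaged over complete loci
            d = G.dosage
            P = np.where(d != MISSING, d / 2.0, 0.0)
            Q = np.where(d != MISSING, 1 - d / 2.0, 0.0)
            M = (d != MISSING).astype(np.float64)
            J12 = P @ P.T + Q @ Q.T
            S = (P * P + Q * Q) * M
            J1 = S @ M.T  # sum over loci complete in (i, j) of i's term
            J2 = M @ S.T
            vals = -np.log(J12 / np.sqrt(J1 * J2))
            vals[np.eye(G.n_samples, dtype=bool)] = 0.0
            units = "nei standard distance"
        else:
            # two-level allele ANOVA per pair: groups = the two individuals
            # (2 alleles each).  Per locus MSB = (p_i - p_j)^2, MSW =
            # p_i q_i + p_j q_j; theta = sum(MSB - MSW) / sum(MSB + MSW).
            diff1 = N[0, 1] + N[1, 0] + N[1, 2] + N[2, 1]
            diff2 = N[0, 2] + N[2, 0]
            D2 = (diff1 + 4 * diff2) / 4.0  # sum of (p_i - p_j)^2
            H = (
                N[1, 0] + N[1, 1] + N[1, 2] + N[0, 1] + N[1, 1] + N[2, 1]
            )  # sum over loci of h_i + h_j
            num = D2 - H / 4.0
            den = D2 + H / 4.0
            vals = np.where(den > 0, num / den, np.nan)
            if method == "rousset":
                vals = vals / (1 - vals)
                units = "rousset linearised F_ST"
            else:
                units = "pairwise F_ST"
            np.fill_diagonal(vals, np.nan)
    if method not in ("fst_wc_pairwise", "rousset"):
        vals = np.asarray(vals, dtype=float)
        np.fill_diagonal(vals, 0.0)
    vals[none_shared & ~np.eye(G.n_samples, dtype=bool)] = np.nan
    return PairwiseMatrix(vals, G.sample_ids, units, {"method": method})


# ---------------------------------------------------------------------------
# Climate covariates

TEMPERATURE_VARS = (
    "temperature_seasonality",
    "max_temp_warmest_month",
    "min_temp_coldest_month",
    "mean_temp_driest_quarter",
)
MOISTURE_VARS = (
    "annual_precip",
    "precip_driest_month",
    "precip_seasonality",
    "precip_warmest_quarter",
)


def prepare_climate(samples: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Standardise the two four-variable climate sets.

    Expects the four temperature and four moisture columns; precipitation
    of the driest month is log(x + 1) transformed (skew adjustment), then
    every column is z-scored.  Returns ``{"temperature": ..., "moisture":
    ...}`` blocks indexed like the input.
    """
    for col in TEMPERATURE_VARS + MOISTURE_VARS:
        if col not in samples.columns:
            raise ValueError(f"missing climate column: {col}")
    out = {}
    for name, cols in (("temperature", TEMPERATURE_VARS), ("moisture", MOISTURE_VARS)):
        block = samples.loc[:, list(cols)].astype(float).copy()
        if name == "moisture":
            block["precip_driest_month"] = np.log1p(block["precip_driest_month"])
        sd = block.std(ddof=1)
        if (sd == 0).any() or sd.isna().any():
            bad = sd.index[(sd == 0) | sd.isna()].tolist()
            raise ValueError(f"zero-variance climate column(s): {bad}")
        out[name] = (block - block.mean()) / sd
    return out
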