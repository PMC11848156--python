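"""Readers and writers for everything the pipeline touches.

GWAS summary statistics (tab/whitespace-delimited with header), gene sets
(GMT), gene annotation (BED-like 6-column), LD-reference dosages (plain TSV
matrix or VCF), and the run configuration (YAML).

Conventions
-----------
* Genomic coordinates are 1-based inclusive internally — the GWAS
  summary-statistic convention.  BED inputs (0-based half-open) are
  converted on read and back on write.
* Chromosome labels are normalised by stripping a leading ``chr``.
* Canonical summary-statistic columns: ``SNP CHR BP A1 A2 BETA SE P MAF
  INFO`` with optional ``N``; ``A1`` is the coded (dose) allele.  Files with
  other headers are remapped through a *dialect* mapping.
* Unknown extra columns are preserved on round-trip but ignored by all
  computation.
"""
from __future__ import annotations

import dataclasses
import logging
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, FormatError, LoadError, MissingSnpError

logger = logging.getLogger("cellprs")

MANDATORY_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P", "MAF", "INFO"]
OPTIONAL_COLUMNS = ["N"]
VALID_ALLELES = frozenset("ACGT")


def normalize_chrom(label) -> str:
    """Strip a leading ``chr``/``CHR`` prefix from a chromosome label."""
    s = str(label)
    return s[3:] if s.lower().startswith("chr") else s


def chrom_sort_key(label: str):
    """Sort numerically-labelled chromosomes before lexical ones."""
    try:
        return (0, int(label), "")
    except ValueError:
        return (1, 0, str(label))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantAssoc:
    """One SNP's association record in one GWAS.

    ``beta`` is the effect per dose of the coded allele ``allele_effect``.
    """

    snp_id: str
    chrom: str
    pos: int
    allele_effect: str
    allele_other: str
    beta: float
    se: float
    pval: float
    maf: float
    info: float
    n: Optional[int] = None


@dataclass
class SummaryStats:
    """A validated collection of per-SNP associations for one trait.

    The backing ``table`` holds the canonical columns and is sorted by
    (chromosome, position) regardless of input file order.
    """

    trait: str
    n_total: int
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise LoadError(f"n_total must be positive, got {self.n_total}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> pd.Index:
        return pd.Index(self.table["SNP"])

    @property
    def pvals(self) -> pd.Series:
        return pd.Series(self.table["P"].to_numpy(), index=self.table["SNP"].to_numpy())

    def variants(self) -> Iterator[VariantAssoc]:
        has_n = "N" in self.table.columns
        for row in self.table.itertuples(index=False):
            yield VariantAssoc(
                snp_id=row.SNP, chrom=row.CHR, pos=int(row.BP),
                allele_effect=row.A1, allele_other=row.A2,
                beta=float(row.BETA), se=float(row.SE), pval=float(row.P),
                maf=float(row.MAF), info=float(row.INFO),
                n=int(row.N) if has_n and pd.notna(row.N) else None,
            )

    def subset(self, snp_ids) -> "SummaryStats":
        keep = self.table["SNP"].isin(set(snp_ids))
        return SummaryStats(self.trait, self.n_total, self.table[keep].reset_index(drop=True))

    @classmethod
    def from_frame(cls, trait: str, n_total: int, df: pd.DataFrame,
                   validate: bool = True) -> "SummaryStats":
        if validate:
            df = _validate_and_sort(df)
        return cls(trait, n_total, df.reset_index(drop=True))


@dataclass(frozen=True)
class GeneRecord:
    """A gene interval, 1-based inclusive, with strand and coding status."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    protein_coding: bool

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise LoadError(f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise LoadError(f"gene {self.gene_id}: bad strand {self.strand!r}")


class CellTypeSets(Mapping):
    """Named cell types, each holding a non-empty set of marker gene ids.

    Optionally carries per-(cell type, gene) log fold change and FDR from a
    marker-enrichment run.
    """

    def __init__(self, sets: Mapping[str, set], descriptions: Optional[Mapping[str, str]] = None,
                 stats: Optional[pd.DataFrame] = None, allow_empty: bool = False):
        clean: dict[str, frozenset] = {}
        for name, genes in sets.items():
            if name in clean:
                raise LoadError(f"duplicate cell type name {name!r}")
            genes = frozenset(genes)
            if not genes and not allow_empty:
                raise LoadError(f"cell type {name!r} has an empty gene set")
            clean[name] = genes
        self._sets = clean
        self.descriptions = dict(descriptions or {})
        #: optional columns gene_id, cell_type, lfc, p_hyper, fdr
        self.stats = stats

    def __getitem__(self, name: str) -> frozenset:
        return self._sets[name]

    def __iter__(self):
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    def all_genes(self) -> frozenset:
        out: set = set()
        for genes in self._sets.values():
            out |= genes
        return frozenset(out)


class DosageTable:
    """Genotype dosages of reference individuals, keyed by SNP id.

    Rows are variants, columns individuals, entries in [0, 2] counting doses
    of the coded allele recorded in ``coded_allele``.
    """

    def __init__(self, matrix: pd.DataFrame, coded_allele: pd.Series):
        vals = matrix.to_numpy(dtype=float)
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 2):
            raise LoadError("dosage entries must lie in [0, 2]")
        if matrix.index.has_duplicates:
            raise LoadError("duplicate snp_id in dosage matrix")
        self.matrix = matrix
        self.coded_allele = coded_allele.reindex(matrix.index)

    @property
    def snp_ids(self) -> pd.Index:
        return self.matrix.index

    @property
    def n_individuals(self) -> int:
        return self.matrix.shape[1]

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self.matrix.index

    def dosages(self, snp_id: str) -> np.ndarray:
        try:
            return self.matrix.loc[snp_id].to_numpy(dtype=float)
        except KeyError:
            raise MissingSnpError(f"SNP {snp_id!r} absent from the LD reference") from None


@dataclass
class RunConfig:
    """Every tunable parameter of one pipeline run.

    Defaults reproduce the published analysis settings: MAF ≥ 0.01 and
    INFO ≥ 0.9 retained, ±10 Mb / r² ≤ 0.001 clumping, APOE and MHC regions
    excluded, 2 kb upstream / 0.5 kb downstream gene windows, three
    p-thresholds spanning 0.01–1.0, 1000 permutations, FWE alpha 0.05.
    """

    maf_min: float = 0.01
    info_min: float = 0.9
    clump_window_kb: int = 10_000
    clump_r2_max: float = 0.001
    excluded_regions: list = field(default_factory=lambda: [
        ("19", 44_500_000, 46_000_000, "APOE"),
        ("6", 26_000_000, 34_000_000, "MHC"),
    ])
    upstream_bp: int = 2_000
    downstream_bp: int = 500
    p_thresholds: list = field(default_factory=lambda: [0.01, 0.5, 1.0])
    n_perm: int = 1000
    rng_seed: int = 0
    fwe_alpha: float = 0.05
    fwe_method: str = "bonferroni"        # or "holm"
    strand_aware_windows: bool = True
    palindromic_policy: str = "keep"      # or "drop"
    missing_ld_policy: str = "retain"     # or "drop"
    pseudo_r2_form: str = "lrt"           # or "linear"
    perm_statistic: str = "abs_z"         # or "abs_alpha"; see inference.permutation_null
    consistency_p: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.maf_min <= 0.5:
            raise ConfigError(f"maf_min out of range: {self.maf_min}")
        if not 0 < self.info_min <= 1.2:
            raise ConfigError(f"info_min out of range: {self.info_min}")
        if self.clump_window_kb <= 0:
            raise ConfigError("clump_window_kb must be positive")
        if not 0 <= self.clump_r2_max < 1:
            raise ConfigError("clump_r2_max must lie in [0, 1)")
        if list(self.p_thresholds) != sorted(set(self.p_thresholds)):
            raise ConfigError("p_thresholds must be strictly increasing")
        if any(not 0 < t <= 1 for t in self.p_thresholds):
            raise ConfigError("p_thresholds must lie in (0, 1]")
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        if not 0 < self.fwe_alpha < 1:
            raise ConfigError("fwe_alpha must lie in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        d = {k: (list(map(tuple, v)) if k == "excluded_regions" else v) for k, v in d.items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        d = self.to_dict()
        d["excluded_regions"] = [list(r) for r in d["excluded_regions"]]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    def override(self, **kwargs) -> "RunConfig":
        """Return a copy with the given keys replaced (CLI flags beat config)."""
        return dataclasses.replace(self, **{k: v for k, v in kwargs.items() if v is not None})


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def _validate_rows(df: pd.DataFrame) -> tuple[pd.Series, dict]:
    """Vectorised row-level invariant checks; returns (keep mask, reject counts)."""
    ok = pd.Series(True, index=df.index)
    reasons: dict[str, int] = {}

    def reject(bad: pd.Series, reason: str) -> None:
        bad = bad.fillna(True) & ok
        n = int(bad.sum())
        if n:
            reasons[reason] = n
        ok.loc[bad] = False

    num = {c: pd.to_numeric(df[c], errors="coerce") for c in ["BP", "BETA", "SE", "P", "MAF", "INFO"]}
    reject(num["BP"].isna() | (num["BP"] <= 0) | (num["BP"] % 1 != 0), "bad_position")
    reject(num["BETA"].isna(), "bad_beta")
    reject(num["SE"].isna() | (num["SE"] <= 0), "nonpositive_se")
    reject(num["P"].isna() | (num["P"] <= 0) | (num["P"] > 1), "pval_out_of_range")
    reject(num["MAF"].isna() | (num["MAF"] <= 0) | (num["MAF"] > 0.5), "maf_out_of_range")
    reject(num["INFO"].isna() | (num["INFO"] <= 0) | (num["INFO"] > 1.2), "info_out_of_range")
    a1 = df["A1"].astype(str).str.upper()
    a2 = df["A2"].astype(str).str.upper()
    reject(~a1.isin(VALID_ALLELES) | ~a2.isin(VALID_ALLELES), "invalid_allele")
    reject(a1 == a2, "identical_alleles")
    return ok, reasons


def _validate_and_sort(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")
    df = df.copy()
    df["CHR"] = df["CHR"].map(normalize_chrom)
    df["SNP"] = df["SNP"].astype(str)
    ok, reasons = _validate_rows(df)
    if reasons:
        logger.info("rejected %d row(s): %s", int((~ok).sum()),
                    ", ".join(f"{k}={v}" for k, v in sorted(reasons.items())))
    df = df[ok].copy()
    for c in ["BP"]:
        df[c] = df[c].astype(np.int64)
    for c in ["BETA", "SE", "P", "MAF", "INFO"]:
        df[c] = df[c].astype(float)
    df["A1"] = df["A1"].astype(str).str.upper()
    df["A2"] = df["A2"].astype(str).str.upper()

    dup_ids = df["SNP"][df["SNP"].duplicated()].unique()
    if len(dup_ids):
        raise LoadError(f"duplicate snp_id(s): {', '.join(map(str, dup_ids[:5]))}")
    dup_pos = df.duplicated(subset=["CHR", "BP"])
    if dup_pos.any():
        r = df[dup_pos].iloc[0]
        raise LoadError(f"duplicate (chrom, pos): {r.CHR}:{r.BP}")

    key = df["CHR"].map(chrom_sort_key)
    order = pd.DataFrame({"k": key, "p": df["BP"]}).sort_values(["k", "p"], kind="stable").index
    return df.loc[order].reset_index(drop=True)


def read_sumstats(path, dialect: Optional[Mapping[str, str]] = None,
                  trait: str = "", n_total: Optional[int] = None) -> SummaryStats:
    """Load and validate a GWAS summary-statistic file.

    ``dialect`` maps canonical column names to the file's column names, e.g.
    ``{"SNP": "rsid", "P": "pval"}``.  Rows violating per-variant invariants
    are rejected with counts logged; duplicate SNP ids or (chrom, pos) pairs
    are load errors.  When ``n_total`` is not given, it is taken from the
    maximum of the per-variant ``N`` column.
    """
    df = pd.read_csv(path, sep=r"\s+")
    if dialect:
        rename = {v: k for k, v in dialect.items()}
        missing = [v for v in dialect.values() if v not in df.columns]
        if missing:
            raise FormatError(f"dialect column(s) not in file: {', '.join(missing)}")
        df = df.rename(columns=rename)
    df = _validate_and_sort(df)
    if n_total is None:
        if "N" in df.columns and len(df):
            n_total = int(pd.to_numeric(df["N"]).max())
        else:
            n_total = 1
    return SummaryStats(trait=trait or str(Path(path).stem), n_total=n_total, table=df)


def write_sumstats(stats: SummaryStats, path) -> None:
    """Write canonical tab-delimited summary statistics (full float precision)."""
    stats.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gene_sets(path) -> CellTypeSets:
    """Parse a GMT file: one set per line, ``name TAB description TAB ids...``."""
    sets: dict[str, set] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if name in sets:
                raise LoadError(f"{path}:{lineno}: duplicate set name {name!r}")
            if not genes:
                raise LoadError(f"{path}:{lineno}: set {name!r} is empty")
            sets[name] = set(genes)
            descriptions[name] = desc
    return CellTypeSets(sets, descriptions)


def write_gene_sets(sets: Mapping[str, set], path,
                    descriptions: Optional[Mapping[str, str]] = None) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# gene annotation (BED-like)
# ---------------------------------------------------------------------------

def read_gene_annotation(path, zero_based: bool = True) -> list[GeneRecord]:
    """Read a 6-column BED-like file: chrom start end gene_id coding strand.

    ``zero_based=True`` declares BED convention (0-based half-open starts),
    converted to the internal 1-based inclusive convention on read.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None,
                     names=["chrom", "start", "end", "gene_id", "coding", "strand"])
    records = []
    for row in df.itertuples(index=False):
        start = int(row.start) + 1 if zero_based else int(row.start)
        end = int(row.end)
        records.append(GeneRecord(
            gene_id=str(row.gene_id), chrom=normalize_chrom(row.chrom),
            start=start, end=end, strand=str(row.strand),
            protein_coding=str(row.coding) in ("1", "True", "true"),
        ))
    records.sort(key=lambda g: (chrom_sort_key(g.chrom), g.start))
    return records


def write_gene_annotation(genes, path, zero_based: bool = True) -> None:
    with open(path, "w") as fh:
        for g in genes:
            start = g.start - 1 if zero_based else g.start
            fh.write(f"{g.chrom}\t{start}\t{g.end}\t{g.gene_id}\t{int(g.protein_coding)}\t{g.strand}\n")


def genes_to_frame(genes) -> pd.DataFrame:
    return pd.DataFrame(
        [(g.gene_id, g.chrom, g.start, g.end, g.strand, g.protein_coding) for g in genes],
        columns=["gene_id", "chrom", "start", "end", "strand", "protein_coding"],
    )


# ---------------------------------------------------------------------------
# LD-reference dosages
# ---------------------------------------------------------------------------

def read_dosage_matrix(path) -> DosageTable:
    """Read reference dosages from a plain TSV matrix or a VCF.

    TSV layout: columns ``SNP``, ``A1`` (coded allele), then one column per
    reference individual.  VCF: doses count ALT alleles in the GT field, so
    the coded allele is ALT.
    """
    path = Path(path)
    if path.suffix.lower() in (".vcf", ".gz") or path.name.endswith(".vcf.gz"):
        return _read_vcf_dosages(path)
    df = pd.read_csv(path, sep="\t")
    if "SNP" not in df.columns or "A1" not in df.columns:
        raise FormatError("dosage TSV needs SNP and A1 columns before sample columns")
    df = df.set_index("SNP")
    coded = df.pop("A1").astype(str)
    return DosageTable(df.astype(float), coded)


def _read_vcf_dosages(path) -> DosageTable:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    rows, ids, alts = [], [], []
    for variant in vcf:
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(variant.gt_types)
        if (gt == 2).any():
            raise LoadError(f"missing genotype at {variant.ID}")
        dose = np.where(gt == 3, 2, gt).astype(float)
        rows.append(dose)
        ids.append(variant.ID)
        alts.append(variant.ALT[0] if variant.ALT else "N")
    samples = list(vcf.samples)
    matrix = pd.DataFrame(np.array(rows), index=pd.Index(ids, name="SNP"), columns=samples)
    return DosageTable(matrix, pd.Series(alts, index=matrix.index))


def write_dosage_matrix(table: DosageTable, path) -> None:
    out = table.matrix.copy()
    out.insert(0, "A1", table.coded_allele)
    out.index.name = "SNP"
    out.to_csv(path, sep="\t")
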