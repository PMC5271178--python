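"""Domain types, readers/writers, configuration and logging.

The pipeline moves four kinds of tabular data around:

* a study design table (one row per serum sample, with subject, cohort,
  age, sex, array plate and visit),
* a samples x probes matrix of log2 protein intensities plus per-probe
  annotations anchoring each probe's target gene on the genome,
* a subjects x variants matrix of imputed effective-allele dosages in
  [0, 2] plus per-variant metadata,
* GWAS summary tables and plain gene-symbol lists used by the enrichment
  stage.

Everything is TSV on disk ('.' decimal, header row); genotypes may
alternatively be ingested from a VCF with per-sample DS dosages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("serumpqtl")

COHORTS = ("CD", "UC", "NC")
SEXES = ("M", "F")
TIME_POINTS = ("baseline", "week22")

#: dosages may stray outside [0, 2] by at most this much (float round-trip);
#: anything further out is a hard error, never a silent clip.
DOSAGE_TOL = 1e-6

RESULT_COLUMNS = ["estimate", "se", "wald", "p", "fdr"]


def setup_logging(level: str = "INFO") -> None:
    """Configure the package logger for CLI use."""
    handler = logging.StreamHandler()
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    logger.handlers[:] = [handler]
    logger.setLevel(level.upper())


def load_config(path: str | Path) -> dict:
    """Read a YAML configuration file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SampleTable:
    """Per-sample study design.

    ``df`` holds one row per serum sample with columns
    ``sample_id, subject_id, cohort, age, sex, plate_id, time_point``.
    A subject's age, sex and cohort are constant across its samples; UC and
    NC subjects contribute exactly one baseline sample while CD subjects
    contribute one or two visits (baseline and week 22).
    """

    df: pd.DataFrame

    COLUMNS = ["sample_id", "subject_id", "cohort", "age", "sex", "plate_id", "time_point"]

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"sample table missing columns: {missing}")
        df = self.df
        dup = df["sample_id"][df["sample_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate sample_id values: {sorted(dup.unique())}")
        bad_cohort = df.loc[~df["cohort"].isin(COHORTS), "sample_id"]
        if len(bad_cohort):
            raise ValueError(
                f"unknown cohort for samples {list(bad_cohort)}; expected one of {COHORTS}"
            )
        bad_sex = df.loc[~df["sex"].isin(SEXES), "sample_id"]
        if len(bad_sex):
            raise ValueError(f"unknown sex for samples {list(bad_sex)}")
        bad_tp = df.loc[~df["time_point"].isin(TIME_POINTS), "sample_id"]
        if len(bad_tp):
            raise ValueError(f"unknown time_point for samples {list(bad_tp)}")
        ages = pd.to_numeric(df["age"], errors="coerce")
        bad_age = df.loc[~np.isfinite(ages) | (ages <= 0), "sample_id"]
        if len(bad_age):
            raise ValueError(f"non-positive or non-numeric age for samples {list(bad_age)}")
        self.df["age"] = ages.astype(float)
        # subject-level constancy of age/sex/cohort
        for col in ("age", "sex", "cohort"):
            per_subj = df.groupby("subject_id")[col].nunique()
            bad = per_subj[per_subj > 1]
            if len(bad):
                raise ValueError(
                    f"subjects with inconsistent {col} across samples: {list(bad.index)}"
                )
        # visit structure
        for subj, grp in df.groupby("subject_id"):
            cohort = grp["cohort"].iloc[0]
            tps = list(grp["time_point"])
            if cohort in ("UC", "NC"):
                if tps != ["baseline"]:
                    raise ValueError(
                        f"{cohort} subject {subj} must have exactly one baseline sample, got {tps}"
                    )
            else:
                if len(tps) != len(set(tps)) or not 1 <= len(tps) <= 2:
                    raise ValueError(
                        f"CD subject {subj} must have 1-2 samples with distinct time points, got {tps}"
                    )

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.df["sample_id"])

    @property
    def subject_ids(self) -> pd.Index:
        return pd.Index(self.df["subject_id"].unique())

    def subset(self, cohort: str) -> "SampleTable":
        """Rows of a single cohort, as a new validated table."""
        if cohort not in COHORTS:
            raise ValueError(f"unknown cohort {cohort!r}")
        return SampleTable(self.df[self.df["cohort"] == cohort].copy())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str, "plate_id": str}))

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


PROBE_COLUMNS = ["probe_id", "target", "gene", "chrom", "pos"]


@dataclass
class ProteinMatrix:
    """Samples x probes log2 intensity matrix plus probe annotations.

    ``values``: DataFrame, index = sample_id, columns = probe_id, all finite.
    ``probes``: DataFrame indexed by probe_id with columns
    ``target, gene, chrom, pos`` — ``chrom``/``pos`` give a single
    representative genomic anchor (TSS-like, 1-based bp) for the probe's
    target gene, used to define the cis window; probes without an anchor
    carry NA in both.
    """

    values: pd.DataFrame
    probes: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()]
            raise ValueError(f"duplicate probe ids: {sorted(set(dup))}")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()]
            raise ValueError(f"duplicate sample ids: {sorted(set(dup))}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = self.values.map(lambda v: not isinstance(v, (int, float, np.number)))
            r, c = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"non-numeric protein value at sample {self.values.index[r]!r}, "
                f"probe {self.values.columns[c]!r}"
            )
        if not np.isfinite(arr).all():
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite protein value at sample {self.values.index[r]!r}, "
                f"probe {self.values.columns[c]!r}"
            )
        if self.probes.index.name != "probe_id":
            if "probe_id" in self.probes.columns:
                self.probes = self.probes.set_index("probe_id")
            else:
                raise ValueError("probe annotation lacks a probe_id column")
        missing = [c for c in ("target", "gene", "chrom", "pos") if c not in self.probes.columns]
        if missing:
            raise ValueError(f"probe annotation missing columns: {missing}")
        unmatched = self.values.columns.difference(self.probes.index)
        if len(unmatched):
            raise ValueError(f"probes without annotation: {sorted(unmatched)}")
        # anchored probes need both chrom and pos
        half = self.probes["chrom"].isna() ^ self.probes["pos"].isna()
        if half.any():
            raise ValueError(
                f"probes with incomplete genomic anchor: {sorted(self.probes.index[half])}"
            )
        self.probes = self.probes.loc[self.values.columns]
        self.probes.index.name = "probe_id"

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.columns

    def anchored_probes(self) -> pd.DataFrame:
        """Annotations of probes that carry a genomic anchor."""
        return self.probes[self.probes["pos"].notna()]


@dataclass
class GenotypeMatrix:
    """Subjects x variants imputed effective-allele dosages in [0, 2].

    ``dosages``: DataFrame, index = subject_id, columns = variant_id.
    ``variants``: DataFrame indexed by variant_id with columns
    ``chrom, pos, effect_allele, alt_allele``.
    """

    dosages: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.dosages.columns.duplicated().any():
            dup = self.dosages.columns[self.dosages.columns.duplicated()]
            raise ValueError(f"duplicate variant ids: {sorted(set(dup))}")
        arr = self.dosages.to_numpy(dtype=float)
        out = (arr < -DOSAGE_TOL) | (arr > 2 + DOSAGE_TOL)
        if out.any():
            r, c = np.argwhere(out)[0]
            raise ValueError(
                f"dosage {arr[r, c]} outside [0, 2] for subject "
                f"{self.dosages.index[r]!r}, variant {self.dosages.columns[c]!r}"
            )
        self.dosages = pd.DataFrame(
            np.clip(arr, 0.0, 2.0), index=self.dosages.index, columns=self.dosages.columns
        )
        if self.variants.index.name != "variant_id":
            if "variant_id" in self.variants.columns:
                self.variants = self.variants.set_index("variant_id")
            else:
                raise ValueError("variant metadata lacks a variant_id column")
        missing = [c for c in ("chrom", "pos") if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant metadata missing columns: {missing}")
        unmatched = self.dosages.columns.difference(self.variants.index)
        if len(unmatched):
            raise ValueError(f"variants without metadata: {sorted(unmatched)}")
        self.variants = self.variants.loc[self.dosages.columns]
        self.variants.index.name = "variant_id"

    @property
    def variant_ids(self) -> pd.Index:
        return self.dosages.columns

    def frequencies(self) -> pd.Series:
        """Per-variant effective-allele frequency, mean(dosage)/2."""
        return self.dosages.mean(axis=0) / 2.0


@dataclass
class AssocResult:
    """One fitted coefficient from an association model."""

    unit_id: object
    term: str
    estimate: float
    se: float
    wald: float
    p: float
    n_obs: int
    fdr: float | None = None
    flag: str | None = None


@dataclass
class GwasTable:
    """GWAS summary results: variant_id, chrom, pos, p."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("variant_id", "p") if c not in self.df.columns]
        if missing:
            raise ValueError(f"GWAS table missing columns: {missing}")
        dup = self.df["variant_id"][self.df["variant_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate variant ids in GWAS table: {sorted(dup.unique())}")
        p = self.df["p"].to_numpy(dtype=float)
        bad = (p <= 0) | (p > 1) | ~np.isfinite(p)
        if bad.any():
            ids = list(self.df["variant_id"].to_numpy()[bad][:5])
            raise ValueError(f"GWAS p-values outside (0, 1] for variants {ids}")
        self.df = self.df.reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GwasTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"variant_id": str}))


@dataclass(frozen=True)
class GeneSet:
    """A labelled set of (upper-cased) gene symbols."""

    label: str
    members: frozenset = field(default_factory=frozenset)

    @classmethod
    def from_symbols(cls, label: str, symbols: Iterable[str]) -> "GeneSet":
        return cls(label, frozenset(str(s).upper() for s in symbols))

    @classmethod
    def from_file(cls, path: str | Path, label: str | None = None) -> "GeneSet":
        """One gene symbol per line; blank lines ignored."""
        syms = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
        return cls.from_symbols(label or Path(path).stem, syms)

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_protein_matrix(values_path: str | Path, probes_path: str | Path) -> ProteinMatrix:
    """Read a samples x probes log2-intensity TSV plus its probe-annotation sidecar.

    The matrix file's first column is ``sample_id``; the header row carries
    probe ids.  Non-numeric cells raise with the offending row/column named.
    """
    values = pd.read_csv(values_path, sep="\t", index_col="sample_id")
    for col in values.columns:
        coerced = pd.to_numeric(values[col], errors="coerce")
        bad = coerced.isna() & values[col].notna() | values[col].isna()
        if bad.any():
            raise ValueError(
                f"non-numeric protein value at sample {values.index[bad.argmax()]!r}, "
                f"probe {col!r}"
            )
        values[col] = coerced
    probes = pd.read_csv(probes_path, sep="\t", dtype={"probe_id": str, "chrom": str})
    return ProteinMatrix(values, probes)


def write_protein_matrix(matrix: ProteinMatrix, values_path: str | Path, probes_path: str | Path) -> None:
    """Write the matrix and its annotation sidecar; full-precision round-trip."""
    out = matrix.values.copy()
    out.index.name = "sample_id"
    out.to_csv(values_path, sep="\t", float_format="%.17g")
    matrix.probes.to_csv(probes_path, sep="\t")


def read_genotypes(
    path: str | Path,
    variants_path: str | Path | None = None,
) -> GenotypeMatrix:
    """Read genotype dosages from a subjects x variants TSV or a VCF.

    TSV dialect: first column ``subject_id``, header row of variant ids,
    cells are effective-allele dosages; ``variants_path`` is the required
    metadata sidecar (variant_id, chrom, pos, effect_allele, alt_allele).
    VCF dialect (.vcf/.vcf.gz): per-sample DS FORMAT values; REF is taken
    as the alternative allele and ALT as the effective (dosage-counted)
    allele, matching the DS convention.
    """
    path = Path(path)
    if path.suffix == ".vcf" or path.name.endswith(".vcf.gz"):
        return _read_genotypes_vcf(path)
    if variants_path is None:
        raise ValueError("TSV genotype input requires a variant metadata sidecar")
    dosages = pd.read_csv(path, sep="\t", index_col="subject_id")
    variants = pd.read_csv(variants_path, sep="\t", dtype={"variant_id": str, "chrom": str})
    return GenotypeMatrix(dosages, variants)


def _read_genotypes_vcf(path: Path) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF ingestion requires cyvcf2") from exc
    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    ids, chroms, poss, eff, alt, rows = [], [], [], [], [], []
    for rec in vcf:
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        ds = rec.format("DS")
        if ds is None:
            raise ValueError(f"variant {vid}: VCF record lacks a DS dosage field")
        ids.append(vid)
        chroms.append(str(rec.CHROM))
        poss.append(int(rec.POS))
        eff.append(rec.ALT[0] if rec.ALT else ".")
        alt.append(rec.REF)
        rows.append(np.asarray(ds, dtype=float).ravel())
    dosages = pd.DataFrame(np.column_stack(rows) if rows else np.empty((len(subjects), 0)),
                           index=pd.Index(subjects, name="subject_id"),
                           columns=ids)
    variants = pd.DataFrame(
        {"variant_id": ids, "chrom": chroms, "pos": poss,
         "effect_allele": eff, "alt_allele": alt}
    )
    return GenotypeMatrix(dosages, variants)


def write_genotypes(gt: GenotypeMatrix, path: str | Path, variants_path: str | Path) -> None:
    out = gt.dosages.copy()
    out.index.name = "subject_id"
    out.to_csv(path, sep="\t", float_format="%.17g")
    gt.variants.to_csv(variants_path, sep="\t")


def write_results(df: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    """Write a result table; the seed used is recorded in a header comment."""
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)
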