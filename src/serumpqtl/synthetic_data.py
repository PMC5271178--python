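"""Synthetic cohorts, genotypes and protein matrices.

Generates data with the statistical structure the downstream association
models assume, so every pipeline stage is testable without access to a
real serum-proteomics cohort: three cohorts (CD with two visits per
subject, UC and NC with one), plate/batch shifts optionally confounded
with cohort, Hardy-Weinberg genotypes at chosen allele frequencies, and
log2 protein intensities built from additive age, sex, plate, time-point
and cis-genotype effects plus a subject-level random intercept.

Randomness is reproducible and stable under edits: each operation seeds a
numpy generator from its ``seed`` argument, and per-probe / per-variant
sub-streams are derived by stably hashing the probe or variant id, so
adding a probe to a design never reshuffles the draws of existing ones.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import COHORTS, GenotypeMatrix, ProteinMatrix, SampleTable

#: study-condition defaults: cohort sizes and age ranges (years)
DEFAULT_COHORT_SIZES = {"CD": 84, "UC": 88, "NC": 15}
DEFAULT_AGE_RANGES = {"CD": (18, 64), "UC": (18, 77), "NC": (39, 62)}
DEFAULT_N_PLATES = 5


def _substream(seed: int, *keys: object) -> np.random.Generator:
    """Generator for a (seed, keys...) sub-stream, stable under re-ordering
    of unrelated keys: the key tuple is hashed with blake2b."""
    h = hashlib.blake2b("\x1f".join(str(k) for k in keys).encode(), digest_size=8)
    return np.random.default_rng(np.random.SeedSequence([int(seed), int.from_bytes(h.digest(), "big")]))


@dataclass
class EffectSpec:
    """Data-generating parameters of one probe.

    The generating model per sample is

        y = intercept + beta_age * age + beta_sex * [sex == M]
            + plate_shift[plate] + beta_time * [time == week22]
            + beta_g * dosage(cis_variant) + u_subject + eps

    with ``u_subject ~ N(0, sigma_subject^2)`` shared across a subject's
    samples and ``eps ~ N(0, sigma_e^2)`` independent per sample.  All
    effects are in log2-intensity units (``beta_age`` per year, ``beta_g``
    per effective-allele copy).
    """

    probe_id: str
    intercept: float = 10.0
    beta_age: float = 0.0
    beta_sex: float = 0.0
    beta_time: float = 0.0
    plate_shifts: dict = field(default_factory=dict)
    cis_variant: str | None = None
    beta_g: float = 0.0
    sigma_subject: float = 1.0
    sigma_e: float = 1.0
    target: str | None = None
    gene: str | None = None
    chrom: str | None = None
    pos: int | None = None

    def __post_init__(self) -> None:
        if self.sigma_subject < 0:
            raise ValueError(f"probe {self.probe_id}: sigma_subject must be >= 0")
        if self.sigma_e <= 0:
            raise ValueError(f"probe {self.probe_id}: sigma_e must be > 0")
        if self.target is None:
            self.target = self.probe_id
        if self.gene is None:
            self.gene = self.probe_id.upper()


def simulate_cohort(
    n_cd: int,
    n_uc: int,
    n_nc: int,
    age_ranges: dict[str, tuple[float, float]] | None = None,
    n_plates: int = DEFAULT_N_PLATES,
    seed: int = 0,
    plate_assignment: str = "confounded",
) -> SampleTable:
    """Simulate the study design table.

    CD subjects contribute two samples (baseline and week 22), UC and NC one
    baseline sample each.  Ages are uniform within the cohort's range, sexes
    Bernoulli(1/2).  With ``plate_assignment='confounded'`` (default) samples
    are laid out cohort-by-cohort and cut into ``n_plates`` contiguous
    plates, so cohort and plate are confounded as in a plate-per-batch
    design; ``'randomized'`` shuffles samples across plates instead.
    """
    if n_cd < 0 or n_uc < 0 or n_nc < 0:
        raise ValueError("cohort sizes must be non-negative")
    if n_cd + n_uc + n_nc == 0:
        raise ValueError("at least one cohort must be non-empty")
    if plate_assignment not in ("confounded", "randomized"):
        raise ValueError(f"unknown plate_assignment {plate_assignment!r}")
    age_ranges = dict(DEFAULT_AGE_RANGES, **(age_ranges or {}))
    for cohort, (lo, hi) in age_ranges.items():
        if not lo < hi:
            raise ValueError(f"cohort {cohort}: age range min must be < max")

    rows = []
    for cohort, n in (("CD", n_cd), ("UC", n_uc), ("NC", n_nc)):
        rng = _substream(seed, "cohort", cohort)
        lo, hi = age_ranges[cohort]
        ages = rng.uniform(lo, hi, size=n)
        sexes = np.where(rng.random(n) < 0.5, "M", "F")
        for i in range(n):
            subj = f"{cohort}{i + 1:04d}"
            visits = ("baseline", "week22") if cohort == "CD" else ("baseline",)
            for tp in visits:
                rows.append(
                    {
                        "sample_id": f"{subj}_{tp}",
                        "subject_id": subj,
                        "cohort": cohort,
                        "age": round(float(ages[i]), 6),
                        "sex": str(sexes[i]),
                        "plate_id": "",
                        "time_point": tp,
                    }
                )
    df = pd.DataFrame(rows)

    n_samples = len(df)
    order = np.arange(n_samples)
    if plate_assignment == "randomized":
        order = _substream(seed, "plates").permutation(n_samples)
    plate_of = np.empty(n_samples, dtype=int)
    chunk = -(-n_samples // n_plates)  # ceil
    plate_of[order] = np.arange(n_samples) // chunk
    df["plate_id"] = [f"plate{p + 1}" for p in plate_of]
    return SampleTable(df)


def simulate_genotypes(
    subjects: list[str],
    variant_specs: list[tuple],
    seed: int = 0,
) -> GenotypeMatrix:
    """Hardy-Weinberg genotypes: dosage ~ Binomial(2, maf) per subject.

    ``variant_specs`` is a list of ``(variant_id, chrom, pos, maf)`` tuples
    with ``0 < maf <= 0.5``.  Dosages are hard allele counts; downstream
    code treats them as (trivially) imputed continuous dosages.
    """
    ids = [v[0] for v in variant_specs]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate variant ids: {dup}")
    cols = {}
    meta = []
    for vid, chrom, pos, maf in variant_specs:
        if not 0 < maf <= 0.5:
            raise ValueError(f"variant {vid}: maf must be in (0, 0.5], got {maf}")
        rng = _substream(seed, "variant", vid)
        cols[vid] = rng.binomial(2, maf, size=len(subjects)).astype(float)
        meta.append({"variant_id": vid, "chrom": str(chrom), "pos": int(pos),
                     "effect_allele": "A", "alt_allele": "G"})
    dosages = pd.DataFrame(cols, index=pd.Index(subjects, name="subject_id"))
    return GenotypeMatrix(dosages, pd.DataFrame(meta, columns=["variant_id", "chrom", "pos", "effect_allele", "alt_allele"]))


def simulate_proteome(
    samples: SampleTable,
    genotypes: GenotypeMatrix | None,
    effects: list[EffectSpec],
    seed: int = 0,
) -> ProteinMatrix:
    """Simulate log2 protein intensities under the additive model of
    :class:`EffectSpec`, one sub-stream per probe."""
    df = samples.df
    n = len(df)
    age = df["age"].to_numpy()
    is_m = (df["sex"] == "M").to_numpy(dtype=float)
    is_wk22 = (df["time_point"] == "week22").to_numpy(dtype=float)
    subj_codes, subj_index = pd.factorize(df["subject_id"])

    values = {}
    probe_meta = []
    for spec in effects:
        rng = _substream(seed, "probe", spec.probe_id)
        y = np.full(n, spec.intercept, dtype=float)
        y += spec.beta_age * age + spec.beta_sex * is_m + spec.beta_time * is_wk22
        if spec.plate_shifts:
            unknown = set(df["plate_id"]) - set(spec.plate_shifts)
            if unknown:
                raise ValueError(
                    f"probe {spec.probe_id}: no plate shift for plates {sorted(unknown)}"
                )
            y += df["plate_id"].map(spec.plate_shifts).to_numpy(dtype=float)
        if spec.cis_variant is not None:
            if genotypes is None or spec.cis_variant not in genotypes.variant_ids:
                raise ValueError(
                    f"probe {spec.probe_id}: cis variant {spec.cis_variant!r} not in genotype matrix"
                )
            dos = genotypes.dosages[spec.cis_variant]
            missing = set(subj_index) - set(dos.index)
            if missing:
                raise ValueError(
                    f"probe {spec.probe_id}: subjects without genotype: {sorted(missing)[:5]}"
                )
            y += spec.beta_g * dos.reindex(df["subject_id"]).to_numpy()
        u = rng.normal(0.0, spec.sigma_subject, size=len(subj_index))
        eps = rng.normal(0.0, spec.sigma_e, size=n)
        y += u[subj_codes] + eps
        values[spec.probe_id] = y
        probe_meta.append(
            {"probe_id": spec.probe_id, "target": spec.target, "gene": spec.gene,
             "chrom": spec.chrom, "pos": spec.pos}
        )
    values_df = pd.DataFrame(values, index=pd.Index(df["sample_id"], name="sample_id"))
    probes = pd.DataFrame(probe_meta, columns=["probe_id", "target", "gene", "chrom", "pos"])
    return ProteinMatrix(values_df, probes)


def design_from_config(cfg: dict) -> dict:
    """Expand a YAML design config into simulate_* keyword arguments.

    Recognised keys (all optional): ``n_cd, n_uc, n_nc, n_plates,
    plate_assignment, age_ranges, n_null_probes, sigma_subject, sigma_e,
    aging_probes`` (list of {probe_id, beta_age, ...}), ``cis_probes``
    (list of {probe_id, variant_id, chrom, pos, maf, beta_g, ...}).
    """
    sizes = {
        "n_cd": int(cfg.get("n_cd", DEFAULT_COHORT_SIZES["CD"])),
        "n_uc": int(cfg.get("n_uc", DEFAULT_COHORT_SIZES["UC"])),
        "n_nc": int(cfg.get("n_nc", DEFAULT_COHORT_SIZES["NC"])),
        "n_plates": int(cfg.get("n_plates", DEFAULT_N_PLATES)),
        "plate_assignment": cfg.get("plate_assignment", "confounded"),
    }
    ranges = cfg.get("age_ranges")
    if ranges:
        sizes["age_ranges"] = {k: tuple(v) for k, v in ranges.items()}
    sig_u = float(cfg.get("sigma_subject", 1.0))
    sig_e = float(cfg.get("sigma_e", 1.0))

    effects: list[EffectSpec] = []
    variant_specs: list[tuple] = []
    for p in cfg.get("aging_probes", []):
        effects.append(
            EffectSpec(
                probe_id=p["probe_id"],
                beta_age=float(p.get("beta_age", 0.011)),
                beta_sex=float(p.get("beta_sex", 0.0)),
                sigma_subject=float(p.get("sigma_subject", sig_u)),
                sigma_e=float(p.get("sigma_e", sig_e)),
                gene=p.get("gene"),
                chrom=p.get("chrom"),
                pos=p.get("pos"),
            )
        )
    for p in cfg.get("cis_probes", []):
        vid = p["variant_id"]
        variant_specs.append((vid, str(p.get("chrom", "1")), int(p.get("pos", 1_000_000)),
                              float(p.get("maf", 0.3))))
        effects.append(
            EffectSpec(
                probe_id=p["probe_id"],
                cis_variant=vid,
                beta_g=float(p.get("beta_g", 0.8)),
                sigma_subject=float(p.get("sigma_subject", sig_u)),
                sigma_e=float(p.get("sigma_e", sig_e)),
                gene=p.get("gene"),
                chrom=str(p.get("chrom", "1")),
                pos=int(p.get("pos", 1_000_000)),
            )
        )
    n_null = int(cfg.get("n_null_probes", 0))
    for i in range(n_null):
        effects.append(
            EffectSpec(probe_id=f"SLN{i + 1:05d}", sigma_subject=sig_u, sigma_e=sig_e)
        )
    return {"cohort_kwargs": sizes, "effects": effects, "variant_specs": variant_specs}
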