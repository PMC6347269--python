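"""Data model and I/O for pedigrees, genotypes and censored phenotypes.

The analysis unit is a nuclear family: two parents (possibly ungenotyped)
and one or more offspring.  Offspring carry a censored phenotype
``(Y, delta)`` — observed time (e.g. age-at-onset or age-at-exam, in years)
and an event indicator — plus optional covariates.  Genotypes are additive
minor-allele counts in {0, 1, 2}; missing calls are stored as NaN.

A :class:`CohortDataset` ties the three together with a canonical subject
order (families contiguous, offspring after parents) and a rare-variant
filter (MAF below a threshold, 0.01 by default).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = np.nan

ROLE_FATHER = "father"
ROLE_MOTHER = "mother"
ROLE_OFFSPRING = "offspring"


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees."""


@dataclass(frozen=True)
class PedigreeRecord:
    family_id: str
    individual_id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    sex: int  # 1 male, 2 female, 0 unknown
    role: str  # father / mother / offspring


class Pedigree:
    """A collection of nuclear families.

    Validates on construction: unique individual ids, parents belong to the
    same family with consistent sex, every family has at least one offspring,
    and no multi-generation chains (a listed parent may not itself have
    parents, and may not parent two families).
    """

    def __init__(self, records: Sequence[PedigreeRecord]):
        self.records = list(records)
        self._validate()
        # stable family order = order of first appearance
        seen: dict[str, None] = {}
        self._by_family: dict[str, list[PedigreeRecord]] = {}
        for r in self.records:
            seen.setdefault(r.family_id, None)
            self._by_family.setdefault(r.family_id, []).append(r)
        self.family_ids = list(seen)

    # -- structure queries -------------------------------------------------
    def _validate(self) -> None:
        ids = [r.individual_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise PedigreeError("duplicate individual ids in pedigree")
        by_id = {r.individual_id: r for r in self.records}
        parent_fams: dict[str, set[str]] = {}
        for r in self.records:
            for pid, want_sex, label in (
                (r.father_id, 1, "father"),
                (r.mother_id, 2, "mother"),
            ):
                if pid is None:
                    continue
                if pid in by_id:
                    p = by_id[pid]
                    if p.family_id != r.family_id:
                        raise PedigreeError(
                            f"{label} {pid} of {r.individual_id} is in a "
                            f"different family"
                        )
                    if p.sex not in (0, want_sex):
                        raise PedigreeError(
                            f"{label} {pid} has sex {p.sex}, inconsistent "
                            f"with parental role"
                        )
                    if p.father_id is not None or p.mother_id is not None:
                        raise PedigreeError(
                            f"parent {pid} itself has parents listed: "
                            f"pedigree is not nuclear"
                        )
                parent_fams.setdefault(pid, set()).add(r.family_id)
        for pid, fams in parent_fams.items():
            if len(fams) > 1:
                raise PedigreeError(
                    f"parent {pid} appears in multiple families: {sorted(fams)}"
                )
        fam_off: dict[str, int] = {}
        for r in self.records:
            if r.role == ROLE_OFFSPRING:
                fam_off[r.family_id] = fam_off.get(r.family_id, 0) + 1
            else:
                fam_off.setdefault(r.family_id, 0)
        for fid, n in fam_off.items():
            if n == 0:
                raise PedigreeError(f"family {fid} has no offspring")

    def members(self, family_id: str) -> list[PedigreeRecord]:
        return list(self._by_family.get(family_id, []))

    def offspring(self, family_id: Optional[str] = None) -> list[PedigreeRecord]:
        pool = self.records if family_id is None else self._by_family.get(family_id, [])
        return [r for r in pool if r.role == ROLE_OFFSPRING]

    def parents(self, family_id: str) -> dict[str, Optional[str]]:
        """Return {'father': id-or-None, 'mother': id-or-None} for a family."""
        father = mother = None
        for r in self.members(family_id):
            if r.role == ROLE_FATHER:
                father = r.individual_id
            elif r.role == ROLE_MOTHER:
                mother = r.individual_id
        # fall back to ids referenced by offspring but not listed as rows
        for r in self.members(family_id):
            if r.role == ROLE_OFFSPRING:
                father = father or r.father_id
                mother = mother or r.mother_id
        return {"father": father, "mother": mother}

    @property
    def offspring_ids(self) -> list[str]:
        return [r.individual_id for r in self.records if r.role == ROLE_OFFSPRING]

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class GenotypeMatrix:
    """Additive minor-allele scores, subjects x variants.

    ``scores`` is float (NaN = missing call) but holds integer values
    {0, 1, 2}.  ``variant_meta`` is indexed by variant id with columns
    ``position`` (1-based bp), ``minor_allele``, ``population_maf``
    (NaN when unknown) and, when read from / destined for VCF, ``ref``,
    ``alt`` and ``minor_is_alt``.
    """

    subject_ids: list[str]
    variant_ids: list[str]
    scores: np.ndarray
    variant_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.subject_ids), len(self.variant_ids)):
            raise ValueError("genotype score matrix shape mismatch")
        valid = np.isnan(self.scores) | np.isin(self.scores, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("genotype scores must be 0/1/2 or missing")
        pm = self.variant_meta.get("population_maf")
        if pm is not None:
            ok = pm.isna() | ((pm > 0) & (pm <= 0.5))
            if not ok.all():
                raise ValueError("population_maf must lie in (0, 0.5]")
        self._index = {s: i for i, s in enumerate(self.subject_ids)}

    def row(self, subject_id: str) -> np.ndarray:
        return self.scores[self._index[subject_id]]

    def has_subject(self, subject_id: str) -> bool:
        return subject_id in self._index

    def subset(
        self,
        subject_ids: Optional[Sequence[str]] = None,
        variant_idx: Optional[np.ndarray] = None,
    ) -> "GenotypeMatrix":
        rows = (
            np.arange(len(self.subject_ids))
            if subject_ids is None
            else np.array([self._index[s] for s in subject_ids])
        )
        cols = (
            np.arange(len(self.variant_ids))
            if variant_idx is None
            else np.asarray(variant_idx)
        )
        return GenotypeMatrix(
            subject_ids=[self.subject_ids[i] for i in rows],
            variant_ids=[self.variant_ids[j] for j in cols],
            scores=self.scores[np.ix_(rows, cols)],
            variant_meta=self.variant_meta.iloc[cols].copy(),
        )


@dataclass
class CensoredPhenotype:
    """Right-censored outcome per subject: Y = min(T, C), delta = 1{T <= C}."""

    subject_ids: list[str]
    time: np.ndarray  # observed time Y, years, > 0
    event: np.ndarray  # delta in {0, 1}
    covariates: np.ndarray  # N x p (p may be 0)
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.covariates.shape[0] != len(self.subject_ids):
            self.covariates = self.covariates.reshape(len(self.subject_ids), -1)
        if np.any(self.time <= 0):
            raise ValueError("observed times must be positive")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0 or 1")
        if len({*self.subject_ids}) != len(self.subject_ids):
            raise ValueError("duplicated subject id in phenotypes")
        self._index = {s: i for i, s in enumerate(self.subject_ids)}

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[1]

    def reorder(self, subject_ids: Sequence[str]) -> "CensoredPhenotype":
        idx = np.array([self._index[s] for s in subject_ids])
        return CensoredPhenotype(
            subject_ids=list(subject_ids),
            time=self.time[idx],
            event=self.event[idx],
            covariates=self.covariates[idx],
            covariate_names=list(self.covariate_names),
        )


@dataclass
class CohortDataset:
    """Pedigree + genotypes + offspring phenotypes, ID-aligned and filtered.

    ``parent_haplotypes``, when present (simulation mode), maps
    {"father": (H1, H2), "mother": (H1, H2)} to per-trio haplotype matrices
    aligned with offspring order; it enables LD-preserving gene-drop.
    """

    pedigree: Pedigree
    genotypes: GenotypeMatrix
    phenotypes: Optional[CensoredPhenotype]
    rare_maf_threshold: float = 0.01
    parent_haplotypes: Optional[dict] = None

    # -- convenience views -------------------------------------------------
    @property
    def offspring_ids(self) -> list[str]:
        return self.pedigree.offspring_ids

    @property
    def n_families(self) -> int:
        return len(self.pedigree.family_ids)

    @property
    def n_variants(self) -> int:
        return len(self.genotypes.variant_ids)

    def offspring_scores(self) -> np.ndarray:
        return np.vstack([self.genotypes.row(s) for s in self.offspring_ids])

    def family_of_offspring(self) -> np.ndarray:
        """Integer family index per offspring, families numbered 0..n-1."""
        fam_idx = {f: i for i, f in enumerate(self.pedigree.family_ids)}
        return np.array(
            [
                fam_idx[r.family_id]
                for r in self.pedigree.records
                if r.role == ROLE_OFFSPRING
            ]
        )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_vcf_genotypes(
    path: str | Path,
    region: Optional[str] = None,
    pop_maf_info: Optional[str] = "PMAF",
) -> GenotypeMatrix:
    """Read additive minor-allele scores from a biallelic VCF.

    The minor allele at each site is the allele with in-file frequency
    <= 0.5, unless ``pop_maf_info`` names an INFO field carrying a
    population MAF for the ALT allele, in which case ALT is taken as the
    minor allele and the INFO value recorded as ``population_maf``.
    Multiallelic records are rejected (split them upstream, e.g. with
    ``bcftools norm``).
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise IOError(f"cannot read VCF {path}: {exc}") from exc
    subjects = list(vcf.samples)
    rows = []
    meta_rows = []
    vids = []
    it = vcf(region) if region else vcf
    for var in it:
        if len(var.ALT) != 1:
            raise ValueError(
                f"multiallelic record at {var.CHROM}:{var.POS}; "
                "split multiallelics before loading"
            )
        # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = np.asarray(var.gt_types)
        alt_count = np.choose(gt, [0.0, 1.0, np.nan, 2.0])
        if np.isnan(alt_count).all():
            raise ValueError(f"all genotypes missing at {var.CHROM}:{var.POS}")
        pmaf = np.nan
        if pop_maf_info is not None:
            v = var.INFO.get(pop_maf_info)
            if v is not None:
                pmaf = float(v)
        if np.isnan(pmaf):
            alt_freq = np.nanmean(alt_count) / 2.0
            minor_is_alt = alt_freq <= 0.5
        else:
            minor_is_alt = True
        score = alt_count if minor_is_alt else 2.0 - alt_count
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        vids.append(vid)
        rows.append(score)
        meta_rows.append(
            {
                "position": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0],
                "minor_is_alt": minor_is_alt,
                "minor_allele": var.ALT[0] if minor_is_alt else var.REF,
                "population_maf": pmaf,
                "chrom": var.CHROM,
            }
        )
    if not rows:
        raise ValueError(f"no variant records read from {path}")
    meta = pd.DataFrame(meta_rows, index=vids)
    return GenotypeMatrix(
        subject_ids=subjects,
        variant_ids=vids,
        scores=np.array(rows).T,
        variant_meta=meta,
    )


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a PLINK .fam file (FID IID PAT MAT SEX PHENO, '0' = missing).

    Roles are inferred: a subject is a father/mother iff its IID appears in
    a PAT/MAT column; everyone else is an offspring.
    """
    raw = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 6:
                raise PedigreeError(f"{path}:{ln}: expected 6 columns")
            raw.append(parts[:6])
    fathers = {r[2] for r in raw if r[2] != "0"}
    mothers = {r[3] for r in raw if r[3] != "0"}
    records = []
    for fid, iid, pat, mat, sex, _pheno in raw:
        if iid in fathers and iid in mothers:
            raise PedigreeError(f"{iid} listed as both father and mother")
        if iid in fathers:
            role = ROLE_FATHER
        elif iid in mothers:
            role = ROLE_MOTHER
        else:
            role = ROLE_OFFSPRING
        if role != ROLE_OFFSPRING and (pat != "0" or mat != "0"):
            raise PedigreeError(
                f"parent {iid} itself has parents listed: not a nuclear family"
            )
        records.append(
            PedigreeRecord(
                family_id=fid,
                individual_id=iid,
                father_id=None if pat == "0" else pat,
                mother_id=None if mat == "0" else mat,
                sex=int(sex),
                role=role,
            )
        )
    return Pedigree(records)


def read_phenotypes(
    path: str | Path,
    time_col: str,
    event_col: str,
    covariate_cols: Sequence[str] = (),
    iid_col: str = "IID",
) -> CensoredPhenotype:
    """Read a delimited phenotype table (TSV/CSV with header)."""
    df = pd.read_csv(path, sep=None, engine="python")
    for col in (iid_col, time_col, event_col, *covariate_cols):
        if col not in df.columns:
            raise ValueError(f"column {col!r} absent from {path}")
    if df[iid_col].duplicated().any():
        dup = df[iid_col][df[iid_col].duplicated()].iloc[0]
        raise ValueError(f"duplicated IID {dup!r} in phenotype file")
    event = df[event_col].astype(float)
    if not event.isin([0.0, 1.0]).all():
        raise ValueError("event column contains values outside {0, 1}")
    cov = (
        df[list(covariate_cols)].to_numpy(float)
        if covariate_cols
        else np.empty((len(df), 0))
    )
    return CensoredPhenotype(
        subject_ids=[str(s) for s in df[iid_col]],
        time=df[time_col].to_numpy(float),
        event=event.to_numpy(int),
        covariates=cov,
        covariate_names=list(covariate_cols),
    )


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def _founder_sample_maf(
    ped: Pedigree, geno: GenotypeMatrix, rng: np.random.Generator
) -> np.ndarray:
    """Per-variant sample MAF from founders (parents when genotyped, else
    one random offspring per family) to avoid relatedness bias."""
    rows = []
    for fid in ped.family_ids:
        par = ped.parents(fid)
        used_parent = False
        for pid in (par["father"], par["mother"]):
            if pid is not None and geno.has_subject(pid):
                rows.append(geno.row(pid))
                used_parent = True
        if not used_parent:
            offs = [
                r.individual_id
                for r in ped.offspring(fid)
                if geno.has_subject(r.individual_id)
            ]
            if offs:
                rows.append(geno.row(offs[int(rng.integers(len(offs)))]))
    mat = np.vstack(rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        freq = np.nanmean(mat, axis=0) / 2.0
    return np.minimum(freq, 1.0 - freq)


def assemble_cohort(
    ped: Pedigree,
    geno: GenotypeMatrix,
    pheno: Optional[CensoredPhenotype],
    rare_maf_threshold: float = 0.01,
    maf_source: str = "population",
    rng: Optional[np.random.Generator] = None,
) -> CohortDataset:
    """Align IDs, canonicalize subject order and keep rare variants only.

    Variants with MAF >= ``rare_maf_threshold`` are dropped; the MAF comes
    from ``variant_meta.population_maf`` (``maf_source='population'``) or is
    computed from founder genotypes (``maf_source='sample'``).  Variants
    monomorphic among genotyped subjects are dropped with a warning.
    """
    if not 0 < rare_maf_threshold <= 0.5:
        raise ValueError("rare_maf_threshold must lie in (0, 0.5]")
    if maf_source not in ("population", "sample"):
        raise ValueError("maf_source must be 'population' or 'sample'")
    rng = rng if rng is not None else np.random.default_rng(0)

    # canonical subject order: per family, father, mother, then offspring
    ordered: list[str] = []
    for fid in ped.family_ids:
        par = ped.parents(fid)
        for pid in (par["father"], par["mother"]):
            if pid is not None and geno.has_subject(pid):
                ordered.append(pid)
        for r in ped.offspring(fid):
            ordered.append(r.individual_id)
    missing_geno = [s for s in ordered if not geno.has_subject(s)]
    off_ids = set(ped.offspring_ids)
    if any(s in off_ids for s in missing_geno):
        raise ValueError(
            f"offspring without genotypes: {[s for s in missing_geno if s in off_ids][:5]}"
        )

    if maf_source == "population":
        maf = geno.variant_meta["population_maf"].to_numpy(float)
        if np.isnan(maf).any():
            raise ValueError(
                "maf_source='population' but population_maf metadata is "
                "missing for some variants"
            )
    else:
        maf = _founder_sample_maf(ped, geno, rng)

    keep = maf < rare_maf_threshold
    sub = geno.subset(subject_ids=ordered)
    col_nanmin = np.nanmin(sub.scores, axis=0, initial=np.inf)
    col_nanmax = np.nanmax(sub.scores, axis=0, initial=-np.inf)
    mono = col_nanmin == col_nanmax
    if (keep & mono).any():
        n_mono = int((keep & mono).sum())
        logger.warning("dropping %d monomorphic variant(s) after MAF filter", n_mono)
        keep &= ~mono
    if not keep.any():
        raise ValueError("no variants remain after rare-variant filtering")
    sub = sub.subset(variant_idx=np.flatnonzero(keep))

    if pheno is not None:
        have = set(pheno.subject_ids)
        lacking = [s for s in ped.offspring_ids if s not in have]
        if lacking:
            raise ValueError(f"offspring lacking phenotype rows: {lacking[:5]}")
        extra = have - set(ped.offspring_ids)
        if extra:
            logger.warning(
                "ignoring %d phenotype row(s) for non-offspring subjects "
                "(the hazard model covers offspring only)",
                len(extra),
            )
        pheno = pheno.reorder(ped.offspring_ids)

    return CohortDataset(
        pedigree=ped,
        genotypes=sub,
        phenotypes=pheno,
        rare_maf_threshold=rare_maf_threshold,
    )


# ---------------------------------------------------------------------------
# writers (round-trip support)
# ---------------------------------------------------------------------------

def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT fields (and PMAF INFO when known)."""
    meta = geno.variant_meta
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=PMAF,Number=1,Type=Float,Description="Population minor allele frequency">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.subject_ids)
            + "\n"
        )
        for j, vid in enumerate(geno.variant_ids):
            row = meta.iloc[j]
            chrom = str(row.get("chrom", "1"))
            ref = str(row.get("ref", "A"))
            alt = str(row.get("alt", "T"))
            minor_is_alt = bool(row.get("minor_is_alt", True))
            pmaf = row.get("population_maf", np.nan)
            info = "." if pd.isna(pmaf) else f"PMAF={pmaf:.6g}"
            gts = []
            for s in geno.scores[:, j]:
                if np.isnan(s):
                    gts.append("./.")
                    continue
                alt_count = int(s) if minor_is_alt else 2 - int(s)
                gts.append(["0/0", "0/1", "1/1"][alt_count])
            fh.write(
                f"{chrom}\t{int(row['position'])}\t{vid}\t{ref}\t{alt}\t.\t.\t"
                f"{info}\tGT\t" + "\t".join(gts) + "\n"
            )


def write_fam(ped: Pedigree, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in ped.records:
            fh.write(
                f"{r.family_id} {r.individual_id} {r.father_id or 0} "
                f"{r.mother_id or 0} {r.sex} -9\n"
            )


def write_phenotypes(pheno: CensoredPhenotype, path: str | Path) -> None:
    df = pd.DataFrame({"IID": pheno.subject_ids, "time": pheno.time, "event": pheno.event})
    for i, name in enumerate(pheno.covariate_names):
        df[name] = pheno.covariates[:, i]
    df.to_csv(path, sep="\t", index=False)
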