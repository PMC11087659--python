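"""Readers and writers for summary statistics, null-SNP z panels, score
weights, reference genotypes and results.

All on-disk formats are plain text: tab-delimited tables for data, JSON for
structured results.  Long-format summary statistics (one row per
variant × trait) are the canonical input; a wide z-matrix reader is provided
as a convenience.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from ._errors import (
    FormatError,
    InsufficientDataError,
    MissingVariantError,
    ValidationError,
)

__all__ = [
    "TraitMeta",
    "ZVector",
    "NullZPanel",
    "read_trait_meta",
    "read_summary_long",
    "read_z_wide",
    "read_null_panel",
    "write_null_panel",
    "write_z_wide",
    "read_score_weights",
    "read_reference_panel",
    "flip_dosage",
    "is_strand_ambiguous",
]

#: tolerance for |z - beta/se| consistency, relative to max(1, |z|)
Z_BETA_RTOL = 1e-6


@dataclass(frozen=True)
class TraitMeta:
    """Per-trait metadata: identity, type and sample sizes."""

    trait_id: str
    trait_type: str  # "continuous" | "binary"
    n: int
    n_case: int | None = None
    n_control: int | None = None

    def __post_init__(self):
        if self.trait_type not in ("continuous", "binary"):
            raise ValidationError(
                f"trait {self.trait_id}: unknown trait_type {self.trait_type!r}"
            )
        if self.n <= 0:
            raise ValidationError(f"trait {self.trait_id}: n must be positive")
        if self.trait_type == "binary":
            if not self.n_case or not self.n_control:
                raise ValidationError(
                    f"trait {self.trait_id}: binary traits need n_case and n_control > 0"
                )
            if self.n_case + self.n_control != self.n:
                raise ValidationError(
                    f"trait {self.trait_id}: n_case + n_control != n"
                )
        else:
            if self.n_case is not None or self.n_control is not None:
                raise ValidationError(
                    f"trait {self.trait_id}: continuous traits must not carry case/control counts"
                )


@dataclass
class ZVector:
    """Per-variant association z-scores across traits, in a fixed trait order."""

    variant_id: str
    trait_ids: list[str]
    z: np.ndarray

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 1 or len(self.z) != len(self.trait_ids):
            raise ValidationError("ZVector: z length must match trait_ids")
        if not np.all(np.isfinite(self.z)):
            raise ValidationError(f"ZVector {self.variant_id}: non-finite z")

    @property
    def p(self) -> int:
        return len(self.trait_ids)


@dataclass
class NullZPanel:
    """K x p matrix of z-scores at null SNPs; NaN marks missing entries."""

    snp_ids: list[str]
    trait_ids: list[str]
    z: np.ndarray
    missing_per_trait: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        if self.z.shape != (len(self.snp_ids), len(self.trait_ids)):
            raise ValidationError("NullZPanel: shape mismatch")
        if len(self.snp_ids) < 2:
            raise InsufficientDataError("null panel needs at least 2 SNPs")
        nonmiss = np.sum(~np.isnan(self.z), axis=0)
        bad = [t for t, c in zip(self.trait_ids, nonmiss) if c < 2]
        if bad:
            raise InsufficientDataError(
                f"null panel: traits with <2 non-missing z: {', '.join(bad)}"
            )
        self.missing_per_trait = {
            t: int(np.isnan(self.z[:, j]).sum()) for j, t in enumerate(self.trait_ids)
        }

    @property
    def K(self) -> int:
        return len(self.snp_ids)

    @property
    def p(self) -> int:
        return len(self.trait_ids)


def read_trait_meta(path) -> list[TraitMeta]:
    """Read a trait metadata TSV: trait_id, trait_type, n [, n_case, n_control]."""
    df = pd.read_csv(path, sep="\t", dtype={"trait_id": str})
    required = {"trait_id", "trait_type", "n"}
    if not required.issubset(df.columns):
        raise FormatError(f"trait meta: missing columns {sorted(required - set(df.columns))}")
    metas = []
    for row in df.itertuples(index=False):
        nc = getattr(row, "n_case", None)
        nk = getattr(row, "n_control", None)
        metas.append(
            TraitMeta(
                trait_id=str(row.trait_id),
                trait_type=str(row.trait_type),
                n=int(row.n),
                n_case=None if nc is None or pd.isna(nc) else int(nc),
                n_control=None if nk is None or pd.isna(nk) else int(nk),
            )
        )
    return metas


def _two_sided_p(z: float) -> float:
    return 2.0 * ndtr(-abs(z))


def read_summary_long(
    path, meta: list[TraitMeta], z_p_rtol: float = 1e-6
) -> tuple[list[ZVector], dict]:
    """Read long-format summary statistics and assemble one ZVector per variant.

    Required columns: ``variant_id``, ``trait_id`` and at least (``beta``,
    ``se``) or ``z``.  z is derived as beta/se when absent.  Returns the
    vectors (traits ordered as in ``meta``) and a validation report listing
    dropped rows.
    """
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "trait_id": str})
    cols = set(df.columns)
    if "variant_id" not in cols or "trait_id" not in cols:
        raise FormatError("summary stats: variant_id and trait_id columns are required")
    if "z" not in cols and not {"beta", "se"}.issubset(cols):
        raise FormatError("summary stats: need a z column or both beta and se")

    meta_ids = [m.trait_id for m in meta]
    meta_set = set(meta_ids)
    unknown = sorted(set(df["trait_id"]) - meta_set)
    if unknown:
        raise ValidationError(f"traits present in file but not in meta: {', '.join(unknown)}")
    dup = df.duplicated(subset=["variant_id", "trait_id"])
    if dup.any():
        pairs = df.loc[dup, ["variant_id", "trait_id"]].drop_duplicates()
        raise ValidationError(
            "duplicate (variant, trait) rows: "
            + "; ".join(f"({a},{b})" for a, b in pairs.itertuples(index=False))
        )

    dropped: list[dict] = []
    z_out = {}
    for row in df.itertuples(index=False):
        beta = getattr(row, "beta", None)
        se = getattr(row, "se", None)
        z = getattr(row, "z", None)
        pval = getattr(row, "pval", None)
        have_bs = beta is not None and se is not None and not (pd.isna(beta) or pd.isna(se))
        have_z = z is not None and not pd.isna(z)
        if have_bs and se <= 0:
            dropped.append({"variant_id": row.variant_id, "trait_id": row.trait_id,
                            "reason": "non-positive se"})
            continue
        if not have_z and not have_bs:
            dropped.append({"variant_id": row.variant_id, "trait_id": row.trait_id,
                            "reason": "no z and no beta/se"})
            continue
        if have_z and have_bs:
            if abs(z - beta / se) > Z_BETA_RTOL * max(1.0, abs(z)):
                raise ValidationError(
                    f"({row.variant_id},{row.trait_id}): z inconsistent with beta/se"
                )
        zval = float(z) if have_z else float(beta) / float(se)
        if pval is not None and not pd.isna(pval):
            if not (0.0 < pval <= 1.0):
                raise ValidationError(
                    f"({row.variant_id},{row.trait_id}): pval outside (0,1]"
                )
            expect = _two_sided_p(zval)
            if abs(pval - expect) > z_p_rtol * max(pval, expect, 1e-300):
                raise ValidationError(
                    f"({row.variant_id},{row.trait_id}): pval {pval} inconsistent with "
                    f"two-sided normal tail of z={zval:.6g} ({expect:.6g})"
                )
        z_out.setdefault(row.variant_id, {})[row.trait_id] = zval

    vectors = []
    incomplete = []
    for vid, zz in z_out.items():
        ids = [t for t in meta_ids if t in zz]
        if len(ids) < len(meta_ids):
            incomplete.append(vid)
            warnings.warn(
                f"variant {vid}: z missing for {len(meta_ids) - len(ids)} trait(s); "
                "scan will use the reduced trait set",
                stacklevel=2,
            )
        vectors.append(ZVector(vid, ids, np.array([zz[t] for t in ids])))
    report = {
        "n_rows": int(len(df)),
        "n_variants": len(vectors),
        "dropped": dropped,
        "incomplete_variants": incomplete,
    }
    return vectors, report


def read_z_wide(path) -> list[ZVector]:
    """Convenience reader: wide TSV with a variant_id column and one column per trait."""
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str},
                     float_precision="round_trip")
    if "variant_id" not in df.columns:
        raise FormatError("wide z table: variant_id column required")
    traits = [c for c in df.columns if c != "variant_id"]
    if not traits:
        raise FormatError("wide z table: no trait columns")
    zmat = df[traits].to_numpy(dtype=float)
    return [
        ZVector(str(vid), list(traits), zmat[i])
        for i, vid in enumerate(df["variant_id"])
    ]


def write_z_wide(vectors: list[ZVector], path) -> None:
    traits = vectors[0].trait_ids
    rows = []
    for v in vectors:
        if v.trait_ids != traits:
            raise ValidationError("write_z_wide: inconsistent trait sets")
        rows.append([v.variant_id] + [repr(float(x)) for x in v.z])
    with open(path, "w") as fh:
        fh.write("variant_id\t" + "\t".join(traits) + "\n")
        for r in rows:
            fh.write("\t".join(r) + "\n")


def read_null_panel(path) -> NullZPanel:
    """Read a null-SNP z panel: first column snp_id, one column per trait.

    Empty cells are treated as missing.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.shape[1] < 2:
        raise FormatError("null panel: need snp_id plus at least one trait column")
    snp_col = df.columns[0]
    trait_ids = list(df.columns[1:])
    if len(df) < 2:
        raise InsufficientDataError("null panel: fewer than 2 SNPs")
    z = df[trait_ids].to_numpy(dtype=float)
    return NullZPanel(list(df[snp_col].astype(str)), trait_ids, z)


def write_null_panel(panel: NullZPanel, path) -> None:
    with open(path, "w") as fh:
        fh.write("snp_id\t" + "\t".join(panel.trait_ids) + "\n")
        for sid, row in zip(panel.snp_ids, panel.z):
            cells = ["" if math.isnan(v) else repr(float(v)) for v in row]
            fh.write(sid + "\t" + "\t".join(cells) + "\n")


def read_score_weights(path) -> pd.DataFrame:
    """Read score weights (variant_id, effect_allele, other_allele, weight).

    Zero-weight rows are dropped with a warning; an all-zero file is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    required = {"variant_id", "effect_allele", "other_allele", "weight"}
    if not required.issubset(df.columns):
        raise FormatError(f"score weights: missing columns {sorted(required - set(df.columns))}")
    if df["variant_id"].duplicated().any():
        dups = df.loc[df["variant_id"].duplicated(), "variant_id"].unique()
        raise ValidationError(f"score weights: duplicate variant_id {', '.join(dups)}")
    nz = df["weight"].astype(float) != 0.0
    if not nz.any():
        raise ValidationError("score weights: all weights are zero (empty score)")
    if (~nz).any():
        warnings.warn(f"dropping {(~nz).sum()} zero-weight score SNP(s)", stacklevel=2)
    out = df.loc[nz].reset_index(drop=True)
    out["weight"] = out["weight"].astype(float)
    return out


_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def is_strand_ambiguous(a1: str, a2: str) -> bool:
    return (a1.upper(), a2.upper()) in _AMBIGUOUS


def flip_dosage(d):
    """Allele flip: dosage counted on the opposite allele. Involution: 2 - (2 - d) = d."""
    return 2.0 - np.asarray(d, dtype=float)


def _read_vcf_dosages(path, wanted: dict[str, tuple[str, str]]):
    import pysam

    found: dict[str, tuple[np.ndarray, str, str]] = {}
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            vid = rec.id
            if vid is None or vid not in wanted or vid in found:
                continue
            if rec.alts is None or len(rec.alts) != 1:
                continue  # biallelic sites only
            alt = rec.alts[0]
            dos = np.full(len(samples), np.nan)
            for i, s in enumerate(samples):
                smp = rec.samples[s]
                gt = smp.get("GT")
                if gt is not None and None not in gt:
                    dos[i] = float(sum(1 for a in gt if a == 1))
                elif "DS" in smp and smp["DS"] is not None:
                    dos[i] = float(smp["DS"])
            found[vid] = (dos, rec.ref, alt)
    return found, samples


def read_reference_panel(
    path,
    variant_ids: list[str],
    effect_alleles: list[str] | None = None,
    other_alleles: list[str] | None = None,
) -> np.ndarray:
    """Read reference dosages (individuals x q) harmonized to the effect allele.

    ``path`` may be a VCF (``.vcf``; alt-allele count from hard GT, DS when GT
    is absent) or a TSV dosage table whose header row names the variants (such
    a table is assumed to be already counted on the effect allele).
    """
    path = str(path)
    if path.endswith(".vcf") or path.endswith(".vcf.gz") or path.endswith(".bcf"):
        wanted = {v: (None, None) for v in variant_ids}
        found, _samples = _read_vcf_dosages(path, wanted)
        missing = [v for v in variant_ids if v not in found]
        if missing:
            raise MissingVariantError(missing)
        cols = []
        for i, vid in enumerate(variant_ids):
            dos, ref, alt = found[vid]
            if effect_alleles is None:
                cols.append(dos)
                continue
            eff = effect_alleles[i].upper()
            oth = other_alleles[i].upper() if other_alleles is not None else None
            if is_strand_ambiguous(eff, oth or ref):
                warnings.warn(
                    f"{vid}: strand-ambiguous alleles ({eff}/{oth or ref}); kept",
                    stacklevel=2,
                )
            if eff == alt.upper() and (oth is None or oth == ref.upper()):
                cols.append(dos)
            elif eff == ref.upper() and (oth is None or oth == alt.upper()):
                cols.append(flip_dosage(dos))
            else:
                raise ValidationError(
                    f"{vid}: score alleles {eff}/{oth} do not match panel {ref}/{alt}"
                )
        dosages = np.column_stack(cols)
    else:
        df = pd.read_csv(path, sep="\t")
        missing = [v for v in variant_ids if v not in df.columns]
        if missing:
            raise MissingVariantError(missing)
        dosages = df[variant_ids].to_numpy(dtype=float)
    if np.nanmin(dosages) < 0 or np.nanmax(dosages) > 2:
        raise ValidationError("reference dosages outside [0, 2]")
    return dosages


def write_scan_result_json(result, path) -> None:
    with open(path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)


def write_selected_traits_tsv(result, path, method: str = "combined") -> None:
    """Flat TSV: one row per trait selected by the chosen test."""
    subset, label = {
        "combined": (result.s_combined, result.winner),
        "hc": (result.s_hc, "hc"),
        "tc": (result.s_tc, "tc"),
    }[method]
    with open(path, "w") as fh:
        fh.write("variant_id\ttrait\tmethod\tz\tz_star\n")
        for j in subset:
            fh.write(
                f"{result.variant_id}\t{result.trait_ids[j]}\t{label}\t"
                f"{result.z[j]:.10g}\t{result.z_star[j]:.10g}\n"
            )
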