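"""GWAS summary-statistic data model, I/O, instrument selection and harmonization.

The unit of analysis downstream is a :class:`HarmonizedSet`: per-SNP exposure and
outcome effect estimates aligned to the same effect allele, with positive
standard errors and unique SNP ids. Everything in this module exists to get raw
summary-statistic tables into that shape, plus the instrument-strength
statistics (R², F) used to screen for weak instruments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical column names for summary-stat tables (TSV/CSV with header).
CANONICAL_COLUMNS = ("snp", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "pval", "n")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = ({"A", "T"}, {"C", "G"})


class ConfigurationError(ValueError):
    """A required column or setting is missing or malformed."""


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP's association summary for one trait.

    ``eaf`` and ``n`` may be ``None`` when the source table omits them;
    everything else is required and validated.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: int | None = None

    def __post_init__(self):
        if self.se <= 0:
            raise ValueError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if not (0 < self.pval <= 1):
            raise ValueError(f"{self.snp_id}: pval must be in (0, 1], got {self.pval}")
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: pos must be >= 1 (1-based)")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele identical")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValueError(f"{self.snp_id}: eaf must be in [0, 1], got {self.eaf}")

    @property
    def maf(self) -> float | None:
        """Minor-allele frequency, ``min(eaf, 1 - eaf)``."""
        return None if self.eaf is None else min(self.eaf, 1.0 - self.eaf)

    def is_palindromic(self) -> bool:
        alleles = {self.effect_allele, self.other_allele}
        return alleles in _PALINDROMIC


@dataclass
class HarmonizedSet:
    """Aligned exposure/outcome effects for a set of instruments.

    ``records`` is a DataFrame with columns
    ``snp, beta_exposure, se_exposure, beta_outcome, se_outcome`` (optionally
    ``eaf``, ``pval_exposure``, ``pval_outcome``, ``chrom``, ``pos``). Allele
    alignment is performed by :func:`harmonize` and trusted thereafter.
    """

    exposure_name: str
    outcome_name: str
    records: pd.DataFrame
    provenance: str = ""

    REQUIRED = ("snp", "beta_exposure", "se_exposure", "beta_outcome", "se_outcome")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"HarmonizedSet missing columns {missing}")
        if len(self.records) < 1:
            raise ValueError("HarmonizedSet needs at least one record")
        if self.records["snp"].duplicated().any():
            dup = self.records["snp"][self.records["snp"].duplicated()].tolist()
            raise ValueError(f"duplicate snp ids {dup}")
        for c in ("se_exposure", "se_outcome"):
            if (self.records[c] <= 0).any():
                raise ValueError(f"non-positive values in {c}")
        self.records = self.records.reset_index(drop=True)

    @property
    def n_snp(self) -> int:
        return len(self.records)

    @property
    def snp_ids(self) -> list[str]:
        return self.records["snp"].tolist()

    @property
    def bx(self) -> np.ndarray:
        return self.records["beta_exposure"].to_numpy(float)

    @property
    def sx(self) -> np.ndarray:
        return self.records["se_exposure"].to_numpy(float)

    @property
    def by(self) -> np.ndarray:
        return self.records["beta_outcome"].to_numpy(float)

    @property
    def sy(self) -> np.ndarray:
        return self.records["se_outcome"].to_numpy(float)

    def wald_ratios(self) -> np.ndarray:
        """Per-SNP ratio estimates beta_outcome / beta_exposure."""
        return self.by / self.bx

    def subset(self, keep: Sequence[int] | np.ndarray) -> "HarmonizedSet":
        return HarmonizedSet(
            self.exposure_name,
            self.outcome_name,
            self.records.iloc[list(keep)].reset_index(drop=True),
            self.provenance,
        )

    def drop_snp(self, snp_id: str) -> "HarmonizedSet":
        keep = self.records.index[self.records["snp"] != snp_id]
        return self.subset(keep)

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, exposure_name="exposure", outcome_name="outcome") -> "HarmonizedSet":
        return cls(exposure_name, outcome_name, pd.read_csv(path, sep="\t"),
                   provenance=f"loaded from {path}")


@dataclass(frozen=True)
class StrengthStats:
    """Instrument-strength summary for one SNP: variance explained and F."""

    snp_id: str
    r2: float
    f: float
    n: int
    m: int = 1

    def __post_init__(self):
        if not (0 <= self.r2 < 1):
            raise ValueError("r2 must be in [0, 1)")
        if self.f < 0:
            raise ValueError("f must be >= 0")


# ---------------------------------------------------------------------------
# I/O


def read_summary_stats(
    path,
    column_map: Mapping[str, str] | None = None,
    *,
    delimiter: str | None = None,
    return_report: bool = False,
):
    """Read a delimited GWAS summary-stat table into records.

    Parameters
    ----------
    path : str or file-like
        Tab- or comma-delimited text table with a header row.
    column_map : mapping, optional
        Maps canonical field names (``snp, chr, pos, ea, oa, eaf, beta, se,
        pval, n``) to the file's column names. Defaults to the canonical names
        themselves.
    return_report : bool
        When True, return ``(records, report)`` where the report counts rows
        dropped for unparsable/invalid beta or se.

    Rows whose beta/se cannot be parsed, or with se <= 0, are dropped and
    counted (logged at WARNING level); a missing required column raises
    :class:`ConfigurationError`.
    """
    cmap = dict(zip(CANONICAL_COLUMNS, CANONICAL_COLUMNS))
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")
    required = ["snp", "chr", "pos", "ea", "oa", "beta", "se", "pval"]
    missing = [cmap[k] for k in required if cmap[k] not in df.columns]
    if missing:
        raise ConfigurationError(f"missing required column(s) {missing} in {path}")

    records: list[SummaryStatRecord] = []
    dropped = 0
    reasons: list[str] = []
    for _, row in df.iterrows():
        try:
            beta = float(row[cmap["beta"]])
            se = float(row[cmap["se"]])
            if not np.isfinite(beta) or not np.isfinite(se):
                raise ValueError("non-finite beta/se")
            rec = SummaryStatRecord(
                snp_id=str(row[cmap["snp"]]),
                chrom=str(row[cmap["chr"]]),
                pos=int(row[cmap["pos"]]),
                effect_allele=str(row[cmap["ea"]]).upper(),
                other_allele=str(row[cmap["oa"]]).upper(),
                beta=beta,
                se=se,
                pval=float(row[cmap["pval"]]),
                eaf=_optional_float(row, cmap.get("eaf"), df.columns),
                n=_optional_int(row, cmap.get("n"), df.columns),
            )
        except (ValueError, TypeError) as exc:
            dropped += 1
            reasons.append(str(exc))
            continue
        records.append(rec)
    if dropped:
        logger.warning("read_summary_stats: dropped %d invalid row(s) from %s", dropped, path)
    if return_report:
        return records, {"n_read": len(records), "n_dropped": dropped, "reasons": reasons}
    return records


def _optional_float(row, col, columns):
    if col is None or col not in columns or pd.isna(row[col]):
        return None
    return float(row[col])


def _optional_int(row, col, columns):
    if col is None or col not in columns or pd.isna(row[col]):
        return None
    return int(row[col])


def write_summary_stats(records: Iterable[SummaryStatRecord], path, delimiter="\t") -> None:
    """Write records as a canonical-header delimited table."""
    rows = [
        {
            "snp": r.snp_id, "chr": r.chrom, "pos": r.pos, "ea": r.effect_allele,
            "oa": r.other_allele, "eaf": r.eaf, "beta": r.beta, "se": r.se,
            "pval": r.pval, "n": r.n,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS)).to_csv(path, sep=delimiter, index=False)


def read_ld_matrix(path, delimiter="\t") -> tuple[list[str], np.ndarray]:
    """Read a square LD r² matrix with a SNP-id header row.

    Returns ``(snp_ids, matrix)``; the matrix must be square with a unit
    diagonal and entries in [0, 1].
    """
    df = pd.read_csv(path, sep=delimiter)
    ids = [str(c) for c in df.columns]
    mat = df.to_numpy(float)
    _validate_ld(mat, len(ids))
    return ids, mat


def _validate_ld(mat: np.ndarray, n: int) -> None:
    if mat.shape != (n, n):
        raise ValueError(f"LD matrix shape {mat.shape} does not match {n} records")
    if np.any(mat < 0) or np.any(mat > 1):
        raise ValueError("LD r2 entries must lie in [0, 1]")
    if not np.allclose(np.diag(mat), 1.0):
        raise ValueError("LD matrix diagonal must be 1")


# ---------------------------------------------------------------------------
# Instrument selection


def select_instruments(
    records: Sequence[SummaryStatRecord], p_threshold: float = 5e-8
) -> list[SummaryStatRecord]:
    """Keep records strictly below the association p-value threshold.

    Uses strict ``pval < p_threshold`` (genome-wide significance is
    conventionally p < 5e-8). Input order is preserved; the operation is
    idempotent.
    """
    if not (0 < p_threshold < 1):
        raise ValueError("p_threshold must be in (0, 1)")
    return [r for r in records if r.pval < p_threshold]


def ld_clump(
    records: Sequence[SummaryStatRecord],
    ld_r2: np.ndarray,
    r2_threshold: float = 0.001,
    min_distance_kb: float = 10_000.0,
) -> list[SummaryStatRecord]:
    """Greedy LD clumping against a caller-supplied r² matrix.

    Repeatedly keeps the remaining record with the smallest p-value (snp_id as
    deterministic tie-break) and discards every remaining record that is either
    in LD with it above ``r2_threshold`` or on the same chromosome within
    ``min_distance_kb``. The surviving set is returned sorted by (chrom, pos),
    so the result does not depend on the input order.
    """
    records = list(records)
    ld_r2 = np.asarray(ld_r2, float)
    _validate_ld(ld_r2, len(records))

    remaining = sorted(range(len(records)), key=lambda i: (records[i].pval, records[i].snp_id))
    kept: list[int] = []
    while remaining:
        lead = remaining.pop(0)
        kept.append(lead)
        lead_rec = records[lead]
        survivors = []
        for j in remaining:
            rec = records[j]
            linked = ld_r2[lead, j] > r2_threshold
            near = (
                rec.chrom == lead_rec.chrom
                and abs(rec.pos - lead_rec.pos) / 1000.0 < min_distance_kb
            )
            if not (linked or near):
                survivors.append(j)
        remaining = survivors
    kept_records = [records[i] for i in kept]
    return sorted(kept_records, key=lambda r: (_chrom_key(r.chrom), r.pos))


def _chrom_key(chrom: str):
    try:
        return (0, int(chrom), "")
    except ValueError:
        return (1, 0, chrom)


# ---------------------------------------------------------------------------
# Harmonization


def harmonize(
    exposure: Sequence[SummaryStatRecord],
    outcome: Sequence[SummaryStatRecord],
    palindromic_policy: str = "drop",
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    eaf_band: tuple[float, float] = (0.42, 0.58),
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect allele.

    For each SNP present on both sides the outcome record is re-oriented:

    * identical allele coding — kept as is;
    * swapped effect/other alleles (directly or on the opposite strand) —
      outcome beta sign flipped, eaf complemented;
    * strand flip without swap — kept, alleles rewritten to the exposure's;
    * palindromic SNPs (A/T or C/G) — handled per ``palindromic_policy``:
      ``"drop"`` removes them; ``"infer_by_eaf"`` keeps them when both eafs sit
      on the same side outside the ambiguity band ``eaf_band`` (flipping when
      they sit on opposite sides), and drops them otherwise;
    * non-complementary allele mismatches are dropped with reason
      ``"allele mismatch"``.

    Harmonizing an already-harmonized pair is a no-op (involution safety).
    """
    if palindromic_policy not in ("drop", "infer_by_eaf"):
        raise ValueError(f"unknown palindromic_policy {palindromic_policy!r}")
    lo, hi = eaf_band
    out_by_id = {r.snp_id: r for r in outcome}
    rows = []
    dropped: dict[str, str] = {}
    for ex in exposure:
        ou = out_by_id.get(ex.snp_id)
        if ou is None:
            dropped[ex.snp_id] = "absent from outcome"
            continue
        if ex.is_palindromic() or ou.is_palindromic():
            if not (ex.is_palindromic() and ou.is_palindromic()):
                dropped[ex.snp_id] = "allele mismatch"
                continue
            if palindromic_policy == "drop":
                dropped[ex.snp_id] = "palindromic"
                continue
            action = _orient_palindromic(ex, ou, lo, hi)
            if action is None:
                dropped[ex.snp_id] = "palindromic, eaf ambiguous"
                continue
        else:
            action = _orient(ex, ou)
            if action is None:
                dropped[ex.snp_id] = "allele mismatch"
                continue
        beta_out = ou.beta if action == "keep" else -ou.beta
        eaf_out = ou.eaf if action == "keep" else (None if ou.eaf is None else 1.0 - ou.eaf)
        rows.append(
            {
                "snp": ex.snp_id, "chrom": ex.chrom, "pos": ex.pos,
                "effect_allele": ex.effect_allele, "other_allele": ex.other_allele,
                "beta_exposure": ex.beta, "se_exposure": ex.se, "pval_exposure": ex.pval,
                "beta_outcome": beta_out, "se_outcome": ou.se, "pval_outcome": ou.pval,
                "eaf": ex.eaf if ex.eaf is not None else eaf_out,
            }
        )
    if not rows:
        raise ValueError("harmonize produced an empty set; nothing to analyse")
    prov = (
        f"harmonized {len(rows)} SNPs ({len(dropped)} dropped: "
        + "; ".join(f"{k}: {v}" for k, v in sorted(dropped.items()))
        + f"); palindromic_policy={palindromic_policy}"
    )
    return HarmonizedSet(exposure_name, outcome_name, pd.DataFrame(rows), provenance=prov)


def _orient(ex: SummaryStatRecord, ou: SummaryStatRecord) -> str | None:
    ea, oa = ou.effect_allele, ou.other_allele
    cea, coa = _COMPLEMENT.get(ea), _COMPLEMENT.get(oa)
    if (ea, oa) == (ex.effect_allele, ex.other_allele):
        return "keep"
    if (oa, ea) == (ex.effect_allele, ex.other_allele):
        return "flip"
    if (cea, coa) == (ex.effect_allele, ex.other_allele):
        return "keep"  # strand flip only
    if (coa, cea) == (ex.effect_allele, ex.other_allele):
        return "flip"  # strand flip and swap
    return None


def _orient_palindromic(ex, ou, lo, hi) -> str | None:
    if ex.eaf is None or ou.eaf is None:
        return None
    if lo <= ex.eaf <= hi or lo <= ou.eaf <= hi:
        return None
    same_side = (ex.eaf < lo) == (ou.eaf < lo)
    return "keep" if same_side else "flip"


# ---------------------------------------------------------------------------
# Instrument strength


def variance_explained(beta: float, se: float, n: int, maf: float) -> float:
    """Fraction of trait variance explained by one SNP (R²).

    Computed from the association z-score as ``R² = z² / (z² + n − 2)`` with
    ``z = beta/se`` — the standard summary-statistic form. ``maf`` is validated
    (the signature keeps the allele-frequency argument so an allele-frequency-
    bearing form can be swapped in) but does not enter this expression.
    """
    if not (0 < maf <= 0.5):
        raise ValueError(f"maf must be in (0, 0.5], got {maf}")
    if se <= 0:
        raise ValueError("se must be > 0")
    if n < 2:
        raise ValueError("n must be >= 2")
    z2 = (beta / se) ** 2
    return z2 / (z2 + n - 2)


def f_statistic(r2: float, n: int, m: int) -> float:
    """Instrument F statistic, ``F = (R²/(1−R²)) · (n − m − 1)/m``.

    ``n`` is the exposure-GWAS sample size and ``m`` the number of instruments
    in the model (1 for per-SNP F). F > 10 is the conventional bar below which
    weak-instrument bias is a concern.
    """
    if not (0 <= r2 < 1):
        raise ValueError("r2 must be in [0, 1)")
    if n <= m + 1 or m < 1:
        raise ValueError("need n > m + 1 >= 2")
    return (r2 / (1.0 - r2)) * (n - m - 1) / m


def strength_stats(
    records: Sequence[SummaryStatRecord], n: int | None = None, m: int = 1
) -> list[StrengthStats]:
    """Per-SNP R² and F for a list of instruments.

    ``n`` falls back to each record's own sample size; records lacking both an
    ``n`` and an ``eaf``-independent default raise.
    """
    out = []
    for r in records:
        n_eff = n if n is not None else r.n
        if n_eff is None:
            raise ValueError(f"{r.snp_id}: sample size unknown; pass n explicitly")
        maf = r.maf if r.maf is not None and r.maf > 0 else 0.5
        r2 = variance_explained(r.beta, r.se, n_eff, maf)
        out.append(StrengthStats(r.snp_id, r2, f_statistic(r2, n_eff, m), n_eff, m))
    return out
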