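"""Tabular/matrix I/O and the shared variant-keying conventions.

Summary statistics are delimited text with a header and a configurable
column map; LD matrices are delimited square tables with variant ids on
both margins.  Coordinates are 1-based inclusive throughout and genome
build is carried as an opaque label, never converted.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantRecord",
    "SummaryStats",
    "LDMatrix",
    "RegionalDataset",
    "TraitVector",
    "ReadReport",
    "PVAL_FLOOR",
    "read_sumstats",
    "write_sumstats",
    "read_ld_matrix",
    "write_ld_matrix",
    "extract_region",
]

#: p-values below this are clamped (and flagged) rather than stored as 0.
PVAL_FLOOR = 1e-300

# canonical column order used by the writer
_CANON_COLS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n", "n_cases", "n_controls",
]

_MANDATORY = ["variant_id", "chrom", "pos", "effect_allele", "other_allele",
              "beta", "se", "pval"]


@dataclass(frozen=True)
class VariantRecord:
    """A single per-variant association record."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: float | None = None
    n_cases: float | None = None
    n_controls: float | None = None

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"{self.variant_id}: se must be > 0, got {self.se}")
        if not (0 < self.pval <= 1):
            raise ValueError(f"{self.variant_id}: pval must be in (0, 1], got {self.pval}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect and other allele identical")
        if self.pos < 1:
            raise ValueError(f"{self.variant_id}: pos must be >= 1")


@dataclass
class ReadReport:
    """Row accounting for a read_sumstats call."""

    n_read: int = 0
    n_kept: int = 0
    drops: int = 0
    drop_reasons: dict[str, int] = field(default_factory=dict)
    pval_clamped: int = 0


@dataclass
class SummaryStats:
    """One trait's GWAS summary statistics, unique by variant_id.

    ``table`` holds the canonical columns (see ``_CANON_COLS``); missing
    optional columns are present as NaN.
    """

    trait_label: str
    table: pd.DataFrame
    trait_type: str = "quantitative"  # or "case-control"
    genome_build: str = "unspecified"

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "case-control"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.table["variant_id"].duplicated().any():
            dups = self.table.loc[self.table["variant_id"].duplicated(), "variant_id"]
            raise ValueError(f"duplicate variant_id(s): {sorted(set(dups))[:5]}")
        if self.trait_type == "case-control":
            if self.table["n_cases"].isna().all() or self.table["n_controls"].isna().all():
                raise ValueError("case-control trait requires n_cases and n_controls")
        self.table = self.table.reset_index(drop=True)

    @property
    def variant_ids(self) -> list[str]:
        return self.table["variant_id"].tolist()

    def lookup(self, variant_ids: Sequence[str]) -> pd.DataFrame:
        sub = self.table.set_index("variant_id").reindex(variant_ids)
        return sub

    def records(self):
        for row in self.table.itertuples(index=False):
            yield VariantRecord(
                variant_id=row.variant_id, chrom=row.chrom, pos=int(row.pos),
                effect_allele=row.effect_allele, other_allele=row.other_allele,
                beta=row.beta, se=row.se, pval=row.pval,
                eaf=None if pd.isna(row.eaf) else row.eaf,
                n=None if pd.isna(row.n) else row.n,
                n_cases=None if pd.isna(row.n_cases) else row.n_cases,
                n_controls=None if pd.isna(row.n_controls) else row.n_controls,
            )

    @classmethod
    def from_records(cls, trait_label: str, records: Sequence[VariantRecord],
                     trait_type: str = "quantitative",
                     genome_build: str = "unspecified") -> "SummaryStats":
        rows = [dataclasses.asdict(r) for r in records]
        tab = pd.DataFrame(rows, columns=_CANON_COLS)
        return cls(trait_label, tab, trait_type=trait_type, genome_build=genome_build)


@dataclass
class LDMatrix:
    """Pairwise variant correlations (signed r; r-squared is derived)."""

    variant_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.variant_ids)
        if self.r.shape != (n, n):
            raise ValueError(f"LD matrix shape {self.r.shape} != ({n}, {n})")
        if np.abs(self.r - self.r.T).max(initial=0.0) > 1e-8:
            raise ValueError("LD matrix not symmetric within 1e-8")
        if np.abs(np.diagonal(self.r) - 1.0).max(initial=0.0) > 1e-8:
            raise ValueError("LD matrix diagonal not 1 within 1e-8")
        if np.abs(self.r).max(initial=0.0) > 1 + 1e-8:
            raise ValueError("LD entries must lie in [-1, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __len__(self) -> int:
        return len(self.variant_ids)

    def index_of(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} not in LD matrix") from None

    def r_between(self, a: str, b: str) -> float:
        return float(self.r[self.index_of(a), self.index_of(b)])

    def r2_between(self, a: str, b: str) -> float:
        return self.r_between(a, b) ** 2

    def subset(self, variant_ids: Sequence[str]) -> "LDMatrix":
        idx = [self.index_of(v) for v in variant_ids]
        return LDMatrix(list(variant_ids), self.r[np.ix_(idx, idx)])


@dataclass
class TraitVector:
    """One trait's aligned vectors inside a RegionalDataset."""

    beta: np.ndarray
    se: np.ndarray
    trait_type: str = "quantitative"
    scale: float = 1.0  # sdY for quantitative, case fraction for case-control

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if self.beta.shape != self.se.shape:
            raise ValueError("beta/se length mismatch")
        if np.any(self.se <= 0):
            raise ValueError("all se must be > 0")

    @property
    def z(self) -> np.ndarray:
        return self.beta / self.se


@dataclass
class RegionalDataset:
    """A genomic window's multi-trait vectors tied to one LD matrix."""

    window: tuple[str, int, int]  # (chrom, start, end), 1-based inclusive
    ld: LDMatrix
    traits: dict[str, TraitVector]
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.ld)
        for label, tv in self.traits.items():
            if len(tv.beta) != n:
                raise ValueError(f"trait {label!r} length {len(tv.beta)} != LD dim {n}")
        if self.positions is not None:
            self.positions = np.asarray(self.positions)

    @property
    def variant_ids(self) -> list[str]:
        return self.ld.variant_ids

    @property
    def n_snps(self) -> int:
        return len(self.ld)

    def subset(self, variant_ids: Sequence[str]) -> "RegionalDataset":
        keep = [self.ld.index_of(v) for v in variant_ids]
        traits = {
            lab: TraitVector(tv.beta[keep], tv.se[keep], tv.trait_type, tv.scale)
            for lab, tv in self.traits.items()
        }
        pos = self.positions[keep] if self.positions is not None else None
        return RegionalDataset(self.window, self.ld.subset(variant_ids), traits, pos)


def _sniff_sep(path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_sumstats(path, column_map: Mapping[str, str], trait_label: str = "trait",
                  trait_type: str = "quantitative",
                  genome_build: str = "unspecified") -> tuple[SummaryStats, ReadReport]:
    """Read a delimited summary-statistics table.

    ``column_map`` maps semantic names (``variant_id``, ``chrom``, ``pos``,
    ``effect_allele``, ``other_allele``, ``beta``, ``se``, ``pval`` and the
    optional ``eaf``/``n``/``n_cases``/``n_controls``) to file columns.
    Rows violating the record invariants are dropped and counted in the
    returned :class:`ReadReport`; p-values below :data:`PVAL_FLOOR` are
    clamped to it and flagged.
    """
    sep = _sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, dtype={column_map.get("chrom", "chrom"): str},
                      float_precision="round_trip")

    for sem in _MANDATORY:
        col = column_map.get(sem)
        if col is None:
            raise ValueError(f"column_map missing mandatory semantic column {sem!r}")
        if col not in raw.columns:
            raise ValueError(f"file lacks mandatory column {col!r} (mapped from {sem!r})")

    tab = pd.DataFrame(index=raw.index)
    for sem in _CANON_COLS:
        col = column_map.get(sem)
        tab[sem] = raw[col] if col is not None and col in raw.columns else np.nan

    report = ReadReport(n_read=len(tab))
    tab["variant_id"] = tab["variant_id"].astype(str)
    tab["chrom"] = tab["chrom"].astype(str)
    tab["effect_allele"] = tab["effect_allele"].astype(str).str.upper()
    tab["other_allele"] = tab["other_allele"].astype(str).str.upper()
    for num in ("pos", "eaf", "beta", "se", "pval", "n", "n_cases", "n_controls"):
        tab[num] = pd.to_numeric(tab[num], errors="coerce")

    clamped = (tab["pval"] < PVAL_FLOOR) & tab["pval"].notna() & (tab["pval"] >= 0)
    report.pval_clamped = int(clamped.sum())
    tab.loc[clamped, "pval"] = PVAL_FLOOR

    checks = {
        "missing_core": tab[["variant_id", "chrom", "pos", "beta", "se", "pval"]].isna().any(axis=1),
        "bad_se": ~(tab["se"] > 0),
        "bad_pval": ~((tab["pval"] > 0) & (tab["pval"] <= 1)),
        "same_alleles": tab["effect_allele"] == tab["other_allele"],
        "bad_pos": ~(tab["pos"] >= 1),
        "bad_eaf": tab["eaf"].notna() & ~((tab["eaf"] > 0) & (tab["eaf"] < 1)),
        "duplicate_id": tab["variant_id"].duplicated(keep="first"),
    }
    bad = pd.Series(False, index=tab.index)
    for reason, mask in checks.items():
        newly = mask & ~bad
        if newly.any():
            report.drop_reasons[reason] = int(newly.sum())
        bad |= mask

    kept = tab[~bad].copy()
    kept["pos"] = kept["pos"].astype(int)
    report.drops = int(bad.sum())
    report.n_kept = len(kept)
    if report.n_kept == 0:
        raise ValueError(f"no valid rows in {path}")

    ss = SummaryStats(trait_label, kept, trait_type=trait_type, genome_build=genome_build)
    return ss, report


def write_sumstats(ss: SummaryStats, path, sep: str = "\t") -> None:
    """Write in the canonical dialect; ``read_sumstats`` round-trips it."""
    out = ss.table[_CANON_COLS].copy()
    out.to_csv(path, sep=sep, index=False, float_format="%.17g")


#: identity column map for files written by write_sumstats
CANONICAL_COLUMN_MAP = {c: c for c in _CANON_COLS}


def read_ld_matrix(path) -> LDMatrix:
    """Read a delimited square LD matrix with variant-id margins.

    Asymmetry up to 1e-6 is repaired by averaging; larger asymmetry, a
    non-square table, an off-unit diagonal or \\|r\\| > 1 + 1e-6 are errors.
    """
    sep = _sniff_sep(path)
    tab = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    ids = [str(c) for c in tab.columns]
    if list(map(str, tab.index)) != ids or tab.shape[0] != tab.shape[1]:
        raise ValueError("LD matrix must be square with matching row/column variant ids")
    r = tab.to_numpy(dtype=float)
    asym = np.abs(r - r.T).max(initial=0.0)
    if asym > 1e-6:
        raise ValueError(f"LD matrix asymmetry {asym:.3g} exceeds 1e-6")
    r = (r + r.T) / 2.0
    if np.abs(r).max(initial=0.0) > 1 + 1e-6:
        raise ValueError("LD matrix has |r| > 1 + 1e-6")
    d = np.diagonal(r)
    if np.abs(d - 1.0).max(initial=0.0) > 1e-6:
        raise ValueError("LD matrix diagonal departs from 1 by more than 1e-6")
    np.fill_diagonal(r, 1.0)
    np.clip(r, -1.0, 1.0, out=r)
    return LDMatrix(ids, r)


def write_ld_matrix(ld: LDMatrix, path, sep: str = "\t") -> None:
    pd.DataFrame(ld.r, index=ld.variant_ids, columns=ld.variant_ids).to_csv(
        path, sep=sep, float_format="%.17g")


def _harmonise_to_reference(ref: pd.Series, other: pd.DataFrame) -> pd.DataFrame:
    """Align ``other`` rows to the reference effect/other alleles.

    Rows whose alleles are swapped get their beta sign (and eaf) flipped;
    rows with incompatible alleles are marked unusable (beta NaN).
    """
    other = other.copy()
    same = (other["effect_allele"] == ref["effect_allele"]) & \
           (other["other_allele"] == ref["other_allele"])
    flipped = (other["effect_allele"] == ref["other_allele"]) & \
              (other["other_allele"] == ref["effect_allele"])
    other.loc[flipped, "beta"] = -other.loc[flipped, "beta"]
    other.loc[flipped, "eaf"] = 1.0 - other.loc[flipped, "eaf"]
    ea, oa = other["effect_allele"].copy(), other["other_allele"].copy()
    other.loc[flipped, "effect_allele"] = oa[flipped]
    other.loc[flipped, "other_allele"] = ea[flipped]
    other.loc[~(same | flipped), "beta"] = np.nan
    return other


def extract_region(ss_list: Sequence[SummaryStats], ld: LDMatrix, center: str,
                   window_kb: float = 150.0) -> RegionalDataset:
    """Cut a multi-trait regional dataset around ``center``.

    Keeps variants within +/- ``window_kb``/2 of the center's position that
    are present in every trait and in the LD matrix; alleles are harmonised
    to the first trait's effect allele.  The default 150 kb total window is
    read as +/-75 kb around the lead variant.
    """
    if not ss_list:
        raise ValueError("need at least one SummaryStats")
    first = ss_list[0]
    if center not in set(first.variant_ids):
        raise ValueError(f"center variant {center!r} absent from trait {first.trait_label!r}")
    if center not in ld._index:
        raise ValueError(f"center variant {center!r} absent from LD matrix")
    for ss in ss_list[1:]:
        if center not in set(ss.variant_ids):
            raise ValueError(f"center variant {center!r} absent from trait {ss.trait_label!r}")

    ref_tab = first.table.set_index("variant_id")
    c_pos = int(ref_tab.loc[center, "pos"])
    c_chrom = str(ref_tab.loc[center, "chrom"])
    half = window_kb * 1000.0 / 2.0
    lo, hi = c_pos - half + 1, c_pos + half  # total span == window_kb * 1000

    in_window = ref_tab[(ref_tab["chrom"] == c_chrom)
                        & (ref_tab["pos"] >= lo) & (ref_tab["pos"] <= hi)]
    keep = [v for v in in_window.index if v in ld._index]
    for ss in ss_list[1:]:
        have = set(ss.variant_ids)
        keep = [v for v in keep if v in have]
    # deterministic order: by position, then id
    keep.sort(key=lambda v: (int(ref_tab.loc[v, "pos"]), v))

    traits: dict[str, TraitVector] = {}
    ref_rows = ref_tab.loc[keep]
    usable = pd.Series(True, index=pd.Index(keep))
    aligned: dict[str, pd.DataFrame] = {}
    for ss in ss_list:
        rows = ss.table.set_index("variant_id").reindex(keep)
        if ss is not first:
            rows = pd.concat(
                [_harmonise_to_reference(ref_rows.loc[v], rows.loc[[v]]) for v in keep])
        usable &= rows["beta"].notna() & rows["se"].notna() & (rows["se"] > 0)
        aligned[ss.trait_label] = rows
    keep = [v for v in keep if usable.loc[v]]
    if len(keep) < 2:
        raise ValueError(f"fewer than 2 variants survive around {center!r}")

    for ss in ss_list:
        rows = aligned[ss.trait_label].loc[keep]
        scale = 1.0
        if ss.trait_type == "case-control":
            nc = rows["n_cases"].to_numpy(float)
            nt = rows["n_controls"].to_numpy(float)
            with np.errstate(invalid="ignore"):
                frac = np.nanmean(nc / (nc + nt))
            scale = float(frac) if np.isfinite(frac) else 0.5
        traits[ss.trait_label] = TraitVector(
            rows["beta"].to_numpy(float), rows["se"].to_numpy(float),
            trait_type=ss.trait_type, scale=scale)

    positions = ref_tab.loc[keep, "pos"].to_numpy(int)
    window = (c_chrom, int(positions.min()), int(positions.max()))
    return RegionalDataset(window, ld.subset(keep), traits, positions)
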