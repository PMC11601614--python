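"""Reading, validating and filtering per-SNP signal-intensity data.

The expected input is a long-format delimited table with one row per
(SNP, sample) pair carrying the normalized Illumina signal metrics:
Log R Ratio (LRR, a log2 intensity ratio centred at 0 for two copies)
and B Allele Frequency (BAF, in [0, 1], clustering near 0/0.5/1 in
diploid samples).  An optional GenTrain score column carries Illumina's
per-SNP genotype-clustering quality in [0, 1].

Coordinates are 1-based basepair positions; all interval membership in
this package uses half-open ``[start, end)`` logic.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_COLUMNS",
    "LoadReport",
    "SignalPanel",
    "VariantWhitelist",
    "read_signal_table",
    "apply_gentrain_filter",
    "read_variant_whitelist",
    "subset_panel",
]

#: default header names mapped onto the canonical internal field names
DEFAULT_COLUMNS: dict[str, str] = {
    "snp_id": "snpID",
    "chromosome": "chromosome",
    "position": "position",
    "sample_id": "sampleID",
    "baf": "BAF",
    "lrr": "LRR",
    "gentrain": "GenTrain_Score",
}

REQUIRED_FIELDS = ("snp_id", "chromosome", "position", "sample_id", "baf", "lrr")

INTERNAL_ORDER = ["snp_id", "chromosome", "position", "sample_id", "baf", "lrr", "gentrain"]


@dataclasses.dataclass(frozen=True)
class LoadReport:
    """Row accounting for one table load: ``parsed + dropped == raw_rows``."""

    raw_rows: int
    parsed_rows: int
    dropped_rows: int
    drop_reasons: dict[str, int] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.parsed_rows + self.dropped_rows != self.raw_rows:
            raise ValueError("load report does not balance: parsed + dropped != raw")


class SignalPanel:
    """Per-SNP, per-sample signal records for one chromosome/region.

    Thin wrapper over a :class:`pandas.DataFrame` with canonical columns
    ``snp_id, chromosome, position, sample_id, baf, lrr, gentrain``.
    Records are unique per (snp_id, sample_id); the SNP index is sorted
    by (chromosome, position).
    """

    def __init__(self, records: pd.DataFrame, load_report: LoadReport | None = None):
        missing = [c for c in INTERNAL_ORDER if c not in records.columns]
        if missing:
            raise ValueError(f"panel records missing columns: {missing}")
        df = records.loc[:, INTERNAL_ORDER].copy()
        df = df.sort_values(["chromosome", "position", "snp_id", "sample_id"], kind="mergesort")
        df = df.reset_index(drop=True)
        if df.duplicated(subset=["snp_id", "sample_id"]).any():
            raise ValueError("duplicate (snp_id, sample_id) records in panel")
        self.records = df
        self.load_report = load_report

    @property
    def samples(self) -> list[str]:
        return sorted(self.records["sample_id"].unique().tolist())

    @property
    def snps(self) -> pd.DataFrame:
        """Unique (snp_id, chromosome, position) sorted by (chromosome, position)."""
        snps = self.records[["snp_id", "chromosome", "position"]].drop_duplicates()
        return snps.sort_values(["chromosome", "position", "snp_id"]).reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.records["sample_id"].nunique()

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalPanel):
            return NotImplemented
        return self.records.equals(other.records)

    def to_table(self, path: str | Path, columns: Mapping[str, str] | None = None,
                 sep: str = "\t") -> None:
        """Write the panel back out in the external signal-table schema."""
        colmap = dict(DEFAULT_COLUMNS if columns is None else columns)
        out = self.records.rename(columns={k: v for k, v in colmap.items()})
        out.to_csv(path, sep=sep, index=False)


def _sniff_separator(path: Path) -> str:
    with open(path, "r") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_signal_table(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> SignalPanel:
    """Read a long-format signal table into a :class:`SignalPanel`.

    Parameters
    ----------
    path
        Delimited text file (tab or comma; auto-detected unless ``sep``
        is given) with one row per (SNP, sample).
    columns
        Mapping from canonical field names (``snp_id``, ``chromosome``,
        ``position``, ``sample_id``, ``baf``, ``lrr``, ``gentrain``) to
        the header names in the file.  Defaults to
        :data:`DEFAULT_COLUMNS`.
    sep
        Field separator; auto-detected from the header line when None.

    Rows whose position, BAF or LRR is present but unparseable, whose
    BAF lies outside [0, 1], or whose position is < 1, are dropped and
    counted in the panel's :class:`LoadReport`.  Genuinely missing BAF,
    LRR or GenTrain values are kept as NaN.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    colmap = dict(DEFAULT_COLUMNS if columns is None else columns)
    if sep is None:
        sep = _sniff_separator(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=True)
    if raw.empty:
        raise ValueError(f"empty signal table: {path}")

    for field in REQUIRED_FIELDS:
        if colmap.get(field) not in raw.columns:
            raise ValueError(f"missing column: {field} (expected header {colmap.get(field)!r})")

    df = pd.DataFrame(index=raw.index)
    df["snp_id"] = raw[colmap["snp_id"]].astype(str)
    df["chromosome"] = raw[colmap["chromosome"]].astype(str).str.strip()
    df["sample_id"] = raw[colmap["sample_id"]].astype(str)

    reasons: dict[str, int] = {}
    bad = pd.Series(False, index=raw.index)

    def _numeric(field: str) -> pd.Series:
        src = raw[colmap[field]] if colmap.get(field) in raw.columns else pd.Series(np.nan, index=raw.index)
        vals = pd.to_numeric(src, errors="coerce")
        unparseable = src.notna() & vals.isna()
        if unparseable.any():
            reasons[f"unparseable_{field}"] = reasons.get(f"unparseable_{field}", 0) + int(unparseable.sum())
        return vals.where(~unparseable, np.nan), unparseable

    pos, bad_pos = _numeric("position")
    bad_pos |= pos.isna() | (pos < 1) | (pos != pos.round())
    n_bad_pos = int((bad_pos & ~bad).sum())
    if n_bad_pos:
        reasons["invalid_position"] = n_bad_pos
    bad |= bad_pos

    baf, bad_baf = _numeric("baf")
    out_of_range = baf.notna() & ((baf < 0) | (baf > 1))
    if out_of_range.any():
        reasons["baf_out_of_range"] = int(out_of_range.sum())
    bad |= bad_baf | out_of_range

    lrr, bad_lrr = _numeric("lrr")
    bad |= bad_lrr

    if colmap.get("gentrain") in raw.columns:
        gtc, bad_gtc = _numeric("gentrain")
        bad |= bad_gtc
    else:
        gtc = pd.Series(np.nan, index=raw.index)

    df["position"] = pos
    df["baf"] = baf
    df["lrr"] = lrr
    df["gentrain"] = gtc

    kept = df.loc[~bad].copy()
    dup = kept.duplicated(subset=["snp_id", "sample_id"], keep="first")
    if dup.any():
        reasons["duplicate_record"] = int(dup.sum())
        kept = kept.loc[~dup]
    kept["position"] = kept["position"].astype(np.int64)

    if kept.empty:
        raise ValueError(f"no parseable rows in signal table: {path}")
    report = LoadReport(
        raw_rows=len(raw),
        parsed_rows=len(kept),
        dropped_rows=len(raw) - len(kept),
        drop_reasons=reasons,
    )
    return SignalPanel(kept, load_report=report)


def apply_gentrain_filter(panel: SignalPanel, cutoff: float = 0.2) -> SignalPanel:
    """Drop SNPs whose GenTrain clustering-quality score is below ``cutoff``.

    The cutoff is the minimum acceptable score: SNPs with
    ``gentrain >= cutoff`` are retained, and SNPs with no score are
    retained (an unavailable score is not evidence of low quality).
    Removal applies per SNP across all samples: a SNP scoring below the
    cutoff in any record is removed everywhere.  Idempotent.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"GenTrain cutoff must be in [0, 1], got {cutoff}")
    rec = panel.records
    low = rec.loc[rec["gentrain"].notna() & (rec["gentrain"] < cutoff), "snp_id"].unique()
    kept = rec.loc[~rec["snp_id"].isin(set(low))]
    if kept.empty:
        raise ValueError("GenTrain filter removed every SNP")
    return SignalPanel(kept, load_report=panel.load_report)


@dataclasses.dataclass(frozen=True)
class VariantWhitelist:
    """Set of variant keys (both SNP ids and ``chrom:pos`` strings)."""

    keys: frozenset[str]

    def __post_init__(self) -> None:
        if not self.keys:
            raise ValueError("empty variant whitelist")

    def __contains__(self, key: str) -> bool:
        return key in self.keys

    def __len__(self) -> int:
        return len(self.keys)


def _norm_chrom(chrom: str) -> str:
    c = chrom.strip()
    return c[3:] if c.lower().startswith("chr") else c


def read_variant_whitelist(path: str | Path, format: str) -> VariantWhitelist:
    """Read a PLINK ``.bim`` (6 whitespace-separated columns, no header)
    or ``.pvar`` (``#CHROM`` header line) file into a whitelist.

    Each variant contributes two keys: its id and ``chromosome:position``
    (chromosome normalised without a ``chr`` prefix).
    """
    path = Path(path)
    if format not in ("bim", "pvar"):
        raise ValueError(f"whitelist format must be 'bim' or 'pvar', got {format!r}")
    keys: set[str] = set()
    if format == "bim":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                parts = line.split()
                if len(parts) != 6:
                    raise ValueError(
                        f"{path}:{lineno}: bim line has {len(parts)} columns, expected 6"
                    )
                chrom, vid, _cm, pos, _a1, _a2 = parts
                if not pos.lstrip("-").isdigit():
                    raise ValueError(f"{path}:{lineno}: non-integer position {pos!r}")
                keys.add(vid)
                keys.add(f"{_norm_chrom(chrom)}:{int(pos)}")
    else:
        header: list[str] | None = None
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.startswith("##") or not line.strip():
                    continue
                if line.startswith("#CHROM"):
                    header = line.lstrip("#").split()
                    continue
                if header is None:
                    raise ValueError(f"{path}:{lineno}: data before #CHROM header")
                parts = line.split()
                if len(parts) < len(header):
                    raise ValueError(
                        f"{path}:{lineno}: pvar line has {len(parts)} columns, "
                        f"expected >= {len(header)}"
                    )
                row = dict(zip(header, parts))
                if not row["POS"].lstrip("-").isdigit():
                    raise ValueError(f"{path}:{lineno}: non-integer position {row['POS']!r}")
                keys.add(row["ID"])
                keys.add(f"{_norm_chrom(row['CHROM'])}:{int(row['POS'])}")
        if header is None:
            raise ValueError(f"{path}: no #CHROM header line found")
    return VariantWhitelist(frozenset(keys))


def subset_panel(panel: SignalPanel, region, whitelist: VariantWhitelist | None = None) -> SignalPanel:
    """Restrict a panel to a buffered region and (optionally) a whitelist.

    SNPs are kept when their chromosome matches the region's and their
    position falls in the half-open buffered interval
    ``[buffered_start, buffered_stop)``.  When a whitelist is given, a
    SNP must additionally match by id or by ``chromosome:position``.
    The sample set is unchanged.
    """
    rec = panel.records
    chrom_mask = rec["chromosome"].map(_norm_chrom) == _norm_chrom(region.chromosome)
    pos = rec["position"]
    mask = chrom_mask & (pos >= region.buffered_start) & (pos < region.buffered_stop)
    if whitelist is not None:
        keyed = rec["snp_id"].isin(whitelist.keys) | (
            rec["chromosome"].map(_norm_chrom) + ":" + pos.astype(str)
        ).isin(whitelist.keys)
        mask &= keyed
    kept = rec.loc[mask]
    if kept.empty:
        raise ValueError(
            f"no SNPs remain after subsetting to {region.chromosome}:"
            f"{region.buffered_start}-{region.buffered_stop}; check that the "
            "region and the array manifest refer to the same assembly"
        )
    return SignalPanel(kept, load_report=panel.load_report)
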