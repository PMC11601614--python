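"""CNV-candidate flagging and per-window feature aggregation.

SNPs are flagged as CNV candidates by the array manufacturer's
intensity ranges — strict inequalities at the LRR thresholds and open
BAF insertion bands:

* deletions:     LRR < −0.2
* duplications:  LRR > 0.2
* insertion pattern: BAF in (0.15, 0.35) or (0.65, 0.85)

A separate, inclusive mid-range BAF band [0.15, 0.85] feeds features
that track the "branching" of heterozygous BAF clusters under dosage
change.  Per-window statistics over these subsets (and over all window
SNPs) are stacked into a dense samples x windows x features array, the
model-ready input.  Missing BAF/LRR never makes a SNP a candidate, and
statistics over empty subsets impute 0 — a zero candidate count is
itself signal.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .regions import WindowScheme
from .signals import SignalPanel

__all__ = [
    "CandidateRule",
    "DELETION_RULE",
    "DUPLICATION_RULE",
    "FeatureCatalog",
    "DELETION_CATALOG",
    "DUPLICATION_CATALOG",
    "ScalingStats",
    "FeatureArray",
    "flag_candidates",
    "flag_insertion_band",
    "flag_midrange_baf",
    "aggregate_window",
    "build_feature_array",
    "catalog_for",
    "rule_for",
]

MIDRANGE_LO, MIDRANGE_HI = 0.15, 0.85
INSERTION_BANDS = ((0.15, 0.35), (0.65, 0.85))


@dataclasses.dataclass(frozen=True)
class CandidateRule:
    """Manufacturer-recommended intensity ranges flagging CNV candidates."""

    cnv_type: str  # "deletion" | "duplication"
    lrr_threshold: float

    def __post_init__(self) -> None:
        if self.cnv_type not in ("deletion", "duplication"):
            raise ValueError(f"cnv_type must be deletion/duplication, got {self.cnv_type!r}")


DELETION_RULE = CandidateRule("deletion", -0.2)
DUPLICATION_RULE = CandidateRule("duplication", 0.2)


def rule_for(cnv_type: str) -> CandidateRule:
    return DELETION_RULE if cnv_type == "deletion" else DUPLICATION_RULE


def flag_candidates(lrr: np.ndarray, rule: CandidateRule) -> np.ndarray:
    """Candidate mask by strict LRR threshold; missing LRR is never a candidate."""
    lrr = np.asarray(lrr, dtype=float)
    with np.errstate(invalid="ignore"):
        if rule.cnv_type == "deletion":
            mask = lrr < rule.lrr_threshold
        else:
            mask = lrr > rule.lrr_threshold
    return mask & ~np.isnan(lrr)


def flag_insertion_band(baf: np.ndarray) -> np.ndarray:
    """Open-interval insertion-pattern bands (0.15, 0.35) ∪ (0.65, 0.85)."""
    baf = np.asarray(baf, dtype=float)
    with np.errstate(invalid="ignore"):
        mask = np.zeros(baf.shape, dtype=bool)
        for lo, hi in INSERTION_BANDS:
            mask |= (baf > lo) & (baf < hi)
    return mask & ~np.isnan(baf)


def flag_midrange_baf(baf: np.ndarray) -> np.ndarray:
    """Inclusive mid-range BAF band [0.15, 0.85]; missing BAF excluded."""
    baf = np.asarray(baf, dtype=float)
    with np.errstate(invalid="ignore"):
        mask = (baf >= MIDRANGE_LO) & (baf <= MIDRANGE_HI)
    return mask & ~np.isnan(baf)


# ---------------------------------------------------------------------------
# feature catalogs

@dataclasses.dataclass(frozen=True)
class FeatureCatalog:
    """Ordered list of named per-window statistics for one CNV type."""

    cnv_type: str
    feature_names: tuple[str, ...]

    @property
    def n_features(self) -> int:
        return len(self.feature_names)


DELETION_CATALOG = FeatureCatalog(
    "deletion",
    (
        "cand_count", "cand_frac", "cand_lrr_avg", "cand_lrr_sd", "cand_lrr_iqr",
        "cand_baf_avg", "cand_baf_sd",
        "mid_count", "mid_baf_avg",
        "all_count", "all_lrr_avg", "all_lrr_sd", "all_baf_avg",
    ),
)

DUPLICATION_CATALOG = FeatureCatalog(
    "duplication",
    (
        "cand_count", "cand_frac", "cand_lrr_avg", "cand_lrr_sd", "cand_lrr_iqr",
        "ins_count", "ins_frac",
        "mid_count", "mid_baf_avg",
        "all_count", "all_lrr_avg",
    ),
)


def catalog_for(cnv_type: str) -> FeatureCatalog:
    return DELETION_CATALOG if cnv_type == "deletion" else DUPLICATION_CATALOG


def _mean(x: np.ndarray) -> float:
    return float(np.mean(x)) if x.size else 0.0


def _sd(x: np.ndarray) -> float:
    # population (n-denominator) form; 0 for empty or single-value subsets
    return float(np.std(x)) if x.size else 0.0


def _iqr(x: np.ndarray) -> float:
    if x.size == 0:
        return 0.0
    q1, q3 = np.percentile(x, [25, 75])  # linear interpolation
    return float(q3 - q1)


def aggregate_window(
    baf: np.ndarray, lrr: np.ndarray, catalog: FeatureCatalog, rule: CandidateRule
) -> np.ndarray:
    """Compute the catalog's statistics for one window of one sample.

    ``baf``/``lrr`` are the window's per-SNP values (NaN = missing).
    Counts count SNP records; value statistics additionally require the
    relevant field to be present.  Empty subsets impute 0.
    """
    baf = np.asarray(baf, dtype=float)
    lrr = np.asarray(lrr, dtype=float)
    n_all = baf.size
    cand = flag_candidates(lrr, rule)
    mid = flag_midrange_baf(baf)
    ins = flag_insertion_band(baf)
    cand_lrr = lrr[cand]
    cand_baf = baf[cand & ~np.isnan(baf)]
    mid_baf = baf[mid]
    all_lrr = lrr[~np.isnan(lrr)]
    all_baf = baf[~np.isnan(baf)]

    values = {
        "cand_count": float(cand.sum()),
        "cand_frac": float(cand.sum()) / n_all if n_all else 0.0,
        "cand_lrr_avg": _mean(cand_lrr),
        "cand_lrr_sd": _sd(cand_lrr),
        "cand_lrr_iqr": _iqr(cand_lrr),
        "cand_baf_avg": _mean(cand_baf),
        "cand_baf_sd": _sd(cand_baf),
        "ins_count": float(ins.sum()),
        "ins_frac": float(ins.sum()) / n_all if n_all else 0.0,
        "mid_count": float(mid.sum()),
        "mid_baf_avg": _mean(mid_baf),
        "all_count": float(n_all),
        "all_lrr_avg": _mean(all_lrr),
        "all_lrr_sd": _sd(all_lrr),
        "all_baf_avg": _mean(all_baf),
    }
    return np.array([values[name] for name in catalog.feature_names], dtype=float)


# ---------------------------------------------------------------------------
# model-ready arrays

@dataclasses.dataclass(frozen=True)
class ScalingStats:
    """Per-feature z-score center/scale learned on a training array."""

    center: np.ndarray  # shape (F,)
    scale: np.ndarray   # shape (F,), zeros replaced by 1

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScalingStats):
            return NotImplemented
        return np.array_equal(self.center, other.center) and np.array_equal(
            self.scale, other.scale
        )


@dataclasses.dataclass
class FeatureArray:
    """Model-ready block of shape (samples, windows, features)."""

    values: np.ndarray
    sample_ids: list[str]
    feature_names: tuple[str, ...]
    cnv_type: str
    scheme: WindowScheme
    scaling: ScalingStats | None = None  # set iff values are scaled

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def to_long_table(self, path: str | Path) -> None:
        """Serialize as a flat delimited (sampleID, window, feature, value) table."""
        n, w, f = self.values.shape
        rows = {
            "sampleID": np.repeat(self.sample_ids, w * f),
            "window_index": np.tile(np.repeat(np.arange(w), f), n),
            "feature_name": np.tile(list(self.feature_names), n * w),
            "value": self.values.reshape(-1),
        }
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _fit_scaling(values: np.ndarray) -> ScalingStats:
    flat = values.reshape(-1, values.shape[-1])
    center = flat.mean(axis=0)
    scale = flat.std(axis=0)
    scale = np.where(scale == 0.0, 1.0, scale)
    return ScalingStats(center=center, scale=scale)


def build_feature_array(
    panel: SignalPanel,
    scheme: WindowScheme,
    cnv_type: str,
    catalog: FeatureCatalog | None = None,
    rule: CandidateRule | None = None,
    scaling: ScalingStats | None = None,
    scale: bool = True,
) -> FeatureArray:
    """Aggregate a panel into a model-ready (N, windows, features) array.

    In training mode (``scaling=None``) the per-feature z-score statistics
    are computed from this array and stored on the result; in inference
    mode the supplied training statistics are applied unchanged.  Pass
    ``scale=False`` to get raw, unscaled features.
    """
    catalog = catalog_for(cnv_type) if catalog is None else catalog
    rule = rule_for(cnv_type) if rule is None else rule
    if catalog.cnv_type != rule.cnv_type:
        raise ValueError(
            f"catalog cnv_type {catalog.cnv_type!r} does not match rule {rule.cnv_type!r}"
        )
    samples = panel.samples
    snps = panel.snps
    positions = snps["position"].to_numpy()

    # align records on a common (snp x sample) grid; absent records are NaN
    key = snps["snp_id"].astype(str) + "\x00" + snps["position"].astype(str)
    order = pd.Series(np.arange(len(snps)), index=key)
    rec = panel.records
    row_idx = order[
        rec["snp_id"].astype(str) + "\x00" + rec["position"].astype(str)
    ].to_numpy()
    col_idx = pd.Series(np.arange(len(samples)), index=samples)[rec["sample_id"]].to_numpy()
    baf_grid = np.full((len(snps), len(samples)), np.nan)
    lrr_grid = np.full((len(snps), len(samples)), np.nan)
    present_grid = np.zeros((len(snps), len(samples)), dtype=bool)
    baf_grid[row_idx, col_idx] = rec["baf"].to_numpy()
    lrr_grid[row_idx, col_idx] = rec["lrr"].to_numpy()
    present_grid[row_idx, col_idx] = True

    window_members = [
        np.flatnonzero((positions >= s) & (positions < e)) for s, e in scheme.windows
    ]
    n, w, f = len(samples), scheme.total_windows, catalog.n_features
    values = np.zeros((n, w, f), dtype=float)
    for wi, members in enumerate(window_members):
        b = baf_grid[members]
        l = lrr_grid[members]
        p = present_grid[members]
        for si in range(n):
            # skip grid slots with no record at all for this sample
            present = p[:, si]
            values[si, wi] = aggregate_window(b[present, si], l[present, si], catalog, rule)

    arr = FeatureArray(
        values=values,
        sample_ids=list(samples),
        feature_names=catalog.feature_names,
        cnv_type=cnv_type,
        scheme=scheme,
    )
    if not scale:
        return arr
    stats = _fit_scaling(values) if scaling is None else scaling
    arr.values = (values - stats.center) / stats.scale
    arr.scaling = stats
    return arr
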