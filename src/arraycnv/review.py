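"""Review-file export, annotation ingestion and training-set accretion.

After scoring a cohort, each sample gets one prediction record (score,
variant count, LRR range in the region) written to a delimited review
file a viewer can filter on, plus a per-SNP plot file for LRR/BAF-vs-
position rendering.  A human reviewer marks samples Yes / Maybe / No;
those logs feed back as labels (Yes → 1, No → 0, Maybe → excluded so an
ambiguous sample is never mislabeled negative), growing the training
set round by round.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .signals import SignalPanel

__all__ = [
    "REVIEW_COLUMNS",
    "TrainingSet",
    "export_app_table",
    "ingest_annotation_log",
    "update_training_set",
]

REVIEW_COLUMNS = [
    "sampleID", "region", "cnv_type", "prediction",
    "n_variants", "lrr_min", "lrr_max", "lrr_mean", "flagged",
]
PLOT_COLUMNS = ["sampleID", "position", "BAF", "LRR"]
DECISIONS = ("Yes", "Maybe", "No")
ANNOTATION_COLUMNS = ["sampleID", "region", "cnv_type", "decision", "timestamp"]


def export_app_table(
    panel: SignalPanel,
    predictions: dict[str, float] | pd.Series,
    region_name: str,
    cnv_type: str,
    out_dir: str | Path,
    review_threshold: float = 0.8,
) -> tuple[Path, Path]:
    """Write the review table and the per-SNP plot file for a scored panel.

    One row per sample, sorted by descending prediction; samples with
    prediction >= ``review_threshold`` (inclusive) are flagged for
    review.  Returns (review_path, plot_path).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    predictions = pd.Series(predictions, dtype=float)
    rec = panel.records
    rows = []
    for sid in panel.samples:
        if sid not in predictions.index:
            raise ValueError(f"no prediction for sample {sid!r}")
        sub = rec.loc[rec["sample_id"] == sid]
        lrr = sub["lrr"].dropna()
        pred = float(predictions[sid])
        if not 0.0 <= pred <= 1.0:
            raise ValueError(f"prediction for {sid!r} outside [0, 1]: {pred}")
        rows.append(
            {
                "sampleID": sid,
                "region": region_name,
                "cnv_type": cnv_type,
                "prediction": pred,
                "n_variants": len(sub),
                "lrr_min": lrr.min() if len(lrr) else np.nan,
                "lrr_max": lrr.max() if len(lrr) else np.nan,
                "lrr_mean": lrr.mean() if len(lrr) else np.nan,
                "flagged": pred >= review_threshold,
            }
        )
    review = pd.DataFrame(rows, columns=REVIEW_COLUMNS)
    review = review.sort_values("prediction", ascending=False, kind="mergesort")
    review_path = out_dir / f"{region_name}_{cnv_type}_review.tsv"
    review.to_csv(review_path, sep="\t", index=False)

    plot = rec.rename(
        columns={"sample_id": "sampleID", "baf": "BAF", "lrr": "LRR"}
    )[PLOT_COLUMNS]
    order = review["sampleID"].tolist()
    plot = plot.set_index("sampleID").loc[order].reset_index() if order else plot
    plot_path = out_dir / f"{region_name}_{cnv_type}_plotdata.tsv"
    plot.to_csv(plot_path, sep="\t", index=False)
    return review_path, plot_path


def ingest_annotation_log(log_path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse a reviewer log into labeled additions and exclusions.

    Yes → label 1, No → label 0, Maybe → returned separately (excluded
    from training).  Duplicate decisions for one (sample, region,
    cnv_type) key resolve to the latest timestamp.
    """
    log = pd.read_csv(log_path, sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in log.columns]
    if missing:
        raise ValueError(f"annotation log missing columns: {missing}")
    bad = ~log["decision"].isin(DECISIONS)
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 2  # 1-based incl. header
        raise ValueError(
            f"unknown decision {log.loc[bad, 'decision'].iloc[0]!r} at line {row}"
        )
    log = log.assign(timestamp=pd.to_datetime(log["timestamp"]))
    log = log.sort_values("timestamp", kind="mergesort")
    latest = log.groupby(["sampleID", "region", "cnv_type"], as_index=False).last()
    maybes = latest.loc[latest["decision"] == "Maybe"].reset_index(drop=True)
    decided = latest.loc[latest["decision"] != "Maybe"].copy()
    decided["label"] = (decided["decision"] == "Yes").astype(int)
    additions = decided[["sampleID", "region", "cnv_type", "label"]].reset_index(drop=True)
    return additions, maybes


@dataclasses.dataclass
class TrainingSet:
    """Labeled (sample, region, cnv_type) collection grown across rounds."""

    samples: pd.DataFrame  # columns sampleID, region, cnv_type, label, round

    KEY = ["sampleID", "region", "cnv_type"]

    @classmethod
    def empty(cls) -> "TrainingSet":
        return cls(pd.DataFrame(columns=cls.KEY + ["label", "round"]))

    def __len__(self) -> int:
        return len(self.samples)


def update_training_set(
    existing: TrainingSet, additions: pd.DataFrame, round_tag: str
) -> tuple[TrainingSet, pd.DataFrame]:
    """Union labeled additions into a training set, rejecting duplicates.

    A key already present keeps its existing label; if the new label
    disagrees, the key lands in the returned conflict report instead of
    silently overwriting.  Returns (new_set, conflicts).
    """
    add = additions.copy()
    required = set(TrainingSet.KEY + ["label"])
    if not required.issubset(add.columns):
        raise ValueError(f"additions need columns {sorted(required)}")
    if not set(add["label"].unique()) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if add.duplicated(subset=TrainingSet.KEY).any():
        raise ValueError("additions contain duplicate keys")
    add["round"] = round_tag
    merged = add.merge(
        existing.samples[TrainingSet.KEY + ["label"]].rename(columns={"label": "label_old"}),
        on=TrainingSet.KEY,
        how="left",
    )
    known = merged["label_old"].notna()
    conflicts = merged.loc[known & (merged["label"] != merged["label_old"]),
                           TrainingSet.KEY + ["label", "label_old"]].reset_index(drop=True)
    new_rows = merged.loc[~known, TrainingSet.KEY + ["label", "round"]]
    combined = pd.concat([existing.samples, new_rows], ignore_index=True)
    return TrainingSet(combined), conflicts
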