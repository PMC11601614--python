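"""Synthetic SNP-array signal panels with known CNV truth.

The generator emulates the long-format signal table the pipeline
consumes: probe positions scattered over a (buffered) region, diploid
BAF clusters near 0 / 0.5 / 1, LRR centred at 0, and CNV states that
shift LRR and restructure the BAF clusters:

* heterozygous deletion — one copy lost; the 0.5 BAF cluster vanishes
  and LRR drops below the −0.2 candidate threshold on average;
* homozygous deletion — both copies lost; strongly negative LRR, BAF
  reduced to uninformative noise;
* duplication — three copies; heterozygous BAF diverges toward 1/3 and
  2/3, LRR rises above +0.2 on average;
* triplication — four copies; BAF clusters at 0, 1/4, 1/2, 3/4, 1
  (allele ratios 1:3, 2:2, 3:1), a further LRR rise.

Genotypes are drawn under Hardy–Weinberg given the state's copy number.
All randomness flows from a single seed, so panels are bit-identical
across runs.  Default intensity parameters are stand-ins chosen to
respect the ±0.2 candidate thresholds with realistic overlap; see
docs/methods.md for what they do and do not emulate.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .regions import RegionSpec
from .signals import SignalPanel

__all__ = [
    "CnvEvent",
    "SignalModel",
    "STATE_COPY_NUMBER",
    "simulate_positions",
    "simulate_snp_signal",
    "simulate_panel",
]

STATES = ("diploid", "het_deletion", "hom_deletion", "duplication", "triplication")
STATE_COPY_NUMBER = {
    "diploid": 2,
    "het_deletion": 1,
    "hom_deletion": 0,
    "duplication": 3,
    "triplication": 4,
}

#: default event-size span, matching the deletion sizes the scorer is
#: expected to resolve (roughly 53-455 kb)
DEFAULT_EVENT_SIZE_RANGE = (53_000, 455_000)


@dataclasses.dataclass(frozen=True)
class CnvEvent:
    """One copy-number event carried by a sample."""

    state: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown CNV state {self.state!r}")
        if self.end <= self.start:
            raise ValueError("event end must exceed start")


@dataclasses.dataclass(frozen=True)
class SignalModel:
    """Per-state intensity model for the generator.

    ``lrr_mean``/``lrr_sd`` give the normal LRR distribution per state;
    ``baf_sd`` is the spread around each genotype's BAF cluster mean.
    """

    lrr_mean: dict = dataclasses.field(
        default_factory=lambda: {
            "diploid": 0.0,
            "het_deletion": -0.45,
            "hom_deletion": -2.5,
            "duplication": 0.3,
            "triplication": 0.55,
        }
    )
    lrr_sd: dict = dataclasses.field(
        default_factory=lambda: {
            "diploid": 0.15,
            "het_deletion": 0.20,
            "hom_deletion": 0.50,
            "duplication": 0.18,
            "triplication": 0.20,
        }
    )
    baf_sd: float = 0.03
    b_freq_range: tuple[float, float] = (0.05, 0.95)

    def __post_init__(self) -> None:
        if self.lrr_mean["diploid"] != 0.0:
            raise ValueError("diploid LRR mean must be 0")
        if not self.lrr_mean["het_deletion"] < -0.2 - self.lrr_sd["het_deletion"]:
            raise ValueError("het-deletion LRR must sit clearly below the -0.2 threshold")
        if not self.lrr_mean["duplication"] > 0.2:
            raise ValueError("duplication LRR mean must exceed the +0.2 threshold")


def simulate_positions(region: RegionSpec, n_snps: int,
                       seed: int | np.random.Generator = 0) -> np.ndarray:
    """Sorted unique probe positions uniform over the buffered region."""
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = region.buffered_start, region.buffered_stop
    if hi - lo < n_snps:
        raise ValueError("region too small for the requested probe count")
    positions = rng.choice(hi - lo, size=n_snps, replace=False) + lo
    return np.sort(positions).astype(np.int64)


def _baf_cluster_means(state: str, n_b: int, copy_number: int) -> float:
    return n_b / copy_number


def simulate_snp_signal(
    state: str,
    b_allele_freq: float,
    signal_model: SignalModel,
    seed: int | np.random.Generator = 0,
    size: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (BAF, LRR) for one SNP under a CNV state.

    The genotype (count of B alleles) is binomial in the copy number and
    the B-allele frequency (Hardy–Weinberg); BAF scatters around the
    genotype's cluster mean ``n_B / copy_number`` truncated to [0, 1].
    A homozygous deletion has no alleles: its BAF is uniform noise.
    """
    if state not in STATES:
        raise ValueError(f"unknown CNV state {state!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cn = STATE_COPY_NUMBER[state]
    if cn == 0:
        baf = rng.uniform(0.0, 1.0, size=size)
    else:
        n_b = rng.binomial(cn, b_allele_freq, size=size)
        baf = np.clip(rng.normal(n_b / cn, signal_model.baf_sd, size=size), 0.0, 1.0)
    lrr = rng.normal(signal_model.lrr_mean[state], signal_model.lrr_sd[state], size=size)
    return baf, lrr


def simulate_panel(
    region: RegionSpec,
    n_samples: int,
    carrier_fraction: float,
    cnv_type: str = "deletion",
    event_size_range: tuple[int, int] = DEFAULT_EVENT_SIZE_RANGE,
    signal_model: SignalModel | None = None,
    n_snps: int | None = None,
    snps_per_kb: float = 1.0,
    carrier_state: str | None = None,
    seed: int = 0,
) -> tuple[SignalPanel, pd.DataFrame]:
    """Simulate a cohort's signal panel over one region.

    Carriers (a ``carrier_fraction`` share of samples, assigned by a
    seeded shuffle) receive one CNV event of the requested type, with a
    size drawn uniformly from ``event_size_range`` and placed uniformly
    inside the unbuffered gene interval.  SNPs inside the event take the
    event state; all other SNPs are diploid.  Returns the panel plus a
    per-sample truth table (label, event bounds, state).

    ``cnv_type`` "deletion" maps to a heterozygous deletion and
    "duplication" to a three-copy gain unless ``carrier_state``
    overrides it (e.g. "hom_deletion", "triplication").
    """
    if not 0.0 <= carrier_fraction <= 1.0:
        raise ValueError("carrier_fraction must be in [0, 1]")
    if cnv_type not in ("deletion", "duplication"):
        raise ValueError("cnv_type must be 'deletion' or 'duplication'")
    signal_model = SignalModel() if signal_model is None else signal_model
    state = carrier_state or ("het_deletion" if cnv_type == "deletion" else "duplication")
    if STATE_COPY_NUMBER[state] < 2 and cnv_type == "duplication":
        raise ValueError(f"state {state!r} is not a gain")
    lo, hi = int(event_size_range[0]), int(event_size_range[1])
    if hi > region.length:
        raise ValueError(
            f"largest event ({hi} bp) exceeds the gene interval ({region.length} bp)"
        )

    rng = np.random.default_rng(seed)
    if n_snps is None:
        n_snps = max(1, int(round(region.buffered_length / 1000.0 * snps_per_kb)))
    positions = simulate_positions(region, n_snps, rng)
    b_freqs = rng.uniform(*signal_model.b_freq_range, size=n_snps)
    gentrain = np.clip(rng.normal(0.8, 0.1, size=n_snps), 0.25, 1.0)

    n_carriers = int(round(carrier_fraction * n_samples))
    carrier_flags = np.zeros(n_samples, dtype=bool)
    carrier_flags[rng.permutation(n_samples)[:n_carriers]] = True

    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    frames = []
    truth_rows = []
    snp_ids = [f"snp_{p}" for p in positions]
    for si, sid in enumerate(sample_ids):
        if carrier_flags[si]:
            size = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(region.start, region.stop - size + 1))
            event = CnvEvent(state=state, start=start, end=start + size)
            inside = (positions >= event.start) & (positions < event.end)
        else:
            event = None
            inside = np.zeros(n_snps, dtype=bool)
        baf = np.empty(n_snps)
        lrr = np.empty(n_snps)
        for snp_state, mask in (("diploid", ~inside), (state, inside)):
            if mask.any():
                idx = np.flatnonzero(mask)
                cn = STATE_COPY_NUMBER[snp_state]
                if cn == 0:
                    baf[idx] = rng.uniform(0.0, 1.0, size=idx.size)
                else:
                    n_b = rng.binomial(cn, b_freqs[idx])
                    baf[idx] = np.clip(
                        rng.normal(n_b / cn, signal_model.baf_sd), 0.0, 1.0
                    )
                lrr[idx] = rng.normal(
                    signal_model.lrr_mean[snp_state],
                    signal_model.lrr_sd[snp_state],
                    size=idx.size,
                )
        frames.append(
            pd.DataFrame(
                {
                    "snp_id": snp_ids,
                    "chromosome": region.chromosome,
                    "position": positions,
                    "sample_id": sid,
                    "baf": baf,
                    "lrr": lrr,
                    "gentrain": gentrain,
                }
            )
        )
        truth_rows.append(
            {
                "sample_id": sid,
                "label": int(carrier_flags[si]),
                "event_start": event.start if event else pd.NA,
                "event_end": event.end if event else pd.NA,
                "state": event.state if event else "diploid",
            }
        )
    records = pd.concat(frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return SignalPanel(records), truth
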