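"""Transcriptional consensus signatures (TCS).

A TCS summarizes a compound's transcriptional response independently of the
cell line.  It is built in two stages from plate-normalized z-score
profiles:

1. Within each (compound, cell line) group, replicates and doses are pooled
   and a gene is called up (+1) or down (-1) when the number of samples with
   |z| above a threshold exceeds a fraction of the pooled samples
   (defaults: |z| > 1 in more than 20% of samples).
2. Across cell lines, the per-line calls are summed into a signed integer
   score per gene (n_up - n_down, so |score| is bounded by the number of
   lines), zeroed wherever the dominant direction is not seen in more than
   30% of the lines.

Both fractional thresholds are strict inequalities.  Profiles are first
restricted to a single treatment time (default 24 h).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import PerturbationProfileSet, SignedSignature, warn_empty

__all__ = [
    "CellLineAggregate",
    "ConsensusSignature",
    "filter_time",
    "aggregate_cell_line",
    "build_tcs",
    "high_confidence",
    "filter_low_support",
    "consensus_signatures",
]


@dataclass
class CellLineAggregate:
    """Per-(compound, cell line) directional call vector.

    ``direction`` is a ternary Series over the gene axis; non-zero only where
    the sample-fraction rule passed for the dominant direction.
    """

    compound_id: str
    cell_line: str
    direction: pd.Series
    n_samples: int

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("an aggregate needs at least one sample")
        self.direction = self.direction.astype(np.int8)


@dataclass
class ConsensusSignature:
    """Signed integer consensus score per gene for one compound.

    ``score[g]`` counts cell lines calling gene g up minus lines calling it
    down; entries lie in [-n_cell_lines, +n_cell_lines].  ``params`` records
    the thresholds used, for provenance.
    """

    compound_id: str
    score: pd.Series
    n_cell_lines: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.score = self.score.astype(int)
        if self.n_cell_lines < 1:
            raise ValueError("n_cell_lines must be >= 1")
        if (self.score.abs() > self.n_cell_lines).any():
            raise ValueError("|score| exceeds the number of cell lines")

    @property
    def support(self) -> int:
        return int((self.score != 0).sum())

    def sign(self) -> pd.Series:
        return np.sign(self.score).astype(np.int8)


def filter_time(profiles: PerturbationProfileSet, time_h: float = 24.0) -> PerturbationProfileSet:
    """Keep only samples treated for ``time_h`` hours (default 24 h)."""
    if "time_h" not in profiles.samples.columns:
        raise ValueError("sample metadata lacks a time_h field")
    times = pd.to_numeric(profiles.samples["time_h"])
    keep = profiles.samples.index[times == float(time_h)]
    out = profiles.subset_samples(keep)
    if out.n_samples == 0:
        warn_empty(f"filter_time(time_h={time_h})")
    return out


def aggregate_cell_line(
    profiles: PerturbationProfileSet,
    z_threshold: float = 1.0,
    sample_fraction: float = 0.2,
) -> CellLineAggregate:
    """Collapse all samples of one (compound, cell line) into a ternary call.

    A gene is called in a direction when the count of samples exceeding the
    z-threshold in that direction is strictly more than ``sample_fraction``
    of the pooled samples and that direction dominates the other; an exact
    up/down count tie yields 0.  Replicates and doses are pooled.
    """
    if profiles.n_samples == 0:
        raise ValueError("cannot aggregate zero samples")
    compounds = profiles.samples["compound_id"].unique()
    lines = profiles.samples["cell_line"].unique()
    if len(compounds) != 1 or len(lines) != 1:
        raise ValueError(
            f"aggregate_cell_line expects one (compound, cell_line) group; "
            f"got compounds={list(compounds)}, cell_lines={list(lines)}"
        )
    z = profiles.z.to_numpy(dtype=float)
    n = z.shape[1]
    up = (z > z_threshold).sum(axis=1)
    down = (z < -z_threshold).sum(axis=1)
    direction = np.zeros(z.shape[0], dtype=np.int8)
    # strict ">" on the fraction, dominant direction wins, ties are zero
    direction[(up > down) & (up / n > sample_fraction)] = 1
    direction[(down > up) & (down / n > sample_fraction)] = -1
    return CellLineAggregate(
        compound_id=str(compounds[0]),
        cell_line=str(lines[0]),
        direction=pd.Series(direction, index=profiles.genes),
        n_samples=n,
    )


def build_tcs(
    aggregates: list[CellLineAggregate],
    cell_fraction: float = 0.3,
) -> ConsensusSignature:
    """Collapse per-line calls into the compound-level consensus signature.

    score = n_up - n_down per gene, zeroed unless the dominant direction was
    called in strictly more than ``cell_fraction`` of the lines.  With a
    single line the aggregate passes through unchanged (1/1 > 0.3).
    """
    if not aggregates:
        raise ValueError("no aggregates supplied")
    compound_ids = {a.compound_id for a in aggregates}
    if len(compound_ids) != 1:
        raise ValueError(f"aggregates span multiple compounds: {sorted(compound_ids)}")
    lines = [a.cell_line for a in aggregates]
    if len(set(lines)) != len(lines):
        raise ValueError("duplicate cell lines for one compound; aggregate within lines first")
    genes = aggregates[0].direction.index
    dirs = np.stack([a.direction.reindex(genes).to_numpy() for a in aggregates])
    n_lines = len(aggregates)
    n_up = (dirs == 1).sum(axis=0)
    n_down = (dirs == -1).sum(axis=0)
    raw = n_up - n_down
    passed = np.maximum(n_up, n_down) / n_lines > cell_fraction
    score = np.where(passed, raw, 0)
    return ConsensusSignature(
        compound_id=compound_ids.pop(),
        score=pd.Series(score, index=genes),
        n_cell_lines=n_lines,
        params={"cell_fraction": cell_fraction},
    )


def high_confidence(tcs: ConsensusSignature, min_fraction: float = 0.5) -> SignedSignature:
    """Ternary high-confidence signature: keep genes with |score| >= ceil(f*N).

    With the default f = 0.5 and six cell lines this keeps genes called
    concordantly in at least half the lines (|score| >= 3).
    """
    cutoff = math.ceil(min_fraction * tcs.n_cell_lines)
    keep = tcs.score.abs() >= cutoff
    vals = np.where(keep, np.sign(tcs.score), 0)
    return SignedSignature(values=pd.Series(vals, index=tcs.score.index), role="reference")


def filter_low_support(
    tcs_set: list[ConsensusSignature],
    reference: SignedSignature,
    min_fraction: float = 0.5,
) -> list[ConsensusSignature]:
    """Drop compounds whose TCS has fewer genes than ``min_fraction`` of the
    reference signature's support ("fewer than" excludes, so >= retains)."""
    if reference.support == 0:
        raise ValueError("reference signature has empty support")
    cutoff = min_fraction * reference.support
    kept = [t for t in tcs_set if t.support >= cutoff]
    if not kept:
        warn_empty("filter_low_support")
    return kept


def consensus_signatures(
    profiles: PerturbationProfileSet,
    z_threshold: float = 1.0,
    sample_fraction: float = 0.2,
    cell_fraction: float = 0.3,
    time_h: float | None = 24.0,
) -> dict[str, ConsensusSignature]:
    """Full two-stage pipeline: time filter -> per-line calls -> TCS per compound.

    Returns a dict keyed by compound id, in sorted-compound order.
    """
    if time_h is not None:
        profiles = filter_time(profiles, time_h)
    out: dict[str, ConsensusSignature] = {}
    if profiles.n_samples == 0:
        return out
    grouped = profiles.samples.groupby(["compound_id", "cell_line"], sort=True).groups
    by_compound: dict[str, list[CellLineAggregate]] = {}
    for (compound, _line), sample_ids in grouped.items():
        agg = aggregate_cell_line(
            profiles.subset_samples(sample_ids), z_threshold, sample_fraction
        )
        by_compound.setdefault(str(compound), []).append(agg)
    for compound in sorted(by_compound):
        tcs = build_tcs(by_compound[compound], cell_fraction)
        tcs.params.update(
            {
                "z_threshold": z_threshold,
                "sample_fraction": sample_fraction,
                "time_h": time_h,
            }
        )
        out[compound] = tcs
    return out
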