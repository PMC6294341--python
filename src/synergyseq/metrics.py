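"""Compound scoring: specificity, concordance, discordance, orthogonality.

Given a compound consensus signature z, a reference signature r (e.g. a
BET-inhibitor high-confidence signature) and a disease signature d, each
compound is scored by

* specificity  S  = |{z!=0 and r!=0}| / |{z!=0}|  in [0, 1],
* concordance  CR = #(z.r > 0) / #(z.r < 0),
* discordance  DR = #(z.d < 0) / #(z.d > 0) restricted to genes with r = 0,

and, after unity-based normalization of CR and DR over the compound cohort,
the orthogonality score OS = sqrt((1 - CR_norm)^2 + DR_norm^2).  High OS
marks compounds that reverse the disease signature through genes the
reference does not touch — the predicted synergy partners.

Zero denominators yield an infinity sentinel (perfect concordance /
reversal), replaced by the cohort's largest finite value before
normalization so the compound lands at the top of the [0, 1] scale; an
optional pseudocount mode avoids sentinels entirely.  All ratios depend
only on the signs of z, d and r.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consensus import ConsensusSignature
from .io_formats import SignedSignature

__all__ = [
    "CompoundScore",
    "specificity",
    "concordance_ratio",
    "discordance_ratio",
    "cell_line_discordance",
    "unity_normalize",
    "orthogonality_score",
    "score_cohort",
]


@dataclass
class CompoundScore:
    """Full score record for one compound, with audit counts."""

    compound_id: str
    specificity: float
    concordance: float  # raw CR; may be math.inf
    discordance: float  # raw DR; may be math.inf
    n_concordant: int
    n_discordant: int
    n_reversing: int
    n_mimicking: int
    cr_norm: float = field(default=float("nan"))
    dr_norm: float = field(default=float("nan"))
    orthogonality: float = field(default=float("nan"))
    rank: int = field(default=0)


def _signs(vec) -> np.ndarray:
    if isinstance(vec, ConsensusSignature):
        vec = vec.score
    elif isinstance(vec, SignedSignature):
        vec = vec.values
    return np.sign(np.asarray(vec, dtype=float))


def _aligned_signs(z, other) -> tuple[np.ndarray, np.ndarray]:
    zs = z.score if isinstance(z, ConsensusSignature) else getattr(z, "values", z)
    os_ = other.values if isinstance(other, SignedSignature) else other
    if isinstance(zs, pd.Series) and isinstance(os_, pd.Series):
        if not zs.index.equals(os_.index):
            os_ = os_.reindex(zs.index, fill_value=0)
    return np.sign(np.asarray(zs, dtype=float)), np.sign(np.asarray(os_, dtype=float))


def specificity(z: ConsensusSignature, r: SignedSignature) -> float:
    """Fraction of the compound's TCS genes that the reference also covers."""
    zs, rs = _aligned_signs(z, r)
    n_z = int((zs != 0).sum())
    if n_z == 0:
        raise ValueError("compound signature has empty support; exclude it upstream")
    return float(((zs != 0) & (rs != 0)).sum() / n_z)


def _ratio(num: int, den: int, pseudocount: float) -> float:
    if pseudocount > 0:
        return (num + pseudocount) / (den + pseudocount)
    if den == 0:
        return math.inf if num > 0 else 0.0
    return num / den


def concordance_ratio(
    z: ConsensusSignature, r: SignedSignature, pseudocount: float = 0.0
) -> float:
    """Same-direction over opposite-direction gene count against the reference."""
    n_con, n_dis = concordance_counts(z, r)
    return _ratio(n_con, n_dis, pseudocount)


def concordance_counts(z, r) -> tuple[int, int]:
    zs, rs = _aligned_signs(z, r)
    prod = zs * rs
    return int((prod > 0).sum()), int((prod < 0).sum())


def discordance_ratio(
    z: ConsensusSignature,
    d: SignedSignature,
    r: SignedSignature,
    pseudocount: float = 0.0,
) -> float:
    """Disease-reversing over disease-mimicking genes, outside the reference.

    Only genes absent from the reference signature (r = 0) are counted:
    reversal means z and d have opposite signs there, mimicry the same sign.
    """
    n_rev, n_mim = discordance_counts(z, d, r)
    return _ratio(n_rev, n_mim, pseudocount)


def discordance_counts(z, d, r) -> tuple[int, int]:
    zs, ds = _aligned_signs(z, d)
    _, rs = _aligned_signs(z, r)
    mask = rs == 0
    prod = zs * ds
    return int(((prod < 0) & mask).sum()), int(((prod > 0) & mask).sum())


def cell_line_discordance(
    z: ConsensusSignature,
    cell_sig: SignedSignature,
    reference: SignedSignature,
    pseudocount: float = 0.0,
) -> float:
    """Discordance ratio against a cell line's baseline signature.

    Identical arithmetic to `discordance_ratio` with the disease vector
    replaced by the cell-line baseline signature, giving a per-line
    (patient-specific) synergy predictor.
    """
    return discordance_ratio(z, cell_sig, reference, pseudocount=pseudocount)


def unity_normalize(values) -> np.ndarray:
    """Unity-based normalization of a cohort of values into [0, 1].

    Infinity sentinels are replaced by the largest finite value first, so a
    perfectly concordant (or perfectly reversing) compound maps to 1.  A
    constant cohort maps to all zeros.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("unity normalization needs a cohort of at least 2 values")
    finite = x[np.isfinite(x)]
    if finite.size == 0:
        return np.zeros_like(x)
    x = np.where(np.isinf(x), finite.max(), x)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def orthogonality_score(cr_norm: float, dr_norm: float) -> float:
    """Distance from the reference anchor (CR_norm = 1, DR_norm = 0).

    0 for the reference itself, sqrt(2) for a maximally orthogonal,
    maximally disease-reversing compound.
    """
    return math.sqrt((1.0 - cr_norm) ** 2 + dr_norm**2)


def score_cohort(
    tcs_set: list[ConsensusSignature],
    disease: SignedSignature,
    reference: SignedSignature,
    pseudocount: float = 0.0,
) -> tuple[list[CompoundScore], pd.DataFrame]:
    """Score and rank a compound cohort for predicted synergy.

    Computes S, CR and DR per compound, unity-normalizes CR and DR over the
    cohort, derives the orthogonality score and ranks descending by OS
    (rank 1 = best predicted partner).  Ties break on higher raw DR, then
    lexicographic compound id.  Also returns the synergy-plot table with
    x = CR_norm, y = DR_norm.
    """
    if len(tcs_set) < 2:
        raise ValueError("cohort normalization needs at least 2 compounds")
    scores: list[CompoundScore] = []
    for tcs in tcs_set:
        n_con, n_dis = concordance_counts(tcs, reference)
        n_rev, n_mim = discordance_counts(tcs, disease, reference)
        scores.append(
            CompoundScore(
                compound_id=tcs.compound_id,
                specificity=specificity(tcs, reference),
                concordance=_ratio(n_con, n_dis, pseudocount),
                discordance=_ratio(n_rev, n_mim, pseudocount),
                n_concordant=n_con,
                n_discordant=n_dis,
                n_reversing=n_rev,
                n_mimicking=n_mim,
            )
        )
    cr_norm = unity_normalize([s.concordance for s in scores])
    dr_norm = unity_normalize([s.discordance for s in scores])
    for s, c, d in zip(scores, cr_norm, dr_norm):
        s.cr_norm = float(c)
        s.dr_norm = float(d)
        s.orthogonality = orthogonality_score(s.cr_norm, s.dr_norm)
    order = sorted(
        range(len(scores)),
        key=lambda i: (
            -scores[i].orthogonality,
            -scores[i].discordance,
            scores[i].compound_id,
        ),
    )
    for rank, i in enumerate(order, start=1):
        scores[i].rank = rank
    table = pd.DataFrame(
        {
            "compound_id": [s.compound_id for s in scores],
            "specificity": [s.specificity for s in scores],
            "concordance_ratio": [s.concordance for s in scores],
            "discordance_ratio": [s.discordance for s in scores],
            "cr_norm": [s.cr_norm for s in scores],
            "dr_norm": [s.dr_norm for s in scores],
            "orthogonality": [s.orthogonality for s in scores],
            "rank": [s.rank for s in scores],
            "n_concordant": [s.n_concordant for s in scores],
            "n_discordant": [s.n_discordant for s in scores],
            "n_reversing": [s.n_reversing for s in scores],
            "n_mimicking": [s.n_mimicking for s in scores],
        }
    ).sort_values("rank", kind="stable").reset_index(drop=True)
    # synergy-plot axes: x = normalized concordance, y = normalized discordance
    table["x"] = table["cr_norm"]
    table["y"] = table["dr_norm"]
    return scores, table
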