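"""Synthetic data with planted ground truth.

Generates every input kind the pipeline consumes, with the truth recorded
so recovery can be measured:

* L1000-style Level-4 z-score profiles with planted mechanism-of-action
  (MOA) groups: compounds in a group share a signed base signature,
  per-cell-line Bernoulli dropout models heterogeneity (what makes the
  cross-line consensus rule non-trivial), Gaussian noise models the
  z-score background.
* Tumor/control negative-binomial count tables with planted differentially
  expressed genes at a stated log2 fold change.
* Dose-response matrices built from Hill-curve monotherapy margins with
  combination wells following Bliss independence or Loewe additivity, plus
  an additive planted synergy perturbation.
* A full ranking scenario: a reference compound, one planted
  disease-reversing compound orthogonal to the reference, and MOA-grouped
  decoys — by construction the planted hit is the orthogonality-score
  maximal compound.

Everything is deterministic under (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .consensus import consensus_signatures, filter_low_support, high_confidence
from .io_formats import DoseMatrix, PerturbationProfileSet, SignedSignature
from .metrics import score_cohort
from .signatures import ExpressionTable
from .synergy import _hill

__all__ = [
    "SimulationConfig",
    "gen_l1000",
    "gen_disease",
    "gen_dose_matrix",
    "gen_scenario_synergyseq",
    "rank_scenario",
    "to_raw_plate",
]

# the 7x7 plate grid: 0-dose margin plus 10 -> 0.3125 uM at 1:2 dilutions
DEFAULT_DOSES = (0.0, 0.3125, 0.625, 1.25, 2.5, 5.0, 10.0)


@dataclass(frozen=True)
class SimulationConfig:
    """All generator knobs, with the study conditions as defaults."""

    seed: int = 0
    # --- L1000 profiles ---
    G: int = 978
    n_moa_groups: int = 3
    compounds_per_group: int = 5
    n_cell_lines: int = 6
    replicates_per_line: int = 6  # pooled replicates x doses per (compound, line)
    offtime_replicates: int = 1  # extra 6-h samples per (compound, line)
    signature_size: int = 60
    signal_z: float = 3.0
    noise_sd: float = 1.0
    dropout: float = 0.2  # per-line Bernoulli loss of a planted gene
    # --- scenario ---
    disease_size: int = 132
    reverser_overlap: float = 0.6  # fraction of disease genes the hit reverses
    reference_overlap: float = 0.25  # fraction of reference genes drawn from disease
    # --- DE fixture ---
    nb_dispersion: float = 0.1
    lfc: float = 2.0
    n_tumor: int = 153
    n_control: int = 5
    base_mean: float = 200.0
    # --- dose matrices ---
    doses: tuple = DEFAULT_DOSES
    hill_a: tuple = (0.0, 100.0, 1.0, 1.0)  # e0, emax, ec50, slope
    hill_b: tuple = (0.0, 100.0, 1.0, 1.0)
    interaction_model: str = "bliss"  # or "loewe"
    synergy_delta: float = 0.0  # percentage points added to combination wells
    plate_noise_sd: float = 2.0  # percentage points

    def __post_init__(self) -> None:
        counts = {
            "G": self.G,
            "n_moa_groups": self.n_moa_groups,
            "compounds_per_group": self.compounds_per_group,
            "n_cell_lines": self.n_cell_lines,
            "replicates_per_line": self.replicates_per_line,
            "signature_size": self.signature_size,
            "disease_size": self.disease_size,
            "n_tumor": self.n_tumor,
            "n_control": self.n_control,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be positive, got {v}")
        for name, v in (
            ("dropout", self.dropout),
            ("reverser_overlap", self.reverser_overlap),
            ("reference_overlap", self.reference_overlap),
        ):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.interaction_model not in ("bliss", "loewe"):
            raise ValueError(f"interaction_model must be bliss or loewe, got {self.interaction_model!r}")


def _gene_axis(G: int) -> pd.Index:
    return pd.Index([f"G{i:04d}" for i in range(G)], name="gene_id")


def _plant_signature(rng, genes: pd.Index, size: int, pool=None) -> pd.Series:
    if size > len(genes):
        raise ValueError(f"signature_size {size} exceeds gene count {len(genes)}")
    pool = np.arange(len(genes)) if pool is None else np.asarray(pool)
    picked = rng.choice(pool, size=size, replace=False)
    sig = pd.Series(np.zeros(len(genes), dtype=np.int8), index=genes)
    sig.iloc[picked] = rng.choice([-1, 1], size=size).astype(np.int8)
    return sig


def _profiles_for_compounds(
    rng, cfg: SimulationConfig, signatures: dict[str, pd.Series]
) -> PerturbationProfileSet:
    """Sample z-score columns for every compound x cell line x replicate."""
    genes = next(iter(signatures.values())).index
    cols, meta = [], []
    for compound, sig in signatures.items():
        planted = sig.to_numpy(dtype=float)
        for line_idx in range(cfg.n_cell_lines):
            line = f"CL{line_idx + 1:02d}"
            keep = rng.random(len(genes)) >= cfg.dropout
            signal = planted * cfg.signal_z * keep
            for rep in range(cfg.replicates_per_line):
                cols.append(rng.normal(0.0, cfg.noise_sd, len(genes)) + signal)
                meta.append((compound, line, 10.0, "uM", 24.0, f"r{rep + 1}"))
            for rep in range(cfg.offtime_replicates):
                cols.append(rng.normal(0.0, cfg.noise_sd, len(genes)))
                meta.append((compound, line, 10.0, "uM", 6.0, f"t6r{rep + 1}"))
    sample_ids = [f"S{i:05d}" for i in range(len(cols))]
    z = pd.DataFrame(np.column_stack(cols), index=genes, columns=sample_ids)
    samples = pd.DataFrame(
        meta,
        index=pd.Index(sample_ids, name="sample_id"),
        columns=["compound_id", "cell_line", "dose", "dose_unit", "time_h", "replicate_id"],
    )
    return PerturbationProfileSet(z=z, samples=samples)


def gen_l1000(config: SimulationConfig) -> tuple[PerturbationProfileSet, dict]:
    """Perturbation profiles with planted MOA groups.

    Returns the profile set and a truth dict with ``moa_labels`` (compound ->
    group), ``signatures`` (genes x compounds DataFrame of planted signs)
    and the config.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_axis(config.G)
    signatures: dict[str, pd.Series] = {}
    moa_labels: dict[str, int] = {}
    for g in range(config.n_moa_groups):
        base = _plant_signature(rng, genes, config.signature_size)
        for c in range(config.compounds_per_group):
            name = f"MOA{g + 1}_C{c + 1:02d}"
            signatures[name] = base
            moa_labels[name] = g + 1
    profiles = _profiles_for_compounds(rng, config, signatures)
    truth = {
        "moa_labels": pd.Series(moa_labels, name="moa_group"),
        "signatures": pd.DataFrame(signatures),
        "config": config,
    }
    return profiles, truth


def gen_disease(config: SimulationConfig) -> tuple[ExpressionTable, dict, dict]:
    """Tumor/control negative-binomial counts with planted DE genes.

    Half the planted genes go up, half down, at |log2 fold change| =
    ``config.lfc`` in tumors.  Returns the count table, the sample groups,
    and a truth dict with the planted sign per gene.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_axis(config.G)
    if config.disease_size > config.G:
        raise ValueError("disease_size exceeds gene count")
    mu = rng.lognormal(np.log(config.base_mean), 1.0, config.G)
    planted_idx = rng.choice(config.G, size=config.disease_size, replace=False)
    signs = np.zeros(config.G, dtype=np.int8)
    half = config.disease_size // 2
    signs[planted_idx[:half]] = 1
    signs[planted_idx[half:]] = -1
    mu_tumor = mu * np.power(2.0, signs * config.lfc)

    r = 1.0 / config.nb_dispersion

    def nb(mu_vec, n):
        p = r / (r + mu_vec)
        return rng.negative_binomial(r, p[:, None], size=(config.G, n))

    tumor = nb(mu_tumor, config.n_tumor)
    control = nb(mu, config.n_control)
    cols = [f"T{i + 1:03d}" for i in range(config.n_tumor)] + [
        f"C{i + 1:03d}" for i in range(config.n_control)
    ]
    table = ExpressionTable(
        values=pd.DataFrame(np.hstack([tumor, control]), index=genes, columns=cols),
        space="counts",
    )
    groups = {"tumor": cols[: config.n_tumor], "control": cols[config.n_tumor :]}
    truth = {"signs": pd.Series(signs, index=genes, name="planted_sign"), "config": config}
    return table, groups, truth


def _loewe_effect(da: float, db: float, hill_a: tuple, hill_b: tuple) -> float:
    """Effect level of a Loewe-additive combination of two Hill curves."""
    e0a, emaxa, ec50a, ha = hill_a
    e0b, emaxb, ec50b, hb = hill_b
    lo = max(e0a, e0b)
    hi = min(emaxa, emaxb)

    def inv(e, e0, emax, ec50, h):
        frac = (e - e0) / (emax - e0)
        return ec50 * (frac / (1.0 - frac)) ** (1.0 / h)

    def g(e):
        total = 0.0
        if da > 0:
            total += da / inv(e, *hill_a)
        if db > 0:
            total += db / inv(e, *hill_b)
        return total - 1.0

    span = hi - lo
    a, b = lo + 1e-12 * span, hi - 1e-12 * span
    # no root below the weaker drug's plateau: the combination saturates there
    if g(b) > 0:
        return float(hi)
    return float(optimize.brentq(g, a, b, xtol=1e-12))


def gen_dose_matrix(config: SimulationConfig) -> tuple[DoseMatrix, dict]:
    """Dose matrix with monotherapy margins from Hill curves.

    Combination wells follow the configured null model (Bliss independence
    or Loewe additivity) plus ``synergy_delta`` percentage points and
    Gaussian plate noise.  Returns the matrix (percent scale) and a truth
    dict.
    """
    rng = np.random.default_rng(config.seed)
    doses = np.asarray(sorted(config.doses), dtype=float)
    if doses[0] != 0:
        raise ValueError("dose grid must include the 0-dose margins")
    m = len(doses)
    ea = _hill(doses, *config.hill_a)
    eb = _hill(doses, *config.hill_b)
    values = np.zeros((m, m))
    values[:, 0] = ea
    values[0, :] = eb
    for i in range(1, m):
        for j in range(1, m):
            if config.interaction_model == "bliss":
                fa, fb = ea[i] / 100.0, eb[j] / 100.0
                base = 100.0 * (fa + fb - fa * fb)
            else:
                base = _loewe_effect(doses[i], doses[j], config.hill_a, config.hill_b)
            values[i, j] = base + config.synergy_delta
    if config.plate_noise_sd > 0:
        noise = rng.normal(0.0, config.plate_noise_sd, values.shape)
        noise[0, 0] = 0.0
        values = values + noise
    dm = DoseMatrix(
        drug_a="drug_a",
        drug_b="drug_b",
        doses_a=doses,
        doses_b=doses,
        values=values,
        dose_unit="uM",
        kind="percent",
    )
    truth = {
        "model": config.interaction_model,
        "synergy_delta": config.synergy_delta,
        "hill_a": config.hill_a,
        "hill_b": config.hill_b,
        "config": config,
    }
    return dm, truth


def to_raw_plate(
    dm: DoseMatrix, ec0: float = 50000.0, ec100: float = 2000.0, n_control_wells: int = 7
) -> DoseMatrix:
    """Map a percent-scale matrix back to raw luminescence with control wells.

    Inverse of the % reduced-proliferation formula: LO = EC0 + pct/100 *
    (EC100 - EC0).  Control wells are written at their nominal means.
    """
    if dm.kind != "percent":
        raise ValueError("expected a percent-scale matrix")
    raw = ec0 + dm.values / 100.0 * (ec100 - ec0)
    return DoseMatrix(
        drug_a=dm.drug_a,
        drug_b=dm.drug_b,
        doses_a=dm.doses_a,
        doses_b=dm.doses_b,
        values=raw,
        dose_unit=dm.dose_unit,
        kind="raw",
        neg_controls=np.full(n_control_wells, float(ec0)),
        pos_controls=np.full(n_control_wells, float(ec100)),
        replicates=dm.replicates,
    )


def gen_scenario_synergyseq(config: SimulationConfig) -> dict:
    """End-to-end ranking scenario with a planted orthogonal disease-reverser.

    The bundle contains profiles for a reference compound (REF), a
    same-mechanism analog of it (REF_ANALOG), a planted hit (HIT) whose
    signature is disjoint from the reference's and reverses
    ``reverser_overlap`` of the disease genes, and MOA-grouped decoys with
    random signatures.  By construction the hit maximizes the orthogonality
    score.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_axis(config.G)
    n_genes = len(genes)

    disease = _plant_signature(rng, genes, config.disease_size)
    disease_idx = np.flatnonzero(disease.to_numpy())

    # reference: a fraction of its genes overlap the disease, the rest do not
    n_from_disease = int(round(config.reference_overlap * config.signature_size))
    non_disease = np.setdiff1d(np.arange(n_genes), disease_idx)
    ref_idx = np.concatenate(
        [
            rng.choice(disease_idx, size=n_from_disease, replace=False),
            rng.choice(non_disease, size=config.signature_size - n_from_disease, replace=False),
        ]
    )
    ref_sig = pd.Series(np.zeros(n_genes, dtype=np.int8), index=genes)
    ref_sig.iloc[ref_idx] = rng.choice([-1, 1], size=len(ref_idx)).astype(np.int8)

    # hit: disjoint from the reference; reverses a fraction of disease genes
    n_reverse = int(round(config.reverser_overlap * config.disease_size))
    reversible = np.setdiff1d(disease_idx, ref_idx)
    n_reverse = min(n_reverse, len(reversible))
    rev_idx = rng.choice(reversible, size=n_reverse, replace=False)
    neutral_pool = np.setdiff1d(np.arange(n_genes), np.union1d(disease_idx, ref_idx))
    n_fill = max(config.signature_size - n_reverse, 0)
    fill_idx = rng.choice(neutral_pool, size=min(n_fill, len(neutral_pool)), replace=False)
    hit_sig = pd.Series(np.zeros(n_genes, dtype=np.int8), index=genes)
    hit_sig.iloc[rev_idx] = (-disease.iloc[rev_idx]).astype(np.int8)
    hit_sig.iloc[fill_idx] = rng.choice([-1, 1], size=len(fill_idx)).astype(np.int8)

    # real cohorts contain same-mechanism analogs of the reference (e.g.
    # several BET inhibitors alongside JQ1); one analog sharing the
    # reference signature pins the top of the concordance scale
    signatures: dict[str, pd.Series] = {
        "REF": ref_sig,
        "REF_ANALOG": ref_sig,
        "HIT": hit_sig,
    }
    for g in range(config.n_moa_groups):
        base = _plant_signature(rng, genes, config.signature_size)
        for c in range(config.compounds_per_group):
            signatures[f"DECOY_G{g + 1}_{c + 1:02d}"] = base

    profiles = _profiles_for_compounds(rng, config, signatures)
    return {
        "profiles": profiles,
        "disease": SignedSignature(values=disease, role="disease"),
        "reference_compound": "REF",
        "planted_hit": "HIT",
        "planted_signatures": pd.DataFrame(signatures),
        "config": config,
    }


def rank_scenario(bundle: dict, min_support_fraction: float = 0.5) -> pd.DataFrame:
    """Run the full consensus + scoring pipeline on a scenario bundle.

    Builds TCSs from the profiles, takes the high-confidence signature of
    the reference compound, drops low-support compounds, and returns the
    ranked score table.
    """
    cfg: SimulationConfig = bundle["config"]
    tcs = consensus_signatures(bundle["profiles"])
    reference = high_confidence(tcs[bundle["reference_compound"]])
    cohort = filter_low_support(list(tcs.values()), reference, min_support_fraction)
    _, table = score_cohort(cohort, bundle["disease"], reference)
    return table
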