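"""Text-format readers and writers.

Everything external to the package travels through this module: GCT 1.3/1.2
matrices of L1000-style z-scores with per-sample metadata, tab-separated
signature and score tables, network edge lists, and dose-response plate
files with their DMSO / positive-control wells.

Gene identifiers are opaque strings and every join is by identifier, never
by position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GctFormatError",
    "PlateFormatError",
    "LandmarkGeneSet",
    "PerturbationProfileSet",
    "SignedSignature",
    "DoseMatrix",
    "read_gct",
    "write_gct",
    "write_signature_table",
    "read_signature_table",
    "write_score_table",
    "write_edge_list",
    "read_dose_plate",
    "write_dose_plate",
]


class GctFormatError(ValueError):
    """Raised when a GCT file violates the format contract."""


class PlateFormatError(ValueError):
    """Raised when a dose-plate file is malformed or lacks control wells."""


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LandmarkGeneSet:
    """Ordered panel of landmark gene identifiers.

    The order of ``gene_ids`` is the canonical axis for every signature and
    matrix in the package (canonically the 978 L1000 landmarks, but any
    unique ordered panel works).
    """

    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("landmark gene identifiers must be unique")

    @classmethod
    def from_iterable(cls, genes) -> "LandmarkGeneSet":
        return cls(tuple(str(g) for g in genes))

    @property
    def index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def as_pandas(self) -> pd.Index:
        return pd.Index(self.gene_ids, name="gene_id")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.gene_ids)


# metadata columns the consensus stage relies on
SAMPLE_FIELDS = ("compound_id", "cell_line", "dose", "dose_unit", "time_h", "replicate_id")


@dataclass
class PerturbationProfileSet:
    """Genes x samples matrix of plate-normalized (Level-4 style) z-scores.

    ``z`` is a DataFrame indexed by gene identifier with one column per
    sample; ``samples`` carries one metadata row per column (compound,
    cell line, dose, treatment time, replicate).  ``row_meta`` preserves any
    per-gene metadata found in the source file verbatim.
    """

    z: pd.DataFrame
    samples: pd.DataFrame
    row_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if list(self.z.columns) != list(self.samples.index):
            raise ValueError("z columns and sample metadata rows do not match")
        if self.z.size and not np.isfinite(self.z.to_numpy(dtype=float)).all():
            raise ValueError("z-score matrix contains non-finite values; missing data are rejected")
        if self.z.index.has_duplicates:
            raise ValueError("duplicate gene identifiers in z matrix")

    @property
    def genes(self) -> pd.Index:
        return self.z.index

    @property
    def n_samples(self) -> int:
        return self.z.shape[1]

    def subset_samples(self, sample_ids) -> "PerturbationProfileSet":
        ids = list(sample_ids)
        return PerturbationProfileSet(
            z=self.z.loc[:, ids], samples=self.samples.loc[ids], row_meta=self.row_meta
        )


@dataclass
class SignedSignature:
    """Ternary up/down/absent vector over the landmark gene axis.

    ``values`` is an integer Series in {-1, 0, +1} indexed by gene id.
    ``role`` records how the signature is used: ``disease`` (the d vector of
    the discordance ratio), ``reference`` (the r vector of concordance and
    the discordance mask), or ``cell_line`` (a baseline-expression signature
    used for cell-line-specific discordance).
    """

    values: pd.Series
    role: str = "reference"

    def __post_init__(self) -> None:
        if self.role not in ("disease", "reference", "cell_line"):
            raise ValueError(f"unknown signature role: {self.role!r}")
        vals = np.sign(pd.to_numeric(self.values)).astype(np.int8)
        self.values = pd.Series(vals, index=self.values.index)

    @classmethod
    def from_values(cls, values: pd.Series, role: str = "reference") -> "SignedSignature":
        """Ternarize arbitrary signed magnitudes to {-1, 0, +1}."""
        return cls(values=values, role=role)

    @property
    def support(self) -> int:
        return int((self.values != 0).sum())

    def __neg__(self) -> "SignedSignature":
        return SignedSignature(values=-self.values, role=self.role)


@dataclass
class DoseMatrix:
    """m x n dose-response grid with monotherapy margins.

    ``doses_a``/``doses_b`` are strictly increasing and include 0 (the
    monotherapy margins); ``values[i, j]`` is the well at
    (doses_a[i], doses_b[j]).  ``kind`` distinguishes raw luminescence
    (as read from a plate) from % reduced proliferation (after
    control-anchored normalization).  Control wells are retained for
    normalization and audit.
    """

    drug_a: str
    drug_b: str
    doses_a: np.ndarray
    doses_b: np.ndarray
    values: np.ndarray
    dose_unit: str = "uM"
    kind: str = "raw"  # "raw" luminescence | "percent" reduced proliferation
    neg_controls: np.ndarray | None = None
    pos_controls: np.ndarray | None = None
    replicates: int = 1

    def __post_init__(self) -> None:
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.doses_a), len(self.doses_b)):
            raise ValueError("value grid shape does not match dose vectors")
        for doses, name in ((self.doses_a, "doses_a"), (self.doses_b, "doses_b")):
            if len(doses) and not np.all(np.diff(doses) > 0):
                raise ValueError(f"{name} must be strictly increasing")
        if self.kind not in ("raw", "percent"):
            raise ValueError(f"unknown dose-matrix kind: {self.kind!r}")

    @property
    def has_margins(self) -> bool:
        return len(self.doses_a) > 0 and self.doses_a[0] == 0 and self.doses_b[0] == 0


# ---------------------------------------------------------------------------
# GCT 1.3 / 1.2
# ---------------------------------------------------------------------------


def _coerce_numeric(col: pd.Series) -> pd.Series:
    """Convert a metadata column to float when every entry parses as one."""
    try:
        return pd.to_numeric(col)
    except (ValueError, TypeError):
        return col


def read_gct(path) -> PerturbationProfileSet:
    """Read a GCT 1.3 (or 1.2) text matrix into a PerturbationProfileSet.

    Column metadata rows become the per-sample table; per-column fields whose
    entries all parse as numbers (dose, time_h, ...) are coerced to float,
    everything else is kept as strings.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or not lines[0].startswith("#1."):
        got = lines[0] if lines else "<empty file>"
        raise GctFormatError(f"expected GCT version line '#1.3' or '#1.2', got: {got!r}")
    version = lines[0].strip()
    dims = lines[1].split("\t")
    if version == "#1.2":
        if len(dims) != 2:
            raise GctFormatError(f"GCT 1.2 dimension line must have 2 fields, got: {lines[1]!r}")
        nrow, ncol = int(dims[0]), int(dims[1])
        nrmeta, ncmeta = 1, 0  # the Description column
    elif version == "#1.3":
        if len(dims) != 4:
            raise GctFormatError(f"GCT 1.3 dimension line must have 4 fields, got: {lines[1]!r}")
        nrow, ncol, nrmeta, ncmeta = (int(d) for d in dims)
    else:
        raise GctFormatError(f"unsupported GCT version line: {version!r}")

    header = lines[2].split("\t")
    expected_width = 1 + nrmeta + ncol
    if len(header) != expected_width:
        raise GctFormatError(
            f"header has {len(header)} fields, dimensions imply {expected_width}: {lines[2]!r}"
        )
    rowmeta_names = header[1 : 1 + nrmeta]
    sample_ids = header[1 + nrmeta :]

    body = lines[3:]
    if len(body) < ncmeta + nrow:
        raise GctFormatError(
            f"file has {len(body)} body lines, dimensions imply {ncmeta + nrow}"
        )

    colmeta: dict[str, list[str]] = {}
    for k in range(ncmeta):
        fields = body[k].split("\t")
        if len(fields) != expected_width:
            raise GctFormatError(f"column-metadata line {k + 4} has wrong width: {body[k]!r}")
        colmeta[fields[0]] = fields[1 + nrmeta :]

    gene_ids: list[str] = []
    rowmeta_rows: list[list[str]] = []
    data = np.empty((nrow, ncol), dtype=float)
    for k in range(nrow):
        fields = body[ncmeta + k].split("\t")
        if len(fields) != expected_width:
            raise GctFormatError(f"data line {ncmeta + k + 4} has wrong width")
        gene_ids.append(fields[0])
        rowmeta_rows.append(fields[1 : 1 + nrmeta])
        try:
            data[k, :] = [float(v) for v in fields[1 + nrmeta :]]
        except ValueError as exc:
            raise GctFormatError(f"non-numeric value in data line {ncmeta + k + 4}: {exc}") from exc

    z = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)
    samples = pd.DataFrame(colmeta, index=pd.Index(sample_ids, name="sample_id"))
    samples = samples.apply(_coerce_numeric)
    row_meta = pd.DataFrame(
        rowmeta_rows, index=z.index, columns=rowmeta_names
    )
    return PerturbationProfileSet(z=z, samples=samples, row_meta=row_meta)


def _fmt(v) -> str:
    """Format a cell so numeric values round-trip exactly through text."""
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    return str(v)


def write_gct(profiles: PerturbationProfileSet, path) -> None:
    """Write a PerturbationProfileSet as GCT 1.3 text.

    Floats are written with shortest round-trip precision, so
    ``read_gct(write_gct(x))`` reproduces the values bit-identically.
    """
    z, samples, row_meta = profiles.z, profiles.samples, profiles.row_meta
    nrow, ncol = z.shape
    nrmeta = row_meta.shape[1]
    ncmeta = samples.shape[1]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#1.3\n")
        fh.write(f"{nrow}\t{ncol}\t{nrmeta}\t{ncmeta}\n")
        fh.write("\t".join(["id", *row_meta.columns, *map(str, z.columns)]) + "\n")
        for name in samples.columns:
            cells = ["na"] * nrmeta + [_fmt(v) for v in samples[name]]
            fh.write("\t".join([str(name), *cells]) + "\n")
        for gene in z.index:
            meta = [_fmt(v) for v in row_meta.loc[gene]] if nrmeta else []
            vals = [_fmt(v) for v in z.loc[gene]]
            fh.write("\t".join([str(gene), *meta, *vals]) + "\n")


# ---------------------------------------------------------------------------
# signature / score tables
# ---------------------------------------------------------------------------


def _signature_series(sig) -> pd.Series:
    if isinstance(sig, pd.Series):
        return sig
    if isinstance(sig, SignedSignature):
        return sig.values
    if hasattr(sig, "score"):  # ConsensusSignature
        return sig.score
    raise TypeError(f"cannot extract a score vector from {type(sig).__name__}")


def write_signature_table(sig, path, include_zeros: bool = False) -> None:
    """Write a signature (ternary or consensus-score) as TSV (gene_id, score).

    Only non-zero rows are written by default; row order follows the gene
    axis, so output is deterministic.
    """
    vals = _signature_series(sig)
    if not include_zeros:
        vals = vals[vals != 0]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tscore\n")
        for gene, v in vals.items():
            fh.write(f"{gene}\t{int(v)}\n")


def read_signature_table(path, genes: LandmarkGeneSet | None = None) -> pd.Series:
    """Read a (gene_id, score) TSV into an integer Series.

    When ``genes`` is given, the result is re-indexed to the full landmark
    axis with zeros for absent genes.
    """
    tbl = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if list(tbl.columns[:2]) != ["gene_id", "score"]:
        raise ValueError(f"signature table must have columns gene_id, score: {path}")
    vals = pd.Series(tbl["score"].to_numpy(dtype=int), index=pd.Index(tbl["gene_id"], name="gene_id"))
    if genes is not None:
        vals = vals.reindex(genes.as_pandas(), fill_value=0).astype(int)
    return vals


def write_score_table(scores: pd.DataFrame, path) -> None:
    """Write a compound score table (or any DataFrame) as TSV."""
    scores.to_csv(path, sep="\t", index=False)


def write_edge_list(edges: pd.DataFrame, path) -> None:
    """Write network edges as TSV (source, target, pearson_r)."""
    edges.to_csv(path, sep="\t", index=False, columns=["source", "target", "pearson_r"])


# ---------------------------------------------------------------------------
# dose plates
# ---------------------------------------------------------------------------


def read_dose_plate(path) -> DoseMatrix:
    """Read a raw-luminescence dose plate.

    Format (tab separated)::

        #drug_a <TAB> JQ1
        #drug_b <TAB> GSK-1070916
        #dose_unit <TAB> uM
        #control <TAB> DMSO <TAB> v1 ... v_k        (negative control wells)
        #control <TAB> POSITIVE <TAB> v1 ... v_k    (positive control wells)
        dose_a\\dose_b <TAB> 0 <TAB> 0.3125 ... 10
        0       <TAB> wells...
        ...

    Dose rows/columns may appear in any order; they are sorted ascending.
    Missing DMSO or positive-control wells are an error because the
    % reduced-proliferation normalization is then impossible.
    """
    meta: dict[str, str] = {}
    neg: list[float] = []
    pos: list[float] = []
    matrix_lines: list[list[str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if fields[0] == "#control":
                wells = [float(v) for v in fields[2:]]
                label = fields[1].upper()
                if label == "DMSO":
                    neg.extend(wells)
                else:
                    pos.extend(wells)
            elif fields[0].startswith("#"):
                meta[fields[0][1:]] = fields[1] if len(fields) > 1 else ""
            else:
                matrix_lines.append(fields)
    if not matrix_lines:
        raise PlateFormatError(f"no dose matrix found in {path}")
    if not neg:
        raise PlateFormatError("no DMSO (negative control) wells; normalization impossible")
    if not pos:
        raise PlateFormatError("no positive-control wells; normalization impossible")

    header = matrix_lines[0]
    doses_b = np.array([float(v) for v in header[1:]])
    doses_a = np.array([float(row[0]) for row in matrix_lines[1:]])
    grid = np.array([[float(v) for v in row[1:]] for row in matrix_lines[1:]])
    if grid.shape != (len(doses_a), len(doses_b)):
        raise PlateFormatError("ragged dose matrix")

    order_a = np.argsort(doses_a)
    order_b = np.argsort(doses_b)
    return DoseMatrix(
        drug_a=meta.get("drug_a", "drug_a"),
        drug_b=meta.get("drug_b", "drug_b"),
        doses_a=doses_a[order_a],
        doses_b=doses_b[order_b],
        values=grid[np.ix_(order_a, order_b)],
        dose_unit=meta.get("dose_unit", "uM"),
        kind="raw",
        neg_controls=np.asarray(neg, dtype=float),
        pos_controls=np.asarray(pos, dtype=float),
        replicates=int(meta.get("replicates", 1)),
    )


def write_dose_plate(dm: DoseMatrix, path) -> None:
    """Write a raw dose plate in the dialect `read_dose_plate` consumes."""
    if dm.neg_controls is None or dm.pos_controls is None:
        raise PlateFormatError("dose matrix lacks control wells; cannot write a plate file")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#drug_a\t{dm.drug_a}\n")
        fh.write(f"#drug_b\t{dm.drug_b}\n")
        fh.write(f"#dose_unit\t{dm.dose_unit}\n")
        fh.write(f"#replicates\t{dm.replicates}\n")
        fh.write("#control\tDMSO\t" + "\t".join(repr(float(v)) for v in dm.neg_controls) + "\n")
        fh.write("#control\tPOSITIVE\t" + "\t".join(repr(float(v)) for v in dm.pos_controls) + "\n")
        fh.write("dose_a\\dose_b\t" + "\t".join(repr(float(d)) for d in dm.doses_b) + "\n")
        for i, da in enumerate(dm.doses_a):
            row = "\t".join(repr(float(v)) for v in dm.values[i])
            fh.write(f"{float(da)!r}\t{row}\n")


def warn_empty(context: str) -> None:
    warnings.warn(f"{context}: result is empty", UserWarning, stacklevel=3)
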