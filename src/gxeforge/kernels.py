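"""Covariance kernels for the reaction-norm mixed models.

Four constructions cover all models in the pipeline: the VanRaden genomic
relationship matrix G over lines, the environmental similarity kernel
E proportional to XX' over records, the incidence expansion that lifts a
line-level kernel to record level (ZGZ'), and the Hadamard product that
builds the gene-environment interaction kernel ZGZ' o E.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, RecordFrame

logger = logging.getLogger(__name__)

__all__ = [
    "Kernel",
    "IncidenceMap",
    "grm_vanraden",
    "env_kernel",
    "incidence",
    "expand_to_records",
    "hadamard",
    "write_kernel",
    "read_kernel",
]


@dataclass
class Kernel:
    """A symmetric PSD similarity matrix keyed by line or record IDs."""

    ids: np.ndarray
    values: np.ndarray
    level: str  # "line" or "record"
    name: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"kernel {self.name}: shape {self.values.shape} != ({n}, {n})")
        if self.level not in ("line", "record"):
            raise ValueError(f"kernel level must be 'line' or 'record', got {self.level!r}")
        scale = max(np.abs(self.values).max(), 1.0)
        if np.abs(self.values - self.values.T).max() > 1e-10 * scale:
            raise ValueError(f"kernel {self.name} is not symmetric")
        # exact symmetry for downstream eigendecompositions
        self.values = (self.values + self.values.T) / 2.0

    @property
    def size(self) -> int:
        return len(self.ids)

    def check_psd(self, rtol: float = 1e-8) -> None:
        """Raise if the minimum eigenvalue is below -rtol * max eigenvalue."""
        w = np.linalg.eigvalsh(self.values)
        if w[0] < -rtol * max(w[-1], 1e-300):
            raise ValueError(
                f"kernel {self.name} not PSD: min eigenvalue {w[0]:.3e} vs max {w[-1]:.3e}"
            )


@dataclass
class IncidenceMap:
    """Assignment of each of q records to exactly one of n lines (the Z matrix)."""

    record_ids: np.ndarray
    line_ids: np.ndarray
    line_index: np.ndarray  # per record, position into line_ids

    def __post_init__(self) -> None:
        self.line_index = np.asarray(self.line_index, dtype=int)
        if len(self.line_index) != len(self.record_ids):
            raise ValueError("one line assignment per record required")
        counts = np.bincount(self.line_index, minlength=len(self.line_ids))
        if (counts == 0).any():
            empty = np.asarray(self.line_ids)[counts == 0]
            raise ValueError(f"lines with no records: {list(empty[:5])}")

    def matrix(self) -> np.ndarray:
        """Dense q x n 0/1 incidence matrix Z."""
        z = np.zeros((len(self.record_ids), len(self.line_ids)))
        z[np.arange(len(self.record_ids)), self.line_index] = 1.0
        return z


def grm_vanraden(g: GenotypeMatrix) -> Kernel:
    """VanRaden genomic relationship matrix G = WW' / (2 sum f(1-f)).

    W is the dosage matrix with missing calls mean-filled (2f per variant)
    and columns centered at 2f, with f the sample alternate-allele frequency.
    Monomorphic variants are excluded from both the numerator and the
    denominator (they carry no relationship information).
    """
    if g.n_lines < 2:
        raise ValueError("GRM needs at least 2 lines")
    f = g.allele_freqs
    poly = np.isfinite(f) & (f > 0.0) & (f < 1.0)
    if not poly.any():
        raise ValueError("degenerate kernel: all variants monomorphic")
    dos = g.dosages[:, poly]
    fp = f[poly]
    w = np.where(np.isnan(dos), 0.0, dos - 2.0 * fp)  # mean-fill == center to 0
    denom = 2.0 * np.sum(fp * (1.0 - fp))
    values = (w @ w.T) / denom
    return Kernel(
        g.line_ids, values, level="line", name="G",
        meta={"n_variants_used": int(poly.sum()), "denominator": float(denom)},
    )


def env_kernel(records: RecordFrame, standardize: bool = True) -> Kernel:
    """Environmental kernel E = XX' / c over records, X the q x c covariates.

    With ``standardize`` (default) each covariate column is centered and
    scaled to unit variance before the cross-product; this puts sex codes
    and temperatures on a common scale. The proportionality constant (1/c)
    and the standardization flag are recorded in the kernel metadata.
    """
    x = records.covariates
    if x.shape[1] < 1:
        raise ValueError("environmental kernel needs at least one covariate")
    if standardize:
        sd = x.std(axis=0, ddof=0)
        constant = sd == 0.0
        if constant.any():
            bad = [records.covariate_names[i] for i in np.flatnonzero(constant)]
            raise ValueError(f"constant covariate(s) cannot be standardized: {bad}")
        x = (x - x.mean(axis=0)) / sd
    c = x.shape[1]
    values = (x @ x.T) / c
    rec_ids = _record_ids(records)
    return Kernel(
        rec_ids, values, level="record", name="E",
        meta={"standardized": bool(standardize), "scale": 1.0 / c},
    )


def _record_ids(records: RecordFrame) -> np.ndarray:
    tab = records.table
    return np.array(
        [f"{l}:{e}" for l, e in zip(tab["line_id"], tab["env_id"])], dtype=object
    )


def incidence(records: RecordFrame) -> IncidenceMap:
    """Map each record to its line (the q x n incidence matrix Z)."""
    lines = records.line_ids
    pos = {lid: i for i, lid in enumerate(lines)}
    idx = records.table["line_id"].map(pos).to_numpy(dtype=int)
    return IncidenceMap(_record_ids(records), np.asarray(lines, dtype=object), idx)


def expand_to_records(k: Kernel, z: IncidenceMap) -> Kernel:
    """Lift a line-level kernel to record level: (ZKZ')_ij = K[line(i), line(j)]."""
    if k.level != "line":
        raise ValueError("expand_to_records expects a line-level kernel")
    pos = {lid: i for i, lid in enumerate(k.ids)}
    try:
        lookup = np.array([pos[lid] for lid in z.line_ids], dtype=int)
    except KeyError as err:
        raise KeyError(f"line {err.args[0]!r} missing from kernel {k.name}") from None
    rows = lookup[z.line_index]
    values = k.values[np.ix_(rows, rows)]
    return Kernel(z.record_ids, values, level="record", name=f"Z{k.name}Z", meta=dict(k.meta))


def hadamard(k1: Kernel, k2: Kernel) -> Kernel:
    """Elementwise product of two aligned kernels (PSD by the Schur product theorem)."""
    if k1.level != k2.level:
        raise ValueError(f"kernel level mismatch: {k1.level} vs {k2.level}")
    if len(k1.ids) != len(k2.ids) or (k1.ids != k2.ids).any():
        raise ValueError(
            f"kernel id mismatch between {k1.name} and {k2.name}; align before multiplying"
        )
    return Kernel(
        k1.ids, k1.values * k2.values, level=k1.level, name=f"{k1.name}x{k2.name}"
    )


def write_kernel(k: Kernel, path) -> None:
    """Write a kernel as a delimited square matrix with an ID header row/column."""
    pd.DataFrame(k.values, index=k.ids, columns=k.ids).to_csv(path)


def read_kernel(path, level: str, name: str = "K") -> Kernel:
    df = pd.read_csv(path, index_col=0)
    return Kernel(df.index.to_numpy(dtype=object), df.to_numpy(dtype=float), level, name)


def write_grm_gcta(k: Kernel, prefix) -> None:
    """Write a line-level GRM in GCTA layout: <prefix>.grm.gz + <prefix>.grm.id.

    The .grm.gz is gzipped text with one lower-triangle entry per row
    (i, j, n_variants, value); the .id file lists family/within-family IDs.
    """
    import gzip

    if k.level != "line":
        raise ValueError("GCTA GRM layout is for line-level kernels")
    prefix = str(prefix)
    n_var = int(k.meta.get("n_variants_used", 0))
    with gzip.open(prefix + ".grm.gz", "wt") as fh:
        for i in range(k.size):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{n_var}\t{k.values[i, j]:.6f}\n")
    with open(prefix + ".grm.id", "w") as fh:
        for lid in k.ids:
            fh.write(f"{lid}\t{lid}\n")
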