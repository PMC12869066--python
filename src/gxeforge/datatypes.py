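"""Core in-memory containers shared by every stage of the pipeline.

Two containers carry the data through the analysis: :class:`GenotypeMatrix`
holds line-by-variant allele dosages for a panel of inbred lines, and
:class:`RecordFrame` holds the long-format phenotype records — one row per
line-by-environment observation, with the numeric environmental covariates
attached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "RecordFrame"]


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(np.unique(ids)) != len(ids):
        uniq, counts = np.unique(ids, return_counts=True)
        dups = uniq[counts > 1][:5]
        raise ValueError(f"duplicate {what}: {list(dups)}")


@dataclass
class GenotypeMatrix:
    """Lines x variants dosage matrix for a panel of inbred lines.

    Dosages count copies of the alternate allele and live in {0, 1, 2};
    missing calls are ``nan``. For fully inbred lines dosages are
    effectively {0, 2}, but heterozygous calls (dosage 1) are kept as-is.

    ``allele_freqs`` is the per-variant alternate-allele frequency computed
    from non-missing calls; it is recomputed whenever variants or lines are
    subset, never carried over.
    """

    line_ids: np.ndarray
    variant_ids: np.ndarray
    dosages: np.ndarray  # (n, p) float, nan = missing
    allele_freqs: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.line_ids), len(self.variant_ids)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.variant_ids)} variants"
            )
        _check_unique(self.line_ids, "line_ids")
        _check_unique(self.variant_ids, "variant_ids")
        finite = self.dosages[~np.isnan(self.dosages)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))]
            raise ValueError(f"dosages outside {{0,1,2,missing}}: {bad[:5]}")
        self.allele_freqs = self._compute_freqs()

    def _compute_freqs(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def missing_rate(self) -> np.ndarray:
        """Per-variant fraction of missing calls."""
        return np.isnan(self.dosages).mean(axis=0)

    @property
    def maf(self) -> np.ndarray:
        """Minor-allele frequency: min(f, 1-f) of the alternate-allele freq."""
        f = self.allele_freqs
        return np.minimum(f, 1.0 - f)

    def subset_variants(self, mask_or_idx) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.line_ids,
            self.variant_ids[mask_or_idx],
            self.dosages[:, mask_or_idx],
        )

    def subset_lines(self, keep_ids) -> "GenotypeMatrix":
        keep = list(keep_ids)
        pos = {lid: i for i, lid in enumerate(self.line_ids)}
        missing = [lid for lid in keep if lid not in pos]
        if missing:
            raise KeyError(f"lines not in genotype matrix: {missing[:5]}")
        idx = [pos[lid] for lid in keep]
        return GenotypeMatrix(self.line_ids[idx], self.variant_ids, self.dosages[idx])


@dataclass
class RecordFrame:
    """Long-format phenotype records: one row per line-by-environment cell.

    ``table`` has columns ``line_id``, ``env_id``, ``phenotype`` plus one
    column per environmental covariate (named in ``covariate_names``).
    Rows are kept sorted line-major / environment-minor so incidence
    matrices and record-level kernels are reproducible across runs.
    Each (line, env) pair appears at most once, and all records sharing an
    ``env_id`` carry identical covariate values.
    """

    table: pd.DataFrame
    covariate_names: list[str]

    def __post_init__(self) -> None:
        required = {"line_id", "env_id", "phenotype", *self.covariate_names}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"RecordFrame table missing columns: {sorted(missing)}")
        dup = self.table.duplicated(subset=["line_id", "env_id"])
        if dup.any():
            offender = self.table.loc[dup, ["line_id", "env_id"]].iloc[0]
            raise ValueError(
                f"duplicate (line, env) record: ({offender.line_id}, {offender.env_id})"
            )
        for env, grp in self.table.groupby("env_id", sort=False):
            cov = grp[self.covariate_names].to_numpy(dtype=float)
            if cov.shape[0] > 1 and not (cov == cov[0]).all():
                raise ValueError(f"covariates differ within env_id {env!r}")
        self.table = (
            self.table.sort_values(["line_id", "env_id"], kind="stable")
            .reset_index(drop=True)
        )

    @property
    def q(self) -> int:
        return len(self.table)

    @property
    def line_ids(self) -> np.ndarray:
        """Unique line IDs in sorted (record) order."""
        return self.table["line_id"].unique()

    @property
    def env_ids(self) -> np.ndarray:
        """Unique environment IDs in sorted order."""
        return np.array(sorted(self.table["env_id"].unique()), dtype=object)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_envs(self) -> int:
        return len(self.env_ids)

    @property
    def phenotype(self) -> np.ndarray:
        return self.table["phenotype"].to_numpy(dtype=float)

    @property
    def covariates(self) -> np.ndarray:
        """The q x c matrix of environmental measurements."""
        return self.table[self.covariate_names].to_numpy(dtype=float)

    def subset(self, idx) -> "RecordFrame":
        return RecordFrame(self.table.iloc[np.asarray(idx)].copy(), list(self.covariate_names))

    def env_covariate_table(self) -> pd.DataFrame:
        """One row per environment with its covariate values."""
        return (
            self.table.groupby("env_id", sort=True)[self.covariate_names]
            .first()
            .reset_index()
        )
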