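"""Dosage-matrix container shared by the simulation, QC and scoring stages.

A :class:`GenotypeMatrix` holds effect-allele dosages (0, 1, 2 or missing,
encoded as NaN) for *samples × SNPs*, together with per-SNP allele labels and
an optional imputation accuracy score in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyInputError, InvalidInputError

__all__ = ["GenotypeMatrix"]

_VALID_DOSAGES = (0.0, 1.0, 2.0)


@dataclass
class GenotypeMatrix:
    """Samples × SNPs effect-allele dosage matrix.

    Parameters
    ----------
    sample_ids, snp_ids
        Unique string identifiers for the rows and columns.
    dosages
        ``(n_samples, n_snps)`` float array with values in {0, 1, 2} or NaN
        for a missing genotype call.
    effect_allele, other_allele
        Per-SNP allele labels; ``dosages`` counts copies of ``effect_allele``.
    imputation_score
        Per-SNP imputation accuracy in [0, 1]; NaN when the SNP was directly
        genotyped or no score is available.
    """

    sample_ids: np.ndarray
    snp_ids: np.ndarray
    dosages: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray
    imputation_score: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.effect_allele = np.asarray(self.effect_allele, dtype=object)
        self.other_allele = np.asarray(self.other_allele, dtype=object)
        if self.imputation_score is None:
            self.imputation_score = np.full(len(self.snp_ids), np.nan)
        self.imputation_score = np.asarray(self.imputation_score, dtype=float)
        self._validate()

    def _validate(self) -> None:
        n, m = self.dosages.shape if self.dosages.ndim == 2 else (-1, -1)
        if self.dosages.ndim != 2:
            raise InvalidInputError("dosages must be a 2-D samples × SNPs array")
        if len(self.sample_ids) != n or len(self.snp_ids) != m:
            raise InvalidInputError(
                f"id lengths ({len(self.sample_ids)}, {len(self.snp_ids)}) do not "
                f"match dosage shape {self.dosages.shape}"
            )
        if len(set(self.sample_ids)) != n:
            raise InvalidInputError("sample ids are not unique")
        if len(set(self.snp_ids)) != m:
            raise InvalidInputError("snp ids are not unique")
        if len(self.effect_allele) != m or len(self.other_allele) != m:
            raise InvalidInputError("allele arrays must have one entry per SNP")
        if len(self.imputation_score) != m:
            raise InvalidInputError("imputation_score must have one entry per SNP")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, _VALID_DOSAGES).all():
            bad = np.unique(vals[~np.isin(vals, _VALID_DOSAGES)])
            raise InvalidInputError(f"dosages must be 0, 1, 2 or NaN; found {bad}")

    # -- basic geometry -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=self.sample_ids.copy(),
            snp_ids=self.snp_ids.copy(),
            dosages=self.dosages.copy(),
            effect_allele=self.effect_allele.copy(),
            other_allele=self.other_allele.copy(),
            imputation_score=self.imputation_score.copy(),
        )

    def subset_samples(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Return a new matrix restricted to samples selected by mask/indices."""
        keep = np.asarray(keep)
        return GenotypeMatrix(
            sample_ids=self.sample_ids[keep],
            snp_ids=self.snp_ids.copy(),
            dosages=self.dosages[keep],
            effect_allele=self.effect_allele.copy(),
            other_allele=self.other_allele.copy(),
            imputation_score=self.imputation_score.copy(),
        )

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Return a new matrix restricted to SNPs selected by mask/indices."""
        keep = np.asarray(keep)
        return GenotypeMatrix(
            sample_ids=self.sample_ids.copy(),
            snp_ids=self.snp_ids[keep],
            dosages=self.dosages[:, keep],
            effect_allele=self.effect_allele[keep],
            other_allele=self.other_allele[keep],
            imputation_score=self.imputation_score[keep],
        )

    # -- summaries used by QC and scoring -------------------------------

    def snp_call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per SNP."""
        if self.n_samples == 0:
            raise EmptyInputError("matrix has no samples")
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per sample."""
        if self.n_snps == 0:
            raise EmptyInputError("matrix has no SNPs")
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    def genotype_counts(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Per-SNP genotype counts ``(n_hom_effect, n_het, n_hom_other)``.

        Parameters
        ----------
        mask
            Optional boolean sample mask (e.g. the control stratum).

        Returns
        -------
        ndarray of shape ``(n_snps, 3)``.
        """
        d = self.dosages if mask is None else self.dosages[np.asarray(mask)]
        return np.stack(
            [np.nansum(d == 2, axis=0), np.nansum(d == 1, axis=0), np.nansum(d == 0, axis=0)],
            axis=1,
        ).astype(int)

    def effect_allele_freq(self) -> np.ndarray:
        """Effect-allele frequency per SNP from non-missing calls (NaN if none)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def snp_index(self, snp_id: str) -> int:
        hits = np.flatnonzero(self.snp_ids == snp_id)
        if hits.size == 0:
            raise KeyError(snp_id)
        return int(hits[0])
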