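"""SNP dosage containers and text-format readers.

Dosages are stored as a dense float array with ``nan`` marking missing
calls; every non-missing entry is an allele count in {0, 1, 2}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "read_dosage_matrix", "read_ped_map"]


@dataclass
class GenotypeMatrix:
    """n x m matrix of alternate-allele counts with sample/SNP labels.

    Parameters
    ----------
    sample_ids : list of str
        Row labels, unique.
    snp_ids : list of str
        Column labels, unique.
    dosages : ndarray of float, shape (n, m)
        Entries in {0, 1, 2} or ``nan`` for missing.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray
    allele_freq: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if len(self.sample_ids) != n or len(self.snp_ids) != m:
            raise ValueError(
                f"label/shape mismatch: {len(self.sample_ids)} samples, "
                f"{len(self.snp_ids)} SNPs vs dosage shape {self.dosages.shape}"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.snp_ids)) != m:
            raise ValueError("duplicate SNP ids")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise ValueError(
                f"dosage at sample {self.sample_ids[bad[0]]}, SNP "
                f"{self.snp_ids[bad[1]]} not in {{0,1,2,missing}}"
            )
        with np.errstate(invalid="ignore"):
            self.allele_freq = np.nanmean(self.dosages, axis=0) / 2.0

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]


def read_dosage_matrix(path) -> GenotypeMatrix:
    """Read a plain dosage table: header row of SNP ids, first column sample ids."""
    df = pd.read_csv(path, sep=r"\s+", index_col=0, na_values=["NA"])
    return GenotypeMatrix(
        sample_ids=[str(i) for i in df.index],
        snp_ids=[str(c) for c in df.columns],
        dosages=df.to_numpy(dtype=float),
    )


def read_ped_map(ped_path, map_path) -> GenotypeMatrix:
    """Read PLINK-style text .ped/.map files.

    The .ped file carries FID IID PAT MAT SEX PHENO then two allele columns
    per SNP ("0" = missing). Dosage counts the minor (less frequent) allele
    at each SNP, with ties broken by allele string order.
    """
    snp_ids = [line.split()[1] for line in open(map_path) if line.strip()]
    sample_ids: list[str] = []
    rows: list[list[str]] = []
    for line in open(ped_path):
        tok = line.split()
        if not tok:
            continue
        expected = 6 + 2 * len(snp_ids)
        if len(tok) != expected:
            raise ValueError(
                f".ped row for {tok[1] if len(tok) > 1 else '?'} has "
                f"{len(tok)} fields, expected {expected}"
            )
        sample_ids.append(tok[1])
        rows.append(tok[6:])
    alleles = np.array(rows, dtype=object).reshape(len(rows), len(snp_ids), 2)
    dosages = np.full((len(rows), len(snp_ids)), np.nan)
    for j in range(len(snp_ids)):
        col = alleles[:, j, :]
        obs = col[col != "0"]
        if obs.size == 0:
            continue
        uniq, counts = np.unique(obs, return_counts=True)
        # count the rarer allele so dosage aligns with minor-allele frequency
        order = np.lexsort((uniq, counts))
        minor = uniq[order[0]]
        missing = (col == "0").any(axis=1)
        dosages[:, j] = (col == minor).sum(axis=1).astype(float)
        dosages[missing, j] = np.nan
    return GenotypeMatrix(sample_ids=sample_ids, snp_ids=snp_ids, dosages=dosages)
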