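"""Reading, validating and writing GWAS summary statistics and LD matrices.

The package works entirely at the summary level: one
:class:`VariantAssociation` per SNP per trait, bundled into a
:class:`SummaryDataset`, plus a pairwise r-squared :class:`LDMatrix` used
for clumping. The on-disk dialect is plain tab-delimited text with the
canonical header ``SNP CHR POS EA OA BETA SE P EAF N``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError

VALID_ALLELES = frozenset("ACGT")

#: canonical column order of the on-disk format
CANONICAL_COLUMNS = ("SNP", "CHR", "POS", "EA", "OA", "BETA", "SE", "P", "EAF", "N")

#: identity column map for files written by :func:`write_summary_table`
IDENTITY_COLUMN_MAP = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "effect_allele": "EA",
    "other_allele": "OA",
    "beta": "BETA",
    "se": "SE",
    "pvalue": "P",
    "eaf": "EAF",
    "n": "N",
}

MANDATORY_FIELDS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pvalue",
    "n",
)


@dataclass(frozen=True)
class VariantAssociation:
    """Summary statistics of one SNP for one trait.

    ``beta`` is on the log-odds scale for binary (disease) traits and in
    standardized abundance units for microbial taxa. ``eaf`` may be ``None``
    when the source file omits allele frequencies.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    n: int
    eaf: float | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise ValidationError(
                f"{self.snp_id}: effect allele {self.effect_allele!r} not in A/C/G/T"
            )
        if self.other_allele not in VALID_ALLELES:
            raise ValidationError(
                f"{self.snp_id}: other allele {self.other_allele!r} not in A/C/G/T"
            )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.snp_id}: effect and other allele identical")
        if not (self.se > 0) or not math.isfinite(self.se):
            raise ValidationError(f"{self.snp_id}: se must be positive, got {self.se}")
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValidationError(f"{self.snp_id}: p-value {self.pvalue} outside [0, 1]")
        if self.pos < 1:
            raise ValidationError(f"{self.snp_id}: position must be 1-based positive")
        if self.n < 1:
            raise ValidationError(f"{self.snp_id}: sample size must be positive")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            raise ValidationError(f"{self.snp_id}: eaf {self.eaf} outside (0, 1)")

    @property
    def is_palindromic(self) -> bool:
        """A/T or C/G allele pairs are strand-ambiguous in summary data."""
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass
class SummaryDataset:
    """A full summary-statistics table for one trait.

    ``trait_kind`` is ``"exposure-taxon"`` for microbial abundance traits
    (which carry a taxonomic rank that later sets the FDR family size) or
    ``"outcome-disease"`` for binary disease traits.
    """

    trait_label: str
    trait_kind: str
    records: dict[str, VariantAssociation] = field(default_factory=dict)
    taxon_rank: str | None = None

    RANKS = ("genus", "family", "order", "class", "phylum")

    def __post_init__(self) -> None:
        if self.trait_kind not in ("exposure-taxon", "outcome-disease"):
            raise ValidationError(f"unknown trait_kind {self.trait_kind!r}")
        if self.trait_kind == "exposure-taxon":
            if self.taxon_rank not in self.RANKS:
                raise ValidationError(
                    f"{self.trait_label}: exposure-taxon requires a taxon_rank "
                    f"from {self.RANKS}, got {self.taxon_rank!r}"
                )
        elif self.taxon_rank is not None:
            raise ValidationError(
                f"{self.trait_label}: taxon_rank only applies to exposure-taxon traits"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self.records

    def add(self, rec: VariantAssociation) -> None:
        if rec.snp_id in self.records:
            raise ValidationError(f"duplicate snp_id {rec.snp_id!r} in {self.trait_label}")
        self.records[rec.snp_id] = rec

    @classmethod
    def from_records(
        cls,
        records: Iterable[VariantAssociation],
        trait_label: str,
        trait_kind: str,
        taxon_rank: str | None = None,
    ) -> "SummaryDataset":
        ds = cls(trait_label=trait_label, trait_kind=trait_kind, taxon_rank=taxon_rank)
        for rec in records:
            ds.add(rec)
        return ds

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "SNP": r.snp_id,
                "CHR": r.chrom,
                "POS": r.pos,
                "EA": r.effect_allele,
                "OA": r.other_allele,
                "BETA": r.beta,
                "SE": r.se,
                "P": r.pvalue,
                "EAF": r.eaf,
                "N": r.n,
            }
            for r in self.records.values()
        ]
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


@dataclass
class LDMatrix:
    """Symmetric pairwise r-squared matrix with per-SNP genomic positions."""

    snp_ids: list[str]
    r2: np.ndarray
    positions: pd.DataFrame  # index snp_id, columns CHR / POS

    def __post_init__(self) -> None:
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def lookup(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index


def _parse_row(row: Mapping, line_no: int) -> VariantAssociation:
    eaf = row.get("eaf")
    if eaf is not None and (isinstance(eaf, float) and math.isnan(eaf)):
        eaf = None
    return VariantAssociation(
        snp_id=str(row["snp_id"]),
        chrom=str(row["chrom"]),
        pos=int(row["pos"]),
        effect_allele=str(row["effect_allele"]).upper(),
        other_allele=str(row["other_allele"]).upper(),
        beta=float(row["beta"]),
        se=float(row["se"]),
        pvalue=float(row["pvalue"]),
        n=int(row["n"]),
        eaf=None if eaf is None else float(eaf),
    )


def read_summary_table(
    path,
    column_map: Mapping[str, str] | None = None,
    *,
    trait_label: str,
    trait_kind: str,
    taxon_rank: str | None = None,
    sep: str = "\t",
    on_invalid: str = "raise",
) -> SummaryDataset:
    """Read a delimited summary-statistics table into a validated dataset.

    Parameters
    ----------
    column_map
        Mapping from field name (``snp_id``, ``chrom``, ``pos``,
        ``effect_allele``, ``other_allele``, ``beta``, ``se``, ``pvalue``,
        ``eaf``, ``n``) to the column name in the file. Defaults to the
        canonical header written by :func:`write_summary_table`. ``eaf``
        is optional; all other fields are mandatory.
    on_invalid
        ``"raise"`` (default) raises a :class:`ValidationError` listing the
        1-based data line numbers of every offending row; ``"skip"`` drops
        them and records ``(line, message)`` pairs on ``dataset.rejected``.
    """
    column_map = dict(column_map or IDENTITY_COLUMN_MAP)
    missing = [f for f in MANDATORY_FIELDS if f not in column_map]
    if missing:
        raise ConfigurationError(f"column_map lacks mandatory fields: {missing}")

    df = pd.read_csv(path, sep=sep, dtype={column_map["chrom"]: str})
    absent = [c for c in column_map.values() if c not in df.columns]
    if absent:
        raise ConfigurationError(f"{path}: columns not found in header: {absent}")

    ds = SummaryDataset(trait_label=trait_label, trait_kind=trait_kind, taxon_rank=taxon_rank)
    rejected: list[tuple[int, str]] = []
    inverse = {field_name: col for field_name, col in column_map.items()}
    for i, (_, raw) in enumerate(df.iterrows(), start=1):
        row = {f: raw[c] for f, c in inverse.items() if c in df.columns}
        try:
            ds.add(_parse_row(row, i))
        except ValidationError as exc:
            if "duplicate snp_id" in str(exc):
                raise
            rejected.append((i, str(exc)))
    if rejected and on_invalid == "raise":
        lines = ", ".join(str(ln) for ln, _ in rejected)
        raise ValidationError(
            f"{path}: {len(rejected)} invalid row(s) at data line(s) {lines}; "
            f"first: {rejected[0][1]}"
        )
    ds.rejected = rejected  # type: ignore[attr-defined]
    return ds


def write_summary_table(dataset: SummaryDataset, path) -> str:
    """Write a dataset as canonical tab-delimited text; returns the path.

    The output round-trips exactly through :func:`read_summary_table` with
    the identity column map: floats are rendered with ``repr`` precision.
    """
    df = dataset.to_frame()
    with open(path, "w") as fh:
        fh.write("\t".join(CANONICAL_COLUMNS) + "\n")
        for _, r in df.iterrows():
            eaf = "" if r["EAF"] is None or (isinstance(r["EAF"], float) and math.isnan(r["EAF"])) else repr(float(r["EAF"]))
            fh.write(
                "\t".join(
                    [
                        str(r["SNP"]),
                        str(r["CHR"]),
                        str(int(r["POS"])),
                        str(r["EA"]),
                        str(r["OA"]),
                        repr(float(r["BETA"])),
                        repr(float(r["SE"])),
                        repr(float(r["P"])),
                        eaf,
                        str(int(r["N"])),
                    ]
                )
                + "\n"
            )
    return str(path)


def validate_ld(matrix: LDMatrix, *, atol: float = 1e-8) -> LDMatrix:
    """Check symmetry, unit diagonal and [0, 1] range; return the matrix."""
    r2 = np.asarray(matrix.r2, dtype=float)
    n = len(matrix.snp_ids)
    if r2.shape != (n, n):
        raise ValidationError(f"LD matrix shape {r2.shape} does not match {n} SNP ids")
    if not np.allclose(r2, r2.T, atol=atol):
        i, j = np.unravel_index(np.argmax(np.abs(r2 - r2.T)), r2.shape)
        raise ValidationError(
            f"LD matrix asymmetric beyond {atol}: "
            f"[{matrix.snp_ids[i]},{matrix.snp_ids[j]}]={r2[i, j]} vs {r2[j, i]}"
        )
    if not np.allclose(np.diag(r2), 1.0, atol=atol):
        raise ValidationError("LD matrix diagonal must be 1")
    if (r2 < -atol).any() or (r2 > 1 + atol).any():
        bad = r2[(r2 < -atol) | (r2 > 1 + atol)][0]
        raise ValidationError(f"LD r2 entry {bad} outside [0, 1]")
    return matrix


def read_ld_matrix(path) -> LDMatrix:
    """Read a square tab-delimited r2 table (SNP ids as header and first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    snp_ids = [str(s) for s in df.index]
    if snp_ids != [str(c) for c in df.columns]:
        raise ValidationError(f"{path}: row and column SNP ids differ")
    positions = pd.DataFrame(index=snp_ids, columns=["CHR", "POS"])
    return validate_ld(LDMatrix(snp_ids=snp_ids, r2=df.to_numpy(float), positions=positions))


def write_ld_matrix(matrix: LDMatrix, path) -> str:
    df = pd.DataFrame(matrix.r2, index=matrix.snp_ids, columns=matrix.snp_ids)
    df.to_csv(path, sep="\t")
    return str(path)


def ld_from_dataset(
    snp_ids: Sequence[str], r2: np.ndarray, dataset: SummaryDataset
) -> LDMatrix:
    """Attach chrom/pos from a dataset's records to an r2 array."""
    positions = pd.DataFrame(
        {
            "CHR": [dataset.records[s].chrom for s in snp_ids],
            "POS": [dataset.records[s].pos for s in snp_ids],
        },
        index=list(snp_ids),
    )
    return validate_ld(LDMatrix(snp_ids=list(snp_ids), r2=np.asarray(r2, float), positions=positions))
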